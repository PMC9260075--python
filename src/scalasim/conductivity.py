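"""Tissue conductivities for the cochlear volume conductor.

Values are the isotropic conductivities commonly used in finite-element
models of the implanted cochlea.  The stria vascularis is so thin that it is
not meshed as a solid; it enters the model as a thin-layer ("contact
impedance") interface with areal resistance ``stria_thickness_m / sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping

#: Default isotropic conductivities in S/m.
DEFAULT_SIGMA_S_PER_M: Dict[str, float] = {
    "scala_tympani": 1.43,      # perilymph (scalas)
    "cochlea_wall": 0.3,
    "basilar_membrane": 0.0125,
    "spiral_ligament": 1.67,
    "stria_vascularis": 0.0053,  # used only through the thin-layer interface
    "spiral_ganglion": 0.33,
    "artery": 0.32,
    "bone": 0.0156,
    "carrier": 1e-7,             # silicone
}

#: Default thickness of the stria vascularis thin layer (m).  Not a meshed
#: solid; only the areal resistance t/sigma enters the equations.
DEFAULT_STRIA_THICKNESS_M = 30e-6


@dataclass(frozen=True)
class ConductivityTable:
    """Per-tissue isotropic conductivities plus the stria thin-layer thickness.

    Parameters
    ----------
    sigma_S_per_m
        Map from region label to conductivity in S/m.  All values must be
        positive.
    stria_thickness_m
        Thickness ``t`` of the stria vascularis thin layer.  Across the
        STRIA_INTERFACE surface the potential jumps by ``(t / sigma) * j_n``
        for normal current density ``j_n``.
    """

    sigma_S_per_m: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_S_PER_M)
    )
    stria_thickness_m: float = DEFAULT_STRIA_THICKNESS_M

    def __post_init__(self) -> None:
        for name, sigma in self.sigma_S_per_m.items():
            if not sigma > 0:
                raise ValueError(f"conductivity of {name!r} must be > 0, got {sigma}")
        if not self.stria_thickness_m > 0:
            raise ValueError("stria_thickness_m must be > 0")

    def __getitem__(self, region: str) -> float:
        try:
            return self.sigma_S_per_m[region]
        except KeyError:
            raise KeyError(f"no conductivity for region {region!r}") from None

    def require(self, regions: Iterable[str]) -> None:
        """Raise KeyError if any of *regions* has no conductivity entry."""
        missing = sorted(set(regions) - set(self.sigma_S_per_m))
        if missing:
            raise KeyError(f"no conductivity for regions {missing}")

    def scaled(self, factor: float, layers: Iterable[str] | None = None) -> "ConductivityTable":
        """Return a copy with conductivities multiplied by *factor*.

        If *layers* is None every entry is scaled (including the stria layer,
        whose conductance scales with sigma at fixed thickness); otherwise only
        the named layers are scaled.
        """
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        if layers is None:
            layers = set(self.sigma_S_per_m)
        else:
            layers = set(layers)
            unknown = layers - set(self.sigma_S_per_m)
            if unknown:
                raise KeyError(f"unknown layers {sorted(unknown)}")
        new = {
            k: (v * factor if k in layers else v) for k, v in self.sigma_S_per_m.items()
        }
        return replace(self, sigma_S_per_m=new)

    @property
    def stria_areal_conductance(self) -> float:
        """Thin-layer conductance per unit area, sigma_stria / t (S/m^2)."""
        return self["stria_vascularis"] / self.stria_thickness_m
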