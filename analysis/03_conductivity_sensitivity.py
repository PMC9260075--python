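#!/usr/bin/env python
"""Sensitivity of the normalized impedance profile to tissue conductivity.

Perturbs the scala-tympani (perilymph) conductivity in +/-5% steps up to
+/-10% and reports the maximum relative change of the mid-scala-normalized
impedance-vs-position profile for the basal contact E16.
"""

from pathlib import Path

from scalasim.io import export_results, plot_sensitivity
from scalasim.protocols import run_conductivity_sensitivity

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    result = run_conductivity_sensitivity()
    export_results(result, OUT)
    plot_sensitivity(result, OUT / "conductivity_sensitivity.png")
    print(
        f"layer={result.layer} contact={result.contact_id} "
        f"positions={len(result.positions_m)}"
    )
    print(f"max normalized deviation: {result.normalized_deviation_pct:.3f}%")
    print(f"max raw impedance shift:  {100 * result.absolute_shift:.2f}%")


if __name__ == "__main__":
    main()
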