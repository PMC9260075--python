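# scalasim

Volume-conductor simulation of cochlear-implant electrode impedance in a
parametric scala-tympani model.

`scalasim` builds a 3D geometric cochlea (a tapering conical-helix duct with
wall, basilar-membrane, spiral-ligament and stria layers inside a grounded
bone block), inserts a 16-contact electrode array, meshes it with a
deterministic structured tet generator, and solves the quasi-static
volume-conduction equation ∇·(σ∇V) = 0 with a P1 finite-element method to
obtain each contact's electrode-to-ground impedance Z = V/I. Protocol
drivers produce impedance maps versus contact-to-wall proximity and insertion
depth, a conductivity-sensitivity analysis, and convergence studies against
closed-form oracles. See `docs/methods.md` for the modeling choices and
known limits.

## Worked example

Impedance of every contact of the fully inserted, mid-scala array, and how
it changes as the carrier approaches the cochlea wall:

```python
from scalasim import (
    run_insertion_depth_profile, run_proximity_sweep,
    depth_rank_correlation, export_results, plot_proximity_profiles,
)

# per-contact impedance, full insertion, mid-scala (one mesh, 16 solves)
profile = run_insertion_depth_profile()
for r in sorted(profile.records, key=lambda r: r.contact_id):
    print(f"{r.contact_id}: {r.Z_el_ohm:.0f} ohm")
print("apical-rank / Z rank correlation:", depth_rank_correlation(profile))

# impedance vs in-plane offset along the x axis (toward the modiolar wall),
# recording the apical and basal end contacts
sweep = run_proximity_sweep(axis="x", recorded_contacts=("E1", "E16"))
export_results(sweep, "results")                    # CSV + JSON sidecar
plot_proximity_profiles(sweep, "results/proximity_x.png")
```

On the default coarse mesh (~1.1×10⁵ tets) the depth profile runs in ~10 s
and the 12-placement sweep in ~2 min on one CPU. Impedance rises
monotonically from the basal contact E16 (~0.4 kΩ) to the apical contact E1
(~1.2 kΩ) and grows as the carrier approaches the wall.

## Command line

Every workflow is also a CLI subcommand; all numerical parameters come from
a YAML/JSON config (an empty or absent config means package defaults —
default tissue conductivities and 34 µA injected current):

```sh
scalasim mesh            --config run.yaml --format vtu   # export the mesh
scalasim solve           --contact E16                     # one placement
scalasim sweep-insertion                                   # 136-record protocol
scalasim sweep-proximity --axis x
scalasim sensitivity                                       # ±10% sigma sweep
scalasim validate                                          # oracle studies
scalasim report          --out results
```

Example config:

```yaml
mesh:
  target_size_near_m: 2.5e-4
  target_size_far_m: 6.0e-4
solver:
  method: cg
  inactive_mode: grounded
conductivity:
  sigma_S_per_m:
    scala_tympani: 1.43
protocol:
  name: conductivity_sensitivity
  contact: E16
```

## Repository layout

- `src/scalasim/` — library: `geometry`, `meshing`, `fem`, `protocols`,
  `validation`, `config`/`io`/`cli`.
- `analysis/` — numbered scripts reproducing the standard experiments into
  `results/`.
- `scripts/acceptance.py` — recomputes the headline sensitivity number from
  scratch and writes it as JSON.
- `tests/` — unit, property-based and acceptance tests (`pytest`).
- `docs/methods.md` — modeling choices, validation, known limits.

## Testing

```sh
python -m pytest
```

One acceptance assertion is an expected failure: the near-wall impedance
rise converges to ≈1.4–1.5×, below the asserted 2×; the analysis is in
`docs/methods.md`. All other tests pass.
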