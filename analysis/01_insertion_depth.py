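#!/usr/bin/env python
"""Sequential-insertion and full-insertion impedance profiles.

Runs the insertion protocols on the default geometric model at coarse
resolution, for both inactive-contact treatments (floating and grounded),
and writes CSVs and plots under results/.
"""

from pathlib import Path

from scalasim.io import export_results, plot_depth_profile
from scalasim.protocols import (
    depth_rank_correlation,
    run_insertion_depth_profile,
    run_sequential_insertion,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for mode in ("float", "grounded"):
        profile = run_insertion_depth_profile(inactive_mode=mode)
        export_results(profile, OUT, basename=f"insertion_depth_profile_{mode}")
        plot_depth_profile(profile, OUT / f"insertion_depth_profile_{mode}.png")
        print(
            f"[{mode}] depth rank correlation:",
            f"{depth_rank_correlation(profile):.3f}",
        )

        sequential = run_sequential_insertion(inactive_mode=mode)
        export_results(sequential, OUT, basename=f"sequential_insertion_{mode}")
        print(f"[{mode}] sequential records:", len(sequential))


if __name__ == "__main__":
    main()
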