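#!/usr/bin/env python
"""Impedance versus in-plane carrier offset along both axes.

The x axis points from mid-scala toward the cochlea (modiolar) wall, the
direction the contacts face; the y axis spans the basilar-membrane /
floor direction.  Invalid placements (carrier touching a wall) are skipped
and logged, never solved.
"""

import logging
from pathlib import Path

from scalasim.io import export_results, plot_proximity_profiles
from scalasim.protocols import run_proximity_sweep

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    logging.basicConfig(level=logging.INFO)
    OUT.mkdir(exist_ok=True)
    for axis in ("x", "y"):
        imap = run_proximity_sweep(axis=axis)
        export_results(imap, OUT, basename=f"proximity_sweep_{axis}")
        plot_proximity_profiles(imap, OUT / f"proximity_sweep_{axis}.png")
        print(
            f"[{axis}] records: {len(imap)}, skipped placements: {len(imap.skipped)}"
        )


if __name__ == "__main__":
    main()
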