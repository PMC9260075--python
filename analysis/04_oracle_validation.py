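#!/usr/bin/env python
"""Analytic-oracle convergence studies (bar, concentric spheres, disk).

Each study solves the same impedance problem on a decreasing mesh-size
sequence and compares against the closed-form resistance; reports include
Richardson extrapolation and the observed convergence order.
"""

from pathlib import Path

from scalasim.io import export_results
from scalasim.validation import ORACLE_TOLERANCES, run_oracle_suite

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for name, report in run_oracle_suite().items():
        export_results(report, OUT, basename=f"convergence_{name}")
        err = report.rel_errors[-1]
        tol = ORACLE_TOLERANCES[name]
        print(report.to_text())
        print(
            f"{name}: finest error {100 * err:.3f}% "
            f"(tolerance {100 * tol:.0f}%) -> {'PASS' if err <= tol else 'FAIL'}\n"
        )


if __name__ == "__main__":
    main()
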