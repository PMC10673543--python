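#!/usr/bin/env python
"""Build the iopamidol ratiometric pH calibration and probe its robustness.

Generates the contrast-ratio-vs-pH curve from the Bloch-McConnell forward
model at the study's acquisition settings (7 T, 3 uT / 5 s CW saturation),
both at the exact label offsets and through the pipeline's smoothing-spline
measurement operator, and measures how the curve moves when the agent
concentration is halved or doubled.

Writes: results/calibration.tsv + .json (pipeline curve),
        results/calibration_concentration.tsv (robustness table).

Finding (printed at run time): the ratio rises strictly monotonically from
~0.43 at pH 6.0 to ~3.1 at pH 7.4, so it is invertible over the whole
physiological grid; halving/doubling the 30 mM agent concentration moves
the ratio by a few-to-ten percent, i.e. concentration cancels only to
first order at detectable contrast levels.
"""

from pathlib import Path

import numpy as np

from acidocest.bmsim import default_background_pools
from acidocest.calibration import IopamidolModel, build_pipeline_calibration
from acidocest.phantom import default_protocol
from acidocest.validation import concentration_independence

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    model = IopamidolModel()
    protocol = default_protocol()
    bg = default_background_pools()
    grid = np.round(np.arange(6.0, 7.4001, 0.05), 6)

    curve = build_pipeline_calibration(model, protocol, grid, background=bg)
    curve.to_files(RESULTS / "calibration.tsv", RESULTS / "calibration.json")
    print(f"calibration: pH {curve.valid_range[0]:.2f}-{curve.valid_range[1]:.2f}, "
          f"ratio {curve.ratio_grid[0]:.3f} -> {curve.ratio_grid[-1]:.3f} "
          f"({'monotone increasing' if curve.increasing else 'monotone decreasing'})")

    conc = concentration_independence(factors=(0.5, 2.0))
    with open(RESULTS / "calibration_concentration.tsv", "w") as fh:
        fh.write("concentration_factor\tmax_relative_ratio_shift\n")
        for f, shift in conc["per_factor"].items():
            fh.write(f"{f}\t{shift:.6f}\n")
            print(f"concentration x{f}: max ratio shift {100 * shift:.1f}% "
                  f"over pH 6.0-7.4")
    print(f"wrote {RESULTS / 'calibration.tsv'}")


if __name__ == "__main__":
    main()
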