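"""Render the two display panels of the analysis.

Panel (a): the adjusted hazard ratios H_t with pointwise 95% bands across
cutoffs; panel (b): the successive differences H_t - H_{t-1} with the fitted
drift as a horizontal line. Reads results/hr_series.csv, writes PNG + SVG
into results/figures/.
"""

import argparse
from pathlib import Path

from nodewalk import HazardRatioSeries, fit_random_walk
from nodewalk.pipeline import render_figures


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    series = HazardRatioSeries.from_csv(
        args.outdir / "hr_series.csv", args.outdir / "skipped.csv"
    )
    fit = fit_random_walk(series)
    paths = render_figures(series, fit, args.outdir / "figures")
    for p in paths:
        print(f"wrote {p}")


if __name__ == "__main__":
    main()
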