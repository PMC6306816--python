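#!/usr/bin/env python
"""Per-image OI(90) across culture conditions, with ANOVA + Holm-Sidak.

Analyzes the 24 culture scenes from analysis/01 (three conditions on
vertically aligned collagen, 8 images each) at reference angle 90 deg —
the collagen direction. Expected outcome: all three conditions score
positive mean OI (co-alignment with the fibrils), with the growth-factor
-like conditions (stronger substrate guidance in the generator) above the
serum-free-like condition, and the ANOVA separating the groups.

Run after 01:  python analysis/03_condition_comparison.py
"""

from pathlib import Path

import pandas as pd

import fibralign as fa
from fibralign.pipeline import RunConfig

IMAGES = Path("results/images")
OUT = Path("results")
CONDITIONS = ("serum_free", "pdgf", "tgfb")


def main() -> None:
    inputs = sorted(
        str(p) for p in IMAGES.glob("*.tif")
        if p.stem.rsplit("_", 1)[0] in CONDITIONS
    )
    config = RunConfig(
        mode="analyze", inputs=inputs, theta_ref_deg=90.0,
        output_dir=str(OUT / "condition_run"),
    )
    table, comparison = fa.run(config)

    means = table.groupby("condition")["oi_percent"].agg(["mean", "std", "count"])
    means.to_csv(OUT / "condition_oi_summary.csv", float_format="%.3f")
    print(means.round(1).to_string())
    print(
        f"\nANOVA: F = {comparison.f_statistic:.2f}, p = {comparison.p_value:.2g}"
    )
    for (a, b), p_raw, p_adj in comparison.pairwise:
        print(f"  {a} vs {b}: raw p = {p_raw:.3g}, Holm-Sidak p = {p_adj:.3g}")


if __name__ == "__main__":
    main()
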