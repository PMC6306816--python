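#!/usr/bin/env python
"""Regional alignment around a freeze wound: tile policy in action.

Splits the wounded scene from analysis/01 into 128 px tiles labeled wound
(fully inside the cell-free disc), non-wound (fully outside) or discarded
(straddling the boundary, excluded to keep each tile's FFT clean), then
compares OI(90) between regions. Expected outcome: tile counts conserve
the grid total, and because freezing spares the collagen architecture, the
substrate alignment inside the wound matches the periphery.

Run after 01:  python analysis/04_wound_regions.py
"""

from collections import Counter
from pathlib import Path

import pandas as pd

import fibralign as fa
from fibralign.pipeline import RunConfig

OUT = Path("results")


def main() -> None:
    path = Path("results/images/wound_scene.tif")
    ras = fa.read_image(path)
    wound = fa.WoundSpec(center_px=(512, 512), radius_um=300.0)

    tiles = fa.tile_regions(ras, wound, 128)
    counts = Counter(label for _, label, _ in tiles)
    total = sum(counts.values())
    print(f"tiles: {dict(counts)} (total {total})")

    config = RunConfig(
        mode="analyze", inputs=[str(path)], theta_ref_deg=90.0,
        region_policy="tiles", tile_size_px=128, wound=wound,
        output_dir=str(OUT / "wound_run"),
    )
    table, _ = fa.run(config)
    table["region_class"] = table["region"].str.split(":").str[0]
    summary = table.groupby("region_class")["oi_percent"].agg(["mean", "std", "count"])
    summary.to_csv(OUT / "wound_region_oi.csv", float_format="%.3f")
    print(summary.round(1).to_string())
    gap = abs(summary.loc["wound", "mean"] - summary.loc["non-wound", "mean"])
    print(f"\nwound vs non-wound mean OI gap: {gap:.1f} points "
          "(substrate alignment preserved through the injury)")


if __name__ == "__main__":
    main()
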