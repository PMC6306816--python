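#!/usr/bin/env python
"""Simulate the study's substrate and culture scenes.

Renders seeded synthetic micrographs to results/images/: an aligned
fibrillar substrate (flow direction horizontal, 0 deg), a random fibrillar
substrate, three cell-culture conditions on vertically aligned collagen
(serum-free-like dendritic cells, PDGF-like and TGFb-like elongated cells
with increasing substrate guidance), and a freeze-wound scene. Each TIFF
carries a JSON sidecar with its full generative spec, so every later stage
can be replayed from disk.

Run from the repository root:  python analysis/01_simulate_substrates.py
"""

import json
from pathlib import Path

import fibralign as fa

OUT = Path("results/images")
SEED = 20260924


def substrate_scenes() -> list[dict]:
    """Fig-1C-style pair: aligned (mean 0 deg) vs random fibril mats."""
    common = dict(image_size_px=(1024, 1024), n_fibrils=300)
    return [
        {"id": "substrate_aligned", "condition": "aligned",
         "fibrils": dict(common, mean_angle_deg=0.0, dispersion_kappa=50.0)},
        {"id": "substrate_random", "condition": "random",
         "fibrils": dict(common, dispersion_kappa=0.0)},
    ]


def culture_scenes() -> list[dict]:
    """Three culture conditions on vertical collagen, 8 images each.

    Substrate guidance strength increases from the serum-free-like to the
    growth-factor-like conditions (kappa 2 vs 20), mirroring weaker vs
    stronger cell/ECM co-alignment; cells are composited on top.
    """
    scenes = []
    conditions = [
        ("serum_free", 2.0, dict(morphology="dendritic", n_processes=5)),
        ("pdgf", 20.0, dict(morphology="elongated", elongation_ratio=4.0, n_processes=0)),
        ("tgfb", 20.0, dict(morphology="elongated", elongation_ratio=2.0, n_processes=0)),
    ]
    for cond, kappa, cell_kw in conditions:
        for k in range(8):
            scenes.append(
                {
                    "id": f"{cond}_{k:02d}",
                    "condition": cond,
                    "fibrils": dict(
                        image_size_px=(512, 512), n_fibrils=150,
                        mean_angle_deg=-90.0, dispersion_kappa=kappa,
                    ),
                    "cells": dict(cell_kw, n_cells=12, body_axis_angle_deg="sampled"),
                }
            )
    return scenes


def wound_scene() -> list[dict]:
    """A vertically aligned substrate with cells and a central freeze wound.

    Pixel size 1 um/px so a wound of practical radius (300 um) leaves
    complete tiles on both sides of its boundary in a 1024 px frame.
    """
    return [
        {
            "id": "wound_scene",
            "condition": "wounded",
            "fibrils": dict(
                image_size_px=(1024, 1024), pixel_size_um=1.0,
                n_fibrils=300, mean_angle_deg=-90.0, dispersion_kappa=30.0,
            ),
            "cells": dict(n_cells=60, morphology="dendritic", n_processes=5),
            "wound": dict(center_px=(512, 512), radius_um=300.0),
        }
    ]


def main() -> None:
    scenes = substrate_scenes() + culture_scenes() + wound_scene()
    paths = fa.simulate_scenes(scenes, OUT, seed=SEED)
    manifest = {"seed": SEED, "n_scenes": len(paths), "images": [p.name for p in paths]}
    Path("results/simulation_manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"wrote {len(paths)} scenes to {OUT}/ (seed {SEED})")


if __name__ == "__main__":
    main()
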