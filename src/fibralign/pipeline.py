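"""End-to-end orchestration: simulate, tile, analyze, compare.

Each run is driven by a :class:`RunConfig` (deserialisable from YAML),
writes a per-image CSV of peak orientations and OI values, optionally a
group-comparison CSV, and a JSON manifest echoing the config and package
version so a run can be replayed byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from . import __version__
from .oi import orientation_index
from .rasters import ImageRaster, read_image, write_tiff
from .spectral import (
    SpectralParams,
    orientation_distribution,
    peak_orientation,
)
from .stats import compare_conditions
from .synthetic import (
    CellFieldSpec,
    FibrilFieldSpec,
    ParameterError,
    WoundSpec,
    apply_wound,
    generate_cells,
    generate_fibril_field,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "tile_regions",
    "analyze_images",
    "simulate_scenes",
    "run",
]

log = logging.getLogger("fibralign")

RESULT_COLUMNS = [
    "image_id",
    "condition",
    "region",
    "peak_deg",
    "oi_percent",
    "theta_ref_deg",
    "n_bins",
    "params_hash",
]


class PipelineError(RuntimeError):
    """A run could not produce any usable result."""


@dataclasses.dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    ``mode`` selects the stage: ``simulate`` (specs to TIFFs), ``analyze``
    (images to per-image OI table), ``compare`` (OI table to group stats),
    or any combination chained by :func:`run`. ``region_policy``
    ``"tiles"`` analyzes non-overlapping square tiles labeled by wound
    membership instead of whole images.
    """

    mode: str = "analyze"
    inputs: list[str] = dataclasses.field(default_factory=list)
    scenes: list[dict] = dataclasses.field(default_factory=list)
    spectral: SpectralParams = dataclasses.field(default_factory=SpectralParams)
    theta_ref_deg: float = 90.0
    region_policy: str = "whole_image"
    tile_size_px: int = 256
    wound: WoundSpec | None = None
    output_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in {"simulate", "analyze", "compare", "full"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.region_policy not in {"whole_image", "tiles"}:
            raise ValueError(f"unknown region policy {self.region_policy!r}")
        if self.region_policy == "tiles" and self.tile_size_px < 64:
            raise ValueError("tile_size_px must be >= 64 under the tiles policy")
        if not (-90.0 <= self.theta_ref_deg <= 90.0):
            raise ValueError("theta_ref_deg must lie in [-90, 90]")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "spectral" in raw and isinstance(raw["spectral"], dict):
            raw["spectral"] = SpectralParams(**raw["spectral"])
        if "wound" in raw and isinstance(raw["wound"], dict):
            w = dict(raw["wound"])
            if "center_px" in w:
                w["center_px"] = tuple(w["center_px"])
            raw["wound"] = WoundSpec(**w)
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


def _params_hash(params: SpectralParams, theta_ref_deg: float) -> str:
    blob = json.dumps(
        {**dataclasses.asdict(params), "theta_ref_deg": theta_ref_deg},
        sort_keys=True,
    )
    return hashlib.sha1(blob.encode()).hexdigest()[:10]


# ---------------------------------------------------------------------------
# tiling


def tile_regions(
    image: ImageRaster,
    wound: WoundSpec | None,
    tile_size_px: int,
) -> list[tuple[ImageRaster, str, tuple[int, int]]]:
    """Split an image into non-overlapping square tiles labeled by wound.

    Tiles fully inside the wound disc are labeled ``"wound"``, tiles fully
    outside ``"non-wound"``; tiles straddling the boundary are labeled
    ``"discarded"`` and excluded from analysis (a tile mixing wound and
    periphery would blur the FFT of both). With no wound every tile is
    ``"non-wound"``. Returned tuples are (tile raster, label, grid index);
    the three label counts always sum to the total tile count.
    """
    h, w = image.shape
    if tile_size_px > min(h, w):
        raise ParameterError("tile does not fit in image")
    n_r, n_c = h // tile_size_px, w // tile_size_px
    if wound is not None:
        radius_px = wound.radius_um / image.pixel_size_um
        rr, cc = np.ogrid[:h, :w]
        disc = (rr - wound.center_px[0]) ** 2 + (cc - wound.center_px[1]) ** 2 < radius_px**2
    tiles = []
    for i in range(n_r):
        for j in range(n_c):
            sl = (
                slice(i * tile_size_px, (i + 1) * tile_size_px),
                slice(j * tile_size_px, (j + 1) * tile_size_px),
            )
            if wound is None:
                label = "non-wound"
            else:
                frac = disc[sl].mean()
                label = "wound" if frac == 1.0 else ("non-wound" if frac == 0.0 else "discarded")
            tile = image.with_pixels(
                image.pixels[sl].copy(),
                provenance={"base": image.provenance, "tile": (i, j)},
            )
            tiles.append((tile, label, (i, j)))
    if wound is not None:
        labels = {lab for _, lab, _ in tiles}
        if "wound" not in labels and "non-wound" not in labels:
            raise ParameterError(
                "no complete tile on either side of the wound boundary"
            )
    return tiles


# ---------------------------------------------------------------------------
# stages


def simulate_scenes(
    scenes: Iterable[dict], output_dir: str | Path, seed: int = 0
) -> list[Path]:
    """Render scene dictionaries to TIFF + sidecar JSON files.

    Each scene dict holds an ``id``, optional ``condition``, a ``fibrils``
    spec mapping, and optional ``cells`` / ``wound`` mappings. Per-scene
    seeds are derived deterministically from the run seed and scene index.
    """
    output_dir = Path(output_dir)
    paths = []
    for k, scene in enumerate(scenes):
        scene = dict(scene)
        scene_seed = (int(seed) * 10007 + k) % (2**31)
        fib = dict(scene.get("fibrils", {}))
        fib.setdefault("seed", scene_seed)
        if "image_size_px" in fib:
            fib["image_size_px"] = tuple(fib["image_size_px"])
        raster = generate_fibril_field(FibrilFieldSpec(**fib))
        mask = None
        if "cells" in scene:
            cell = dict(scene["cells"])
            cell.setdefault("seed", scene_seed + 1)
            raster, mask = generate_cells(CellFieldSpec(**cell), raster)
        if "wound" in scene and mask is not None:
            wnd = dict(scene["wound"])
            if "center_px" in wnd:
                wnd["center_px"] = tuple(wnd["center_px"])
            raster = apply_wound(raster, mask, WoundSpec(**wnd))
        image_id = scene.get("id", f"scene_{k:03d}")
        condition = scene.get("condition", "")
        raster = raster.with_pixels(
            raster.pixels,
            provenance={
                "image_id": image_id,
                "condition": condition,
                "scene": scene,
                "seed": scene_seed,
            },
        )
        path = write_tiff(raster, output_dir / f"{image_id}.tif")
        log.info("simulated %s (condition=%s)", path.name, condition or "-")
        paths.append(path)
    return paths


def _analyze_one(
    raster: ImageRaster,
    image_id: str,
    condition: str,
    config: RunConfig,
) -> list[dict]:
    phash = _params_hash(config.spectral, config.theta_ref_deg)
    rows = []
    if config.region_policy == "tiles":
        units = [
            (tile, label, f"{label}:{idx[0]},{idx[1]}")
            for tile, label, idx in tile_regions(raster, config.wound, config.tile_size_px)
            if label != "discarded"
        ]
    else:
        units = [(raster, "whole", "whole")]
    for tile, label, region in units:
        dist = orientation_distribution(tile, config.spectral)
        oi = orientation_index(dist, config.theta_ref_deg)
        rows.append(
            {
                "image_id": image_id,
                "condition": condition,
                "region": region if config.region_policy == "tiles" else "whole",
                "peak_deg": peak_orientation(dist),
                "oi_percent": oi.oi_percent,
                "theta_ref_deg": config.theta_ref_deg,
                "n_bins": config.spectral.n_bins,
                "params_hash": phash,
            }
        )
    return rows


def analyze_images(
    config: RunConfig,
    rasters: list[tuple[str, str, ImageRaster]] | None = None,
) -> pd.DataFrame:
    """Per-image (or per-tile) orientation analysis.

    ``rasters`` is a list of (image_id, condition, raster); when omitted,
    ``config.inputs`` paths are loaded (condition read from each sidecar's
    provenance if present). Unreadable files are logged and skipped; the
    run fails only if nothing could be analyzed.
    """
    if rasters is None:
        if not config.inputs:
            raise PipelineError("no input images")
        rasters = []
        for p in config.inputs:
            try:
                raster = read_image(p)
            except Exception as exc:  # noqa: BLE001 - collected per file
                log.error("failed to read %s: %s", p, exc)
                continue
            prov = raster.provenance
            condition = ""
            image_id = Path(p).stem
            if isinstance(prov, dict):
                condition = prov.get("condition", "")
                image_id = prov.get("image_id", image_id)
            rasters.append((image_id, condition, raster))
        if not rasters:
            raise PipelineError("all input images failed to load")
    rows: list[dict] = []
    failures = 0
    for image_id, condition, raster in rasters:
        try:
            rows.extend(_analyze_one(raster, image_id, condition, config))
        except Exception as exc:  # noqa: BLE001 - collected per file
            failures += 1
            log.error("analysis failed for %s: %s", image_id, exc)
    if not rows:
        raise PipelineError(f"analysis failed for all {failures} image(s)")
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run(config: RunConfig, rasters: list[tuple[str, str, ImageRaster]] | None = None):
    """Execute a full pipeline run and write CSV/JSON outputs.

    Writes ``per_image.csv`` (one row per analyzed image or tile),
    ``group_comparison.csv`` when two or more conditions are present, and
    ``manifest.json``. Deterministic for a fixed config and seed. Returns
    (per-image table, GroupComparison or None).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode in {"simulate", "full"} and config.scenes:
        paths = simulate_scenes(config.scenes, out / "images", config.seed)
        if config.mode == "simulate":
            _write_manifest(config, out)
            return None, None
        config = dataclasses.replace(config, inputs=[str(p) for p in paths])

    table = analyze_images(config, rasters=rasters)
    table.to_csv(out / "per_image.csv", index=False, float_format="%.6f")
    log.info("wrote %s (%d rows)", out / "per_image.csv", len(table))

    comparison = None
    labeled = table[table["condition"] != ""]
    if labeled["condition"].nunique() >= 2 and all(
        (labeled["condition"] == c).sum() >= 2 for c in labeled["condition"].unique()
    ):
        comparison = compare_conditions(labeled)
        comparison.to_frame().to_csv(
            out / "group_comparison.csv", index=False, float_format="%.6g"
        )
        log.info(
            "ANOVA across %s: F=%.3f p=%.3g",
            comparison.group_labels,
            comparison.f_statistic,
            comparison.p_value,
        )
    _write_manifest(config, out)
    return table, comparison


def _write_manifest(config: RunConfig, out: Path) -> None:
    manifest = {"fibralign_version": __version__, "config": config.to_jsonable()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
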