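"""Per-well analysis drivers and the umbrella pipeline.

`process_actin_well` runs orientation -> defects -> VoC on an actin (or
phase-contrast) well; `process_nucleus_well` runs the condensation
pipeline on a nucleus well.  `run_pipeline` maps these over an image
table, joins protein readouts when available, and writes the result CSVs.
Every CSV carries a ``config_hash`` column tying rows to the exact
parameter set that produced them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .correlation import correlate_by_day
from .defects import DefectSet, coarse_grain_director, detect_defects
from .io import CircularMask, RunConfig, WellImage, read_well_image
from .nuclei import aggregate_area, density_heatmap, preprocess_nuclei
from .orientation import OrientationField, compute_orientation_field
from .voc import VoCResult, variance_of_coherency

logger = logging.getLogger("swirlquant")


@dataclass
class ActinWellResult:
    field: OrientationField
    defects: DefectSet
    voc: VoCResult


def _analysis_mask(image: WellImage, config: RunConfig) -> CircularMask:
    """Coherency-analysis circle, shrunk to fit small (e.g. synthetic) wells."""
    h, w = image.shape
    radius = min(config.coherency_radius_px, 0.45 * min(h, w))
    return CircularMask.centered((h, w), radius)


def process_actin_well(image: WellImage, config: Optional[RunConfig] = None
                       ) -> ActinWellResult:
    """Orientation field, defect set and VoC for one actin/phase well."""
    config = config or RunConfig()
    field = compute_orientation_field(
        image, gradient_sigma=config.gradient_sigma, window_sigma=config.window_sigma)
    grid = coarse_grain_director(field, block_px=config.block_px)
    defects = detect_defects(grid, field, min_abs_charge=config.min_abs_charge,
                             merge_radius_blocks=config.merge_radius_blocks)
    voc = variance_of_coherency(field, _analysis_mask(image, config),
                                bins=config.histogram_bins)
    return ActinWellResult(field=field, defects=defects, voc=voc)


@dataclass
class NucleusWellResult:
    heatmap: np.ndarray
    total_area_px: int
    total_area_um2: float
    n_components: int


def process_nucleus_well(image: WellImage, config: Optional[RunConfig] = None
                         ) -> NucleusWellResult:
    """Condensation heatmap and total aggregate area for one nucleus well."""
    config = config or RunConfig()
    h, w = image.shape
    radius = min(config.nuclei_radius_px, 0.45 * min(h, w))
    mask = CircularMask.centered((h, w), radius)
    cleaned = preprocess_nuclei(
        image, mask, clahe_clip_limit=config.clahe_clip_limit,
        clahe_tiles=config.clahe_tiles,
        local_window_px=config.local_threshold_window_px,
        combine=config.mask_combine)
    heat = density_heatmap(cleaned, filter_radius_px=config.density_filter_radius_px,
                           kernel=config.density_kernel)
    agg = aggregate_area(heat, threshold=config.aggregate_threshold,
                         min_component_px=config.min_component_px,
                         pixel_size_um=config.pixel_size_um)
    return NucleusWellResult(heatmap=heat.values, total_area_px=agg.total_area_px,
                             total_area_um2=agg.total_area_um2,
                             n_components=agg.n_components)


_TABLE_COLUMNS = ("path", "channel", "well_id", "donor_id", "day", "replicate")


def run_pipeline(
    config: RunConfig,
    image_table: pd.DataFrame,
    out_dir: str | Path,
    proteins: Optional[pd.DataFrame] = None,
) -> dict[str, pd.DataFrame]:
    """Run every stage over an image table and write result CSVs.

    *image_table* needs columns path, channel, well_id, donor_id, day,
    replicate.  Actin/phase wells produce VoC and defect rows; nucleus
    wells produce aggregate-area rows.  When *proteins* is given (one row
    per donor with sGAG/Col2 columns), per-day correlations are computed
    for each available metric.  Per-well failures are logged and skipped;
    the run fails only if every well fails.
    """
    missing = set(_TABLE_COLUMNS) - set(image_table.columns)
    if missing:
        raise ValueError(f"image table is missing columns: {sorted(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    metric_rows, defect_rows, area_rows = [], [], []
    n_failed = 0
    for rec in image_table.to_dict("records"):
        try:
            image = read_well_image(
                rec["path"], pixel_size_um=config.pixel_size_um,
                channel=rec["channel"], well_id=rec["well_id"],
                donor_id=rec["donor_id"], day=int(rec["day"]),
                replicate=int(rec["replicate"]))
            if image.channel in ("actin", "phase"):
                res = process_actin_well(image, config)
                metric_rows.append({
                    "well_id": image.well_id, "donor_id": image.donor_id,
                    "day": image.day, "replicate": image.replicate,
                    "voc": res.voc.voc, "mean_coherency": res.voc.mean_coherency,
                    "n_pixels": res.voc.n_pixels, "n_defects": len(res.defects),
                    "total_charge": res.defects.total_charge(),
                    "config_hash": chash})
                for d in res.defects.defects:
                    defect_rows.append({
                        "well_id": image.well_id, "x_px": d.x_px, "y_px": d.y_px,
                        "x_um": d.x_px * config.pixel_size_um,
                        "y_um": d.y_px * config.pixel_size_um,
                        "charge": d.charge, "type": d.type,
                        "core_coherency": d.core_coherency,
                        "raw_winding": d.raw_winding, "config_hash": chash})
            elif image.channel == "nucleus":
                res_n = process_nucleus_well(image, config)
                area_rows.append({
                    "well_id": image.well_id, "donor_id": image.donor_id,
                    "day": image.day, "replicate": image.replicate,
                    "total_area_px": res_n.total_area_px,
                    "total_area_um2": res_n.total_area_um2,
                    "n_components": res_n.n_components, "config_hash": chash})
            else:
                logger.warning("well %s: channel %r not analyzed", rec["well_id"],
                               rec["channel"])
        except Exception:
            n_failed += 1
            logger.exception("well %s failed; skipping", rec.get("well_id"))
    if n_failed == len(image_table):
        raise RuntimeError("all wells failed; see log for per-well errors")

    outputs: dict[str, pd.DataFrame] = {}
    if metric_rows:
        outputs["voc"] = pd.DataFrame(metric_rows)
        outputs["voc"].to_csv(out_dir / "voc.csv", index=False)
    if defect_rows:
        outputs["defects"] = pd.DataFrame(defect_rows)
        outputs["defects"].to_csv(out_dir / "defects.csv", index=False)
    if area_rows:
        outputs["clusters"] = pd.DataFrame(area_rows)
        outputs["clusters"].to_csv(out_dir / "clusters.csv", index=False)

    if proteins is not None:
        metrics = [m for m, k in (("voc", "voc"), ("total_area_um2", "clusters"))
                   if k in outputs]
        frames = []
        for metric in metrics:
            key = "voc" if metric == "voc" else "clusters"
            corr = correlate_by_day(outputs[key], proteins, metrics=[metric],
                                    pooled=config.pooled_replicates, seed=config.seed)
            frames.append(corr)
        if frames:
            corr_df = pd.concat(frames, ignore_index=True)
            corr_df["config_hash"] = chash
            outputs["correlations"] = corr_df
            corr_df.to_csv(out_dir / "correlations.csv", index=False)
    else:
        logger.warning("no protein table supplied; correlation stage skipped")
    return outputs
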