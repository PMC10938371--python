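"""End-to-end orchestration from a plain-text (YAML) config to CSV reports.

A run is fully determined by (config, seeds): every stage writes diffable CSV
tables plus a run log recording parameters and seeds. Stage failures are
isolated — one bad input does not abort the remaining stages; the failure and
the offending input are named in the report.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aggregates import label_aggregates, summarize_aggregates
from .colocalization import colocalization_profile
from .community_stats import (
    AbundanceTable,
    bray_curtis,
    copy_number_correct,
    kruskal_wallis_bh,
    pcoa,
    permanova,
)
from .image_io import read_stack
from .quant_utils import fit_standard_curve, interpolate_copies, normalize_per_root
from .quantify import biomass_volume
from .thresholding import binarize, max_entropy_threshold

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "DEFAULTS"]

DEFAULTS = {
    "bins": 256,
    "n_focal": 1000,
    "max_dist_um": 51.0,
    "runs": 5,
    "adjacency": (3, 3, 3),
    "min_volume_um3": 10.0,
    "permutations": 999,
    "seed": 0,
}


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    output_dir: Path
    seed: int
    images: tuple  # dicts: id, path, spacing_um, channels, day, replicate
    bins: int
    coloc_pairs: tuple  # (focal, target) channel-name pairs
    n_focal: int
    max_dist_um: float
    runs: int
    adjacency: tuple
    min_volume_um3: float
    community: dict | None  # counts_csv, copy_numbers_csv, group_column, permutations
    qpcr: dict | None  # standards_csv, samples_csv


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(raw: dict, base_dir=".") -> PipelineConfig:
    """Validate a parsed config document, reporting every problem at once."""
    base = Path(base_dir)
    errors = []

    def err(msg):
        errors.append(msg)

    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")

    out_dir = Path(raw.get("output_dir", "biofilmvoxel_out"))
    seed = raw.get("seed", DEFAULTS["seed"])
    if not isinstance(seed, int):
        err(f"seed must be an integer, got {seed!r}")

    images = []
    for i, img in enumerate(raw.get("images", []) or []):
        label = img.get("id", f"image{i}")
        path = img.get("path")
        if path is None:
            err(f"image {label}: missing 'path'")
        elif not (base / path).exists():
            err(f"image {label}: stack path not found: {base / path}")
        spacing = img.get("spacing_um")
        if not spacing or len(spacing) != 3 or any(s <= 0 for s in spacing):
            err(f"image {label}: spacing_um must be three positive numbers")
        channels = img.get("channels")
        if not channels:
            err(f"image {label}: missing 'channels'")
        images.append(
            {
                "id": label,
                "path": str(base / path) if path else "",
                "spacing_um": tuple(spacing) if spacing else (1, 1, 1),
                "channels": list(channels or []),
                "day": img.get("day"),
                "replicate": img.get("replicate"),
            }
        )

    thr = raw.get("threshold", {}) or {}
    bins = thr.get("bins", DEFAULTS["bins"])
    if not isinstance(bins, int) or bins < 2:
        err(f"threshold.bins must be an integer >= 2, got {bins!r}")

    co = raw.get("coloc", {}) or {}
    pairs = tuple(tuple(p) for p in co.get("pairs", []) or [])
    n_focal = co.get("n_focal", DEFAULTS["n_focal"])
    max_dist = co.get("max_dist_um", DEFAULTS["max_dist_um"])
    runs = co.get("runs", DEFAULTS["runs"])
    if n_focal < 1:
        err(f"coloc.n_focal must be >= 1, got {n_focal}")
    if max_dist < 1:
        err(f"coloc.max_dist_um must be >= 1, got {max_dist}")
    if runs < 1:
        err(f"coloc.runs must be >= 1, got {runs}")

    ag = raw.get("aggregates", {}) or {}
    adjacency = tuple(ag.get("adjacency", DEFAULTS["adjacency"]))
    min_vol = ag.get("min_volume_um3", DEFAULTS["min_volume_um3"])
    if len(adjacency) != 3 or any((not isinstance(a, int)) or a < 1 or a % 2 == 0 for a in adjacency):
        err(f"aggregates.adjacency must be three odd integers, got {adjacency}")
    if min_vol < 0:
        err(f"aggregates.min_volume_um3 must be nonnegative, got {min_vol}")

    community = raw.get("community")
    if community:
        for key in ("counts_csv", "copy_numbers_csv"):
            p = community.get(key)
            if p is None:
                err(f"community.{key} is required")
            elif not (base / p).exists():
                err(f"community.{key} not found: {base / p}")
        community = dict(community)
        community.setdefault("group_column", "day")
        community.setdefault("permutations", DEFAULTS["permutations"])
        for key in ("counts_csv", "copy_numbers_csv"):
            if community.get(key):
                community[key] = str(base / community[key])

    qpcr = raw.get("qpcr")
    if qpcr:
        for key in ("standards_csv", "samples_csv"):
            p = qpcr.get(key)
            if p is None:
                err(f"qpcr.{key} is required")
            elif not (base / p).exists():
                err(f"qpcr.{key} not found: {base / p}")
        qpcr = dict(qpcr)
        for key in ("standards_csv", "samples_csv"):
            if qpcr.get(key):
                qpcr[key] = str(base / qpcr[key])

    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))

    return PipelineConfig(
        output_dir=out_dir,
        seed=int(seed),
        images=tuple(images),
        bins=int(bins),
        coloc_pairs=pairs,
        n_focal=int(n_focal),
        max_dist_um=float(max_dist),
        runs=int(runs),
        adjacency=adjacency,
        min_volume_um3=float(min_vol),
        community=community,
        qpcr=qpcr,
    )


def _image_stage(config: PipelineConfig, log: list):
    biomass_rows, thr_rows, agg_rows, agg_sum_rows, coloc_rows = [], [], [], [], []
    for img in config.images:
        stack = read_stack(img["path"], img["spacing_um"], img["channels"])
        masks = {}
        for grid in stack.channels:
            res = max_entropy_threshold(grid, n_bins=config.bins)
            mask = binarize(grid, res.threshold)
            masks[grid.name] = mask
            thr_rows.append(
                {"image": img["id"], "channel": grid.name,
                 "threshold": res.threshold, "n_bins": res.n_bins}
            )
            rec = biomass_volume(mask, image_id=img["id"], day=img["day"],
                                 replicate=img["replicate"])
            biomass_rows.append(dataclasses.asdict(rec))
            aggs = label_aggregates(mask, adjacency=config.adjacency)
            for a in aggs:
                agg_rows.append(
                    {"image": img["id"], "species": grid.name, "id": a.id,
                     "voxel_count": a.voxel_count, "volume_um3": a.volume_um3,
                     "centroid_z_um": a.centroid_um[0],
                     "centroid_y_um": a.centroid_um[1],
                     "centroid_x_um": a.centroid_um[2]}
                )
            summ = summarize_aggregates(
                aggs, threshold_um3=config.min_volume_um3, species=grid.name,
                image_id=img["id"], day=img["day"], replicate=img["replicate"])
            agg_sum_rows.append(dataclasses.asdict(summ))
        for focal_name, target_name in config.coloc_pairs:
            if focal_name not in masks or target_name not in masks:
                log.append(f"coloc pair ({focal_name}, {target_name}) skipped for "
                           f"{img['id']}: channel missing")
                continue
            prof = colocalization_profile(
                masks[focal_name], masks[target_name], n_focal=config.n_focal,
                max_dist_um=config.max_dist_um, n_runs=config.runs, seed=config.seed)
            for run in range(prof.n_runs):
                for b, center in enumerate(prof.bin_centers_um):
                    coloc_rows.append(
                        {"image": img["id"], "focal": focal_name, "target": target_name,
                         "bin_center_um": int(center), "run": run,
                         "proportion": prof.per_run_proportions[run, b]}
                    )
        log.append(f"image stage done: {img['id']}")
    return {
        "thresholds.csv": pd.DataFrame(thr_rows),
        "biomass.csv": pd.DataFrame(biomass_rows),
        "aggregates.csv": pd.DataFrame(agg_rows),
        "aggregate_summaries.csv": pd.DataFrame(agg_sum_rows),
        "colocalization.csv": pd.DataFrame(coloc_rows),
    }


def _community_stage(config: PipelineConfig, log: list):
    cfg = config.community
    counts = pd.read_csv(cfg["counts_csv"], index_col=0)
    copies = pd.read_csv(cfg["copy_numbers_csv"], index_col=0).iloc[:, 0].to_dict()
    group_col = cfg["group_column"]
    meta_cols = [c for c in counts.columns if c in (group_col, "replicate")]
    metadata = counts[meta_cols] if meta_cols else None
    taxa_cols = [c for c in counts.columns if c not in (meta_cols or [])]
    table = AbundanceTable(counts=counts[taxa_cols], copy_numbers=copies, metadata=metadata)
    rel = copy_number_correct(table)
    dm = bray_curtis(rel)
    groups = rel.metadata[group_col].values
    perm = permanova(dm, groups, n_permutations=cfg["permutations"], seed=config.seed)
    ord_res = pcoa(dm)
    grouped = {
        taxon: [rel.counts.loc[rel.metadata[group_col] == g, taxon].values
                for g in pd.unique(groups)]
        for taxon in rel.taxa
    }
    kw = kruskal_wallis_bh(grouped, group_labels=[str(g) for g in pd.unique(groups)])
    log.append(f"community stage: PERMANOVA F={perm.pseudo_f:.4g} R2={perm.r2:.4g} "
               f"p={perm.p_value:.4g}")
    return {
        "relative_abundance.csv": rel.counts,
        "permanova.csv": pd.DataFrame([dataclasses.asdict(perm)]),
        "pcoa_coordinates.csv": ord_res.coordinates,
        "kruskal_wallis.csv": pd.DataFrame([dataclasses.asdict(r) for r in kw]),
    }


def _qpcr_stage(config: PipelineConfig, log: list):
    cfg = config.qpcr
    standards = pd.read_csv(cfg["standards_csv"])
    samples = pd.read_csv(cfg["samples_csv"])
    curve = fit_standard_curve(list(zip(standards["copies"], standards["ct"])))
    rows = []
    for _, row in samples.iterrows():
        copies = interpolate_copies(curve, row["ct"])
        entry = {"sample": row.get("sample", ""), "ct": row["ct"], "copies": copies}
        if "root_length_mm" in row and pd.notna(row["root_length_mm"]):
            entry["copies_per_mm"] = normalize_per_root(copies, row["root_length_mm"]).per_mm
        rows.append(entry)
    log.append(f"qpcr stage: slope={curve.slope:.4f} efficiency={curve.efficiency:.3f} "
               f"r2={curve.r_squared:.4f}")
    return {"qpcr_quantification.csv": pd.DataFrame(rows)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns {filename: DataFrame} and writes CSVs.

    Stages with no configured inputs are skipped (and noted in the log); a
    stage that raises is recorded with its error and does not abort the rest.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = [f"biofilmvoxel {__version__}", f"seed: {config.seed}",
           f"parameters: bins={config.bins} n_focal={config.n_focal} "
           f"max_dist_um={config.max_dist_um} runs={config.runs} "
           f"adjacency={config.adjacency} min_volume_um3={config.min_volume_um3}"]
    outputs = {}
    stages = []
    if config.images:
        stages.append(("images", _image_stage))
    else:
        log.append("image stage skipped: no images configured")
    if config.community:
        stages.append(("community", _community_stage))
    else:
        log.append("community stage skipped: not configured")
    if config.qpcr:
        stages.append(("qpcr", _qpcr_stage))
    else:
        log.append("qpcr stage skipped: not configured")

    for name, stage in stages:
        try:
            outputs.update(stage(config, log))
        except Exception as exc:  # stage isolation
            log.append(f"stage {name} FAILED: {exc}")
            logger.exception("stage %s failed", name)

    for fname, frame in outputs.items():
        frame.to_csv(out_dir / fname, index=True)
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    return outputs
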