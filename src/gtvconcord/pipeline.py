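"""End-to-end orchestration: simulate -> delineate -> compare -> stats.

Each stage writes its intermediates under the configured output directory:

* ``manifest.csv`` — one row per simulated patient with every applied
  perturbation (the ground truth the metrics should recover);
* ``masks/`` (and optionally ``volumes/``) — NIfTI contours and images;
* ``delineation_qa.csv`` — per-patient auto-contour quality: effective SUV
  threshold, ROI SUVmax, and Dice of the SUV- and CT-rule contours against
  the simulated truth;
* ``metrics.csv`` / ``metrics.json`` — all pairwise concordance measures;
* ``tables/`` — the five cohort report tables plus ``tests.json``;
* ``run_info.json`` — seed, config hash and stage log.

The contours compared in the tables are the simulated variants (whose
differences are known by construction); the rule-based delineation runs on
the same volumes as a per-patient QA stage.  A fixed configuration and seed
reproduce every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .delineate import ct_wall_rule, suv_threshold, tumor_roi
from .io import write_manifest, write_mask, write_volume
from .metrics import compare_gtv_set, overlap
from .phantom import make_cohort
from .stats import CohortResult, build_tables

log = logging.getLogger("gtvconcord")

__all__ = ["run_all", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _dice_vs_truth(mask, truth) -> float:
    if mask.is_empty or truth.is_empty:
        return 0.0
    return overlap(mask, truth).dice


def run_all(config: PipelineConfig) -> CohortResult:
    """Run the whole pipeline and return the cohort tables."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    info = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")

    # ---- simulate ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        patients = make_cohort(
            n_a=config.n_a, n_b=config.n_b, n_c=config.n_c,
            distributions=config.perturbations, seed=config.seed,
            base_spec=config.phantom,
        )
        write_manifest(patients, out / "manifest.csv")
        if config.save_masks or config.save_volumes:
            (out / "masks").mkdir(exist_ok=True)
        for p in patients:
            if config.save_volumes:
                (out / "volumes").mkdir(exist_ok=True)
                write_volume(p.planning_ct, out / "volumes" / f"{p.id}_ct.nii.gz")
                write_volume(p.pet_suv, out / "volumes" / f"{p.id}_pet.nii.gz")
            if config.save_masks:
                write_mask(p.truth_mask, out / "masks" / f"{p.id}_truth.nii.gz")
                for name, m in p.gtv_set.items():
                    tag = name.replace("GTV_", "").replace("-", "_").lower()
                    write_mask(m, out / "masks" / f"{p.id}_{tag}.nii.gz")
    except Exception as err:
        raise StageError(f"simulate: {err}") from err
    info["stages"]["simulate"] = {"seconds": time.perf_counter() - t0,
                                  "n_patients": len(patients)}
    log.info("simulated %d patients", len(patients))

    # ---- delineate (QA against ground truth) --------------------------
    t0 = time.perf_counter()
    try:
        qa_rows = []
        for p in patients:
            roi = tumor_roi(p)
            spec = replace(
                config.threshold, roi_center=roi.roi_center, roi_radius=roi.roi_radius
            )
            res = suv_threshold(p.pet_suv, spec)
            ct_mask = ct_wall_rule(p.planning_ct, p.esophagus_axis_mm, config.ct_rule)
            qa_rows.append({
                "patient_id": p.id,
                "group": p.group,
                "roi_suvmax": res.suvmax,
                "effective_threshold": res.effective_threshold,
                "suv_mask_voxels": res.voxel_count,
                "suv_dice_vs_truth": _dice_vs_truth(res.mask, p.truth_mask),
                "ct_rule_dice_vs_truth": _dice_vs_truth(ct_mask, p.truth_mask),
            })
            log.info(
                "%s: SUVmax=%.2f threshold=%.2f voxels=%d",
                p.id, res.suvmax, res.effective_threshold, res.voxel_count,
            )
        pd.DataFrame(qa_rows).to_csv(out / "delineation_qa.csv", index=False)
    except Exception as err:
        raise StageError(f"delineate: {err}") from err
    info["stages"]["delineate"] = {"seconds": time.perf_counter() - t0}

    # ---- compare -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        records = [compare_gtv_set(p.gtv_set, p.id, p.group) for p in patients]
        metrics_df = pd.DataFrame([r.to_flat_dict() for r in records])
        metrics_df.to_csv(out / "metrics.csv", index=False)
        metrics_df.to_json(out / "metrics.json", orient="records", indent=2)
    except Exception as err:
        raise StageError(f"compare: {err}") from err
    info["stages"]["compare"] = {"seconds": time.perf_counter() - t0}

    # ---- stats ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        result = build_tables(records, holm=config.holm)
        result.write(out / "tables")
    except Exception as err:
        raise StageError(f"stats: {err}") from err
    info["stages"]["stats"] = {"seconds": time.perf_counter() - t0}
    info["group_sizes"] = result.group_sizes

    with open(out / "run_info.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
    return result
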