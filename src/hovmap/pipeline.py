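"""Per-eye biomarker extraction and cohort-level statistics orchestration.

``run_eye`` turns one eye's raw inputs (duplicate exams, H/V scans) into a
flat biomarker record; ``run_cohort`` screens all structure-function
relationships with mixed-effects model selection and runs the inter-eye
and H-vs-V comparison tests.  Everything is deterministic given inputs
plus configuration, and every output carries the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bscan as bs
from .perimetry import (
    FieldExam,
    NormalFieldModel,
    combine_exams,
    defect_hov,
    global_indices,
    interpolate_hov,
)
from .registration import Registration, hybrid_measures
from .stats import paired_eye_test, orientation_test, relationship_screen
from .topography import (
    ContourUndefinedError,
    hov_max,
    hov_volume,
    line_biomarkers,
    radial_slope_contour,
    slope_summaries,
)

logger = logging.getLogger("hovmap")

__all__ = ["PipelineConfig", "run_eye", "run_cohort", "functional_biomarkers"]

#: Structural covariates / functional responses screened by default.
DEFAULT_STRUCTURAL = ["W_EZ_H", "W_EZ_V", "T_REC_AVG_H", "T_REC_AVG_V",
                      "T_ONL_AVG_H", "T_OS_AVG_H"]
DEFAULT_FUNCTIONAL = ["MS", "MD", "S_V", "S_V30", "d_grad_S_avg", "grad_S_avg",
                      "S_MAX_H", "S_MAX_V", "d_grad_S_avg_H"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable analysis parameters (defaults follow the study protocol)."""

    spacing_deg: float = 0.36
    n_spokes: int = 501
    search_radius_deg: float = 30.0
    min_radius_deg: float | None = None  # default: one grid step
    central_volume_radius_deg: float = 30.0
    slope_floor_db_per_deg: float = 0.05
    line_extent_deg: float = 15.0
    mm_per_degree: float = 0.3
    normal_model: NormalFieldModel = field(default_factory=NormalFieldModel)
    apply_flatten: bool = False
    df_method: str = "between_within"
    base_alpha: float = 0.05
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def functional_biomarkers(
    exam: FieldExam, config: PipelineConfig = PipelineConfig()
) -> dict:
    """All global + local functional biomarkers for one (combined) exam."""
    exam = exam.to_canonical()
    surface = interpolate_hov(exam, spacing=config.spacing_deg)
    normal = config.normal_model.surface(exam.age, like=surface)
    defect = defect_hov(normal, surface)
    n_nodes = config.normal_model.at(
        exam.grid.points[:, 0], exam.grid.points[:, 1], exam.age
    )
    ms, md, lv = global_indices(exam, n_nodes)
    out = {"MS": ms, "MD": md, "LV": lv}

    out["S_V"] = hov_volume(surface)
    out["D_V"] = hov_volume(defect)
    out["S_V30"] = hov_volume(surface, config.central_volume_radius_deg)
    out["D_V30"] = hov_volume(defect, config.central_volume_radius_deg)
    out["S_MAX"], out["d_S_MAX"] = hov_max(surface)
    out["D_MAX"], out["d_D_MAX"] = hov_max(defect)

    for surf, tag in ((surface, "S"), (defect, "D")):
        try:
            contour = radial_slope_contour(
                surf, n_spokes=config.n_spokes,
                search_radius=config.search_radius_deg,
                min_radius=config.min_radius_deg,
                slope_floor=config.slope_floor_db_per_deg,
            )
            smax, dmax, savg, davg = slope_summaries(contour)
        except ContourUndefinedError as exc:
            logger.warning("slope contour undefined for %s surface: %s", tag, exc)
            smax = dmax = savg = davg = np.nan
        out[f"grad_{tag}_max"] = smax
        out[f"d_grad_{tag}_max"] = dmax
        out[f"grad_{tag}_avg"] = savg
        out[f"d_grad_{tag}_avg"] = davg
        for orientation in ("H", "V"):
            lb = line_biomarkers(
                surf, orientation, extent=config.line_extent_deg,
                slope_floor=config.slope_floor_db_per_deg,
                min_radius=config.min_radius_deg,
            )
            out[f"{tag}_MAX_{orientation}"] = lb.max_value
            out[f"d_{tag}_MAX_{orientation}"] = lb.max_distance
            out[f"grad_{tag}_avg_{orientation}"] = (
                np.nan if lb.slope_avg is None else lb.slope_avg
            )
            out[f"d_grad_{tag}_avg_{orientation}"] = (
                np.nan if lb.d_slope_avg is None else lb.d_slope_avg
            )
    out["_surface"] = surface
    out["_defect"] = defect
    return out


def run_eye(
    exam1: FieldExam,
    exam2: FieldExam | None = None,
    scan_h: "bs.BScan | None" = None,
    scan_v: "bs.BScan | None" = None,
    registration: Registration | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Full per-eye biomarker record (functional + structural + hybrid).

    Missing scans degrade gracefully: the corresponding structural and
    hybrid columns are NaN and a warning is logged.  Returns a flat dict;
    surfaces are attached under keys starting with ``_`` for downstream
    reuse and stripped before CSV export.
    """
    exam = combine_exams(exam1, exam2) if exam2 is not None else exam1
    record: dict = {
        "participant": exam.participant_id,
        "eye": exam.grid.laterality,
        "age": exam.age,
        "rf": exam.rf,
        "config_hash": config.config_hash(),
    }
    record.update(functional_biomarkers(exam, config))

    scans = {}
    fovea = [0.0, 0.0]
    for scan, orientation, axis in ((scan_h, "H", 0), (scan_v, "V", 1)):
        if scan is None:
            logger.warning("missing %s scan: structural columns set to NA", orientation)
            continue
        try:
            sb = bs.structural_biomarkers(scan, apply_flatten=config.apply_flatten)
        except (bs.SegmentationError, ValueError) as exc:
            logger.warning("structural extraction failed for %s scan: %s",
                           orientation, exc)
            continue
        fovea[axis] = sb.pop("fovea_mm")
        for key, val in sb.items():
            record[f"{key}_{orientation}"] = val
        scans[orientation] = scan

    if len(scans) == 2:
        if registration is None:
            registration = Registration(
                fovea_mm=tuple(fovea), mm_per_degree=config.mm_per_degree,
                laterality=exam.grid.laterality,
            )
        try:
            hyb = hybrid_measures(
                record["_surface"], record["_defect"], scans, registration,
                line_extent_deg=config.line_extent_deg,
            )
            record.update(hyb.as_dict())
        except ValueError as exc:
            logger.warning("hybrid measures unavailable: %s", exc)
    return record


def strip_private(record: dict) -> dict:
    return {k: v for k, v in record.items() if not k.startswith("_")}


def run_cohort(
    eye_records: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    structural: list | None = None,
    functional: list | None = None,
) -> dict:
    """Cohort statistics: relationship screen + eye and orientation tests.

    ``eye_records`` has one row per eye (output of run_eye, stripped).
    Returns {"relationships": df, "eye_differences": df,
    "orientation_differences": df}.
    """
    if eye_records["participant"].nunique() < 2:
        raise ValueError("cohort analysis needs at least 2 participants")
    structural = structural or [c for c in DEFAULT_STRUCTURAL if c in eye_records]
    functional = functional or [c for c in DEFAULT_FUNCTIONAL if c in eye_records]
    rel = relationship_screen(
        eye_records, structural, functional,
        base_alpha=config.base_alpha, df_method=config.df_method,
    )
    rel["config_hash"] = config.config_hash()

    eye_rows = []
    both = eye_records.pivot_table(
        index="participant", columns="eye", aggfunc="first",
        values=[c for c in eye_records.columns
                if eye_records[c].dtype.kind == "f" and c not in ("age", "rf")],
    )
    for biom in both.columns.levels[0]:
        if "OD" not in both[biom] or "OS" not in both[biom]:
            continue
        pairs = both[biom][["OD", "OS"]].dropna()
        if len(pairs) < 5:
            continue
        try:
            stat, p = paired_eye_test(pairs["OS"], pairs["OD"])
        except ValueError:
            continue
        eye_rows.append(
            {"biomarker": biom, "n_pairs": len(pairs),
             "mean_diff_od_minus_os": float((pairs["OD"] - pairs["OS"]).mean()),
             "statistic": stat, "p": p}
        )
    eye_diff = pd.DataFrame(eye_rows)

    orient_rows = []
    for base in sorted({c[:-2] for c in eye_records.columns if c.endswith("_H")}):
        ch, cv = f"{base}_H", f"{base}_V"
        if cv not in eye_records:
            continue
        h = eye_records[ch].dropna().to_numpy(float)
        v = eye_records[cv].dropna().to_numpy(float)
        if len(h) < 3 or len(v) < 3:
            continue
        stat, p = orientation_test(h, v)
        orient_rows.append(
            {"biomarker": base, "n_h": len(h), "n_v": len(v),
             "statistic": stat, "p": p}
        )
    return {
        "relationships": rel,
        "eye_differences": eye_diff,
        "orientation_differences": pd.DataFrame(orient_rows),
    }
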