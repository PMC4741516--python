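"""Plain-text CSV/JSON schemas for exams, scans and outputs.

Schemas:
  grid.csv        point_id, x_deg, y_deg
  exam<k>.csv     point_id, dls_db
  exam<k>_meta.json  rf, age, laterality, participant_id, exam_index
  boundaries_<o>.csv lateral_mm, inl_um, elm_um, ez_um, prpe_um (empty = undefined)
  scan_<o>_meta.json orientation, mm_per_degree, um_per_px_axial, laterality,
                     fovea_hint_mm
  registration.json  offset_deg, mm_per_degree, fovea_mm, laterality
  truth.json         all generator ground-truth parameters
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bscan import BScan
from .perimetry import FieldExam, TestGrid
from .registration import Registration

__all__ = [
    "write_exam",
    "read_exam",
    "write_bscan",
    "read_bscan",
    "write_registration",
    "read_registration",
    "write_study",
]


class SchemaError(ValueError):
    """An input file does not match its documented schema."""


def _require(df: pd.DataFrame, cols: list, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def write_exam(exam: FieldExam, out_dir, exam_index: int = 1) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid_path = out / "grid.csv"
    if not grid_path.exists():
        pd.DataFrame(
            {"point_id": np.arange(exam.grid.n_points),
             "x_deg": exam.grid.points[:, 0], "y_deg": exam.grid.points[:, 1]}
        ).to_csv(grid_path, index=False)
    pd.DataFrame(
        {"point_id": np.arange(exam.grid.n_points), "dls_db": exam.dls}
    ).to_csv(out / f"exam{exam_index}.csv", index=False)
    meta = {
        "rf": exam.rf, "age": exam.age, "laterality": exam.grid.laterality,
        "participant_id": exam.participant_id, "exam_index": exam_index,
    }
    (out / f"exam{exam_index}_meta.json").write_text(json.dumps(meta, indent=1))


def read_exam(exam_dir, exam_index: int = 1) -> FieldExam:
    d = Path(exam_dir)
    grid_df = pd.read_csv(d / "grid.csv")
    _require(grid_df, ["point_id", "x_deg", "y_deg"], d / "grid.csv")
    exam_df = pd.read_csv(d / f"exam{exam_index}.csv")
    _require(exam_df, ["point_id", "dls_db"], d / f"exam{exam_index}.csv")
    meta = json.loads((d / f"exam{exam_index}_meta.json").read_text())
    merged = grid_df.merge(exam_df, on="point_id", validate="one_to_one")
    grid = TestGrid(
        merged[["x_deg", "y_deg"]].to_numpy(float),
        laterality=meta.get("laterality", "OD"),
    )
    return FieldExam(
        grid=grid, dls=merged["dls_db"].to_numpy(float), rf=float(meta.get("rf", 0.0)),
        age=float(meta.get("age", 50.0)),
        participant_id=str(meta.get("participant_id", "anon")),
    )


_BOUND_COLS = {"INL": "inl_um", "ELM": "elm_um", "EZ": "ez_um", "pRPE": "prpe_um"}


def write_bscan(scan: BScan, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    o = scan.orientation.lower()
    df = pd.DataFrame({"lateral_mm": scan.lateral_mm})
    for name, col in _BOUND_COLS.items():
        df[col] = scan.depth(name)  # effective (flattened) depths
    df.to_csv(out / f"boundaries_{o}.csv", index=False, na_rep="")
    meta = {
        "orientation": scan.orientation, "mm_per_degree": scan.mm_per_degree,
        "um_per_px_axial": scan.um_per_px_axial, "laterality": scan.laterality,
        "fovea_hint_mm": scan.fovea_hint_mm,
    }
    (out / f"scan_{o}_meta.json").write_text(json.dumps(meta, indent=1))


def read_bscan(scan_dir, orientation: str) -> BScan:
    d = Path(scan_dir)
    o = orientation.lower()
    df = pd.read_csv(d / f"boundaries_{o}.csv")
    _require(df, ["lateral_mm", *_BOUND_COLS.values()], d / f"boundaries_{o}.csv")
    meta = json.loads((d / f"scan_{o}_meta.json").read_text())
    return BScan(
        orientation=meta["orientation"],
        lateral_mm=df["lateral_mm"].to_numpy(float),
        boundaries={n: df[c].to_numpy(float) for n, c in _BOUND_COLS.items()},
        mm_per_degree=float(meta.get("mm_per_degree", 0.3)),
        um_per_px_axial=float(meta.get("um_per_px_axial", 3.9)),
        laterality=meta.get("laterality", "OD"),
        fovea_hint_mm=meta.get("fovea_hint_mm"),
    )


def write_registration(reg: Registration, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(reg), indent=1))


def read_registration(path) -> Registration:
    d = json.loads(Path(path).read_text())
    return Registration(
        fovea_mm=tuple(d.get("fovea_mm", (0.0, 0.0))),
        offset_deg=tuple(d.get("offset_deg", (0.0, 0.0))),
        mm_per_degree=float(d.get("mm_per_degree", 0.3)),
        laterality=d.get("laterality", "OD"),
        fovea_field_deg=tuple(d.get("fovea_field_deg", (0.0, 0.0))),
    )


def write_study(study, out_dir) -> None:
    """Write a synthetic study as per-eye directories plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for eye in study.eyes:
        d = out / f"{eye.participant_id}_{eye.laterality}"
        write_exam(eye.exam1, d, exam_index=1)
        write_exam(eye.exam2, d, exam_index=2)
        write_bscan(eye.scan_h, d)
        write_bscan(eye.scan_v, d)
        truth_rows.append(
            {"eye_dir": d.name, **dataclasses.asdict(eye.truth),
             "ez_halfwidth_mm": eye.ez_halfwidth_mm, "age": eye.age}
        )
    (out / "truth.json").write_text(json.dumps(truth_rows, indent=1))
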