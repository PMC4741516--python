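"""Registration of OCT b-scans to the visual field, and hybrid measures.

The field and the retina are linked by anchoring the field center (0,0)
at the fovea, scaling retinal mm to visual degrees, and optionally adding
a small translational offset (misalignments beyond ~3 degrees indicate a
registration failure rather than a correction).  Left-eye scans are
mirrored into the canonical right-eye field frame.  The physiologic blind
spot in the defect surface provides an automated alignment check.

Hybrid measures sample one modality at a landmark defined by the other:
HOV sensitivity/defect (and their radial slopes) at the EZ-edge field
positions, and photoreceptor-complex (REC) thickness at the field position
of the along-scan HOV maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bscan import BScan, layer_profiles
from .perimetry import BLIND_SPOT_CENTER, HOVSurface
from .topography import line_biomarkers

__all__ = [
    "Registration",
    "scan_to_field",
    "field_to_scan",
    "blind_spot_check",
    "hybrid_measures",
    "summarize_hybrid",
    "coefficient_of_variation",
]

MAX_OFFSET_DEG = 3.0  # registration guard: larger manual offsets are suspect


@dataclass(frozen=True)
class Registration:
    """Fovea-anchored field<->retina mapping for one eye."""

    fovea_mm: tuple = (0.0, 0.0)  # fovea lateral position in (H, V) scans
    offset_deg: tuple = (0.0, 0.0)  # manual translational correction
    mm_per_degree: float = 0.3
    laterality: str = "OD"
    fovea_field_deg: tuple = (0.0, 0.0)  # field location of the fovea

    def __post_init__(self) -> None:
        if self.mm_per_degree <= 0:
            raise ValueError("mm_per_degree must be positive")
        if np.hypot(*self.offset_deg) >= MAX_OFFSET_DEG:
            raise ValueError(
                f"offset {self.offset_deg} exceeds the {MAX_OFFSET_DEG} deg guard"
            )


def scan_to_field(scan: BScan, reg: Registration) -> np.ndarray:
    """Map every scan column to canonical field coordinates (degrees).

    A horizontal-scan column at lateral position u maps to
    ((u - fovea)/scale, 0) plus the registration offset; vertical scans
    map analogously onto the y axis.  Left-eye x coordinates are mirrored
    into the right-eye convention.
    """
    axis = 0 if scan.orientation == "H" else 1
    fovea = reg.fovea_mm[axis]
    t = (scan.lateral_mm - fovea) / reg.mm_per_degree
    coords = np.zeros((scan.n_columns, 2))
    coords[:, axis] = t
    coords[:, 0] += reg.fovea_field_deg[0] + reg.offset_deg[0]
    coords[:, 1] += reg.fovea_field_deg[1] + reg.offset_deg[1]
    if reg.laterality == "OS":
        coords[:, 0] *= -1.0
    return coords


def field_to_scan(xy_deg: np.ndarray, orientation: str, reg: Registration) -> np.ndarray:
    """Inverse of :func:`scan_to_field` along one scan's lateral axis."""
    xy = np.atleast_2d(np.asarray(xy_deg, dtype=float)).copy()
    if reg.laterality == "OS":
        xy[:, 0] *= -1.0
    xy[:, 0] -= reg.fovea_field_deg[0] + reg.offset_deg[0]
    xy[:, 1] -= reg.fovea_field_deg[1] + reg.offset_deg[1]
    axis = 0 if orientation == "H" else 1
    return xy[:, axis] * reg.mm_per_degree + reg.fovea_mm[axis]


def blind_spot_check(
    hov_defect: HOVSurface,
    expected_center: tuple = BLIND_SPOT_CENTER,
    window_deg: float = 6.0,
    polygon_radius_deg: float = 3.0,
) -> tuple[bool, tuple]:
    """Verify registration against the physiologic blind spot.

    Looks for the defect local maximum in a window around the expected
    blind-spot location; returns (aligned, suggested_offset) where the
    offset would move the found scotoma onto the expected center.  Raises
    ``LookupError`` when no local maximum stands out (the caller keeps a
    zero offset, mirroring the expected-location fallback).
    """
    cx, cy = expected_center
    xx, yy = hov_defect.meshgrid()
    win = (
        hov_defect.mask
        & (np.abs(xx - cx) <= window_deg)
        & (np.abs(yy - cy) <= window_deg)
    )
    if not win.any():
        raise LookupError("defect surface undefined around the blind spot")
    vals = np.where(win, hov_defect.values, -np.inf)
    i, j = np.unravel_index(np.argmax(vals), vals.shape)
    peak = vals[i, j]
    background = float(np.median(hov_defect.values[win]))
    if peak - background < 1.0:  # dB; no discernible natural scotoma
        raise LookupError("no discernible blind-spot scotoma")
    found = (float(xx[i, j]), float(yy[i, j]))
    suggested = (cx - found[0], cy - found[1])
    aligned = bool(np.hypot(*suggested) <= polygon_radius_deg)
    return aligned, suggested


def _radial_slope_at(surface: HOVSurface, x: float, y: float) -> float:
    """Radial first derivative (dB/deg) at one field point, central diff."""
    h = surface.spacing
    r = float(np.hypot(x, y))
    if r < h:
        return 0.0
    ux, uy = x / r, y / r
    s1 = float(surface.sample(x + ux * h, y + uy * h))
    s0 = float(surface.sample(x - ux * h, y - uy * h))
    return (s1 - s0) / (2.0 * h)


@dataclass(frozen=True)
class HybridMeasures:
    """Per-eye hybrid structure-function record (H/V combined by mean)."""

    sens_at_ez_edge: float  # dB
    defect_at_ez_edge: float  # dB
    slope_at_ez_edge: float  # dB/deg, sensitivity surface
    defect_slope_at_ez_edge: float  # dB/deg, defect surface
    rec_at_hov_max: float  # um
    rec_at_defect_max: float  # um

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _ez_edge_field_points(scan: BScan, reg: Registration) -> list:
    depth = scan.boundaries["EZ"]
    ok = np.flatnonzero(np.isfinite(depth))
    if len(ok) == 0:
        raise ValueError("EZ band is nowhere defined")
    coords = scan_to_field(scan, reg)
    return [tuple(coords[ok[0]]), tuple(coords[ok[-1]])]


def _rec_at_field_point(scan: BScan, reg: Registration, xy: tuple) -> float:
    u = float(field_to_scan(np.array([xy]), scan.orientation, reg)[0])
    prof = layer_profiles(scan)["REC"]
    i = int(np.argmin(np.abs(scan.lateral_mm - u)))
    return float(prof[i])


def hybrid_measures(
    hov: HOVSurface,
    defect: HOVSurface,
    scans: dict,
    reg: Registration,
    line_extent_deg: float = 15.0,
) -> HybridMeasures:
    """Compute the per-eye hybrid measures from registered H and V scans.

    Sensitivity, defect and their radial slopes are sampled at the four
    EZ-edge field positions (two per scan) and averaged; REC thickness is
    sampled at the field position of the along-scan local HOV maximum
    (and defect maximum) of each scan, then averaged over H and V.
    """
    edge_pts = []
    for scan in scans.values():
        edge_pts.extend(_ez_edge_field_points(scan, reg))
    for x, y in edge_pts:
        if not hov.defined(x, y):
            raise ValueError(f"EZ edge at field ({x:.1f},{y:.1f}) is outside the HOV")

    sens = float(np.mean([hov.sample(x, y) for x, y in edge_pts]))
    dfct = float(np.mean([defect.sample(x, y) for x, y in edge_pts]))
    slope = float(np.mean([_radial_slope_at(hov, x, y) for x, y in edge_pts]))
    dslope = float(np.mean([_radial_slope_at(defect, x, y) for x, y in edge_pts]))

    rec_at_smax, rec_at_dmax = [], []
    for scan in scans.values():
        for surface, acc in ((hov, rec_at_smax), (defect, rec_at_dmax)):
            lb = line_biomarkers(surface, scan.orientation, extent=line_extent_deg)
            axis = 0 if scan.orientation == "H" else 1
            # recover the signed position of the line maximum
            t = lb.max_distance
            cand = []
            for sgn in (+1, -1):
                xy = [0.0, 0.0]
                xy[axis] = sgn * t
                cand.append((float(surface.sample(*xy)), tuple(xy)))
            xy = max(cand)[1]
            acc.append(_rec_at_field_point(scan, reg, xy))
    return HybridMeasures(
        sens_at_ez_edge=sens,
        defect_at_ez_edge=dfct,
        slope_at_ez_edge=slope,
        defect_slope_at_ez_edge=dslope,
        rec_at_hov_max=float(np.mean(rec_at_smax)),
        rec_at_defect_max=float(np.mean(rec_at_dmax)),
    )


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV = sd / |mean|; the magnitude keeps CVs of negative means positive."""
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return sd / abs(mean)


def summarize_hybrid(records: list) -> "pd.DataFrame":
    """Cohort-level mean, SD and CV of each hybrid measure across eyes."""
    import pandas as pd

    df = pd.DataFrame([r.as_dict() if isinstance(r, HybridMeasures) else r for r in records])
    rows = []
    for col in df.columns:
        m, s = float(df[col].mean()), float(df[col].std(ddof=1))
        rows.append(
            {"measure": col, "mean": m, "sd": s,
             "cv": coefficient_of_variation(m, s) if m != 0 else np.nan}
        )
    return pd.DataFrame(rows)
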