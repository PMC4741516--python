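"""Structural biomarkers from segmented OCT b-scan boundary traces.

A b-scan arrives as four boundary depth profiles — distal inner nuclear
layer border (INL), external limiting membrane (ELM), ellipsoid zone (EZ)
and proximal RPE border (pRPE) — sampled along the lateral axis in mm,
with depth in micrometers increasing posteriorly from an arbitrary
reference (all biomarkers are differences, so the reference cancels).
The composite outer-retina layers are boundary pairs:

    ONL+  = ELM - INL      (outer nuclear + Henle fiber + outer plexiform)
    OS+   = pRPE - EZ      (outer segment + interdigitation zone)
    ISOS+ = pRPE - ELM     (inner segment + OS+)
    REC   = pRPE - INL     (total photoreceptor complex)

The EZ and ELM traces may be undefined (NaN) over sub-ranges; band width
is the physical length of the segment joining the outermost defined
columns.  The fovea is the point of maximum posterior displacement of the
smoothed INL boundary, and curvature can be removed by a cubic-polynomial
flattening of the pRPE that shifts whole columns and therefore leaves
every thickness profile bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BScan",
    "SegmentationError",
    "LAYER_BOUNDARIES",
    "layer_profiles",
    "thickness_summaries",
    "band_width",
    "locate_fovea",
    "flatten",
    "structural_biomarkers",
]

BOUNDARY_NAMES = ("INL", "ELM", "EZ", "pRPE")

#: Composite layer -> (proximal boundary, distal boundary)
LAYER_BOUNDARIES = {
    "ONL": ("INL", "ELM"),
    "OS": ("EZ", "pRPE"),
    "ISOS": ("ELM", "pRPE"),
    "REC": ("INL", "pRPE"),
}


class SegmentationError(ValueError):
    """Boundary traces violate the proximal-to-distal ordering."""


class FoveaUndefinedError(RuntimeError):
    """No foveal depression found in the scan."""


@dataclass(frozen=True)
class BScan:
    """One OCT line scan with segmented boundary depth profiles."""

    orientation: str  # H | V
    lateral_mm: np.ndarray  # (n,) monotone lateral positions
    boundaries: dict  # name -> (n,) depth in um; NaN = undefined
    mm_per_degree: float = 0.3
    um_per_px_axial: float = 3.9
    laterality: str = "OD"
    fovea_hint_mm: float | None = None
    #: per-column flattening shift (um, subtracted from every boundary).
    #: Kept separate from the raw traces so that thickness — always a
    #: within-column difference — is exactly invariant under flattening.
    axial_shift_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("H", "V"):
            raise ValueError("orientation must be 'H' or 'V'")
        lat = np.asarray(self.lateral_mm, dtype=float)
        if lat.ndim != 1 or len(lat) < 4 or np.any(np.diff(lat) <= 0):
            raise ValueError("lateral_mm must be a monotone 1-D array, n >= 4")
        object.__setattr__(self, "lateral_mm", lat)
        bnd = {k: np.asarray(v, dtype=float) for k, v in self.boundaries.items()}
        for name in BOUNDARY_NAMES:
            if name not in bnd:
                raise ValueError(f"missing boundary trace {name!r}")
            if bnd[name].shape != lat.shape:
                raise ValueError(f"boundary {name!r} does not align with lateral axis")
        object.__setattr__(self, "boundaries", bnd)
        if self.axial_shift_um is not None:
            shift = np.asarray(self.axial_shift_um, dtype=float)
            if shift.shape != lat.shape:
                raise ValueError("axial_shift_um must align with the lateral axis")
            object.__setattr__(self, "axial_shift_um", shift)
        self._check_ordering()

    def _check_ordering(self) -> None:
        stack = [self.boundaries[n] for n in BOUNDARY_NAMES]
        for upper, lower, un, ln in zip(stack, stack[1:], BOUNDARY_NAMES, BOUNDARY_NAMES[1:]):
            both = np.isfinite(upper) & np.isfinite(lower)
            bad = both & (upper > lower + 1e-9)
            if bad.any():
                col = int(np.argmax(bad))
                raise SegmentationError(
                    f"boundary order {un} <= {ln} violated at column {col} "
                    f"(lateral {self.lateral_mm[col]:.3f} mm)"
                )

    def depth(self, name: str) -> np.ndarray:
        """Effective boundary depth (um) with any flattening shift applied."""
        d = self.boundaries[name]
        return d if self.axial_shift_um is None else d - self.axial_shift_um

    @property
    def n_columns(self) -> int:
        return len(self.lateral_mm)

    @property
    def extent_mm(self) -> float:
        return float(self.lateral_mm[-1] - self.lateral_mm[0])


def layer_profiles(scan: BScan) -> dict:
    """Thickness-vs-lateral-position profile (um) for each composite layer.

    NaN where either bounding trace is undefined.
    """
    out = {}
    for layer, (prox, dist) in LAYER_BOUNDARIES.items():
        out[layer] = scan.boundaries[dist] - scan.boundaries[prox]
    return out


def thickness_summaries(
    profiles: dict, lateral_mm: np.ndarray, fovea_mm: float
) -> dict:
    """AVG / FOV / MAX summaries per layer.

    AVG = mean over defined columns, FOV = value at the column nearest the
    fovea, MAX = maximum over defined columns.  FOV is NaN if the profile
    is undefined at the foveal column.
    """
    lateral_mm = np.asarray(lateral_mm, dtype=float)
    if not lateral_mm[0] - 1e-9 <= fovea_mm <= lateral_mm[-1] + 1e-9:
        raise ValueError("fovea position lies outside the scan")
    i_fov = int(np.argmin(np.abs(lateral_mm - fovea_mm)))
    out = {}
    for layer, prof in profiles.items():
        ok = np.isfinite(prof)
        if not ok.any():
            out[layer] = {"AVG": np.nan, "FOV": np.nan, "MAX": np.nan}
            continue
        out[layer] = {
            "AVG": float(np.mean(prof[ok])),
            "FOV": float(prof[i_fov]) if ok[i_fov] else np.nan,
            "MAX": float(np.max(prof[ok])),
        }
    return out


def band_width(scan: BScan, band: str = "EZ") -> tuple[float, bool]:
    """Width of the EZ or ELM band and whether the scan edge truncates it.

    The endpoints are the outermost columns where the band is defined
    (interior gaps are spanned, not subtracted); the width is the
    Euclidean length in mm of the segment joining the two endpoint points,
    including any axial offset between them.
    """
    if band not in ("EZ", "ELM"):
        raise ValueError("band must be 'EZ' or 'ELM'")
    depth = scan.depth(band)
    ok = np.flatnonzero(np.isfinite(depth))
    if len(ok) == 0:
        raise ValueError(f"{band} band is nowhere defined")
    i0, i1 = ok[0], ok[-1]
    dx = scan.lateral_mm[i1] - scan.lateral_mm[i0]
    dz = (depth[i1] - depth[i0]) / 1000.0  # um -> mm
    truncated = bool(i0 == 0 or i1 == scan.n_columns - 1)
    return float(np.hypot(dx, dz)), truncated


def locate_fovea(scan: BScan, smoothing_window_mm: float = 0.15) -> float:
    """Fovea as the maximum posterior displacement of the INL boundary.

    The INL trace is smoothed by a moving average, then the candidate
    depressions are its interior local depth maxima with prominence above
    ``min_prominence_um``; the curvature sign (second difference) at the
    candidate must confirm a pit.  This rejects the scan-edge depth
    maxima that retinal curvature alone produces.  Ties and multiple pits
    resolve toward the scan center.  A flat trace raises
    ``FoveaUndefinedError`` so callers can fall back on
    ``fovea_hint_mm``.
    """
    inl = scan.depth("INL")
    if not np.isfinite(inl).all():
        raise SegmentationError("INL trace must be fully defined to locate the fovea")
    step = float(np.median(np.diff(scan.lateral_mm)))
    win = max(1, int(round(smoothing_window_mm / step)))
    kernel = np.ones(win) / win
    smooth = np.convolve(inl, kernel, mode="same")
    s = smooth[win : -win] if len(smooth) > 2 * win + 2 else smooth
    lat = scan.lateral_mm[win : -win] if len(smooth) > 2 * win + 2 else scan.lateral_mm
    interior = np.zeros(len(s), dtype=bool)
    interior[1:-1] = (s[1:-1] >= s[:-2]) & (s[1:-1] >= s[2:])
    # curvature-sign validation: a pit has locally decreasing slope of depth
    d2 = np.zeros(len(s))
    d2[1:-1] = s[2:] - 2 * s[1:-1] + s[:-2]
    interior[1:-1] &= d2[1:-1] <= 0
    cand = np.flatnonzero(interior)
    min_prominence_um = 5.0
    good = []
    for i in cand:
        lo = s[max(0, i - 4 * win) : i + 1].min()
        hi = s[i : i + 4 * win + 1].min()
        if s[i] - max(lo, hi) >= min_prominence_um:
            good.append(i)
    if not good:
        raise FoveaUndefinedError("no foveal depression found in INL trace")
    center = 0.5 * (scan.lateral_mm[0] + scan.lateral_mm[-1])
    best = min(good, key=lambda i: abs(lat[i] - center))
    return float(lat[best])


def fovea_or_hint(scan: BScan, **kwargs) -> float:
    """locate_fovea with fallback to the scan's fovea hint."""
    try:
        return locate_fovea(scan, **kwargs)
    except (FoveaUndefinedError, SegmentationError):
        if scan.fovea_hint_mm is not None:
            return scan.fovea_hint_mm
        raise


def flatten(scan: BScan) -> BScan:
    """Remove retinal curvature via a cubic fit to the pRPE boundary.

    A least-squares cubic polynomial is fitted to the pRPE depths and
    every boundary at column x is shifted vertically by
    -(fit(x) - mean(fit)).  The shift is carried as the scan's
    ``axial_shift_um`` field: because thickness is always a within-column
    boundary difference, this representation makes thickness profiles
    exactly (bit-for-bit) invariant under flattening, while effective
    depths — band-width endpoints, fovea search — see the flattened
    geometry.  Only the fit residuals survive as pRPE curvature.
    """
    prpe = scan.depth("pRPE")
    ok = np.isfinite(prpe)
    if ok.sum() < 4:
        raise ValueError("need >= 4 defined pRPE columns for a cubic fit")
    if np.ptp(scan.lateral_mm[ok]) <= 0:
        raise ValueError("degenerate lateral positions for the cubic fit")
    coeffs = np.polyfit(scan.lateral_mm[ok], prpe[ok], deg=3)
    fit = np.polyval(coeffs, scan.lateral_mm)
    shift = fit - np.mean(fit[ok])
    prev = scan.axial_shift_um if scan.axial_shift_um is not None else 0.0
    return replace(scan, axial_shift_um=prev + shift)


def structural_biomarkers(
    scan: BScan, apply_flatten: bool = False, fovea_mm: float | None = None
) -> dict:
    """All per-scan structural biomarkers as a flat dict.

    Keys follow the ``T_<layer>_<summary>`` / ``W_<band>`` convention with
    the scan orientation appended by the caller (the pipeline joins H and
    V records).  ``fovea_mm`` overrides fovea localization (e.g. from the
    orthogonal scan's estimate).
    """
    if apply_flatten:
        scan = flatten(scan)
    if fovea_mm is None:
        fovea_mm = fovea_or_hint(scan)
    profiles = layer_profiles(scan)
    summ = thickness_summaries(profiles, scan.lateral_mm, fovea_mm)
    w_ez, ez_trunc = band_width(scan, "EZ")
    w_elm, elm_trunc = band_width(scan, "ELM")
    out: dict = {"fovea_mm": fovea_mm}
    for layer in LAYER_BOUNDARIES:
        for stat in ("FOV", "AVG", "MAX"):
            out[f"T_{layer}_{stat}"] = summ[layer][stat]
    out.update(
        W_EZ=w_ez, ez_truncated=ez_trunc, W_ELM=w_elm, elm_truncated=elm_trunc
    )
    return out
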