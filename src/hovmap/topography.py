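"""Topographic functional biomarkers of the hill of vision.

Volumes are solid-angle integrals (dB.sr) over the visual field treated as
a sphere of directions; maxima carry their radial distance from fixation;
and the slope contour captures where the field transitions most rapidly
from preserved center to depressed periphery: along each of ``n_spokes``
radial spokes the extremum of the radial first derivative is located, and
the contour is summarized by its mean/max slope value and mean/max radial
distance.  For a sensitivity surface the extremum is the most negative
slope; for a defect surface, the most positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .perimetry import HOVSurface

__all__ = [
    "SlopeContour",
    "ContourUndefinedError",
    "hov_volume",
    "hov_max",
    "radial_slope_contour",
    "slope_summaries",
    "line_biomarkers",
    "LineBiomarkers",
]

DEFAULT_N_SPOKES = 501  # even angular sampling: 360/501 ~ 0.72 deg apart
DEFAULT_SLOPE_FLOOR = 0.05  # dB/deg; smaller extrema mean "no transition"


class ContourUndefinedError(RuntimeError):
    """No spoke carried a discernible slope transition."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def _solid_angle_weights(surface: HOVSurface) -> np.ndarray:
    """Per-cell solid angle (sr) under the azimuthal-equidistant mapping.

    A cell at eccentricity theta (radians) subtends
    dOmega = (pi/180)^2 * sinc-like factor (sin theta / theta) * spacing^2,
    which integrates a spherical cap exactly in the refinement limit.
    """
    theta = np.deg2rad(surface.eccentricity())
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(theta > 0, np.sin(theta) / np.where(theta > 0, theta, 1.0), 1.0)
    return (np.pi / 180.0) ** 2 * ratio * surface.spacing**2


def hov_volume(surface: HOVSurface, max_eccentricity: float | None = None) -> float:
    """Riemann-sum HOV volume in dB.steradian.

    Cells outside the surface's defined domain are excluded; if
    ``max_eccentricity`` is given, integration is restricted to the disc
    of that radius (degrees) about fixation — e.g. 30 for the central
    volume.
    """
    sel = surface.mask
    if max_eccentricity is not None:
        sel = sel & (surface.eccentricity() <= max_eccentricity)
    if not sel.any():
        raise ValueError("volume domain is empty")
    w = _solid_angle_weights(surface)
    return float(np.sum(surface.values[sel] * w[sel]))


def hov_max(surface: HOVSurface) -> tuple[float, float]:
    """Maximum surface value and its radial distance from fixation.

    Ties are broken toward the smallest distance, then the smallest
    azimuthal angle in [0, 2pi).
    """
    sel = surface.mask
    if not sel.any():
        raise ValueError("surface has no defined cells")
    vals = surface.values[sel]
    xx, yy = surface.meshgrid()
    xs, ys = xx[sel], yy[sel]
    vmax = vals.max()
    at_max = np.isclose(vals, vmax, rtol=0, atol=1e-12)
    dists = np.hypot(xs[at_max], ys[at_max])
    angles = np.mod(np.arctan2(ys[at_max], xs[at_max]), 2.0 * np.pi)
    order = np.lexsort((angles, dists))
    return float(vmax), float(dists[order[0]])


@dataclass
class SlopeContour:
    """Per-spoke radial-gradient extrema around the HOV center.

    ``extremum_slope`` is signed (dB/degree); spokes whose extremum falls
    below the validity floor, or which never enter the search annulus, are
    flagged invalid and excluded from all summaries.
    """

    spoke_angles: np.ndarray  # degrees, length n
    extremum_slope: np.ndarray  # dB/degree, signed
    extremum_distance: np.ndarray  # degrees from fixation
    valid: np.ndarray  # bool
    kind: str  # sensitivity | defect

    def __post_init__(self) -> None:
        if len(self.spoke_angles) < 8:
            raise ValueError("a slope contour needs at least 8 spokes")

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))


def radial_slope_contour(
    surface: HOVSurface,
    kind: str | None = None,
    n_spokes: int = DEFAULT_N_SPOKES,
    search_radius: float = 30.0,
    min_radius: float | None = None,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
) -> SlopeContour:
    """Locate the radial-gradient extremum along each spoke.

    Each spoke is sampled at the grid spacing by bicubic interpolation;
    the radial derivative is a central difference with step equal to the
    spacing.  The search runs over [min_radius, min(search_radius, hull
    exit)].  ``kind`` defaults to the surface's own kind and decides the
    extremum sense (most negative for sensitivity, most positive for
    defect).
    """
    kind = kind or surface.kind
    if kind == "normal":
        kind = "sensitivity"
    if kind not in ("sensitivity", "defect"):
        raise ValueError(f"unknown contour kind {kind!r}")
    if n_spokes < 8:
        raise ValueError("need at least 8 spokes")
    h = surface.spacing
    if min_radius is None:
        min_radius = h
    if min_radius < h:
        raise ValueError("min_radius must be at least one grid step")

    angles = np.arange(n_spokes) * (360.0 / n_spokes)
    radii = np.arange(min_radius, search_radius + 1e-9, h)
    slope, dist, valid = _spoke_extrema(
        surface, np.deg2rad(angles), radii, h, kind, slope_floor
    )
    if not valid.any():
        raise ContourUndefinedError(
            "no spoke shows a slope transition above the floor",
            diagnostics={
                "slope_floor": slope_floor,
                "max_abs_slope": float(np.nanmax(np.abs(slope)))
                if np.isfinite(slope).any()
                else 0.0,
                "n_spokes": n_spokes,
            },
        )
    return SlopeContour(
        spoke_angles=angles, extremum_slope=slope,
        extremum_distance=dist, valid=valid, kind=kind,
    )


def _spoke_extrema(surface, angles_rad, radii, h, kind, slope_floor):
    """Vectorized per-spoke extremum search; returns (slope, dist, valid)."""
    ca, sa = np.cos(angles_rad)[:, None], np.sin(angles_rad)[:, None]
    r = radii[None, :]
    # central-difference radial derivative at every (spoke, radius) sample
    s_out = surface.sample(ca * (r + h), sa * (r + h))
    s_in = surface.sample(ca * (r - h), sa * (r - h))
    deriv = (s_out - s_in) / (2.0 * h)
    ok = (
        surface.defined(ca * (r + h), sa * (r + h))
        & surface.defined(ca * r, sa * r)
        & surface.defined(ca * (r - h), sa * (r - h))
    )
    # stop each spoke at its first exit from the defined domain
    ok = np.logical_and.accumulate(ok, axis=1)
    score = deriv if kind == "defect" else -deriv  # maximize
    score = np.where(ok, score, -np.inf)
    idx = np.argmax(score, axis=1)
    rows = np.arange(len(angles_rad))
    best = score[rows, idx]
    slope = np.where(np.isfinite(best), deriv[rows, idx], np.nan)
    dist = np.where(np.isfinite(best), radii[idx], np.nan)
    # parabolic sub-step refinement of the extremum location and value,
    # removing the half-step quantization of the radial sampling
    interior = np.isfinite(best) & (idx > 0) & (idx < len(radii) - 1)
    i = idx[interior]
    r_i = rows[interior]
    s_m, s_0, s_p = (score[r_i, i - 1], score[r_i, i], score[r_i, i + 1])
    refine = np.isfinite(s_m) & np.isfinite(s_p)
    denom = s_m - 2 * s_0 + s_p
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(refine & (np.abs(denom) > 1e-12),
                         0.5 * (s_m - s_p) / denom, 0.0)
    delta = np.clip(delta, -1.0, 1.0)
    vertex = s_0 - 0.25 * (s_m - s_p) * delta
    sgn = 1.0 if kind == "defect" else -1.0
    slope[interior] = sgn * vertex
    dist[interior] = dist[interior] + delta * h
    valid = np.isfinite(best) & (best >= slope_floor)
    return slope, dist, valid


def slope_summaries(contour: SlopeContour) -> tuple[float, float, float, float]:
    """Summarize a contour: (slope_max, d_slope_max, slope_avg, d_slope_avg).

    "max" is the extreme slope over valid spokes (most negative for a
    sensitivity contour, most positive for defect) with its spoke's radial
    distance; "avg" is the mean slope and mean distance over valid spokes.
    """
    if contour.n_valid == 0:
        raise ContourUndefinedError("contour has no valid spokes")
    s = contour.extremum_slope[contour.valid]
    d = contour.extremum_distance[contour.valid]
    i = int(np.argmax(s)) if contour.kind == "defect" else int(np.argmin(s))
    return float(s[i]), float(d[i]), float(np.mean(s)), float(np.mean(d))


@dataclass(frozen=True)
class LineBiomarkers:
    """Local (along one scan line) functional biomarkers for one surface."""

    max_value: float  # dB
    max_distance: float  # degrees from fixation, along the line
    slope_avg: float | None  # dB/degree, mean of the two collinear spokes
    d_slope_avg: float | None  # degrees
    orientation: str  # H | V


def line_biomarkers(
    surface: HOVSurface,
    orientation: str,
    kind: str | None = None,
    extent: float = 15.0,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
    min_radius: float | None = None,
) -> LineBiomarkers:
    """Biomarkers restricted to the scan line through fixation.

    The 1-D profile along the horizontal (H) or vertical (V) line is
    sampled at the grid spacing over +/- ``extent`` degrees; the maximum
    and its distance are read off the profile, and the local slope values
    are the mean over exactly the two opposing spokes collinear with the
    line (when both carry a valid transition; None otherwise).
    """
    if orientation not in ("H", "V"):
        raise ValueError("orientation must be 'H' or 'V'")
    kind = kind or surface.kind
    h = surface.spacing
    n = int(np.floor(extent / h))
    t = np.arange(-n, n + 1) * h  # symmetric, includes fixation exactly
    x, y = (t, np.zeros_like(t)) if orientation == "H" else (np.zeros_like(t), t)
    ok = surface.defined(x, y)
    if not ok.any():
        raise ValueError("scan line lies outside the surface domain")
    prof = np.where(ok, surface.sample(x, y), -np.inf)
    vmax = prof.max()
    at_max = np.isclose(prof, vmax, rtol=0, atol=1e-12)
    dist = float(np.min(np.abs(t[at_max])))

    # the two collinear spokes: 0/180 deg for H, 90/270 deg for V
    base = 0.0 if orientation == "H" else 90.0
    angles = np.deg2rad(np.array([base, base + 180.0]))
    if min_radius is None:
        min_radius = h
    radii = np.arange(min_radius, extent + 1e-9, h)
    slope, sdist, valid = _spoke_extrema(surface, angles, radii, h, kind, slope_floor)
    if valid.any():
        s_avg = float(np.mean(slope[valid]))
        d_avg = float(np.mean(sdist[valid]))
    else:
        s_avg = d_avg = None
    return LineBiomarkers(
        max_value=float(vmax), max_distance=dist,
        slope_avg=s_avg, d_slope_avg=d_avg, orientation=orientation,
    )
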