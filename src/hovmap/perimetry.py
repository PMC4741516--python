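"""Static perimetry ingestion and hill-of-vision (HOV) surface construction.

A full-field static perimetry exam measures differential luminance
sensitivity (DLS, in dB) at a sparse set of visual-field locations.  This
module combines duplicate exams, interpolates the scattered measurements
onto a dense uniform grid with a thin-plate-spline radial basis function
(yielding the HOV surface), evaluates a slowly varying age-adjusted normal
surface, forms the defect surface (normal minus patient), and computes the
classical global indices MS/MD/LV from the raw test points.

All surfaces live in a canonical right-eye field frame: left-eye data are
mirrored (x -> -x) at ingestion so that, e.g., the physiologic blind spot
always sits on the positive-x side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator, RectBivariateSpline
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "TestGrid",
    "FieldExam",
    "HOVSurface",
    "NormalFieldModel",
    "combine_exams",
    "interpolate_hov",
    "defect_hov",
    "global_indices",
]

#: Expected field location of the physiologic blind spot in the canonical
#: right-eye frame (degrees); the optic disc sits nasally, hence +x.
BLIND_SPOT_CENTER = (15.0, -1.5)


class PerimetryError(ValueError):
    """Invalid perimetry input (geometry, weights, or degenerate system)."""


@dataclass(frozen=True)
class TestGrid:
    """Scattered perimetry test locations, in visual-field degrees."""

    points: np.ndarray  # (n, 2) float array of (x, y) degrees
    laterality: str = "OD"  # OD = right eye, OS = left eye
    blind_spot_polygon: np.ndarray | None = None  # optional (m, 2) degrees

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise PerimetryError("grid points must be an (n, 2) array")
        if len(np.unique(pts.round(9), axis=0)) != len(pts):
            raise PerimetryError("grid points must be unique")
        object.__setattr__(self, "points", pts)
        if self.laterality not in ("OD", "OS"):
            raise PerimetryError(f"laterality must be OD or OS, got {self.laterality!r}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def mirrored(self) -> "TestGrid":
        """Reflect the grid across the vertical midline (x -> -x)."""
        pts = self.points * np.array([-1.0, 1.0])
        poly = None
        if self.blind_spot_polygon is not None:
            poly = np.asarray(self.blind_spot_polygon) * np.array([-1.0, 1.0])
        lat = "OS" if self.laterality == "OD" else "OD"
        return TestGrid(pts, laterality=lat, blind_spot_polygon=poly)


@dataclass(frozen=True)
class FieldExam:
    """One perimetry exam: a grid, DLS values, and its reliability factor.

    ``rf`` is the percentage of failed catch trials (0 = perfectly
    reliable); it drives the weighting when duplicate exams are merged.
    """

    grid: TestGrid
    dls: np.ndarray  # dB, aligned with grid.points
    rf: float = 0.0  # percent, 0..100
    age: float = 50.0  # years
    participant_id: str = "anon"

    def __post_init__(self) -> None:
        dls = np.asarray(self.dls, dtype=float)
        if dls.shape != (self.grid.n_points,):
            raise PerimetryError("dls length must match the grid")
        if np.any(dls < 0):
            raise PerimetryError("DLS values must be >= 0 dB")
        if not 0.0 <= self.rf <= 100.0:
            raise PerimetryError("RF must be in [0, 100] percent")
        object.__setattr__(self, "dls", dls)

    def to_canonical(self) -> "FieldExam":
        """Mirror left-eye exams into the right-eye field convention."""
        if self.grid.laterality == "OD":
            return self
        return replace(self, grid=self.grid.mirrored())


def combine_exams(exam1: FieldExam, exam2: FieldExam) -> FieldExam:
    """Merge duplicate exams by the reliability-weighted arithmetic mean.

    Each exam's weight is ``100 - RF`` so that less reliable exams (more
    failed catch trials) contribute less.  The combined RF is the plain
    mean of the two RFs and is used only for reporting.
    """
    if exam1.grid.laterality != exam2.grid.laterality:
        raise PerimetryError("exams must come from the same eye")
    if not np.allclose(exam1.grid.points, exam2.grid.points):
        raise PerimetryError("exams must share the same test grid")
    w1, w2 = 100.0 - exam1.rf, 100.0 - exam2.rf
    if w1 + w2 <= 0:
        raise PerimetryError("both exams have RF=100: zero total weight")
    dls = (w1 * exam1.dls + w2 * exam2.dls) / (w1 + w2)
    return replace(exam1, dls=dls, rf=0.5 * (exam1.rf + exam2.rf))


@dataclass
class HOVSurface:
    """A dense sensitivity / defect / normal surface on a uniform degree grid.

    ``values`` is NaN outside the source grid's convex hull, where the
    thin-plate-spline interpolant is extrapolatory and undefined by policy.
    A full (unmasked) value array backs the bicubic sampler so that
    interpolation near the hull boundary never mixes in NaNs; callers must
    gate samples through :meth:`defined`.
    """

    x: np.ndarray  # (nx,) grid x coordinates, degrees
    y: np.ndarray  # (ny,) grid y coordinates, degrees
    values: np.ndarray  # (ny, nx), NaN outside hull
    kind: str = "sensitivity"  # sensitivity | defect | normal
    laterality: str = "OD"
    _values_full: np.ndarray | None = None
    _hull: Delaunay | None = field(default=None, repr=False)
    #: exact source interpolant (the TPS), kept so node-exact evaluation
    #: does not pass through the gridded bicubic resampler
    interpolant: Callable | None = field(default=None, repr=False)
    _spline: RectBivariateSpline | None = field(default=None, repr=False, init=False)

    def __post_init__(self) -> None:
        if self.kind not in ("sensitivity", "defect", "normal"):
            raise PerimetryError(f"unknown surface kind {self.kind!r}")
        if self._values_full is None:
            self._values_full = np.array(self.values)
        if np.isnan(self._values_full).any():
            raise PerimetryError("backing value array must be fully defined")

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def mask(self) -> np.ndarray:
        """Boolean (ny, nx) array: True where the surface is defined."""
        return ~np.isnan(self.values)

    def _get_spline(self) -> RectBivariateSpline:
        if self._spline is None:
            self._spline = RectBivariateSpline(
                self.y, self.x, self._values_full, kx=3, ky=3
            )
        return self._spline

    def sample(self, x, y):
        """Bicubic sample at field coordinates (degrees); not hull-gated."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return self._get_spline().ev(y, x)

    def evaluate(self, x, y):
        """Evaluate through the exact source interpolant when available.

        Falls back to the bicubic sample for surfaces that only exist as
        gridded values.  Use this for node-exactness checks and wherever
        resampling error matters.
        """
        if self.interpolant is None:
            return self.sample(x, y)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        pts = np.column_stack([np.ravel(x), np.ravel(y)])
        return np.asarray(self.interpolant(pts)).reshape(np.shape(x))

    def defined(self, x, y):
        """True where (x, y) lies inside the surface's valid domain."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = (
            (x >= self.x[0]) & (x <= self.x[-1]) & (y >= self.y[0]) & (y <= self.y[-1])
        )
        if self._hull is not None:
            pts = np.column_stack([np.ravel(x), np.ravel(y)])
            in_hull = self._hull.find_simplex(pts) >= 0
            inside = inside & in_hull.reshape(np.shape(x))
        return inside

    def meshgrid(self):
        return np.meshgrid(self.x, self.y)

    def eccentricity(self) -> np.ndarray:
        xx, yy = self.meshgrid()
        return np.hypot(xx, yy)

    @classmethod
    def from_function(
        cls,
        fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
        span: float = 60.0,
        spacing: float = 0.36,
        kind: str = "sensitivity",
        span_y: float | None = None,
    ) -> "HOVSurface":
        """Build an analytic surface (no hull restriction) for synthesis/tests."""
        span_y = span if span_y is None else span_y
        x = _axis(span, spacing)
        y = _axis(span_y, spacing)
        xx, yy = np.meshgrid(x, y)
        vals = np.asarray(fn(xx, yy), dtype=float)
        return cls(x=x, y=y, values=vals, kind=kind)


def _axis(span: float, spacing: float) -> np.ndarray:
    half = span / 2.0
    n = int(np.floor(half / spacing))
    return np.arange(-n, n + 1) * spacing


def interpolate_hov(
    exam: FieldExam, spacing: float = 0.36, kind: str = "sensitivity"
) -> HOVSurface:
    """Interpolate scattered DLS onto a uniform grid: the HOV surface.

    Uses an exact (smoothing = 0) thin-plate-spline radial basis function,
    phi(r) = r^2 log r, plus an affine term; the interpolant reproduces the
    measured DLS at every test location and reproduces affine data exactly.
    The surface is undefined outside the convex hull of the test grid.
    """
    exam = exam.to_canonical()
    pts = exam.grid.points
    if len(pts) < 3:
        raise PerimetryError("need at least 3 grid points to interpolate")
    try:
        hull = Delaunay(pts)
    except QhullError as exc:  # collinear or degenerate point sets
        raise PerimetryError(f"degenerate test grid: {exc}") from exc
    try:
        rbf = RBFInterpolator(pts, exam.dls, kernel="thin_plate_spline", degree=1)
    except np.linalg.LinAlgError as exc:
        raise PerimetryError(f"singular interpolation system: {exc}") from exc

    x = _axis(2.0 * np.abs(pts[:, 0]).max(), spacing)
    y = _axis(2.0 * np.abs(pts[:, 1]).max(), spacing)
    xx, yy = np.meshgrid(x, y)
    flat = np.column_stack([xx.ravel(), yy.ravel()])
    full = rbf(flat).reshape(xx.shape)
    inside = hull.find_simplex(flat) >= 0
    vals = np.where(inside.reshape(xx.shape), full, np.nan)
    return HOVSurface(
        x=x, y=y, values=vals, kind=kind, laterality="OD",
        _values_full=full, _hull=hull, interpolant=rbf,
    )


@dataclass(frozen=True)
class NormalFieldModel:
    """Age-adjusted normal hill of vision.

    N(x, y; age) = n0 - k1*ecc - k2*ecc^2 - s_age*max(0, age - age0),
    a radially symmetric surface that is nearly flat centrally, declines
    slowly with eccentricity, and loses sensitivity linearly with age past
    ``age0``.  Defaults approximate normative size-V full-field values.
    """

    n0: float = 32.0  # dB at fixation for a reference-age eye
    k1: float = 0.05  # dB per degree of eccentricity
    k2: float = 0.0004  # dB per degree^2
    s_age: float = 0.05  # dB lost per year beyond age0
    age0: float = 45.0  # years

    def at(self, x, y, age: float) -> np.ndarray:
        if age < 0:
            raise PerimetryError("age must be >= 0")
        ecc = np.hypot(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        decline = self.s_age * max(0.0, age - self.age0)
        return self.n0 - self.k1 * ecc - self.k2 * ecc**2 - decline

    def surface(self, age: float, like: HOVSurface) -> HOVSurface:
        """Evaluate the normal model on the geometry (and hull) of ``like``."""
        xx, yy = like.meshgrid()
        full = self.at(xx, yy, age)
        vals = np.where(like.mask, full, np.nan)
        return HOVSurface(
            x=like.x, y=like.y, values=vals, kind="normal",
            laterality=like.laterality, _values_full=full, _hull=like._hull,
        )


def defect_hov(normal: HOVSurface, patient: HOVSurface) -> HOVSurface:
    """Pointwise defect surface: normal minus patient sensitivity.

    Positive values are sensitivity loss; supranormal (negative) values are
    retained unclamped.
    """
    if normal.x.shape != patient.x.shape or normal.y.shape != patient.y.shape:
        raise PerimetryError("surface geometries do not match")
    if not (np.allclose(normal.x, patient.x) and np.allclose(normal.y, patient.y)):
        raise PerimetryError("surface geometries do not match")
    full = normal._values_full - patient._values_full
    vals = np.where(normal.mask & patient.mask, full, np.nan)
    return HOVSurface(
        x=patient.x, y=patient.y, values=vals, kind="defect",
        laterality=patient.laterality, _values_full=full, _hull=patient._hull,
    )


def global_indices(
    exam: FieldExam, normal_at_nodes: np.ndarray | Sequence[float]
) -> tuple[float, float, float]:
    """Classical global indices from the raw test points.

    Returns (MS, MD, LV): mean sensitivity (dB), mean defect (dB, positive
    = loss) and loss variance (dB^2, unbiased).  Computed from the measured
    node values, independent of any interpolation.
    """
    normal_at_nodes = np.asarray(normal_at_nodes, dtype=float)
    if normal_at_nodes.shape != exam.dls.shape:
        raise PerimetryError("normal values must align with the exam grid")
    if exam.grid.n_points < 2:
        raise PerimetryError("need at least 2 points for global indices")
    ms = float(np.mean(exam.dls))
    d = normal_at_nodes - exam.dls
    md = float(np.mean(d))
    lv = float(np.var(d, ddof=1))
    return ms, md, lv
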