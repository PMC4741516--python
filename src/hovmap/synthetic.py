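"""Synthetic perimetry + OCT study generator with known ground truth.

Every downstream stage of the pipeline is testable without patient data:
this module fabricates centrally condensed radial test grids, duplicate
noisy exams over analytic truth surfaces, paired H/V b-scan boundary
traces whose ellipsoid-zone extent is coupled to the functional
transition radius, clustered cohort tables for the mixed-model stage, and
a full paired structure-function study.

Truth surfaces emulate the canonical visual-field patterns of retinitis
pigmentosa: a smooth dome (mild diffuse loss), a logistic edge (preserved
central island with a steep transition at radius r0), and a ring scotoma.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bscan import BScan
from .perimetry import FieldExam, TestGrid

__all__ = [
    "TruthSurface",
    "CohortSpec",
    "LayerSpec",
    "make_test_grid",
    "simulate_exams",
    "simulate_bscan_pair",
    "simulate_mem_cohort",
    "simulate_structfunc_cohort",
    "SyntheticStudy",
]

MM_PER_DEGREE = 0.3  # emmetropic retinal scale used to couple EZ and field


class ParameterizationError(ValueError):
    """Generator parameters are incompatible."""


@dataclass(frozen=True)
class TruthSurface:
    """Analytic ground-truth sensitivity surface S(x, y).

    families:
      dome          S = s_max * exp(-r^2 / (2 r0^2))
      logistic_edge S = s_max / (1 + exp((r - r0)/w)) — a preserved
                    central island whose sensitivity halves at r0 with
                    maximal radial slope -s_max/(4w) there
      ring_scotoma  logistic island with a smooth ring-shaped notch
                    between ring_inner and ring_outer
    """

    family: str = "logistic_edge"
    s_max: float = 30.0  # dB
    r0: float = 12.0  # degrees, transition radius
    w: float = 2.0  # degrees, transition softness
    ring_inner: float = 10.0
    ring_outer: float = 20.0
    ring_depth: float = 0.8  # fraction of s_max removed inside the ring
    center_offset: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.family not in ("dome", "logistic_edge", "ring_scotoma"):
            raise ParameterizationError(f"unknown truth family {self.family!r}")
        if self.s_max < 0 or self.w <= 0:
            raise ParameterizationError("require s_max >= 0 and w > 0")
        if self.family == "ring_scotoma" and not self.ring_inner < self.ring_outer:
            raise ParameterizationError("require ring_inner < ring_outer")

    def __call__(self, x, y):
        x = np.asarray(x, dtype=float) - self.center_offset[0]
        y = np.asarray(y, dtype=float) - self.center_offset[1]
        r = np.hypot(x, y)
        if self.family == "dome":
            return self.s_max * np.exp(-(r**2) / (2.0 * self.r0**2))
        if self.family == "logistic_edge":
            return self.s_max / (1.0 + np.exp((r - self.r0) / self.w))
        sig = lambda u: 1.0 / (1.0 + np.exp(-u))
        notch = sig((r - self.ring_inner) / self.w) - sig((r - self.ring_outer) / self.w)
        return self.s_max * (1.0 - self.ring_depth * notch)


def make_test_grid(
    n_points: int = 164,
    span_h: float = 140.0,
    span_v: float = 130.0,
    rings: int = 9,
    condensation: float = 2.0,
    laterality: str = "OD",
) -> TestGrid:
    """Radially organized, centrally condensed, mirror-symmetric test grid.

    One point sits at fixation; the remaining ``n_points - 1`` are placed
    on ``rings`` concentric elliptical rings whose fractional radii follow
    (i/rings)**condensation — for condensation > 1 the rings crowd toward
    the center, so point density falls with eccentricity.  Points per
    ring: the integer share of (n_points-1)/rings, with the remainder
    added one point each to the innermost rings.  Ring angles start at
    90 degrees with uniform spacing, which makes every ring symmetric
    under x -> -x regardless of its point count.
    """
    if rings < 1 or n_points - 1 < rings:
        raise ParameterizationError(
            f"cannot place {n_points - 1} ring points on {rings} rings"
        )
    if span_h <= 0 or span_v <= 0 or condensation <= 0:
        raise ParameterizationError("spans and condensation must be positive")
    n_ring_pts = n_points - 1
    base, extra = divmod(n_ring_pts, rings)
    counts = [base + (1 if i < extra else 0) for i in range(rings)]
    pts = [(0.0, 0.0)]
    for i, c in enumerate(counts, start=1):
        f = (i / rings) ** condensation
        ang = np.pi / 2.0 + 2.0 * np.pi * np.arange(c) / c
        pts.extend(
            zip(f * (span_h / 2.0) * np.cos(ang), f * (span_v / 2.0) * np.sin(ang))
        )
    points = np.round(np.array(pts), 9) + 0.0  # normalize -0.0
    return TestGrid(points, laterality=laterality)


BLIND_SPOT_FIELD = (15.0, -1.5)  # canonical right-eye frame, degrees


def simulate_exams(
    truth: TruthSurface,
    grid: TestGrid,
    noise_sd: float = 1.0,
    rf_pair: tuple = (5.0, 10.0),
    seed: int = 0,
    age: float = 50.0,
    participant_id: str = "anon",
    blind_spot: bool = False,
    blind_spot_depth_db: float = 25.0,
) -> tuple[FieldExam, FieldExam]:
    """Duplicate noisy exams of one eye over a truth surface.

    DLS = truth(x, y) + Gaussian noise (dB), clamped at the 0 dB floor
    (perimetric thresholds cannot be negative).  With ``blind_spot`` the
    physiologic scotoma is imprinted as a Gaussian notch at
    (+15 deg, -1.5 deg) — mirrored for left-eye grids — before the noise;
    it is off by default so radially symmetric truths stay symmetric.
    """
    if noise_sd < 0:
        raise ParameterizationError("noise_sd must be >= 0")
    if not all(0.0 <= rf <= 100.0 for rf in rf_pair):
        raise ParameterizationError("RF values must be in [0, 100]")
    rng = np.random.default_rng(seed)
    clean = truth(grid.points[:, 0], grid.points[:, 1])
    if blind_spot:
        bx = BLIND_SPOT_FIELD[0] * (1 if grid.laterality == "OD" else -1)
        d2 = (grid.points[:, 0] - bx) ** 2 + (
            grid.points[:, 1] - BLIND_SPOT_FIELD[1]) ** 2
        clean = np.clip(
            clean - blind_spot_depth_db * np.exp(-d2 / (2 * 1.8**2)), 0.0, None
        )
    exams = []
    for rf in rf_pair:
        dls = np.clip(clean + rng.normal(0.0, noise_sd, size=len(clean)), 0.0, None)
        exams.append(
            FieldExam(grid=grid, dls=dls, rf=float(rf), age=age,
                      participant_id=participant_id)
        )
    return exams[0], exams[1]


@dataclass(frozen=True)
class LayerSpec:
    """Flat-layer thickness profile for synthetic b-scans (um)."""

    onl_um: float = 90.0  # INL -> ELM
    inner_segment_um: float = 25.0  # ELM -> EZ
    os_um: float = 35.0  # EZ -> pRPE
    pit_depth_um: float = 60.0  # posterior INL displacement at the fovea
    pit_sigma_mm: float = 0.35
    curvature_um_per_mm2: float = 3.0  # shared quadratic column shift
    curvature_um_per_mm3: float = 1.0  # shared cubic column shift

    @property
    def rec_um(self) -> float:
        return self.onl_um + self.inner_segment_um + self.os_um


def simulate_bscan_pair(
    truth: TruthSurface,
    ez_halfwidth_mm: float = 1.75,
    layers: LayerSpec = LayerSpec(),
    mm_per_degree: float = MM_PER_DEGREE,
    axial_noise_sd: float = 0.0,
    seed: int = 0,
    scan_extent_deg: float = 30.0,
    lateral_step_mm: float = 0.006,
    fovea_mm: float = 0.0,
    laterality: str = "OD",
) -> tuple[BScan, BScan]:
    """Paired H and V b-scans with the EZ band spanning +/- ez_halfwidth.

    All four boundaries share a cubic curvature (a per-column vertical
    shift, exactly what flattening removes) and a foveal pit imprinted on
    the INL; boundary ordering is guaranteed by building depths as
    cumulative non-negative thickness increments.  ``truth`` is accepted
    for interface symmetry with the functional generator (scan geometry
    does not depend on it).
    """
    del truth  # geometry-only generator; linkage happens in the cohort op
    half_extent = scan_extent_deg * mm_per_degree / 2.0
    if not 0 < ez_halfwidth_mm <= half_extent:
        raise ParameterizationError("ez_halfwidth must be in (0, half scan extent]")
    if mm_per_degree <= 0 or lateral_step_mm <= 0:
        raise ParameterizationError("scales must be positive")
    rng = np.random.default_rng(seed)
    scans = []
    for orientation in ("H", "V"):
        u = np.arange(-half_extent, half_extent + lateral_step_mm / 2, lateral_step_mm)
        curve = (
            layers.curvature_um_per_mm2 * u**2 + layers.curvature_um_per_mm3 * u**3
        )
        pit = layers.pit_depth_um * np.exp(
            -((u - fovea_mm) ** 2) / (2.0 * layers.pit_sigma_mm**2)
        )
        noise = lambda: (
            rng.normal(0.0, axial_noise_sd, size=u.shape) if axial_noise_sd > 0
            else np.zeros_like(u)
        )
        inl = 100.0 + curve + pit + noise()
        onl = np.maximum(layers.onl_um - pit + noise(), 1.0)
        isg = np.maximum(layers.inner_segment_um + noise(), 1.0)
        osg = np.maximum(layers.os_um + noise(), 1.0)
        elm = inl + onl
        ez = elm + isg
        prpe = ez + osg
        ez = np.where(np.abs(u) <= ez_halfwidth_mm + 1e-12, ez, np.nan)
        scan = BScan(
            orientation=orientation, lateral_mm=u,
            boundaries={"INL": inl, "ELM": elm, "EZ": ez, "pRPE": prpe},
            mm_per_degree=mm_per_degree, laterality=laterality,
            fovea_hint_mm=fovea_mm,
        )
        scans.append(scan)
    return scans[0], scans[1]


@dataclass(frozen=True)
class CohortSpec:
    """Clustered-cohort generator settings for the mixed-model stage."""

    n_participants: int = 35
    eyes_per_participant: int = 2
    model_family: str = "linear"
    a: float = 1.0
    b: float = 0.5
    sigma_alpha: float = 1.0  # between-participant SD
    sigma_eps: float = 1.0  # residual SD
    covariate_range: tuple = (0.5, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_family not in ("inverse_quadratic", "linear", "quadratic"):
            raise ParameterizationError(f"unknown family {self.model_family!r}")
        if self.sigma_alpha < 0 or self.sigma_eps <= 0:
            raise ParameterizationError("require sigma_alpha >= 0 and sigma_eps > 0")
        if self.covariate_range[0] <= 0:
            raise ParameterizationError(
                "covariate_range min must be > 0 (inverse-quadratic diverges at 0)"
            )
        if self.eyes_per_participant not in (1, 2):
            raise ParameterizationError("eyes_per_participant must be 1 or 2")


def _fixed_effect(family: str, x: np.ndarray, a: float, b: float) -> np.ndarray:
    if family == "inverse_quadratic":
        return a - b / x**2
    if family == "linear":
        return a + b * x
    return a + b * x**2


def simulate_mem_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per eye: participant, eye, covariate X, clustered response Y.

    Y = f(X; a, b) + u_participant + eps, with the random intercept u
    shared by both eyes of a participant.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for pid in range(spec.n_participants):
        u = rng.normal(0.0, spec.sigma_alpha) if spec.sigma_alpha > 0 else 0.0
        for eye in ("OD", "OS")[: spec.eyes_per_participant]:
            x = rng.uniform(*spec.covariate_range)
            y = _fixed_effect(spec.model_family, x, spec.a, spec.b)
            y += u + rng.normal(0.0, spec.sigma_eps)
            rows.append({"participant": f"P{pid:03d}", "eye": eye, "x": x, "y": y})
    return pd.DataFrame(rows)


@dataclass
class SyntheticEye:
    participant_id: str
    laterality: str
    age: float
    exam1: FieldExam
    exam2: FieldExam
    scan_h: BScan
    scan_v: BScan
    truth: TruthSurface
    ez_halfwidth_mm: float


@dataclass
class SyntheticStudy:
    """A full paired structure-function study with its ground truth."""

    eyes: list = field(default_factory=list)
    truth_table: pd.DataFrame | None = None


def simulate_structfunc_cohort(
    n_participants: int = 35,
    two_eye_fraction: float = 0.7,
    s_max_range: tuple = (15.0, 33.0),
    w_range_deg: tuple = (1.5, 2.5),
    ez_halfwidth_range_mm: tuple = (0.9, 2.4),
    eye_sd_mm: float = 0.08,
    dls_noise_sd: float = 1.0,
    axial_noise_sd: float = 0.0,
    mm_per_degree: float = MM_PER_DEGREE,
    grid: TestGrid | None = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Paired exams + scans per eye with r0 = EZ half-width / scale.

    Each eye's functional truth is a logistic edge whose transition radius
    equals its EZ half-width converted to degrees — the coupling that
    makes the EZ width and the mean slope-contour distance collinear.
    EZ half-widths carry a participant-shared component so eyes cluster
    within people.  Island height (s_max) and transition softness (w)
    vary independently across participants, as they do across patients:
    this decouples amplitude-driven biomarkers (MS, volumes, maxima) from
    the transition radius, which only the slope-contour distance tracks
    directly.  Ages emulate an adult degenerative-disease cohort
    (~52 +/- 11 years).
    """
    if n_participants < 4:
        raise ParameterizationError("need at least 4 participants")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = make_test_grid()
    lo, hi = ez_halfwidth_range_mm
    study = SyntheticStudy()
    rows = []
    for pid_i in range(n_participants):
        pid = f"P{pid_i:03d}"
        center = rng.uniform(lo, hi)
        s_max_center = rng.uniform(*s_max_range)
        age = float(np.clip(rng.normal(52.0, 11.0), 20.0, 85.0))
        n_eyes = 2 if rng.random() < two_eye_fraction else 1
        for lat in ("OD", "OS")[:n_eyes]:
            hw = center + rng.normal(0.0, eye_sd_mm)
            hw = float(np.clip(hw, 0.3, 0.98 * 30.0 * mm_per_degree / 2.0))
            r0 = hw / mm_per_degree
            s_max = float(np.clip(s_max_center + rng.normal(0.0, 0.5), 5.0, 40.0))
            w_deg = float(rng.uniform(*w_range_deg))
            truth = TruthSurface(family="logistic_edge", s_max=s_max, r0=r0, w=w_deg)
            # outer-retina thicknesses track disease stage (wider EZ, thicker
            # layers) with independent per-eye variation, so structural
            # biomarkers other than EZ width are informative but noisier
            layers = LayerSpec(
                onl_um=float(np.clip(75.0 + 10.0 * hw + rng.normal(0, 5), 20, 140)),
                os_um=float(np.clip(22.0 + 5.0 * hw + rng.normal(0, 3), 5, 60)),
            )
            eye_seed = int(rng.integers(0, 2**31 - 1))
            exam1, exam2 = simulate_exams(
                truth, grid, noise_sd=dls_noise_sd, rf_pair=(5.0, 10.0),
                seed=eye_seed, age=age, participant_id=pid,
            )
            scan_h, scan_v = simulate_bscan_pair(
                truth, ez_halfwidth_mm=hw, layers=layers,
                mm_per_degree=mm_per_degree,
                axial_noise_sd=axial_noise_sd, seed=eye_seed + 1,
                laterality=lat,
            )
            study.eyes.append(
                SyntheticEye(pid, lat, age, exam1, exam2, scan_h, scan_v, truth, hw)
            )
            rows.append(
                {"participant": pid, "eye": lat, "age": age,
                 "ez_halfwidth_mm": hw, "ez_width_mm": 2.0 * hw, "r0_deg": r0,
                 "s_max": s_max, "w_deg": w_deg}
            )
    study.truth_table = pd.DataFrame(rows)
    return study
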