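# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `hovmap`, in the spirit of the methods documentation of
packages like statsmodels or msprime: what is computed, under which
assumptions, and what the bundled simulations do and do not demonstrate.

## Hill-of-vision construction

A full-field static perimetry exam yields differential luminance
sensitivity (DLS, dB) at scattered test locations. Duplicate exams are
merged by a reliability-weighted arithmetic mean with weights
`100 - RF` (RF = percentage of failed catch trials); the combined RF is
reported as the plain mean of the two and plays no further computational
role.

The merged exam is interpolated onto a uniform grid (default spacing
0.36°) with an exact thin-plate-spline radial basis function
(`φ(r) = r² log r` plus an affine tail and its orthogonality side
conditions; smoothing λ = 0). Exactness at the nodes is the contract:
the surface reproduces every measured threshold to < 1e-6 dB, and
reproduces affine data exactly. The surface is *undefined outside the
convex hull* of the test grid, where TPS extrapolation is unbounded;
every downstream biomarker restricts itself to the hull. The exact
interpolant is retained on the surface object (`evaluate`), while dense
resampling for topographic work goes through a bicubic spline of the
gridded values (`sample`), which introduces ~1e-3 dB of resampling error
— negligible against perimetric test-retest variability but relevant to
exactness checks, hence the two entry points.

Left-eye data are mirrored (x → −x) into a canonical right-eye field
frame at ingestion, so the physiologic blind spot is always nasal
(+15°, −1.5°) internally.

### Normal surface and defect

The age-adjusted normal hill of vision is modeled as

    N(x, y; age) = N0 − k1·ecc − k2·ecc² − s_age·max(0, age − age0)

with defaults N0 = 32 dB, k1 = 0.05 dB/°, k2 = 4e-4 dB/°², s_age = 0.05
dB/year beyond age0 = 45 — a slowly declining, centrally near-flat
surface approximating size-V normative behavior. The exact form is a
package model choice (normative databases are device-specific); all
parameters are configurable. The defect surface is `normal − patient`,
pointwise, with supranormal (negative) values retained.

MS, MD and LV are computed from the raw test points (not the
interpolated surface): MS is the mean DLS, MD the mean of per-point
defects (positive = loss), LV their unbiased variance.

## Topographic biomarkers

**Volumes** treat the field as a sphere of directions: each grid cell at
eccentricity θ contributes `value · (π/180)² · (sin θ/θ) · spacing²`
dB·sr (azimuthal-equidistant Jacobian, with sinθ/θ → 1 at fixation).
A constant 30 dB disc of 30° radius then integrates to the closed-form
spherical-cap value 30·2π(1−cos30°) within 0.5% at 0.36° spacing.
The "central 30°" domain is the disc of 30° *radius* by default; the
limit is configurable because the definition is ambiguous in common
usage (radius, diameter, or a 30° square image footprint).

**Maxima** are taken over grid cells of the (bicubically represented)
surface; the reported distance is the Euclidean distance from fixation
to the argmax, with ties broken toward the smallest distance and then
the smallest azimuth.

**Slope contour.** Along each of `n_spokes` (default 501, i.e. 0.72°
apart) radial spokes from fixation, the surface is sampled at the grid
spacing via the bicubic spline and the radial first derivative is formed
by central differences with step equal to the spacing. The per-spoke
extremum (most negative for a sensitivity surface, most positive for a
defect surface) is searched over `[min_radius, min(search_radius, hull
exit)]` with defaults min_radius = one grid step (avoids the center
singularity) and search_radius = 30°. The discrete extremum is refined
by a parabolic fit through the three neighboring derivative samples,
which removes the half-step quantization of the extremum location; the
refinement offset is clamped to one step. A spoke with |extremum| below
the validity floor (default 0.05 dB/°) carries no discernible
transition and is excluded from all summaries; if no spoke is valid the
contour is undefined and an error carrying diagnostics is raised rather
than returning a fabricated value. Contour summaries are the extreme
slope and its distance, and the mean slope and mean distance, over valid
spokes. The contour may be discontinuous in angle (ring scotomas); no
continuity is assumed anywhere.

Local (along-scan) biomarkers use the 1-D profile through fixation at
the scan orientation (default ±15°, half the 30° scan): profile maximum
and its distance, plus the slope statistics restricted to exactly the
two opposing collinear spokes.

On a noiseless logistic edge `s_max/(1+exp((r−r0)/w))` the machinery
recovers the transition radius within one grid step and the mean slope
within 5% of the analytic `−s_max/(4w)` for r0 ∈ {6, 12, 20}°.

## OCT structural biomarkers

Inputs are four segmented boundary depth profiles (INL, ELM, EZ, pRPE;
μm, increasing posteriorly from an arbitrary reference that cancels in
all outputs). Composite layers are boundary differences (ONL+ =
ELM−INL, OS+ = pRPE−EZ, ISOS+ = pRPE−ELM, REC = pRPE−INL), summarized
as mean, foveal (column nearest the fovea) and maximum over defined
columns. Band widths (EZ, ELM) join the outermost defined columns with
a Euclidean segment in physical units (interior gaps are spanned, not
subtracted) and flag truncation at the scan edge.

The fovea is the maximum posterior displacement of the INL boundary
after moving-average smoothing (window 0.15 mm), restricted to interior
local maxima with ≥ 5 μm prominence and pit-like curvature sign — a
guard against the scan-edge depth maxima that global retinal curvature
alone produces. Ties resolve toward the scan center; an absent pit
raises an error so the caller can use a provided hint.

**Flattening** fits a least-squares cubic to the pRPE and shifts each
column by −(fit − mean fit). The shift is stored as a per-column field
of the scan rather than baked into the boundary arrays: thickness is
always a within-column difference, so this representation makes every
thickness profile and summary exactly (bit-for-bit) invariant under
flattening, while effective depths (band-width endpoints, fovea search)
see the flattened geometry. EZ width changes by < 0.5% for curvatures
up to ~100 μm across the scan.

## Registration and hybrid measures

The field and the retina are linked by anchoring field (0°, 0°) at the
fovea, scaling with a single mm↔degree factor (default 0.3 mm/°, the
emmetropic approximation), mirroring left eyes, and optionally adding a
small translational offset; offsets ≥ 3° are rejected as registration
failures rather than corrections. The mapping is exactly invertible on
its domain. An automated check locates the physiologic blind spot in
the defect surface near its expected location and suggests the
centering offset; an undetectable scotoma is reported as such (the
caller keeps offset zero).

Hybrid measures sample one modality at a landmark of the other:
sensitivity, defect, and their radial slopes at the four EZ-edge field
positions (two per scan, averaged); REC thickness at the field position
of the along-scan HOV maximum and defect maximum (H and V averaged).
Cohort summaries report mean ± SD and the coefficient of variation
CV = SD/|mean| (the magnitude keeps CVs of negative-mean quantities
positive).

## Mixed-effects structure-function modeling

For a structural covariate X and functional response Y, three candidate
fixed-effects forms of equal parsimony are fitted:

    inverse quadratic  Y = a − b/X²
    linear             Y = a + bX
    quadratic          Y = a + bX²

each as `Y = a + b·g(X) + u_participant + ε` with a participant random
intercept (eyes cluster within people), estimated by **maximum
likelihood** — not REML — because AIC comparisons across different
fixed-effects forms require it. AIC = −2ℓ + 2k with k = 4 (a, b, and
the two variance components); the AIC minimum wins, with exact ties
resolved toward the linear form. Rows with non-positive X are dropped
for the inverse-quadratic family only (the transform diverges at 0).
When the between-participant variance estimate collapses to its zero
boundary, statsmodels' MixedLM cannot invert its Hessian; the
implementation then falls back to ordinary least squares, which *is*
the ML solution at that boundary, and flags nothing — the fit is valid.

Goodness of fit is the marginal/conditional variance decomposition:
R²m = σf²/(σf²+σα²+σε²), R²c = (σf²+σα²)/(σf²+σα²+σε²), with σf² the
sample variance of the fixed-effect predictions. Slope significance is
an F-test, F = (b̂/SE)² with 1 numerator df; the denominator df is
`n_obs − n_clusters − 1` ("between-within") by default with the simple
residual `n − 2` available behind a flag, and the method used is
recorded in output metadata. A Satterthwaite approximation was
considered but requires the variance-covariance of the variance
components, which the ML fitting machinery does not expose; at the
cohort sizes involved (tens of observations) the df choice moves
p-values negligibly, and the null simulations below confirm
calibration. Screened relationships are Bonferroni-corrected by the
number of functional responses per structural covariate.

An optional Wald test for an age covariate (`Y = a + b·g(X) + c·age`)
is provided to justify leaving age out of the candidate forms; on
age-independent synthetic cohorts it flags age as non-significant in
~95% of seeds, as expected at the 0.05 level.

Inter-eye comparisons use the paired Wilcoxon signed-rank test on
right−left differences (zeros dropped; exact null for ≤ 25 untied
pairs, normal approximation with tie correction otherwise; all-zero
differences give p = 1 by convention). H-vs-V comparisons use the
two-sided Wilcoxon rank-sum test (exact for ≤ 10 untied values per
group). Both are verified against brute-force enumeration of the exact
null distribution for n ≤ 7.

## Synthetic study conditions

The generator fabricates everything downstream stages consume, with
known ground truth:

* **Test grid** — radially organized, centrally condensed,
  mirror-symmetric; defaults: 164 points spanning 140°×130°, one point
  at fixation, 9 elliptical rings with fractional radii
  `(i/rings)^condensation` (condensation 2), remainder points assigned
  to the innermost rings. Only the span, count and symmetry are
  protocol-anchored; the exact clinical point layout is not public, and
  no specific commercial pattern is imitated.
* **Exams** — DLS = truth + Gaussian noise in dB (default SD 1 dB,
  consistent with reported test-retest variability), clamped at the
  0 dB floor; duplicate exams carry RF 5% and 10%.
* **Truth surfaces** — dome, logistic edge (preserved island, half
  height at r0, maximal slope −s_max/4w), and ring scotoma; these span
  the canonical field patterns of retinitis pigmentosa.
* **B-scans** — four boundary traces built as cumulative non-negative
  thickness increments (ordering INL ≤ ELM ≤ EZ ≤ pRPE holds by
  construction), flat layers (ONL+ 90, ELM→EZ 25, OS+ 35 μm), a
  Gaussian foveal pit (60 μm deep, σ 0.35 mm) imprinted on the INL, a
  shared cubic curvature (what flattening removes), lateral step 6 μm
  over a 30° scan, and optional per-boundary axial noise.
* **Linked cohort** — per eye, the functional transition radius equals
  the EZ half-width divided by the mm/° scale. EZ half-widths are
  uniform (0.9–2.4 mm) per participant with 0.08 mm inter-eye jitter;
  island height s_max is uniform 15–33 dB per participant (±0.5 dB per
  eye) and softness w uniform 1.5–2.5° per eye. The amplitude
  heterogeneity is essential to the design: without it every functional
  biomarker is a deterministic function of r0 and all relationships are
  equally perfect; with it, amplitude-driven biomarkers (MS, volumes,
  maxima) decouple from the transition radius, which only the
  slope-contour distance tracks directly — the qualitative structure
  the screen is expected to find. About 70% of participants contribute
  two eyes, ages ~52 ± 11 years.
* **Clustered tables** for the mixed-model stage draw X uniformly,
  add the family's fixed effect, a shared participant intercept and
  residual noise.

What the simulations do *not* emulate: perimetric staircase dynamics,
fixation instability, media opacity, real segmentation error structure,
eccentric preferred retinal loci, or genotype effects. Passing tests
therefore demonstrate the correctness and calibration of the
*machinery* under the stated noise model, not clinical performance.

## Problem sizes and determinism

Every generator is bit-reproducible given its seed. The bundled
acceptance computations use: 100 fuzzed exams for interpolation
exactness; 50 fuzzed scans for flattening; 100 seeds for AIC family
selection, 200 for coefficient bias, 500 for the null rejection rate
(35 participants × 2 eyes each); and one 35-participant linked cohort
(~60 eyes) for the end-to-end screen — sizes chosen to match the
trial-scale cohort the pipeline targets while keeping a full run within
about a minute.

## Known limitations

* The normal surface is a package model, not a device normative
  database; MD/LV values are therefore internally consistent but not
  device-comparable.
* Slope-contour distances inherit the edge-localization limit of the
  test grid: with the sparse full-field pattern, transition radii
  between ring eccentricities are biased toward the nearer sampled
  ring (about ±1° in the 3–8° range used by the linked cohort).
* The hybrid "HOV maximum" is read along the scan line (the local
  maximum), since thickness exists only on the scan; a global-maximum
  reading would need thickness off the line.
* `T_ISOS` is summarized as FOV, AVG and MAX for both orientations, so
  either a foveal or a maximum reading of the H-scan ISOS+ thickness is
  available.
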