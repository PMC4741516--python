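# hovmap

Structure–function analysis of the degenerating retina: topographic
**hill-of-vision (HOV)** biomarkers from full-field static perimetry,
outer-retina biomarkers from segmented OCT b-scans, fovea-anchored
registration between the two, and mixed-effects modeling of their
relationships.

The package targets researchers analyzing retinitis pigmentosa-style
cohorts, where vision collapses from a preserved central island across a
*transition zone* into a depressed periphery, and where the lateral
extent of the photoreceptor ellipsoid zone (EZ) on OCT is expected to
track that transition.

## What it computes

**Functional (from perimetry).** Duplicate exams are merged by
reliability weighting (weights `100 − RF`) and interpolated with an
exact thin-plate spline onto a 0.36° grid — the HOV surface. From it:
the classical indices MS, MD, LV; solid-angle volumes `S_V`, `D_V` and
their central-30° versions (dB·sr); surface maxima with distances; and
the **HOV slope contour** — along each of 501 radial spokes, the
extremum of the radial derivative

&nbsp;&nbsp;&nbsp;&nbsp;∇S(r) = ∂S/∂r (most negative for sensitivity, most positive for defect),

summarized by ∇S_MAX, ∇S_AVG and their radial distances d_∇S,MAX,
d_∇S,AVG. On a logistic island `S(r) = s_max/(1+exp((r−r0)/w))` the
contour sits at r0 with slope −s_max/4w, so d_∇S,AVG is a direct
transition-zone radius estimate. Local (along-scan) variants restrict
to the scan line.

**Structural (from OCT).** Layer thicknesses from the four segmented
boundaries (ONL+, OS+, ISOS+, REC; foveal/mean/max summaries), EZ and
ELM widths with truncation flags, fovea localization from the INL
depression, and cubic-polynomial pRPE flattening that leaves thickness
exactly invariant.

**Hybrid.** After fovea-anchored registration (0.3 mm/°, blind-spot
verification, optional small offset): sensitivity/defect and slope at
the EZ-edge field positions, REC thickness at the HOV maximum, with
cohort mean ± SD and CV.

**Statistics.** Every (structural X, functional Y) pair is fitted with
three equal-parsimony candidate forms — `Y = a − b/X²`, `Y = a + bX`,
`Y = a + bX²` — as random-intercept mixed models (eyes cluster within
participants) by maximum likelihood; AIC selects the form; marginal and
conditional R² (R²m, R²c) quantify fit; F-tests with Bonferroni
correction flag significance; paired Wilcoxon signed-rank and rank-sum
tests compare eyes and scan orientations.

A bundled synthetic-cohort generator produces exams, b-scan boundary
traces, and linked studies (transition radius = scaled EZ half-width)
with known ground truth, so the entire pipeline is testable without
patient data.

## Worked example

```bash
python examples/02_slope_contour.py
```

prints (island with s_max = 30 dB, r0 = 12°, w = 2°):

```
valid spokes          : 501 / 501
grad_S_max            :  -3.740 dB/deg  (steepest decline)
d_grad_S_max          :   12.00 deg
grad_S_avg            :  -3.740 dB/deg  (theory: -3.750)
d_grad_S_avg          :   12.00 deg     (theory: 12.00)
```

i.e. the contour machinery recovers the analytic transition radius and
slope. `examples/06_full_synthetic_study.py` runs the whole pipeline on
a small linked cohort and ends with the relationship screen:

```
 structural   functional            family sign      R2m      R2c        p  significant
     W_EZ_H d_grad_S_avg            linear    +    0.919    0.989    0.002         True
     W_EZ_H          S_V inverse_quadratic    +    0.592    0.982    0.029        False
T_REC_AVG_H d_grad_S_avg         quadratic    +    0.486    0.874    0.082        False
     ...
```

— the EZ width pairs most strongly with the slope-contour mean
distance: the functional transition sits at the photoreceptor band's
edge, which is the construction the generator encodes and the claim the
analysis is designed to detect. The other examples cover HOV indices
and volumes, structural biomarkers with flattening, registration with
hybrid measures, and mixed-model selection.

A thin CLI wraps the same functions
(`hovmap simulate | hov | run-eye | run-all | stats`; see `hovmap --help`).

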