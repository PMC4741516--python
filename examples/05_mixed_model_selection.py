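"""Fit and select structure-function relationship models on a clustered cohort.

A 35-participant, two-eyes-each cohort is generated from a quadratic
truth (Y = 1 + 0.5 X^2) with participant-level random intercepts; the
three candidate fixed-effects forms are fitted as random-intercept
mixed models by maximum likelihood and compared by AIC.
"""

from hovmap import (
    CohortSpec,
    fit_candidates,
    r2_mixed,
    select_model,
    significance,
    simulate_mem_cohort,
)

spec = CohortSpec(model_family="quadratic", a=1.0, b=0.5,
                  sigma_alpha=1.0, sigma_eps=1.0, seed=3)
cohort = simulate_mem_cohort(spec)
print(f"cohort: {len(cohort)} eyes, {cohort.participant.nunique()} participants")

fits = fit_candidates(cohort)
for f in fits:
    r2m, r2c = r2_mixed(f)
    print(f"  {f.family:18s} AIC = {f.aic:7.2f}  a = {f.a:6.3f}  "
          f"b = {f.b:6.3f}  R2m = {r2m:.3f}  R2c = {r2c:.3f}")

best = select_model(fits)
p, thr, sig = significance(best, n_comparisons=9)
print(f"\nselected: {best.family} (sign {best.sign}); truth was quadratic "
      f"with a = 1.0, b = 0.5")
print(f"F-test p = {p:.2e} vs Bonferroni threshold 0.05/9 = {thr:.4f} "
      f"-> significant = {sig}")
print("\nAIC picks the generating family and the coefficients land on the"
      "\ntruth; R2c > R2m reflects the real participant clustering.")
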