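"""Mixed-model fitting/selection, R2 decomposition, and the rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hypothesis import given, settings, strategies as st

from hovmap import (
    CohortSpec,
    ModelFit,
    fit_candidates,
    orientation_test,
    paired_eye_test,
    r2_mixed,
    relationship_screen,
    select_model,
    significance,
    simulate_mem_cohort,
)
from hovmap.stats import AnalysisError


def fit(df, **kw):
    return fit_candidates(df, **kw)


class TestFitCandidates:
    def test_noiseless_linear_recovery(self):
        spec = CohortSpec(model_family="linear", a=2.0, b=3.0,
                          sigma_alpha=0.0, sigma_eps=1e-6, seed=1)
        df = simulate_mem_cohort(spec)
        best = select_model(fit(df))
        assert best.family == "linear"
        assert best.a == pytest.approx(2.0, abs=1e-3)
        assert best.b == pytest.approx(3.0, abs=1e-3)

    def test_quadratic_family_wins_aic(self):
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            df = simulate_mem_cohort(CohortSpec(
                model_family="quadratic", a=1.0, b=0.5,
                sigma_alpha=1.0, sigma_eps=1.0, seed=seed))
            if select_model(fit(df)).family == "quadratic":
                wins += 1
        assert wins >= 0.9 * n_seeds

    def test_no_clustering_gives_r2m_equal_r2c(self):
        df = simulate_mem_cohort(CohortSpec(
            model_family="linear", sigma_alpha=0.0, sigma_eps=1.0, seed=3))
        best = [f for f in fit(df) if f.family == "linear"][0]
        r2m, r2c = r2_mixed(best)
        assert abs(r2c - r2m) < 0.02
        assert best.sigma_alpha2 == pytest.approx(0.0, abs=0.05)

    def test_inverse_quadratic_excludes_nonpositive_x(self):
        df = simulate_mem_cohort(CohortSpec(model_family="linear", seed=4))
        df.loc[df.index[:3], "x"] = -1.0
        fits = fit(df)
        iq = [f for f in fits if f.family == "inverse_quadratic"][0]
        lin = [f for f in fits if f.family == "linear"][0]
        assert iq.n_obs == lin.n_obs - 3

    def test_too_few_clusters_rejected(self):
        df = pd.DataFrame({"participant": ["a"] * 8,
                           "x": np.arange(1.0, 9.0), "y": np.arange(8.0)})
        with pytest.raises(AnalysisError, match="participants"):
            fit(df)


class TestSelection:
    def mk(self, family, aic):
        return ModelFit(family, 0, 1, 1, 1, 1, 1, 0, aic, 10, 5, True)

    def test_minimum_aic_selected(self):
        fits = [self.mk("inverse_quadratic", 10), self.mk("linear", 8),
                self.mk("quadratic", 12)]
        assert select_model(fits).family == "linear"
        fits[2] = self.mk("quadratic", 5)
        assert select_model(fits).family == "quadratic"

    def test_tie_prefers_linear(self):
        fits = [self.mk("quadratic", 8.0), self.mk("linear", 8.0)]
        assert select_model(fits).family == "linear"

    def test_single_converged_fit(self):
        bad = ModelFit("linear", 0, 1, 1, 1, 1, 1, 0, np.inf, 10, 5, False)
        assert select_model([bad, self.mk("quadratic", 9)]).family == "quadratic"
        with pytest.raises(AnalysisError):
            select_model([bad])


class TestR2:
    def test_direct_formula(self):
        f = ModelFit("linear", 0, 1, 1, sigma_alpha2=1.0, sigma_eps2=1.0,
                     sigma_f2=4.0, llf=0, aic=0, n_obs=10, n_groups=5,
                     converged=True)
        r2m, r2c = r2_mixed(f)
        assert r2m == pytest.approx(4 / 6)
        assert r2c == pytest.approx(5 / 6)

    def test_flat_fixed_effect_zero_marginal(self):
        f = ModelFit("linear", 0, 0, 1, 1.0, 1.0, 0.0, 0, 0, 10, 5, True)
        assert r2_mixed(f)[0] == 0.0

    @given(
        sf=st.floats(0, 100), sa=st.floats(0, 100),
        se=st.floats(1e-6, 100),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bounds_property(self, sf, sa, se):
        f = ModelFit("linear", 0, 1, 1, sa, se, sf, 0, 0, 10, 5, True)
        r2m, r2c = r2_mixed(f)
        assert 0 <= r2m <= r2c <= 1


class TestSignificance:
    def base_fit(self, b=1.0, se=0.2, n=70, g=35):
        return ModelFit("linear", 0, b, se, 1, 1, 1, 0, 0, n, g, True)

    def test_bonferroni_threshold(self):
        _, thr, _ = significance(self.base_fit(), n_comparisons=9)
        assert round(thr, 4) == 0.0056

    def test_single_comparison_keeps_base_alpha(self):
        _, thr, _ = significance(self.base_fit(), n_comparisons=1)
        assert thr == 0.05

    def test_df_methods_differ_but_agree_in_direction(self):
        f = self.base_fit(b=1.0, se=0.1)
        p_bw = significance(f, df_method="between_within")[0]
        p_res = significance(f, df_method="residual")[0]
        assert p_bw < 0.001 and p_res < 0.001
        assert p_bw >= p_res  # fewer df -> more conservative

    def test_null_type_i_error_calibrated(self):
        """Uncorrected rejection rate under b=0 stays near 0.05."""
        n_seeds, rejections = 200, 0
        for seed in range(n_seeds):
            df = simulate_mem_cohort(CohortSpec(
                model_family="linear", a=1.0, b=0.0,
                sigma_alpha=1.0, sigma_eps=1.0, seed=seed))
            lin = [f for f in fit(df, families=("linear",)) if f.converged][0]
            p, _, _ = significance(lin, n_comparisons=1)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_seeds <= 0.08


class TestAgeCovariate:
    def test_age_not_flagged_when_generator_is_age_independent(self):
        from hovmap.stats import age_covariate_wald

        non_sig = 0
        n_seeds = 40
        for seed in range(n_seeds):
            df = simulate_mem_cohort(CohortSpec(
                model_family="linear", a=1.0, b=0.5,
                sigma_alpha=1.0, sigma_eps=1.0, seed=seed))
            rng = np.random.default_rng(seed + 999)
            ages = rng.uniform(25, 80, df.participant.nunique())
            df["age"] = df.participant.map(
                dict(zip(df.participant.unique(), ages)))
            _, p = age_covariate_wald(df)
            non_sig += p >= 0.05
        assert non_sig >= 0.9 * n_seeds

    def test_strong_age_effect_detected(self):
        from hovmap.stats import age_covariate_wald

        df = simulate_mem_cohort(CohortSpec(
            model_family="linear", a=1.0, b=0.5,
            sigma_alpha=0.5, sigma_eps=0.5, seed=1))
        rng = np.random.default_rng(7)
        df["age"] = rng.uniform(25, 80, len(df))
        df["y"] = df["y"] + 0.5 * df["age"]
        c, p = age_covariate_wald(df)
        assert c == pytest.approx(0.5, abs=0.05)
        assert p < 1e-6


def exact_signed_rank_p(diffs):
    """Enumerate all 2^n sign patterns of |d| ranks (no ties, no zeros)."""
    d = np.asarray(diffs, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    t_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    total = ranks.sum()
    hits = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        t_plus = sum(r for s, r in zip(signs, ranks) if s)
        if min(t_plus, total - t_plus) <= t_obs + 1e-12:
            hits += 1
    return hits / 2 ** len(d)


def exact_rank_sum_p(a, b):
    """Enumerate all C(n1+n2, n1) rank assignments (no ties)."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = sum(sorted(ranks)[i] for i in combo)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestRankTests:
    def test_five_concordant_pairs(self):
        """All five right > left: exact two-sided p = 2/2^5 = 0.0625."""
        left = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        right = left + np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        _, p = paired_eye_test(left, right)
        assert p == pytest.approx(0.0625)

    def test_identical_eyes(self):
        x = np.arange(8.0)
        assert paired_eye_test(x, x)[1] == 1.0

    def test_label_swap_same_p(self):
        rng = np.random.default_rng(0)
        l, r = rng.normal(size=9), rng.normal(size=9)
        assert paired_eye_test(l, r)[1] == pytest.approx(paired_eye_test(r, l)[1])

    def test_signed_rank_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for n in (5, 6, 7):
            for _ in range(5):
                l = rng.normal(size=n)
                r = l + rng.normal(size=n)
                _, p = paired_eye_test(l, r)
                assert p == pytest.approx(exact_signed_rank_p(r - l), abs=1e-12)

    def test_rank_sum_separated_groups(self):
        """{1,2,3} vs {10,11,12}: 2 of the C(6,3)=20 assignments are as
        extreme, p = 0.1."""
        _, p = orientation_test([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_rank_sum_identical_samples(self):
        x = np.arange(6.0)
        assert orientation_test(x, x)[1] == 1.0

    def test_rank_sum_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for n1, n2 in [(3, 4), (5, 5), (7, 6)]:
            for _ in range(4):
                a, b = rng.normal(size=n1), rng.normal(size=n2)
                _, p = orientation_test(a, b)
                assert p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)


class TestRelationshipScreen:
    def cohort(self, seed=0):
        df = simulate_mem_cohort(CohortSpec(
            model_family="linear", a=1.0, b=2.0,
            sigma_alpha=0.5, sigma_eps=0.5, seed=seed))
        rng = np.random.default_rng(seed + 100)
        df = df.rename(columns={"x": "struct1", "y": "func1"})
        df["func_noise"] = rng.normal(size=len(df))
        return df

    def test_true_relationship_detected(self):
        out = relationship_screen(
            self.cohort(), ["struct1"], ["func1", "func_noise"]
        )
        row = out[out.functional == "func1"].iloc[0]
        assert bool(row.significant)
        assert row.threshold == 0.025
        assert row.sign == "+"
        noise = out[out.functional == "func_noise"].iloc[0]
        assert noise.R2m < row.R2m

    def test_failed_pairs_reported_as_na(self):
        df = self.cohort()
        df["bad"] = np.nan
        out = relationship_screen(df, ["struct1"], ["bad"])
        assert len(out) == 1
        assert pd.isna(out.iloc[0].family)
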