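"""Exact and asymptotic association tests, logistic regression, ANCOVA, and
partial correlation."""

import math

import numpy as np
import pandas as pd
import pytest

from fcdsre.association import (ModelSpec, Predictor, ancova_group_test,
                                auto_2x2_test, chi_square_2x2,
                                fisher_exact_2x2, logistic_fit,
                                odds_ratio_2x2, partial_correlation,
                                select_univariate, wilcoxon_rank_sum)
from fcdsre.cohort import CrossTab2x2


def fisher_oracle(a, b, c, d):
    """Independent enumeration: sum point hypergeometric probabilities not
    exceeding the observed table's, over all tables with the same margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    p_obs = point(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(point(x) for x in range(lo, hi + 1)
               if point(x) <= p_obs * (1 + 1e-7))


class TestFisherExact:
    def test_published_subgroup_table(self):
        """7/8 small vs 1/6 large with SRE in the IIa subgroup: p = 0.026."""
        res = fisher_exact_2x2([[7, 1], [1, 5]])
        assert round(res.p_two_sided, 3) == 0.026
        assert res.p_two_sided == pytest.approx(77 / 3003, rel=1e-9)

    def test_degenerate_margin_returns_one(self):
        res = fisher_exact_2x2([[0, 0], [3, 4]])
        assert res.p_two_sided == 1.0
        assert "degenerate margin" in res.warnings

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            t = rng.integers(0, 11, 4)
            a, b, c, d = map(int, t)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            res = fisher_exact_2x2([[a, b], [c, d]])
            assert res.p_two_sided == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-6)


class TestChiSquare:
    def test_statistic_from_expected_count_oracle(self):
        """Pearson statistic on the main size-by-SRE table, checked against a
        hand computation from expected counts."""
        t = np.array([[25, 16], [9, 25]], dtype=float)
        expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
        oracle = ((t - expected) ** 2 / expected).sum()
        res = chi_square_2x2([[25, 16], [9, 25]], yates=False)
        assert res.statistic == pytest.approx(oracle, rel=1e-12)
        assert res.statistic == pytest.approx(8.93, abs=0.005)
        assert res.df == 1

    def test_independent_table_gives_zero(self):
        res = chi_square_2x2([[10, 20], [20, 40]], yates=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_small_expected_counts_warn(self):
        res = chi_square_2x2([[3, 1], [1, 3]], yates=False)
        assert any("expected count" in w for w in res.warnings)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="exact"):
            chi_square_2x2([[0, 0], [3, 4]])

    def test_pearson_at_least_yates(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b, c, d = map(int, rng.integers(1, 30, 4))
            plain = chi_square_2x2([[a, b], [c, d]], yates=False).statistic
            corr = chi_square_2x2([[a, b], [c, d]], yates=True).statistic
            assert plain >= corr - 1e-12

    def test_main_table_dialects_bracket(self):
        """Pearson, Yates, and exact p for the main table all fall in the
        narrow band around the published value."""
        tab = [[25, 16], [9, 25]]
        ps = [chi_square_2x2(tab, yates=False).p_two_sided,
              chi_square_2x2(tab, yates=True).p_two_sided,
              fisher_exact_2x2(tab).p_two_sided]
        assert all(0.002 < p < 0.007 for p in ps)


class TestAuto2x2:
    def test_switches_on_expected_counts(self):
        assert auto_2x2_test([[3, 1], [1, 3]]).method == "fisher_exact"
        assert auto_2x2_test([[25, 16], [9, 25]]).method == "chi_square"


class TestOddsRatio:
    def test_main_table_value(self):
        est = odds_ratio_2x2([[25, 16], [9, 25]])
        assert est.ratio == pytest.approx(625 / 144, rel=1e-12)
        assert round(est.ratio, 2) == 4.34
        assert est.ci_low < est.ratio < est.ci_high

    def test_null_table(self):
        est = odds_ratio_2x2([[1, 1], [1, 1]])
        assert est.ratio == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_transpose_inverts(self):
        est = odds_ratio_2x2([[25, 16], [9, 25]])
        inv = odds_ratio_2x2([[16, 25], [25, 9]])
        assert inv.ratio == pytest.approx(1 / est.ratio, rel=1e-12)

    def test_zero_cell_requires_correction(self):
        with pytest.raises(ValueError, match="continuity"):
            odds_ratio_2x2([[5, 0], [3, 4]])
        est = odds_ratio_2x2([[5, 0], [3, 4]], continuity_correction=True)
        assert any("continuity" in d for d in est.diagnostics)


class TestWilcoxon:
    def test_complete_separation_exact(self):
        """n=m=4, fully separated: only 2 of the 70 rank arrangements are as
        extreme, so the exact two-sided p is 2/70."""
        res = wilcoxon_rank_sum([1, 2, 3, 4], [10, 11, 12, 13])
        assert res.method == "wilcoxon_rank_sum_exact"
        assert res.p_two_sided == pytest.approx(2 / 70, rel=1e-9)
        assert round(res.p_two_sided, 4) == 0.0286

    def test_symmetry(self):
        x, y = [1.2, 5.0, 2.2], [3.1, 0.4, 8.8, 2.0]
        assert wilcoxon_rank_sum(x, y).p_two_sided == pytest.approx(
            wilcoxon_rank_sum(y, x).p_two_sided)

    def test_identical_samples(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4, 5] * 5, [1, 2, 3, 4, 5] * 5)
        assert res.p_two_sided == pytest.approx(1.0, abs=0.02)

    def test_ties_use_asymptotic(self):
        res = wilcoxon_rank_sum([1, 1, 2], [2, 3, 3])
        assert res.method == "wilcoxon_rank_sum_asymptotic"

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestLogistic:
    def test_parameter_recovery(self):
        """True small-lesion odds ratio 3.67 at n=5000 recovers within 10%."""
        rng = np.random.default_rng(17)
        n = 5000
        small = rng.random(n) < 0.55
        logit = math.log(9 / 25) + math.log(3.67) * small
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame({"sre": y, "small": small})
        est = logistic_fit(df, ModelSpec("sre", [Predictor("small", "binary")]))[0]
        assert est.ratio == pytest.approx(3.67, rel=0.10)
        assert est.ci_low < est.ratio < est.ci_high

    def test_wald_coverage_and_bias_under_replication(self):
        """Across 200 simulated cohorts (n=2000), the mean log-ratio bias is
        below 5% of the true log effect and Wald CI coverage is near 95%."""
        rng = np.random.default_rng(23)
        true_log = math.log(3.67)
        n, covered, logs = 2000, 0, []
        reps = 200
        for _ in range(reps):
            small = rng.random(n) < 0.55
            y = rng.random(n) < 1 / (1 + np.exp(-(math.log(9 / 25)
                                                  + true_log * small)))
            df = pd.DataFrame({"sre": y, "small": small})
            est = logistic_fit(df, ModelSpec("sre",
                                             [Predictor("small", "binary")]))[0]
            logs.append(math.log(est.ratio))
            covered += est.ci_low <= 3.67 <= est.ci_high
        assert abs(np.mean(logs) - true_log) < 0.05 * true_log
        assert 0.92 <= covered / reps <= 0.98

    def test_separated_level_flagged(self):
        """A categorical level with zero outcome variation must be flagged as
        separated, not reported as a valid ratio."""
        df = pd.DataFrame({
            "sre": [True] * 2 + [True, False] * 20,
            "location": ["temporal"] * 2 + ["frontal"] * 40,
        })
        ests = logistic_fit(df, ModelSpec(
            "sre", [Predictor("location", "categorical", reference="frontal")]))
        temporal = [e for e in ests if "temporal" in e.term][0]
        assert "separated" in temporal.diagnostics
        assert temporal.reference == "frontal"

    def test_single_class_outcome_errors(self):
        df = pd.DataFrame({"sre": [True] * 5, "x": [1, 2, 3, 4, 5]})
        with pytest.raises(ValueError, match="both classes"):
            logistic_fit(df, ModelSpec("sre", [Predictor("x", "continuous")]))


class TestAncova:
    def test_no_covariates_matches_pooled_t(self):
        """With no covariates the group p equals the equal-variance
        two-sample t test from the equivalent linear model."""
        from scipy import stats
        rng = np.random.default_rng(31)
        x = rng.normal(0, 1, 40)
        g = np.repeat([0, 1], 20)
        res = ancova_group_test(x, g)
        t, p = stats.ttest_ind(x[g == 1], x[g == 0], equal_var=True)
        assert res.p_two_sided == pytest.approx(p, rel=1e-9)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(41)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            y = rng.normal(0, 1, 60)
            g = rng.random(60) < 0.5
            age = rng.uniform(5, 60, 60)
            res = ancova_group_test(y, g.astype(float),
                                    covariates={"age": age})
            rejections += res.p_two_sided < 0.05
        # binomial 95% band around 0.05 at 1000 replicates
        assert 0.0365 <= rejections / reps <= 0.0635

    def test_bonferroni_flag_threshold(self):
        rng = np.random.default_rng(43)
        y = np.concatenate([rng.normal(0, 1, 30), rng.normal(1.0, 1, 30)])
        g = np.repeat([0.0, 1.0], 30)
        res = ancova_group_test(y, g, alpha_family=3)
        # family of three comparisons: flag follows p < 0.05/3 = 0.0167
        assert res.significant_bonferroni == (res.p_two_sided < 0.05 / 3)

    def test_collinear_design_errors(self):
        y = np.arange(10.0)
        g = np.repeat([0.0, 1.0], 5)
        with pytest.raises(ValueError, match="collinear"):
            ancova_group_test(y, g, covariates={"g2": g})


class TestPartialCorrelation:
    def test_no_controls_is_pearson(self):
        from scipy import stats
        rng = np.random.default_rng(51)
        x, y = rng.normal(size=(2, 50))
        res = partial_correlation(x, y)
        r, p = stats.pearsonr(x, y)
        assert res.statistic == pytest.approx(r, abs=1e-12)
        assert res.p_two_sided == pytest.approx(p, rel=1e-6)

    def test_controlling_for_x_kills_correlation(self):
        rng = np.random.default_rng(53)
        x = rng.normal(size=60)
        y = 2 * x + rng.normal(scale=0.1, size=60)
        res = partial_correlation(x, y, controls=[x])
        assert abs(res.statistic) < 1e-8

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(57)
        age = rng.uniform(5, 60, 80)
        sex = (rng.random(80) < 0.5).astype(float)
        x = 0.3 * age + rng.normal(size=80)
        y = -0.2 * age + 0.5 * sex + rng.normal(size=80)
        res = partial_correlation(x, y, controls=[age, sex])
        df = pd.DataFrame({"x": x, "y": y, "age": age, "sex": sex})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["age", "sex"])
        pcol = "p-val" if "p-val" in ref.columns else "p_val"
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]),
                                              abs=1e-9)
        assert res.p_two_sided == pytest.approx(float(ref[pcol].iloc[0]),
                                                rel=1e-6)

    def test_constant_residuals_error(self):
        x = np.ones(20)
        y = np.arange(20.0)
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(x, y)


class TestSelectUnivariate:
    def test_thresholding(self):
        rng = np.random.default_rng(61)
        n = 200
        y = rng.random(n) < 0.5
        strong = y ^ (rng.random(n) < 0.1)   # strongly associated
        noise = rng.random(n) < 0.5
        df = pd.DataFrame({"sre": y, "strong": strong, "noise": noise,
                           "cont": rng.normal(size=n) + y})
        out = {r.name: r for r in select_univariate(df, ["strong", "noise",
                                                         "cont"])}
        assert out["strong"].retained
        assert out["cont"].retained
        assert not out["noise"].retained or \
            out["noise"].test.p_two_sided < 0.1  # consistency with its record

    def test_fixture_small_lesion_retained(self, fixture_cohort, is_small):
        df = fixture_cohort.to_frame()
        df = df[df["lesion_volume_mm3"].notna()]
        df["small"] = df["lesion_volume_mm3"] < 3217.0
        out = {r.name: r for r in select_univariate(df, ["small", "bosd"])}
        assert out["small"].retained
        assert out["small"].test.p_two_sided < 0.01

    def test_untestable_candidate_skipped(self, fixture_cohort):
        out = select_univariate(fixture_cohort, ["no_such_column"])
        assert not out[0].retained and out[0].test is None
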