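from fractions import Fraction
from math import comb, factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtburden import stats
from mtburden.errors import (
    DegenerateLabelError,
    DegenerateTableError,
    GroupingError,
    InsufficientDataError,
    RankDeficiencyError,
    StatsDomainError,
)

# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

_FACT = [factorial(i) for i in range(45)]


def fisher_oracle(a, b, c, d):
    """Independent oracle: exact-rational enumeration of fixed-margin tables."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    num = _FACT[r1] * _FACT[r2] * _FACT[c1] * _FACT[c2]

    def prob(k):
        b_, c_ = r1 - k, c1 - k
        d_ = r2 - c_
        if min(b_, c_, d_) < 0:
            return None
        return Fraction(num, _FACT[n] * _FACT[k] * _FACT[b_] * _FACT[c_] * _FACT[d_])

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(min(r1, c1) + 1):
        p = prob(k)
        if p is not None and p <= p_obs:
            total += p
    return float(total)


class TestFisher2x2:
    def test_enumerated_fixture(self):
        assert stats.fisher_exact_2x2(1, 9, 11, 3) == pytest.approx(
            0.0027594561852200836, rel=1e-12
        )

    def test_mode_table_p_one(self):
        assert stats.fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_perfect_split_doubled_tail(self):
        assert stats.fisher_exact_2x2(0, 10, 10, 0) == pytest.approx(
            2 / comb(20, 10), rel=1e-12
        )

    def test_negative_count_raises(self):
        with pytest.raises(StatsDomainError):
            stats.fisher_exact_2x2(-1, 2, 3, 4)

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateTableError):
            stats.fisher_exact_2x2(0, 0, 0, 0)

    def test_exhaustive_agreement_up_to_n_40(self):
        for n in range(1, 41):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        assert stats.fisher_exact_2x2(a, b, c, d) == pytest.approx(
                            fisher_oracle(a, b, c, d), abs=1e-10
                        ), (a, b, c, d)

    def test_matches_scipy_convention(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + b + c + d == 0:
                continue
            ours = stats.fisher_exact_2x2(int(a), int(b), int(c), int(d))
            theirs = fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-7)


def rxc_enumeration_oracle(table):
    """Exhaustive fixed-margin enumeration for a 2x3 table."""
    t = np.asarray(table)
    rows, cols, n = t.sum(1), t.sum(0), t.sum()

    def prob(tab):
        num = np.prod([float(_FACT[int(r)]) for r in rows]) * np.prod(
            [float(_FACT[int(c)]) for c in cols]
        )
        den = float(_FACT[int(n)]) * np.prod([float(_FACT[int(x)]) for x in tab.flat])
        return num / den

    p_obs = prob(t)
    total = 0.0
    for a in range(min(rows[0], cols[0]) + 1):
        for b in range(min(rows[0] - a, cols[1]) + 1):
            c = rows[0] - a - b
            if not 0 <= c <= cols[2]:
                continue
            tab = np.array([[a, b, c], [cols[0] - a, cols[1] - b, cols[2] - c]])
            if (tab < 0).any():
                continue
            p = prob(tab)
            if p <= p_obs * (1 + 1e-9):
                total += p
    return total


class TestFisherRxC:
    def test_2x2_delegates_exactly(self):
        assert stats.fisher_exact_rxc([[1, 9], [11, 3]]) == stats.fisher_exact_2x2(1, 9, 11, 3)

    def test_identical_rows_p_near_one(self):
        res = stats.fisher_exact_rxc([[5, 5, 5], [5, 5, 5]], mc_iterations=20_000, seed=1)
        assert res.p > 0.95

    def test_2x3_matches_enumeration_within_mc_error(self):
        table = [[3, 2, 1], [1, 2, 3]]
        exact = rxc_enumeration_oracle(table)
        res = stats.fisher_exact_rxc(table, mc_iterations=100_000, seed=2)
        assert exact == pytest.approx(0.7662337662337663, rel=1e-9)
        assert abs(res.p - exact) < 5 * res.se + 0.005

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateTableError):
            stats.fisher_exact_rxc([[0, 0], [0, 0], [0, 0]])

    def test_seeded_determinism(self):
        a = stats.fisher_exact_rxc([[4, 1, 2], [2, 3, 4]], mc_iterations=5000, seed=3)
        b = stats.fisher_exact_rxc([[4, 1, 2], [2, 3, 4]], mc_iterations=5000, seed=3)
        assert a.p == b.p


# ---------------------------------------------------------------------------
# ANOVA linear model
# ---------------------------------------------------------------------------


class TestAnovaLinear:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        res = stats.anova_linear(2 * x + 1, x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_fixture(self):
        # frozen from a by-hand sums-of-squares decomposition
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = np.array([2.1, 2.9, 3.3, 4.8, 5.1, 5.9, 7.2, 7.8])
        res = stats.anova_linear(y, x)
        assert res.slope == pytest.approx(0.8273809523809523, rel=1e-12)
        assert res.f_statistic == pytest.approx(434.24483068624517, rel=1e-10)
        assert res.p_value == pytest.approx(7.951574707978412e-07, rel=1e-9)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = stats.anova_linear(y, x)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.slope == pytest.approx(fit.params[1], rel=1e-10)
        assert res.p_value == pytest.approx(fit.f_pvalue, rel=1e-8)

    def test_constant_x_raises(self):
        with pytest.raises(RankDeficiencyError):
            stats.anova_linear([1.0, 2, 3], [5.0, 5, 5])

    def test_too_few_points(self):
        with pytest.raises(StatsDomainError):
            stats.anova_linear([1.0, 2], [1.0, 2])

    @given(
        a=st.floats(-5, 5), b=st.floats(0.1, 5),
        c=st.floats(-5, 5), d=st.floats(0.1, 5),
    )
    @settings(max_examples=50)
    def test_p_invariant_to_affine_rescaling(self, a, b, c, d):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = 0.3 * x + rng.normal(size=20)
        base = stats.anova_linear(y, x)
        scaled = stats.anova_linear(a + b * y, c + d * x)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-6, abs=1e-12)

    def test_type_i_calibration(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(1000):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            if stats.anova_linear(y, x).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07


class TestBonferroni:
    def test_printed_value(self):
        assert round(stats.bonferroni_threshold(0.05, 7), 4) == 0.0071

    def test_identity(self):
        assert stats.bonferroni_threshold(0.05, 1) == 0.05

    def test_five(self):
        assert stats.bonferroni_threshold(0.05, 5) == pytest.approx(0.01)

    def test_zero_tests_raises(self):
        with pytest.raises(StatsDomainError):
            stats.bonferroni_threshold(0.05, 0)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curve = stats.km_estimate([5.0, 6.0, 7.0], [0, 0, 0])
        assert len(curve.times) == 0  # no steps: S(t) = 1 throughout

    def test_three_events_no_censoring(self):
        curve = stats.km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert list(curve.at_risk) == [3, 2, 1]

    def test_hand_computed_mixed_censoring(self):
        # t=[1,2,2,3,4,5], e=[1,0,1,1,0,1]; hand product-limit table frozen
        curve = stats.km_estimate([1, 2, 2, 3, 4, 5], [1, 0, 1, 1, 0, 1])
        assert curve.times == pytest.approx([1, 2, 3, 5])
        assert curve.survival == pytest.approx([5 / 6, 2 / 3, 4 / 9, 0.0])

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=50).round(3)
        events = np.ones(50, dtype=int)
        curve = stats.km_estimate(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((times > t).mean())

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(10, size=80).round(2) + 0.01
        events = rng.integers(0, 2, size=80)
        if events.sum() == 0:
            events[0] = 1
        curve = stats.km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(kmf.predict(t), abs=1e-9)

    def test_nonpositive_time_raises(self):
        with pytest.raises(StatsDomainError):
            stats.km_estimate([0.0, 1.0], [1, 1])


def _logrank_chi2(times, events, groups):
    return stats.logrank_hr(times, events, groups).chi_square


class TestLogRank:
    def _fixture(self, seed=5, n=20):
        rng = np.random.default_rng(seed)
        times = rng.exponential(20, size=n).round(2) + 0.01
        events = rng.integers(0, 2, size=n)
        groups = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
        if events.sum() == 0:
            events[0] = 1
        return times, events, groups

    def test_identical_groups_null(self):
        times = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        groups = np.array(["A"] * 4 + ["B"] * 4)
        res = stats.logrank_hr(times, events, groups)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.hazard_ratio == pytest.approx(1.0)

    def test_label_swap_inverts_hr(self):
        times, events, groups = self._fixture()
        res = stats.logrank_hr(times, events, groups, exposed="B")
        swapped = stats.logrank_hr(times, events, groups, exposed="A")
        assert res.chi_square == pytest.approx(swapped.chi_square)
        assert res.hazard_ratio == pytest.approx(1 / swapped.hazard_ratio)
        assert res.ci_low == pytest.approx(1 / swapped.ci_high)
        assert res.ci_high == pytest.approx(1 / swapped.ci_low)

    def test_ci_brackets_hr(self):
        times, events, groups = self._fixture()
        res = stats.logrank_hr(times, events, groups)
        assert res.ci_low <= res.hazard_ratio <= res.ci_high

    def test_matches_lifelines_chi2(self):
        from lifelines.statistics import logrank_test

        times, events, groups = self._fixture(seed=9, n=60)
        res = stats.logrank_hr(times, events, groups)
        ll = logrank_test(
            times[groups == "A"], times[groups == "B"],
            events[groups == "A"], events[groups == "B"],
        )
        assert res.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-9)

    def test_permutation_oracle(self):
        times, events, groups = self._fixture(seed=17, n=20)
        res = stats.logrank_hr(times, events, groups)
        rng = np.random.default_rng(0)
        perms = 5000
        hits = 0
        for _ in range(perms):
            perm = rng.permutation(groups)
            if _logrank_chi2(times, events, perm) >= res.chi_square - 1e-12:
                hits += 1
        p_perm = hits / perms
        # analytic chi-square p vs the exact permutation distribution at n=20
        assert abs(res.p_value - p_perm) < 0.05

    def test_single_group_raises(self):
        with pytest.raises(GroupingError):
            stats.logrank_hr([1.0, 2.0], [1, 1], ["A", "A"])

    def test_no_events_raises(self):
        with pytest.raises(GroupingError):
            stats.logrank_hr([1.0, 2.0], [0, 0], ["A", "B"])

    def test_type_i_calibration(self):
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(1000):
            times = rng.exponential(50, size=60)
            censor = rng.uniform(20, 80, size=60)
            obs = np.minimum(times, censor)
            events = (times <= censor).astype(int)
            groups = np.array(["A"] * 30 + ["B"] * 30)
            if events.sum() == 0:
                continue
            if stats.logrank_hr(obs, events, groups).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07


class TestDichotomize:
    @pytest.mark.parametrize("n,cut,expected", [(0, 1, "low"), (1, 1, "high"), (1, 2, "low"), (3, 2, "high")])
    def test_examples(self, n, cut, expected):
        assert stats.dichotomize_burden(n, cut) == expected


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------


def auc_pairwise_oracle(scores, labels):
    """Brute-force mean over all (positive, negative) pairs, exact rationals."""
    scores = list(scores)
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = Fraction(0)
    for p in pos:
        for q in neg:
            if p > q:
                total += 1
            elif p == q:
                total += Fraction(1, 2)
    return float(total / (len(pos) * len(neg)))


class TestRocAuc:
    def test_perfect_separation(self):
        res = stats.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_null_expectation(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert abs(stats.roc_auc(scores, labels).auc - 0.5) < 0.05

    def test_ties_match_pairwise_oracle(self):
        scores = [1, 1, 2, 2, 3, 3, 4]
        labels = [0, 1, 0, 1, 0, 1, 1]
        res = stats.roc_auc(scores, labels)
        assert res.auc == pytest.approx(auc_pairwise_oracle(scores, labels), abs=1e-12)

    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=30),
        st.data(),
    )
    @settings(max_examples=100)
    def test_property_matches_oracle(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            return
        res = stats.roc_auc(scores, labels)
        assert res.auc == pytest.approx(auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        labels = (rng.random(200) < 1 / (1 + np.exp(-scores))).astype(int)
        assert stats.roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        res = stats.roc_auc(scores, labels)
        fpr = 1 - res.specificities
        assert (np.diff(fpr) >= -1e-12).all()
        assert (np.diff(res.sensitivities) >= -1e-12).all()

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelError):
            stats.roc_auc([1, 2, 3], [1, 1, 1])


class TestCombinePredictors:
    def test_constant_second_predictor_equals_first_alone(self, rng):
        x1 = rng.normal(size=100)
        labels = (rng.random(100) < 1 / (1 + np.exp(-2 * x1))).astype(int)
        combined = stats.combine_predictors(x1, np.full(100, 3.0), labels)
        auc_combined = stats.roc_auc(combined.scores, labels).auc
        auc_alone = stats.roc_auc(x1, labels).auc
        assert auc_combined == pytest.approx(auc_alone, abs=1e-12)

    def test_irrelevant_predictor_coefficient_near_zero(self, rng):
        n = 5000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        labels = (rng.random(n) < 1 / (1 + np.exp(-x1))).astype(int)
        combined = stats.combine_predictors(x1, x2, labels)
        assert abs(combined.coefficients[2]) < 0.1
        assert abs(combined.coefficients[1] - 1.0) < 0.2

    def test_matches_statsmodels_logit(self, rng):
        import statsmodels.api as sm

        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        labels = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * x1 + 0.8 * x2)))).astype(int)
        combined = stats.combine_predictors(x1, x2, labels)
        fit = sm.Logit(labels, sm.add_constant(np.column_stack([x1, x2]))).fit(disp=0)
        assert combined.coefficients == pytest.approx(fit.params, abs=1e-6)

    def test_separation_fallback_warns(self):
        x1 = np.array([0.0] * 10 + [1.0] * 10)
        labels = np.array([0] * 10 + [1] * 10)
        x2 = np.linspace(0, 1, 20)
        with pytest.warns(UserWarning, match="separation"):
            combined = stats.combine_predictors(x1, x2, labels)
        assert combined.separation_fallback

    def test_combined_beats_singles_in_sample(self):
        from mtburden import simulate

        cfg = simulate.SimulationConfig(n_patients=400, seed=21)
        clinical, _, truths = simulate.simulate_cohort(cfg)
        k = np.array([len(t.variants) for t in truths], dtype=float)
        g = clinical["gleason_category"].map({"<7": 1, "=7": 2, ">7": 3}).to_numpy(float)
        labels = clinical["relapse"].to_numpy(int)
        combined = stats.combine_predictors(g, k, labels)
        auc_c = stats.roc_auc(combined.scores, labels).auc
        auc_g = stats.roc_auc(g, labels).auc
        auc_k = stats.roc_auc(k, labels).auc
        assert auc_c >= max(auc_g, auc_k) - 0.01


class TestDeLong:
    def test_identical_scores(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        auc_a, auc_b, p = stats.delong_test(scores, scores, labels)
        assert auc_a == auc_b
        assert p == 1.0

    def test_variance_matches_jackknife_within_10_percent(self):
        rng = np.random.default_rng(31)
        # average agreement over several n=12 fixtures (jackknife is noisy)
        ratios = []
        for _ in range(30):
            n = 12
            labels = np.array([0] * 6 + [1] * 6)
            sa = rng.normal(size=n) + labels
            sb = rng.normal(size=n) + 0.5 * labels
            _, _, var = stats.delong_variance(sa, sb, labels)

            def diff_auc(idx):
                return (
                    stats.roc_auc(sa[idx], labels[idx]).auc
                    - stats.roc_auc(sb[idx], labels[idx]).auc
                )

            loo = []
            for i in range(n):
                idx = np.array([j for j in range(n) if j != i])
                if len(set(labels[idx])) < 2:
                    continue
                loo.append(diff_auc(idx))
            loo = np.array(loo)
            var_jack = (len(loo) - 1) / len(loo) * ((loo - loo.mean()) ** 2).sum()
            if var > 0 and var_jack > 0:
                ratios.append(var / var_jack)
        assert abs(np.mean(ratios) - 1.0) < 0.10

    def test_type_i_calibration(self):
        rng = np.random.default_rng(404)
        rejections = 0
        for _ in range(1000):
            n = 80
            labels = np.array([0] * 40 + [1] * 40)
            sa = rng.normal(size=n)
            sb = rng.normal(size=n)
            _, _, p = stats.delong_test(sa, sb, labels)
            if p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_unpaired_raises(self):
        with pytest.raises((StatsDomainError, Exception)):
            stats.delong_test([1, 2, 3], [1, 2], [0, 1, 1])


# ---------------------------------------------------------------------------
# relapse classification
# ---------------------------------------------------------------------------


class TestClassifyRelapse:
    def test_two_consecutive_elevated(self):
        record = {"psa_series": [(3, 0.1), (6, 0.3), (9, 0.4)], "follow_up_months": 24}
        assert stats.classify_relapse(record) == (1, 9.0)

    def test_non_consecutive_not_event(self):
        record = {"psa_series": [(3, 0.1), (6, 0.3), (9, 0.1)], "follow_up_months": 24}
        assert stats.classify_relapse(record) == (0, 24.0)

    def test_non_curative_surgery(self):
        assert stats.classify_relapse({"non_curative": True, "follow_up_months": 60}) == (1, 1.0)

    def test_precomputed_flag(self):
        assert stats.classify_relapse(
            {"relapse": 1, "relapse_month": 33.0, "follow_up_months": 107.0}
        ) == (1, 33.0)
        assert stats.classify_relapse(
            {"relapse": 0, "follow_up_months": 107.0}
        ) == (0, 107.0)

    def test_metastasis_event(self):
        record = {
            "psa_series": [(3, 0.1)], "metastasis": True,
            "event_month": 40, "follow_up_months": 60,
        }
        assert stats.classify_relapse(record) == (1, 40.0)

    def test_missing_everything_raises(self):
        with pytest.raises(InsufficientDataError):
            stats.classify_relapse({"follow_up_months": 24})
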