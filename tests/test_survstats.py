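"""Survival and agreement statistics against hand computation and brute force."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lungsig.containers import LungsigError
from lungsig.survstats import (
    censor_at,
    compare_auc,
    cox_multivariate,
    dss_outcome_labels,
    km_estimate,
    logrank,
    passing_bablok,
    roc_auc,
    treatment_benefit,
)

from _oracles import brute_auc, brute_passing_bablok_slope, hand_logrank, km_by_hand


def frame(times, events, **extra):
    return pd.DataFrame({"followup_months": times, "dss_event": events, **extra})


class TestCensorAt:
    def test_rules(self):
        cl = frame([70.0, 59.0, 36.0], [1, 1, 0])
        out = censor_at(cl, 60.0)
        assert out.followup_months.tolist() == [60.0, 59.0, 36.0]
        assert out.dss_event.tolist() == [0, 1, 0]

    def test_idempotent_composition(self):
        cl = frame([70.0, 45.0, 30.0], [1, 1, 1])
        a = censor_at(censor_at(cl, 60.0), 36.0)
        b = censor_at(cl, 36.0)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_horizon_errors(self):
        with pytest.raises(LungsigError):
            censor_at(frame([1.0], [1]), 0.0)


class TestKaplanMeier:
    def test_equals_empirical_survival_without_censoring(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        lookup = dict(zip(km.time, km.survival))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        km = km_estimate([5.0, 8.0, 2.0], [0, 0, 0])
        assert (km.survival == 1.0).all()

    def test_hand_product_limit_with_censoring(self):
        # events at 1 and 3; censored at 2, 4, 5 -> S(1)=4/5, S(3)=8/15
        km = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 0, 0])
        lookup = dict(zip(km.time, km.survival))
        assert lookup[1.0] == pytest.approx(4 / 5)
        assert lookup[3.0] == pytest.approx(8 / 15)
        for t, s in km_by_hand(np.array([1, 2, 3, 4, 5]), np.array([1, 0, 1, 0, 0])):
            assert lookup[t] == pytest.approx(s)

    def test_curves_start_at_one_and_non_increasing(self):
        rng = np.random.default_rng(2)
        km = km_estimate(rng.exponential(5, 50), rng.integers(0, 2, 50))
        assert km.survival.iloc[0] <= 1.0 and (np.diff(km.survival) <= 1e-12).all()

    def test_negative_time_errors(self):
        with pytest.raises(LungsigError):
            km_estimate([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        chi2, p = logrank(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_hand_computation(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        t = np.round(rng.exponential(5, n), 2)
        e = rng.integers(0, 2, n)
        e[0] = 1
        g = np.array(["a"] * 5 + ["b"] * 5)
        chi2, _ = logrank(t, e, g)
        assert chi2 == pytest.approx(hand_logrank(t, e, g), abs=1e-10)

    def test_p_matches_permutation_null(self):
        rng = np.random.default_rng(7)
        n = 24
        t = rng.exponential(5, n)
        e = np.ones(n, dtype=int)
        g = np.array([0] * 12 + [1] * 12)
        chi2, p = logrank(t, e, g)
        stats_perm = []
        for _ in range(10_000):
            stats_perm.append(hand_logrank(t, e, rng.permutation(g)))
        phat = float(np.mean(np.asarray(stats_perm) >= chi2 - 1e-12))
        mc_sd = np.sqrt(max(phat * (1 - phat), 1e-6) / 10_000)
        assert abs(p - phat) <= 3 * mc_sd + 0.01

    def test_single_group_or_no_events_error(self):
        with pytest.raises(LungsigError):
            logrank([1, 2], [1, 1], ["a", "a"])
        with pytest.raises(LungsigError):
            logrank([1, 2], [0, 0], ["a", "b"])


class TestCoxMultivariate:
    def test_null_indicator_ci_covers_one(self):
        """Independent indicator: the 95% CI covers HR=1 at ~nominal rate."""
        rng = np.random.default_rng(12)
        cover = 0
        n_rep = 100
        for _ in range(n_rep):
            n = 80
            df = frame(
                rng.exponential(10, n), np.ones(n, dtype=int),
                ind=rng.integers(0, 2, n).astype(float),
                z=rng.normal(size=n),
            )
            s = cox_multivariate(df, "followup_months", "dss_event", "ind", ["z"])
            cover += s.ci_low <= 1.0 <= s.ci_high
        assert cover >= 90

    def test_small_case_matches_grid_search(self):
        from _oracles import grid_search_cox

        rng = np.random.default_rng(23)
        for sub in range(10):
            rng2 = np.random.default_rng([23, sub])
            n = 8
            x = rng2.normal(size=n)
            ind = rng2.integers(0, 2, n).astype(float)
            df = frame(rng2.exponential(8, n), np.ones(n, dtype=int), ind=ind, z=x)
            s = cox_multivariate(df, "followup_months", "dss_event", "ind", ["z"])
            if abs(np.log(s.hr)) < 2.5:
                break
        X = df[["ind", "z"]].to_numpy()
        oracle = grid_search_cox(X, df.followup_months.to_numpy(), df.dss_event.to_numpy())
        assert np.log(s.hr) == pytest.approx(oracle[0], abs=1e-3)

    def test_duplicate_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        n = 60
        ind = rng.integers(0, 2, n).astype(float)
        df = frame(rng.exponential(10, n), np.ones(n, dtype=int), ind=ind, dup=ind.copy(),
                   z=rng.normal(size=n))
        with pytest.warns(UserWarning, match="dropping"):
            s = cox_multivariate(df, "followup_months", "dss_event", "ind", ["dup", "z"])
        assert np.isfinite(s.hr)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        n = 100
        df = frame(rng.exponential(10, n), np.ones(n, dtype=int),
                   ind=rng.integers(0, 2, n).astype(float))
        s = cox_multivariate(df, "followup_months", "dss_event", "ind")
        assert s.ci_low <= s.hr <= s.ci_high and 0 <= s.p <= 1


class TestOutcomeLabels:
    def test_rules(self):
        cl = frame(
            [10.0, 40.0, 20.0, 50.0, 30.0],
            [0, 1, 1, 0, 1],
        )
        labels, included = dss_outcome_labels(cl, 24.0, 12.0, 36.0)
        # alive at 10m, <12m follow-up -> excluded
        assert not included.iloc[0]
        # death at 40m with 36m late-event exclusion -> excluded
        assert not included.iloc[1]
        # death at 20m within 24m horizon -> positive
        assert labels.iloc[2] == 1.0
        # alive at 50m -> negative
        assert labels.iloc[3] == 0.0
        # death at 30m: after horizon, within exclusion window -> negative
        assert labels.iloc[4] == 0.0

    def test_invalid_horizon(self):
        with pytest.raises(LungsigError):
            dss_outcome_labels(frame([1.0], [1]), -1.0, 12.0)


class TestRocAuc:
    def test_perfect_and_degenerate(self):
        auc, lo, hi, p = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0 and p < 0.05
        auc, _, _, p = roc_auc([5.0] * 8, [0, 1] * 4)
        assert auc == 0.5 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=20), 1)  # rounding forces ties
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        auc, lo, hi, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_auc(scores, labels), abs=1e-12)
        assert lo <= auc <= hi

    def test_one_class_errors(self):
        with pytest.raises(LungsigError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestCompareAuc:
    def test_identical_scores_give_p_one(self):
        s = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = [0, 0, 0, 1, 1, 1]
        assert compare_auc(s, s, labels) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=40), rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert compare_auc(a, b, labels) == pytest.approx(compare_auc(b, a, labels))

    def test_consistent_with_paired_bootstrap(self):
        rng = np.random.default_rng(15)
        n = 120
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        signal = labels + rng.normal(scale=1.2, size=n)
        a = signal + rng.normal(scale=0.6, size=n)
        b = rng.normal(size=n)
        p = compare_auc(a, b, labels)
        diffs = []
        idx = np.arange(n)
        for _ in range(2000):
            s = rng.choice(idx, size=n, replace=True)
            if len(np.unique(labels[s])) < 2:
                continue
            diffs.append(brute_auc(a[s], labels[s]) - brute_auc(b[s], labels[s]))
        diffs = np.asarray(diffs)
        z = (brute_auc(a, labels) - brute_auc(b, labels)) / diffs.std(ddof=1)
        p_boot = 2 * stats.norm.sf(abs(z))
        agree = (p < 0.05) == (p_boot < 0.05)
        assert agree or abs(p - p_boot) < 0.05

    def test_unpaired_errors(self):
        with pytest.raises(LungsigError):
            compare_auc([1, 2], [1, 2, 3], [0, 1, 1])


class TestPassingBablok:
    def test_identity_line(self):
        x = np.arange(1.0, 11.0)
        res = passing_bablok(x, x)
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0)
        assert res["linearity_p"] > 0.10

    def test_exact_linear_transform(self):
        x = np.linspace(0, 5, 12)
        res = passing_bablok(x, 2 * x + 1)
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_slope_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, 10)
        y = 1.4 * x + 0.5 + rng.normal(scale=0.8, size=10)
        res = passing_bablok(x, y)
        assert res["slope"] == pytest.approx(brute_passing_bablok_slope(x, y), abs=1e-12)
        lo, hi = res["slope_ci"]
        assert lo <= res["slope"] <= hi

    def test_swap_invariance_for_exact_linear_data(self):
        x = np.linspace(1, 6, 11)
        y = 2.0 * x + 1.0
        fwd = passing_bablok(x, y)
        rev = passing_bablok(y, x)
        assert rev["slope"] == pytest.approx(1.0 / fwd["slope"])
        assert rev["intercept"] == pytest.approx(-fwd["intercept"] / fwd["slope"])

    def test_too_few_points_or_constant_x_error(self):
        with pytest.raises(LungsigError):
            passing_bablok([1, 2], [1, 2])
        with pytest.raises(LungsigError):
            passing_bablok([2, 2, 2], [1, 2, 3])


class TestTreatmentBenefit:
    def base_frame(self, rng, n, benefit_in=None):
        treated = rng.random(n) < 0.5
        responder = rng.random(n) < 0.5 if benefit_in is None else benefit_in
        lp = -1.5 * (treated & responder)
        t = rng.exponential(20.0 * np.exp(-lp))
        return (
            pd.DataFrame(
                {
                    "followup_months": np.minimum(t, 60.0),
                    "dss_event": (t <= 60.0).astype(int),
                    "treatment": np.where(treated, "ACT", "OBS"),
                    "age": rng.uniform(50, 80, n),
                    "gender": rng.choice(["male", "female"], n),
                    "stage": rng.choice(["IA", "IB", "IIA"], n),
                    "histology": "adenocarcinoma",
                },
                index=[f"s{i}" for i in range(n)],
            ),
            responder,
        )

    def test_single_arm_class_reported_not_evaluable(self):
        rng = np.random.default_rng(1)
        cl, resp = self.base_frame(rng, 60)
        cl["treatment"] = "ACT"
        res = treatment_benefit(cl, pd.Series("all", index=cl.index))
        assert not res["all"].evaluable

    def test_benefit_detected_in_responder_class(self):
        rng = np.random.default_rng(6)
        cl, resp = self.base_frame(rng, 400)
        calls = pd.Series(np.where(resp, "responder", "non-responder"), index=cl.index)
        res = treatment_benefit(cl, calls, censor_horizon=60.0)
        assert res["responder"].hr < 1.0 and res["responder"].p < 0.05
        assert res["non-responder"].p > 0.05
        assert set(res["responder"].km_curves) == {"ACT", "OBS"}
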