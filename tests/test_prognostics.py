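"""Prognostic statistics: AUC, cutpoint scan, Cox, PH check, KM, Spearman."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from scipy import stats

from histofract import prognostics as pg
from histofract import synthgen as sg


@pytest.fixture
def seeded_cohort():
    rng = np.random.default_rng(42)
    n = 60
    feature = rng.normal(size=n)
    time = rng.exponential(60, size=n) + 1
    event = (rng.random(n) < 0.4).astype(int)
    return feature, time, event


class TestAUC:
    def test_worked_four_point_example(self):
        # events {2,4} vs non-events {1,3}: 3 of 4 pairs concordant
        assert pg.mann_whitney_auc(np.array([2, 4, 1, 3]), np.array([1, 1, 0, 0])) == 0.75

    def test_perfect_separation(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        assert pg.mann_whitney_auc(x, y) == 1.0

    def test_sign_flip_symmetry(self, seeded_cohort):
        x, _, y = seeded_cohort
        assert pg.mann_whitney_auc(x, y) + pg.mann_whitney_auc(-x, y) == pytest.approx(1.0)

    def test_matches_sklearn(self, seeded_cohort):
        sk = pytest.importorskip("sklearn.metrics")
        x, _, y = seeded_cohort
        assert pg.mann_whitney_auc(x, y) == pytest.approx(sk.roc_auc_score(y, x))

    def test_single_class_rejected(self):
        with pytest.raises(pg.EvaluationError):
            pg.mann_whitney_auc(np.arange(5.0), np.ones(5, int))

    def test_bootstrap_ci_brackets_point(self, seeded_cohort):
        x, _, y = seeded_cohort
        res = pg.roc_auc(x, y, n_boot=200, seed=1)
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0 <= res.p_value <= 1
        assert res.low_risk_direction == (res.auc < 0.5)


class TestOptimalCutpoint:
    def test_block_separated_feature(self):
        x = np.concatenate([np.linspace(0, 1, 10), np.linspace(5, 6, 10)])
        t = np.concatenate([np.full(10, 100.0), np.full(10, 10.0)])
        d = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        cut = pg.optimal_cutpoint(x, t, d)
        assert 1 < cut < 5

    def test_constant_feature_rejected(self):
        with pytest.raises(pg.EvaluationError):
            pg.optimal_cutpoint(np.ones(20), np.arange(1.0, 21), np.ones(20, int))

    def test_matches_exhaustive_lifelines_scan(self, seeded_cohort):
        x, t, d = seeded_cohort
        uniq = np.unique(x)
        cuts = (uniq[:-1] + uniq[1:]) / 2
        n = x.size
        best, best_cut = -np.inf, None
        for c in cuts:
            g = x > c
            if g.sum() < 6 or (~g).sum() < 6:
                continue
            chi = logrank_test(t[g], t[~g], d[g], d[~g]).test_statistic
            if chi > best:
                best, best_cut = chi, c
        assert pg.optimal_cutpoint(x, t, d) == pytest.approx(best_cut)

    def test_invariant_under_monotone_transform(self, seeded_cohort):
        x, t, d = seeded_cohort
        cut = pg.optimal_cutpoint(x, t, d)
        cut_exp = pg.optimal_cutpoint(np.exp(x), t, d)
        assert np.array_equal(x > cut, np.exp(x) > cut_exp)


class TestCoxUnivariate:
    def test_reciprocal_under_label_swap(self, seeded_cohort):
        x, t, d = seeded_cohort
        g = (x > np.median(x)).astype(int)
        r1 = pg.cox_univariate(g, t, d, n_boot=0)
        r2 = pg.cox_univariate(1 - g, t, d, n_boot=0)
        assert r1.hr * r2.hr == pytest.approx(1.0, abs=1e-9)

    def test_planted_hazard_ratio_recovered(self):
        """HR = 3 recovery at n = 200 with ~25% censoring: the median point
        estimate lands near truth and the 95% CI covers it in most reps."""
        hrs, covered = [], 0
        for seed in range(1, 31):
            df = sg.gen_survival_groups(n=200, hr=3.0, event_rate=0.75, seed=seed)
            res = pg.cox_univariate(
                df.group.to_numpy(), df.time_months.to_numpy(), df.event.to_numpy(), n_boot=0
            )
            hrs.append(res.hr)
            covered += res.ci_low <= 3.0 <= res.ci_high
        assert 2.4 <= np.median(hrs) <= 3.75
        assert covered >= 27  # ~95% nominal coverage

    def test_bootstrap_ci_present(self):
        df = sg.gen_survival_groups(n=100, hr=3.0, event_rate=0.5, seed=4)
        res = pg.cox_univariate(df.group.to_numpy(), df.time_months.to_numpy(),
                                df.event.to_numpy(), n_boot=80, seed=2)
        assert res.ci_low < res.hr < res.ci_high
        assert res.boot_ci_low < res.boot_ci_high
        assert res.n_boot == 80

    def test_monotone_likelihood_flagged(self):
        g = np.array([0] * 10 + [1] * 10)
        t = np.arange(1.0, 21)
        d = np.array([0] * 10 + [1] * 10)
        res = pg.cox_univariate(g, t, d, n_boot=0)
        assert res.monotone_likelihood

    def test_no_events_rejected(self):
        with pytest.raises(pg.EvaluationError):
            pg.cox_univariate(np.arange(10) % 2, np.arange(1.0, 11), np.zeros(10, int))


class TestSchoenfeld:
    def test_null_ph_data_gives_moderate_p(self):
        # under exact proportional hazards the test should rarely reject
        ps = []
        for seed in range(30):
            df = sg.gen_survival_groups(n=120, hr=2.0, event_rate=0.4, seed=seed)
            ps.append(
                pg.schoenfeld_ph_test(
                    df[["group"]], df.time_months.to_numpy(), df.event.to_numpy()
                )["group"]
            )
        assert np.mean(np.array(ps) < 0.05) < 0.25
        # and p-values should not pile up at 0 (rough uniformity check)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_events_rejected(self):
        with pytest.raises(pg.EvaluationError):
            pg.schoenfeld_ph_test(
                pd.DataFrame({"g": np.arange(10) % 2}),
                np.arange(1.0, 11),
                np.array([1] + [0] * 9),
            )


class TestCoxMultivariate:
    def _simulate(self, seed, n=200):
        rng = np.random.default_rng(seed)
        true = rng.normal(size=n)
        noise = {f"noise_{i}": rng.normal(size=n) for i in range(5)}
        lam = 0.01 * np.exp(0.8 * true)
        t_event = rng.exponential(1 / lam)
        c = rng.uniform(20, 150, n)
        return (
            pd.DataFrame({"true_feature": true, **noise}),
            np.minimum(t_event, c),
            (t_event <= c).astype(int),
        )

    def test_true_feature_retained(self):
        hits = 0
        for seed in range(10):
            feats, t, d = self._simulate(seed)
            mv = pg.cox_multivariate(feats, t, d)
            hits += "true_feature" in mv.selected.index
        assert hits >= 8

    def test_all_noise_usually_empty(self):
        empties = 0
        for seed in range(10):
            feats, t, d = self._simulate(seed + 100)
            mv = pg.cox_multivariate(feats.drop(columns="true_feature"), t, d)
            empties += len(mv.selected) == 0
        assert empties >= 6

    def test_duplicate_feature_dropped_and_flagged(self):
        feats, t, d = self._simulate(3)
        feats["true_copy"] = feats["true_feature"]
        mv = pg.cox_multivariate(feats, t, d)
        assert "true_copy" in mv.dropped_collinear
        assert "true_feature" in mv.selected.index


class TestKMAndSpearman:
    def test_no_events_flat_curves(self):
        g = np.arange(12) % 2
        t = np.linspace(5, 60, 12)
        curves, p = pg.km_summary(g, t, np.zeros(12, int))
        assert (curves.survival == 1.0).all()

    def test_hand_computed_product_limit(self):
        # single group of 6: events at 2, 4; censored at 3
        g = np.array([0, 0, 0, 1, 1, 1])
        t = np.array([2.0, 3.0, 4.0, 10.0, 11.0, 12.0])
        d = np.array([1, 0, 1, 0, 0, 0])
        curves, _ = pg.km_summary(g, t, d)
        grp0 = curves[curves.group == 0]
        # S(2) = 1 - 1/3 = 2/3 ; S(4) = 2/3 * (1 - 1/1) = 0
        assert grp0.loc[grp0.time_months == 2.0, "survival"].iloc[0] == pytest.approx(2 / 3)
        assert grp0.loc[grp0.time_months == 4.0, "survival"].iloc[0] == pytest.approx(0.0)

    def test_spearman_identity_antirank_and_hand_value(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [5, 4, 3, 2, 1], "c": [2, 1, 4, 3, 5]})
        rho, p, const = pg.spearman_matrix(df)
        assert rho.loc["a", "a"] == 1.0
        assert rho.loc["a", "b"] == pytest.approx(-1.0)
        # hand rank formula: 1 - 6*sum(d^2)/(n(n^2-1)), d = (1,1,1,1,0) vs c
        assert rho.loc["a", "c"] == pytest.approx(1 - 6 * 4 / (5 * 24))
        assert const == []

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "k": [7, 7, 7, 7]})
        rho, _, const = pg.spearman_matrix(df)
        assert const == ["k"]
        assert np.isnan(rho.loc["a", "k"])


class TestOptimismExposure:
    def test_cutpoint_selection_inflates_type_one_error(self):
        """Log-rank at the optimized cutpoint rejects a true null too often,
        and the report carries uncorrected and corrected p side by side."""
        rng = np.random.default_rng(7)
        n, reps, alpha = 73, 40, 0.05
        uncorrected_hits = 0
        for _ in range(reps):
            x = rng.standard_normal(n)  # independent of outcome
            t = rng.exponential(80, n) + 1
            d = (rng.random(n) < 0.25).astype(int)
            if d.sum() < 5:
                continue
            cut = pg.optimal_cutpoint(x, t, d)
            g = (x > cut).astype(int)
            res = pg.cox_univariate(g, t, d, n_boot=0)
            uncorrected_hits += res.p_value < alpha
        assert uncorrected_hits / reps > alpha  # optimism bias exposed

    def test_report_row_contains_both_p_values(self, seeded_cohort):
        x, t, d = seeded_cohort
        row = pg.evaluate_feature(x, t, d, n_boot=60, seed=9)
        assert {"hr_p", "hr_p_boot", "auc", "auc_corrected", "cutpoint"} <= set(row)
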