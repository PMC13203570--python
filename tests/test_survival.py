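"""Clinical encoding, ridge Cox fits against a grid-search oracle,
concordance, IPCW AUC, Kaplan-Meier/log-rank and the bootstrap CI."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from habitatmsi.survival import (
    ModelGridParams,
    bootstrap_ci,
    breslow_partial_loglik,
    c_index,
    cv_select_penalty,
    encode_clinical,
    fit_cox_ridge,
    km_logrank,
    run_model_grid,
    time_dependent_auc,
)


def records_frame(ages, t, n, ebv):
    return pd.DataFrame(
        {
            "age_years": ages,
            "t_stage": t,
            "n_stage": n,
            "ebv_dna_copies_per_ml": ebv,
        }
    )


class TestEncodeClinical:
    def test_ebv_cutoff_boundary(self):
        rec = records_frame([50, 30], [1, 2], [0, 1], [3999.0, 4000.0])
        X = encode_clinical(rec).X
        assert list(X["ebv_ge_4000"]) == [0, 1]

    def test_age_at_median_counts_as_high(self):
        rec = records_frame([40, 43, 46], [1, 1, 1], [0, 0, 0], [0, 0, 0])
        enc = encode_clinical(rec)
        assert enc.age_median == 43.0
        assert list(enc.X["age_ge_median"]) == [0, 1, 1]

    def test_training_median_applied_to_test(self):
        train = records_frame([30, 40, 50], [1, 1, 1], [0, 0, 0], [0, 0, 0])
        enc = encode_clinical(train)
        test = records_frame([41, 39], [2, 3], [1, 2], [5000, 100])
        Xt = encode_clinical(test, age_median=enc.age_median).X
        assert list(Xt["age_ge_median"]) == [1, 0]

    def test_fixed_column_order(self):
        rec = records_frame([50], [4], [3], [9000.0])
        X = encode_clinical(rec).X
        assert list(X.columns) == [
            "age_ge_median", "t_stage", "n_stage", "ebv_ge_4000",
        ]

    def test_missing_value_rejected(self):
        rec = records_frame([50, np.nan], [1, 2], [0, 1], [1, 2])
        with pytest.raises(ValueError, match="missing"):
            encode_clinical(rec)


class TestCoxRidge:
    def test_unpenalized_fit_matches_grid_search_oracle(self):
        """Tiny data (times 1,2,3,4; events 1,1,1,0; x 1,0,1,0): the
        MLE from a dense 1-D grid over the Breslow partial likelihood
        must agree with the Newton fit to 1e-4.  (The covariate pattern
        is interleaved so the partial likelihood has an interior
        maximum.)"""
        X = np.array([1.0, 0.0, 1.0, 0.0])
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 0])
        grid = np.linspace(-5, 5, 200001)
        ll = [
            breslow_partial_loglik(np.array([b]), X[:, None], time, event)
            for b in grid
        ]
        beta_oracle = grid[int(np.argmax(ll))]
        fit = fit_cox_ridge(X[:, None], time, event, penalty=0.0)
        assert fit.coef[0] == pytest.approx(beta_oracle, abs=1e-4)

    def test_huge_penalty_shrinks_to_zero(self, rng):
        X = rng.normal(size=(60, 3))
        time = rng.exponential(10, size=60)
        event = rng.integers(0, 2, size=60)
        event[0] = 1
        fit = fit_cox_ridge(X, time, event, penalty=1e8)
        assert np.all(np.abs(fit.coef) < 1e-3)

    def test_sign_recovery_and_consistency(self, rng):
        """Known beta = (1, -1): signs recovered at n=200 and n=500 and
        the error shrinks with n."""
        beta = np.array([1.0, -1.0])
        errs = {}
        for n in (200, 500):
            X = rng.normal(size=(n, 2))
            rate = 0.05 * np.exp(X @ beta)
            t_event = rng.exponential(1 / rate)
            t_cens = rng.exponential(40, size=n)
            time = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(int)
            fit = fit_cox_ridge(X, time, event, penalty=0.01)
            assert np.all(np.sign(fit.coef) == np.sign(beta))
            errs[n] = np.linalg.norm(fit.coef - beta)
        assert errs[500] < errs[200]

    def test_penalty_monotone_shrinkage(self, rng):
        X = rng.normal(size=(80, 4))
        time = rng.exponential(10, size=80)
        event = np.ones(80, dtype=int)
        norms = [
            np.linalg.norm(fit_cox_ridge(X, time, event, penalty=lam).coef_std)
            for lam in (0.0, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox_ridge(
                np.ones((3, 1)), np.array([1.0, 2, 3]), np.zeros(3, int)
            )

    def test_cv_returns_grid_value(self, rng):
        X = rng.normal(size=(60, 3))
        time = rng.exponential(10, size=60)
        event = rng.integers(0, 2, size=60)
        event[:10] = 1
        lam = cv_select_penalty(X, time, event, grid=np.array([0.1, 1.0, 10.0]))
        assert lam in (0.1, 1.0, 10.0)


class TestCIndex:
    def test_perfect_ordering(self):
        time = np.array([1.0, 2, 3, 4])
        risk = np.array([4.0, 3, 2, 1])
        assert c_index(risk, time, np.ones(4, int)) == 1.0

    def test_hand_enumerated_pairs(self):
        """times 1,2,3 all events; risks 3,1,2: pairs (1,2) and (1,3)
        concordant, (2,3) discordant -> 2/3."""
        assert c_index(
            np.array([3.0, 1.0, 2.0]),
            np.array([1.0, 2.0, 3.0]),
            np.ones(3, int),
        ) == pytest.approx(2 / 3)

    def test_null_risk_near_half(self, rng):
        n = 2000
        time = rng.exponential(10, size=n)
        event = rng.integers(0, 2, size=n)
        event[:50] = 1
        risk = rng.normal(size=n)
        assert abs(c_index(risk, time, event) - 0.5) < 0.03

    def test_antisymmetry_on_tie_free_data(self, rng):
        n = 50
        time = rng.exponential(10, size=n)
        event = rng.integers(0, 2, size=n)
        event[0] = 1
        risk = rng.normal(size=n)
        assert c_index(risk, time, event) + c_index(-risk, time, event) == (
            pytest.approx(1.0)
        )


class TestTimeDependentAUC:
    def test_perfect_indicator_risk(self):
        time = np.array([10.0, 20, 30, 80, 90, 100])
        event = np.array([1, 1, 1, 0, 0, 0])
        risk = np.array([1.0, 1, 1, 0, 0, 0])
        assert time_dependent_auc(risk, time, event, horizon=60) == 1.0

    def test_reduces_to_rank_sum_without_censoring(self, rng):
        """With no censoring the IPCW AUC at the horizon equals the
        plain ROC AUC of (event-before-horizon) vs risk (Wilcoxon)."""
        n = 300
        time = rng.exponential(50, size=n)
        event = np.ones(n, int)
        risk = -0.02 * time + 0.3 * rng.normal(size=n)
        auc = time_dependent_auc(risk, time, event, horizon=60.0)
        pos = risk[time <= 60.0]
        neg = risk[time > 60.0]
        greater = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        wilcoxon = (greater + 0.5 * ties) / (len(pos) * len(neg))
        assert auc == pytest.approx(wilcoxon, abs=1e-10)

    def test_null_risk_near_half(self, rng):
        n = 2000
        time = rng.exponential(80, size=n)
        event = np.ones(n, int)
        risk = rng.normal(size=n)
        assert abs(time_dependent_auc(risk, time, event, 60.0) - 0.5) < 0.03

    def test_no_events_before_horizon_rejected(self):
        with pytest.raises(ValueError):
            time_dependent_auc(
                np.array([1.0, 2.0]), np.array([70.0, 80.0]),
                np.array([1, 1]), horizon=60.0,
            )


class TestKMLogrank:
    def test_identical_groups_null(self):
        time = np.array([5.0, 10, 15, 20] * 2)
        event = np.array([1, 0, 1, 0] * 2)
        groups = np.repeat(["a", "b"], 4)
        res = km_logrank(groups, time, event)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_risk_set_arithmetic(self):
        """Group A times (1,2) both events; group B times (3,4), one
        event.  Risk-set bookkeeping gives U = 7/6, Var = 17/36, so the
        chi-square statistic is 49/17."""
        groups = np.array(["A", "A", "B", "B"])
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 0])
        res = km_logrank(groups, time, event)
        assert res.statistic == pytest.approx(49 / 17, abs=1e-9)
        assert res.p_value == pytest.approx(
            chi2.sf(49 / 17, 1), abs=1e-12
        )

    def test_km_curve_shape(self):
        groups = np.array(["a"] * 4 + ["b"] * 4)
        time = np.array([1.0, 2, 3, 4, 1.5, 2.5, 3.5, 10])
        event = np.array([1, 1, 0, 1, 1, 1, 1, 0])
        res = km_logrank(groups, time, event)
        for curve in res.curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)

    def test_zero_event_group_warns(self):
        groups = np.array(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="zero events"):
            km_logrank(
                groups, np.array([1.0, 2, 3, 4]), np.array([1, 1, 0, 0])
            )


class TestBootstrapCI:
    def test_constant_metric_collapses(self, rng):
        lo, hi = bootstrap_ci(
            lambda x: 0.7, (np.arange(30),), n_boot=200, seed=0
        )
        assert lo == hi == 0.7

    def test_deterministic_per_seed(self, rng):
        data = (rng.normal(size=40),)
        ci1 = bootstrap_ci(np.mean, data, n_boot=300, seed=9)
        ci2 = bootstrap_ci(np.mean, data, n_boot=300, seed=9)
        assert ci1 == ci2

    def test_covers_point_estimate(self, rng):
        data = (rng.normal(size=80),)
        lo, hi = bootstrap_ci(np.mean, data, n_boot=400, seed=2)
        assert lo <= float(np.mean(data[0])) <= hi


class TestModelGrid:
    def _toy_inputs(self, seed=0, n=80):
        rng = np.random.default_rng(seed)
        ids = [f"P{i:03d}" for i in range(n)]
        msi = pd.DataFrame(
            rng.normal(size=(n, 5)),
            index=ids,
            columns=[f"MSI {i}" for i in range(1, 6)],
        )
        lp = msi["MSI 1"].to_numpy()
        t_event = rng.exponential(1 / (0.02 * np.exp(lp)))
        t_cens = np.minimum(rng.exponential(100, n), 96)
        records = pd.DataFrame(
            {
                "time_months": np.maximum(np.minimum(t_event, t_cens), 1e-3),
                "event": (t_event <= t_cens).astype(int),
                "age_years": rng.normal(43, 8, n),
                "t_stage": rng.integers(1, 5, n),
                "n_stage": rng.integers(0, 4, n),
                "ebv_dna_copies_per_ml": rng.lognormal(8, 1.2, n),
            },
            index=ids,
        )
        split = pd.Series(
            ["train"] * (3 * n // 4) + ["test"] * (n - 3 * n // 4), index=ids
        )
        tables = {("T1", "GTVp"): msi, ("T1", "MLN"): msi * 0.5 + 1}
        return tables, records, split

    def test_c_model_identical_across_cells_and_layout(self):
        tables, records, split = self._toy_inputs()
        grid = run_model_grid(
            tables, records, split,
            params=ModelGridParams(penalty=1.0, n_boot=100, seed=0),
        )
        c_rows = grid[grid["model"] == "C"]
        assert len(c_rows) == 2  # one per split
        assert set(grid["model"]) == {"C", "R", "CR"}
        r_rows = grid[grid["model"] != "C"]
        assert len(r_rows) == 2 * 2 * 2  # 2 cells x 2 models x 2 splits
        assert grid["c_index"].between(0, 1).all()

    def test_informative_features_beat_null_c_model(self):
        tables, records, split = self._toy_inputs(seed=3, n=120)
        grid = run_model_grid(
            tables, records, split,
            params=ModelGridParams(penalty=1.0, n_boot=100, seed=0),
        ).set_index(["channel", "region", "model", "split"])
        r_train = grid.loc[("T1", "GTVp", "R", "train"), "c_index"]
        assert r_train > 0.6
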