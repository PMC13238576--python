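import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ntheat import casecrossover as cc


def dummy_poisson_mle(X, y, strata):
    """Independent oracle: full Poisson MLE with explicit stratum intercepts."""
    dummies = (strata[:, None] == np.unique(strata)[None, :]).astype(float)
    design = np.hstack([dummies, X])
    res = sm.GLM(y, design, family=sm.families.Poisson()).fit(maxiter=200, tol=1e-12)
    return res.params[dummies.shape[1]:]


def random_instance(rng, n_strata=None, n_days=None, p_cols=4):
    """Random identified instance: resamples until the conditional design has full rank."""
    while True:
        ns = n_strata or rng.integers(2, 7)
        nd = n_days or rng.integers(3, 9)
        strata = np.repeat(np.arange(ns), nd)
        n = len(strata)
        X = np.column_stack(
            [
                rng.integers(0, 2, n).astype(float),
                rng.integers(0, 2, n).astype(float),
                rng.integers(0, 2, n).astype(float),
                rng.normal(8, 2, n),
            ]
        )[:, :p_cols]
        beta = np.array([0.05, 0.1, -0.05, 0.01])[:p_cols]
        mu = 5 * np.exp(X @ beta)
        y = rng.poisson(mu).astype(float)
        d = make_design(X, y, strata)
        if d.n_strata_used == 0:
            continue
        # identified iff the within-stratum centered design has full column rank
        centered = np.vstack(
            [d.X[d.strata == s] - d.X[d.strata == s].mean(axis=0) for s in np.unique(d.strata)]
        )
        if np.linalg.matrix_rank(centered, tol=1e-8) == d.X.shape[1]:
            return X, y, strata


def make_design(X, y, strata, cols=None):
    cols = cols or [f"x{j}" for j in range(X.shape[1])]
    order = np.argsort(strata, kind="stable")
    return cc._filter_design(X[order], y[order], strata[order], cols)


class TestFilterDesign:
    def test_zero_total_stratum_dropped(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        y = np.array([0.0, 0.0, 2.0, 3.0])
        strata = np.array([0, 0, 1, 1])
        d = make_design(X, y, strata)
        assert d.n_strata_dropped_zero == 1
        assert d.n_strata_used == 1

    def test_invariant_stratum_dropped(self):
        X = np.array([[1.0], [1.0], [0.0], [1.0]])
        y = np.array([2.0, 1.0, 2.0, 3.0])
        strata = np.array([0, 0, 1, 1])
        d = make_design(X, y, strata)
        assert d.n_strata_dropped_invariant == 1
        assert d.n_strata_used == 1

    def test_dropping_invariant_strata_changes_no_estimate(self):
        rng = np.random.default_rng(8)
        X, y, strata = random_instance(rng, n_strata=4, n_days=6)
        fit_all = cc.fit_conditional_poisson(make_design(X, y, strata))
        # append an exposure-invariant stratum: contributes a constant to the likelihood
        X2 = np.vstack([X, np.tile([1.0, 0.0, 1.0, 8.0], (4, 1))])
        y2 = np.concatenate([y, [3, 2, 4, 1]])
        strata2 = np.concatenate([strata, [99] * 4])
        fit_aug = cc.fit_conditional_poisson(make_design(X2, y2, strata2))
        assert np.allclose(fit_all.beta, fit_aug.beta, atol=1e-10)


class TestConditionalPoissonFit:
    def test_single_stratum_closed_form(self):
        # counts (4,5,3) unexposed vs (6,6) exposed: RR = mean ratio = 1.5
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0]])
        y = np.array([4.0, 5.0, 3.0, 6.0, 6.0])
        d = make_design(X, y, np.zeros(5, dtype=int))
        fit = cc.fit_conditional_poisson(d)
        assert fit.rr[0] == pytest.approx(1.5, abs=1e-8)
        assert fit.beta[0] == pytest.approx(np.log(1.5), abs=1e-8)

    def test_no_contrast_gives_null_estimate(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        y = np.array([3.0, 3.0, 5.0, 5.0])
        d = make_design(X, y, np.array([0, 0, 1, 1]))
        fit = cc.fit_conditional_poisson(d)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.rr[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_stratum_dummy_mle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            X, y, strata = random_instance(rng)
            d = make_design(X, y, strata)
            if d.n_strata_used == 0:
                continue
            fit = cc.fit_conditional_poisson(d)
            ref = dummy_poisson_mle(d.X, d.y, d.strata)
            assert np.allclose(fit.beta, ref, atol=1e-6)

    def test_stratum_constant_offset_invariance(self):
        rng = np.random.default_rng(13)
        X, y, strata = random_instance(rng, n_strata=5, n_days=6)
        d = make_design(X, y, strata)
        fit = cc.fit_conditional_poisson(d)
        # add a per-stratum constant to the continuous column
        X_off = d.X.copy()
        offsets = {s: v for s, v in enumerate(np.linspace(-3, 3, d.n_strata_used))}
        X_off[:, 3] += np.array([offsets[s] for s in d.strata])
        d_off = cc.DesignMatrix(
            X=X_off, y=d.y, strata=d.strata, columns=d.columns,
            n_strata_used=d.n_strata_used, n_strata_dropped_zero=0,
            n_strata_dropped_invariant=0,
        )
        fit_off = cc.fit_conditional_poisson(d_off)
        assert np.allclose(fit.beta, fit_off.beta, atol=1e-7)

    def test_separation_raises(self):
        # exposure present exactly on the single positive-count day per stratum
        X = np.array([[1.0], [0.0], [0.0], [1.0], [0.0], [0.0]])
        y = np.array([5.0, 0.0, 0.0, 7.0, 0.0, 0.0])
        strata = np.array([0, 0, 0, 1, 1, 1])
        d = make_design(X, y, strata)
        with pytest.raises((cc.SeparationError, cc.ConvergenceError)):
            cc.fit_conditional_poisson(d, max_iter=25)


class TestDispersion:
    @staticmethod
    def _design(rng, n_strata=2500, n_days=4, nb=False):
        strata = np.repeat(np.arange(n_strata), n_days)
        X = rng.integers(0, 2, n_strata * n_days).astype(float)[:, None]
        mu = 8.0 * np.exp(0.1 * X[:, 0])
        if nb:
            lam = rng.gamma(shape=mu, scale=1.0)  # variance 2*mu mixture
            y = rng.poisson(lam).astype(float)
        else:
            y = rng.poisson(mu).astype(float)
        return make_design(X, y, strata)

    def test_poisson_data_phi_in_theoretical_band(self):
        rng = np.random.default_rng(17)
        d = self._design(rng)
        fit = cc.fit_conditional_poisson(d)
        df = d.X.shape[0] - d.X.shape[1] - d.n_strata_used
        lo, hi = cc.dispersion_band(df)
        assert lo <= fit.dispersion <= hi

    def test_overdispersed_data_phi_near_two(self):
        rng = np.random.default_rng(18)
        d = self._design(rng, nb=True)
        fit = cc.fit_conditional_poisson(d)
        assert 1.8 <= fit.dispersion <= 2.2

    def test_perfect_fit_gives_zero(self):
        d = cc.DesignMatrix(
            X=np.array([[0.0], [1.0]]), y=np.array([2.0, 3.0]),
            strata=np.array([0, 0]), columns=["x"], n_strata_used=1,
            n_strata_dropped_zero=0, n_strata_dropped_invariant=0,
        )
        # fitted means equal observed: saturated single stratum
        with pytest.raises(ValueError, match="degrees of freedom"):
            cc.estimate_dispersion(d, np.array([2.0, 3.0]))
        d3 = cc.DesignMatrix(
            X=np.array([[0.0], [1.0], [0.0]]), y=np.array([2.0, 3.0, 2.0]),
            strata=np.array([0, 0, 0]), columns=["x"], n_strata_used=1,
            n_strata_dropped_zero=0, n_strata_dropped_invariant=0,
        )
        assert cc.estimate_dispersion(d3, np.array([2.0, 3.0, 2.0])) == pytest.approx(0.0)


class TestBuildDesignFromStratumDays:
    @staticmethod
    def _stratum_days():
        dates = pd.date_range("2002-01-01", periods=28)
        df = pd.DataFrame(
            {
                "region_id": "A",
                "date": dates,
                "year": dates.year,
                "month": dates.month,
                "dow": dates.dayofweek + 1,
                "count": np.arange(28) % 5 + 1,
                "exposure_level": ["none"] * 20 + ["low"] * 4 + ["severe_extreme"] * 4,
                "holiday": [False] * 7 + [True] + [False] * 20,
                "pm25_ugm3": np.linspace(5, 9, 28),
            }
        )
        return df

    def test_exposure_reference_coding(self):
        d = cc.build_design(self._stratum_days())
        assert d.columns == ["hw_low", "hw_severe_extreme", "holiday", "pm25"]

    def test_missing_pm25_row_excluded(self):
        df = self._stratum_days()
        df.loc[3, "pm25_ugm3"] = np.nan
        d = cc.build_design(df)
        assert d.n_rows_dropped_missing == 1
        d2 = cc.build_design(df, use_pm25=False)
        assert d2.n_rows_dropped_missing == 0
        assert "pm25" not in d2.columns

    def test_different_dow_different_strata(self):
        df = self._stratum_days()
        d = cc.build_design(df, use_pm25=False)
        # 7 day-of-week strata in one region-month, minus invariant/zero drops
        total = d.n_strata_used + d.n_strata_dropped_zero + d.n_strata_dropped_invariant
        assert total == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cc.build_design(self._stratum_days().iloc[:0])


class TestSummaries:
    def test_percent_change_formatting(self):
        fit = cc.FitResult(
            columns=["hw_low", "hw_severe_extreme"],
            beta=np.array([0.0, np.log(1.061)]),
            cov=np.diag([0.0001, 0.0001]),
            dispersion=1.0, n_rows=10, n_strata_used=2,
            n_strata_dropped_zero=0, n_strata_dropped_invariant=0,
            n_rows_dropped_missing=0, n_iter=3, loglik=0.0,
        )
        rows = cc.summarize_rr(fit)
        assert rows.loc[0, "rr"] == pytest.approx(1.0)
        assert rows.loc[0, "pct_change"] == pytest.approx(0.0)
        assert rows.loc[1, "rr"] == pytest.approx(1.061)
        assert rows.loc[1, "pct_change"] == pytest.approx(6.1)

    def test_rr_percent_identity(self):
        assert round((1.044 - 1) * 100, 1) == 4.4
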