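"""Stage-1 mixed models: OLS and brute-force REML oracles, heritability
closed forms, and standardization round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from mtgwas.simulate import DesignSpec, simulate_trial
from mtgwas.trials import TrialFit, cullis_h2, fit_trial, standardize_traits


def rcbd_records(vals: pd.Series, n_reps=3, sigma_block=1.0, sigma_e=1.0, seed=0):
    d = DesignSpec(kind="rcbd", n_reps=n_reps, sigma_block=sigma_block,
                   sigma_e=sigma_e)
    return simulate_trial(vals, d, rng=np.random.default_rng(seed)), d


class TestFitTrial:
    def test_balanced_rcbd_blues_equal_ols_two_way_fit(self):
        vals = pd.Series([2.0, -1.0, 0.5, 3.0, -2.5], index=list("abcde"))
        rec, d = rcbd_records(vals, seed=2)
        fit = fit_trial(rec, d, line_as="fixed")
        # OLS oracle: cell-means for lines, sum-zero block contrasts
        lines = sorted(vals.index)
        blocks = sorted(rec["block"].unique())
        Xl = pd.get_dummies(rec["line"]).reindex(columns=lines).to_numpy(float)
        cb = pd.Categorical(rec["block"], categories=blocks)
        C = np.vstack([np.eye(len(blocks) - 1), -np.ones((1, len(blocks) - 1))])
        X = np.hstack([Xl, C[cb.codes]])
        beta = np.linalg.lstsq(X, rec["value"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.blues.reindex(lines).to_numpy(),
                           beta[: len(lines)], atol=1e-8)
        # in a balanced complete design the BLUE is the raw line mean
        raw = rec.groupby("line")["value"].mean()
        assert np.allclose(fit.blues.reindex(lines), raw.reindex(lines), atol=1e-8)

    def test_tiny_reml_matches_direct_optimizer_oracle(self):
        # 6 lines x 2 complete blocks, line random, block fixed
        vals = pd.Series([1.0, 0.2, -0.5, 2.0, -1.0, 0.3],
                         index=[f"L{i}" for i in range(6)])
        rec, d = rcbd_records(vals, n_reps=2, sigma_block=0.5, sigma_e=0.8, seed=4)
        fit = fit_trial(rec, d, line_as="random")

        # independent dense REML oracle over (sigma_g2, sigma_e2)
        y = rec["value"].to_numpy()
        m = len(y)
        lines = sorted(vals.index)
        Z = pd.get_dummies(rec["line"]).reindex(columns=lines).to_numpy(float)
        blocks = sorted(rec["block"].unique())
        cb = pd.Categorical(rec["block"], categories=blocks)
        C = np.vstack([np.eye(len(blocks) - 1), -np.ones((1, len(blocks) - 1))])
        X = np.hstack([np.ones((m, 1)), C[cb.codes]])
        q = X.shape[1]

        def neg_reml(log_var):
            sg2, se2 = np.exp(log_var)
            V = sg2 * Z @ Z.T + se2 * np.eye(m)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            resid = y - X @ beta
            ll = -0.5 * (
                (m - q) * np.log(2 * np.pi)
                + np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XtViX)[1]
                + resid @ Vi @ resid
            )
            return -ll

        res = minimize(neg_reml, np.log([1.0, 1.0]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)
        sg2, se2 = np.exp(res.x)
        assert fit.sigma_g2 == pytest.approx(sg2, rel=1e-3, abs=1e-6)
        assert fit.sigma_e2 == pytest.approx(se2, rel=1e-3, abs=1e-6)

    def test_lattice_parameter_recovery(self):
        # truth: sigma_g2=4, sigma_b2=1, sigma_e2=2; averaged over simulations
        rng = np.random.default_rng(8)
        truth = dict(g=4.0, b=1.0, e=2.0)
        d = DesignSpec(kind="lattice", n_reps=3, n_blocks=10, block_size=10,
                       checks=("C1", "C2"), sigma_rep=0.3,
                       sigma_block=np.sqrt(truth["b"]), sigma_e=np.sqrt(truth["e"]))
        est = []
        for _ in range(50):
            vals = pd.Series(rng.normal(0, np.sqrt(truth["g"]), 80),
                             index=[f"L{i}" for i in range(80)])
            rec = simulate_trial(vals, d, rng=rng)
            fit = fit_trial(rec, d, line_as="random")
            est.append([fit.sigma_g2, fit.varcomps["block"], fit.sigma_e2])
        mean = np.mean(est, axis=0)
        assert mean[0] == pytest.approx(truth["g"], rel=0.15)
        assert mean[1] == pytest.approx(truth["b"], rel=0.15)
        assert mean[2] == pytest.approx(truth["e"], rel=0.15)

    def test_blue_blup_correlation_on_balanced_data(self):
        rng = np.random.default_rng(9)
        vals = pd.Series(rng.normal(0, 2, 60), index=[f"L{i}" for i in range(60)])
        rec, d = rcbd_records(vals, seed=10)
        blues = fit_trial(rec, d, line_as="fixed").blues
        blups = fit_trial(rec, d, line_as="random").blups
        r = np.corrcoef(blues.sort_index(), blups.sort_index())[0, 1]
        assert r > 0.99

    def test_unbalanced_data_handled(self):
        rng = np.random.default_rng(12)
        vals = pd.Series(rng.normal(0, 2, 30), index=[f"L{i}" for i in range(30)])
        d = DesignSpec(kind="rcbd", n_reps=3, missing_rate=0.15)
        rec = simulate_trial(vals, d, rng=rng)
        fit = fit_trial(rec, d, line_as="random")
        assert fit.sigma_g2 > 0
        assert cullis_h2(fit).h2 <= 1.0

    def test_confounded_design_errors(self):
        # every line in its own block: block and line confounded
        rec = pd.DataFrame({
            "line": [f"L{i}" for i in range(6)],
            "rep": ["r1"] * 6,
            "block": [f"b{i}" for i in range(6)],
            "is_check": [False] * 6,
            "value": np.arange(6.0),
        })
        with pytest.raises(ValueError):
            fit_trial(rec, DesignSpec(kind="rcbd"), line_as="fixed")

    def test_log_transform_applied(self):
        vals = pd.Series([1.0, 2.0, 4.0], index=list("abc"))
        d = DesignSpec(kind="rcbd", n_reps=2, sigma_block=0.0, sigma_e=0.0)
        rec = simulate_trial(np.exp(vals), d, line_ids=list("abc"),
                             rng=np.random.default_rng(0))
        fit = fit_trial(rec, d, line_as="fixed", log_transform=True)
        assert np.allclose(fit.blues.reindex(list("abc")), vals, atol=1e-8)

    def test_reml_estimates_are_local_optimum(self):
        vals = pd.Series(np.random.default_rng(1).normal(0, 2, 25),
                         index=[f"L{i}" for i in range(25)])
        rec, d = rcbd_records(vals, seed=3)
        fit = fit_trial(rec, d, line_as="random")
        from mtgwas.trials import _profiled_reml, _build_design
        X, _, rand, _, _ = _build_design(rec, d, "random")
        # perturbing the fitted ratio lowers the restricted likelihood
        # (re-fit from a distant start reaches the same optimum)
        gamma2, s2b, ll2 = _profiled_reml(rec["value"].to_numpy(), X,
                                          [rand[t] for t in rand])
        assert ll2 == pytest.approx(fit.loglik, abs=1e-6)


class TestCullisH2:
    def _fit_with_pev(self, sg2, pev):
        lines = [f"L{i}" for i in range(pev.shape[0])]
        return TrialFit(
            varcomps={"line": sg2, "residual": 1.0},
            fixed_effects=pd.Series(dtype=float),
            blues=None,
            blups=pd.Series(np.zeros(len(lines)), index=lines),
            pev=pd.DataFrame(pev, index=lines, columns=lines),
            loglik=0.0, n_obs=10, design_kind="rcbd", line_as="random",
        )

    def test_zero_vbar_gives_one(self):
        # constant PEV matrix -> all pairwise difference variances are zero
        fit = self._fit_with_pev(2.0, np.full((4, 4), 0.7))
        assert cullis_h2(fit).h2 == 1.0

    def test_vbar_two_sigma_g2_gives_zero(self):
        sg2 = 1.5
        pev = np.eye(4) * sg2   # vbar = 2 sg2 for diagonal PEV = sg2 I
        res = cullis_h2(self._fit_with_pev(sg2, pev))
        assert res.vbar_blup == pytest.approx(2 * sg2)
        assert res.h2 == 0.0

    def test_zero_genetic_variance_defined_as_zero(self):
        fit = self._fit_with_pev(0.0, np.eye(3))
        assert cullis_h2(fit).h2 == 0.0

    def test_balanced_rcbd_equals_entry_mean_heritability(self):
        rng = np.random.default_rng(20)
        vals = pd.Series(rng.normal(0, 2, 40), index=[f"L{i}" for i in range(40)])
        rec, d = rcbd_records(vals, n_reps=3, seed=21)
        fit = fit_trial(rec, d, line_as="random")
        h2 = cullis_h2(fit).h2
        closed = fit.sigma_g2 / (fit.sigma_g2 + fit.sigma_e2 / 3)
        assert h2 == pytest.approx(closed, abs=1e-6)

    def test_h2_in_unit_interval(self):
        rng = np.random.default_rng(22)
        for seed in range(3):
            vals = pd.Series(rng.normal(0, 0.5, 20),
                             index=[f"L{i}" for i in range(20)])
            rec, d = rcbd_records(vals, sigma_e=2.0, seed=seed)
            fit = fit_trial(rec, d, line_as="random")
            assert 0.0 <= cullis_h2(fit).h2 <= 1.0


class TestStandardize:
    def test_simple_column(self):
        out = standardize_traits(pd.DataFrame({"t": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["t"], [-1.0, 0.0, 1.0])

    def test_missing_preserved_and_moments_over_observed(self):
        out = standardize_traits(pd.DataFrame({"t": [1.0, np.nan, 3.0]}))
        assert np.isnan(out["t"].iloc[1])
        obs = out["t"].dropna()
        assert obs.mean() == pytest.approx(0.0, abs=1e-12)
        assert obs.var(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_roundtrip_moments_random_input(self):
        rng = np.random.default_rng(30)
        df = pd.DataFrame(rng.normal(5, 3, size=(50, 4)))
        out = standardize_traits(df)
        assert np.allclose(out.mean(), 0.0, atol=1e-12)
        assert np.allclose(out.var(ddof=1), 1.0, atol=1e-12)

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="[Zz]ero variance"):
            standardize_traits(pd.DataFrame({"t": [1.0, 1.0, 1.0]}))
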