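"""GLS scan, thresholds, classification, refits and variance explained."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtgwas.genotypes import KinshipMatrix, loco_grms, vanraden_grm
from mtgwas.multitrait import NullModelFit
from mtgwas.scan import (
    bonferroni_threshold,
    classify_associations,
    gls_scan,
    refit_snp,
    variance_explained,
)
from mtgwas.simulate import SimConfig, simulate_genotypes

from conftest import make_genotypes


def make_null_fit(sigma_T, sigma_R, traits=None):
    sigma_T = np.asarray(sigma_T, float)
    T = sigma_T.shape[0]
    return NullModelFit(
        structure="UNS", sigma_T=sigma_T, sigma_R=np.asarray(sigma_R, float),
        beta=np.zeros((1, T)), beta_cov=np.eye(T), loglik=0.0, k=0, aic=0.0,
        n_lines=0, trait_names=traits or [f"t{i+1}" for i in range(T)],
        converged=True,
    )


class TestBonferroniThreshold:
    def test_single_test_reduces_to_alpha(self):
        assert bonferroni_threshold(0.05, 150_000, 150_000) == pytest.approx(
            np.log10(1 / 0.05), abs=1e-9
        )
        assert round(bonferroni_threshold(0.05, 150_000, 150_000), 3) == 1.301

    def test_five_thousand_tests(self):
        thr = bonferroni_threshold(0.05, 5_000 * 150_000, 150_000)
        assert thr == pytest.approx(5.0, abs=1e-12)

    def test_published_default_threshold(self):
        assert round(bonferroni_threshold(), 2) == 4.94

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0)


class TestGlsScan:
    def dense_gls_oracle(self, Y, x, K, S, sR):
        """Explicit (nT)x(nT) GLS for one SNP: estimates and covariance."""
        n, T = Y.shape
        V = np.kron(K, S) + np.kron(np.eye(n), np.diag(sR))
        X = np.hstack([np.kron(np.ones((n, 1)), np.eye(T)),
                       np.kron(x.reshape(-1, 1), np.eye(T))])
        Vi = np.linalg.inv(V)
        A = X.T @ Vi @ X
        est = np.linalg.solve(A, X.T @ Vi @ Y.ravel())
        cov = np.linalg.inv(A)
        return est[T:], cov[T:, T:]

    def test_matches_dense_oracle_tiny(self):
        rng = np.random.default_rng(50)
        n, T = 8, 2
        A = rng.standard_normal((n, n + 4))
        K = A @ A.T / (n + 4)
        Y = rng.standard_normal((n, T))
        x = rng.choice([0.0, 2.0], size=n)
        S = np.array([[1.0, 0.3], [0.3, 0.8]])
        sR = np.array([0.4, 0.6])
        G = make_genotypes(np.column_stack([x, rng.choice([0.0, 2.0], n)]),
                           chrom=["1", "2"], pos=[100, 100])
        null = make_null_fit(S, sR)
        loco = {"1": KinshipMatrix(K, G.line_ids),
                "2": KinshipMatrix(K, G.line_ids)}
        scan = gls_scan(Y, G, null, loco)
        alpha_o, cov_o = self.dense_gls_oracle(Y, x, K, S, sR)
        row = scan.loc[scan["chrom"] == "1"].iloc[0]
        est = np.array([row["effect_t1"], row["effect_t2"]])
        assert np.allclose(est, alpha_o, atol=1e-10)
        w_o = alpha_o @ np.linalg.solve(cov_o, alpha_o)
        assert row["wald"] == pytest.approx(w_o, abs=1e-10)
        assert row["minus_log10_p"] == pytest.approx(
            -np.log10(stats.chi2.sf(w_o, T)), abs=1e-8
        )

    def test_diagonal_covariance_decomposes_into_single_trait_statistics(self):
        # with diagonal Sigma_T and Sigma_R traits are independent, so the
        # joint Wald statistic is the sum of per-trait statistics
        rng = np.random.default_rng(51)
        n, T = 40, 3
        G = simulate_genotypes(SimConfig(n_lines=n, n_chrom=2, snps_per_chrom=30,
                                         chrom_length_bp=5_000_000, seed=52))
        K = vanraden_grm(G)
        Y = rng.standard_normal((n, T))
        S = np.diag([0.6, 0.8, 0.4])
        sR = np.array([0.5, 0.4, 0.7])
        loco = loco_grms(G)
        joint = gls_scan(Y, G, make_null_fit(S, sR), loco)
        singles = []
        for t in range(T):
            st = gls_scan(Y[:, [t]], G,
                          make_null_fit(S[np.ix_([t], [t])], sR[[t]]), loco)
            singles.append(st.set_index("snp")["wald"])
        total = sum(s.reindex(joint["snp"]).to_numpy() for s in singles)
        assert np.allclose(joint["wald"].to_numpy(), total, atol=1e-8)

    def test_pvalues_invariant_to_joint_permutation(self, small_panel):
        rng = np.random.default_rng(53)
        G = small_panel
        n = G.n_lines
        Y = rng.standard_normal((n, 2))
        null = make_null_fit([[0.5, 0.2], [0.2, 0.5]], [0.5, 0.5])
        loco = loco_grms(G)
        scan = gls_scan(Y, G, null, loco)
        perm = rng.permutation(n)
        Gp = make_genotypes(G.calls[perm], chrom=G.snp_map["chrom"].tolist(),
                            pos=G.snp_map["pos"].tolist(),
                            line_ids=[G.line_ids[i] for i in perm])
        locop = {c: KinshipMatrix(k.values[np.ix_(perm, perm)], Gp.line_ids)
                 for c, k in loco.items()}
        scanp = gls_scan(Y[perm], Gp, null, locop)
        assert np.allclose(scanp["minus_log10_p"].to_numpy(),
                           scan["minus_log10_p"].to_numpy(), atol=1e-8)

    def test_monomorphic_snp_skipped(self):
        rng = np.random.default_rng(54)
        n = 30
        calls = np.column_stack([np.zeros(n), rng.choice([0.0, 2.0], n)])
        G = make_genotypes(calls, chrom=["1", "1"], pos=[10, 20])
        K = KinshipMatrix(np.eye(n) * 2, G.line_ids)
        scan = gls_scan(rng.standard_normal((n, 2)), G,
                        make_null_fit(np.eye(2) * 0.5, [0.5, 0.5]), {"1": K})
        assert scan["snp"].tolist() == ["S1_20"]


class TestClassify:
    def test_partition_counts(self):
        rec = pd.DataFrame({"minus_log10_p": [5.1, 4.5, 3.9]})
        out = classify_associations(rec)
        assert out["classification"].tolist() == ["significant", "suggestive", "none"]

    def test_boundary_at_significance_threshold_is_significant(self):
        rec = pd.DataFrame({"minus_log10_p": [4.94, 4.0, 3.9999]})
        out = classify_associations(rec, threshold_sig=4.94, threshold_sug=4.0)
        assert out["classification"].tolist() == ["significant", "suggestive", "none"]

    def test_empty_input(self):
        out = classify_associations(pd.DataFrame({"minus_log10_p": []}))
        assert len(out) == 0 and "classification" in out.columns

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            classify_associations(pd.DataFrame({"minus_log10_p": [1.0]}),
                                  threshold_sig=3.0, threshold_sug=4.0)


class TestVarianceExplained:
    def test_closed_form(self):
        ve = variance_explained(0.5, 0.5, 1.0)
        assert ve.v_m == pytest.approx(0.25)      # Var(x) = 4pq = 1
        assert ve.percent == pytest.approx(25.0)

    def test_fixed_allele_explains_nothing(self):
        assert variance_explained(3.0, 0.0, 1.0).percent == 0.0

    def test_monte_carlo_sampling_oracle(self):
        rng = np.random.default_rng(55)
        p, alpha = 0.3, 0.7
        x = rng.choice([0.0, 2.0], size=100_000, p=[1 - p, p])
        empirical = np.var(x * alpha)
        assert variance_explained(alpha, p, 1.0).v_m == pytest.approx(
            empirical, rel=0.02
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            variance_explained(1.0, 1.5, 1.0)
        with pytest.raises(ValueError):
            variance_explained(1.0, 0.5, 0.0)


class TestRefit:
    def _simulated_hit(self, seed=60, n=300, alpha=(0.6, 0.0)):
        rng = np.random.default_rng(seed)
        G = simulate_genotypes(SimConfig(n_lines=n, n_chrom=2, snps_per_chrom=80,
                                         chrom_length_bp=20_000_000, seed=seed))
        K = vanraden_grm(G)
        maf_ok = np.abs(G.calls.mean(axis=0) / 2 - 0.5) < 0.2
        j = int(np.flatnonzero(maf_ok)[0])
        x = G.calls[:, j]
        T = len(alpha)
        Lk = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
        S = np.array([[0.4, 0.1], [0.1, 0.4]])
        U = Lk @ rng.standard_normal((n, T)) @ np.linalg.cholesky(S).T
        Y = np.outer(x - x.mean(), alpha) + U + rng.standard_normal((n, T)) * 0.6
        return Y, x, K, j, G

    def test_refit_close_to_gls_on_strong_hit(self):
        Y, x, K, j, G = self._simulated_hit()
        null = make_null_fit([[0.4, 0.1], [0.1, 0.4]], [0.36, 0.36])
        loco = {c: K for c in G.chromosomes}   # same K: isolates the estimator
        scan = gls_scan(Y, G, null, loco)
        snp_id = G.snp_map.at[j, "snp"]
        row = scan.set_index("snp").loc[snp_id]
        res = refit_snp(Y, x, K, "UNS", snp_id=snp_id, null_fit=null)
        assert res.effects["effect"].iloc[0] == pytest.approx(
            row["effect_t1"], rel=0.10
        )
        assert res.refit_converged

    def test_wald_inference_and_favorable_allele(self):
        Y, x, K, j, G = self._simulated_hit()
        res = refit_snp(Y, x, K, "UNS", snp_id="s")
        eff = res.effects
        # trait 1 carries the planted effect, trait 2 does not
        assert eff["wald_p"].iloc[0] < 0.01
        assert eff["ci_low"].iloc[0] > 0 or eff["ci_high"].iloc[0] < 0
        assert eff["ci_low"].iloc[1] < 0 < eff["ci_high"].iloc[1]
        assert eff["favorable_allele"].iloc[0] == (
            "minor" if eff["effect"].iloc[0] > 0 else "major"
        )
        assert np.allclose(eff["ci_high"] - eff["effect"], 1.96 * eff["se"])
        assert (eff["pct_var_explained"] >= 0).all()
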