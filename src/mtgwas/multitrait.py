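"""Multi-trait null mixed model with Kronecker covariance.

Model: for line i and trait t,

    y_it = mu_t + G_it + e_it,

with ``vec(G) ~ N(0, K x Sigma_T)`` (``x`` the Kronecker product), ``K`` the
genomic relationship matrix between lines, ``Sigma_T`` the between-trait
genetic covariance, and residuals independent across traits with diagonal
``Sigma_R``.  ``Sigma_T`` is parameterized as factor-analytic of order 1 or 2
(``Lambda Lambda' + diag(Psi)``) or unstructured (Cholesky); the structure is
chosen by AIC over the REML log-likelihood, counting covariance parameters
only (all candidates share the same fixed effects).

With complete trait data the restricted likelihood is evaluated in the
eigenbasis of ``K``: rotating by ``U`` (``K = U diag(d) U'``) de-correlates
lines, leaving independent T-variate normals with covariance
``d_i Sigma_T + Sigma_R`` — an O(n T^3) evaluation.  With missing trait
cells the exact observed-cell dense restricted likelihood is used instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "FactorAnalyticParams",
    "NullModelFit",
    "fa_covariance",
    "covariance_param_count",
    "reml_fit",
    "reml_null",
    "select_structure",
]

_LOG2PI = np.log(2.0 * np.pi)
STRUCTURES = ("FA1", "FA2", "UNS")


@dataclass
class FactorAnalyticParams:
    """Loadings (T x q) and specific variances (T,) of Sigma_T = LL' + diag(Psi).

    For order 2 the rotational freedom is pinned by the constraint
    ``loadings[0, 1] == 0`` (first trait loads only on the first factor).
    """

    loadings: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        self.psi = np.asarray(self.psi, dtype=float)
        if (self.psi < 0).any():
            raise ValueError("specific variances must be >= 0")
        q = self.loadings.shape[1]
        if q == 2 and self.loadings[0, 1] != 0.0:
            raise ValueError("FA2 identifiability requires loadings[0, 1] == 0")
        if q > 2:
            raise ValueError("only factor-analytic orders 1 and 2 are supported")


def fa_covariance(params: FactorAnalyticParams) -> np.ndarray:
    """Sigma_T = Lambda Lambda' + diag(Psi)."""
    L = params.loadings
    return L @ L.T + np.diag(params.psi)


def covariance_param_count(structure: str, T: int) -> int:
    """Number of covariance parameters (Sigma_T plus T residual variances)."""
    if structure == "FA1":
        return 3 * T
    if structure == "FA2":
        return 4 * T - 1
    if structure == "UNS":
        return T * (T + 1) // 2 + T
    raise ValueError(f"unknown structure {structure!r}")


@dataclass
class NullModelFit:
    """REML fit of the Kronecker-covariance multi-trait model."""

    structure: str
    sigma_T: np.ndarray          # T x T genetic covariance
    sigma_R: np.ndarray          # T residual variances (diagonal of Sigma_R)
    beta: np.ndarray             # p x T fixed effects (row 0 = intercepts mu_t)
    beta_cov: np.ndarray         # (pT x pT) covariance of vec(beta), row-major (k,t)
    loglik: float
    k: int
    aic: float
    n_lines: int
    trait_names: list[str]
    converged: bool
    fa_params: FactorAnalyticParams | None = None

    @property
    def mu(self) -> np.ndarray:
        return self.beta[0]

    @property
    def n_traits(self) -> int:
        return self.sigma_T.shape[0]

    def phenotypic_variance(self) -> np.ndarray:
        """Per-trait total (genetic + residual) variance under the null."""
        return np.diag(self.sigma_T) + self.sigma_R

    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "sigma_T": self.sigma_T.tolist(),
            "sigma_R": self.sigma_R.tolist(),
            "mu": self.mu.tolist(),
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "n_lines": self.n_lines,
            "traits": self.trait_names,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _unpack_full(theta: np.ndarray, structure: str, T: int):
    """theta -> (Sigma_T, sigma_R, factor) with variances on the log scale.

    ``factor`` is the loadings matrix (FA) or the Cholesky factor (UNS),
    kept for the analytic gradient's chain rule.
    """
    if structure == "FA1":
        lam = theta[:T].reshape(T, 1)
        psi = np.exp(theta[T : 2 * T])
        sR = np.exp(theta[2 * T : 3 * T])
        S = lam @ lam.T + np.diag(psi)
        return S, sR, lam
    if structure == "FA2":
        lam = np.zeros((T, 2))
        lam[:, 0] = theta[:T]
        lam[1:, 1] = theta[T : 2 * T - 1]     # lam[0, 1] pinned at 0
        psi = np.exp(theta[2 * T - 1 : 3 * T - 1])
        sR = np.exp(theta[3 * T - 1 : 4 * T - 1])
        S = lam @ lam.T + np.diag(psi)
        return S, sR, lam
    if structure == "UNS":
        L = np.zeros((T, T))
        idx = np.tril_indices(T, -1)
        L[np.diag_indices(T)] = np.exp(theta[:T])
        L[idx] = theta[T : T + len(idx[0])]
        sR = np.exp(theta[T + len(idx[0]) :])
        return L @ L.T, sR, L
    raise ValueError(f"unknown structure {structure!r}")


def _unpack(theta: np.ndarray, structure: str, T: int) -> tuple[np.ndarray, np.ndarray]:
    S, sR, _ = _unpack_full(theta, structure, T)
    return S, sR


def _grad_theta(
    G_T: np.ndarray, G_R_diag: np.ndarray, theta: np.ndarray,
    structure: str, T: int, factor: np.ndarray,
) -> np.ndarray:
    """Chain rule from matrix gradients (dl/dSigma_T, diag dl/dSigma_R) to theta.

    ``G_T`` treats the entries of Sigma_T as unconstrained (it is symmetric);
    for S = F F' the loadings/Cholesky gradient is 2 G_T F.
    """
    dF = 2.0 * G_T @ factor
    if structure == "FA1":
        psi = np.exp(theta[T : 2 * T])
        sR = np.exp(theta[2 * T : 3 * T])
        return np.concatenate([dF[:, 0], np.diag(G_T) * psi, G_R_diag * sR])
    if structure == "FA2":
        psi = np.exp(theta[2 * T - 1 : 3 * T - 1])
        sR = np.exp(theta[3 * T - 1 : 4 * T - 1])
        return np.concatenate(
            [dF[:, 0], dF[1:, 1], np.diag(G_T) * psi, G_R_diag * sR]
        )
    # UNS: diagonal of L on the log scale, strict lower triangle free
    idx = np.tril_indices(T, -1)
    sR = np.exp(theta[T + len(idx[0]) :])
    return np.concatenate(
        [np.diag(dF) * np.diag(factor), dF[idx], G_R_diag * sR]
    )


def _fa_params_from_theta(theta: np.ndarray, structure: str, T: int):
    if structure == "FA1":
        return FactorAnalyticParams(theta[:T].reshape(T, 1), np.exp(theta[T : 2 * T]))
    if structure == "FA2":
        lam = np.zeros((T, 2))
        lam[:, 0] = theta[:T]
        lam[1:, 1] = theta[T : 2 * T - 1]
        return FactorAnalyticParams(lam, np.exp(theta[2 * T - 1 : 3 * T - 1]))
    return None


def _project_fa(S: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-truncation of a covariance onto the FA(order) family (for starts)."""
    w, V = np.linalg.eigh(S)
    idx = np.argsort(w)[::-1][:order]
    lam = V[:, idx] * np.sqrt(np.clip(w[idx], 1e-8, None))
    lam = np.atleast_2d(lam.reshape(S.shape[0], order))
    if order == 2:
        # rotate so lam[0, 1] = 0 (Givens on the two factor columns)
        a, b = lam[0, 0], lam[0, 1]
        r = np.hypot(a, b)
        if r > 0:
            c, s = a / r, b / r
            lam = lam @ np.array([[c, -s], [s, c]])
            lam[0, 1] = 0.0
    psi = np.clip(np.diag(S) - np.sum(lam**2, axis=1), 1e-4, None)
    return lam, psi


def _theta_bounds(structure: str, T: int) -> list[tuple[float, float]]:
    """Box bounds keeping log-variances and loadings in a numerically safe
    range (traits are standardized, so |loadings| far above 1 are never
    plausible; variances below e^-12 are effectively zero)."""
    LOG = (-12.0, 4.0)
    LOAD = (-6.0, 6.0)
    if structure == "FA1":
        return [LOAD] * T + [LOG] * T + [LOG] * T
    if structure == "FA2":
        return [LOAD] * (2 * T - 1) + [LOG] * T + [LOG] * T
    n_off = T * (T - 1) // 2
    return [LOG] * T + [LOAD] * n_off + [LOG] * T


def _start_theta(Y: np.ndarray, structure: str) -> np.ndarray:
    T = Y.shape[1]
    S_emp = pd.DataFrame(Y).cov().to_numpy()
    S_emp = np.where(np.isfinite(S_emp), S_emp, 0.0)
    S_emp += 1e-3 * np.eye(T)
    Sg = 0.5 * S_emp
    sR = np.clip(0.5 * np.diag(S_emp), 1e-4, None)
    if structure == "FA1":
        lam, psi = _project_fa(Sg, 1)
        return np.concatenate([lam[:, 0], np.log(psi), np.log(sR)])
    if structure == "FA2":
        lam, psi = _project_fa(Sg, 2)
        return np.concatenate([lam[:, 0], lam[1:, 1], np.log(psi), np.log(sR)])
    L = np.linalg.cholesky(Sg + 1e-4 * np.eye(T))
    idx = np.tril_indices(T, -1)
    return np.concatenate([np.log(np.diag(L)), L[idx], np.log(sR)])


# ---------------------------------------------------------------------------
# restricted likelihood
# ---------------------------------------------------------------------------

class _CompleteContext:
    """Complete-data likelihood pieces in the eigenbasis of K."""

    def __init__(self, Y: np.ndarray, K: np.ndarray, X: np.ndarray):
        d, U = np.linalg.eigh((K + K.T) / 2.0)
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.Yt = U.T @ Y
        self.Xt = U.T @ X
        self.n, self.T = Y.shape
        self.p = X.shape[1]

    def loglik(self, S: np.ndarray, sR: np.ndarray, with_beta: bool = False):
        n, T, p = self.n, self.T, self.p
        V = self.d[:, None, None] * S[None] + np.diag(sR)[None]
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return (-np.inf, None, None) if with_beta else -np.inf
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        Vi = np.linalg.inv(V)
        A = np.einsum("ip,iq,itu->ptqu", self.Xt, self.Xt, Vi, optimize=True)
        A = A.reshape(p * T, p * T)
        b = np.einsum("ip,itu,iu->pt", self.Xt, Vi, self.Yt, optimize=True).ravel()
        quad_y = np.einsum("it,itu,iu->", self.Yt, Vi, self.Yt, optimize=True)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return (-np.inf, None, None) if with_beta else -np.inf
        beta = np.linalg.solve(A, b)
        yPy = quad_y - b @ beta
        ll = -0.5 * ((n * T - p * T) * _LOG2PI + logdet + logdet_A + yPy)
        if with_beta:
            return float(ll), beta.reshape(p, T), np.linalg.inv(A)
        return float(ll)

    def loglik_grads(self, S: np.ndarray, sR: np.ndarray):
        """Restricted log-likelihood plus matrix gradients dl/dSigma_T (full
        symmetric T x T) and the diagonal of dl/dSigma_R.

        Uses dl = -1/2 tr(P dV) + 1/2 y'P dV P y with the projection P of the
        REML likelihood; P y reduces to V^-1 (y - X beta_hat) and the trace
        splits into per-eigenvalue T x T pieces.
        """
        n, T, p = self.n, self.T, self.p
        V = self.d[:, None, None] * S[None] + np.diag(sR)[None]
        try:
            np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        sign_all, logdets = np.linalg.slogdet(V)
        if (sign_all <= 0).any():
            return -np.inf, None, None
        logdet = logdets.sum()
        Vi = np.linalg.inv(V)
        A = np.einsum("ip,iq,itu->ptqu", self.Xt, self.Xt, Vi, optimize=True)
        A = A.reshape(p * T, p * T)
        b = np.einsum("ip,itu,iu->pt", self.Xt, Vi, self.Yt, optimize=True).ravel()
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf, None, None
        Ainv = np.linalg.inv(A)
        beta = (Ainv @ b).reshape(p, T)
        r = self.Yt - self.Xt @ beta
        e = np.einsum("itu,iu->it", Vi, r)
        quad_y = np.einsum("it,itu,iu->", self.Yt, Vi, self.Yt, optimize=True)
        yPy = quad_y - b @ (Ainv @ b)
        ll = -0.5 * ((n * T - p * T) * _LOG2PI + logdet + logdet_A + yPy)
        # M_i = V_i^-1 - V_i^-1 C_i V_i^-1 - e_i e_i'  with  C_i the projection block
        Ainv4 = Ainv.reshape(p, T, p, T)
        C = np.einsum("ik,il,ktlu->itu", self.Xt, self.Xt, Ainv4, optimize=True)
        VCV = np.einsum("itu,iuv,ivw->itw", Vi, C, Vi, optimize=True)
        M = Vi - VCV - e[:, :, None] * e[:, None, :]
        G_T = -0.5 * np.einsum("i,itu->tu", self.d, M)
        G_R_diag = -0.5 * np.einsum("itt->t", M)
        return float(ll), G_T, G_R_diag


class _MissingContext:
    """Exact observed-cell dense restricted likelihood (line-major vec order)."""

    def __init__(self, Y: np.ndarray, K: np.ndarray, X: np.ndarray):
        self.n, self.T = Y.shape
        self.p = X.shape[1]
        self.K = (K + K.T) / 2.0
        self.obs = ~np.isnan(Y).ravel()           # (i, t) row-major
        self.y = Y.ravel()[self.obs]
        Xf = np.kron(X, np.eye(self.T))           # rows (i,t), cols (k,t)
        self.X = Xf[self.obs]

    def loglik(self, S: np.ndarray, sR: np.ndarray, with_beta: bool = False):
        V = np.kron(self.K, S) + np.kron(np.eye(self.n), np.diag(sR))
        V = V[np.ix_(self.obs, self.obs)]
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return (-np.inf, None, None) if with_beta else -np.inf
        from scipy.linalg import cho_solve

        logdet = 2.0 * np.log(np.diag(L)).sum()
        Vi_y = cho_solve((L, True), self.y)
        Vi_X = cho_solve((L, True), self.X)
        A = self.X.T @ Vi_X
        b = self.X.T @ Vi_y
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return (-np.inf, None, None) if with_beta else -np.inf
        beta = np.linalg.solve(A, b)
        yPy = float(self.y @ Vi_y - b @ beta)
        N, q = len(self.y), self.X.shape[1]
        ll = -0.5 * ((N - q) * _LOG2PI + logdet + logdet_A + yPy)
        if with_beta:
            return float(ll), beta.reshape(self.p, self.T), np.linalg.inv(A)
        return float(ll)


def restricted_loglik(
    Y: np.ndarray,
    K: np.ndarray,
    sigma_T: np.ndarray,
    sigma_R: np.ndarray,
    X_cov: np.ndarray | None = None,
) -> float:
    """REML log-likelihood at fixed covariance parameters (used by tests and
    for dense-oracle comparisons)."""
    Y = np.asarray(Y, dtype=float)
    if X_cov is None:
        X_cov = np.ones((Y.shape[0], 1))
    ctx = (
        _CompleteContext(Y, K, X_cov)
        if not np.isnan(Y).any()
        else _MissingContext(Y, K, X_cov)
    )
    return ctx.loglik(np.asarray(sigma_T, float), np.asarray(sigma_R, float))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def reml_fit(
    Y,
    K,
    structure: str,
    X_cov: np.ndarray | None = None,
    trait_names: list[str] | None = None,
    max_iter: int = 500,
) -> NullModelFit:
    """Fit the Kronecker-covariance model by REML for one Sigma_T structure.

    ``Y`` is an n x T matrix (or DataFrame) of standardized line means with
    NaN for unscored trait/line cells; ``K`` a :class:`KinshipMatrix` or
    plain array aligned to the rows of ``Y``.  ``X_cov`` adds fixed
    covariates with trait-specific coefficients (column of ones is implied
    when omitted); this is how a candidate SNP enters in the refit step.
    """
    if isinstance(Y, pd.DataFrame):
        trait_names = trait_names or [str(c) for c in Y.columns]
        Y = Y.to_numpy(dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, T = Y.shape
    if T < 2:
        raise ValueError("multi-trait model needs at least 2 traits")
    if trait_names is None:
        trait_names = [f"trait{t+1}" for t in range(T)]
    Kv = K.values if hasattr(K, "values") else np.asarray(K, dtype=float)
    if Kv.shape != (n, n):
        raise ValueError("kinship not aligned to trait matrix rows")
    if np.linalg.eigvalsh((Kv + Kv.T) / 2.0).min() < -1e-6:
        raise ValueError("kinship matrix is not PSD")
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    if X_cov is None:
        X_cov = np.ones((n, 1))
    X_cov = np.atleast_2d(np.asarray(X_cov, dtype=float))
    if X_cov.shape[0] != n:
        X_cov = X_cov.T

    complete = not np.isnan(Y).any()
    ctx = _CompleteContext(Y, Kv, X_cov) if complete else _MissingContext(Y, Kv, X_cov)

    theta0 = _start_theta(Y, structure)
    bounds = _theta_bounds(structure, T)
    best = {"nll": np.inf, "theta": theta0}

    def _track(theta: np.ndarray, val: float) -> None:
        if val < best["nll"]:
            best["nll"] = val
            best["theta"] = np.array(theta)

    def nll(theta: np.ndarray) -> float:
        S, sR = _unpack(theta, structure, T)
        ll = ctx.loglik(S, sR)
        val = -ll if np.isfinite(ll) else 1e12
        _track(theta, val)
        return val

    if complete:
        # analytic REML gradient in the eigenbasis of K
        def nll_jac(theta: np.ndarray):
            S, sR, factor = _unpack_full(theta, structure, T)
            ll, G_T, G_R = ctx.loglik_grads(S, sR)
            if not np.isfinite(ll):
                return 1e12, np.zeros_like(theta)
            grad = _grad_theta(G_T, G_R, theta, structure, T, factor)
            _track(theta, -ll)
            return -ll, -grad

        objective, jac = nll_jac, True
        opts = {"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-6}
    else:
        objective, jac = nll, False
        opts = {"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-6}

    # L-BFGS-B occasionally ends a line search abnormally near the optimum;
    # restart from the best iterate and call it converged when a restart no
    # longer improves the restricted likelihood (relative tol 1e-8)
    res = optimize.minimize(objective, theta0, jac=jac, method="L-BFGS-B",
                            bounds=bounds, options=opts)
    converged = bool(res.success)
    for _ in range(5):
        if converged:
            break
        prev = best["nll"]
        res = optimize.minimize(objective, best["theta"], jac=jac,
                                method="L-BFGS-B", bounds=bounds, options=opts)
        improvement = prev - min(best["nll"], float(res.fun))
        if bool(res.success) or improvement < 1e-8 * (abs(prev) + 1.0):
            converged = True
    theta_hat = best["theta"] if best["nll"] < res.fun else res.x
    final_nll = min(best["nll"], float(res.fun))
    if not np.isfinite(final_nll) or final_nll >= 1e12:
        raise RuntimeError(
            f"REML fit diverged for structure {structure}: {res.message}"
        )
    if not converged:
        logger.warning("REML %s: no convergence after restarts (message %r)",
                       structure, res.message)

    S, sR = _unpack(theta_hat, structure, T)
    ll, beta, beta_cov = ctx.loglik(S, sR, with_beta=True)
    if beta is None:
        raise RuntimeError(f"REML fit ended at a non-PD point for {structure}")
    k = covariance_param_count(structure, T)
    return NullModelFit(
        structure=structure,
        sigma_T=S,
        sigma_R=sR,
        beta=beta,
        beta_cov=beta_cov,
        loglik=float(ll),
        k=k,
        aic=float(-2.0 * ll + 2.0 * k),
        n_lines=n,
        trait_names=list(trait_names),
        converged=converged,
        fa_params=_fa_params_from_theta(theta_hat, structure, T),
    )


def reml_null(Y, K, structure: str, **kwargs) -> NullModelFit:
    """No-marker null fit (per-trait intercepts only)."""
    fit = reml_fit(Y, K, structure, X_cov=None, **kwargs)
    if not fit.converged:
        raise RuntimeError(f"null model ({structure}) did not converge")
    return fit


def select_structure(fits: list[NullModelFit]) -> NullModelFit:
    """Minimum-AIC fit; exact ties break to the fewest covariance parameters."""
    if len(fits) < 2:
        raise ValueError("need at least two candidate fits")
    traits = {tuple(f.trait_names) for f in fits}
    if len(traits) != 1:
        raise ValueError("candidate fits are not on the same trait set")
    return min(fits, key=lambda f: (f.aic, f.k))
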