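"""Stage-1 single-trait mixed models for designed trials.

Three designs are supported, mirroring how multi-environment sorghum panels
are typically phenotyped:

* ``lattice`` — replicates of incomplete blocks: replicate fixed, block
  random within replicate, checks fixed, line fixed (BLUE) or random (BLUP).
* ``rcbd`` — randomized complete blocks: block fixed, line fixed/random.
* ``augmented`` — unreplicated test lines with repeated checks: block
  random, checks fixed, line fixed/random.

Variance components are estimated by REML with the residual variance
profiled out, so the optimizer works over the (1-2) variance ratios of the
declared random terms.  BLUPs and their prediction-error variances come from
the mixed-model equations at the REML estimates, which is what the Cullis
generalized heritability needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .simulate import DesignSpec

logger = logging.getLogger(__name__)

__all__ = [
    "TrialFit",
    "HeritabilityResult",
    "fit_trial",
    "cullis_h2",
    "standardize_traits",
]

_VAR_FLOOR = 1e-10


@dataclass
class TrialFit:
    """REML fit of one trial/trait."""

    varcomps: dict[str, float]            # random-term variances + "residual"
    fixed_effects: pd.Series              # named fixed-effect estimates
    blues: pd.Series | None               # adjusted line means (line fixed)
    blups: pd.Series | None               # line BLUPs (line random)
    pev: pd.DataFrame | None              # PEV matrix of the line BLUPs
    loglik: float
    n_obs: int
    design_kind: str
    line_as: str

    @property
    def sigma_g2(self) -> float:
        return self.varcomps.get("line", 0.0)

    @property
    def sigma_e2(self) -> float:
        return self.varcomps["residual"]


@dataclass
class HeritabilityResult:
    h2: float
    vbar_blup: float
    sigma_g2: float


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _dummies(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    cats = pd.Categorical(labels)
    Z = np.eye(len(cats.categories))[cats.codes]
    return Z, [str(c) for c in cats.categories]


def _sum_zero(labels: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero contrasts: k levels -> k-1 columns (last level = -1)."""
    cats = pd.Categorical(labels)
    k = len(cats.categories)
    if k == 1:
        return np.empty((len(labels), 0)), []
    C = np.vstack([np.eye(k - 1), -np.ones((1, k - 1))])
    return C[cats.codes], [f"{prefix}[{c}]" for c in cats.categories[:-1]]


def _build_design(
    rec: pd.DataFrame, design: DesignSpec, line_as: str
) -> tuple[np.ndarray, list[str], dict[str, np.ndarray], list[str], list[str]]:
    """Fixed matrix X, its column names, random-term Z matrices, line level
    names for the line term (fixed or random), and check level names."""
    is_check = rec["is_check"].astype(bool).to_numpy()
    test = rec.loc[~is_check]
    checks = rec.loc[is_check]

    X_parts: list[np.ndarray] = []
    names: list[str] = []
    rand: dict[str, np.ndarray] = {}
    line_levels: list[str] = []
    check_levels: list[str] = []

    def check_columns() -> None:
        nonlocal check_levels
        if len(checks) == 0:
            return
        cats = pd.Categorical(rec["line"].where(is_check, other=None))
        check_levels = [str(c) for c in cats.categories]
        Z = np.zeros((len(rec), len(check_levels)))
        obs = cats.codes >= 0
        Z[np.flatnonzero(obs), cats.codes[obs]] = 1.0
        X_parts.append(Z)
        names.extend(f"check[{c}]" for c in check_levels)

    def line_columns() -> np.ndarray:
        nonlocal line_levels
        cats = pd.Categorical(rec["line"].where(~is_check, other=None))
        line_levels = [str(c) for c in cats.categories]
        Z = np.zeros((len(rec), len(line_levels)))
        obs = cats.codes >= 0
        Z[np.flatnonzero(obs), cats.codes[obs]] = 1.0
        return Z

    Zline = line_columns()

    if design.kind == "lattice":
        # replicate fixed, block random within replicate, checks fixed
        if line_as == "fixed":
            X_parts.append(Zline)                       # cell means for lines
            names.extend(f"line[{c}]" for c in line_levels)
            check_columns()
            Xr, nr = _sum_zero(rec["rep"], "rep")
            X_parts.append(Xr); names.extend(nr)
        else:
            X_parts.append(np.ones((len(rec), 1))); names.append("mu")
            Xr, nr = _sum_zero(rec["rep"], "rep")
            X_parts.append(Xr); names.extend(nr)
            check_columns()
            rand["line"] = Zline
        Zb, _ = _dummies(rec["block"])
        rand["block"] = Zb
    elif design.kind == "rcbd":
        # block fixed (block == replicate), no checks expected
        if line_as == "fixed":
            X_parts.append(Zline)
            names.extend(f"line[{c}]" for c in line_levels)
            check_columns()
        else:
            X_parts.append(np.ones((len(rec), 1))); names.append("mu")
            check_columns()
            rand["line"] = Zline
        Xb, nb = _sum_zero(rec["block"], "block")
        X_parts.append(Xb); names.extend(nb)
    elif design.kind == "augmented":
        # block random, checks fixed
        if line_as == "fixed":
            X_parts.append(Zline)
            names.extend(f"line[{c}]" for c in line_levels)
            check_columns()
        else:
            X_parts.append(np.ones((len(rec), 1))); names.append("mu")
            check_columns()
            rand["line"] = Zline
        Zb, _ = _dummies(rec["block"])
        rand["block"] = Zb
    else:
        raise ValueError(f"unknown design kind {design.kind!r}")

    X = np.hstack(X_parts)
    return X, names, rand, line_levels, check_levels


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------

def _profiled_reml(
    y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray]
) -> tuple[np.ndarray, float, float]:
    """REML over variance ratios gamma_r = sigma_r^2 / sigma_e^2.

    Returns (gamma, sigma_e^2, restricted log-likelihood).
    """
    m, q = X.shape
    ZZ = [Z @ Z.T for Z in Zs]

    def neg_loglik(log_gamma: np.ndarray) -> float:
        gamma = np.exp(log_gamma)
        H = np.eye(m)
        for g, A in zip(gamma, ZZ):
            H = H + g * A
        try:
            L = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            return 1e10
        logdet_H = 2.0 * np.log(np.diag(L)).sum()
        Hi_y = np.linalg.solve(H, y)  # could reuse L; clarity first
        Hi_X = np.linalg.solve(H, X)
        XtHiX = X.T @ Hi_X
        sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
        if sign <= 0:
            return 1e10
        beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
        yPy = float(y @ Hi_y - (X.T @ Hi_y) @ beta)
        if yPy <= 0:
            return 1e10
        s2 = yPy / (m - q)
        ll = -0.5 * (
            (m - q) * (np.log(2 * np.pi) + np.log(s2) + 1.0)
            + logdet_H
            + logdet_XtHiX
        )
        return -ll

    if not Zs:
        nll = neg_loglik(np.empty(0))
        # recompute sigma_e^2 for the no-random-term case
        Hi_y = y
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ y)
        s2 = float((y - X @ beta) @ (y - X @ beta)) / (m - q)
        return np.empty(0), s2, -nll

    x0 = np.zeros(len(Zs))
    res = optimize.minimize(
        neg_loglik, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    log_gamma = res.x
    gamma = np.exp(log_gamma)
    # recover sigma_e^2 at the optimum
    H = np.eye(m)
    for g, A in zip(gamma, ZZ):
        H = H + g * A
    Hi_y = np.linalg.solve(H, y)
    Hi_X = np.linalg.solve(H, X)
    XtHiX = X.T @ Hi_X
    beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
    yPy = float(y @ Hi_y - (X.T @ Hi_y) @ beta)
    s2 = yPy / (m - q)
    return gamma, s2, -res.fun


def fit_trial(
    records: pd.DataFrame,
    design: DesignSpec,
    line_as: str = "random",
    log_transform: bool = False,
) -> TrialFit:
    """Fit the stage-1 mixed model for one trait.

    ``records`` needs columns ``line, rep, block, is_check, value``; rows with
    missing ``value`` are dropped (unbalanced data are handled by REML).
    ``line_as="random"`` estimates the genetic variance and line BLUPs with
    prediction-error variances; ``line_as="fixed"`` produces BLUEs (adjusted
    line means) for downstream association mapping.  ``log_transform`` takes
    the natural log of the response first (used for the right-skewed
    convex-hull and median-roots traits).
    """
    if line_as not in ("random", "fixed"):
        raise ValueError("line_as must be 'random' or 'fixed'")
    rec = records.dropna(subset=["value"]).reset_index(drop=True)
    n_lines = rec.loc[~rec["is_check"].astype(bool), "line"].nunique()
    if n_lines < 2:
        raise ValueError("need at least two test lines")
    y = rec["value"].to_numpy(dtype=float)
    if log_transform:
        if (y <= 0).any():
            raise ValueError("log transform requires positive values")
        y = np.log(y)

    X, names, rand, line_levels, _ = _build_design(rec, design, line_as)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design is not identifiable (rank-deficient fixed-effect matrix); "
            "check block/line confounding"
        )
    if X.shape[0] <= X.shape[1]:
        raise ValueError("more fixed-effect parameters than observations")

    terms = list(rand)
    Zs = [rand[t] for t in terms]
    gamma, s2, loglik = _profiled_reml(y, X, Zs)
    varcomps = {t: max(float(g * s2), 0.0) for t, g in zip(terms, gamma)}
    varcomps["residual"] = float(s2)

    # GLS fixed effects and (if line random) MME BLUPs with PEV
    m = len(y)
    H = np.eye(m)
    for t, Z in zip(terms, Zs):
        H += (varcomps[t] / s2) * (Z @ Z.T)
    Hi_X = np.linalg.solve(H, X)
    Hi_y = np.linalg.solve(H, y)
    XtHiX = X.T @ Hi_X
    beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
    fixed = pd.Series(beta, index=names)

    blues = blups = pev = None
    if line_as == "fixed":
        blues = pd.Series(
            [fixed[f"line[{c}]"] for c in line_levels], index=line_levels
        )
    else:
        blups, pev = _line_blups(y, X, rand, varcomps, line_levels)

    return TrialFit(
        varcomps=varcomps,
        fixed_effects=fixed,
        blues=blues,
        blups=blups,
        pev=pev,
        loglik=float(loglik),
        n_obs=m,
        design_kind=design.kind,
        line_as=line_as,
    )


def _line_blups(
    y: np.ndarray,
    X: np.ndarray,
    rand: dict[str, np.ndarray],
    varcomps: dict[str, float],
    line_levels: list[str],
) -> tuple[pd.Series, pd.DataFrame]:
    """Henderson mixed-model equations; PEV = sigma_e^2 * (M^-1)_uu block."""
    s2 = varcomps["residual"]
    terms = list(rand)
    Z = np.hstack([rand[t] for t in terms])
    sizes = [rand[t].shape[1] for t in terms]
    dinv = np.concatenate(
        [np.full(c, s2 / max(varcomps[t], _VAR_FLOOR)) for t, c in zip(terms, sizes)]
    )
    q = X.shape[1]
    M = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + np.diag(dinv)]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    Minv = np.linalg.inv(M)
    sol = Minv @ rhs
    offset = q
    for t, c in zip(terms, sizes):
        if t == "line":
            u = sol[offset : offset + c]
            pev = s2 * Minv[offset : offset + c, offset : offset + c]
            return (
                pd.Series(u, index=line_levels),
                pd.DataFrame(pev, index=line_levels, columns=line_levels),
            )
        offset += c
    raise RuntimeError("line term missing from random effects")


def cullis_h2(fit: TrialFit) -> HeritabilityResult:
    """Generalized heritability H^2 = 1 - vbar(BLUP) / (2 sigma_g^2).

    ``vbar`` is the average over all line pairs of the prediction-error
    variance of BLUP differences, computed exactly from the PEV matrix.
    Defined as 0 when the genetic variance is (numerically) zero; clipped to
    [0, 1].
    """
    if fit.pev is None:
        raise ValueError("Cullis H2 needs a line-random fit with PEVs")
    sg2 = fit.sigma_g2
    if sg2 <= _VAR_FLOOR:
        return HeritabilityResult(h2=0.0, vbar_blup=float("nan"), sigma_g2=sg2)
    P = fit.pev.to_numpy()
    n = P.shape[0]
    d = np.diag(P)
    # mean over i<j of P_ii + P_jj - 2 P_ij = (n * tr(P) - sum(P)) / C(n,2)
    vbar = (n * d.sum() - P.sum()) / (n * (n - 1) / 2.0)
    h2 = 1.0 - vbar / (2.0 * sg2)
    return HeritabilityResult(h2=float(np.clip(h2, 0.0, 1.0)), vbar_blup=float(vbar),
                              sigma_g2=float(sg2))


def standardize_traits(blues: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each trait column to mean 0, sample variance 1.

    Missing entries stay missing and are excluded from the moments
    (sample variance, n-1 denominator).  A constant column is an error.
    """
    out = blues.copy().astype(float)
    for col in out.columns:
        v = out[col]
        obs = v.dropna()
        if len(obs) < 2:
            raise ValueError(f"trait {col!r} has fewer than 2 observed values")
        sd = obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero variance trait {col!r}")
        out[col] = (v - obs.mean()) / sd
    return out
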