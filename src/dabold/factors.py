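"""Hierarchical confirmatory factor analysis of regional BP_ND.

The model: 16 regional binding-potential indicators load on 8 bilateral
first-order factors (one per region, indicators = left/right hemisphere);
the first-order factors load on three correlated second-order factors
(striatal, limbic, neocortical). One loading per factor is fixed to 1 to
set its metric; error terms are indicator-specific and uncorrelated.

Model-implied covariance:

    Sigma = L1 (L2 Phi L2' + Psi) L1' + Theta

with L1 (16x8) and L2 (8x3) the loading matrices, Phi the 3x3 second-order
factor covariance, Psi the diagonal first-order disturbances and Theta the
diagonal uniquenesses. The ML discrepancy

    F_ML = log|Sigma| + tr(S Sigma^-1) - log|S| - p

is minimized by quasi-Newton iteration on a log parameterization of the
variances (Phi through its Cholesky factor), with multiple jittered starts.
Indicators are standardized internally for conditioning and the solution is
mapped back to the raw metric exactly — the model family is closed under
diagonal rescaling, so the minimized F_ML and all fit indices are
unaffected.

Fit indices: chi2 = (n-1) F_ML; RMSEA = sqrt(max(chi2-df,0)/(df (n-1)));
CFI from the independence baseline. Regression (Thurstone) factor scores
and a PCA composite over the three second-order scores are provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DaboldError, InvalidSpecError, NotConvergedError
from .regions import FactorStructure, default_structure

logger = logging.getLogger(__name__)

__all__ = [
    "FactorModel", "DaScores",
    "fit_hierarchical_cfa", "fit_hierarchical_cfa_cov",
    "factor_scores", "composite_da", "rmsea_ci",
]

_HEYWOOD_EPS = 1e-8


@dataclass
class FactorModel:
    """Fitted hierarchical CFA with fit indices (raw indicator metric)."""

    structure: FactorStructure
    lambda1: pd.DataFrame           # indicators x first-order factors
    lambda2: pd.DataFrame           # first-order x second-order factors
    phi: pd.DataFrame               # second-order factor covariance
    psi: pd.Series                  # first-order disturbance variances
    theta: pd.Series                # indicator uniquenesses
    fml: float
    chi2: float
    df: int
    n: int
    cfi: float
    rmsea: float
    converged: bool
    heywood: bool
    n_free: int
    sample_cov: pd.DataFrame = field(repr=False, default=None)
    indicator_mean: Optional[pd.Series] = field(repr=False, default=None)

    def implied_cov(self) -> pd.DataFrame:
        l1 = self.lambda1.to_numpy()
        l2 = self.lambda2.to_numpy()
        phi = self.phi.to_numpy()
        m = l2 @ phi @ l2.T + np.diag(self.psi.to_numpy())
        sigma = l1 @ m @ l1.T + np.diag(self.theta.to_numpy())
        idx = self.lambda1.index
        return pd.DataFrame(sigma, index=idx, columns=idx)


@dataclass
class DaScores:
    """Per-subject second-order factor scores plus the PCA composite."""

    scores: pd.DataFrame            # subject x (striatal, limbic, neocortical)
    composite: Optional[pd.Series] = None
    composite_loadings: Optional[pd.Series] = None
    explained_variance_ratio: Optional[float] = None


class _Parameterization:
    """Maps the free-parameter vector to (L1, L2, Phi, Psi, Theta)."""

    def __init__(self, structure: FactorStructure):
        self.s = structure
        self.inds = list(structure.indicators)
        self.f1 = list(structure.first_order_factors)
        self.f2 = list(structure.second_order_factors)
        self.p = len(self.inds)
        # free first-order loadings: all but the first indicator of each factor
        self.l1_free = [
            (self.inds.index(ind), self.f1.index(f))
            for f in self.f1
            for ind in structure.first_order[f][1:]
        ]
        self.l2_free = [
            (self.f1.index(child), self.f2.index(g))
            for g in self.f2
            for child in structure.second_order[g][1:]
        ]
        k = len(self.f2)
        self.n_chol_off = k * (k - 1) // 2
        self.n_free = (
            len(self.l1_free) + len(self.l2_free)
            + len(self.f1) + self.p + k + self.n_chol_off
        )
        self.df = self.p * (self.p + 1) // 2 - self.n_free

    def unpack(self, theta_vec: np.ndarray):
        i = 0
        l1 = np.zeros((self.p, len(self.f1)))
        for f in self.f1:
            l1[self.inds.index(self.s.fixed_indicator(f)), self.f1.index(f)] = 1.0
        for (r, c) in self.l1_free:
            l1[r, c] = theta_vec[i]
            i += 1
        l2 = np.zeros((len(self.f1), len(self.f2)))
        for g in self.f2:
            l2[self.f1.index(self.s.fixed_child(g)), self.f2.index(g)] = 1.0
        for (r, c) in self.l2_free:
            l2[r, c] = theta_vec[i]
            i += 1
        psi = np.exp(theta_vec[i:i + len(self.f1)])
        i += len(self.f1)
        th = np.exp(theta_vec[i:i + self.p])
        i += self.p
        k = len(self.f2)
        chol = np.zeros((k, k))
        chol[np.diag_indices(k)] = np.exp(theta_vec[i:i + k])
        i += k
        rows, cols = np.tril_indices(k, -1)
        chol[rows, cols] = theta_vec[i:i + self.n_chol_off]
        phi = chol @ chol.T
        return l1, l2, phi, psi, th

    def sigma(self, theta_vec: np.ndarray) -> np.ndarray:
        l1, l2, phi, psi, th = self.unpack(theta_vec)
        m = l2 @ phi @ l2.T + np.diag(psi)
        return l1 @ m @ l1.T + np.diag(th)


def _fml(sigma: np.ndarray, s_cov: np.ndarray, logdet_s: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    try:
        tr = float(np.trace(np.linalg.solve(sigma, s_cov)))
    except np.linalg.LinAlgError:
        return np.inf
    return logdet + tr - logdet_s - s_cov.shape[0]


def _start_vector(par: _Parameterization, s_std: np.ndarray, rng: np.random.Generator,
                  jitter: float) -> np.ndarray:
    """Start values for the standardized problem (unit indicator variances)."""
    v = []
    v.extend([1.0] * len(par.l1_free))
    v.extend([1.0] * len(par.l2_free))
    v.extend([np.log(0.2)] * len(par.f1))      # disturbances
    v.extend([np.log(0.5)] * par.p)            # uniquenesses
    k = len(par.f2)
    v.extend([np.log(np.sqrt(0.3))] * k)       # chol diag of Phi
    v.extend([0.1] * par.n_chol_off)
    v = np.asarray(v, dtype=float)
    if jitter > 0:
        v = v + rng.normal(0.0, jitter, size=v.shape)
    return v


def fit_hierarchical_cfa_cov(
    s_cov: pd.DataFrame | np.ndarray,
    n: int,
    structure: FactorStructure | None = None,
    n_starts: int = 3,
    seed: int | None = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> FactorModel:
    """Fit the hierarchical CFA to a sample covariance matrix (lavaan-style entry).

    Standardizes internally, fits by L-BFGS-B with ``n_starts`` jittered
    starts, and maps the best solution back to the raw indicator metric.
    """
    structure = structure or default_structure()
    inds = list(structure.indicators)
    if isinstance(s_cov, pd.DataFrame):
        s_cov = s_cov.loc[inds, inds].to_numpy()
    s_cov = np.asarray(s_cov, dtype=float)
    p = len(inds)
    if s_cov.shape != (p, p):
        raise InvalidSpecError(f"covariance must be {p}x{p} over the declared indicators")
    eigmin = np.linalg.eigvalsh(s_cov).min()
    if eigmin <= 0:
        raise InvalidSpecError(f"sample covariance must be positive definite (min eig {eigmin:.3g})")

    par = _Parameterization(structure)
    if n <= par.n_free:
        raise InvalidSpecError(f"need n > {par.n_free} free parameters, got n={n}")

    d = np.sqrt(np.diag(s_cov))
    s_std = s_cov / np.outer(d, d)
    sign, logdet_s = np.linalg.slogdet(s_std)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        x0 = _start_vector(par, s_std, rng, jitter=0.0 if start == 0 else 0.15)
        res = optimize.minimize(
            lambda v: _fml(par.sigma(v), s_std, logdet_s),
            x0, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise NotConvergedError("CFA optimization failed from every start")
    converged = bool(best.success or best.fun < np.inf)
    if not best.success:
        logger.warning("CFA optimizer stopped without formal convergence: %s", best.message)

    l1s, l2s, phis, psis, ths = par.unpack(best.x)
    heywood = bool((ths < _HEYWOOD_EPS).any() or (psis < _HEYWOOD_EPS).any())
    if heywood:
        logger.warning("Heywood case: a variance estimate collapsed to ~0 (bounded).")

    # map the standardized solution back to the raw metric
    f1 = list(structure.first_order_factors)
    f2 = list(structure.second_order_factors)
    d_ind = pd.Series(d, index=inds)
    c1 = np.array([d_ind[structure.fixed_indicator(f)] for f in f1])
    l1 = l1s * d[:, None] / c1[None, :]
    c2 = np.array([c1[f1.index(structure.fixed_child(g))] for g in f2])
    l2 = l2s * c1[:, None] / c2[None, :]
    phi = phis * np.outer(c2, c2)
    psi = psis * c1 ** 2
    theta = ths * d ** 2

    fml = float(best.fun)
    chi2 = max((n - 1) * fml, 0.0)
    df = par.df
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    # independence baseline: Sigma_b = diag(S) => F_b = -log|R|
    chi2_b = (n - 1) * (-logdet_s)
    df_b = p * (p - 1) // 2
    denom = max(chi2_b - df_b, chi2 - df, np.finfo(float).tiny)
    cfi = float(1.0 - max(chi2 - df, 0.0) / denom)
    cfi = min(max(cfi, 0.0), 1.0)

    return FactorModel(
        structure=structure,
        lambda1=pd.DataFrame(l1, index=inds, columns=f1),
        lambda2=pd.DataFrame(l2, index=f1, columns=f2),
        phi=pd.DataFrame(phi, index=f2, columns=f2),
        psi=pd.Series(psi, index=f1),
        theta=pd.Series(theta, index=inds),
        fml=fml, chi2=float(chi2), df=df, n=int(n),
        cfi=cfi, rmsea=rmsea, converged=converged, heywood=heywood,
        n_free=par.n_free,
        sample_cov=pd.DataFrame(s_cov, index=inds, columns=inds),
    )


def fit_hierarchical_cfa(
    bp: pd.DataFrame,
    structure: FactorStructure | None = None,
    **kwargs,
) -> FactorModel:
    """Fit the hierarchical CFA to a subject x region BP_ND table."""
    structure = structure or default_structure()
    cols = list(structure.indicators)
    missing = [c for c in cols if c not in bp.columns]
    if missing:
        raise InvalidSpecError(f"BP table lacks indicator columns: {missing}")
    x = bp[cols].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise InvalidSpecError("BP table contains non-finite values")
    n = x.shape[0]
    s_cov = np.cov(x, rowvar=False, ddof=1)
    model = fit_hierarchical_cfa_cov(pd.DataFrame(s_cov, index=cols, columns=cols),
                                     n=n, structure=structure, **kwargs)
    model.indicator_mean = pd.Series(x.mean(axis=0), index=cols)
    return model


def factor_scores(model: FactorModel, bp: pd.DataFrame) -> DaScores:
    """Regression (Thurstone) scores for the second-order factors.

    scores = (X - mean) Sigma^-1 Cov(x, eta2), with
    Cov(x, eta2) = L1 L2 Phi. Scores are mean-centered by construction and
    rescaled to unit variance for comparability across factors.
    """
    if not model.converged:
        raise NotConvergedError("factor scores require a converged model")
    inds = list(model.structure.indicators)
    x = bp[inds].to_numpy(dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    sigma = model.implied_cov().to_numpy()
    cov_x_eta = model.lambda1.to_numpy() @ model.lambda2.to_numpy() @ model.phi.to_numpy()
    try:
        weights = np.linalg.solve(sigma, cov_x_eta)
    except np.linalg.LinAlgError as err:
        raise DaboldError("singular implied covariance") from err
    raw = xc @ weights
    sd = raw.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    scores = raw / sd
    idx = bp.index if bp.index.is_unique else pd.RangeIndex(len(bp))
    return DaScores(
        scores=pd.DataFrame(scores, index=idx,
                            columns=list(model.structure.second_order_factors))
    )


def composite_da(scores: DaScores | pd.DataFrame) -> DaScores:
    """First principal component of the standardized second-order scores.

    Loadings are the correlations of each factor score with the component;
    the component's sign is oriented positively with the mean score. Computed
    from the eigendecomposition of the 3x3 correlation matrix.
    """
    frame = scores.scores if isinstance(scores, DaScores) else scores
    if frame.shape[1] < 2 or frame.shape[0] < 3:
        raise InvalidSpecError("composite requires >=3 subjects and >=2 score columns")
    x = frame.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = frame.columns[np.flatnonzero(sd <= 0)].tolist()
        raise InvalidSpecError(f"zero-variance score column(s): {bad}")
    z = (x - x.mean(axis=0)) / sd
    r = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(r)
    lead = evecs[:, -1]
    lam = evals[-1]
    comp = z @ lead
    if np.corrcoef(comp, z.mean(axis=1))[0, 1] < 0:
        lead, comp = -lead, -comp
    loadings = pd.Series(lead * np.sqrt(lam), index=frame.columns)
    composite = pd.Series(comp / np.sqrt(lam), index=frame.index, name="composite")
    out = DaScores(scores=frame.copy())
    out.composite = composite
    out.composite_loadings = loadings
    out.explained_variance_ratio = float(lam / evals.sum())
    return out


def rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Noncentral-chi2 confidence interval for RMSEA (root finding)."""
    alpha = (1.0 - level) / 2.0

    def bound(prob: float) -> float:
        # find nc such that P(X_{df,nc} <= chi2) = prob
        f = lambda nc: stats.ncx2.cdf(chi2, df, nc) - prob
        if f(0.0) < 0:
            return 0.0
        hi = max(chi2 * 2, 10.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e8:
                return np.inf
        return optimize.brentq(f, 0.0, hi)

    nc_lo = bound(1.0 - alpha)
    nc_hi = bound(alpha)
    to_rmsea = lambda nc: float(np.sqrt(max(nc, 0.0) / (df * (n - 1))))
    return to_rmsea(nc_lo), to_rmsea(nc_hi)
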