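"""Latent profile analysis of n-back accuracy and inclusion screening.

Working-memory performance subgroups are identified from the three sum-correct
scores (1-, 2-, 3-back; each 0-90 from 9 blocks x 10 trials) with
Gaussian-mixture latent profile analysis. Candidate models with 1..5 classes
are fitted by EM with multiple restarts and compared by BIC in the minimized
convention (BIC = -2 logL + p log n; "lowest BIC wins"), with a parametric
bootstrap likelihood-ratio test available for adjacent class counts.

Subjects performing below chance on ALL three load conditions are excluded
before profiling; "chance" is an exact one-sided binomial threshold at a
configurable alpha (a two-choice task gives success probability 0.5 per
trial).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .exceptions import InvalidSpecError, SingularFitError

logger = logging.getLogger(__name__)

__all__ = [
    "ACCURACY_COLUMNS", "TRIALS_PER_CONDITION",
    "LatentProfileModel", "fit_lpa", "bootstrap_lrt",
    "screen_performance", "chance_threshold", "label_groups",
]

ACCURACY_COLUMNS = ("back1", "back2", "back3")
TRIALS_PER_CONDITION = 90  # 9 blocks x 10 trials


@dataclass
class LatentProfileModel:
    """A fitted Gaussian-mixture latent profile solution."""

    k: int
    weights: np.ndarray
    means: np.ndarray                   # k x d
    covariances: np.ndarray
    covariance_family: str
    log_likelihood: float               # total over subjects
    bic: float
    responsibilities: np.ndarray        # n x k
    assignments: np.ndarray             # n hard labels
    bic_by_k: dict[int, float]
    estimator: GaussianMixture

    @property
    def class_shares(self) -> np.ndarray:
        """Empirical share of subjects hard-assigned to each class."""
        return np.bincount(self.assignments, minlength=self.k) / self.assignments.size


def _as_matrix(acc: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(acc, pd.DataFrame):
        cols = [c for c in ACCURACY_COLUMNS if c in acc.columns]
        x = acc[cols].to_numpy(dtype=float) if cols else acc.to_numpy(dtype=float)
    else:
        x = np.asarray(acc, dtype=float)
    if x.ndim != 2:
        raise InvalidSpecError("accuracy data must be 2-D (subjects x conditions)")
    return x


def _fit_single(x: np.ndarray, k: int, covariance_family: str, n_starts: int,
                seed: int | None) -> GaussianMixture:
    gm = GaussianMixture(
        n_components=k,
        covariance_type=covariance_family,
        n_init=n_starts,
        reg_covar=1e-6,
        max_iter=500,
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            gm.fit(x)
        except (ConvergenceWarning, FloatingPointError) as err:
            raise SingularFitError(f"all EM restarts degenerate for K={k}: {err}") from err
    if not gm.converged_:
        raise SingularFitError(f"EM failed to converge for K={k}")
    return gm


def fit_lpa(
    acc: pd.DataFrame | np.ndarray,
    k_range: Sequence[int] = range(1, 6),
    covariance_family: str = "full",
    n_starts: int = 10,
    seed: int | None = 0,
) -> LatentProfileModel:
    """Fit LPA over ``k_range`` classes; return the lowest-BIC model.

    BICs of every candidate are retained in ``bic_by_k``.
    """
    x = _as_matrix(acc)
    n, d = x.shape
    bic_by_k: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in k_range:
        if n <= k * d:
            logger.info("skipping K=%d: n=%d too small", k, n)
            continue
        try:
            gm = _fit_single(x, k, covariance_family, n_starts, seed)
        except SingularFitError:
            logger.warning("K=%d degenerate on all restarts; skipped", k)
            continue
        bic_by_k[k] = float(gm.bic(x))
        fits[k] = gm
    if not fits:
        raise SingularFitError("no candidate class count produced a stable fit")
    best_k = min(bic_by_k, key=bic_by_k.get)
    gm = fits[best_k]
    resp = gm.predict_proba(x)
    return LatentProfileModel(
        k=best_k,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        covariance_family=covariance_family,
        log_likelihood=float(gm.score(x) * n),
        bic=bic_by_k[best_k],
        responsibilities=resp,
        assignments=resp.argmax(axis=1),
        bic_by_k=bic_by_k,
        estimator=gm,
    )


def bootstrap_lrt(
    acc: pd.DataFrame | np.ndarray,
    k: int,
    B: int = 100,
    covariance_family: str = "full",
    n_starts: int = 4,
    seed: int | None = 0,
) -> dict:
    """Parametric bootstrap LRT of k vs k+1 classes.

    The observed statistic is 2 (logL_{k+1} - logL_k). Under the fitted
    k-class model, B replicate datasets of the same size are drawn and the
    statistic recomputed; p = (1 + #{boot >= observed}) / (B + 1).
    """
    if B < 1:
        raise InvalidSpecError("bootstrap_lrt requires B >= 1 replicates")
    x = _as_matrix(acc)
    n = x.shape[0]
    rng = np.random.default_rng(seed)

    def lrt_stat(data: np.ndarray, s0: int, s1: int) -> tuple[float, GaussianMixture]:
        g0 = _fit_single(data, k, covariance_family, n_starts, s0)
        g1 = _fit_single(data, k + 1, covariance_family, n_starts, s1)
        return 2.0 * n * (g1.score(data) - g0.score(data)), g0

    observed, null_model = lrt_stat(x, int(rng.integers(2**31)), int(rng.integers(2**31)))
    exceed = 0
    for _ in range(B):
        # sample() reseeds from the estimator's random_state on every call;
        # refresh it so replicates are independent draws
        null_model.random_state = int(rng.integers(2**31))
        boot, _ = null_model.sample(n)
        try:
            stat, _ = lrt_stat(boot, int(rng.integers(2**31)), int(rng.integers(2**31)))
        except SingularFitError:
            stat = np.inf  # degenerate replicate counted conservatively
        if stat >= observed:
            exceed += 1
    return {"statistic": float(observed), "p": (1 + exceed) / (B + 1), "B": B, "k": k}


def chance_threshold(alpha: float = 0.05, n_trials: int = TRIALS_PER_CONDITION,
                     p_chance: float = 0.5) -> int:
    """Smallest score c with upper-tail P(Bin(n, p) >= c) < alpha."""
    # sf(c-1) = P(X >= c); find the smallest c where it drops below alpha
    for c in range(n_trials + 2):
        if stats.binom.sf(c - 1, n_trials, p_chance) < alpha:
            return c
    raise AssertionError("unreachable")


def screen_performance(
    acc: pd.DataFrame,
    alpha: float = 0.05,
    n_trials: int = TRIALS_PER_CONDITION,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Apply the below-chance inclusion screen.

    A subject is excluded only if the score is below the chance threshold on
    ALL three load conditions. Returns (kept, excluded, threshold).
    """
    thr = chance_threshold(alpha=alpha, n_trials=n_trials)
    x = acc[list(ACCURACY_COLUMNS)].to_numpy(dtype=float)
    below_all = (x < thr).all(axis=1)
    return acc.loc[~below_all], acc.loc[below_all], thr


def label_groups(model: LatentProfileModel) -> dict[int, str]:
    """Name classes by 3-back performance: highest mean -> 'normal', other(s) -> 'low'.

    With more than two classes the non-top classes are 'low', 'low2', ...
    in decreasing 3-back order.
    """
    order = np.argsort(-model.means[:, -1])
    names = {int(order[0]): "normal"}
    for i, cls in enumerate(order[1:]):
        names[int(cls)] = "low" if i == 0 else f"low{i + 1}"
    return names
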