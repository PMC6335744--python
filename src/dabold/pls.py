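"""Behavioral (spatiotemporal) partial least squares of DA-BOLD associations.

The method correlates one or more per-subject dopamine measures with
condition-averaged BOLD data across subjects, separately within every
(DA variable, load condition, performance group) cell. Stacking those
per-voxel correlation rows gives the cross-block correlation matrix R,
whose singular value decomposition

    R = U S V'

yields orthogonal latent variables: U holds the DA/design weights, V the
voxel saliences, and s_j^2 / sum(s^2) the share of cross-block correlation
each LV accounts for. Subject "brain scores" are the projection of a
subject's BOLD vector onto a salience pattern; their within-block Pearson
correlation with the DA measure ("correlation scores") summarizes how
strongly each cell expresses the LV.

Inference is nonparametric: LV significance by permutation of the DA
assignments (within performance group, preserving group structure), and
salience stability by bootstrap resampling of subjects with replacement
within group, with each replicate's singular vectors aligned to the original
solution by greedy maximal-|inner product| matching with sign flips. The
bootstrap ratio BSR = salience / bootstrap SE behaves like a Z-score;
percentile bootstrap gives 95% CIs for the correlation scores. Subjects with
LV1 brain scores beyond 3 SD of the mean are excluded and the analysis
recomputed once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DaboldError, InvalidSpecError

logger = logging.getLogger(__name__)

__all__ = [
    "BoldBlock", "CrossBlockMatrix", "LatentVariable", "BootstrapResult",
    "n_estimable_lvs", "build_cross_block", "decompose", "brain_scores",
    "correlation_scores", "permutation_test", "bootstrap_saliences",
    "exclude_outlier_subjects",
]


@dataclass
class BoldBlock:
    """Onset-averaged BOLD for one (group, condition) cell.

    ``data`` is subjects x voxel(-lag) columns; ``subjects`` aligns rows with
    the DA table's index. Grid metadata is carried for volume output.
    """

    group: str
    condition: str
    data: np.ndarray
    subjects: Sequence
    shape: Optional[tuple] = None          # 3-D voxel grid (before lags)
    affine: Optional[np.ndarray] = None
    n_lags: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidSpecError("block data must be 2-D (subjects x voxels)")
        if len(self.subjects) != self.data.shape[0]:
            raise InvalidSpecError("subject list length != data rows")
        if not np.isfinite(self.data).all():
            raise InvalidSpecError(f"non-finite BOLD values in block ({self.group}, {self.condition})")


@dataclass
class CrossBlockMatrix:
    """Stacked per-block DA-voxel correlations; rows follow design order."""

    values: np.ndarray                     # rows x voxel(-lag) columns
    row_index: list                        # (da_variable, condition, group) tuples

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


@dataclass
class LatentVariable:
    index: int
    u: np.ndarray
    s: float
    v: np.ndarray
    pct_crossblock: float
    perm_p: Optional[float] = None


@dataclass
class BootstrapResult:
    salience_se: np.ndarray                # per voxel(-lag), LV-major: (n_lv, n_vox)
    bsr: np.ndarray                        # original salience / SE
    ci_low: pd.Series                      # per (lv, block) correlation-score CI
    ci_high: pd.Series
    n_boot: int
    n_redrawn: int = 0
    degenerate_se: bool = False
    correlation_scores: Optional[pd.DataFrame] = None


def n_estimable_lvs(n_da: int, n_cond: int, n_group: int) -> int:
    """Number of estimable latent variables for a behavioral PLS design.

    Equals the cross-block matrix's row count, n_da * n_cond * n_group
    (assuming at least that many voxels): e.g. one composite DA measure over
    three load conditions and two performance groups gives 6.
    """
    for name, v in (("n_da", n_da), ("n_cond", n_cond), ("n_group", n_group)):
        if int(v) < 1:
            raise InvalidSpecError(f"{name} must be >= 1, got {v}")
    return int(n_da) * int(n_cond) * int(n_group)


def _pearson_rows(da_vec: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Pearson r of one DA vector against every column; constant columns -> 0."""
    n = da_vec.size
    if n < 3:
        raise InvalidSpecError("need >= 3 subjects per block")
    dz = da_vec - da_vec.mean()
    sd_da = dz.std()
    if sd_da == 0:
        raise InvalidSpecError("constant DA variable within a block")
    xc = data - data.mean(axis=0, keepdims=True)
    sd_x = xc.std(axis=0)
    const = sd_x == 0
    if const.any():
        logger.warning("%d constant voxel column(s); correlation set to 0", int(const.sum()))
    denom = np.where(const, 1.0, sd_x) * sd_da * n
    r = (dz @ xc) / denom
    r[const] = 0.0
    return np.clip(r, -1.0, 1.0)


def build_cross_block(
    blocks: Sequence[BoldBlock],
    da: pd.DataFrame,
) -> CrossBlockMatrix:
    """Stack per-voxel Pearson correlations for every (DA variable, block) pair.

    Row order: DA variables outermost (column order of ``da``), then blocks in
    their given (condition-within-group) order.
    """
    if not blocks:
        raise InvalidSpecError("no blocks supplied")
    n_cols = {b.data.shape[1] for b in blocks}
    if len(n_cols) != 1:
        raise InvalidSpecError("all blocks must share the voxel(-lag) column count")
    rows, index = [], []
    for da_var in da.columns:
        for block in blocks:
            missing = [s for s in block.subjects if s not in da.index]
            if missing:
                raise InvalidSpecError(f"subjects missing from DA table: {missing[:5]}")
            vec = da.loc[list(block.subjects), da_var].to_numpy(dtype=float)
            rows.append(_pearson_rows(vec, block.data))
            index.append((da_var, block.condition, block.group))
    return CrossBlockMatrix(values=np.vstack(rows), row_index=index)


def decompose(R: CrossBlockMatrix) -> list[LatentVariable]:
    """Full SVD of the cross-block matrix, LVs ordered by decreasing singular value.

    SVD sign is arbitrary, so each LV is oriented deterministically: the DA
    weight vector u sums positive (falling back to the largest-|u| entry on a
    zero sum), keeping "positive salience = positive DA association".
    """
    vals = R.values if isinstance(R, CrossBlockMatrix) else np.asarray(R, float)
    if not np.isfinite(vals).all():
        raise InvalidSpecError("cross-block matrix contains non-finite entries")
    u, s, vt = np.linalg.svd(vals, full_matrices=False)
    total = float((s ** 2).sum())
    lvs = []
    for j in range(s.size):
        uj, vj = u[:, j], vt[j]
        tot = uj.sum()
        flip = tot < 0 or (tot == 0 and uj[np.abs(uj).argmax()] < 0)
        if flip:
            uj, vj = -uj, -vj
        pct = 100.0 * s[j] ** 2 / total if total > 0 else 0.0
        lvs.append(LatentVariable(index=j, u=uj, s=float(s[j]), v=vj, pct_crossblock=pct))
    return lvs


def brain_scores(v: np.ndarray, block: BoldBlock) -> pd.Series:
    """Project each subject's BOLD vector onto the saliences: score_m = sum_i V_i * BOLD_mi."""
    v = np.asarray(v, dtype=float)
    if v.size != block.data.shape[1]:
        raise InvalidSpecError(
            f"salience length {v.size} != voxel columns {block.data.shape[1]}"
        )
    return pd.Series(block.data @ v, index=list(block.subjects),
                     name=f"{block.group}:{block.condition}")


def correlation_scores(
    scores_by_block: Mapping[tuple, pd.Series],
    da: pd.DataFrame | pd.Series,
    da_var: Optional[str] = None,
) -> pd.Series:
    """Within-block Pearson r between brain scores and the DA variable."""
    if isinstance(da, pd.DataFrame):
        if da_var is None and da.shape[1] == 1:
            da_var = da.columns[0]
        da = da[da_var]
    out = {}
    for key, scores in scores_by_block.items():
        if scores.size < 3:
            raise InvalidSpecError(f"block {key}: need >= 3 subjects")
        if scores.std(ddof=0) == 0:
            raise DaboldError(f"block {key}: zero-variance brain scores, correlation undefined")
        vec = da.loc[scores.index].to_numpy(dtype=float)
        out[key] = float(np.corrcoef(scores.to_numpy(), vec)[0, 1])
    return pd.Series(out, name="correlation_score")


def _group_subject_map(blocks: Sequence[BoldBlock]) -> dict[str, list]:
    """Each group's subject list (must be consistent across its conditions)."""
    groups: dict[str, list] = {}
    for b in blocks:
        subs = list(b.subjects)
        if b.group in groups:
            if groups[b.group] != subs:
                raise InvalidSpecError(
                    f"group {b.group!r}: subject lists differ across conditions"
                )
        else:
            groups[b.group] = subs
    return groups


def permutation_test(
    blocks: Sequence[BoldBlock],
    da: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = 0,
    within_group: bool = True,
    add_one: bool = False,
) -> tuple[list[LatentVariable], np.ndarray]:
    """Permutation significance of each LV.

    DA values are reassigned across subjects (within group by default), the
    cross-block matrix and SVD recomputed, and p_j is the fraction of draws
    whose j-th singular value meets or exceeds the observed one. With
    ``add_one`` the (1+count)/(1+n_perm) convention is used instead of the
    raw exceedance count.
    """
    if n_perm < 1:
        raise InvalidSpecError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    lvs = decompose(build_cross_block(blocks, da))
    s_obs = np.array([lv.s for lv in lvs])
    groups = _group_subject_map(blocks)
    all_subjects = [s for subs in groups.values() for s in subs]
    exceed = np.zeros_like(s_obs)
    for _ in range(n_perm):
        da_perm = da.copy()
        if within_group:
            for subs in groups.values():
                perm = rng.permutation(len(subs))
                da_perm.loc[subs] = da.loc[subs].to_numpy()[perm]
        else:
            perm = rng.permutation(len(all_subjects))
            da_perm.loc[all_subjects] = da.loc[all_subjects].to_numpy()[perm]
        s_perm = np.linalg.svd(build_cross_block(blocks, da_perm).values, compute_uv=False)
        exceed += s_perm >= s_obs
    if add_one:
        p = (1.0 + exceed) / (1.0 + n_perm)
    else:
        p = exceed / n_perm
    for lv, pj in zip(lvs, p):
        lv.perm_p = float(pj)
    return lvs, p


def _align_to_original(v_orig: np.ndarray, v_rep: np.ndarray) -> np.ndarray:
    """Match replicate LVs to originals by greedy max |dot|, flipping signs.

    v matrices are (n_lv, n_vox). Returns the reordered, sign-aligned
    replicate rows.
    """
    sim = v_orig @ v_rep.T                    # n_lv x n_lv inner products
    n = sim.shape[0]
    out = np.empty_like(v_rep[:n])
    taken = np.zeros(sim.shape[1], dtype=bool)
    for j in np.argsort(-np.abs(sim).max(axis=1)):  # strongest matches first
        cand = np.abs(sim[j]).copy()
        cand[taken] = -1
        m = int(cand.argmax())
        taken[m] = True
        out[j] = v_rep[m] * np.sign(sim[j, m] or 1.0)
    return out


def bootstrap_saliences(
    blocks: Sequence[BoldBlock],
    da: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = 0,
    n_lv: Optional[int] = None,
    max_redraws: int = 100,
) -> BootstrapResult:
    """Bootstrap SEs for voxel saliences and percentile CIs for correlation scores.

    Subjects are resampled with replacement within each group; replicates in
    which any block retains fewer than 3 unique subjects are redrawn (and
    counted). Each replicate's singular vectors are aligned to the original
    solution before accumulation.
    """
    if n_boot < 2:
        raise InvalidSpecError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    R = build_cross_block(blocks, da)
    lvs = decompose(R)
    if n_lv is None:
        n_lv = len(lvs)
    v_orig = np.vstack([lv.v for lv in lvs[:n_lv]])

    groups = _group_subject_map(blocks)
    block_keys = [(b.condition, b.group) for b in blocks]

    # observed correlation scores per (lv, block)
    obs_corr = {}
    for j in range(n_lv):
        for b in blocks:
            sc = brain_scores(v_orig[j], b)
            for da_var in da.columns:
                key = (j, da_var, b.condition, b.group)
                obs_corr[key] = correlation_scores({key: sc}, da, da_var)[key]

    v_acc = np.zeros((n_boot, n_lv, v_orig.shape[1]))
    corr_acc = {key: np.empty(n_boot) for key in obs_corr}
    n_redrawn = 0
    for rep in range(n_boot):
        for attempt in range(max_redraws + 1):
            draw = {g: [subs[i] for i in rng.integers(0, len(subs), len(subs))]
                    for g, subs in groups.items()}
            if all(len(set(draw[g])) >= 3 for g in draw):
                break
            n_redrawn += 1
            logger.info("bootstrap replicate %d redrawn (degenerate block)", rep)
        else:
            raise DaboldError("could not draw a non-degenerate bootstrap replicate")
        rep_blocks = []
        for b in blocks:
            subs = draw[b.group]
            pos = {s: i for i, s in enumerate(b.subjects)}
            idx = [pos[s] for s in subs]
            rep_blocks.append(BoldBlock(b.group, b.condition, b.data[idx],
                                        subjects=list(range(len(subs))),
                                        shape=b.shape, affine=b.affine, n_lags=b.n_lags))
        # DA table for the resample; positional ids are namespaced per group so
        # resampled duplicates stay distinct rows
        da_rep_frames = []
        for g, subs in draw.items():
            f = da.loc[subs].copy()
            f.index = range(len(subs))
            da_rep_frames.append((g, f))
        da_rep = pd.concat(
            [f.set_axis([f"{g}:{i}" for i in f.index]) for g, f in da_rep_frames]
        )
        for b in rep_blocks:
            b.subjects = [f"{b.group}:{i}" for i in b.subjects]
        R_rep = build_cross_block(rep_blocks, da_rep)
        u_r, s_r, vt_r = np.linalg.svd(R_rep.values, full_matrices=False)
        v_aligned = _align_to_original(v_orig, vt_r)
        v_acc[rep] = v_aligned
        for j in range(n_lv):
            for b in rep_blocks:
                sc = brain_scores(v_aligned[j], b)
                for da_var in da.columns:
                    key = (j, da_var, b.condition, b.group)
                    corr_acc[key][rep] = correlation_scores({key: sc}, da_rep, da_var)[key]

    se = v_acc.std(axis=0, ddof=1)
    degenerate = bool((se == 0).any())
    if degenerate:
        logger.warning("zero bootstrap SE for %d salience value(s); BSR set to +/-inf",
                       int((se == 0).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, v_orig / se,
                       np.sign(v_orig) * np.inf)
        bsr = np.where((se == 0) & (v_orig == 0), 0.0, bsr)

    keys = sorted(obs_corr)
    lo = pd.Series({k: float(np.percentile(corr_acc[k], 2.5)) for k in keys})
    hi = pd.Series({k: float(np.percentile(corr_acc[k], 97.5)) for k in keys})
    cs = pd.DataFrame(
        {
            "lv": [k[0] for k in keys],
            "da_variable": [k[1] for k in keys],
            "condition": [k[2] for k in keys],
            "group": [k[3] for k in keys],
            "r": [obs_corr[k] for k in keys],
            "ci_low": [lo[k] for k in keys],
            "ci_high": [hi[k] for k in keys],
        }
    )
    return BootstrapResult(salience_se=se, bsr=bsr, ci_low=lo, ci_high=hi,
                           n_boot=n_boot, n_redrawn=n_redrawn,
                           degenerate_se=degenerate, correlation_scores=cs)


def exclude_outlier_subjects(
    scores_by_block: Mapping[tuple, pd.Series],
    k_sd: float = 3.0,
) -> tuple[list, list, bool]:
    """Flag subjects whose LV1 brain score lies beyond ``k_sd`` SD of the mean.

    Scores from all blocks are pooled (z-scored within block so conditions
    are comparable); a subject is excluded if any of its block scores is
    outlying. Returns (kept, excluded, refit_needed).
    """
    pooled = []
    for key, sc in scores_by_block.items():
        sd = sc.std(ddof=0)
        z = (sc - sc.mean()) / sd if sd > 0 else sc * 0.0
        pooled.append(z)
    allz = pd.concat(pooled)
    if allz.index.size < 4:
        raise InvalidSpecError("outlier screen requires >= 4 subjects")
    outlying = allz.abs() > k_sd
    excluded = sorted(set(allz.index[outlying]))
    kept = sorted(set(allz.index) - set(excluded))
    return kept, excluded, bool(excluded)
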