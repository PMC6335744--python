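"""Synthetic multimodal cohort with planted ground truth.

Generates every input the analysis pipeline consumes, with known truth so
each downstream stage can be validated without any real data:

* n-back accuracy (sum correct per load, 0-90) from a two-class Gaussian
  mixture of normal- and low-performing subjects, truncated to range by
  resampling (not clipping, which would distort the mixture shape);
* 16 regional BP_ND values per subject from the hierarchical
  striatal/limbic/neocortical factor model, at raclopride-like scales;
* one SRTM-kinetic time-activity curve per region on the 18-frame schedule,
  plus the cerebellar reference curve;
* voxelwise condition-averaged BOLD where a contiguous "signal" blob of
  voxels carries a planted correlation with the subject's composite DA score
  that differs by load condition and performance group, via the exact linear
  construction  y = r z(DA) + sqrt(1 - r^2) eps  with standard-normal eps
  (so the expected within-block correlation equals the planted r), and all
  remaining voxels are pure noise. The blob's noise has a shared spatial
  component (``voxel_noise_corr``): without it, summing voxels would average
  the noise away and every block-level brain-score correlation would
  saturate near 1, erasing the planted load-by-group contrast that real
  spatially smoothed BOLD data retain.

Identical config + seed gives a bit-identical cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .exceptions import InvalidSpecError
from .frames import DEFAULT_SCHEDULE_SPEC, FrameSchedule, make_schedule
from .kinetics import simulate_tac
from .logan import write_tac_csv
from .regions import BILATERAL_REGIONS, REGIONS, SECOND_ORDER_MAP

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "write_cohort",
           "CONDITIONS", "GROUPS"]

CONDITIONS = ("back1", "back2", "back3")
GROUPS = ("normal", "low")

#: Raclopride-like regional BP_ND means and coefficients of variation.
_REGION_MEAN = {
    "putamen": 3.10, "caudate": 2.30, "hippocampus": 0.35, "amygdala": 0.50,
    "frontal": 0.25, "occipital": 0.35, "temporal": 0.45, "parietal": 0.30,
}
_REGION_CV = 0.15

#: Standardized first-order loadings (L, R) per region.
_LAMBDA1 = {
    "putamen": (0.93, 0.92), "caudate": (0.90, 0.91),
    "hippocampus": (0.85, 0.83), "amygdala": (0.82, 0.84),
    "frontal": (0.90, 0.89), "occipital": (0.86, 0.87),
    "temporal": (0.91, 0.90), "parietal": (0.88, 0.89),
}
#: Standardized second-order loadings per first-order factor.
_LAMBDA2 = {
    "putamen": 0.85, "caudate": 0.80,
    "hippocampus": 0.85, "amygdala": 0.80,
    "frontal": 0.85, "occipital": 0.78, "temporal": 0.88, "parietal": 0.84,
}
#: Second-order factor correlations (striatal, limbic, neocortical order).
_PHI_CORR = np.array([
    [1.00, 0.45, 0.40],
    [0.45, 1.00, 0.75],
    [0.40, 0.75, 1.00],
])


def _default_planted_r() -> Dict[Tuple[str, str], float]:
    # Load x group interaction: the DA-BOLD link peaks at 3-back in the
    # normal group and at 2-back in the low group.
    return {
        ("normal", "back1"): 0.10, ("normal", "back2"): 0.20, ("normal", "back3"): 0.65,
        ("low", "back1"): 0.10, ("low", "back2"): 0.50, ("low", "back3"): 0.05,
    }


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults define the study conditions: 168 included subjects split
    113/55 (67.3%/32.7%) between a normal- and a low-performing class, three
    load conditions, a 12x12x12 voxel grid at 3.4 mm spacing with a
    contiguous planted-signal blob, and the 55-min 18-frame PET schedule.
    """

    n_subjects: int = 168
    class_proportions: Tuple[float, ...] = (113 / 168, 55 / 168)
    class_means: Tuple[Tuple[float, ...], ...] = ((87.0, 79.0, 68.0), (75.0, 59.0, 41.0))
    class_sds: Tuple[Tuple[float, ...], ...] = ((3.0, 5.5, 7.0), (5.0, 7.0, 8.0))
    class_corr: float = 0.35
    planted_r: Dict[Tuple[str, str], float] = field(default_factory=_default_planted_r)
    grid_shape: Tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: Tuple[float, float, float] = (3.4, 3.4, 3.4)
    signal_radius_vox: float = 2.6
    voxel_noise_corr: float = 0.5
    lags: int = 1
    lag_decay: float = 0.8
    tac_noise_sd: float = 0.0
    schedule_spec: Tuple[Tuple[int, float], ...] = DEFAULT_SCHEDULE_SPEC
    r1: float = 1.0
    k2_ref: float = 0.16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise InvalidSpecError("n_subjects must be >= 1 (empty cohort)")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
            raise InvalidSpecError("class_proportions must be nonnegative and sum to 1")
        if any(abs(r) >= 1 for r in self.planted_r.values()):
            raise InvalidSpecError("planted correlations must satisfy |r| < 1")
        if int(np.prod(self.grid_shape)) < 1:
            raise InvalidSpecError("n_voxels must be >= 1")
        if not 0.0 <= self.voxel_noise_corr < 1.0:
            raise InvalidSpecError("voxel_noise_corr must be in [0, 1)")
        if self.lags < 1:
            raise InvalidSpecError("lags must be >= 1")
        if self.tac_noise_sd < 0:
            raise InvalidSpecError("tac_noise_sd must be >= 0")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        for i, (dim, size) in enumerate(zip(self.grid_shape, self.voxel_size_mm)):
            aff[i, i] = size
            aff[i, 3] = -size * (dim - 1) / 2.0
        return aff


@dataclass
class SyntheticCohort:
    """Generated inputs plus the complete planted-truth record."""

    config: CohortConfig
    accuracy: pd.DataFrame                       # subject, back1..back3
    bp_regional: pd.DataFrame                    # subject x 16 region columns
    schedule: FrameSchedule
    tacs: Dict[str, np.ndarray]                  # region -> target TAC
    reference_tac: np.ndarray
    bold: Dict[str, np.ndarray]                  # condition -> n_subjects x (V * lags)
    truth: Dict

    @property
    def subjects(self) -> list:
        return list(self.accuracy.index)

    def group_subjects(self, group: str) -> list:
        lab = np.asarray(self.truth["group"])
        return [s for s, g in zip(self.subjects, lab) if g == group]


def _signal_mask(config: CohortConfig) -> np.ndarray:
    """Boolean flat mask of the planted-signal blob (a central ball)."""
    grid = np.indices(config.grid_shape).reshape(3, -1).T
    center = (np.asarray(config.grid_shape) - 1) / 2.0
    dist = np.linalg.norm(grid - center, axis=1)
    return dist <= config.signal_radius_vox


def _sample_accuracy(config: CohortConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    n = config.n_subjects
    classes = rng.choice(len(config.class_proportions), size=n, p=config.class_proportions)
    d = len(CONDITIONS)
    out = np.empty((n, d))
    corr = np.full((d, d), config.class_corr) + (1 - config.class_corr) * np.eye(d)
    for k, (mu, sd) in enumerate(zip(config.class_means, config.class_sds)):
        idx = np.flatnonzero(classes == k)
        cov = corr * np.outer(sd, sd)
        need = idx.copy()
        while need.size:
            draw = rng.multivariate_normal(mu, cov, size=need.size)
            ok = ((draw >= 0) & (draw <= 90)).all(axis=1)
            out[need[ok]] = draw[ok]
            need = need[~ok]          # resample, never clip
        del need
    acc = pd.DataFrame(np.rint(out).astype(int), columns=list(CONDITIONS))
    acc.index.name = "subject"
    return acc, classes


def _sample_bp(config: CohortConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regional BPs from the hierarchical factor model; returns (bp, factor scores)."""
    n = config.n_subjects
    f2_names = list(SECOND_ORDER_MAP)
    eta2 = rng.multivariate_normal(np.zeros(3), _PHI_CORR, size=n)
    eta1 = {}
    for g_idx, (g, children) in enumerate(SECOND_ORDER_MAP.items()):
        for region in children:
            lam2 = _LAMBDA2[region]
            zeta = rng.normal(0.0, np.sqrt(1.0 - lam2**2), size=n)
            eta1[region] = lam2 * eta2[:, g_idx] + zeta
    cols = {}
    for region in BILATERAL_REGIONS:
        for hemi, lam1 in zip(("L", "R"), _LAMBDA1[region]):
            eps = rng.normal(0.0, np.sqrt(1.0 - lam1**2), size=n)
            z = lam1 * eta1[region] + eps
            mean = _REGION_MEAN[region]
            cols[f"{region}_{hemi}"] = mean + mean * _REGION_CV * z
    bp = pd.DataFrame(cols)[list(REGIONS)]
    bp.index.name = "subject"
    scores = pd.DataFrame(eta2, columns=f2_names)
    return bp, scores


def _composite_truth(eta2: pd.DataFrame) -> np.ndarray:
    """First PC of the true factor scores, oriented with their mean."""
    z = (eta2 - eta2.mean()) / eta2.std(ddof=1)
    r = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(r)
    comp = z.to_numpy() @ evecs[:, -1]
    if np.corrcoef(comp, z.mean(axis=1))[0, 1] < 0:
        comp = -comp
    return comp


def _sample_bold(config: CohortConfig, groups: np.ndarray, composite: np.ndarray,
                 rng: np.random.Generator) -> tuple[Dict[str, np.ndarray], np.ndarray]:
    n, v = config.n_subjects, config.n_voxels
    mask = _signal_mask(config)
    bold: Dict[str, np.ndarray] = {}
    rho = config.voxel_noise_corr
    sig_cols = np.flatnonzero(mask)
    for cond in CONDITIONS:
        mats = []
        for lag in range(config.lags):
            mat = rng.standard_normal((n, v))
            shared = rng.standard_normal(n)        # common blob noise per subject
            for g in GROUPS:
                rows = np.flatnonzero(groups == g)
                if rows.size < 2:
                    continue
                r = config.planted_r[(g, cond)] * config.lag_decay**lag
                z = composite[rows]
                z = (z - z.mean()) / z.std(ddof=0)
                eps = mat[np.ix_(rows, sig_cols)]
                noise = np.sqrt(rho) * shared[rows, None] + np.sqrt(1.0 - rho) * eps
                mat[np.ix_(rows, sig_cols)] = r * z[:, None] + np.sqrt(1.0 - r**2) * noise
            mats.append(mat)
        bold[cond] = np.hstack(mats)
    return bold, mask


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort described by ``config``."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)

    acc, classes = _sample_accuracy(config, rng)
    # class 0 is the larger, higher-performing one by the default means
    group = np.where(classes == 0, "normal", "low")

    bp, eta2 = _sample_bp(config, rng)
    composite = _composite_truth(eta2)

    schedule = make_schedule(config.schedule_spec)
    tacs: Dict[str, np.ndarray] = {}
    reference = None
    for region in BILATERAL_REGIONS:
        bp_region = float(bp[[f"{region}_L", f"{region}_R"]].mean().mean())
        target, ref = simulate_tac(bp_region, config.r1, config.k2_ref, schedule,
                                   noise_sd=config.tac_noise_sd, seed=rng)
        tacs[region] = target
        reference = ref if reference is None else reference
    tacs["cerebellum_ref"] = reference

    bold, mask = _sample_bold(config, group, composite, rng)

    truth = {
        "class": classes.tolist(),
        "group": group.tolist(),
        "factor_scores": eta2,
        "composite": composite,
        "planted_r": dict(config.planted_r),
        "signal_mask": mask,
        "bp_region_truth": {r: float(bp[[f"{r}_L", f"{r}_R"]].mean().mean())
                            for r in BILATERAL_REGIONS},
        "grid_shape": config.grid_shape,
        "affine": config.affine,
    }
    return SyntheticCohort(config=config, accuracy=acc, bp_regional=bp,
                           schedule=schedule, tacs={r: tacs[r] for r in BILATERAL_REGIONS},
                           reference_tac=reference, bold=bold, truth=truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict:
    """Write the cohort to disk; returns a manifest of paths.

    Accuracy and BP tables as CSV, TACs as one CSV, BOLD as one 4-D NIfTI
    per condition x group (subject as 4th axis), and a JSON truth record.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    acc = cohort.accuracy.reset_index()
    acc.to_csv(out / "accuracy.csv", index=False)
    paths["accuracy"] = str(out / "accuracy.csv")

    bp = cohort.bp_regional.reset_index()
    bp.to_csv(out / "bp_regional.csv", index=False)
    paths["bp_regional"] = str(out / "bp_regional.csv")

    tac_cols = dict(cohort.tacs)
    tac_cols["cerebellum_ref"] = cohort.reference_tac
    write_tac_csv(out / "tacs.csv", cohort.schedule, tac_cols)
    paths["tacs"] = str(out / "tacs.csv")

    cfg = cohort.config
    shape = cfg.grid_shape
    group_arr = np.asarray(cohort.truth["group"])
    for cond, mat in cohort.bold.items():
        for g in GROUPS:
            rows = np.flatnonzero(group_arr == g)
            vol = mat[rows, : cfg.n_voxels].T.reshape(*shape, rows.size)
            img = nib.Nifti1Image(vol.astype(np.float32), cfg.affine)
            p = out / f"bold_{cond}_{g}.nii.gz"
            nib.save(img, p)
            paths[f"bold_{cond}_{g}"] = str(p)

    truth = {
        "class": cohort.truth["class"],
        "group": cohort.truth["group"],
        "planted_r": {f"{g}|{c}": r for (g, c), r in cohort.truth["planted_r"].items()},
        "composite": np.asarray(cohort.truth["composite"]).tolist(),
        "factor_scores": cohort.truth["factor_scores"].to_dict(orient="list"),
        "signal_mask": np.asarray(cohort.truth["signal_mask"]).astype(int).tolist(),
        "bp_region_truth": cohort.truth["bp_region_truth"],
        "grid_shape": list(shape),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh)
    paths["truth"] = str(out / "truth.json")
    return paths
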