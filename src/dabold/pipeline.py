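"""Configuration-driven orchestration of the full analysis.

Stages (each individually toggleable): simulate -> quantify -> profile ->
factors -> pls -> report. Every random stage consumes a named seed spawned
from the master seed, so a config + seed pair reproduces the run byte for
byte. Each invocation writes one run directory containing a manifest
(config hash, seeds, versions), a JSON summary, CSV tables, NIfTI volumes
and a log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ConfigValidationError, InvalidSpecError
from .factors import composite_da, factor_scores, fit_hierarchical_cfa
from .logan import TimeActivityCurve, logan_bp, read_tac_csv
from .pls import (BoldBlock, bootstrap_saliences, brain_scores,
                  exclude_outlier_subjects, n_estimable_lvs, permutation_test)
from .profiling import fit_lpa, label_groups, screen_performance
from .clusters import threshold_and_cluster
from .steiger import ci_overlap_decision, reliability, steiger_z
from .synth import CONDITIONS, GROUPS, CohortConfig, SyntheticCohort, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_cohort"]

_STAGES = ("simulate", "quantify", "profile", "factors", "pls", "report")


@dataclass
class PipelineConfig:
    """Validated end-to-end configuration. Unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "dabold_run"
    input_dir: Optional[str] = None          # read a previously written cohort
    stages: tuple = _STAGES
    cohort: Dict = field(default_factory=dict)   # CohortConfig overrides
    t_star: float = 18.0
    k_range: tuple = (1, 2, 3, 4, 5)
    lpa_covariance: str = "full"
    lpa_starts: int = 10
    use_regional_da: bool = False            # False: composite (6 LVs); True: 3 factors (18)
    n_perm: int = 1000
    n_boot: int = 1000
    bsr_threshold: float = 3.29
    min_cluster_size: int = 50
    min_sep_mm: float = 10.0
    connectivity: int = 26
    outlier_k_sd: float = 3.0
    chance_alpha: float = 0.05

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ConfigValidationError(f"unknown stage(s): {unknown}")
        if self.n_perm < 1:
            raise ConfigValidationError("n_perm must be >= 1")
        if self.n_boot < 2:
            raise ConfigValidationError("n_boot must be >= 2")
        if self.bsr_threshold <= 0 or self.min_cluster_size < 1 or self.min_sep_mm < 0:
            raise ConfigValidationError("invalid cluster parameters")
        if self.connectivity not in (6, 18, 26):
            raise ConfigValidationError("connectivity must be 6, 18 or 26")
        known = {f.name for f in dataclasses.fields(CohortConfig)}
        bad = set(self.cohort) - known
        if bad:
            raise ConfigValidationError(f"unknown cohort key(s): {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigValidationError(f"unknown config key(s): {sorted(bad)}")
        d = dict(d)
        for key in ("stages", "k_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigValidationError("config file must contain a mapping")
        return cls.from_dict(data)

    def canonical_json(self, include_paths: bool = True) -> str:
        d = dataclasses.asdict(self)
        d["cohort"] = {k: list(v) if isinstance(v, tuple) else v
                       for k, v in d["cohort"].items()}
        if not include_paths:
            # paths are run bookkeeping, not analysis parameters
            d.pop("out_dir"), d.pop("input_dir")
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.canonical_json(include_paths=False).encode()).hexdigest()[:16]


def _spawn_seeds(seed: int) -> Dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("cohort", "lpa", "cfa", "perm", "boot")
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def load_cohort(in_dir: str | Path) -> SyntheticCohort:
    """Reload a cohort written by :func:`dabold.synth.write_cohort`."""
    import nibabel as nib

    d = Path(in_dir)
    acc = pd.read_csv(d / "accuracy.csv", index_col="subject")
    bp = pd.read_csv(d / "bp_regional.csv", index_col="subject")
    schedule, curves = read_tac_csv(d / "tacs.csv")
    with open(d / "truth.json") as fh:
        truth = json.load(fh)
    group = np.asarray(truth["group"])
    shape = tuple(truth["grid_shape"])
    n_vox = int(np.prod(shape))
    n = len(acc)
    bold = {}
    affine = None
    for cond in CONDITIONS:
        mat = np.empty((n, n_vox))
        for g in GROUPS:
            img = nib.load(d / f"bold_{cond}_{g}.nii.gz")
            affine = img.affine
            rows = np.flatnonzero(group == g)
            mat[rows] = np.asarray(img.dataobj).reshape(n_vox, rows.size).T
        bold[cond] = mat
    cfg = CohortConfig(n_subjects=n, grid_shape=shape, seed=0)
    truth_rec = {
        "class": truth["class"],
        "group": truth["group"],
        "planted_r": {tuple(k.split("|")): v for k, v in truth["planted_r"].items()},
        "composite": np.asarray(truth["composite"]),
        "factor_scores": pd.DataFrame(truth["factor_scores"]),
        "signal_mask": np.asarray(truth["signal_mask"], dtype=bool),
        "bp_region_truth": truth["bp_region_truth"],
        "grid_shape": shape,
        "affine": affine,
    }
    ref = curves.pop("cerebellum_ref").activity
    tacs = {name: c.activity for name, c in curves.items()}
    return SyntheticCohort(config=cfg, accuracy=acc, bp_regional=bp, schedule=schedule,
                           tacs=tacs, reference_tac=ref, bold=bold, truth=truth_rec)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _pls_once(cohort: SyntheticCohort, groups: pd.Series, da: pd.DataFrame,
              cfg: PipelineConfig, seeds: Dict[str, int],
              subjects: Optional[list] = None) -> Dict:
    """One full PLS pass (cross-block, SVD, permutation, bootstrap)."""
    blocks = []
    for g in GROUPS:
        subs = [s for s in groups.index if groups[s] == g]
        if subjects is not None:
            subs = [s for s in subs if s in subjects]
        for cond in CONDITIONS:
            rows = [cohort.subjects.index(s) for s in subs]
            blocks.append(BoldBlock(group=g, condition=cond,
                                    data=cohort.bold[cond][rows], subjects=subs,
                                    shape=cohort.config.grid_shape,
                                    affine=cohort.config.affine,
                                    n_lags=cohort.config.lags))
    lvs, perm_p = permutation_test(blocks, da, n_perm=cfg.n_perm, seed=seeds["perm"])
    boot = bootstrap_saliences(blocks, da, n_boot=cfg.n_boot, seed=seeds["boot"], n_lv=1)
    scores_lv1 = {(b.condition, b.group): brain_scores(lvs[0].v, b) for b in blocks}
    return {"blocks": blocks, "lvs": lvs, "perm_p": perm_p, "boot": boot,
            "scores_lv1": scores_lv1}


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all enabled stages; returns the summary dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("dabold")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seeds = _spawn_seeds(config.seed)
    summary: Dict = {"seeds": seeds, "config_hash": config.config_hash()}
    try:
        manifest = {
            "config": json.loads(config.canonical_json()),
            "config_hash": config.config_hash(),
            "seeds": seeds,
            "versions": {"dabold": __version__, "numpy": np.__version__},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

        # --- simulate (or load) -------------------------------------------
        if config.input_dir:
            cohort = load_cohort(config.input_dir)
            logger.info("loaded cohort from %s", config.input_dir)
        elif "simulate" in config.stages:
            cohort_cfg = CohortConfig(**{"seed": seeds["cohort"], **config.cohort})
            cohort = generate_cohort(cohort_cfg)
            write_cohort(cohort, out / "cohort")
            logger.info("simulated cohort: n=%d", cohort_cfg.n_subjects)
        else:
            raise InvalidSpecError("stage 'simulate' disabled and no input_dir given")

        # --- quantify ------------------------------------------------------
        if "quantify" in config.stages:
            ref = TimeActivityCurve(cohort.reference_tac, cohort.schedule, "cerebellum_ref")
            est = {}
            for region, act in cohort.tacs.items():
                tac = TimeActivityCurve(act, cohort.schedule, region)
                est[region] = logan_bp(tac, ref, cohort.schedule, t_star=config.t_star)
            bp_est = pd.Series(est, name="bp_nd_logan")
            bp_est.to_csv(out / "bp_logan.csv")
            summary["logan_bp"] = {k: float(v) for k, v in est.items()}
            summary["logan_bp_truth"] = cohort.truth["bp_region_truth"]

        # --- profile -------------------------------------------------------
        needs_profiling = any(st in config.stages
                              for st in ("profile", "factors", "pls", "report"))
        if not needs_profiling:
            summary = _round_floats(summary)
            with open(out / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            return summary
        kept_acc, excluded_acc, thr = screen_performance(cohort.accuracy,
                                                         alpha=config.chance_alpha)
        lpa = fit_lpa(kept_acc, k_range=config.k_range,
                      covariance_family=config.lpa_covariance,
                      n_starts=config.lpa_starts, seed=seeds["lpa"])
        orig_names = label_groups(lpa)
        # the PLS design declares two performance subgroups: any extra class
        # below the top 3-back performer is folded into "low"
        names = {c: ("normal" if n == "normal" else "low") for c, n in orig_names.items()}
        groups = pd.Series([names[int(c)] for c in lpa.assignments], index=kept_acc.index,
                           name="group")
        for g in GROUPS:
            if (groups == g).sum() < 3:
                raise InvalidSpecError(f"group {g!r} has <3 subjects after profiling")
        if "profile" in config.stages:
            summary["profiling"] = {
                "chance_threshold": int(thr),
                "n_excluded_below_chance": int(len(excluded_acc)),
                "k_selected": lpa.k,
                "bic_by_k": {str(k): float(v) for k, v in lpa.bic_by_k.items()},
                "class_shares": {orig_names[i]: float(s) for i, s in enumerate(lpa.class_shares)},
                "group_sizes": groups.value_counts().to_dict(),
            }
            groups.to_frame().reset_index().to_csv(out / "groups.csv", index=False)

        # --- factors ---------------------------------------------------------
        bp_kept = cohort.bp_regional.loc[kept_acc.index]
        model = fit_hierarchical_cfa(bp_kept, seed=seeds["cfa"])
        scores = factor_scores(model, bp_kept)
        scores = composite_da(scores)
        if "factors" in config.stages:
            summary["factors"] = {
                "chi2": model.chi2, "df": model.df, "n": model.n, "cfi": model.cfi,
                "rmsea": model.rmsea, "converged": model.converged,
                "heywood": model.heywood,
                "composite_loadings": scores.composite_loadings.to_dict(),
                "explained_variance_ratio": scores.explained_variance_ratio,
            }
            sc = scores.scores.copy()
            sc["composite"] = scores.composite
            sc.reset_index().to_csv(out / "da_scores.csv", index=False)

        # --- pls -------------------------------------------------------------
        if "pls" in config.stages or "report" in config.stages:
            if config.use_regional_da:
                da = scores.scores.copy()
            else:
                da = scores.composite.to_frame("composite")
            res = _pls_once(cohort, groups, da, config, seeds)
            kept, excl, refit = exclude_outlier_subjects(res["scores_lv1"],
                                                         k_sd=config.outlier_k_sd)
            if refit:
                logger.info("excluding %d brain-score outlier(s); recomputing", len(excl))
                res = _pls_once(cohort, groups.loc[kept], da.loc[kept], config, seeds,
                                subjects=kept)
            lvs = res["lvs"]
            boot = res["boot"]
            summary["pls"] = {
                "n_estimable_lvs": n_estimable_lvs(da.shape[1], len(CONDITIONS), len(GROUPS)),
                "outliers_excluded": [str(s) for s in excl],
                "refit": bool(refit),
                "lv_table": [
                    {"lv": lv.index, "s": lv.s, "pct_crossblock": lv.pct_crossblock,
                     "perm_p": lv.perm_p}
                    for lv in lvs
                ],
                "bootstrap_redrawn": boot.n_redrawn,
            }
            boot.correlation_scores.to_csv(out / "correlation_scores.csv", index=False)

        # --- report ----------------------------------------------------------
        if "report" in config.stages:
            import nibabel as nib

            v = cohort.config.n_voxels
            bsr_lag0 = boot.bsr[0, :v]
            bsr_map = np.nan_to_num(bsr_lag0, posinf=0.0, neginf=0.0)
            bsr_vol = bsr_map.reshape(cohort.config.grid_shape)
            nib.save(nib.Nifti1Image(bsr_vol.astype(np.float32), cohort.config.affine),
                     out / "bsr_lv1.nii.gz")
            sal_vol = lvs[0].v[:v].reshape(cohort.config.grid_shape)
            nib.save(nib.Nifti1Image(sal_vol.astype(np.float32), cohort.config.affine),
                     out / "salience_lv1.nii.gz")
            ct = threshold_and_cluster(bsr_vol, cohort.config.affine,
                                       threshold=config.bsr_threshold,
                                       min_size=config.min_cluster_size,
                                       min_sep_mm=config.min_sep_mm,
                                       connectivity=config.connectivity)
            ct.table.to_csv(out / "clusters.csv", index=False)
            summary["clusters"] = ct.table.to_dict(orient="records")
            summary["decisions"] = _ci_decisions(boot.correlation_scores, res, da)
        summary = _round_floats(summary)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    finally:
        root.removeHandler(handler)
        handler.close()
    return summary


def _ci_decisions(cs: pd.DataFrame, res: Dict, da: pd.DataFrame) -> Dict:
    """Reliability and pairwise CI/Steiger decisions on LV1 correlation scores."""
    lv1 = cs[cs["lv"] == 0]
    out: Dict = {"reliability": {}, "within_group": {}, "between_group": {}}
    for _, row in lv1.iterrows():
        key = f"{row['da_variable']}|{row['group']}|{row['condition']}"
        out["reliability"][key] = reliability((row["ci_low"], row["ci_high"]))
    scores = res["scores_lv1"]
    for da_var in lv1["da_variable"].unique():
        sub = lv1[lv1["da_variable"] == da_var].set_index(["group", "condition"])
        for g in GROUPS:
            for c1, c2 in (("back1", "back2"), ("back2", "back3"), ("back1", "back3")):
                a, b = sub.loc[(g, c1)], sub.loc[(g, c2)]
                decision = ci_overlap_decision((a["ci_low"], a["ci_high"]),
                                               (b["ci_low"], b["ci_high"]))
                entry = {"ci_decision": decision, "r_1": float(a["r"]), "r_2": float(b["r"])}
                if decision == "not-distinguished":
                    s1, s2 = scores[(c1, g)], scores[(c2, g)]
                    common = s1.index.intersection(s2.index)
                    davec = da.loc[common, da_var].to_numpy(dtype=float)
                    r23 = float(np.corrcoef(s1.loc[common], s2.loc[common])[0, 1])
                    st = steiger_z(float(a["r"]), float(b["r"]),
                                   np.clip(r23, -0.999999, 0.999999), n=len(common))
                    entry["steiger_z"] = st.z
                    entry["steiger_p"] = st.p
                out["within_group"][f"{da_var}|{g}|{c1}_vs_{c2}"] = entry
        for cond in CONDITIONS:
            a, b = sub.loc[("normal", cond)], sub.loc[("low", cond)]
            out["between_group"][f"{da_var}|{cond}"] = {
                "ci_decision": ci_overlap_decision((a["ci_low"], a["ci_high"]),
                                                   (b["ci_low"], b["ci_high"])),
                "r_normal": float(a["r"]), "r_low": float(b["r"]),
            }
    return out
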