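"""Generate a synthetic multimodal cohort and look at its planted truth.

The generator produces every input the analysis needs: n-back accuracy from
a two-class mixture, 16 regional binding potentials from a hierarchical
factor model, SRTM-kinetic PET time-activity curves, and voxelwise BOLD
with a planted DA-BOLD correlation that differs by load and group.
"""

import numpy as np

import dabold

cohort = dabold.generate_cohort(dabold.CohortConfig(seed=42))

print(f"subjects: {len(cohort.accuracy)}")
print("accuracy means by true group (sum correct, 0-90):")
groups = np.asarray(cohort.truth["group"])
for g in ("normal", "low"):
    rows = cohort.accuracy[groups == g]
    print(f"  {g:>7}: n={len(rows):3d} " +
          " ".join(f"{c}={rows[c].mean():5.1f}" for c in rows.columns))

print("\nregional BP_ND means (first four regions):")
print(cohort.bp_regional.mean().head(4).round(3).to_string())

print("\nplanted DA-BOLD correlations per (group, condition):")
for (g, c), r in cohort.truth["planted_r"].items():
    print(f"  {g:>7} {c}: r = {r:.2f}")
print("\nThe planted r values are the ground truth the PLS stage must recover;")
print("signal lives in a contiguous blob of",
      int(np.sum(cohort.truth["signal_mask"])), "voxels.")
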