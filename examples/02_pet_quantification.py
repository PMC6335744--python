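"""Quantify D2/3 binding potential from dynamic PET curves by Logan analysis.

Simulates SRTM-kinetic time-activity curves with known BP_ND on the 55-min
18-frame schedule and recovers the binding potential from the asymptotic
slope of the Logan reference plot (slope = DVR, BP_ND = DVR - 1).
"""

import dabold

schedule = dabold.make_schedule(dabold.DEFAULT_SCHEDULE_SPEC)
print(f"dynamic schedule: {schedule.n_frames} frames, "
      f"{schedule.total_duration / 60:.0f} min total")

print(f"{'true BP':>8} {'Logan estimate':>15} {'error %':>8}")
for bp_true in (0.3, 1.0, 2.0, 3.0):
    target_act, ref_act = dabold.simulate_tac(bp_true, r1=1.0, k2_ref=0.16,
                                              schedule=schedule)
    target = dabold.TimeActivityCurve(target_act, schedule, "striatum")
    reference = dabold.TimeActivityCurve(ref_act, schedule, "cerebellum")
    est = dabold.logan_bp(target, reference, schedule, t_star=18.0)
    print(f"{bp_true:8.2f} {est:15.3f} {100 * (est - bp_true) / bp_true:8.2f}")

print("\nEstimates sit within a few percent of truth for raclopride-like")
print("kinetics; the small negative bias at high BP is the classic late-")
print("equilibration effect of the graphical method on a 55-min window.")
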