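"""Full group-comparison study on the default synthetic cohort.

Generates the 3 control / 3 global-mild / 3 focal-severe phantom cohort at
the full 128-cube study scale, runs every subject through the pipeline
(octree at 40 HU -> unit blocks -> variogram truncated at 56 voxels), and
compares the heterogeneity score Delta with the densitometric comparators
(emphysema index, coefficient of variation).

Expected picture, mirroring the disease biology the phantoms emulate:
Delta orders the groups with no overlap, while EI and CoV confound healthy
and mildly diseased subjects because animal-to-animal baseline variation
(~45 HU) swamps the mild -50 HU shift.  Takes ~20 s.
"""

from octovario import StudyConfig, generate_cohort, run_study

cohort = generate_cohort(seed=0, dims=128)
cfg = StudyConfig(threshold_hu=40.0, filter_method="none")
result = run_study(cohort, cfg)

print(result.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nemphysema-index cutoff (control mean - 2 sigma): "
      f"{result.ei_threshold_hu:.0f} HU")
print(f"Kruskal-Wallis across the three controls: p = {result.kw_control.p_value:.3g}")
for (a, b), test in result.mww_pairwise.items():
    verdict = "distinct" if test.significant else "not distinct"
    print(f"Mann-Whitney {a} vs {b}: p = {test.p_value:.3g} ({verdict} at alpha=0.05)")

frame = result.to_frame()
by = frame.groupby("group")["delta_hu2"]
print(f"\nDelta ranges: control [{by.min()['control']:.0f}, {by.max()['control']:.0f}], "
      f"mild [{by.min()['global_mild']:.0f}, {by.max()['global_mild']:.0f}], "
      f"severe [{by.min()['focal_severe']:.0f}, {by.max()['focal_severe']:.0f}] HU^2")
print("Delta separates the groups; EI and CoV overlap between control and mild.")
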