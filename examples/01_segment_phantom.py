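"""Segment a synthetic CE-SSFP study with the full four-block pipeline.

Generates the default phantom (90-degree myocardium-at-risk wedge, contrast
1.3, 5 % noise, planted coil gradient, microvascular-obstruction core), runs
the automatic segmentation, and compares against the generative truth.
"""

from marquant import PhantomSpec, dice_timeframes, generate_case, run_segment_mar

case = generate_case(PhantomSpec(seed=7))
result = run_segment_mar(case.study)

print(f"truth MaR:      {case.truth_percent_lvm:5.1f} %LVM")
print(f"automatic MaR:  {result.percent_lvm:5.1f} %LVM")
print(f"Dice vs truth:  {dice_timeframes(result.masks, case.truth_mar):5.3f}")
for tf, prov in result.provenance["timeframes"].items():
    corr = prov["correction"]
    print(f"{tf}: coil correction applied={corr['applied']} "
          f"(remote CoV {corr['cov_before']:.3f} -> {corr['cov_after']:.3f}); "
          f"EM classes {prov['em']['mu_normal']:.2f} / {prov['em']['mu_mar']:.2f}")

# The automatic %LVM should sit within a few %LVM of the truth and the Dice
# near 1; the provenance shows each block's decisions (the correction is
# accepted because it reduced remote variability while keeping the culprit
# territory hyperintense).
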