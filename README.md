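# marquant

Automatic quantification of **myocardium at risk (MaR)** in contrast-enhanced
SSFP (CE-SSFP) cardiac MR.

MaR is the ischemic myocardium during a coronary occlusion — the region that
will infarct if flow is not restored. Together with final infarct size (MI,
from late gadolinium enhancement, LGE) it gives the myocardial salvage index
`MSI = 1 − MI/MaR`, the efficacy measure of reperfusion therapy. In CE-SSFP
cine images (acquired ~5 min after gadolinium) MaR appears hyperintense;
delineating it manually is slow and subjective. `marquant` implements an
automatic segmentation pipeline for researchers analysing such studies, plus
the standard threshold baselines, validation statistics, and a synthetic
phantom generator so every stage is testable without patient data.

## The algorithm

Inputs are the manually delineated endo/epicardial contours (end-diastole and
end-systole), the culprit artery (LAD, LCx, RCA or LM), and the anterior
right-ventricular insertion angle that anchors a 24-sector circumferential
division of the myocardium. A per-artery *maximal extent model* — the largest
perfusion territory of a proximal occlusion — provides the a priori prior;
myocardium outside it is the *remote* region. Four processing blocks:

1. **Surface-coil intensity correction.** A second-order polynomial bias
   field is fitted per slice (least squares, log domain) to blood-pool and
   remote-myocardium intensities and divided out. It is kept only if it
   reduces the remote coefficient of variation *and* leaves the culprit
   territory's mean above the remote mean.
2. **EM intensity classification.** Myocardial intensities are modelled as a
   two-class Gaussian mixture (normal, MaR) fitted by
   expectation-maximization, initialized from the maximal extent model:

   `p(x) = (1 − w) N(x; μ_normal, σ_normal²) + w N(x; μ_MaR, σ_MaR²)`

3. **A priori regional criteria.** The classification is applied sector-wise
   (mean MaR posterior > 0.5) within the maximal extent model only; per slice
   the largest circumferentially contiguous run of MaR sectors is kept, and
   MaR is assumed transmural.
4. **LGE infarct fusion.** Infarct is delineated on the LGE stack (remote
   mean + 1.8 SD threshold, region filtering, enclosed hypointense cores =
   microvascular obstruction counted as 100 % infarct) and any
   infarct-containing sector is forced into MaR — MVO suppresses CE-SSFP
   intensity, so these sectors would otherwise be missed.

MaR is reported as percent of left-ventricular mass (%LVM), averaged over
end-diastole and end-systole. Validation uses the Dice similarity
coefficient `DSC = 2|A∩B|/(|A|+|B|)`, Bland-Altman bias ± SD with 1.96-SD
limits of agreement, Pearson R, and paired t-tests (Bonferroni) for the
incremental value of each block. Baselines: 2SD-from-remote, FWHM and Otsu
thresholds, applied slice by slice.

## Worked example

```python
from marquant import PhantomSpec, dice_timeframes, generate_case, run_segment_mar

case = generate_case(PhantomSpec(seed=7))   # synthetic CE-SSFP + LGE study
result = run_segment_mar(case.study)
print(f"truth {case.truth_percent_lvm:.1f} %LVM, "
      f"auto {result.percent_lvm:.1f} %LVM, "
      f"Dice {dice_timeframes(result.masks, case.truth_mar):.3f}")
```

prints

```
truth 25.0 %LVM, auto 25.0 %LVM, Dice 0.997
```

i.e. the pipeline recovers the planted 90° risk wedge (25 % of the LV mass)
essentially exactly despite the planted coil gradient, noise, and a
hypointense MVO core. The `examples/` scripts walk through the pipeline,
the baselines, cohort validation and disk I/O; a thin CLI (`mar run`,
`mar baseline`, `mar phantom`, `mar evaluate`) wraps the same functions for
study directories (NIfTI volumes + JSON annotation sidecar).

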