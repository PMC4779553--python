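# Methods

This note documents the model, the numerical choices, and what the synthetic
phantom does and does not establish.

## Problem setting and conventions

Short-axis CE-SSFP cine stacks (end-diastole, ED, and end-systole, ES) with a
matched LGE stack. Volumes are `(slice, row, col)` with slices ordered
base→apex; the centre of pixel `(r, c)` is at `(x, y) = (c·s, r·s)` mm for
in-plane spacing `s`. The myocardium between the (manual) endocardial and
epicardial contours is divided into 24 circumferential sectors of 15°;
sector 0 starts at the anterior right-ventricular insertion angle and indices
increase counterclockwise in the `(x, y)` plane. Sector bins are half-open
`[a, a+15°)`: an angle exactly on a boundary belongs to the sector starting
there. Slice levels (basal/mid/apical) are assigned by thirds of the
delineated slice range. Masks are rasterized by pixel-centre point-in-polygon
tests; a zero-thickness wall (endocardium = epicardium) is a valid empty
mask, while an endocardium extending outside the epicardium is an error.

## Maximal extent models

The per-artery maximal perfusion territories are shipped as a replaceable
JSON table (`marquant/data/territories.json`), derived from the standard AHA
17-segment artery assignment and dilated by one sector per circumferential
edge to represent a proximal occlusion's maximal extent (LAD: sectors 19–4;
LCx: 3–12; RCA: 11–20; apical LAD one sector wider per side; LM = LAD ∪ LCx).
Results that depend on territory boundaries are configuration-sensitive;
users with better expert-drawn tables should substitute their own file.

## Block 1 — surface-coil correction

The coil gain is modelled as a multiplicative field `exp(P₂(x̂, ŷ))` with
`P₂` a full degree-2 polynomial (6 coefficients) over FOV-normalized in-plane
coordinates, fitted per slice because through-plane coil distance varies
slice to slice. Fitting in the log domain makes the multiplicative model
linear: each blood-pool or remote-myocardium sample contributes its
log-intensity minus its class's per-slice mean log-intensity, and the
residuals are regressed on the polynomial basis (ordinary least squares,
requiring > 6 samples per class per slice; slices with too-small blood pools
inherit the nearest fitted slice's coefficients). The blood pool is the
endocardial interior eroded by one pixel to avoid the partial-volume rim.
Correction divides by the field and rescales so the remote mean is preserved
exactly. It is *applied* only if the remote coefficient of variation
decreases and the culprit-territory mean stays above the remote mean;
otherwise the input passes through unchanged (the block is optional, and a
correction that inverts the MaR contrast must be rejected). Fit failures
degrade gracefully to "not applied" with a recorded reason.

## Block 2 — EM classification

Two-component Gaussian mixture over all myocardial voxel intensities of a
timeframe (one fit per timeframe, not per slice — the coil correction has
already removed the in-plane gradient, and pooling maximizes sample size).
The fit uses voxel samples directly rather than a binned histogram.
Initialization: class statistics of voxels inside (MaR) and outside (normal)
the maximal extent model, with the inside fraction as initial weight.
Defaults: convergence at relative mean-log-likelihood change ≤ 1e-6, at most
500 iterations, class SDs floored at 1e-3 of the intensity range (collapse
guard, flagged when active). Labels are ordered so the MaR class is the
brighter one. Both classes are Gaussian: CE-SSFP does not null remote
myocardium, so a Rayleigh component is not appropriate.

**Degenerate inputs.** If the fitted mixture does not beat a single Gaussian
by BIC (3 extra parameters), the intensity histogram carries no evidence of a
second class — e.g. a contrast-free acquisition — and the classification is
declared empty rather than letting a near-constant posterior flag arbitrary
regions. This guard never fires on studies with genuine MaR contrast.

## Block 3 — a priori regional criteria

A sector is MaR when the mean MaR posterior over its voxels is strictly
greater than 0.5 (mean posterior is the natural sector aggregate and robust
to single-voxel noise; ties are not flagged). Only sectors inside the
maximal extent model participate. Continuity is enforced per slice in
circular sector order restricted to the territory: only the largest
contiguous run survives, ties broken toward the run closer to the
territory's angular centre. Continuity is deliberately 2-D (per slice), not
3-D, matching the sector-wise formulation. Flagged sectors are made
transmural (every myocardial voxel of the sector, endocardium to epicardium).

## Block 4 — LGE infarct fusion

Infarct on the LGE stack: threshold = remote mean + 1.8·SD; suprathreshold
myocardial voxels are kept after discarding in-plane connected components
smaller than 1 % of the slice's myocardial voxels (8-connectivity); enclosed
hypointense regions within the hyperenhancement are microvascular obstruction
(MVO) and count as 100 % infarct. (The cited full infarct algorithm's
partial-volume weighted summation is out of scope; binary infarct + MVO fill
suffices for fusion.) LGE is sectorized with its own RV insertion; CE-SSFP
and LGE sectors correspond by slice-level thirds and sector index — no
deformable registration. Any sector containing infarct is forced into MaR
*before* continuity re-enforcement; the fusion contract outranks continuity,
so an infarct sector dropped by the largest-run rule is restored with a
warning. Infarct outside the configured territory is still fused (infarct is
by definition inside MaR; the territory table may be imperfect), with a
warning. Without an LGE stack the block is skipped and logged.

ED and ES are processed independently; %LVM is the mean of the two
timeframes. Dice between mask sets pools ED and ES voxel sets (a
per-timeframe mode exists). All Bland-Altman SDs are sample (n−1) SDs.

## Phantom generator

The phantom emulates the study conditions end to end: a 128×128×8 grid at
1.5×1.5 mm in-plane and 8 mm contiguous slices; an annular LV (ED epicardial
radius 30 mm, endocardial 20 mm; ES epicardial radius scaled by 0.85 with
mass-preserving wall thickening); base intensities normal myocardium 1.0,
blood 1.8, background 0.1 (arbitrary units); a transmural, circumferentially
contiguous MaR wedge (default 90°, contrast 1.3) centred in the culprit
territory; an infarct sub-wedge (default 50°) with an optional MVO core; a
multiplicative degree-2 coil field; additive Gaussian noise (default SD 5 %
of the normal-myocardium mean — myocardial SNR ≈ 20, realistic for SSFP
cine). The default coil coefficients produce ≈ 30 % peak-to-peak gain
variation across the LV, consistent with surface-coil physics (the heart
occupies roughly the central third of the FOV, so much larger FOV-level
amplitudes are needed than naive normalization suggests).

The MVO core attenuates CE-SSFP intensity by 0.7 over radial wall fraction
0.1–0.9 — enough that the affected sectors' mean intensity falls below
normal myocardium, defeating pure intensity classification and exercising
the fusion block — while the LGE dark core occupies the mid-wall band
0.3–0.7 so that a hyperenhanced rim of at least two pixels encloses it
in-plane (physically, the LGE appearance of MVO).

Cohorts sample wedge extent 60–150°, contrast 1.2–1.5, noise SD 0.05–0.10,
infarct 0.3–0.6 of the wedge, culprit ∈ {LAD, LCx, RCA}, with an MVO core in
every other case. Truth %LVM then spans ≈ 17–42 (mean ≈ 29); the ≈ 150°
territory width caps how large a contiguous wedge can be, so clinical
cohorts with larger mean MaR are not fully emulated.

**What the phantom does not model:** partial-volume edge voxels, intra-class
intensity texture, SSFP banding, motion, papillary muscles (assumed excluded
by the contours), or contour error. Classes are exactly Gaussian — the EM
model is correctly specified — so intensity classification alone performs
substantially better here than on clinical data. Consequently the per-block
ablation shows its documented behaviour: adding the coil correction and the
LGE fusion each raise mean Dice, and the a priori block swings the bias from
over- to under-estimation (it drops MVO-suppressed sectors, which fusion then
restores), but the a priori block's mean Dice on this phantom dips below the
EM+correction level — there is too little scattered misclassification left
for the priors to clean up, while the MVO cases pay the largest-run penalty
until block 4. Passing cohort tests therefore demonstrate correct mechanics
and the designed interplay of the blocks, not clinical-grade effect sizes.

## Numerical details

* Posterior threshold: the equal-posterior intensity solves a quadratic in
  the log-densities; the upward crossing between the class means is returned.
* Otsu uses 256 equal-width bins over the slice's myocardial intensity
  range; mask inclusion is strict `>` for all threshold methods; baselines
  operate on uncorrected intensities.
* All randomness flows through explicit integer seeds; a fixed seed gives
  bit-identical phantoms and results. Images are stored float32 so disk
  round-trips are exact.
* Primary format NIfTI-1 with a JSON annotation sidecar (contours in mm per
  slice and timeframe, RV insertion angles, culprit); DICOM series read-only.
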