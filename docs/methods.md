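# Methods

`metsperf` analyzes longitudinal MRI of multifocal brain metastases in a
mouse model: dynamic susceptibility contrast (DSC) perfusion for relative
cerebral blood volume (rCBV), T2-weighted detection and sizing of lesions,
T1-weighted post-contrast classification of blood–tumor-barrier (BTB)
permeability, lesion tracking across weekly scans, and microvessel density
(MVD) from two-channel fluorescence histology. Because no imaging data are
deposited for this kind of study, the package ships a digital mouse-brain
phantom whose presets emulate the statistical structure of such a cohort;
every analysis stage runs end-to-end on synthetic data with known ground
truth.

## DSC perfusion model

The signal model is the standard single-echo gradient-echo relation

    ΔR2*(t) = −(1/TE) · ln(S_t / S_0),        S_0 = mean pre-bolus signal,

with TE in seconds, so ΔR2* is in s⁻¹ and is proportional to the
intravascular contrast concentration. The first pass of the bolus is the
gamma-variate

    y(t) = K (t − t0)^α exp(−(t − t0)/β)   for t > t0,  else 0,

whose area — the CBV surrogate — has the closed form K β^(α+1) Γ(α+1).
Every converged fit cross-checks this closed form against trapezoidal
quadrature (tolerance 0.1%); disagreement flags the fit in QC.

Processing per curve:

1. **Bolus extent.** A first-pass pharmacokinetic model (FPPM) is fitted to
   the whole ΔR2* curve: `c0 + K·g(t) + k_leak·∫g dτ`, where `g` is a
   peak-normalized gamma-variate and the cumulative term absorbs contrast
   retention/recirculation so the post-bolus tail does not bias the bolus
   shape. Bolus start and end are where the fitted first-pass component
   crosses 5% of its peak (the literature states no threshold; 5% is this
   package's convention). If the fit fails, a detector based on threshold
   crossings of the smoothed curve substitutes — the model is used here
   *only* to locate the bolus, so any monotone-consistent detector is an
   acceptable fallback. Curves whose peak is below 5× the baseline noise SD
   return a "no bolus" result and are excluded via QC.
2. **Three-segment baseline.** The pre-bolus trend (least-squares line over
   pre-bolus frames) is subtracted, setting the pre-bolus baseline to zero;
   a linear fit over the post-bolus frames models slow drift; the straight
   line connecting the two segments bridges under the bolus. Fitting a line
   (rather than a constant) to the pre-bolus frames makes the correction
   annihilate a global linear drift exactly, which is the property the
   oracle tests pin down. Curves with fewer than 3 post-bolus frames are
   excluded.
3. **Gamma-variate fit.** Nonlinear least squares with an analytic
   Jacobian; t0 is initialized one frame before the detected bolus start,
   α and β from the log-linearization ln y = ln K + α ln τ − τ/β over
   points above 10% of the peak. Bounds: α ∈ (0, 20], β ∈ (0, 60 s], t0
   within a few frames of the detected start. Failed or at-bound fits get
   CBV = NaN and a QC flag.

ROI-level fitting (the mean ΔR2* curve over an ROI) is the reference path
for tabulated values; per-voxel maps (`compute_cbv_map`) are intended for
display. The bolus window defaults to a single detection on the brain-mean
curve, since bolus timing is global within an acquisition; per-voxel
re-detection is available by flag.

## Multi-reference rCBV normalization

With multifocal disease no single normal region is a usable reference, and
normal-brain CBV is itself heterogeneous. Each tumor ROI is therefore
mirrored across the per-slice midline to a contralateral site; if that site
is abnormal (more than 5% of its voxels overlap lesions or QC failures),
the nearest lesion-free equal-area disc in the same region code and
hemisphere substitutes, with provenance recorded; if none exists the pair
is excluded. The per-animal reference is the mean CBV over all normal
ROIs, and every ROI's rCBV is its mean CBV divided by that reference — so
the mean rCBV over an animal's normal ROIs is exactly 1 by construction,
and the whole table is invariant to global CBV rescaling. ROI means use
QC-passed voxels only; an ROI is dropped when fewer than half its voxels
pass.

## Lesion detection, permeability, tracking

T2w detection is per-slice 2D: voxels above the robust background level
(median + 2 × 1.4826·MAD over the brain mask) are candidates; 8-connected
components with equivalent diameter ≥ 310 µm (the detectability floor at
78 µm resolution) are kept. Size is the in-plane area in mm² — at 1 mm
slice thickness most lesion diameters are below the slice, so area is the
meaningful quantity and no 3D volumetry is attempted. A lesion's region is
the majority anatomy label under its mask, ties broken by the centroid
label.

BTB permeability is read from the T1w post-contrast image: a lesion voxel
is enhancing when brighter than the mirrored contralateral tissue mean +
2 SD; the lesion is non-permeable below an enhancing-area fraction of 0.1,
fully enhancing above 0.9, and partially enhancing between — the
reproducible analogue of a visual iso/hyper/partial call.

Tracking between weekly scans is greedy nearest-centroid matching on the
same slice within 0.5 mm (lesions at these densities are well separated);
unmatched later-week lesions start new tracks and unmatched earlier-week
lesions terminate with a log entry.

## Statistics

All rCBV values are natural-log transformed before t-tests (their
distribution is right-skewed, approximately lognormal); means ± s.e. are
reported on the original scale alongside. Tumor-vs-contralateral uses a
paired test; permeable-vs-non-permeable comparisons use unpaired tests
(log scale for rCBV, raw scale for areas); size–rCBV association is the
per-group OLS R². Tests are two-sided; no multiple-testing correction is
applied (a Holm helper exists but is off by default). Lesions are pooled
across animals, ignoring within-animal correlation; the rendered report
flags this rather than replacing the pooled analysis with a mixed model.

## The phantom

**Anatomy** is a stylized 2.5D label map: per-slice 2D regions (cortex
shell, olfactory bulb, basal ganglia, hippocampus, thalamus/midbrain/
cerebellum pooled, paired ventricles) stacked over 14 coronal 1 mm slices
at 256×256/78 µm, exactly mirror-symmetric about a stored integer midline
column. No atlas registration is attempted because the whole analysis is
per-slice in-plane. The DSC grid (64×64, 4 slices) is an integer block
downsampling; its mirror axis falls between columns, so DSC mirroring uses
a half-integer midline.

**Lesions** are perturbed-ellipse blobs (irregular outlines without
overfitting any particular shape model), non-overlapping, seeded with:

| parameter | default | rationale |
|---|---|---|
| lesions/animal | Poisson(51.5), 9 animals | ≈464 lesions/cohort |
| regional incidence | cortex .49, OB .17, BG .16, hippo .13, thal/mid/cb .05 | cortex and thalamus shares as reported; remainder split over the other regions |
| in-plane area | lognormal(ln 0.38, 0.6), clipped 0.09–1.7 mm² | observed size range, mean ≈0.45 mm² |
| enhancing proportion | 0.34 (40% of those partial, fraction U(0.25, 0.75)) | reported enhancing share; partial enhancement models intratumoral BTB heterogeneity |
| CBV ratio vs local normal | lognormal, mean 0.89, σ_ln 0.505 | mean as reported; σ_ln chosen so 212 draws span ≈0.16–2.84 |
| weekly area growth | lognormal(ln 1.6, 0.25), floored at 1 | growth is reported only qualitatively; the floor makes growth monotone |
| slice placement | Gaussian, center 6.5, σ 2.5 slices | makes the best 4-slice DSC window cover ≈45% of lesions, i.e. ≈200 of 464 rCBV-eligible |

Normal-tissue CBV is a smooth mirror-symmetric random field (Gaussian,
correlation length 1.5 mm, CV 0.12) scaled to a mean first-pass area of
1300 s⁻¹·s — at α = 2.5, β = 4 s this gives a peak ΔR2* ≈ 80 s⁻¹ and a
~27% signal dip at TE = 4 ms, a realistic first pass. Ventricles carry 10%
of tissue CBV. Tumor voxels (lesion occupancy ≥ 50% of a DSC voxel) carry
the local normal CBV times the lesion's ratio. The forward model is the
same gamma-variate the analysis fits, plus an optional delayed
recirculation bump (12% of the first-pass area, delay 30 s, 1.6× broader)
and optional linear drift; signal noise is additive Gaussian by default
(Rician optional) at SD 10 on S0 = 1000 (SNR 100). The stored ground-truth
CBV map is the first-pass area per voxel, exactly the closed-form gamma
area by construction.

The **longitudinal preset** (5 animals, 32 tracked lesions) starts tracked
lesions at ratio mean 1.05 (week 3) declining by a lognormal factor to
mean 0.88 a week later. Tracked-lesion dispersion is kept modest
(σ_ln 0.15, decline σ_ln 0.10): a tracked lesion is compared against its
own mirrored reference, which cancels the regional CBV variation that
dominates the cross-sectional spread, so the paired comparison is
well-powered at n = 32. Tracked lesions are seeded on the central slices
with the olfactory bulb excluded, since follow-up lesions must lie inside
the fixed 4-slice DSC window at both weeks to be measurable twice.

**Histology fields** are 450×450 px at 1 µm/px: the green channel holds a
tumor blob (or a large reference-tissue region in normal mode), the red
channel disjoint vessel cross-sections with Poisson counts at 669/mm²
inside tumor tissue and 965/mm² in normal tissue; a configurable fraction
(30%) of tumor vessels is dilated/elongated, mimicking the irregular tumor
vasculature. MVD analysis thresholds each channel (Otsu), labels
8-connected vessel components (≥ 4 px), and counts vessels whose centroid
lies inside the mask — centroid counting avoids double counting at mask
borders. Aggregation over a lesion's fields is pooled count over pooled
area (ratio of means), with per-field ratios also emitted.

### What the phantom does and does not emulate

It reproduces the cohort's statistical structure: lesion counts, sizes,
regional incidence, enhancing share, CBV-ratio distribution and its weekly
drift, vessel densities, and the geometry that limits rCBV eligibility to
the DSC-covered slices. It does **not** simulate k-space or pulse-sequence
physics, partial-volume effects beyond grid downsampling, motion or
susceptibility artifacts, edema/necrosis compartments, arterial input
variability, or stain variability in histology. Passing tests therefore
demonstrate correctness of the analysis chain and recoverability of the
generating parameters under idealized-but-noisy imaging, not robustness to
every artifact of real acquisitions.

## Numerical and design choices

- Times are seconds internally; frame index ↔ time via the frame interval.
  Coordinates are 0-based voxel indices; areas use the geometry pixel size.
- Gaussian noise is the default (closed-form sanity checks stay simple);
  the Rician option exists for magnitude-signal realism.
- Problem sizes in the test suite and acceptance script: 20 seeds for the
  cohort-level recoveries, 10,000 lesions for regional incidence, 200
  fields per tissue class for MVD, 1000 replicates for test calibration —
  large enough that the Monte-Carlo error is a fraction of each accepted
  tolerance.
- Degenerate inputs fail loudly and early: non-positive signals are
  QC-flagged NaN (never raised mid-map), empty masks and too-small
  matrices raise configuration/usage errors, unplaceable lesions or
  vessels raise placement errors after bounded retries.

## Known limitations

- The anatomy is stylized; regional shapes are schematic and region areas
  do not match a real atlas, so regional incidence is imposed by the
  seeding distribution, not by tissue volume.
- Lesions are single-slice objects; a physical lesion spanning slices
  would be counted per slice, consistent with in-plane reporting at 1 mm
  slices but not with 3D volumetry.
- No contrast-agent leakage correction of ΔR2* is applied, and no CBF/MTT
  or AIF deconvolution is attempted; rCBV is the only perfusion readout.
- Pooling lesions across animals understates uncertainty when lesions
  within an animal are correlated; the report flags this.
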