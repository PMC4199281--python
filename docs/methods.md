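# Methods

## Model and assumptions

The package treats the BOLD response around a peak as a smooth, radially
decaying field sampled on a regular grid. The spread measure makes one
substantive assumption: that after normalization to the 3-mm sphere, the
mean signal added in successive spherical shells decays approximately in
proportion to the inverse square of the distance from the peak. The slope of
the OLS fit s = a + b/r̄² is then a single-number summary of decay speed that
is, by construction, invariant to any positive rescaling of the underlying
volume — amplitude and spread are decoupled. The fit makes no claim that
1/r² is the true generative law (our synthetic truth is Gaussian); it is a
monotone index: for noise-free Gaussian bumps the fitted slope decreases
strictly as the width σ grows over the 3–7 mm range, which is what licenses
its use as an ordinal spread measure.

Geometry is deliberately restricted: only axis-aligned, positive-scale
affines are accepted, voxel indices are 0-based, and mm coordinates refer to
voxel centers. Sphere membership is center-in-closed-ball (distance ≤
radius). Rotated or sheared grids raise instead of being silently resampled;
resampling is preprocessing and out of scope. Anisotropic voxels are
accepted (all distances are computed in mm), and the smallest sampling
radius must be at least the largest voxel dimension so no sphere is empty.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| sampling radii | mm | 3,4,…,10 | 3 mm ≈ one voxel up to the largest common ROI kernels; 1-mm steps give 7 shells |
| shell abscissa r̄ | mm | midpoint of bounding radii | unbiased for thin shells; `abscissa="outer"` available |
| fit intercept | – | included | slope magnitudes near 8–12 on unit-normalized profiles arise under an intercept-bearing fit; zero-intercept is a flag |
| normalization guard ε | % | 1e−9 | a 3-mm mean this small (or with the wrong sign for the contrast) cannot anchor a ratio; the record is excluded and logged |
| d50 reference level | – | 0.5 of the normalized (3-mm) level | solved from the fitted curve, a + b/d² = 0.5; undefined (NaN) unless a < 0.5 and b > 0 |
| dispersion log base | – | log10 | any base only rescales group contrasts |
| tie-break for equal extrema | – | smallest linear voxel index | platform-independent determinism; continuous data never tie |

Peaks are located per run on the same (unsmoothed) volumes that are sampled;
`spread_pipeline(..., peak_vols=)` accepts a separate map (e.g. a smoothed
analysis) when peak localization and sampling should be decoupled.
Normalized profiles are averaged across runs before shell-differencing, so
each subject × ROI yields one decay fit.

Shell volumes use the analytic (4/3)πr³ even though the sphere mean is taken
over in-brain voxel centers only; this is what makes the 4-mm sphere 268 mm³
and keeps the shell transform independent of mask clipping. When clipping
occurs the mean and the volume refer to slightly different voxel sets; the
discrepancy is second-order for the interior peaks the method targets.

## Group statistics

Group comparisons are OLS ANCOVAs `value ~ group + covariates` (type-II F
for the group term; non-numeric covariates are dummy-coded; adjusted means
evaluate covariates at their sample means). With no covariates the F reduces
exactly to the one-way ANOVA F, which the tests assert to 1e−9. The
age-criterion regression standardizes criterion and predictors, so its betas
are standardized coefficients; a zero-variance predictor is dropped and
reported with β = 0 rather than raised, because "spread identical across
subjects" is a legitimate degenerate input for which the peak-only model is
the right answer.

The shared-variance analysis computes, per network, the mean Pearson r²
between: spread in different regions (SS), peak in different regions (PP),
spread in one region and peak in *other* regions (SP-all, the baseline), and
spread and peak from the *same* region (SP-same). Averages over pairs are
arithmetic (a Fisher-z option was considered and rejected as the plain mean
is what the r² summaries represent); the overall row averages the two
networks with equal weight. Significance of the planned contrasts SS vs
SP-same and PP vs SP-same uses a seeded permutation test in which the
spread/peak measure-type labels are exchanged independently within each
region (columns z-scored first; 10 000 permutations by default). A
mixed-design ANOVA over correlation types was considered and set aside: its
random-effects structure (regions nested in networks, correlated correlation
estimates) is not identifiable from the summary quantities, whereas the
exchange null states exactly the hypothesis of interest — that measure type
carries no information beyond region and network.

## Synthetic cohorts

`synth.generate_cohort` emulates the statistical structure the method
assumes: isotropic Gaussian bumps (signed amplitude A in %, width σ in mm)
at nominal ROI centers, per-subject center jitter (SD τ mm per axis, drawn
once per subject so runs share the subject's anatomy), per-subject A and σ
drawn around group means, and i.i.d. Gaussian voxel noise per run (a
per-group noise SD can override the cohort default so that amplitude-scaled
noise keeps relative noise equal across groups). Deactivation ROIs simply
carry negative A; one signed volume is written per run and the negative
contrast is its negation. ROI masks are fixed spheres around nominal
centers; the brain mask is a box covering every bump (center ± 2σ) with a
10-mm margin. Everything derives from one explicitly seeded generator, so
cohorts are bit-reproducible.

The default study emulates an aging working-memory cohort: 14 younger vs 28
older subjects, five runs, two task-positive ROIs (A = 1.57 vs 2.20 %,
σ = 5 vs 6 mm for young vs old) and two task-negative ROIs (A = −1.25 vs
−1.35 %, σ = 6 vs 5 mm), τ = 2 mm, noise SD 0.15 %, between-subject SDs
0.25 % (amplitude) and 0.5 mm (width). These encode the dissociation of
interest — older adults activate more strongly and more broadly but
deactivate more focally — at percent-signal-change magnitudes typical of
3-mm-sphere measures.

What the generator does **not** emulate: spatially correlated (smoothed)
noise, anatomical boundaries and cortical folding, network-level covariance
between regional parameters, hemodynamic time-series structure, or
inter-regional distance heterogeneity. Passing tests therefore demonstrate
that the estimator recovers known width/amplitude/jitter structure under
clean radial geometry and white noise — not that it is robust to
registration error or physiological noise in real data.

## Problem sizes and numerical choices

Replicate simulations (width-contrast recovery, null calibration,
dispersion-vs-jitter) use a single-ROI 17³ grid at 3 mm with one run per
subject — the smallest geometry in which all 3–10-mm spheres plus a 10-mm
brain margin fit — keeping hundreds of replicates cheap while preserving the
cohort sizes (14 vs 28) of the study design. The full-study demonstration
uses the 40³ default grid with four ROIs and five runs. Degenerate inputs
are handled explicitly rather than propagated: constant shell profiles give
slope 0 with an undefined fit correlation (NaN), d50 is NaN whenever the
fitted curve never crosses 0.5, empty ROI∩brain intersections and non-finite
voxels raise or are masked with a warning, and jitter draws that would push
a bump center within 10 mm of a grid face are redrawn (bounded retries).

## Known limitations

* The 1/r² slope is an ordinal, not metric, width estimate; mapping slopes
  back to σ depends on grid resolution and the sampled radius range.
* On coarse grids consecutive radii can add no voxels (3→4 mm at 3-mm
  isotropic), flattening the first shell; the fit absorbs this but very
  coarse grids lower its resolution.
* d50 extrapolates the fitted curve below the smallest sampling radius for
  very focal responses; its absolute value should be interpreted cautiously
  there, its group contrasts less so.
* Peak-sphere amplitude measures (3/5/10 mm) are sphere means, not voxel
  maxima, so they under-report the generative A by the kernel's curvature —
  by design, since that is the quantity practitioners report.
* The shared-variance permutation test conditions on the observed regional
  correlation structure; with few regions per network (here 2–4) its p-value
  resolution is limited.
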