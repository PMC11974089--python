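# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the `dtialps` package. It states nothing the tests or
`scripts/acceptance.py` do not themselves compute.

## Axis convention

RAS+ affines throughout; x = left–right (the perivascular direction of the
medullary veins at the lateral-ventricle level), y = anterior–posterior
(association fibers), z = superior–inferior (projection fibers). This is
the geometric premise of the ALPS method and is enforced in the phantom,
the fitter (scanner-frame diagonals, not eigenvalues) and the index.

## DWI phantom

Single-tensor Stejskal–Tanner forward model per voxel,
`S = S0·exp(−b·gᵀDg)`, on a 64×64×16 grid at 2×2×4 mm (4 mm slices match
the acquisition protocol; the grid is small enough for seconds-scale
tests). Region blocks per hemisphere: a CSF ventricle box (isotropic
3.0×10⁻³ mm²/s), a projection-fiber band (diag 0.6, 0.45, 1.5 ×10⁻³;
long axis z), an association-fiber band (diag 0.6, 1.5, 0.45 ×10⁻³; long
axis y), GM-like background (isotropic 0.8×10⁻³), and optionally a
spherical tumor (isotropic 1.0×10⁻³, radius 6 mm) with an edema shell
(isotropic 1.6×10⁻³, outer radius 12 mm, tumor excluded). With these
defaults the noiseless ALPS index is 0.6/0.45 = 4/3, inside the healthy
range reported for the method.

Glymphatic impairment is modelled by one number per hemisphere: the
perivascular factor α multiplies Dxx inside that hemisphere's fiber bands
(α < 1 ⇒ reduced perivascular-direction diffusivity ⇒ lower index; the
noiseless index is exactly (4/3)α because the denominator diffusivities
are untouched).

Noise is Rician — the magnitude of the complex-Gaussian-perturbed signal,
σ = S0/SNR — which is the standard model for magnitude MR images. `SNR =
None` disables noise; all draws come from one `numpy` generator seeded by
the spec, so reruns are bit-identical.

Gradient schemes place the requested number of directions on a Fibonacci
spiral over the upper hemisphere (antipodal directions are equivalent for
diffusion encoding) and apply a seeded random rotation. Tables are written
in the FSL dialect (one row of b-values; three rows x/y/z of components).

## Tensor fitting

Log-linearized least squares over all volumes for the 7 unknowns
(ln S0 and the 6 tensor components). `wls` (default) performs one
reweighted pass with weights equal to the squared predicted signal, the
standard correction for log-transform heteroscedasticity; one pass keeps
the estimator deterministic and matches common practice. Signals are
floored at 10⁻⁶·S0 before the log. Negative fitted diagonals are kept
(clamping would bias ALPS ratios, which average diagonals over VOIs) and
only eigenvalues are clamped at zero for FA/MD. A rank-deficient design
(fewer than 6 independent directions) raises an error listing the
directions. On noiseless phantoms the fit reproduces the generating
tensors to ≤10⁻⁹ mm²/s (the log-linear model is exact without noise); at
SNR 30 the median component error over fiber voxels is below 5×10⁻⁵ mm²/s.

## VOIs and the index

A "4-voxel cubic VOI" cannot tile a cube; the package reads it literally
as a 2×2 in-plane square on one designated slice (edge configurable,
minimum 4 voxels). Boxes are 0-based and half-open everywhere. On
phantoms, VOIs are placed automatically at the fiber-band centroids of the
label mask; on real data they are reader-supplied JSON. Multiple readers'
VOI sets are combined by averaging the resulting indices (the combination
rule used when two radiologists read each case is not standardized; the
mean is the symmetric choice). Per-hemisphere indices are labelled
tumor-side / contralateral (patients) or left / right (controls); the
subject-level value is the arithmetic mean of the two hemispheres.

## Volumetrics

Volume of a label = voxel count × |det| of the 3×3 affine block, in cm³.
Segmentation itself (tissue classification, manual tumor/edema outlines)
is an input, not re-implemented. PTBE is defined exclusive of the tumor
label; an overlap in user data warns and excludes. Voxelized sphere
volumes agree with (4/3)πr³ to within one voxel shell, and volumes are
invariant under axis permutation and additive over disjoint labels.
`synthetic_volume_mask` materializes a mask realizing requested volumes to
the nearest voxel (0.016 cm³ at 2×2×4 mm) so simulated subjects can be
routed through the same code path as image-derived masks.

## Cohort simulator

The generator's defaults are the study conditions: 112 glioma (35 LGG /
77 HGG) and 56 controls; bilateral-mean ALPS Gaussian 1.266 ± 0.258
(glioma) and 1.395 ± 0.174 (controls); CSF volume Gaussian 174.53 ± 34.89
and 154.25 ± 20.89 cm³; tumor and PTBE volumes and Ki-67 log-normal,
parameterized in closed form from the printed median (IQR) — 29.77
(36.79), 37.48 (65.11) cm³ and 20.0 (25.0)% respectively (for q =
IQR/median, σ = ln((q+√(q²+4))/2)/z₀.₇₅, μ = ln median). Categorical
structure (sex 49F/63M vs 27F/29M, tumor side 60/42/10, IDH 36/76, type
44/14/54) is assigned by exact-count permutation; glioblastomas are always
high-grade, the astro/oligo pool fills the remaining slots, and IDH is
assigned independently of grade (the grade×IDH cross-table is not
published).

**Paired hemispheres.** The within-subject contralateral-minus-tumor-side
difference is N(0.066, 0.292²); sides are mean ∓ δ/2 so the bilateral
mean is exactly their average. 0.292 is the unique difference-SD
consistent with all three published SDs (0.297/0.296 per side, 0.258 for
the mean) and implies an inter-hemisphere correlation of 0.51. A direct
consequence, computable by noncentral-t: the paired t test at n = 112 has
power 0.66 at α = 0.05 under these parameters, so a single cohort detects
the hemispheric shift about two times in three.

**Copula.** ALPS, tumor volume, PTBE volume and CSF volume share a
Gaussian copula with rank-correlation targets −0.353 (ALPS↔tumor), −0.266
(ALPS↔PTBE), +0.427 (tumor↔PTBE); latent Pearson correlations are
2·sin(πρₛ/6). CSF's cross-correlations default to 0 (not published).
Non-positive-definite matrices are rejected naming the offending
eigenvalue. Spearman targets are recovered within ±0.05 at n = 10,000.

**Grade effect.** Patient ALPS follows a linear structural model on
standardized grade (LGG=0/HGG=1), age, and Olig-2 immunopositivity with
standardized coefficients (−0.244, −0.20, −0.22) and predictor
correlations (grade↔age −0.142, grade↔Olig-2 +0.029, age↔Olig-2 +0.285).
These six numbers are the exact solution making the population univariate
correlations equal −0.222 / −0.228 / −0.284, the population multivariate
grade coefficient −0.244, and the implied LGG/HGG means 1.351 / 1.227 —
i.e. the full set of published regression-adjacent quantities is
consistent with one linear model, with the unpublished predictor
correlations as the free parameters. The residual keeps total ALPS
variance at the configured SD. Olig-2 is recorded on a linear % scale
(50 ± 20, clipped to [0, 100]) so regression coefficients are not
attenuated by a nonlinear transform.

What the generator does *not* emulate: per-grade tumor/PTBE volume
distributions (volumes link to grade only through ALPS and the copula, so
the configured copula is exactly recoverable), any grade×IDH association,
spatial/imaging-level variation behind each subject's index (subjects are
drawn at the index level; the imaging chain is validated separately on
phantoms), and longitudinal structure. Passing tests therefore demonstrate
parameter-recovery and internal consistency of the analysis chain, not
fidelity to any real patient population.

## Statistics

Parametric iff Shapiro–Wilk p ≥ 0.05 in every group; constant-valued
groups go nonparametric (normality untestable, Gaussian model
degenerate). Two groups: pooled-variance Student t (SPSS-style default;
Welch by flag) or Wilcoxon rank-sum as a tie-corrected normal
approximation without continuity correction. k ≥ 3: one-way ANOVA with
LSD post hoc (pairwise t on the pooled MSE, deliberately unadjusted —
that is the definition of LSD) or Kruskal–Wallis with Dunn z-tests, whose
p-values are reported both raw and Holm-adjusted (Holm recommended; the
choice of adjustment for Dunn is a genuine free choice). Chi-square is
Pearson without continuity correction; Spearman uses average ranks and
the two-tailed t approximation, pairwise-complete. The regression screen
z-scores outcome and predictors for standardized β, enters univariate
p < 0.05 candidates into one multivariable OLS, and rejects collinear
designs (condition number > 10⁸). All tests are two-tailed; every result
records its effective n. Each statistic is checked against an independent
brute-force implementation on ≤10-row tables to 10⁻⁸, and the gated
two-group path holds its null rejection rate within [0.035, 0.065] over
2000 replicates.

Two-stage screens conditionally bias reported coefficients: averaging the
multivariate grade β only over cohorts where grade passes the univariate
gate (its power is ≈0.65 at n = 112) yields ≈ −0.27 rather than the
population −0.244 — the familiar winner's-curse inflation, visible in the
acceptance output and left uncorrected because it is a property of the
published procedure itself.

## Pipeline and formats

`run_pipeline` executes phantom → fit → ALPS → volumes → stats, writes
every intermediate, and ends with a manifest of SHA-256 hashes; reruns
with the same config and seed are byte-identical (timings live in a
separate log). NIfTI artifacts are written uncompressed (`.nii`) so the
hashes depend only on header and voxel data; readers accept `.nii.gz`
equally. Cohorts are TSV with header; VOIs and configs are JSON/YAML.
Exit codes: 0 success, 2 config error, 3 data error.

## Problem sizes

Defaults were chosen so each piece runs in seconds on one CPU: the
64×64×16×49 phantom fits in ~2 s; the replicate analyses use 200 cohorts
of 112/56 subjects; the null-calibration checks use 500–2000 replicates
of ≤100 observations.
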