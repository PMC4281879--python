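# Methods

This note documents the models, numerical choices and limitations of
`handsym`: what each analysis computes, what the synthetic cohort
generator does and does not emulate, and where the design was genuinely
open.

## Image model and left–right geometry

All images live on a shared voxel lattice (`ImageGrid`). Axis 0 is
left–right with the mid-sagittal plane between columns (nx−1)//2 and
nx//2, axis 2 is inferior–superior (the slice axis of the slice-wise
laterality analysis). Mirror flipping is a pure index reversal along
axis 0 — exact, involutive and lossless — and no affine handling or
resampling is performed: the package operates downstream of spatial
normalisation, so images that are combined must already share a grid,
and grid mismatches are hard errors rather than silent resampling.
Subjects whose affected side is opposite to the cohort convention are
stored mirror-flipped by the generator and un-flipped by the pipeline,
reproducing the common practice of aligning the hemisphere contralateral
to the missing (or non-dominant) hand across subjects. In the canonical
orientation used throughout, the *left* hemisphere is contralateral to
the intact/dominant hand, and the right-hemisphere hand ROI (the mirror
of the intact-hand ROI) is the missing-hand territory used as the
connectivity seed.

## Structural analysis

Fractional anisotropy can be computed from tensor eigenvalues with the
standard formula FA = sqrt(3/2)·‖λ−λ̄‖/‖λ‖; the pipeline otherwise
consumes FA volumes directly. Tract summaries follow the white-matter
skeleton convention: only skeleton voxels with FA strictly above a floor
(default 0.2) enter the mean, so edge voxels with partial-volume
contamination are excluded. The floor is a parameter of the extraction
rather than being baked into the masks, which keeps synthetic masks
simple; the same floor is applied in the slice-wise profile for
consistency. Slices where either side has no voxel above the floor are
excluded from the profile (the laterality index is undefined there), not
zero-filled.

The laterality index LI = (A−B)/(A+B) is bounded in [−1, 1] for
nonnegative inputs, antisymmetric, zero at symmetry, and undefined when
A+B = 0 (an error). Which side counts as "intact" is metadata carried by
the subject record, never inferred from the data.

## Randomisation inference

All Monte-Carlo tests share the same conventions:

* p = (1 + b)/(n_iter + 1), where b counts null draws at least as
  extreme as the observed statistic. p is never zero and the test is
  exact-level under exchangeability.
* Ties count as extreme (conservative). Extremity comparisons use a
  relative tolerance of 1e−12 so that relabellings that are exact ties
  in real arithmetic (e.g. the identity labelling) are not dropped by
  floating-point round-off in the recomputed statistic.
* Two-sided tests compare |statistic|; one-sided tests compare the
  signed statistic.
* Every result carries its seed and iteration count; identical seeds
  give bit-identical results.

**Group-size equating.** With 14 patients and 23 controls, each null
iteration first draws a fresh random subsample of 14 controls, pools
them with the patients and shuffles the 28 labels; the observed
statistic is the difference of the *full* group means. This size-equating scheme is the procedure the pipeline is built
around, but it makes the test conservative: the null
statistic has standard deviation σ·sqrt(2/14) while the observed
difference has σ·sqrt(1/14+1/23), so the true type-I error at nominal
0.05 is ≈ 0.025 (measured over 20,000 null simulations). Users who need
exact calibration should either skip the subsampling (the plain
permutation test is exact for unequal groups) or studentise; the default keeps the
size-equated null, and its conservativeness is a documented property,
not a bug.

**Exhaustive oracle.** For instances with ≤ 1e5 label assignments, an
exhaustive enumeration (no add-one correction) provides the exact
permutation p; the Monte-Carlo tests converge to it within binomial
error, which the test suite asserts.

**Correlation test.** The null shuffles one vector against the other
unshuffled one. Permuting a vector leaves its norm unchanged, so the
null correlations are computed with a single matrix product per batch.

## TFCE on slice profiles

The slice-wise group statistic (pooled two-sample t per slice, group 1
minus group 2) is enhanced with 1-D threshold-free cluster enhancement:
TFCE(p) = Σ_{h=dh..stat(p)} extent(p,h)^E · h^H · dh, where extent(p,h)
is the length of the contiguous run of slices with stat ≥ h containing
p. Negative statistics contribute nothing; the test is one-tailed for
higher values in group 1 (the direction of interest: higher laterality
in one-handers). Defaults E = 1, H = 2, dh = 0.1 — the usual convention
for skeletonised, effectively one-dimensional data — are exposed in
`TfceParams`. The implementation is vectorised over permutations (run
extents via cumulative maxima/minima over the threshold mask) and is
validated against the closed form for a constant block,
L^E·h0^(H+1)/(H+1), at small dh. Familywise correction uses the maximum
enhanced value across slices per permutation; permutations apply the
same control-subsampling as the tract-level test. Slices with zero
pooled variance get t = 0 rather than NaN, so degenerate profiles pass
through without poisoning the map.

An alternative observed statistic (group difference of mean LI rather
than t) would weight slices by their variance differently; the
studentised form was chosen because it is scale-free across slices.

## Resting-state preprocessing

Per subject, in order:

1. **High-pass, 150 s.** Regression on a discrete-cosine drift basis
   with frequencies below 1/150 Hz (k < 2·T·tr/cutoff; 4 regressors for
   the default 128 × 2.41 s scan), the series mean re-added. This is a
   deterministic, closed-form filter; it differs from running-line
   filters used by some packages, which is acceptable here because only
   frequencies far from the band edge carry signal in the generative
   model.
2. **Confound regression.** Least squares on [intercept, confounds],
   with the confound courses themselves high-passed with the *same*
   basis first. Sequential projections on non-orthogonal bases otherwise
   reintroduce what the first projection removed: regressing raw slow
   confounds from filtered data adds drift back through the confound
   fit (measured on synthetic data as an upward bias of ≈ 0.15 in
   inter-hemispheric r). Filtering the regressors makes the two
   projections consistent; this is standard practice in modern
   connectivity pipelines. Rank-deficient confound matrices are rejected
   with the collinear columns named.
3. **Smoothing.** Separable Gaussian, FWHM in mm converted to voxel
   sigmas via the voxel size (σ = FWHM/2.3548), reflect boundary
   handling (preserves constants), frame-wise for 4-D data, applied
   after the temporal cleaning, never before it.

Pearson correlations are Fisher-z transformed with |r| clamped at
0.999999 (configurable) so z stays finite at machine-precision perfect
correlations. Zero-variance voxels are flagged NaN ("missing") and
excluded from group statistics and from the FDR count; a constant seed
mean time-course is an error. The group disparity map uses the classic
pooled-variance two-sample t (not Welch), matching the era's default;
group-level FDR (Benjamini–Hochberg step-up, q = 0.05) runs over brain
voxels only. BH-FDR delegates to statsmodels and is verified against a
literal implementation of the step-up rule in the tests.

Whether the seed time-course should come from smoothed or unsmoothed
data is a free choice; both seed and target series are taken
post-smoothing here.

## Behaviour coupling

Voxel-wise: Pearson r across patients between connectivity z and usage
score, with the one-tailed positive p from t = r·sqrt(n−2)/sqrt(1−r²) on
n−2 df, then FDR. (The alternative reading — a one-sample t test over
Fisher-transformed per-subject coefficients — is not well defined for a
single cross-subject r per voxel, so the standard r-to-t transform is
used.) ROI-level: r between mean connectivity under the intact-hand ROI
and usage, with a one-tailed permutation p from shuffling connectivity
against the unshuffled scores. The structural LI–usage correlation is
reported with both one-sided permutation p values, since its direction
convention is not fixed by the design; the directional hypothesis
(more residual-arm use, less asymmetry) corresponds to the negative
tail.

## Synthetic cohort generator

The generator's defaults are the study conditions: 14 one-handers vs 23
controls; grid 32 × 32 × 24 at 3 mm (a desk-scale stand-in for a
standard-space grid — the statistics are grid-size agnostic); 128
volumes at TR 2.41 s; 4 of 14 patients and 8 of 23 controls stored
flipped.

**BOLD.** Two unit-variance latent Gaussian sources with correlation ρ
drive the left and right hand ROIs. Every voxel adds white Gaussian
noise (SD 1.0), a baseline of 100, scanner drift (linear ramp plus a
random mix of the two slowest cosine harmonics of the scan — periods
2·T·tr ≈ 617 s and T·tr ≈ 308 s, genuinely below the 150 s cutoff so the
high-pass can remove them), and eight nuisance courses (six AR(1)
pseudo-motion parameters, an AR(1) "ventricle" and "white-matter"
course) with voxel-specific gains ~ N(1, 0.3). The recorded confound
table contains the true nuisance courses, so regression can remove them
exactly; drift is deliberately *not* recorded and must be handled by the
filter. Controls have ρ = 0.6; patients follow ρ_i = ρ0 + b·usage_i
(ρ0 = 0.1, usage uniform on [0, 1], clipped to [0, 0.95]).

**Coupling-law calibration.** The default slope b is solved so that the
population correlation between usage and *measured* Fisher-z
connectivity equals the configured target (0.66, at n = 14). The
measurement model behind the solver: the smoothed ROI mean retains
signal fraction W_in = Σ_ROI w (with w = smooth(ROI indicator)/|ROI|)
and passes noise variance σ²·Σw², giving attenuation
a = 1/(1 + σ²Σw²/(s²W_in²)) of the latent ρ; the per-subject z estimate
adds noise of variance 1/(T_eff − 3) with T_eff the frames left after
the intercept, 8 confounds and 4 drift regressors. b is found by
root-finding on the resulting population correlation (quadrature over
the usage distribution). Measured recovery over 200 replicate cohorts:
mean sample r ≈ 0.67. For studies of a configured group gap Δρ = 0.3 the
slope is set to 0.4 (patient mean coupling 0.3 vs control 0.6).

**FA.** Tract-skeleton voxels draw FA ~ N(μ_side,group + δ_subject,side,
0.08) with δ ~ N(0, 0.02); defaults μ = 0.50/0.44 (patients,
intact/residual) and 0.50/0.48 (controls, dominant/non-dominant), i.e. a
mean LI of ≈ 0.064 vs ≈ 0.020 — about 1.4 within-group SDs apart, which
the randomisation test detects in ≈ 95 % of replicate cohorts.
Background voxels draw N(0.12, 0.02), safely below the skeleton floor.
An optional "bump" (`fa_bump_slices`, `fa_bump_delta`) deepens the
residual-side deficit on a z-slice range, for exercising the TFCE
localisation.

**Determinism.** One master seed is split with numpy's `SeedSequence`:
the first child stream draws cohort-level quantities (usage scores, flip
assignment), then one child stream per subject draws that subject's
images. Flip flags are applied by actually flipping the stored arrays
*after* the draw, so a cohort generated with different flip settings but
the same master seed contains the same underlying images — the basis of
the pipeline's flip-invariance test.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: haemodynamic response shape and
autocorrelated physiological noise (sources and noise are temporally
white); spatial noise correlations beyond those induced by smoothing;
anatomy-realistic tract geometry, registration error, or atlas
uncertainty; non-Gaussian FA distributions; motion that actually moves
the image (motion exists only as nuisance regressors). The pipeline's
calibration and power results are statements about this generative
model at the configured dials, not estimates of any real cohort's
effect sizes, which would require real imaging data.

## Replicate studies (calibration / power / recovery)

The operating-characteristic studies in `handsym.studies` run hundreds
of replicate cohorts. For the functional replicates only the two
smoothed ROI mean time-courses matter, so the replicates use an exact
reduction: because smoothing is linear and symmetric, the ROI mean of
the smoothed image equals the w-weighted sum of the unsmoothed voxel
series (w = smooth(indicator)/|ROI|), and the temporal projections
(high-pass, confound regression) are one common linear operator for all
series and therefore commute with the weighting. Replicates simulate
the voxel field only on the finite support of w and reduce immediately.
This is exact for ROIs far enough from the grid boundary that the
truncated kernel never reaches the edge (the default geometry keeps a
full kernel radius of clearance); the test suite verifies the identity
against the full image pipeline to ~1e−10. Problem sizes used by the
acceptance studies — 1,000 null simulations at 999 iterations for the
calibration checks, 100 replicate cohorts for the power checks, 200 for
behaviour recovery, and a 6+8-subject cohort for the determinism and
flip-invariance checks — were chosen to give Monte-Carlo standard errors
comfortably inside the asserted bands on a single CPU.

## Known limitations

* The subsampled group test is conservative by construction (see above).
* The DCT high-pass and the reflect-boundary Gaussian differ in detail
  from FSL's implementations; parameters match, algorithms are
  documented here.
* The TFCE slice test is one-tailed (group 1 > group 2); a two-tailed
  variant would enhance |t| or combine two one-tailed runs.
* NIfTI volumes are written as float32; statistics recomputed from disk
  agree with in-memory values to storage precision (~1e−7), not exactly.
* `bh_fdr` assumes independent or positively dependent tests (the
  standard BH condition); no Benjamini–Yekutieli option is provided.
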