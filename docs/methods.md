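# Methods

This note documents the models and procedures implemented in `avafp`, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not establish about real data.

## Avalanche extraction

Each region of a recording (n_regions × n_samples, default 68 regions in a
fixed Desikan–Killiany-style order, 250 Hz) is z-scored against its own
temporal mean and standard deviation.  The population SD (1/N) is the
default; the sample convention is available via `ddof=1` and the difference
is negligible at the ≥ 25,000-sample recordings the pipeline targets.  A
region with zero variance is an error naming the ROI, not a silent NaN.

Binarization marks a region active when |Z| strictly exceeds the threshold
(default 2.8 SD; 2.6 and 3.0 are the conventional robustness settings).
Both excursion signs count, so the raster is invariant to signal negation.
Avalanches are maximal runs of bins with ≥ 1 active region.  Runs touching
the recording edge are boundary-truncated; they are kept by default (no
principled exclusion rule exists for resting-state data) and can be dropped
with a flag.

The branching ratio is estimated per avalanche as the geometric mean of
successive event-count ratios, σᵢ = (∏ n(j+1)/n(j))^(1/(Nbin−1)), and pooled
as the geometric mean of σᵢ over avalanches with ≥ 2 bins.  Single-bin
avalanches carry no ratio; they are excluded from σ but still count toward
avalanche totals and ATMs.  The implementation aggregates in the log domain,
which is algebraically identical to the product form but immune to over- and
underflow at large avalanche counts.  Note the estimator telescopes to
(n_last/n_first)^(1/(Nbin−1)) and conditions on survival, which biases it
slightly above 1 for a critical process seeded with one unit; the effect is
within ~0.07 at 68-region capacity and is part of what the acceptance
simulation measures, not something the estimator corrects.

Bin-scale selection computes σ at scales 1, 2, 3 (4/8/12 ms) and keeps the
scale with σ closest to 1, ties toward the smaller scale.  The per-recording
operation (`select_scale`) applies this to one raster; the cohort pipeline
instead pools the per-recording σ values geometrically and picks **one**
scale for the whole dataset (`PipelineConfig.scale_selection="cohort"`, the
default).  Mixing scales across sessions of the same subject would inject
bin-width differences into test-retest similarity, and a single dataset-wide
choice matches how such analyses are reported in practice; per-recording
selection remains available as `"recording"`, and an integer forces a scale.

## Avalanche transition matrices

Within one avalanche, entry (i, j) is the conditional frequency that region
j is active δ bins after region i, with the source window running over bins
0 … Nbin−1−δ.  Rows whose region never fires in the source window are
zero-filled (probability of an unobserved condition).  δ defaults to one bin
— the smallest realizable lag at 250 Hz — and a positive lag is what guards
against zero-lag field spread: two regions that are only ever simultaneously
active contribute nothing.  Avalanches shorter than the lag carry no
transition and are excluded from the recording average by default
(`include_short` adds their zero matrices to the denominator).  The
recording-level ATM is the plain mean over avalanches, then symmetrized as
(M + Mᵀ)/2.  Diagonal entries (self-transitions) are computed but excluded
from edge vectorization, which takes the strict upper triangle in row-major
ROI order (2278 edges at 68 regions).

## Fingerprint indices

The identifiability matrix holds Pearson correlations between test-session
edge vectors (rows) and retest-session edge vectors (columns).  Iself is the
diagonal; Iothers for subject i averages the off-diagonal entries of row i
*and* column i — the session-symmetric reading of "off-diagonal elements" —
with a row-only option; Idiff = Iself − Iothers exactly.  Indices are
reported on the correlation scale (not ×100); every downstream statistic is
invariant to that choice.  Fingerprint indices are computed within each
display group's own identifiability matrix (HC, UTLE-L, UTLE-R, BTLE); for
the three-group statistics the unilateral subgroups are pooled afterwards.

Iclinical uses as reference the element-wise mean over controls of each
control's session-averaged ATM, and averages the patient's test- and
retest-edge correlations with that reference.  Which of the patient's
sessions enters the published quantity is underdetermined by its usual
verbal definition; `sessions={"both","test","retest","average"}` exposes all
readings, with `"both"` the default — at the generator's noise levels the
four differ by far less than between-subject spread.

## Edge stability

Per edge, subjects × 2 sessions form a one-way ANOVA layout; the default
reliability measure is the one-way random-effects ICC(1,1) =
(MSB − MSW)/(MSB + MSW) at k = 2, with two-way variants (ICC(2,1) absolute
agreement, ICC(3,1) consistency) as options.  Edges with zero mean squares
are flagged undefined (NaN) rather than forced to a value.  Node stability
averages the defined ICCs incident to a region; the group mean averages the
defined upper-triangle edges; the conventional display cut keeps edges with
ICC ≥ 0.65.

ICC is a group-level, per-edge quantity, so "average stability compared
between groups" is not a per-participant statistic.  The implemented group
comparison permutes subject labels between two groups and recomputes the
difference of group-mean ICC (10,000 permutations by default); this is the
one place where the package substitutes a well-defined test for a published
description that does not pin one down, and it is flagged here deliberately.

## Inferential layer

The omnibus test on a per-subject scalar is a permutation ANOVA: the
statistic is the classical one-way F (identical to the PERMANOVA pseudo-F
under Euclidean distance on scalars), the null is label permutation, and
p = (1 + #{F* ≥ F})/(1 + n_perm) — the add-one convention, so p ≥
1/(n_perm+1).  Post-hoc tests permute two-group labels with |Δmean| as the
statistic.  FDR is Benjamini–Hochberg.  The correction families are: the
three fingerprint omnibus tests as one family; each index's post-hoc trio as
a family; and the clinical correlations corrected across the
neuropsychological battery.  Family membership is a reporting convention,
not a mathematical necessity, and is documented here because it changes
which q-values clear 0.05.

The clinical prediction model is ordinary least squares on z-scored
predictors (Hemisphere, Gender, Age, Iclinical; binary predictors are
z-scored like continuous ones so betas share a scale).  Coefficients, their
two-sided t p-values and the overall F come from the full-sample fit — a
cross-validation scheme averages thousands of coefficient sets and cannot
report "the" beta.  Predictive performance comes from nested k-fold
cross-validation (k = 5): per iteration, a random outer split; within each
outer-training set an inner 5-fold split fits OLS on every inner-training
set and the coefficient set with the lowest inner-validation NRMSE predicts
the outer test fold; pooled out-of-fold predictions give per-iteration
NRMSE, R² and Spearman, averaged over 4000 iterations by default.  NRMSE is
RMSE divided by the observed response range (the most common "percentage"
reading); CV R² is 1 − SSE/SST on pooled predictions, with the
squared-correlation variant as an option.  A rank-deficient design is an
error that names the collinear columns.

## Synthetic cohorts

The generator emulates the structure of a two-session resting-state study of
temporal-lobe epilepsy: 35 controls, 31 left and 17 right unilateral
patients, 20 bilateral patients; 68 regions at 250 Hz; two 180-s sessions
per subject, of which the analysis uses a random 100-s window (180 s
reproduces the whole-trial variant).

Each subject owns a latent propagation kernel derived from one global
template T and a subject-specific random kernel R (both sparse, 15% density,
U(0,1) entries): every entry of K_s comes from R with probability w_s and
from T otherwise.  The per-entry swap — rather than a convex value blend —
keeps the kernel's sparsity and entry distribution identical at every w, so
the idiosyncrasy knob moves within-group similarity (Iothers) without
changing ATM estimation noise and thereby leaking into Iself; value blending
demonstrably inverted the planted Iself ordering.  w_s is drawn as
N(w_g, 0.1) clipped to [0,1]; without subject-level spread the similarity to
the control template is nearly constant within a group and a clinical score
coupled to it could not be recovered by correlation.  Session kernels add
zero-mean Gaussian noise of SD eps_g to the kernel support only (dense
jitter plus clipping would hand every sparse kernel a large diffuse mass).

Group defaults: w = 0.20 (HC), 0.50 (UTLE-L/R), 0.75 (BTLE); eps = 0.35
(HC), 0.18 (UTLE-L/R), 0.07 (BTLE).  Controls are most flexible (high
session jitter, low idiosyncrasy), bilateral patients most stereotyped and
idiosyncratic — the qualitative group pattern of the motivating literature.

Dynamics: unit-variance white Gaussian background plus avalanche pulse
trains.  Initiations arrive at Poisson times (5/s); each seeds one uniformly
random region; propagation is bin-to-bin with the kernel probabilities after
rescaling the kernel so the mean expected offspring equals the branching
parameter m (default 1.0, near-critical); per-row offspring still varies, so
avalanche sizes are heavy-tailed, with a 2-s duration cap.  Active
(region, bin) positions get a ±pulse of 6 noise-SDs with random sign.
Concurrent avalanches are disallowed (initiations during an ongoing one are
dropped) so planted boundaries stay unambiguous.

Patients receive a synthetic figure-recall score
a + b·corr(K_s, T) + N(0, s), defaults a = −15, b = 60, s = 4, giving a
score distribution (≈ 10 ± 10 points) and a planted similarity-score
correlation around 0.8, which the pipeline recovers at ≈ 0.4–0.7 after ATM
estimation noise.  The remaining battery entries (digit span, Corsi, copy,
RAVLT, TMT) are drawn at published-scale means and SDs, uncoupled, and exist
to exercise the FDR family.  Ages are drawn near 35 ± 9 (controls) and
41 ± 17 (patients); hemisphere is L/R for unilateral patients and B for
bilateral; all patients have complete scores.

What the generator does *not* emulate: 1/f spectral structure and temporal
autocorrelation of source-reconstructed EEG (the background is white, so
threshold crossings are independent across bins and many detected
"avalanches" are noise runs — the planted kernel signal must survive that
dilution, which is itself a useful stress test); spatial cortical geometry
and volume conduction; interictal discharges; realistic inter-regional delay
structure.  Passing tests therefore establish that the pipeline recovers
planted propagation structure, stereotypy ordering and clinical coupling
under honest estimation noise — not that real EEG satisfies those models.

## Problem sizes and numerical choices

The end-to-end acceptance sweep runs 20 full-size cohorts (206 recordings
each) with 2,000 permutations per omnibus test; permutation counts only set
p-value resolution (minimum 5×10⁻⁴ here), not the statistic.  The regression
criterion runs 200 CV iterations; iteration count only narrows the
across-iteration averaging noise (SD ∝ 1/√n_iter, verified in tests).  The
Galton–Watson acceptance simulation uses 25,000 seeded avalanches (≥ 10,000
multi-bin).  Edge-case conventions: strict inequality at the binarization
threshold; trailing partial windows dropped in coarse-graining; ties in
scale selection go to the smaller scale; undefined ICC edges are NaN and
excluded from means; permutation p-values can never be zero.  All
randomness flows from numpy SeedSequence spawning (one child stream per
subject, per stage), so every cohort and every pipeline run is bit-for-bit
reproducible from its seed; the compiled propagation loop uses its own
seeded generator derived from the same stream.

## Known limitations

- The branching-ratio estimator's survivorship bias (above) means σ → 1 is
  assessed with ±0.1 tolerance, not as an unbiased point estimate.
- White background noise makes the detected avalanche count much larger than
  the planted one; avalanche-count statistics from the generator should not
  be compared with published empirical counts.
- The group comparison of mean edge stability is a package-defined
  permutation test (see above), not a reconstruction of a published
  per-participant procedure.
- Published effect sizes from patient EEG (F statistics, ICC group means,
  r = 0.48, R² = 0.218) depend on non-shareable data; the package reproduces
  the *logic* and direction of those findings on synthetic cohorts, and its
  tests assert exactly that.
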