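# Methods

This note documents the statistical procedures implemented in `cytopls`,
the choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Replicate cleaning

Multiplex bead-array panels report, per well, a fluorescence (or
curve-interpolated concentration) value and a bead count. Cleaning proceeds
in three stages, each fully audited:

1. **Bead-count review.** Wells with fewer than `min_beads` beads (default
   35, a common platform acceptance threshold; no universal standard exists)
   are flagged. The default is flag-only; `strict` mode removes them before
   outlier detection. Flag-only is the conservative default because a low
   bead count degrades precision but does not by itself invalidate a well.
2. **Triplicate outlier designation.** Within each technical triplicate,
   replicate *x* with companions *y, z* is designated iff
   `min(|x−y|, |x−z|) > 2·|y−z|`, with strict inequality (ties are
   retained) and at most one designation per triplicate — "the distance
   between the other two" is undefined once only a pair remains, so the rule
   is never iterated and never applied to duplicates. The rule is covariant
   under positive affine maps of the triplicate, so it behaves identically
   on fluorescence or interpolated concentrations; it is applied to
   whichever scale the user supplies, untransformed.
3. **Averaging.** The cleaned value is the arithmetic mean of retained
   replicates; a cell losing all replicates is reported missing, never
   imputed. The exclusion log is sufficient to reconstruct the raw replicate
   multiset from the cleaned matrix.

Before modeling, analytes are dropped unless strictly more than a fraction
(default 25%) of samples have non-zero values; dropped analytes are logged.

**A property worth knowing:** the gap-ratio rule is scale-free, so on
triplicates whose three values are i.i.d. noise it fires with a constant
probability — about 0.64 for Gaussian or log-normal replicate noise (the
largest order-statistic gap exceeds twice the smaller one most of the time
for three i.i.d. draws; the acceptance suite measures this directly). The
rule therefore behaves as a *variance-trimming* heuristic on noisy
triplicates, not as a rare-event detector: on synthetic panels with i.i.d.
5%-CV replicate noise it removes roughly one replicate in five overall
while still recalling ≥ 99% of planted 10-SD gross outliers with the
correct replicate identified essentially always. Real plate data can behave
very differently (tight, discretized, or systematically drifting
triplicates fire far less often); the trimming rate on a given dataset is
always reported as `fraction_excluded` so users can see it.

## PLS models

Predictors are mean-centered and unit-variance scaled (Z-scored, sample SD
with n−1). Held-out rows are always transformed with training-fold
constants; nothing from a held-out sample ever touches the scaling.

Single-response PLS is fit by NIPALS with X-deflation (weight-vector
convergence tolerance 1e−12, 500-iteration cap — immediate convergence for
a single response column). Discriminant models encode the two classes as
+1/−1 on one response column and classify by the sign of the prediction; an
exact-zero prediction is assigned to the larger training class (first
sorted label at equal counts). Requesting more components than `rank(X)` is
an error. Fitted weight vectors are orthonormal and score vectors mutually
orthogonal, which the test suite asserts.

`SS_l(Y)`, the response variation attributed to component *l*, is the
reduction in the response residual sum of squares during sequential fitting
(`c_l² tᵀt`, identical to `(t_lᵀy)²/(t_lᵀt_l)` while scores are
orthogonal).

### Orthogonalization on LV1

After fitting, the latent basis is rotated so that LV1 scores have maximal
covariance with the (encoded) response among all rotations of the fitted
subspace: the first rotated direction is `r₁ ∝ Tᵀy`, completed to an
orthonormal basis by Householder QR. Weights, loadings, scores and response
loadings rotate together, so the prediction operator — and hence every
fitted and held-out prediction — is unchanged; the suite checks this to
1e−8 and checks LV1 optimality against a 721-angle brute-force rotation
grid. The rotated components beyond LV1 are exactly uncorrelated with the
response (an O-PLS-style predictive/orthogonal split), so after rotation
the per-LV response attribution places all explained variation on LV1.
Rotated score vectors are no longer mutually orthogonal in general; the
orthogonality invariant applies to freshly fitted models. This post-fit
rotation was chosen over pre-filtering the predictors because it leaves the
fitted model's predictions bit-identical while making scores plots and VIP
reflect the response-aligned direction.

### VIP

`VIP_j = sqrt(m Σ_l w_lj² SS_l(Y) / Σ_l SS_l(Y))`. Because weight columns
have unit norm, the mean of squared VIP scores is exactly 1 for any m and L
(fitted or orthogonalized), so VIP > 1 is an above-average contribution.
For an orthogonalized model the VIP consequently ranks analytes by their
weight on the response-aligned LV1, which is the ranking the pipeline
reports — it is markedly more stable across seeds than raw multi-LV VIP on
small n.

## Validation

Cross-validation is *repeated stratified random subsampling*: each repeat
holds out a random third of the samples (per class in discriminant mode, so
no fold loses a class), refits on the rest, and scores the held-out third;
the reported metric is the mean over repeats (default 100). A single-split
mode is just `n_repeats=1`. Repeat-averaging is why reported accuracies
need not be multiples of a fold size. Regression error is RMSECV computed
on the response standardized by training-fold mean and SD, making it
comparable across response units (and invariant to rescaling the response,
which the suite asserts).

The latent-variable count is chosen as the argmin of CV error over
1..L_max, all candidates evaluated on the same fold sequence, ties broken
toward the smaller L; the full error-vs-L table is retained. The chosen L
is then held fixed while building the null.

Confidence: each of `n_permutations` (default 100) randomized models
uniformly permutes the response rows against the intact predictor block and
repeats the identical CV procedure. Confidence is the percentage of
permuted metrics strictly worse than the true model's (lower accuracy /
higher RMSECV), ties counting one half (mid-rank, which makes the statistic
uniform on [0, 100] under the null — verified by a KS test across seeds).
Note that L-selection and the final CV estimate reuse the same data — there
is no nested CV — so the reported metric is optimistically biased in the
usual way; the confidence statistic is unaffected because the null models
undergo the same procedure at the same L.

## Synthetic panel generator

The generator emulates the study shape the pipeline targets, with defaults
fixed as the reference conditions:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | 10 | samples per (genotype × treatment) cell, 40 total |
| `n_analytes` | 32 | panel width |
| `n_informative` | min(8, m) | analytes carrying a group shift (half genotype, half treatment) |
| `effect_size` | 1.0 | standardized log-scale mean shift between groups |
| `block_size`, `block_correlation` | 4, 0.3 | within-block analyte correlation (shared regulation) |
| `between_sample_sd` | 0.4 | biological log-SD (≈ 40% CV, typical for secreted cytokines) |
| `replicate_cv` | 0.05 | technical replicate coefficient of variation |
| `outlier_rate`, `outlier_scale` | 0.02, 10 | per-triplicate gross-outlier probability and displacement (replicate SDs) |
| `bead_count_mean` | 70 | Poisson mean beads/well |
| `response_noise_sd` | 0.5 | SD of the response noise around the sparse linear signal |

Intensities are log-normal: per-analyte base abundances are drawn uniformly
on log [10, 5000], biological variation and group shifts act additively on
the log scale (keeping values positive and right-skewed, as bead-array
readouts are), and technical replicates apply multiplicative log-normal
noise with exactly the requested CV. Outliers displace one replicate
additively by `outlier_scale` replicate SDs (random sign, flipped if the
result would be negative), and the truth record stores every planted
outlier, the informative analyte sets, the latent log values, and the
response coefficients/signal — so recall, calibration and R² are all
checkable against construction. An optional zero-inflation knob plants
structural zeros on trailing non-informative analytes to exercise the
low-prevalence filter. All randomness flows from one seed through
`numpy.random.SeedSequence`, so identical configs are bit-identical across
runs and platforms.

What the generator does **not** emulate: standard-curve interpolation and
censoring at the assay's quantification limits, plate/batch effects and
positional drift, discretized fluorescence values, heavy-tailed or
correlated replicate noise, and non-linear analyte–response relationships.
Passing tests therefore demonstrate correctness of the algorithms under the
stated generative model, not robustness to every artifact of real plate
data.

## Numerical and procedural choices

- Z-scoring uses the sample SD (n−1); recorded so tests can be exact.
- NIPALS deflates X only; single-response models need no Y-deflation for
  correctness (it is applied to the residual only for the SS bookkeeping).
- Rank is checked with `numpy.linalg.matrix_rank` before fitting; a
  vanishing weight vector mid-fit also raises.
- Exact-zero discriminant predictions (probability zero for continuous
  data) go to the larger training class, deterministically.
- Degenerate inputs fail loudly with the offending column named:
  zero-variance or missing predictor columns, single-class labels,
  constant responses, all-analytes-dropped filters.
- CV fold draws, permutation shuffles and generator streams are all
  spawned from `SeedSequence(seed)`, so every reported number is
  reproducible from the recorded seed; run logs contain no timestamps so
  re-runs are byte-identical.
- Problem sizes in the test and acceptance suites (e.g. 20-seed sweeps,
  100-seed calibration at n = 24 with 8 analytes, 100 permutations × 20 CV
  repeats) were sized to estimate each property with comfortable margin at
  interactive runtimes.

## Known limitations

- Two-class discriminant models only; no multi-class, kernel, or sparse
  PLS variants.
- No standard-curve (4PL/5PL) fitting; inputs are taken as already
  quantified (or raw fluorescence modeled directly).
- No nested cross-validation: L-selection and error estimation share data,
  as noted above, and the reports flag the optimistic bias rather than
  removing it.
- The triplicate gap-ratio rule is aggressive on i.i.d.-noise triplicates
  (see the cleaning section); users who want a rare-event detector should
  raise the ratio threshold — the designation function takes the rule as
  stated and the audit trail makes its effect visible.
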