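# Methods

## The probe-level model

Observed linear-scale intensities are treated as background-corrected; on
the log2 scale each probeset is modeled additively,

```
Y_pa = K_a + theta_ga + phi_p + eps_pa
```

with `K_a` an array effect (overall brightness), `theta_ga` log2 expression,
`phi_p` a probe-affinity effect and `eps` measurement error. `K_a` is never
estimated: quantile normalization is applied first and absorbs it, so the
fitted model is `Y_pa = theta_a + phi_p + eps_pa` per probeset with the
identifiability constraint `sum_p phi_p = 0`. A flag exists to skip
normalization (used by the equivariance diagnostics only); the pipeline
itself always normalizes before fitting.

**Quantile normalization.** Without a reference, each array's sorted log2
values are replaced by the across-array mean of sorted values. With a frozen
reference, the reference quantile vector is used instead. Ties receive the
mean of the reference values at their tied ranks, making the result
independent of input order.

**Robust fit.** Huber M-estimation with tuning constant k = 1.345 via
iteratively reweighted least squares; residual scale is the MAD of the
probeset's residuals times 1.4826, recomputed each iteration; convergence
when `max |d theta| < 1e-6`, capped at 50 iterations (non-converged
probesets keep their last iterate and are flagged). The first IRLS pass
reproduces the unweighted initialization, so convergence is only tested from
the second iteration on. `SE(theta_a)` is the square root of the
`(theta_a, theta_a)` entry of `scale^2 (X'WX)^{-1}` at the final weights,
floored at 1e-8 so downstream ratios are always defined. The normal
equations are solved in block form — the theta block is diagonal, and a
Schur complement reduces the probe block to a (P−1)×(P−1) solve — batched
across all probesets with the same probe count. This makes a 96-array,
200-probeset refit take well under a second, which is what keeps
leave-one-out and removal-curve experiments (dozens to hundreds of refits)
cheap.

The SE estimator is a deliberate, documented choice: the quality-metric
literature defines NUSE in terms of probe-level-model standard errors
without fixing the estimator, so all downstream properties here are defined
with respect to this WLS-covariance SE.

## Frozen reference and single-array scoring

A reference batch (≥ 3 arrays; larger is better — the published construction
used 1,000) is normalized and fitted once; the frozen parameters are

* the mean sorted log2 intensity vector (normalization target),
* the fitted probe effects `phi_hat`,
* the per-probeset median SE across reference arrays (GNUSE denominator).

A new array is normalized to the frozen quantiles, frozen probe effects are
subtracted (`z_p = Y_p − phi_hat_p`), and each probeset's expression is the
one-sample Huber location of its `z` values with `SE = scale / sqrt(sum of
final weights)` — the one-column restriction of the batch machinery. The
fRMA-style probe-specific variance weighting is intentionally not
implemented; this simplification keeps the single-array and multi-array
estimators mutually consistent and testable.

**Finite-sample SE calibration.** The single-array scale comes from only P
residuals while the batch scale pools P×A; their finite-sample biases
differ, and uncorrected, a perfectly clean array would score a GNUSE median
a few percent off 1. The single-array SE is therefore divided by a
consistency factor: the median ratio between the raw single-array SE and the
batch-median multi-array SE, computed once per probe count on simulated
Gaussian probesets (40-array batches, fixed internal stream) by the very
same IRLS code paths. It is a numerical constant in the spirit of the MAD's
1.4826, cached per probe count.

**Multi-array GNUSE dilutes minority defects.** Within a batch fit the
robust scale is pooled across arrays, so one bad array in a mostly-good
batch inflates everyone's denominator slightly and its own multi-array GNUSE
only moderately (e.g. 1.2 where single-array scoring gives ~2.7). The
single-array path is the operative detector; the multi-array path is what
makes the mostly-bad-batch comparison with NUSE meaningful. For the same
reason the single-array estimator is noisier per array (its scale has ~P
residuals of information): single- and multi-array GNUSE medians agree in
location but not in dispersion, and the tests check location agreement.

## Quality report

Per array: median and IQR (75th − 25th percentile) of RLE, NUSE and GNUSE,
plus simplified single-array metrics — average background (mean over grid
zones of the 2nd percentile of linear intensities; 4×4 zones when probe
coordinates exist, else whole-array), scale factor (median feature
intensity, the literal definition; the MAS5 software actually uses a
trimmed-mean scaling constant, a recorded divergence), and percent present
(probesets whose median probe intensity strictly exceeds the array's 50th
percentile; a documented simplification of the MM-probe Wilcoxon detection
call, recorded in reports as `detection_method: "simplified_quantile"`).
All quantiles use linear interpolation between order statistics.

Arrays are flagged poor quality iff median GNUSE strictly exceeds the
threshold (default 1.25 — precision 25% worse than typical). Without a
reference the flag stays unset: absence of evidence is not acceptability.
A large IQR is reported but not flagged on (no established numeric cutoff).

## Evaluation framework

`Delta_j = Q(A_-j) − Q(A)` with the model refitted on every subset. All Q
are oriented "higher is better" so `Delta_j > 0` uniformly means array `j`
was harmful:

* **Differential expression**: pooled-variance two-sample t per probeset
  (Welch behind a flag), Benjamini–Hochberg q-values; probesets ranked by q
  with deterministic tie-breaks (|t| descending, then probeset id); Q = AUC
  for recovering the known spiked probesets (trapezoidal over the total
  ranking, identical to Mann–Whitney U / n1 n2).
* **Clustering**: Q = negated mean Euclidean distance between replicate
  arrays' expression vectors (negation keeps the orientation uniform).
* **Prediction**: nearest-shrunken-centroid classifier (class centroid
  deviations standardized by pooled within-class deviation plus a median
  offset, soft-thresholded; priors = training frequencies; no
  cross-validated shrinkage path — shrinkage is a config value), scored by
  Matthews correlation coefficient (0 when a confusion marginal is 0).

Worst-first removal curves recompute the ranking metric after every refit,
since relative metrics change with the batch.

## Variance components

The crossed two-factor random model `response = mu + S_type + L_lab + eps`
is estimated by Henderson-type method of moments: the quadratic forms
`T_A − T_mu`, `T_B − T_mu` and the residual form are equated to their
expectations, whose coefficients are exact functions of the (possibly
unbalanced) cell counts; a 3×3 linear solve yields the components, negative
solutions are truncated at zero and recorded. On balanced designs this
reduces exactly to the textbook expected-mean-square solution and is
unbiased. REML would pool information differently on unbalanced data but
adds an iterative dependency for no benefit at this scale.

Per-tissue lab effects use a one-way fixed-effects ANOVA of log-transformed
quality responses with sum-to-zero coding (lab mean minus unweighted mean of
lab means), the classical F test, and per-lab t-tests against the grand mean
using the pooled residual variance (significance at 0.05). Model-2 responses
are analyzed untransformed; the one-way tissue tables use logs.

## Synthetic data: what it emulates, and what it does not

The generator draws directly from the fitted model: probe effects
(N(0, 1), centered per probeset) and baseline expressions (Uniform(4, 12)
log2) come from a `platform_seed` — they are fixed chip/transcriptome
properties, so data sets sharing a platform are mutually comparable and a
frozen reference built on one simulation scores arrays from another.
Array effects K ~ N(0, 0.2), Gaussian measurement error on the log2 scale,
tissue blocks, two-group designs with spiked probesets, and a crossed
lab × sample-type response generator mirror the study designs the framework
is evaluated on.

Poor quality is modeled as (i) inflated error sd (multiplier 3 by default)
and/or (ii) a contiguous spatial blob offset on the probe grid — stand-ins
for real degradation, whose noise distribution no one has characterized.
Real probe-sequence effects (GC content), MM probes, and spatially
correlated gradients are not emulated; passing tests therefore demonstrate
the metrics' behavior under the additive model with these defect classes,
not under every failure mode of real hybridizations.

### Standard study conditions

Chosen once, by power analysis, as the package defaults:

* `n_probesets = 200`, `probes_per_set = 4`: desk scale; 4 probes is the
  minimum at which probe effects and robust weights are meaningfully
  estimable per array, and it makes the robustness/precision trade-offs
  visible rather than washed out.
* `baseline_sd = 0.5` log2: upper range of realistic probe-level noise,
  chosen so that the 16-spike, 8-array design sits in the informative
  regime (full-set AUC ≈ 0.8) instead of at ceiling — influence analysis is
  uninformative when every analysis is perfect.
* `spike_log_fc = 0.5` (1.4-fold): a subtle, realistic differential signal;
  with 4+4 arrays this gives spike t-statistics ≈ 2, i.e. detection that a
  single noisy array can visibly degrade.
* `bad_multiplier = 3`: the degraded arrays' error sd, matching the
  evaluation designs throughout.
* Prediction design: 96 training arrays (48/48 two classes, 10 bad:
  noise ×3 plus a blob of 2.0 log2 over a quarter-side square — pure iid
  noise diluted over 48-array centroids barely harms prediction, while
  real flagged arrays carry gross regional artifacts), 50 clean test
  arrays, 5 informative probesets at class effect 0.3, shrinkage 1.0;
  targets ~15% test error so removal has headroom to help.
* Variance-component preset: lab variance 0.0162, sample-type variance
  0.0035, residual sd 0.1, balanced 120 labs × 10 types × 4 replicates.

## Numerical choices

* Quantile/IQR convention: linear interpolation everywhere.
* SE floor 1e-8 (exactly-fitting probesets would otherwise divide by 0).
* Degenerate robust scale (< 1e-12) ends iteration with unit weights.
* t-test with zero variance in both groups: p = 0 if means differ, else 1.
* Ranking tie-breaks: q, then |t| descending, then probeset id.
* Present-call ties: strictly greater than the threshold percentile.
* Flag boundary: strictly greater than the GNUSE threshold.
* All generator randomness derives substreams from (seed, operation name);
  fitting itself is deterministic.

## Known limitations

* A lone bad array in a small multi-array batch can evade the 1.25
  multi-array GNUSE threshold because the pooled scale absorbs part of its
  noise; score arrays singly when that matters.
* The sample-type variance component rests on however many type levels the
  design has (10 in the preset); with J levels its estimate carries the
  ~sqrt(2/(J−1)) relative noise of any quadratic estimator, regardless of
  the number of arrays.
* Leave-one-out influence is itself noisy: with subtle signals, removing a
  good array occasionally helps more than removing the genuinely bad one
  (the robust fit already shields estimates from moderate outliers), so the
  bad array tops the Delta ranking in most but not all replicates.
* Single-array SEs are calibrated to the multi-array scale in median, not
  distribution; per-array GNUSE medians from single-array scoring carry a
  few percent more spread.
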