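# Methods

`methrisk` implements a cell-type-aware analysis for building and auditing a
DNA-methylation risk index from heterogeneous cervical-smear beta values.
This note records the statistical models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic benchmark does and
does not establish.

## The measurement model

A methylation array reports, per CpG site and sample, a beta value in
[0, 1]: the proportion of methylated molecules. A cervical smear is a bulk
mixture of epithelial cells, fibroblasts, immune cells and — potentially —
shed tumour DNA. The observed beta is modelled as a convex combination of
compartment-level betas,

    beta_obs = f_epi * beta_epi + f_fib * beta_fib + f_imm * beta_imm + f_tum * beta_tum,

with non-negative fractions summing to one. Two consequences drive the whole
design: (i) any case/control difference confined to the epithelium is
diluted in proportion to the immune-cell (IC) fraction, and (ii) every
linear functional of the betas — in particular the risk index — is exactly
linear under in-silico mixing.

## Synthetic methylome generator

The generator (`methrisk.simulate`) is first-class, tested code: it defines
the conditions under which every estimator is validated.

* **Per-CpG, per-cell-type Beta distributions.** Each CpG gets a Beta(a, b)
  per cell type. Background means are drawn from a bimodal mixture (40%
  hypo-, 40% hyper-methylated, 20% intermediate), matching the
  characteristic U-shape of array methylomes; per-type mean jitter is
  N(0, 0.03). Precisions a+b are log-normal around 120 (CV ≈ 0.4), giving
  within-cell-type biological SDs of roughly 0.02–0.08 — needed so the
  variance-decomposition model has within-compartment variance to estimate.
* **Markers.** A designated subset per cell type (default n_cpgs/50 per
  type) places the owning type at mean 0.90 (or 0.10) and all other types at
  0.10 (0.90), a separation ≥ 0.5 by construction. These play the role of
  purified-cell marker CpGs for reference-panel construction.
* **Cell fractions.** Default model: IC ~ Uniform(0, 0.8) (a wide immune
  marginal keeps the beta-on-IC regressions well conditioned and mirrors the
  broad IC spread of real smears), fibroblast = (1-IC)·Beta(2, 18) (a small,
  variable share), epithelium the remainder; a Dirichlet alternative is
  provided. Tumour contamination is injected by scaling all fractions by
  (1-rho) and assigning rho to the tumour compartment.
* **Planted effect.** Cases receive a signed shift of the epithelial-
  compartment mean (same precision) at a chosen CpG subset; shifts that push
  a mean outside (0, 1) are rejected, and `feasible_effect_cpgs` lists the
  admissible sites. The default planted effect in the end-to-end benchmark
  is 0.1 at 500 of 10,000 CpGs — a moderate, realistic epithelial
  delta-beta.
* **Noise and failures.** Measurement noise is Gaussian on the beta scale,
  clipped to [0, 1] (SD 0.02 by default, the scale of array technical
  replicates); detection failures occur at rate 1e-5 (of the order of the
  fraction of failed probes in processed array data) and are marked by a
  detection-p matrix, not by corrupting the betas.
* **Streams.** Each component (fractions, each cell type's draws, noise,
  detection, sample sheet) uses an independent child RNG stream, so a
  component that is never drawn (e.g. tumour at rho = 0) leaves every other
  output bit-identical.

What the generator does **not** emulate: probe-type chemistry, spatial/batch
structure, correlated neighbouring CpGs, age-related drift (available but
off by default), or immune-subtype heterogeneity. Passing tests therefore
demonstrate correctness of the estimators under the mixture model, not
performance on real arrays.

## QC

Entries with detection p > 0.01 are failures. Samples with > 10% failures
are removed, then probes with > 10% failure rate; the two filters are
iterated to a fixed point so no retained row or column exceeds its
threshold. Remaining failures are imputed from the k = 10 nearest probes by
Euclidean distance over pairwise-complete samples (uniform weights); k and
the metric are package choices — the upstream convention fixes only the
method family. The intensity-level sample filter used before beta matrices
exist requires raw intensities and is recorded in the `QcReport` as not
applied. The discovery split is a one-off random 2/3 : 1/3 partition
(optionally stratified by case status); it is persisted and reused.

## Reference-based deconvolution

Markers are selected per cell type by one-vs-rest two-sided Wilcoxon
rank-sum tests, Benjamini–Hochberg adjusted across CpGs, intersected with an
absolute group-mean-difference threshold (default 0.5; per-type values or an
auto-tuned target count per type are supported). A CpG eligible for two
types goes to the type with the larger difference, keeping markers
type-exclusive. Sample fractions solve non-negative least squares of the
sample's marker betas on the panel centroids, renormalised to sum to one —
a deterministic constrained-projection variant of reference-based
deconvolution that recovers noiseless centroid mixtures exactly and matches
an exhaustive 0.01-resolution simplex search within 0.02 under 0.02 noise.
Missing markers are dropped, not imputed; fitting requires ≥ 50% of the
panel present.

The tumour fraction is additionally residual-corrected: a loess smooth
(default span 0.75) of tumour on epithelial fraction is fitted on controls
only, and every sample's corrected value is its raw tumour fraction minus
the smooth at its epithelial fraction. Corrected values may be slightly
negative and are deliberately left unnormalised — they are residuals, not
proportions. Samples outside the controls' epithelial range are linearly
extrapolated from the end segments of the smooth and flagged.

## Intercept-method delta-betas

Per CpG, beta is regressed linearly on IC within cases and controls
separately. The intercept difference at IC = 0 estimates the epithelial
delta-beta; the fitted-value difference at IC = 1 the immune delta-beta.
Under exact linear mixing with exactly measured IC the epithelial estimate
equals the true compartment difference up to the (small) dilution by the
non-epithelial, non-immune share — with the default fraction model the
fibroblast share attenuates a planted 0.15 delta to ≈ 0.136, inside the
0.02 recovery band the tests enforce. Betas are regressed directly (no
logit/M-value transform). Groups with zero IC variance yield records flagged
unavailable rather than silent zeros.

Ranking is by absolute delta of the chosen compartment (absolute value is
the only reading under which hypo- and hyper-methylated CpGs both
contribute); "combined" mode ranks by the larger of the two absolute
deltas; ties break lexicographically by CpG id. The covariate-adjusted scan
fits beta ~ label + IC + age per CpG with a two-sided t-test on the label
coefficient and a Bonferroni multiplier equal to the number of CpGs tested.

## The penalized index

Ridge (alpha = 0) or lasso (alpha = 1) logistic classifiers are trained on
the top-n ranked CpGs. Lambda is selected by K-fold (default 10)
cross-validated binomial deviance over a geometric grid of default 100
points spanning the data-driven anchor max|x'(y - ybar)|/n down to 1e-4 of
it; a one-standard-error rule is available for sparse fits. Features are
not internally standardised: beta values already share the [0, 1] scale.
The index-size sweep trains one classifier per n (lambda re-tuned per n),
scores the disjoint validation set by AUC and takes the maximising n
(ties → smallest). The finalised model is refitted on the full discovery
set at the fixed lambda.

The index of a sample is (Σ w_i x_i − μ)/σ, where μ and σ are the mean and
SD (ddof = 1) of Σ w_i x_i over the training samples — zero mean and unit
SD in training by construction, exactly linear in the betas, intercept
excluded (it cancels under the scaling). At scoring time up to 5% of model
CpGs may be absent; they are imputed at their training mean beta (stored in
the serialised model) and the fit refuses matrices below 95% overlap.

## Beta-mixture variance attribution

Per CpG, betas are modelled as a two-component mixture of Beta
distributions with *known* per-sample weights: the immune fraction rho_i
weights Beta(a1, b1) against the epithelial Beta(a0, b0). The average
negative log-likelihood is minimised over log-parameterised shapes
(Nelder–Mead, xatol 1e-6) from three method-of-moments starts: moments of
the low-rho half for the epithelial component paired with the high-rho half
for the immune one, global moments, and the swapped pairing. Betas are
clipped to [1e-6, 1−1e-6] so the density is finite at the boundaries. With
all rho = 0 (or 1) the unweighted component is unidentifiable; the fit
reduces to a single beta and flags it. CpGs are classified epithelial /
immune / shared by whether one fitted compartment variance exceeds the
other by a configurable ratio (default 2) — the classification rule behind
the published class percentages is not recorded anywhere, so those
percentages are not a reproduction target.

## Contamination simulation

Mixing is beta = (1−rho)·beta_control + rho·beta_tumour elementwise. The
shift curve reports the mean index of the mixed cohort minus the unmixed
controls' mean, in units of the unmixed controls' index SD; by linearity of
the index, shift(rho) = rho·shift(1) exactly, and the test suite asserts
this identity to 1e-10. rho* is the smallest grid value reaching the target
shift (linear interpolation between grid points); an unreached target is
reported as unreachable, never extrapolated. With a tumour profile placed
5 control-SDs above the control mean, the 1.25-SD target is crossed at
rho* = 0.25 analytically — the testable surrogate for contamination levels
that would mimic an observed case/control separation.

## Evaluation layer

* **AUC**: Mann–Whitney with ties counted 1/2, equal to the exhaustive
  pairwise win fraction; CI from the DeLong structural-component variance,
  normal on the AUC scale, clipped to [0, 1].
* **Mid-p median-unbiased odds ratio**: the psi at which the upper mid-p
  tail of Fisher's noncentral hypergeometric distribution of the
  exposed-case cell equals 1/2; CI limits invert the tail at alpha/2
  (root-finding to 1e-6 relative tolerance; direct log-scale summation over
  the support). Boundary tables return 0 or infinity for the affected
  estimate/limit. For large balanced tables the estimate approaches the
  cross-product ratio from below.
* **Quartile tables**: cutpoints are the 25/50/75 percentiles (linear
  interpolation between order statistics) of a *control* reference
  distribution — the only reading that splits 297 controls 75/74/74/74 —
  with intervals closed on the right; unadjusted ORs versus the bottom
  quartile use the mid-p estimator, adjusted ORs a logistic regression on
  quartile indicators plus covariates with Wald CIs, and non-convergence is
  reported rather than dropped.
* **Region enrichment**: per relation-to-island class, the mid-p OR of the
  2×2 (selected vs not) × (in class vs not) against the array background.
* **PRS** is the dot product of effect-allele dosages with log-OR weights
  (missing dosages imputed at 2× allele frequency when frequencies are
  supplied); **PMR** is 100 × (sample target:reference ratio)/(fully
  methylated control ratio).

## End-to-end benchmark and problem sizes

The default pipeline configuration simulates 600 samples (150 cases, 450
controls — a case fraction like a discovery cohort enriched for cases) at
10,000 CpGs with 500 planted epithelial-effect CpGs, QCs, deconvolves,
ranks by epithelial delta-beta on the training two-thirds, sweeps
n ∈ {100, 500, 1500, 3000} with 5-fold CV over 20 lambdas, and evaluates on
the held-out third. These sizes keep a full run under two minutes on one
CPU while leaving the planted-signal benchmark (validation AUC ≥ 0.85) and
its null counterpart (AUC in [0.4, 0.6]) cleanly separated; the variance
decomposition runs on the top 100 index CpGs by |weight|. A single global
seed expands to per-stage seeds (seed + stage index); rerunning a config
reproduces every numeric output exactly, and written runs carry a manifest
with file hashes.

## Known limitations

* The deconvolution solver is plain NNLS + renormalisation; robust-
  regression variants used by some reference-based tools are not
  reproduced (at the noise levels probed here they coincide).
* Immune cells are one aggregate class; no hierarchical immune-subtype
  decomposition.
* The intercept method inherits the dilution of whatever compartments are
  neither epithelial nor immune; it is exact only when those shares vanish.
* The beta-mixture fit is a local optimiser with multi-start; pathological
  CpGs can converge to a local optimum, which the `converged` flag and nll
  cross-checks only partially guard against.
* Published cohort-level AUCs and quartile tables from restricted-access
  data are not reproducible here; the package reproduces the published
  odds-ratio *estimator* exactly from printed counts and substitutes
  property-based synthetic benchmarks for the rest.
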