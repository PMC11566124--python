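# Methods

`sccrt` tests, for each gene g (or gene group A), the conditional
independence null

    H0_g :  x_g  ⟂  y  |  x_{-g}, s

where x is a cells × genes count matrix, y a per-cell response (surface
protein level, perturbation readout, spatial covariate, ...), and s
observed nuisance factors (batch indicators, optionally log library
size). Rejecting H0_g says gene g carries information about y that the
rest of the transcriptome cannot explain — a far stricter notion than
marginal correlation, which in single-cell data is dominated by cell-type
structure and technical covariation.

## The conditional randomization test

The test needs two fitted components, both trained only on a development
split of the cells (default 70%; the remaining 30% is the validation
split on which all p-values are computed):

1. **A generative model of the counts.** A latent-variable model
   factorized as p(x, z | s) = p(z) Π_g p(x_g | z, s): a low-dimensional
   cell state z (standard-normal prior) renders genes conditionally
   independent, and each gene is negative-binomial with mean = library
   size × decoded proportion and a gene-specific dispersion θ_g.
2. **An importance score.** Any predictive model of y from (x, s); the
   test statistic is its average per-cell negative log-likelihood on the
   validation cells,

       T(X, Y, S) = (1/N) Σ_n −log p(y_n | x_n, s_n).

For each hypothesis, K synthetic versions of the target column(s) are
drawn from the model's conditional null and swapped into the validation
matrix; the p-value is the rank of the observed score among the
synthetic ones:

    p_g = (1 + #{k : T(X̃(k), Y, S) ≤ T(X, Y, S)}) / (K + 1).

Ties count toward the null (the conservative direction). p-values are
valid for *any* importance score — a poor predictor costs power, never
calibration. Discoveries are declared by Benjamini–Hochberg at the
target FDR, applied within one run (one response dimension, one
resolution); multivariate responses are tested dimension-by-dimension,
sharing the generative model, with BH per dimension.

### Fixed-posterior-particle sampling

Sampling from the exact conditional p(x_g | x_{-g}, s) would require a
per-gene model. Instead one particle z̄ per validation cell is drawn
once from the encoder posterior q(z | x, s) and cached; every synthetic
count, for every gene, group, and Monte-Carlo replicate, is then an
i.i.d. NB draw from the decoder at z̄. This yields valid (super-uniform)
null p-values and reduces the whole Monte-Carlo loop to forward passes.
Per-gene seed substreams make draws independent of batching and of group
membership, so a singleton group reproduces the gene-level test exactly.

The package deliberately does not implement the alternative of sampling
from the complement conditional p(x_A | x_{A^C}, s) per hypothesis (a
Gibbs-style scheme): with amortized encoders it would require a separate
model per feature. See "Known limitations" for the power consequence.

## The NB-VAE

The generative model is a conditional variational autoencoder written
directly in NumPy (hand-derived gradients, Adam): one 128-unit ReLU
hidden layer in encoder and decoder, latent dimension 10, nuisance
covariates concatenated to both encoder and decoder inputs, softmax
decoder proportions scaled by the observed library size, free per-gene
log-dispersions. At the scales this package targets (thousands of cells,
tens to hundreds of genes) a fit takes seconds on one CPU.

Training choices that matter:

- **lr 1e-3, batch 256, max 400 epochs, early stopping** on a 10% slice
  of the development cells with patience 10. Model fit quality is a
  calibration parameter as much as a likelihood one: a decoder that
  misrepresents the conditional means of genes correlated with
  informative ones surfaces those genes as false positives (a failure
  mode directly observable by swapping in the oracle sampler, which
  removes them), while extra capacity that overfits the development
  cells produces the same artifact on validation cells. The defaults sit
  at the measured optimum of that trade-off for the benchmark scale.
- **KL warmup** over the first 40 epochs (the reconstruction term is
  learned before the prior squeezes the posterior); early stopping only
  engages once the full objective is active.
- **Dispersion learning rate ×20.** Adam's unit-normalized steps move
  each parameter by roughly lr per step; a log-dispersion that must
  travel several log-units from its init would otherwise stay underfit,
  which directly miscalibrates the test (synthetic nulls too noisy make
  observed scores look extreme).
- Degenerate inputs: training aborts with the epoch index if the loss
  goes non-finite; a validation gene set differing from the fitted one
  is rejected.

The generative-model interface (fit / make_cache) is pluggable. A
per-gene NB model with constant proportions ships as a minimal
alternative; the simulation module exposes the true simulator as an
oracle model, which is how validity is tested with no fitting error in
the way.

## Importance scores

Built-in families: linear Gaussian (closed-form OLS with a learned
homoscedastic variance), one-hidden-layer MLPs (64 units, ReLU, adam,
early stopping; Gaussian or Bernoulli likelihood; fit via scikit-learn,
with the forward pass re-done in NumPy so that a replaced column becomes
a rank-|A| update of the hidden layer — the entire Monte-Carlo loop
costs one matrix multiply per hypothesis), a constant (intercept-only)
baseline, and a plug-in adapter accepting any callable
`(X, y, S) -> per-cell losses` for external models (tree ensembles,
boosting, ...), fit once on development cells and never refit per
replicate.

Predictor inputs are log1p-transformed counts by default (raw counts via
config); the identical transform is applied to observed and synthetic
columns, so the score comparison is well defined. Continuous responses
use a Gaussian NLL with a single learned variance — this orders scores
identically to MSE but keeps the same scale as the Bernoulli case. When
several candidate predictors are fit, the one with the best held-out
predictive loss (a 15% slice of the development cells, shared across
candidates) is selected; ties go to the simpler family.

## Cell-level scores

For a tested gene, the per-cell score is the mean synthetic NLL minus
the observed NLL of that cell. Positive values mark cells in which
randomizing the gene damages the prediction, localizing a detected
association to cell subsets. By construction the cell scores average
exactly to (mean synthetic score − observed score).

## Multi-resolution testing

Strongly correlated genes can be individually untestable: the
conditional null regenerates any one of them from the others. Group
nulls H0_A : x_A ⟂ y | x_{A^C} are therefore tested on nested gene
partitions obtained by agglomerative clustering (average linkage,
distance 1 − Pearson correlation, signed so co-regulated genes stay
together) of the generative model's normalized (denoised) expression; a
raw log-CPM fallback exists for model-free runs. Cutting one linkage
tree at several cluster counts guarantees nested partitions; default
resolutions are {100, 250, 500, G} clipped to the gene count. Group
draws reuse the per-gene streams, each resolution is BH-corrected
independently, and a consistency report checks (empirically, not as a
guarantee) whether fine-level detections have detected coarser
ancestors.

## The synthetic-data generator

The simulator emulates a semi-synthetic single-cell benchmark in which
the count-generating process is fully known:

- cell state z ~ N(0, I_d) (default d = 5); gene proportions
  softmax(z·V + intercepts + batch offset); library ~ log-normal
  (median 2000, sd 0.25 on the log scale); counts ~ NB with per-gene
  dispersions ~ LogNormal(log 5, 0.5). Batches, when requested, add
  per-gene offsets (sd 0.3) and enter the dataset as reference-coded
  indicator covariates.
- response: signal = Σ_{g∈causal} w_g · (centered log-CPM_g)², with
  causal genes drawn uniformly and w i.i.d. standard normal; Gaussian
  noise with sd = 0.25 × sd(signal), or a Poisson response with rate
  exp(log 5 − 0.5 + standardized signal) (mean ≈ 5, unit log-scale sd).
  The squared link makes linear baselines misspecified by construction.
- an optional block of strongly correlated genes: fixed-norm loadings
  sharing a latent direction with correlation knob c, high abundance and
  weak overdispersion so the shared signal dominates count noise.

The default benchmark configuration — 2000 cells, 100 genes, 20 causal
(keeping the ~0.2–0.3 causal fraction of full-scale designs), noise at
25% of the signal sd, K = 200, five replicates — was chosen so that a
full benchmark runs in minutes on one CPU with intermediate power
(neither floor nor ceiling), which is what calibration measurements
need. log-CPM uses pseudocount 1 on the CPM scale (log(0) must be
avoided; the convention is stated rather than assumed).

What the generator does **not** emulate: real cell-type cluster
structure, zero-inflation beyond NB, ambient RNA/background counts,
doublets, or gene-length effects. Passing tests therefore demonstrate
the statistical machinery (calibration, power ordering, reproducibility)
under a correctly-specified-to-mildly-misspecified model family, not
robustness to every artifact of real data.

A design subtlety worth knowing: because log-CPM divides by the realized
total count, every gene enters the response weakly through the
normalization denominator, so "null" genes are not mathematically null.
At the default scale the effect is negligible (measured: false positives
are not concentrated in abundant genes, and an oracle-sampler run shows
the same FDR as expected from BH alone), but at much larger sample sizes
it would surface.

## Baselines and evaluation

OLS (one multiple regression of y on all centered log-CPM features plus
nuisance, per-coefficient t-tests) and the marginal per-gene t-test are
the comparison baselines; both use all cells (development + validation),
deliberately granting them more data than the CRT. All methods receive
the same BH correction. Evaluation: FDR = FP / max(1, discoveries) (0/0
counts as 0), TPR = recovered causal genes / causal genes; at group
level a group is a true positive iff it contains at least one causal
gene, and power is the fraction of causal genes covered by detected
groups.

## Numerical and reproducibility choices

- One master seed; every stochastic stage (split, generative fit,
  posterior cache, null draws per gene, predictor fit, simulation,
  weights, response noise) draws from a named SeedSequence substream, so
  stages can be re-run in isolation and results do not depend on
  evaluation order. Replaying a run from its manifest reproduces result
  files byte for byte.
- K defaults to 500 (granularity 1/(K+1) ≈ 0.002, fine enough for BH at
  conventional levels over hundreds of genes); the benchmark uses
  K = 200. Note BH at level α over m hypotheses cannot reject a single
  minimum-rank p-value unless 1/(K+1) ≤ α/m: choose K ≥ m/α.
- NB means are floored at 1e-8; posterior log-variances are capped above
  at 10 (no lower cap at inference, so a degenerate posterior is exact);
  log-dispersions are clipped to [−8, 12].
- p-values are validated to lie in (0, 1] before BH; a constant gene in
  the hierarchy gets correlation 0 to all others with a warning; a
  constant gene in the marginal baseline gets p = 1 with a warning.

## Known limitations

- **Group-test power under near-duplicate genes.** With the fixed-
  particle scheme, the particle z̄ is drawn from the posterior given the
  *full* expression vector. For a pair of near-perfectly correlated
  genes the posterior pins their shared signal, so synthetic draws
  regenerate it, and the group test differs from the gene test only
  through the predictor's weight on the partner column (a factor ≤ ~2 in
  score shift, measured across designs). Group testing therefore buys
  power through fewer hypotheses, coarser BH, and aggregation of several
  causal genes per cluster — not through an idealized
  "individually-invisible pair, always-visible group" dichotomy, which
  would require per-hypothesis complement conditionals (the Gibbs scheme
  this package does not implement).
- Amortized posteriors underestimate uncertainty; a mild optimistic bias
  in the conditional null is possible when the model is undertrained.
  The KL warmup and dispersion learning-rate multiplier exist to keep
  this small; the acceptance suite measures the resulting FDR directly.
- Only NB likelihoods are provided; modalities needing other noise
  models (binarized chromatin accessibility) would need a new generative
  model behind the pluggable interface.
- The OLS baseline requires N > G + T + 1; it is a comparison method,
  not part of the CRT itself.
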