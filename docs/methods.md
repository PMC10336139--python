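# Methods

This document describes the models implemented in `codal`, the numerical
choices behind them, and the scope and limitations of the bundled data
generators.

## 1. Generative model

Counts from a multi-batch single-cell experiment are modeled as draws from
a topic model whose per-cell composition is distorted by a batch-dependent
technical channel.

**Topics.** Each cell carries a composition `Z ~ Dirichlet(alpha)` over
`K` topics. The concentration vector is given a Gamma(2, 2K/I) hyperprior
with `I = 50` total pseudocounts and is learned by MAP: the model keeps a
`log alpha` parameter whose Gamma log-prior (with the log-transform
Jacobian) is added to the objective, scaled per cell. A full variational
posterior over `alpha` is not maintained; the hyperprior only has to adapt
the prior's sparsity to the data.

**Biological rates.** The decoder maps `Z` through a linear layer
(`beta`, topics x genes), dropout, and a per-gene batch normalization with
learned affine terms, producing biological log-rates `lambda`. Because
batchnorm standardizes each gene and the affine terms absorb scale and
shift, `beta` is identified only up to a per-gene affine transform; all
loading comparisons therefore standardize columns first
(`evaluation.match_topics`).

**Technical effects.** A two-layer network takes `Z` concatenated with
the covariate encoding `C` (batch one-hots), passes a hidden layer of 32
units with batchnorm/ReLU/dropout, maps to genes, standardizes per gene
without affine terms (centering over the training population), and scales
by a learned per-gene `gamma_t`. During training the technical output of
each cell is zeroed with probability 0.05 (Bernoulli corruption, per-cell
by default, per-entry as a configuration switch), which regularizes the
channel toward effects that the reconstruction genuinely needs.

**Observation models.** The composed rate is
`rho = softmax(lambda + t)`. RNA counts are negative binomial with mean
`n_i * rho_ij` and per-gene inverse dispersion `theta_j`; the latent size
factor `n_i` has a LogNormal posterior whose prior is centered at the
observed log depth with unit scale. ATAC counts are binarized and modeled
multinomially (the multinomial coefficient is omitted by default; it is
constant in the parameters).

## 2. Encoders

The RNA encoder receives Poisson deviance residuals of the counts
concatenated with `C`, passes two 512-unit blocks (linear, batchnorm,
ReLU, dropout), and emits `2K + 2` heads: topic-posterior mean and
log-variance, and the size-factor posterior mean offset and log-variance.
The ATAC encoder is a Deep Averaging Network: learned peak embeddings are
averaged over each cell's accessible peaks (with embedding-level
corruption during training), combined with `C` through a hidden layer,
and added back through a skip connection.

The Dirichlet prior is mapped to softmax-basis Gaussian moments by the
Laplace approximation (`mu_k = log alpha_k − mean log alpha`,
`sigma2_k = (1 − 2/K)/alpha_k + sum_l alpha_l^{-1}/K^2`), so the KL term
between the Gaussian posterior and the prior is closed-form. Sampled
logits are softmaxed to give compositions. Downstream geometry
(neighbors, clustering, silhouettes) uses isometric log-ratio (ILR)
coordinates of the compositions.

## 3. Mutual-information regularizer

A critic `T(lambda, t)` scores pairs of biological-rate and
technical-effect rows (concatenated input, one 64-unit hidden layer, two
ReLU blocks). Its Donsker–Varadhan bound

```
MINE = mean_i T(lambda_i, t_i) − log mean_ij exp T(lambda_i, t_j)
```

estimates the mutual information between the two channels; the training
objective subtracts it. The Kantorovich-dual Wasserstein form is kept as a
diagnostic. After every critic update each weight matrix is divided by
its leading singular value (power iteration with persistent, warm-started
vectors, iterated to a 1e-7 relative tolerance), keeping the critic
1-Lipschitz.

A consequence worth stating: the 1-Lipschitz constraint caps the bound
well below the true mutual information when the dependence is strong. For
a bivariate Gaussian with correlation 0.8 the constrained optimum is
about 0.218 nats versus a true MI of 0.511; the trained critic reaches
roughly 92% of the constrained optimum and approaches it from below. The
regularizer is therefore a dependence penalty, not an MI meter.

## 4. Training

The objective per minibatch is
`V = recon − eps1 * KL − eps2 * mi_weight * MINE` plus the per-cell
share of the alpha hyperprior. `eps2` follows the cyclic schedule
`r(s) = min(1, 2 mod(s, L)/L)` with `L = s_total/3`; `eps1` follows the
step-up cyclic schedule `(1/3) ceil(s/L) r(s)` whose cycle maxima ramp
1/3, 2/3, 1. Topic-model parameters are updated with AdamW (weight decay
0.01) under a one-cycle policy: cosine learning-rate ramp between
`lr_max/25` and `lr_max` with momentum annealed inversely in
[0.85, 0.95]. The critic uses Adam at 1e-4 and is re-normalized after
every step. Defaults: batch size 128, 24 epochs, 3 cycles.

`lr_max` comes from a learning-rate range test: a geometric sweep over
[1e-6, 1] with a divergence stop, exponential smoothing of the loss
trace, and selection at the halfway point of the smoothed descent (the
steepest-improvement point of its sigmoid-shaped profile). The literal
per-step steepest-drop rule is dominated by minibatch noise at these
problem sizes.

**Batchnorm finalization.** The per-gene standardizations are defined
over the training population, but minibatch training leaves exponential
running averages — noisy snapshots. After the last step the model runs
one noise-free full-data pass (momentum 1, dropout and corruption off,
posterior-mean topics) to replace them with exact population moments.

Gradient clipping at global norm 10 guards against NaNs; a non-finite
objective aborts the fit with the step's component values.

## 5. Hyperparameter search

The tuner searches `(n_topics, dropout)` with dropout boxed to
[0.05, 0.1]. Trials are checkpointed at epochs 8, 16, and 24; at
intermediate rungs a trial scoring below the 50th percentile of recorded
scores at that rung is pruned. A Gaussian process with a Matern-5/2
kernel (inputs min-max scaled, scores standardized) is fitted on all
(hyperparameters, rung, score) tuples. Candidates (300 uniform draws) are
ranked by pruning-aware expected improvement: classical EI at the final
rung against a margin-adjusted best score `f* + 0.1 |f*|`, multiplied by
the product of per-rung survival probabilities (rung independence is an
explicit approximation). The first 15 trials are random; batched
proposals impute running trials at the mean completed score (constant
liar). Stopping: minimum 48 trials, patience 12, ceiling 128. Trial
scores are the full objective (term weights 1) on a held-out stratified
split.

## 6. Regulatory-potential model

For a gene with TSS-assigned peak sets (upstream/downstream within
±600 kb, promoter within ±1.5 kb, strand-aware midpoints), the
regulatory potential of cell `i` is
`c_i = sum_eta a_eta sum_k A_ik 2^(−delta_k / Delta_eta)` with learned
positive effects `a`, learned decay distances `Delta > 1 kb` for the two
distal arms, and infinite promoter decay. Accessibility `A` is the
batch-free compositional rate from a trained ATAC topic model. Expression
is negative binomial with
`log mean = gamma * zscore(c) + b + t_ij − log kappa_i + log n_i`, where
the technical vector `t`, softmax denominator `kappa`, and size factors
`n` are fixed constants from trained topic models. Setting `t = 0`
recovers the unaugmented model exactly. Parameters (log-effects,
log-(decay−1), affine, log-dispersion) are MAP-estimated by L-BFGS-B with
three random restarts under weakly informative normal priors (sd 2;
decay centered at 10 kb). In-silico deletion scores a motif by the
log-likelihood drop when its peaks are zeroed, parameters fixed; motif
enrichment over a gene set uses a one-sided Wilcoxon rank-sum test with
Bonferroni correction across motifs.

## 7. Trajectory simulator

Synthetic differentiation datasets are built by mixing reads from pure
base populations along a hematopoiesis-like tree over seven cell types.
Node mixing-weight rows are stored symbolically in the similarity
parameter `k` and verified to sum to one for all admissible `k`
(`k` in [0, 0.25]). A cell samples a Markov path from the root
(root→progenitor 1; progenitor→myeloid 0.4 / lymphoid 0.6; myeloid→Mono
0.5 / Dendritic 0.5; lymphoid→B-cell 1−P / T-cell P), draws a progress
`p ~ Beta(0.5, 1)` along the whole path, and interpolates the selected
edge's endpoint weights through the logistic `delta = sigma(2 p_edge − 1)`.
Read synthesis draws a LogNormal depth, splits it into per-type quotas by
largest remainder, picks one donor cell per type from the batch's pool,
and samples each quota without replacement from the donor's gene counts
(multivariate hypergeometric; shallow donors are redrawn up to ten times,
then sampled with replacement). Two batches generated from plans
differing only in `P_T-cell` (1 versus 0) give completely confounded
fates.

Base populations are themselves synthetic: each type upregulates a
disjoint marker block (8x) over a shared lognormal baseline, counts are
Gamma–Poisson, and batch 2 is distorted by gene-wise LogNormal(0, 0.4)
factors plus a depth shift. They stand in for annotated pools from a real
multi-batch experiment; no external data is required.

## 8. Evaluation

Diagnostics include per-cell silhouette widths (with singleton clusters
scored zero), per-gene Pearson correlation between predicted biological
rates and technical effects (summary: median absolute correlation,
constant genes excluded), the law-of-total-variance decomposition of
repeated estimates across seeds (within = mean across-model variance,
between = variance of the across-model mean; the identity holds to
machine precision), Hungarian topic matching on column-standardized
loadings, and adjusted Rand index of k-means on ILR coordinates against
true branch labels. Branch ARI is computed on cells past the trunk:
trunk cells have no branch identity, and the Beta(0.5, 1) progress prior
places roughly a third of cells there, capping whole-population ARI near
0.61 even for a perfect embedding.

## 9. Numerical core

The networks run on a small reverse-mode automatic-differentiation core
over numpy arrays (broadcast arithmetic, matmul, the needed
nonlinearities, reductions, indexing, log-gamma), with Adam/AdamW,
batchnorm, dropout, and spectral normalization implemented on top. The
hyperparameter search uses scikit-learn's Gaussian process; compositions,
clustering, and tests use scikit-bio, scikit-learn, and scipy.

## 10. Scope and limitations

- Problem sizes throughout (hundreds to thousands of cells, hundreds of
  features) are desk-scale choices; the method's published behavior at
  two orders of magnitude more data is not reproduced here.
- At desk scale the MI regularizer's marginal effect on the
  repeatability of technical-effect estimates is small: with a few
  hundred training steps the critic remains far from the constrained
  Donsker–Varadhan optimum while the annealed ELBO already pins most of
  the technical channel. The regularization machinery is exercised and
  verified mechanically (the critic trains; large weights change the
  solution), but the large fold-reductions in across-seed variance seen
  at full scale should not be expected from the bundled benchmarks.
- The tuner runs in-process; distributed brokers are out of scope.
- The RP model handles one gene at a time; genome-scale batching and
  sequence-based motif scanning are out of scope.
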