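"""The CODAL generative distribution.

Cells are Dirichlet-distributed mixtures of topics.  A linear decoder maps
the topic composition Z to per-gene biological log-rates lambda (batch-
normalized product Z beta); a small neural network on (Z, C) produces
zero-centered technical effects t; softmax(lambda + t) gives the
compositional rate rho, which parameterizes a negative binomial (RNA,
with a latent per-cell size factor) or multinomial (ATAC) likelihood.

Removing t and the covariates from the composed rate yields the
disentangled, batch-free expression prediction rho-bar.
"""
from __future__ import annotations

import numpy as np
from scipy.special import gammaln as _gammaln

from ._autodiff import Tensor, as_tensor, concat, softmax
from .nn import BatchNorm1d, Dropout, Linear, Module, Parameter

__all__ = ["TopicPrior", "BiologicalDecoder", "TechnicalEffectNet",
           "compose_rates", "nb_log_likelihood", "multinomial_log_likelihood",
           "disentangled_rates", "sample_generative"]


class TopicPrior(Module):
    """Dirichlet topic prior with a Gamma hyperprior on the pseudocounts.

    alpha_d ~ Gamma(2, 2 N_topics / I) so that E[sum_d alpha_d] equals the
    total-pseudocount budget I (default 50, independent of N_topics).
    alpha is learned by MAP through its log-parameterization.
    """

    def __init__(self, n_topics: int, total_pseudocounts: float = 50.0):
        super().__init__()
        self.n_topics = n_topics
        self.total_pseudocounts = total_pseudocounts
        init = total_pseudocounts / n_topics
        self.log_alpha = Parameter(np.full(n_topics, np.log(init)))

    @property
    def alpha(self) -> np.ndarray:
        return np.exp(self.log_alpha.data)

    def log_hyperprior(self) -> Tensor:
        """Gamma(2, 2K/I) log-density of alpha plus the log-Jacobian of the
        log parameterization (MAP in log-alpha space)."""
        rate = 2.0 * self.n_topics / self.total_pseudocounts
        shape = 2.0
        la = self.log_alpha
        alpha = la.exp()
        # log p(alpha) + log |d alpha / d log alpha|
        return ((shape - 1.0) * la - alpha * rate + la).sum() \
            + Tensor(self.n_topics * (shape * np.log(rate) - _gammaln(shape)))

    def laplace_moments(self):
        """Mean/variance of the softmax-basis Laplace approximation to
        Dirichlet(alpha): mu_k = log a_k - mean_l log a_l,
        sigma2_k = (1 - 2/K)/a_k + (1/K^2) sum_l 1/a_l."""
        alpha = self.alpha
        k = self.n_topics
        mu = np.log(alpha) - np.mean(np.log(alpha))
        sigma2 = (1.0 - 2.0 / k) / alpha + np.sum(1.0 / alpha) / k**2
        return mu, sigma2

    def laplace_moments_tensor(self):
        la = self.log_alpha
        k = self.n_topics
        mu = la - la.mean()
        inv = (-la).exp()
        sigma2 = inv * (1.0 - 2.0 / k) + inv.sum() * (1.0 / k**2)
        return mu, sigma2

    def sample(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        return rng.dirichlet(self.alpha, size=n_cells)


class BiologicalDecoder(Module):
    """lambda = batchnorm(dropout(Z) beta): linear topic->gene decoder with
    per-gene standardization and affine rescale (gamma_b, b_b)."""

    def __init__(self, n_topics: int, n_features: int, dropout: float = 0.05,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.beta = Parameter(rng.normal(0.0, 0.1, size=(n_topics, n_features)))
        self.bn = BatchNorm1d(n_features)
        self.dropout = Dropout(dropout)

    def __call__(self, Z, rng: np.random.Generator | None = None) -> Tensor:
        Z = as_tensor(Z)
        if self.training and rng is None:
            raise ValueError("training-mode decoding needs an rng for dropout")
        h = self.dropout(Z, rng) if self.training else Z
        return self.bn(h @ self.beta)


class TechnicalEffectNet(Module):
    """t = gamma_t * zscore(h_phi(Z ++ C)): one 32-unit hidden layer, output
    zero-centered per gene then rescaled by the technical-variance vector.

    In training mode the whole technical-effect row of a cell is zeroed by
    a Bernoulli(corruption_prob) draw (per-cell corruption unit); optionally
    the corruption can be applied per entry instead.
    """

    def __init__(self, n_topics: int, n_covariates: int, n_features: int,
                 hidden: int = 32, corruption_prob: float = 0.05,
                 dropout: float = 0.05, per_cell_corruption: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_covariates = n_covariates
        self.corruption_prob = corruption_prob
        self.per_cell_corruption = per_cell_corruption
        self.input_dropout = Dropout(dropout)
        self.hidden_dropout = Dropout(dropout)
        self.fc0 = Linear(n_topics + n_covariates, hidden, rng)
        self.bn0 = BatchNorm1d(hidden)
        self.fc1 = Linear(hidden, n_features, rng)
        self.center = BatchNorm1d(n_features, affine=False)
        self.gamma_t = Parameter(np.ones(n_features))

    def __call__(self, Z, C, rng: np.random.Generator | None = None) -> Tensor:
        Z, C = as_tensor(Z), as_tensor(C)
        if C.shape[1] != self.n_covariates:
            raise ValueError(
                f"covariate width {C.shape[1]} != expected {self.n_covariates}")
        if self.training and rng is None:
            raise ValueError("training-mode forward needs an rng")
        zin = self.input_dropout(Z, rng) if self.training else Z
        h = self.fc0(concat([zin, C], axis=1))
        h = self.bn0(h).relu()
        if self.training:
            h = self.hidden_dropout(h, rng)
        t_raw = self.fc1(h)
        t = self.center(t_raw) * self.gamma_t
        if self.training and self.corruption_prob > 0:
            if self.per_cell_corruption:
                keep = (rng.random(Z.shape[0]) >= self.corruption_prob)
                mask = np.repeat(keep[:, None], t.shape[1], axis=1).astype(float)
            else:
                mask = (rng.random(t.shape) >= self.corruption_prob).astype(float)
            t = t * Tensor(mask)
        return t


def compose_rates(lam, t) -> Tensor:
    """Row-stochastic compositional rate rho = softmax(lambda + t)."""
    lam, t = as_tensor(lam), as_tensor(t)
    if lam.shape != t.shape:
        raise ValueError("lambda and t must have the same shape")
    return softmax(lam + t, axis=1)


def nb_log_likelihood(X, mu, theta) -> Tensor:
    """Negative binomial log-pmf summed over features, per cell.

    Parameterized by mean mu and inverse-dispersion theta:
    Var = mu + mu^2 / theta.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("negative counts")
    mu, theta = as_tensor(mu), as_tensor(theta)
    Xt = Tensor(X)
    lgx = Tensor(_gammaln(X + 1.0))
    ll = ((Xt + theta).gammaln() - theta.gammaln() - lgx
          + theta * (theta.log() - (theta + mu).log())
          + Xt * (mu.log() - (theta + mu).log()))
    return ll.sum(axis=1)


def multinomial_log_likelihood(X, rho, include_coefficient: bool = False) -> Tensor:
    """Multinomial log-pmf of binary accessibility rows given rate rho.

    The multinomial coefficient is constant in the parameters and omitted
    from the training objective by default.
    """
    X = np.asarray(X, dtype=float)
    depth = X.sum(axis=1)
    if (depth == 0).any():
        raise ValueError("zero-depth cell")
    rho = as_tensor(rho)
    ll = (Tensor(X) * rho.log()).sum(axis=1)
    if include_coefficient:
        coef = _gammaln(depth + 1.0) - _gammaln(X + 1.0).sum(axis=1)
        ll = ll + Tensor(coef)
    return ll


def disentangled_rates(Z_bar, decoder: BiologicalDecoder) -> np.ndarray:
    """Batch-free compositional prediction rho_bar = softmax(lambda_bar).

    Uses the decoder in evaluation mode (running batchnorm statistics); no
    covariate enters, so the output is identical across batch labels by
    construction.
    """
    was_training = decoder.training
    decoder.eval()
    lam = decoder(np.asarray(Z_bar)).data
    if was_training:
        decoder.train()
    e = np.exp(lam - lam.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def sample_generative(decoder: BiologicalDecoder, technet: TechnicalEffectNet,
                      prior: TopicPrior, C: np.ndarray, theta: np.ndarray,
                      depth_logmean: float = np.log(2000.0),
                      depth_logsd: float = 0.3,
                      modality: str = "RNA", seed: int = 0,
                      Z: np.ndarray | None = None):
    """Forward-sample counts from the generative model.

    Standardization statistics are taken from the sampled population itself
    (training-mode batchnorm on the full sample), so the draw is a
    self-consistent realization of the model.  Returns (counts, Z, lambda, t).
    """
    rng = np.random.default_rng(seed)
    n_cells = C.shape[0]
    if Z is None:
        Z = prior.sample(n_cells, rng)
    # population statistics, no dropout/corruption: temporarily switch off
    dec_p, tech_p = decoder.dropout.p, technet.corruption_prob
    in_p, hid_p = technet.input_dropout.p, technet.hidden_dropout.p
    decoder.dropout.p = 0.0
    technet.corruption_prob = 0.0
    technet.input_dropout.p = technet.hidden_dropout.p = 0.0
    decoder.train()
    technet.train()
    try:
        lam = decoder(Z, rng).data
        t = technet(Z, C, rng).data
    finally:
        decoder.dropout.p = dec_p
        technet.corruption_prob = tech_p
        technet.input_dropout.p, technet.hidden_dropout.p = in_p, hid_p
    logits = lam + t
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    rho = e / e.sum(axis=1, keepdims=True)
    if modality == "RNA":
        n = rng.lognormal(depth_logmean, depth_logsd, size=n_cells)
        mu = n[:, None] * rho
        # NB draw via Gamma-Poisson mixture
        lam_gp = rng.gamma(shape=theta[None, :], scale=mu / theta[None, :])
        counts = rng.poisson(lam_gp)
    else:
        n = np.maximum(rng.lognormal(depth_logmean, depth_logsd,
                                     size=n_cells).astype(int), 1)
        counts = np.vstack([rng.multinomial(n[i], rho[i])
                            for i in range(n_cells)])
        counts = (counts > 0).astype(int)
    return counts, Z, lam, t
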