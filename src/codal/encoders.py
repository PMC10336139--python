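"""Amortized variational posterior q(Z | X, C) and the compositional latent space.

The expression encoder consumes deviance residuals (plus covariates) through
two 512-unit feed-forward/batchnorm/ReLU/dropout blocks and outputs mean and
log-variance heads for each topic plus two heads for the latent size factor.
The accessibility encoder is a Deep Averaging Network over peak embeddings
with a skip connection.  Gaussian samples in the softmax basis are mapped to
the simplex (the Laplace approximation to the Dirichlet), giving closed-form
KL to the topic prior.  Posterior-mean compositions are mapped to Euclidean
coordinates with the isometric log-ratio transform for kNN-graph analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from skbio.stats.composition import ilr
from sklearn.neighbors import NearestNeighbors

from ._autodiff import Tensor, as_tensor, concat, softmax
from .generative import TopicPrior
from .nn import BatchNorm1d, Dropout, Linear, Module, Parameter

LOGVAR_CLAMP = 10.0

__all__ = ["PosteriorParams", "ExpressionEncoder", "AccessibilityEncoder",
           "reparameterized_sample", "kl_to_prior", "size_factor_kl",
           "posterior_mean_topics", "ilr_coordinates", "ilr_knn"]


@dataclass
class PosteriorParams:
    topic_mu: Tensor
    topic_logvar: Tensor
    depth_mu: Tensor | None = None      # RNA only: LogNormal posterior of n_i
    depth_logvar: Tensor | None = None

    def detach(self) -> "PosteriorParams":
        return PosteriorParams(
            self.topic_mu.detach(), self.topic_logvar.detach(),
            None if self.depth_mu is None else self.depth_mu.detach(),
            None if self.depth_logvar is None else self.depth_logvar.detach())


class ExpressionEncoder(Module):
    def __init__(self, n_genes: int, n_covariates: int, n_topics: int,
                 hidden: int = 512, dropout: float = 0.05,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_topics = n_topics
        self.fc0 = Linear(n_genes + n_covariates, hidden, rng)
        self.bn0 = BatchNorm1d(hidden)
        self.fc1 = Linear(hidden, hidden, rng)
        self.bn1 = BatchNorm1d(hidden)
        self.drop = Dropout(dropout)
        self.out = Linear(hidden, 2 * n_topics + 2, rng)
        self.bn_out = BatchNorm1d(2 * n_topics + 2)

    def __call__(self, residuals, C, rng=None) -> PosteriorParams:
        x = np.asarray(residuals, dtype=float)
        if not np.isfinite(x).all():
            raise ValueError("non-finite encoder input")
        h = concat([Tensor(x), as_tensor(np.asarray(C, dtype=float))], axis=1)
        h = self.bn0(self.fc0(h)).relu()
        if self.training:
            h = self.drop(h, rng)
        h = self.bn1(self.fc1(h)).relu()
        if self.training:
            h = self.drop(h, rng)
        out = self.bn_out(self.out(h))
        k = self.n_topics
        return PosteriorParams(
            topic_mu=out[:, :k],
            topic_logvar=out[:, k:2 * k].clip(-LOGVAR_CLAMP, LOGVAR_CLAMP),
            depth_mu=out[:, 2 * k],
            depth_logvar=out[:, 2 * k + 1].clip(-LOGVAR_CLAMP, LOGVAR_CLAMP))


class AccessibilityEncoder(Module):
    """Deep Averaging Network over the cell's accessible-peak set.

    v0 = mean of embedding rows over retained accessible peaks (training mode
    drops peaks at rate 1/20, resampling a cell's mask if everything drops);
    the hidden layer consumes v0 ++ C and a skip connection adds v0 back
    before the output layer.
    """

    def __init__(self, n_peaks: int, n_covariates: int, n_topics: int,
                 embed: int = 256, corruption_prob: float = 0.05,
                 dropout: float = 0.05, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_topics = n_topics
        self.corruption_prob = corruption_prob
        self.embedding = Parameter(rng.normal(0, np.sqrt(1.0 / embed),
                                              size=(n_peaks, embed)))
        self.fc1 = Linear(embed + n_covariates, embed, rng)
        self.bn1 = BatchNorm1d(embed)
        self.drop = Dropout(dropout)
        self.out = Linear(embed, 2 * n_topics, rng)
        self.bn_out = BatchNorm1d(2 * n_topics)

    def _averaging_matrix(self, X, rng) -> np.ndarray:
        X = sp.csr_matrix(X)
        M = (X > 0).astype(float).toarray()
        if self.training and self.corruption_prob > 0:
            for i in range(M.shape[0]):
                on = np.flatnonzero(M[i])
                for _ in range(5):
                    keep = on[rng.random(len(on)) >= self.corruption_prob]
                    if len(keep):
                        break
                else:
                    raise RuntimeError("all accessible peaks dropped repeatedly")
                row = np.zeros_like(M[i])
                row[keep] = 1.0
                M[i] = row
        sizes = M.sum(axis=1, keepdims=True)
        if (sizes == 0).any():
            raise ValueError("cell with no accessible peaks")
        return M / sizes

    def __call__(self, X, C, rng=None) -> PosteriorParams:
        M = self._averaging_matrix(X, rng)
        v0 = Tensor(M) @ self.embedding
        h = self.bn1(self.fc1(concat([v0, as_tensor(np.asarray(C, float))],
                                     axis=1))).relu()
        if self.training:
            h = self.drop(h, rng)
        out = self.bn_out(self.out(h + v0))
        k = self.n_topics
        return PosteriorParams(
            topic_mu=out[:, :k],
            topic_logvar=out[:, k:2 * k].clip(-LOGVAR_CLAMP, LOGVAR_CLAMP))


def reparameterized_sample(post: PosteriorParams,
                           rng: np.random.Generator) -> Tensor:
    """Z = softmax(mu + sigma * eps): a Laplace-approximate Dirichlet draw."""
    eps = rng.standard_normal(post.topic_mu.shape)
    gauss = post.topic_mu + (post.topic_logvar * 0.5).exp() * Tensor(eps)
    return softmax(gauss, axis=1)


def kl_to_prior(post: PosteriorParams, prior: TopicPrior) -> Tensor:
    """Closed-form Gaussian KL (per cell) between the diagonal posterior and
    the Laplace-approximated Dirichlet prior in the softmax basis."""
    mu_p, sigma2_p = prior.laplace_moments_tensor()
    mu, logvar = post.topic_mu, post.topic_logvar
    var = logvar.exp()
    kl = 0.5 * (sigma2_p.log() - logvar
                + (var + (mu - mu_p) ** 2) / sigma2_p - 1.0)
    return kl.sum(axis=1)


def size_factor_kl(post: PosteriorParams, observed_depth: np.ndarray,
                   prior_sd: float = 1.0) -> Tensor:
    """KL of the LogNormal size-factor posterior to its LogNormal prior
    centered at the observed log depth (Gaussian KL in log space)."""
    mu0 = Tensor(np.log(np.asarray(observed_depth, dtype=float)))
    var = post.depth_logvar.exp()
    return 0.5 * (Tensor(np.log(prior_sd**2)) - post.depth_logvar
                  + (var + (post.depth_mu - mu0) ** 2) / prior_sd**2 - 1.0)


def posterior_mean_topics(post: PosteriorParams, n_samples: int = 0,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Posterior-mean composition Z-bar: average of reparameterized softmax
    samples, or the zero-noise softmax(mu) when n_samples == 0."""
    mu = post.topic_mu.data
    if n_samples <= 0:
        e = np.exp(mu - mu.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)
    rng = rng or np.random.default_rng(0)
    acc = np.zeros_like(mu)
    for _ in range(n_samples):
        acc += reparameterized_sample(post, rng).data
    return acc / n_samples


def ilr_coordinates(Z_bar: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Isometric log-ratio coordinates (Helmert orthonormal basis) of the
    composition matrix; dimension n_topics - 1."""
    Z = np.maximum(np.asarray(Z_bar, dtype=float), floor)
    Z = Z / Z.sum(axis=1, keepdims=True)
    return ilr(Z)


def ilr_knn(Z_bar: np.ndarray, k: int):
    """kNN graph on ILR coordinates under Manhattan (L1) distance.

    Returns (coords, adjacency) with a sparse boolean kNN adjacency
    (self excluded).
    """
    coords = ilr_coordinates(Z_bar)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1, metric="manhattan").fit(coords)
    graph = nn.kneighbors_graph(coords, mode="connectivity")
    graph = graph.tolil()
    graph.setdiag(0)
    return coords, graph.tocsr()
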