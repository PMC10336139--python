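"""MINE critic under a 1-Lipschitz spectral-norm contract.

The critic T(lambda, t) scores concatenated (biological rate, technical
effect) rows; its Donsker-Varadhan lower bound on mutual information
(paired mean minus log of the full cross-pair mean of exp scores) enters
the training objective, and the Kantorovich-dual Wasserstein form is kept
as a diagnostic.  Spectral normalization (one persistent-vector power
iteration per weight matrix after each update) bounds the network's
Lipschitz constant, which stabilizes the estimate.
"""
from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, as_tensor, concat, logsumexp
from .nn import Adam, Dropout, Linear, Module

__all__ = ["Critic", "spectral_normalize", "mine_estimate",
           "wasserstein_bound", "update_critic"]


class Critic(Module):
    """T_theta: R^{2G} -> R with one 64-unit hidden layer (two ReLU blocks)."""

    def __init__(self, n_features: int, hidden: int = 64,
                 input_dropout: float = 0.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fc0 = Linear(2 * n_features, hidden, rng)
        self.fc1 = Linear(hidden, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng)
        self.drop = Dropout(input_dropout)
        # persistent power-iteration vectors
        self._pi = {name: np.random.default_rng(1).standard_normal(
            getattr(self, name).weight.shape[1])
            for name in ("fc0", "fc1", "fc2")}
        spectral_normalize(self, n_iter=20)

    def score_matrix(self, lam, t, rng=None) -> Tensor:
        """All m x m cross-pair scores T(lambda_i, t_j).

        The first layer acts additively on the concatenated input, so the
        m^2 pairs are scored in the 64-dim hidden space instead of
        materializing m^2 rows of width 2G.
        """
        lam, t = as_tensor(lam), as_tensor(t)
        if lam.shape[1] != t.shape[1]:
            raise ValueError("lambda/t feature widths differ")
        m, g = lam.shape
        if self.training and self.drop.p > 0:
            lam = self.drop(lam, rng)
            t = self.drop(t, rng)
        W0, b0 = self.fc0.weight, self.fc0.bias
        a = lam @ W0[:g]          # m x hidden
        b = t @ W0[g:]            # m x hidden
        hdim = a.shape[1]
        h0 = (a.reshape(m, 1, hdim) + b.reshape(1, m, hdim) + b0).relu()
        h1 = self.fc1(h0.reshape(m * m, hdim)).relu()
        return self.fc2(h1).reshape(m, m)

    def __call__(self, lam_row, t_row, rng=None) -> Tensor:
        lam = np.atleast_2d(np.asarray(lam_row, dtype=float))
        t = np.atleast_2d(np.asarray(t_row, dtype=float))
        return self.score_matrix(lam, t, rng=rng).reshape(1)


def spectral_normalize(critic: Critic, n_iter: int | None = None,
                       eps: float = 1e-12, tol: float = 1e-7,
                       max_iter: int = 100) -> Critic:
    """Divide each weight matrix by its leading singular value.

    Power iteration with persistent (warm-started) vectors; by default it
    iterates until the singular-value estimate stabilizes to relative
    tolerance ``tol`` (at least one step per call), which keeps the
    post-normalization spectral norm within 1e-3 of one even right after
    an optimizer step.  Biases are untouched (they do not affect the
    Lipschitz constant).
    """
    for name in ("fc0", "fc1", "fc2"):
        W = getattr(critic, name).weight.data
        v = critic._pi[name]
        sigma_prev = -np.inf
        steps = max_iter if n_iter is None else max(1, n_iter)
        for it in range(steps):
            u = W @ v
            u = u / (np.linalg.norm(u) + eps)
            v = W.T @ u
            v = v / (np.linalg.norm(v) + eps)
            sigma = float(u @ W @ v)
            if n_iter is None and abs(sigma - sigma_prev) <= tol * abs(sigma):
                break
            sigma_prev = sigma
        critic._pi[name] = v
        if sigma > eps:
            getattr(critic, name).weight.data = W / sigma
    return critic


def mine_estimate(lam, t, critic: Critic, rng=None) -> Tensor:
    """Donsker-Varadhan bound: mean_i T(l_i,t_i) - log mean_{ij} e^{T(l_i,t_j)}."""
    lam, t = as_tensor(lam), as_tensor(t)
    m = lam.shape[0]
    if m < 2:
        raise ValueError("MINE needs a batch of at least 2")
    S = critic.score_matrix(lam, t, rng=rng)
    paired = Tensor(np.eye(m))
    joint = (S * paired).sum() * (1.0 / m)
    cross = logsumexp(S.reshape(m * m), axis=0) - np.log(m * m)
    return joint - cross


def wasserstein_bound(lam, t, critic: Critic) -> float:
    """Kantorovich-dual diagnostic:
    mean_i T(l_i,t_i) - mean_i log sum_j e^{T(l_i,t_j)}."""
    lam, t = as_tensor(lam), as_tensor(t)
    m = lam.shape[0]
    if m < 2:
        return 0.0
    S = critic.score_matrix(lam, t).data
    paired = np.trace(S) / m
    from scipy.special import logsumexp as _lse
    return float(paired - _lse(S, axis=1).mean())


def update_critic(critic: Critic, lam, t, optimizer: Adam | None = None,
                  lr: float = 1e-4, rng=None) -> float:
    """One gradient-ascent step on the MINE bound followed by spectral
    normalization.  Inputs must be detached from the topic-model graph."""
    if optimizer is None:
        optimizer = Adam(critic.parameters(), lr=lr)
    lam = as_tensor(lam).detach()
    t = as_tensor(t).detach()
    est = mine_estimate(lam.data, t.data, critic, rng=rng)
    optimizer.zero_grad()
    est.backward()
    # ascent: flip gradient sign
    for p in critic.parameters():
        if p.grad is not None:
            p.grad = -p.grad
    optimizer.step()
    spectral_normalize(critic)
    return est.item()
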