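"""The CODAL topic-model estimator and its training loop.

``CodalTopicModel`` is a scikit-learn-style estimator: ``fit(X, C)`` runs
cyclical annealed minibatch gradient ascent on the objective

    V-hat = reconstruction - eps1 * KL - eps2 * mi_weight * MINE,

with the KL weight following a step-up cyclic schedule and the MINE weight
the plain cyclic schedule (three cycles), AdamW with a one-cycle learning
rate/momentum policy on the topic-model parameters, and Adam plus spectral
normalization on the MINE critic.  ``transform`` returns posterior-mean
topic compositions; ``predict_rates`` returns the disentangled (batch-free)
compositional expression; ``technical_effects`` the estimated distortions.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from ._autodiff import Tensor
from . import data as data_mod
from .data import CountMatrix, CovariateDesign, MinibatchStream, load_cached
from .encoders import (AccessibilityEncoder, ExpressionEncoder, kl_to_prior,
                       posterior_mean_topics, reparameterized_sample,
                       size_factor_kl)
from .generative import (BiologicalDecoder, TechnicalEffectNet, TopicPrior,
                         compose_rates, disentangled_rates,
                         multinomial_log_likelihood, nb_log_likelihood)
from .mi import Critic, mine_estimate, spectral_normalize, update_critic
from .nn import Adam, AdamW, Parameter

logger = logging.getLogger(__name__)

__all__ = ["CodalTopicModel", "anneal_weights", "one_cycle", "lr_range_test"]


def anneal_weights(s: float, s_total: float, n_cycles: int = 3):
    """Objective term weights at step s: (eps1, eps2).

    eps2 follows the cyclic schedule r(s) = min(1, 2 mod(s, L)/L) with cycle
    length L = s_total/n_cycles; eps1 follows the step-up cyclic schedule
    (1/n_cycles) * ceil(s/L) * r(s), whose cycle maxima ramp 1/3, 2/3, 1.
    """
    L = s_total / n_cycles
    r = min(1.0, 2.0 * np.mod(s, L) / L)
    r_stepup = np.ceil(s / L) / n_cycles * r
    return float(r_stepup), float(r)


def one_cycle(s: float, s_total: float, lr_min: float, lr_max: float,
              mom_min: float = 0.85, mom_max: float = 0.95,
              pct_up: float = 0.3):
    """One-cycle policy: cosine ramp of the learning rate from lr_min up to
    lr_max over the first pct_up of training then back down, with momentum
    annealed inversely between mom_max and mom_min."""
    frac = np.clip(s / max(s_total, 1), 0.0, 1.0)
    if frac < pct_up:
        u = frac / pct_up
    else:
        u = 1.0 - (frac - pct_up) / (1.0 - pct_up)
    cos_u = 0.5 * (1 - np.cos(np.pi * u))
    lr = lr_min + (lr_max - lr_min) * cos_u
    mom = mom_max - (mom_max - mom_min) * cos_u
    return float(lr), float(mom)


def _coerce_inputs(X, C):
    if isinstance(X, MinibatchStream):
        counts, cov = load_cached(X)
        manifest = X.manifest()
        modality = manifest["modality"]
        schema = manifest["schema"]
        return counts, cov, modality, schema
    if isinstance(X, CountMatrix):
        counts, modality = X.counts, X.modality
    else:
        counts, modality = sp.csr_matrix(X), "RNA"
    if C is None:
        cov, schema = np.zeros((counts.shape[0], 0)), []
    elif isinstance(C, CovariateDesign):
        cov, schema = C.matrix, C.schema
    else:
        cov, schema = np.asarray(C, dtype=float), []
    return counts, cov, modality, schema


class CodalTopicModel(BaseEstimator):
    """Mutual-information-regularized topic model of multi-batch counts.

    Parameters
    ----------
    n_topics : latent dimensionality of the biological state.
    dropout : decoder dropout rate (regularization; tuned in [0.05, 0.1]).
    mi_weight : multiplier on the MI regularization term; 0 recovers a
        plain annealed topic-model VAE.
    epochs, batch_size, n_cycles : training schedule; s_total =
        epochs * ceil(N/batch_size).
    lr_max : peak one-cycle learning rate; None triggers the range test.
    encoder_hidden : width of the expression-encoder blocks (ATAC uses
        embed = encoder_hidden // 2 per the Deep Averaging Network design).
    """

    def __init__(self, n_topics: int = 8, dropout: float = 0.05,
                 mi_weight: float = 1.0, epochs: int = 24,
                 batch_size: int = 128, n_cycles: int = 3,
                 lr_max: float | None = None, critic_lr: float = 1e-4,
                 weight_decay: float = 0.01, total_pseudocounts: float = 50.0,
                 encoder_hidden: int = 512, technical_hidden: int = 32,
                 corruption_prob: float = 0.05,
                 per_cell_corruption: bool = True, grad_clip: float = 10.0,
                 seed: int = 0):
        self.n_topics = n_topics
        self.dropout = dropout
        self.mi_weight = mi_weight
        self.epochs = epochs
        self.batch_size = batch_size
        self.n_cycles = n_cycles
        self.lr_max = lr_max
        self.critic_lr = critic_lr
        self.weight_decay = weight_decay
        self.total_pseudocounts = total_pseudocounts
        self.encoder_hidden = encoder_hidden
        self.technical_hidden = technical_hidden
        self.corruption_prob = corruption_prob
        self.per_cell_corruption = per_cell_corruption
        self.grad_clip = grad_clip
        self.seed = seed

    # ------------------------------------------------------------------
    def _build(self, n_features: int, n_covariates: int, modality: str,
               rng: np.random.Generator):
        self.prior_ = TopicPrior(self.n_topics, self.total_pseudocounts)
        self.decoder_ = BiologicalDecoder(self.n_topics, n_features,
                                          dropout=self.dropout, rng=rng)
        self.technical_net_ = TechnicalEffectNet(
            self.n_topics, n_covariates, n_features,
            hidden=self.technical_hidden,
            corruption_prob=self.corruption_prob,
            per_cell_corruption=self.per_cell_corruption, rng=rng)
        if modality == "RNA":
            self.encoder_ = ExpressionEncoder(
                n_features, n_covariates, self.n_topics,
                hidden=self.encoder_hidden, rng=rng)
            self.log_theta_ = Parameter(np.zeros(n_features))
        else:
            self.encoder_ = AccessibilityEncoder(
                n_features, n_covariates, self.n_topics,
                embed=max(self.encoder_hidden // 2, 16), rng=rng)
            self.log_theta_ = None
        self.critic_ = Critic(n_features, rng=rng)

    def _parameters(self):
        params = (self.prior_.parameters() + self.decoder_.parameters()
                  + self.technical_net_.parameters()
                  + self.encoder_.parameters())
        if self.log_theta_ is not None:
            params.append(self.log_theta_)
        return params

    def _encoder_input(self, counts: np.ndarray) -> np.ndarray:
        if self.modality_ == "RNA":
            depth = counts.sum(axis=1, keepdims=True)
            mu = depth * self.pi_hat_[None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                xlogx = np.where(counts > 0, counts * np.log(counts / mu), 0.0)
            dev = 2.0 * (xlogx - (counts - mu))
            return np.sign(counts - mu) * np.sqrt(np.maximum(dev, 0.0))
        return counts

    def _objective(self, counts: np.ndarray, cov: np.ndarray, eps1: float,
                   eps2: float, rng: np.random.Generator,
                   training: bool = True):
        """Minibatch objective graph; returns (objective, components)."""
        enc_in = self._encoder_input(counts)
        post = self.encoder_(enc_in, cov, rng=rng)
        Z = reparameterized_sample(post, rng)
        lam = self.decoder_(Z, rng=rng)
        t = self.technical_net_(Z, cov, rng=rng)
        rho = compose_rates(lam, t)
        kl = kl_to_prior(post, self.prior_)
        if self.modality_ == "RNA":
            depth = counts.sum(axis=1)
            eps_n = rng.standard_normal(len(depth))
            n_i = (post.depth_mu + Tensor(np.log(depth))
                   + (post.depth_logvar * 0.5).exp() * Tensor(eps_n)).exp()
            theta = self.log_theta_.exp()
            mu = n_i.reshape(-1, 1) * rho
            recon = nb_log_likelihood(counts, mu, theta)
            kl = kl + size_factor_kl(
                PostShim(post.depth_mu + Tensor(np.log(depth)),
                         post.depth_logvar), depth)
        else:
            recon = multinomial_log_likelihood(counts, rho)
        mine = mine_estimate(lam, t, self.critic_) if self.mi_weight else None
        obj = recon.mean() - eps1 * kl.mean()
        alpha_prior = 0.0
        if training:
            # MAP contribution of the Gamma hyperprior on alpha, per cell
            prior_term = self.prior_.log_hyperprior() * (eps1 / self.n_cells_)
            obj = obj + prior_term
            alpha_prior = prior_term.item()
        mine_val = 0.0
        if mine is not None:
            obj = obj - (eps2 * self.mi_weight) * mine
            mine_val = mine.item()
        comps = {"recon": recon.mean().item(), "kl": kl.mean().item(),
                 "mine": mine_val, "alpha_prior": alpha_prior}
        return obj, (lam, t), comps

    # ------------------------------------------------------------------
    def fit(self, X, C=None, rung_callback=None):
        """Train the model.

        ``rung_callback(epoch, model)`` is invoked after every epoch; a
        False return stops training early (used for trial pruning by the
        hyperparameter tuner).
        """
        counts, cov, modality, schema = _coerce_inputs(X, C)
        counts = sp.csr_matrix(counts)
        self.modality_ = modality
        self.schema_ = schema
        n, g = counts.shape
        self.n_cells_, self.n_features_ = n, g
        rng = np.random.default_rng(self.seed)
        dense = np.asarray(counts.todense(), dtype=float)
        if modality == "ATAC":
            dense = (dense > 0).astype(float)
        self.pi_hat_ = dense.sum(axis=0) / dense.sum()
        self._build(g, cov.shape[1], modality, rng)

        m = min(self.batch_size, n)
        steps_per_epoch = int(np.ceil(n / m))
        s_total = self.epochs * steps_per_epoch
        lr_max = self.lr_max
        if lr_max is None:
            lr_max = lr_range_test(self, dense, cov, rng)[1]
        lr_min = lr_max / 25.0

        opt = AdamW(self._parameters(), lr=lr_min,
                    weight_decay=self.weight_decay)
        critic_opt = Adam(self.critic_.parameters(), lr=self.critic_lr)
        self.history_ = []
        s = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, m):
                idx = order[lo:lo + m]
                if len(idx) < 2:
                    continue
                s += 1
                lr, mom = one_cycle(s, s_total, lr_min, lr_max)
                opt.lr, opt.betas[0] = lr, mom
                eps1, eps2 = anneal_weights(s, s_total, self.n_cycles)
                batch_counts, batch_cov = dense[idx], cov[idx]
                obj, (lam, t), comps = self._objective(
                    batch_counts, batch_cov, eps1, eps2, rng)
                opt.zero_grad()
                (-obj).backward()
                total_norm = opt.clip_grad_norm(self.grad_clip)
                if not np.isfinite(obj.item()):
                    raise FloatingPointError(
                        f"NaN objective at step {s}: {comps}")
                opt.step()
                if self.mi_weight:
                    update_critic(self.critic_, lam.data, t.data,
                                  optimizer=critic_opt, rng=rng)
                self.history_.append(
                    {"step": s, "eps1": eps1, "eps2": eps2, "lr": lr,
                     "objective": obj.item(), "grad_norm": float(total_norm),
                     **comps})
            if rung_callback is not None:
                keep_going = rung_callback(epoch + 1, self)
                if keep_going is False:
                    break
        self._finalize_batchnorm(dense, cov)
        self._set_eval()
        self.beta_ = self.decoder_.beta.data.copy()
        self.alpha_ = self.prior_.alpha.copy()
        if self.log_theta_ is not None:
            self.dispersion_ = np.exp(self.log_theta_.data)
        return self

    def _finalize_batchnorm(self, dense: np.ndarray, cov: np.ndarray):
        """Replace running batchnorm statistics with exact population
        moments from one noise-free full-data pass.

        The generative contract standardizes Z-beta and the technical-net
        output per feature over the training population; the exponential
        running averages kept during minibatch training are noisy
        snapshots of that population, so they are recalibrated here.
        """
        from .nn import BatchNorm1d, Dropout

        saved = []
        for mod in (self.encoder_, self.decoder_, self.technical_net_):
            for sub in mod.modules():
                if isinstance(sub, BatchNorm1d):
                    saved.append((sub, "momentum", sub.momentum))
                    sub.momentum = 1.0
                elif isinstance(sub, Dropout):
                    saved.append((sub, "p", sub.p))
                    sub.p = 0.0
        corr = self.technical_net_.corruption_prob
        self.technical_net_.corruption_prob = 0.0
        acc_corr = getattr(self.encoder_, "corruption_prob", None)
        if acc_corr is not None:
            self.encoder_.corruption_prob = 0.0
        self._set_train()
        rng = np.random.default_rng(self.seed)
        try:
            post = self.encoder_(self._encoder_input(dense), cov, rng=rng)
            Z_bar = posterior_mean_topics(post)
            self.decoder_(Z_bar, rng=rng)
            self.technical_net_(Z_bar, cov, rng=rng)
        finally:
            for obj, attr, val in saved:
                setattr(obj, attr, val)
            self.technical_net_.corruption_prob = corr
            if acc_corr is not None:
                self.encoder_.corruption_prob = acc_corr

    def _set_eval(self):
        for mod in (self.encoder_, self.decoder_, self.technical_net_,
                    self.critic_, self.prior_):
            mod.eval()

    def _set_train(self):
        for mod in (self.encoder_, self.decoder_, self.technical_net_,
                    self.critic_, self.prior_):
            mod.train()

    # -- evaluation-mode views -----------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "beta_"):
            raise RuntimeError("model is not fitted")

    def _posterior(self, X, C=None):
        counts, cov, _, _ = _coerce_inputs(X, C)
        dense = np.asarray(sp.csr_matrix(counts).todense(), dtype=float)
        if self.modality_ == "ATAC":
            dense = (dense > 0).astype(float)
        self._set_eval()
        return self.encoder_(self._encoder_input(dense), cov), dense, cov

    def transform(self, X, C=None, n_samples: int = 0) -> np.ndarray:
        """Posterior-mean topic compositions Z-bar (cells x topics)."""
        self._check_fitted()
        post, _, _ = self._posterior(X, C)
        return posterior_mean_topics(
            post, n_samples, np.random.default_rng(self.seed))

    def fit_transform(self, X, C=None):
        return self.fit(X, C).transform(X, C)

    def predict_rates(self, X, C=None) -> np.ndarray:
        """Disentangled compositional rates rho-bar (no covariate enters)."""
        self._check_fitted()
        return disentangled_rates(self.transform(X, C), self.decoder_)

    def biological_rates(self, X, C=None) -> np.ndarray:
        """Eval-mode biological log-rates lambda-bar."""
        self._check_fitted()
        Zbar = self.transform(X, C)
        self.decoder_.eval()
        return self.decoder_(Zbar).data

    def technical_effects(self, X, C=None) -> np.ndarray:
        """Eval-mode technical-effect estimates t-hat."""
        self._check_fitted()
        post, _, cov = self._posterior(X, C)
        Zbar = posterior_mean_topics(post)
        self.technical_net_.eval()
        return self.technical_net_(Zbar, cov).data

    def softmax_denominator(self, X, C=None) -> np.ndarray:
        """Per-cell kappa_i = sum_j exp(lambda_ij + t_ij) (eval mode)."""
        self._check_fitted()
        lam = self.biological_rates(X, C)
        t = self.technical_effects(X, C)
        return np.exp(lam + t).sum(axis=1)

    def size_factors(self, X, C=None) -> np.ndarray:
        """Posterior-mean latent read depths (RNA only)."""
        self._check_fitted()
        if self.modality_ != "RNA":
            raise ValueError("size factors are an RNA-model quantity")
        post, dense, _ = self._posterior(X, C)
        depth = dense.sum(axis=1)
        mu = post.depth_mu.data + np.log(depth)
        var = np.exp(post.depth_logvar.data)
        return np.exp(mu + 0.5 * var)

    def score(self, X, C=None, seed: int = 0) -> float:
        """CODAL objective (term weights 1) on held-out cells."""
        if not hasattr(self, "decoder_"):
            raise RuntimeError("model is not built")
        counts, cov, _, _ = _coerce_inputs(X, C)
        dense = np.asarray(sp.csr_matrix(counts).todense(), dtype=float)
        if self.modality_ == "ATAC":
            dense = (dense > 0).astype(float)
        self._set_eval()
        obj, _, _ = self._objective(dense, cov, 1.0, 1.0,
                                    np.random.default_rng(seed),
                                    training=False)
        return obj.item()


class PostShim:
    """Lightweight (depth_mu, depth_logvar) carrier for size_factor_kl."""

    def __init__(self, depth_mu, depth_logvar):
        self.depth_mu = depth_mu
        self.depth_logvar = depth_logvar


def lr_range_test(model: CodalTopicModel, dense: np.ndarray, cov: np.ndarray,
                  rng: np.random.Generator, lr_lo: float = 1e-6,
                  lr_hi: float = 1.0, n_steps: int = 40):
    """Geometric learning-rate sweep; returns (lr_min, lr_max).

    The loss trace over the sweep is exponentially smoothed; its descent
    from the small-lr plateau to its minimum is sigmoid-shaped, and the
    steepest improvement sits at the halfway point of that descent, so
    lr_max is the rate at which the smoothed loss first crosses the
    midpoint between plateau and minimum (stopping at the divergence
    heuristic: loss exceeding 2.5x its best).  lr_min = lr_max / 25.
    Falls back to (1e-3/25, 1e-3) when no stable descent is found.
    """
    n = dense.shape[0]
    m = min(model.batch_size, n)
    state = {p: p.data.copy() for p in model._parameters()}
    critic_state = {p: p.data.copy() for p in model.critic_.parameters()}
    lrs = np.geomspace(lr_lo, lr_hi, n_steps)
    losses = []
    opt = Adam(model._parameters(), lr=lr_lo)
    try:
        for lr in lrs:
            opt.lr = lr
            idx = rng.choice(n, size=m, replace=False)
            obj, _, _ = model._objective(dense[idx], cov[idx], 0.5, 0.5, rng)
            loss = -obj.item()
            if not np.isfinite(loss) or (losses and
                                         loss > 2.5 * np.min(losses)):
                break
            losses.append(loss)
            opt.zero_grad()
            (-obj).backward()
            opt.clip_grad_norm(model.grad_clip)
            opt.step()
    finally:
        for p, d in state.items():
            p.data = d
        for p, d in critic_state.items():
            p.data = d
    if len(losses) < 5:
        warnings.warn("no stable learning-rate region found; using defaults")
        return 1e-3 / 25.0, 1e-3
    sm = [losses[0]]
    for loss in losses[1:]:
        sm.append(0.7 * sm[-1] + 0.3 * loss)
    sm = np.array(sm)
    plateau = np.median(sm[:max(3, len(sm) // 4)])
    lo = sm.min()
    if plateau - lo <= 0:
        warnings.warn("no stable learning-rate region found; using defaults")
        return 1e-3 / 25.0, 1e-3
    midpoint = 0.5 * (plateau + lo)
    cross = int(np.argmax(sm <= midpoint))
    lr_max = float(lrs[cross])
    return lr_max / 25.0, lr_max
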