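"""Bayesian hyperparameter search with pruning-aware expected improvement.

The search is over H = (n_topics, dropout).  Trials are trained with
checkpoints ("rungs") after the 8th and 16th epoch plus the final epoch;
at intermediate rungs a trial in the bottom 50th percentile of previously
recorded scores is pruned.  A Gaussian-process surrogate (Matern nu=5/2)
is fitted on all (hyperparameters, rung) -> score tuples, and candidates
are ranked by EI_p: the classical expected improvement at the final rung
(with an exploration margin xi * f_best) multiplied by the probability of
surviving every intermediate rung's pruning threshold.  Running trials are
imputed at the mean completed score ("constant liar") so that batched
proposals spread out.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .data import stratified_split
from .model import CodalTopicModel

__all__ = ["TrialLedger", "Surrogate", "pruning_thresholds",
           "expected_improvement_pruned", "propose_next", "run_trial", "tune"]

DEFAULT_RUNG_EPOCHS = (8, 16, 24)


@dataclass
class TrialLedger:
    """History of hyperparameter trials feeding the GP surrogate."""

    trials: list = field(default_factory=list)
    rung_epochs: tuple = DEFAULT_RUNG_EPOCHS
    prune_quantile: float = 50.0

    @property
    def n_rungs(self) -> int:
        return len(self.rung_epochs)

    def add(self, H, scores, status: str) -> dict:
        scores = list(scores) + [None] * (self.n_rungs - len(scores))
        rec = {"H": tuple(H), "scores": scores, "status": status}
        self.trials.append(rec)
        return rec

    def scores_at_rung(self, r: int) -> np.ndarray:
        vals = [t["scores"][r] for t in self.trials
                if t["scores"][r] is not None]
        return np.array(vals, dtype=float)

    def best_final(self) -> float | None:
        """f*: max final-rung score among complete trials."""
        finals = [t["scores"][-1] for t in self.trials
                  if t["status"] == "complete" and t["scores"][-1] is not None]
        return max(finals) if finals else None

    def to_json(self) -> str:
        return json.dumps({"rung_epochs": list(self.rung_epochs),
                           "prune_quantile": self.prune_quantile,
                           "trials": [{"H": list(t["H"]),
                                       "scores": t["scores"],
                                       "status": t["status"]}
                                      for t in self.trials]})

    @classmethod
    def from_json(cls, text: str) -> "TrialLedger":
        d = json.loads(text)
        ledger = cls(rung_epochs=tuple(d["rung_epochs"]),
                     prune_quantile=d["prune_quantile"])
        for t in d["trials"]:
            ledger.trials.append({"H": tuple(t["H"]), "scores": t["scores"],
                                  "status": t["status"]})
        return ledger

    def save(self, path):
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "TrialLedger":
        return cls.from_json(Path(path).read_text())


def pruning_thresholds(ledger: TrialLedger) -> list:
    """q-th percentile of recorded scores at each intermediate rung
    (-inf where no score has been recorded: no pruning)."""
    out = []
    for r in range(ledger.n_rungs - 1):
        vals = ledger.scores_at_rung(r)
        out.append(float(np.percentile(vals, ledger.prune_quantile))
                   if len(vals) else -np.inf)
    return out


class Surrogate:
    """GP over (hyperparameters, rung) with a Matern-5/2 kernel.

    Inputs are min-max scaled to [0, 1] over the search box; sklearn's
    ``normalize_y`` standardizes the scores before fitting.
    """

    def __init__(self, topic_range, n_rungs: int,
                 dropout_range=(0.05, 0.1), seed: int = 0):
        self.topic_range = topic_range
        self.dropout_range = dropout_range
        self.n_rungs = n_rungs
        kernel = (ConstantKernel(1.0) * Matern(length_scale=0.3, nu=2.5)
                  + WhiteKernel(noise_level=1e-2))
        self.gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                           random_state=seed)
        self.fitted = False

    def _scale(self, H, r):
        lo, hi = self.topic_range
        dlo, dhi = self.dropout_range
        return np.array([(H[0] - lo) / max(hi - lo, 1),
                         (H[1] - dlo) / max(dhi - dlo, 1e-12),
                         r / max(self.n_rungs - 1, 1)])

    def fit(self, ledger: TrialLedger, liar_scores: list | None = None):
        X, y = [], []
        for t in ledger.trials:
            for r, s in enumerate(t["scores"]):
                if s is not None:
                    X.append(self._scale(t["H"], r))
                    y.append(s)
        for H, s in (liar_scores or []):
            X.append(self._scale(H, ledger.n_rungs - 1))
            y.append(s)
        if len(X) < 2:
            return self
        self.gp.fit(np.array(X), np.array(y))
        self.fitted = True
        return self

    def predict(self, H, r):
        mu, sd = self.gp.predict(self._scale(H, r).reshape(1, -1),
                                 return_std=True)
        return float(mu[0]), float(max(sd[0], 1e-9))


def expected_improvement_pruned(H, surrogate: Surrogate, thresholds,
                                f_star: float, xi: float = 0.1) -> float:
    """EI_p(H): survival through intermediate rungs times expected
    improvement over the margin-adjusted best score at the final rung."""
    survival = 1.0
    for r, thr in enumerate(thresholds):
        if np.isneginf(thr):
            continue
        mu, sd = surrogate.predict(H, r)
        survival *= norm.cdf(-(thr - mu) / sd)
    mu, sd = surrogate.predict(H, surrogate.n_rungs - 1)
    target = f_star + xi * abs(f_star)
    if sd <= 1e-9:
        ei = max(0.0, mu - target)
    else:
        z = (mu - target) / sd
        ei = (mu - target) * norm.cdf(z) + sd * norm.pdf(z)
    return float(survival * max(ei, 0.0))


def _random_H(topic_range, dropout_range, rng) -> tuple:
    return (int(rng.integers(topic_range[0], topic_range[1] + 1)),
            float(rng.uniform(*dropout_range)))


def propose_next(ledger: TrialLedger, topic_range, seed: int = 0,
                 n_candidates: int = 300, n_startup: int = 15,
                 dropout_range=(0.05, 0.1), xi: float = 0.1,
                 running: list | None = None) -> tuple:
    """Next hyperparameters: random during the startup phase, then the
    EI_p argmax over uniformly drawn candidates (constant-liar imputation
    for running trials)."""
    rng = np.random.default_rng(seed)
    done = [t for t in ledger.trials if t["status"] in ("complete", "pruned")]
    if len(done) < n_startup:
        return _random_H(topic_range, dropout_range, rng)
    f_star = ledger.best_final()
    if f_star is None:
        # bootstrap: best observed anywhere minus one sd
        allscores = np.concatenate([ledger.scores_at_rung(r)
                                    for r in range(ledger.n_rungs)
                                    if len(ledger.scores_at_rung(r))])
        f_star = float(allscores.max() - allscores.std())
    liar = None
    if running:
        finals = [t["scores"][-1] for t in ledger.trials
                  if t["status"] == "complete"]
        liar_val = float(np.mean(finals)) if finals else f_star
        liar = [(H, liar_val) for H in running]
    surrogate = Surrogate(topic_range, ledger.n_rungs,
                          dropout_range, seed=seed).fit(ledger, liar)
    if not surrogate.fitted:
        return _random_H(topic_range, dropout_range, rng)
    thresholds = pruning_thresholds(ledger)
    cands = [_random_H(topic_range, dropout_range, rng)
             for _ in range(n_candidates)]
    scores = [expected_improvement_pruned(H, surrogate, thresholds, f_star,
                                          xi) for H in cands]
    return cands[int(np.argmax(scores))]


def run_trial(H, train_data, test_data, ledger: TrialLedger,
              seed: int = 0, model_kwargs: dict | None = None):
    """Train one trial, scoring the CODAL objective on the held-out split at
    each rung and pruning below the current percentile threshold.

    Returns (trial record, fitted model or None when pruned).
    """
    X_train, C_train = train_data
    X_test, C_test = test_data
    n_topics, p_dropout = H
    kwargs = dict(model_kwargs or {})
    epochs = max(ledger.rung_epochs)
    model = CodalTopicModel(n_topics=int(n_topics), dropout=float(p_dropout),
                            epochs=epochs, seed=seed, **kwargs)
    thresholds = pruning_thresholds(ledger)
    scores: list = []
    state = {"pruned": False}
    rung_for_epoch = {e: r for r, e in enumerate(ledger.rung_epochs)}

    def callback(epoch, m):
        r = rung_for_epoch.get(epoch)
        if r is None:
            return True
        s = m.score(X_test, C_test, seed=seed)
        m._set_train()
        scores.append(s)
        if r < ledger.n_rungs - 1 and s < thresholds[r]:
            state["pruned"] = True
            return False
        return True

    try:
        model.fit(X_train, C_train, rung_callback=callback)
    except FloatingPointError:
        rec = ledger.add(H, scores=[], status="failed")
        return rec, None
    status = "pruned" if state["pruned"] else "complete"
    rec = ledger.add(H, scores=scores, status=status)
    return rec, (None if state["pruned"] else model)


def tune(X, C, topic_range, max_trials: int = 128, min_trials: int = 48,
         patience: int = 12, n_startup: int = 15, n_parallel: int = 5,
         split_ratio: float = 0.8, seed: int = 0,
         model_kwargs: dict | None = None, trainer=None,
         dropout_range=(0.05, 0.1), ledger: TrialLedger | None = None):
    """Full Bayesian tuning loop.

    Proposals are made in waves of up to ``n_parallel`` using constant-liar
    imputation and evaluated in-process.  Stops after ``min_trials`` once
    the best final score has not improved over the last ``patience``
    trials, or at ``max_trials``.  ``trainer(H, seed)`` may replace real
    training (it must return (scores per rung, model-or-None, status)).

    Returns (best_model, best_H, ledger).
    """
    rng = np.random.default_rng(seed)
    ledger = ledger or TrialLedger()
    if trainer is None:
        train_idx, test_idx = stratified_split(X, C, ratio=split_ratio,
                                               seed=seed)
        train_data = (X.subset(train_idx), C.subset(train_idx))
        test_data = (X.subset(test_idx), C.subset(test_idx))

        def trainer(H, trial_seed):
            thresholds_snapshot = pruning_thresholds(ledger)  # noqa: F841
            rec, model = run_trial(H, train_data, test_data, ledger,
                                   seed=trial_seed,
                                   model_kwargs=model_kwargs)
            return rec["scores"], model, rec["status"]

        trainer_records = True
    else:
        trainer_records = False

    best_model, best_H, best_score = None, None, -np.inf
    last_improvement = 0
    while len(ledger.trials) < max_trials:
        wave = min(n_parallel, max_trials - len(ledger.trials))
        running: list = []
        proposals = []
        for _ in range(wave):
            H = propose_next(ledger, topic_range,
                             seed=int(rng.integers(2**31)),
                             n_startup=n_startup,
                             dropout_range=dropout_range, running=running)
            proposals.append(H)
            running.append(H)
        for H in proposals:
            trial_seed = int(rng.integers(2**31))
            scores, model, status = trainer(H, trial_seed)
            if not trainer_records:
                ledger.add(H, scores=scores, status=status)
            n_done = len(ledger.trials)
            final = scores[-1] if (status == "complete" and scores) else None
            if final is not None and final > best_score:
                best_score, best_H, best_model = final, H, model
                last_improvement = n_done
            if (best_H is not None and n_done >= min_trials
                    and n_done - last_improvement >= patience):
                return best_model, best_H, ledger
    if best_H is None:
        raise RuntimeError("all trials failed")
    return best_model, best_H, ledger
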