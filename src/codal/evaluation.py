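"""Benchmark diagnostics: silhouette widths, per-gene disentanglement
correlation, across-model variance decomposition, topic matching, and the
MI-weight sweep experiment."""
from __future__ import annotations

import json
import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .encoders import ilr_coordinates
from .model import CodalTopicModel

__all__ = ["silhouette_widths", "disentanglement_correlation",
           "variance_decomposition", "match_topics", "mi_weight_sweep",
           "branch_ari"]


def silhouette_widths(coords: np.ndarray, labels, metric: str = "euclidean"):
    """Per-cell silhouette widths and their mean (ASW).

    Cells in singleton clusters are scored 0 with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 labels")
    singletons = set(uniq[counts < 2])
    if singletons:
        warnings.warn(f"singleton clusters scored 0: {sorted(map(str, singletons))}")
        keep = ~np.isin(labels, list(singletons))
        widths = np.zeros(len(labels))
        if len(np.unique(labels[keep])) >= 2:
            widths[keep] = silhouette_samples(coords[keep], labels[keep],
                                              metric=metric)
    else:
        widths = silhouette_samples(coords, labels, metric=metric)
    return widths, float(widths.mean())


def disentanglement_correlation(lam_hat: np.ndarray, t_hat: np.ndarray):
    """Per-gene Pearson correlation across cells between predicted
    biological rates and technical effects; summary = median |r|.

    Genes with a constant column get a NaN correlation and are excluded
    from the summary.
    """
    lam_hat = np.asarray(lam_hat, dtype=float)
    t_hat = np.asarray(t_hat, dtype=float)
    if lam_hat.shape != t_hat.shape:
        raise ValueError("shape mismatch")
    lc = lam_hat - lam_hat.mean(axis=0)
    tc = t_hat - t_hat.mean(axis=0)
    denom = lc.std(axis=0) * tc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (lc * tc).mean(axis=0) / denom, np.nan)
    summary = float(np.nanmedian(np.abs(r)))
    return r, summary


def variance_decomposition(stack: np.ndarray):
    """Law-of-total-variance split of repeated estimates.

    ``stack`` has shape (cells, genes, models).  Per gene:
    within  = mean over cells of the across-model variance (repeatability),
    between = variance across cells of the across-model mean,
    total   = within + between (identity holds to machine precision).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[2] < 2:
        raise ValueError("need a (cells, genes, models>=2) stack")
    within = stack.var(axis=2).mean(axis=0)
    between = stack.mean(axis=2).var(axis=0)
    total = within + between
    frac = float(within.sum() / max(total.sum(), 1e-300))
    return {"within": within, "between": between, "total": total,
            "within_fraction": frac}


def match_topics(beta_true: np.ndarray, beta_est: np.ndarray):
    """Hungarian topic matching by Pearson correlation of loadings.

    Loadings are standardized per gene (column) first: the decoder's
    per-gene batchnorm makes beta identifiable only up to a per-gene
    affine rescale.  Returns (permutation, matched correlations).
    """
    def colstd(b):
        return (b - b.mean(axis=0)) / (b.std(axis=0) + 1e-12)

    bt, be = colstd(np.asarray(beta_true)), colstd(np.asarray(beta_est))
    k = bt.shape[0]
    bt = (bt - bt.mean(axis=1, keepdims=True))
    be = (be - be.mean(axis=1, keepdims=True))
    bt /= np.linalg.norm(bt, axis=1, keepdims=True)
    be /= np.linalg.norm(be, axis=1, keepdims=True)
    corr = bt @ be.T
    ri, cj = linear_sum_assignment(-corr)
    return cj, corr[ri, cj]


def branch_ari(Z_bar: np.ndarray, branches, n_clusters: int | None = None,
               seed: int = 0) -> float:
    """Adjusted Rand index of k-means on ILR coordinates versus true
    branch labels (trajectory-quality proxy)."""
    branches = np.asarray(branches)
    k = n_clusters or len(np.unique(branches))
    coords = ilr_coordinates(Z_bar)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
    return float(adjusted_rand_score(branches, km.labels_))


def mi_weight_sweep(X, C, truth_branches, weights=(0.0, 0.5, 1.0, 2.0, 4.0,
                                                   8.0),
                    n_models: int = 10, seed: int = 0,
                    model_kwargs: dict | None = None) -> dict:
    """Train ``n_models`` seeds per MI weight on a fixed dataset and report
    variance decompositions of the technical-effect and biological-rate
    estimates plus a trajectory-quality proxy (branch ARI).

    Returns a JSON-serializable report; fold reductions are relative to
    weight 0.
    """
    kwargs = dict(model_kwargs or {})
    report = {"weights": list(weights), "per_weight": {}}
    stacks = {}
    for w in weights:
        t_stack, lam_stack, aris = [], [], []
        for rep in range(n_models):
            model = CodalTopicModel(mi_weight=w, seed=seed + rep,
                                    **kwargs).fit(X, C)
            lam_stack.append(model.biological_rates(X, C))
            t_stack.append(model.technical_effects(X, C))
            aris.append(branch_ari(model.transform(X, C), truth_branches,
                                   seed=seed))
        t_stack = np.stack(t_stack, axis=2)
        lam_stack = np.stack(lam_stack, axis=2)
        vd_t = variance_decomposition(t_stack)
        vd_l = variance_decomposition(lam_stack)
        stacks[w] = (lam_stack, t_stack)
        report["per_weight"][str(w)] = {
            "t_within": float(vd_t["within"].sum()),
            "t_within_fraction": vd_t["within_fraction"],
            "lambda_within": float(vd_l["within"].sum()),
            "lambda_within_fraction": vd_l["within_fraction"],
            "branch_ari_mean": float(np.mean(aris)),
            "branch_ari": [float(a) for a in aris]}
    base = report["per_weight"].get("0.0") or report["per_weight"].get("0")
    if base is not None:
        for w in weights:
            entry = report["per_weight"][str(w)]
            entry["t_within_fold_vs_0"] = (
                base["t_within"] / max(entry["t_within"], 1e-300))
    report["_stacks"] = stacks  # in-memory only; stripped on serialization
    return report


def serialize_report(report: dict) -> str:
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(clean)
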