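"""Frankencell: synthetic batch-confounded differentiation trajectories.

Cells are built by hypergeometrically mixing reads from pure base
populations along a tree-structured construction plan: a sampled Markov
path from the root to a terminal state, a Beta(0.5, 1) progress draw
placing the cell on an edge, and a sigmoidal interpolation of the edge's
endpoint mixing weights.  Two batches with distinct gene-wise
multiplicative technical distortions are generated from separate plans
whose only difference is the T-cell transition probability, so terminal
states can be made batch-exclusive ("completely confounded").

The base populations here are themselves synthetic (negative-binomial
pools with disjoint marker-gene blocks per cell type), standing in for
pure annotated cell-type clusters of a real multi-batch experiment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import sympy
from scipy.special import expit

from .data import CountMatrix, CovariateDesign, encode_covariates

__all__ = ["CELL_TYPES", "TrajectoryPlan", "BasePopulations", "build_plan",
           "node_weight_expressions", "sample_cell_path",
           "interpolate_weights", "synthesize_cell",
           "synthetic_base_populations", "generate_dataset"]

CELL_TYPES = ["HSC", "CD16+Mono", "B1B", "NK", "CD8+T", "pDC", "cDC2"]

_K = sympy.Symbol("k", nonnegative=True)

# node id -> (label, parent, {cell type: weight expression in k})
_NODE_TABLE = {
    "root": ("HSC", None, {"HSC": sympy.Integer(1)}),
    "1": ("progenitor", "root", {"HSC": sympy.Rational(1, 2),
                                 "CD16+Mono": sympy.Rational(1, 8),
                                 "B1B": sympy.Rational(1, 8),
                                 "NK": sympy.Rational(1, 8),
                                 "CD8+T": sympy.Rational(1, 8)}),
    "2": ("myeloid", "1", {"HSC": sympy.Rational(1, 5) + _K,
                           "CD16+Mono": sympy.Rational(2, 5) - _K / 2,
                           "pDC": sympy.Rational(1, 5) - _K / 4,
                           "cDC2": sympy.Rational(1, 5) - _K / 4}),
    "3": ("lymphoid", "1", {"HSC": sympy.Rational(1, 5) + _K,
                            "B1B": sympy.Rational(2, 5) - _K / 2,
                            "NK": sympy.Rational(1, 5) - _K / 4,
                            "CD8+T": sympy.Rational(1, 5) - _K / 4}),
    "4": ("Mono", "2", {"HSC": _K, "CD16+Mono": 1 - 2 * _K,
                        "pDC": _K / 2, "cDC2": _K / 2}),
    "5": ("Dendritic", "2", {"HSC": _K, "CD16+Mono": _K,
                             "pDC": sympy.Rational(1, 2) - _K,
                             "cDC2": sympy.Rational(1, 2) - _K}),
    "6": ("B-cell", "3", {"HSC": _K, "B1B": 1 - 2 * _K,
                          "NK": _K / 2, "CD8+T": _K / 2}),
    "7": ("T-cell", "3", {"HSC": _K, "B1B": _K,
                          "NK": sympy.Rational(1, 2) - _K,
                          "CD8+T": sympy.Rational(1, 2) - _K}),
}

TERMINALS = ("4", "5", "6", "7")


def node_weight_expressions() -> dict:
    """Symbolic mixing-weight rows (sympy expressions in k) per node."""
    return {nid: dict(row) for nid, (_, _, row) in _NODE_TABLE.items()}


@dataclass
class TrajectoryPlan:
    """Numeric construction plan at a fixed (k, P_T-cell)."""

    k: float
    p_tcell: float
    weights: dict = field(default_factory=dict)   # node id -> weight vector
    labels: dict = field(default_factory=dict)
    parents: dict = field(default_factory=dict)
    transitions: dict = field(default_factory=dict)  # node -> [(child, prob)]

    def terminal_label(self, node: str) -> str:
        return self.labels[node]


def build_plan(k: float, p_tcell: float) -> TrajectoryPlan:
    if not 0 <= k <= 0.25:
        raise ValueError("k must be in [0, 0.25]")
    if not 0 <= p_tcell <= 1:
        raise ValueError("P_T-cell must be in [0, 1]")
    weights, labels, parents = {}, {}, {}
    for nid, (label, parent, row) in _NODE_TABLE.items():
        w = np.zeros(len(CELL_TYPES))
        for j, ct in enumerate(CELL_TYPES):
            if ct in row:
                w[j] = float(sympy.sympify(row[ct]).subs(_K, k))
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError(f"node {nid} weights outside [0,1] at k={k}")
        if abs(w.sum() - 1) > 1e-9:
            raise ValueError(f"node {nid} weights do not sum to 1")
        weights[nid] = w
        labels[nid] = label
        parents[nid] = parent
    transitions = {"root": [("1", 1.0)],
                   "1": [("2", 0.4), ("3", 0.6)],
                   "2": [("4", 0.5), ("5", 0.5)],
                   "3": [("6", 1.0 - p_tcell), ("7", p_tcell)]}
    return TrajectoryPlan(k=k, p_tcell=p_tcell, weights=weights,
                          labels=labels, parents=parents,
                          transitions=transitions)


def check_weights_symbolic() -> bool:
    """Verify symbolically that every node's mixing weights sum to 1 for
    all k (used by tests; returns True when the identity holds)."""
    for nid, (_, _, row) in _NODE_TABLE.items():
        total = sympy.simplify(sum(row.values()))
        if total != 1:
            return False
    return True


def sample_cell_path(plan: TrajectoryPlan, rng: np.random.Generator):
    """Markov path from the root to a terminal node, plus a Beta(0.5, 1)
    progress draw along the path."""
    path = ["root"]
    node = "root"
    while node not in TERMINALS:
        children, probs = zip(*plan.transitions[node])
        node = children[rng.choice(len(children), p=np.array(probs))]
        path.append(node)
    p = rng.beta(0.5, 1.0)
    return path, float(p)


def interpolate_weights(plan: TrajectoryPlan, path, p: float) -> np.ndarray:
    """Mixing weights of a cell a fraction p along its path.

    p spans the whole root-to-terminal path; within the selected edge the
    position maps through the logistic delta = sigma(2 p_edge - 1) to a
    convex combination of the edge's endpoint weights.
    """
    edges = list(zip(path[:-1], path[1:]))
    pos = np.clip(p, 0.0, 1.0) * len(edges)
    edge_idx = min(int(pos), len(edges) - 1)
    p_edge = pos - edge_idx
    start, end = edges[edge_idx]
    delta = expit(2.0 * p_edge - 1.0)
    w = (1.0 - delta) * plan.weights[start] + delta * plan.weights[end]
    return w / w.sum()


def locate_on_path(path, p: float) -> tuple:
    """(edge end-node, within-edge fraction) for a cell a fraction p along
    its path; the end node's label is the cell's ground-truth branch."""
    edges = list(zip(path[:-1], path[1:]))
    pos = np.clip(p, 0.0, 1.0) * len(edges)
    edge_idx = min(int(pos), len(edges) - 1)
    return edges[edge_idx][1], pos - edge_idx


@dataclass
class BasePopulations:
    """Per-(batch, cell type) pools of integer count vectors."""

    pools: dict                   # (batch, cell type) -> int array (cells x genes)
    n_genes: int

    def __post_init__(self):
        for key, pool in self.pools.items():
            if len(pool) == 0:
                raise ValueError(f"empty pool for {key}")


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer quotas summing exactly to total, proportional to weights."""
    raw = total * weights
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def synthesize_cell(pi_cell: np.ndarray, base: BasePopulations, batch: str,
                    rng: np.random.Generator,
                    depth_logmean: float = np.log(2000.0),
                    depth_logsd: float = 0.3) -> np.ndarray:
    """Mix reads for one synthetic cell.

    Depth ~ LogNormal; per-population quotas by largest remainder; for each
    population one donor cell is drawn from that batch's pool and the quota
    is sampled from its gene counts without replacement (multivariate
    hypergeometric).  A donor too shallow for its quota is redrawn up to 10
    times, then sampled with replacement.
    """
    n_total = max(int(round(rng.lognormal(depth_logmean, depth_logsd))), 1)
    quotas = _largest_remainder(n_total, pi_cell)
    out = np.zeros(base.n_genes, dtype=int)
    for ct_idx, quota in enumerate(quotas):
        if quota == 0:
            continue
        pool = base.pools[(batch, CELL_TYPES[ct_idx])]
        donor = None
        for _ in range(10):
            cand = pool[rng.integers(len(pool))]
            if cand.sum() >= quota:
                donor = cand
                break
        if donor is not None:
            out += rng.multivariate_hypergeometric(donor.astype(int),
                                                   int(quota))
        else:  # shallow pool: sample with replacement from donor profile
            cand = pool[rng.integers(len(pool))]
            probs = cand / cand.sum()
            out += rng.multinomial(int(quota), probs)
    return out


def synthetic_base_populations(n_genes: int = 300, cells_per_pool: int = 40,
                               batch_effect_sd: float = 0.4,
                               depth_logmean: float = np.log(20000.0),
                               depth_logsd: float = 0.25,
                               markers_per_type: int | None = None,
                               seed: int = 0) -> BasePopulations:
    """Synthetic stand-in for pure annotated cell-type pools.

    Each type upregulates a disjoint marker-gene block over a shared
    baseline profile; batch 2 counts are distorted by gene-wise
    LogNormal(0, batch_effect_sd) multiplicative factors and a mild depth
    shift, emulating distinct technical conditions.
    """
    rng = np.random.default_rng(seed)
    n_types = len(CELL_TYPES)
    markers = markers_per_type or max(n_genes // (2 * n_types), 3)
    baseline = rng.lognormal(0.0, 1.0, size=n_genes)
    type_rates = {}
    for i, ct in enumerate(CELL_TYPES):
        rate = baseline.copy()
        block = slice(i * markers, (i + 1) * markers)
        rate[block] *= 8.0
        type_rates[ct] = rate / rate.sum()
    batch2_factor = rng.lognormal(0.0, batch_effect_sd, size=n_genes)
    pools = {}
    for batch_i, batch in enumerate(("batch1", "batch2")):
        for ct in CELL_TYPES:
            rate = type_rates[ct].copy()
            dlm = depth_logmean
            if batch_i == 1:
                rate = rate * batch2_factor
                rate = rate / rate.sum()
                dlm = depth_logmean + 0.2   # depth-distribution shift
            depths = rng.lognormal(dlm, depth_logsd, size=cells_per_pool)
            # NB counts via Gamma-Poisson around the pool profile
            shape = 3.0
            g = rng.gamma(shape, 1.0 / shape,
                          size=(cells_per_pool, n_genes))
            lam = depths[:, None] * rate[None, :] * g
            pools[(batch, ct)] = rng.poisson(lam).astype(int)
    return BasePopulations(pools=pools, n_genes=n_genes)


def generate_dataset(plan_batch1: TrajectoryPlan, plan_batch2: TrajectoryPlan,
                     base: BasePopulations, n_per_batch: int = 2000,
                     seed: int = 0,
                     depth_logmean: float = np.log(2000.0),
                     depth_logsd: float = 0.3):
    """Two-batch confounded trajectory dataset.

    Returns (CountMatrix, CovariateDesign, truth DataFrame) where the truth
    table records batch, sampled path, progress, branch label, pseudotime
    and the interpolated mixing weights per cell.
    """
    if plan_batch1.k != plan_batch2.k:
        raise ValueError("the two plans must share the base-similarity k")
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for batch, plan in (("batch1", plan_batch1), ("batch2", plan_batch2)):
        for i in range(n_per_batch):
            path, p = sample_cell_path(plan, rng)
            pi_cell = interpolate_weights(plan, path, p)
            counts = synthesize_cell(pi_cell, base, batch, rng,
                                     depth_logmean, depth_logsd)
            node, _ = locate_on_path(path, p)
            rows.append(counts)
            truth.append({"cell": f"{batch}_cell{i}", "batch": batch,
                          "path": "->".join(path), "progress": p,
                          "branch": plan.labels[node],
                          "fate": plan.terminal_label(path[-1]),
                          "pseudotime": p,
                          **{f"pi_{ct}": pi_cell[j]
                             for j, ct in enumerate(CELL_TYPES)}})
    counts = sp.csr_matrix(np.vstack(rows))
    truth = pd.DataFrame(truth).set_index("cell")
    X = CountMatrix(counts, feature_ids=[f"gene{j}" for j in
                                         range(base.n_genes)],
                    cell_ids=list(truth.index), modality="RNA")
    truth = truth.loc[X.cell_ids]  # CountMatrix drops zero-depth cells
    C = encode_covariates(truth, {"batch": "categorical"}, batch_key="batch")
    return X, C, truth
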