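"""Count-matrix and covariate handling.

Reads 10x-style MatrixMarket triplets, HDF5 single-cell containers
(via anndata), or dense TSV; builds covariate design matrices (one-hot
categoricals, standardized continuous columns); computes Poisson deviance
residuals for the expression encoder; and provides stratified splitting
and an on-disk minibatch cache for streamed training.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["CountMatrix", "CovariateDesign", "MinibatchStream",
           "load_counts", "encode_covariates", "deviance_residuals",
           "stratified_split", "write_cache", "stream_minibatches"]


@dataclass
class CountMatrix:
    """Sparse nonnegative-integer cell x feature count matrix with labels.

    ATAC matrices are binarized on construction: any positive entry is
    treated as an accessibility indicator.
    """

    counts: sp.csr_matrix
    feature_ids: list
    cell_ids: list
    modality: str = "RNA"
    feature_coords: pd.DataFrame | None = None  # BED-style: chrom/start/end

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if self.modality not in ("RNA", "ATAC"):
            raise ValueError(f"unknown modality {self.modality!r}")
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.feature_ids) != g:
            raise ValueError(
                f"label/matrix dimension mismatch: matrix {n}x{g}, "
                f"{len(self.cell_ids)} cell ids, {len(self.feature_ids)} feature ids")
        if self.modality == "ATAC":
            self.counts.data = np.ones_like(self.counts.data)
        # drop zero-count cells: they carry no information and break the
        # deviance-residual and multinomial-depth transforms
        depth = np.asarray(self.counts.sum(axis=1)).ravel()
        if (depth == 0).any():
            keep = depth > 0
            logger.info("dropping %d zero-count cells", int((~keep).sum()))
            self.counts = self.counts[keep]
            self.cell_ids = [c for c, k in zip(self.cell_ids, keep) if k]

    @property
    def shape(self):
        return self.counts.shape

    def subset(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(self.counts[idx],
                           feature_ids=list(self.feature_ids),
                           cell_ids=[self.cell_ids[i] for i in idx],
                           modality=self.modality,
                           feature_coords=self.feature_coords)

    def depths(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


@dataclass
class CovariateDesign:
    """Real cell x covariate design matrix with per-column provenance.

    Categorical source columns expand to one-hot groups summing to one per
    cell; continuous columns are standardized over the design population.
    """

    matrix: np.ndarray
    schema: list = field(default_factory=list)  # {name, kind, columns, ...}
    batch_key: str | None = None

    @property
    def n_covariates(self) -> int:
        return self.matrix.shape[1]

    def subset(self, idx) -> "CovariateDesign":
        return CovariateDesign(self.matrix[np.asarray(idx)], schema=self.schema,
                               batch_key=self.batch_key)

    def batch_labels(self) -> np.ndarray:
        """Joint categorical level per cell (for stratification)."""
        labels = []
        for spec_ in self.schema:
            if spec_["kind"] != "categorical-one-hot":
                continue
            block = self.matrix[:, spec_["columns"]]
            labels.append(np.array(spec_["categories"])[block.argmax(axis=1)])
        if not labels:
            return np.zeros(len(self.matrix), dtype=object)
        out = labels[0].astype(object)
        for extra in labels[1:]:
            out = np.char.add(np.char.add(out.astype(str), "|"), extra.astype(str))
        return out


def load_counts(path, format: str, modality: str = "RNA",
                feature_coords=None) -> CountMatrix:
    """Load a count matrix.

    Formats: ``mtx`` (10x triplet directory: matrix.mtx + barcodes.tsv +
    features.tsv, features x cells orientation), ``h5ad`` (anndata
    container), ``tsv`` (dense, cells as rows, header = feature ids,
    first column = cell ids).
    """
    path = Path(path)
    if format == "mtx":
        mat = scipy.io.mmread(path / "matrix.mtx")
        barcodes = (path / "barcodes.tsv").read_text().split()
        feats = [line.split("\t")[0] for line in
                 (path / "features.tsv").read_text().splitlines() if line]
        mat = sp.csr_matrix(mat.T)  # 10x stores features x cells
        if mat.shape[0] != len(barcodes) or mat.shape[1] != len(feats):
            raise ValueError(
                f"matrix shape {mat.shape} does not match {len(barcodes)} "
                f"barcodes / {len(feats)} features")
        return CountMatrix(mat, feature_ids=feats, cell_ids=barcodes,
                           modality=modality, feature_coords=feature_coords)
    if format == "h5ad":
        import anndata
        adata = anndata.read_h5ad(path)
        return CountMatrix(sp.csr_matrix(adata.X),
                           feature_ids=list(adata.var_names),
                           cell_ids=list(adata.obs_names), modality=modality,
                           feature_coords=feature_coords)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(sp.csr_matrix(df.values),
                           feature_ids=list(df.columns),
                           cell_ids=list(df.index), modality=modality,
                           feature_coords=feature_coords)
    raise ValueError(f"unknown format {format!r}")


def encode_covariates(table: pd.DataFrame, schema: dict,
                      batch_key: str | None = None,
                      fitted: "CovariateDesign | None" = None) -> CovariateDesign:
    """Build the covariate design matrix C.

    ``schema`` maps column name -> 'categorical' | 'continuous'.  When
    ``fitted`` is given, categories and standardization moments are reused
    (unseen categories raise).
    """
    blocks, out_schema, col = [], [], 0
    fitted_by_name = ({s["name"]: s for s in fitted.schema} if fitted else {})
    for name, kind in schema.items():
        values = table[name].values
        if kind == "categorical":
            if name in fitted_by_name:
                cats = fitted_by_name[name]["categories"]
                unseen = set(map(str, values)) - set(cats)
                if unseen:
                    raise ValueError(
                        f"unseen categories for {name!r}: {sorted(unseen)}")
            else:
                cats = sorted(map(str, set(values)))
            lookup = {c: i for i, c in enumerate(cats)}
            block = np.zeros((len(values), len(cats)))
            block[np.arange(len(values)),
                  [lookup[str(v)] for v in values]] = 1.0
            out_schema.append({"name": name, "kind": "categorical-one-hot",
                               "categories": list(cats),
                               "columns": list(range(col, col + len(cats)))})
            col += len(cats)
        elif kind == "continuous":
            v = np.asarray(values, dtype=float)
            if name in fitted_by_name:
                mu = fitted_by_name[name]["mean"]
                sd = fitted_by_name[name]["sd"]
            else:
                mu, sd = float(v.mean()), float(v.std())
                sd = sd if sd > 0 else 1.0
            block = ((v - mu) / sd)[:, None]
            out_schema.append({"name": name, "kind": "continuous-standardized",
                               "mean": mu, "sd": sd, "columns": [col]})
            col += 1
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
        blocks.append(block)
    matrix = (np.concatenate(blocks, axis=1) if blocks
              else np.zeros((len(table), 0)))
    return CovariateDesign(matrix, schema=out_schema, batch_key=batch_key)


def deviance_residuals(X: CountMatrix) -> np.ndarray:
    """Poisson deviance residuals under a constant-composition null.

    The null expects cell i to allocate its depth n_i across genes at the
    pooled proportions pi_j; the signed square-root deviance stabilizes the
    variance of counts for the expression encoder.
    """
    if X.modality != "RNA":
        raise ValueError("deviance residuals are defined for RNA counts")
    counts = np.asarray(X.counts.todense(), dtype=float)
    depth = counts.sum(axis=1, keepdims=True)
    if (depth == 0).any():
        raise ValueError("all-zero cell encountered")
    pi = counts.sum(axis=0) / counts.sum()
    mu = depth * pi[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        xlogx = np.where(counts > 0, counts * np.log(counts / mu), 0.0)
    dev = 2.0 * (xlogx - (counts - mu))
    return np.sign(counts - mu) * np.sqrt(np.maximum(dev, 0.0))


def stratified_split(X: CountMatrix, C: CovariateDesign, ratio: float = 0.8,
                     seed: int = 0):
    """Split cells into train/test per joint categorical covariate level.

    Train gets floor(ratio * n) cells per stratum, the remainder goes to
    test; strata with fewer than 2 cells are placed entirely in train.
    Returns (train_idx, test_idx) cell-index arrays.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata = C.batch_labels()
    train_idx, test_idx = [], []
    for level in pd.unique(strata):
        members = np.flatnonzero(strata == level)
        if len(members) < 2:
            warnings.warn(f"stratum {level!r} has <2 cells; placed in train")
            train_idx.extend(members)
            continue
        perm = rng.permutation(members)
        n_train = int(np.floor(ratio * len(members)))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(train_idx).astype(int), np.sort(test_idx).astype(int)


@dataclass
class MinibatchStream:
    chunk_dir: Path
    batch_size: int
    order_seed: int = 0

    def manifest(self) -> dict:
        return json.loads((Path(self.chunk_dir) / "manifest.json").read_text())


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def write_cache(X: CountMatrix, C: CovariateDesign, chunk_dir,
                chunk_size: int = 128, order_seed: int = 0) -> MinibatchStream:
    """Write (X, C) to disk as compressed sparse chunks with checksums."""
    chunk_dir = Path(chunk_dir)
    chunk_dir.mkdir(parents=True, exist_ok=True)
    n = X.shape[0]
    chunks = []
    for ci, lo in enumerate(range(0, n, chunk_size)):
        hi = min(lo + chunk_size, n)
        block = X.counts[lo:hi].tocoo()
        cov = C.matrix[lo:hi]
        fname = f"chunk_{ci:05d}.npz"
        np.savez_compressed(chunk_dir / fname, row=block.row, col=block.col,
                            data=block.data, shape=np.array(block.shape),
                            cov=cov)
        chunks.append({"file": fname, "n_cells": hi - lo,
                       "checksum": _checksum(cov) + _checksum(block.data)})
    manifest = {"n_cells": n, "n_features": X.shape[1],
                "modality": X.modality, "chunk_size": chunk_size,
                "feature_ids": list(map(str, X.feature_ids)),
                "cell_ids": list(map(str, X.cell_ids)),
                "schema": C.schema, "chunks": chunks}
    (chunk_dir / "manifest.json").write_text(json.dumps(manifest))
    return MinibatchStream(chunk_dir=chunk_dir, batch_size=chunk_size,
                           order_seed=order_seed)


def stream_minibatches(stream: MinibatchStream, order_seed: int | None = None):
    """Yield (X_chunk csr, C_chunk) over one full pass, in shuffled chunk order."""
    manifest = stream.manifest()
    order = np.arange(len(manifest["chunks"]))
    seed = stream.order_seed if order_seed is None else order_seed
    order = np.random.default_rng(seed).permutation(order)
    for ci in order:
        meta = manifest["chunks"][ci]
        with np.load(Path(stream.chunk_dir) / meta["file"]) as z:
            cov = z["cov"]
            data = z["data"]
            if _checksum(cov) + _checksum(data) != meta["checksum"]:
                raise IOError(f"corrupted chunk {meta['file']}")
            mat = sp.csr_matrix((data, (z["row"], z["col"])),
                                shape=tuple(z["shape"]))
        yield mat, cov


def load_cached(stream: MinibatchStream):
    """Materialize the full (X, C) from a cache (test/eval convenience)."""
    mats, covs = [], []
    for m, c in stream_minibatches(stream, order_seed=0):
        mats.append(m)
        covs.append(c)
    manifest = stream.manifest()
    order = np.random.default_rng(0).permutation(len(manifest["chunks"]))
    inv = np.argsort(order)
    mats = [mats[i] for i in inv]
    covs = [covs[i] for i in inv]
    return sp.vstack(mats).tocsr(), np.concatenate(covs, axis=0)
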