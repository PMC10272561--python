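"""Per-sample and per-cell module activity scores.

Two scorers are provided. ``ssgsea_score`` is the rank-weighted running-sum
single-sample enrichment score for bulk matrices (microarray / RNA-seq /
pseudo-bulk). ``additive_module_score`` is the expression-bin-controlled
additive score used for single cells: each module gene is compared to
control genes drawn from the same average-expression bin, which removes the
mean-expression and library-size trend from the score.

Bulk matrices are scored as given; count matrices are log-normalized for
library size first (``ln(1 + count / library_size * scale)``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin


def _as_dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_score(expr: pd.DataFrame, gene_set: list[str], alpha: float = 0.25,
                 minmax_normalize: bool = True) -> pd.Series:
    """Single-sample rank-weighted enrichment score of a gene set.

    Per sample, genes are walked in descending expression order; the score
    is the sum over positions of ``P_in(i) - P_out(i)`` where ``P_in``
    accumulates set-gene rank weights ``rank^alpha`` (rank = ascending
    average rank, so the top gene weighs most) and ``P_out`` is the ECDF of
    non-set genes. If ``minmax_normalize``, all sample scores are divided
    by their range across samples.
    """
    genes = expr.index
    in_set = genes.isin(set(gene_set))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("no gene of the set is present in the matrix")
    if n_in == len(genes):
        raise ValueError("gene set covers the whole matrix; score undefined")
    X = expr.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    scores = np.empty(n_samples)
    gene_order = np.arange(n_genes)
    for s in range(n_samples):
        x = X[:, s]
        r = rankdata(x)  # ascending, average ties: top gene has rank ~N
        # deterministic walk: descending expression, gene position tie-break
        order = np.lexsort((gene_order, -x))
        w = np.where(in_set[order], r[order] ** alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_set[order]) / (n_genes - n_in)
        scores[s] = float(np.sum(p_in - p_out))
    out = pd.Series(scores, index=expr.columns, name="ssgsea")
    if minmax_normalize:
        rng = out.max() - out.min()
        if rng > 0:
            out = out / rng
    return out


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def lognormalize(counts, scale: float = 1e4):
    """Library-size normalize counts: value = ln(1 + count/libsize * scale).

    Accepts a genes x cells sparse matrix or DataFrame; returns the same
    container type.
    """
    if isinstance(counts, pd.DataFrame):
        lib = counts.sum(axis=0).to_numpy(dtype=float)
        if (lib <= 0).any():
            bad = list(counts.columns[lib <= 0][:10])
            raise ValueError(f"cells with zero library size: {bad}")
        return np.log1p(counts / lib * scale)
    mat = counts.tocsc() if sp.issparse(counts) else sp.csc_matrix(counts)
    lib = np.asarray(mat.sum(axis=0)).ravel()
    if (lib <= 0).any():
        raise ValueError(f"cells with zero library size at columns "
                         f"{np.where(lib <= 0)[0][:10].tolist()}")
    norm = mat.astype(float).multiply(scale / lib[None, :]).tocsr()
    norm.data = np.log1p(norm.data)
    return norm


def additive_module_score(norm, gene_set: list[str], gene_ids: list[str],
                          n_bins: int = 24, n_ctrl: int = 100,
                          seed: int = 0) -> np.ndarray:
    """Bin-controlled additive module score per cell.

    Genes are binned into ``n_bins`` by average expression across cells;
    for every set gene, ``n_ctrl`` control genes are drawn from its bin
    (set genes never eligible; with replacement only when the bin is too
    small). The score is mean(set genes) - mean(pooled controls) per cell.
    """
    X = _as_dense(norm)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    set_idx = np.array([gene_index[g] for g in gene_set if g in gene_index])
    if set_idx.size == 0:
        raise ValueError("no gene of the set is present in the matrix")
    avg = X.mean(axis=1)
    n_genes = len(gene_ids)
    eff_bins = min(n_bins, n_genes)
    if eff_bins < n_bins:
        import warnings
        warnings.warn(f"reducing bins from {n_bins} to {eff_bins}")
    # equal-occupancy bins on the average-expression rank
    rank = rankdata(avg, method="ordinal") - 1
    bins = np.floor(rank * eff_bins / n_genes).astype(int)
    in_set = np.zeros(n_genes, dtype=bool)
    in_set[set_idx] = True
    rng = np.random.default_rng(seed)
    ctrl_pool: list[np.ndarray] = []
    for g in set_idx:
        candidates = np.where((bins == bins[g]) & ~in_set)[0]
        if candidates.size == 0:
            candidates = np.where(~in_set)[0]
        replace = candidates.size < n_ctrl
        ctrl_pool.append(rng.choice(candidates, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_pool)
    return X[set_idx].mean(axis=0) - X[ctrl_idx].mean(axis=0)


def pseudobulk(counts, sample_labels, gene_ids: list[str]) -> pd.DataFrame:
    """Sum counts per gene within each sample; columns sorted by label."""
    labels = pd.Series(sample_labels).astype(object)
    if labels.isna().any():
        raise ValueError("every cell must carry a sample label")
    mat = counts.tocsr() if sp.issparse(counts) else sp.csr_matrix(counts)
    samples = sorted(labels.unique())
    out = np.zeros((mat.shape[0], len(samples)))
    lab = labels.to_numpy()
    for j, s in enumerate(samples):
        cols = np.where(lab == s)[0]
        out[:, j] = np.asarray(mat[:, cols].sum(axis=1)).ravel()
    return pd.DataFrame(out, index=gene_ids, columns=samples)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class SSGSEAScorer(BaseEstimator, TransformerMixin):
    """Transform a samples x genes matrix into samples x gene-set scores."""

    def __init__(self, gene_sets: dict[str, list[str]], alpha: float = 0.25,
                 minmax_normalize: bool = True):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.minmax_normalize = minmax_normalize

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        expr = X.T  # genes x samples
        cols = {name: ssgsea_score(expr, genes, self.alpha,
                                   self.minmax_normalize)
                for name, genes in self.gene_sets.items()}
        return pd.DataFrame(cols, index=X.index)


class AdditiveModuleScorer(BaseEstimator, TransformerMixin):
    """Transform a cells x genes count matrix into cells x gene-set scores.

    Log-normalizes for library size unless ``assume_normalized``.
    """

    def __init__(self, gene_sets: dict[str, list[str]], n_bins: int = 24,
                 n_ctrl: int = 100, scale: float = 1e4,
                 assume_normalized: bool = False, seed: int = 0):
        self.gene_sets = gene_sets
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.scale = scale
        self.assume_normalized = assume_normalized
        self.seed = seed

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        gene_ids = list(X.columns)
        mat = X.T  # genes x cells
        if not self.assume_normalized:
            mat = lognormalize(mat, scale=self.scale)
        cols = {name: additive_module_score(mat, genes, gene_ids,
                                            self.n_bins, self.n_ctrl, self.seed)
                for name, genes in self.gene_sets.items()}
        return pd.DataFrame(cols, index=X.index)
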