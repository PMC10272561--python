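"""Weighted co-expression module discovery and characterization.

The chain mirrors the standard WGCNA workflow: keep the most variable
genes, drop outlier samples by static cut of a sample dendrogram, pick a
soft-threshold power by the scale-free topology fit, build a biweight
midcorrelation (bicor) adjacency, convert it to topological overlap (TOM),
cluster genes on TOM dissimilarity with a static cut, merge modules with
correlated eigengenes, and characterize modules by eigengene–trait
correlation, kME (gene–eigengene correlation) and top-kME hub genes.

Dendrogram cutting uses a fully specified static height cut plus a minimum
module size instead of the dynamic hybrid tree cut, so module assignment is
deterministic and reproducible from the parameters alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats
from sklearn.base import BaseEstimator

GREY = "grey"


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_transform(X: np.ndarray) -> np.ndarray:
    """Row-wise weighted centering for bicor; Pearson fallback at MAD = 0."""
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        u = (X - med) / (9.0 * mad)
        w = np.nan_to_num((1.0 - u**2) ** 2 * (np.abs(u) < 1.0))
    xt = (X - med) * w
    # Pearson fallback: MAD of 0 (weights undefined) or a numerically zero
    # weighted vector (all weight mass sitting exactly at the median)
    fallback = ((mad[:, 0] == 0) | ~np.isfinite(mad[:, 0])
                | (np.linalg.norm(xt, axis=1) == 0))
    if fallback.any():
        Xf = X[fallback]
        xt[fallback] = Xf - Xf.mean(axis=1, keepdims=True)
    return xt


def bicor(x, y) -> float:
    """Biweight midcorrelation of two sample vectors.

    Observations are weighted by ``(1 - u^2)^2`` with
    ``u = (x - median) / (9 MAD)`` and zero weight for ``|u| >= 1``; vectors
    with MAD = 0 fall back to Pearson centering.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("bicor needs at least 3 observations")
    xt = _bicor_transform(np.vstack([x, y]))
    nx_, ny_ = np.linalg.norm(xt[0]), np.linalg.norm(xt[1])
    if nx_ == 0 or ny_ == 0:
        raise ValueError("bicor undefined for constant vectors")
    return float(np.clip(xt[0] @ xt[1] / (nx_ * ny_), -1.0, 1.0))


def bicor_matrix(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """All-pairs bicor of the rows of a genes x samples matrix."""
    vals = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if vals.shape[1] < 3:
        raise ValueError("bicor needs at least 3 samples")
    xt = _bicor_transform(vals)
    norms = np.linalg.norm(xt, axis=1)
    if (norms == 0).any():
        bad = np.where(norms == 0)[0]
        raise ValueError(f"constant rows at positions {bad[:5].tolist()}")
    xt = xt / norms[:, None]
    return np.clip(xt @ xt.T, -1.0, 1.0)


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------

def filter_variable_genes(expr: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the k genes with the largest sample standard deviation."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > expr.shape[0]:
        raise ValueError(f"k={k} exceeds gene count {expr.shape[0]}")
    sd = expr.std(axis=1, ddof=1)
    keep = sd.sort_values(ascending=False, kind="stable").index[:k]
    return expr.loc[expr.index.intersection(keep, sort=False)]


def remove_outlier_samples(expr: pd.DataFrame, height_threshold: float,
                           min_cluster_size: int = 10
                           ) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples that sit in small clusters above a dendrogram cut.

    Samples are clustered by average linkage on Euclidean distance of
    gene-standardized expression; the tree is cut at ``height_threshold``
    and samples in clusters of size < ``min_cluster_size`` are removed.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    vals = expr.to_numpy(float)
    sd = vals.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    Z = linkage(z.T, method="average", metric="euclidean")
    labels = fcluster(Z, t=height_threshold, criterion="distance")
    counts = pd.Series(labels).value_counts()
    small = set(counts.index[counts < min_cluster_size])
    dropped = [s for s, lab in zip(expr.columns, labels) if lab in small]
    if len(dropped) == expr.shape[1]:
        raise ValueError("outlier removal dropped every sample; lower the "
                         "min cluster size or raise the height threshold")
    kept = [s for s in expr.columns if s not in set(dropped)]
    return expr[kept], dropped


# ---------------------------------------------------------------------------
# soft threshold
# ---------------------------------------------------------------------------

@dataclass
class SoftThresholdScan:
    powers: list[int]
    fit_r2: list[float]
    mean_connectivity: list[float]
    chosen_power: int
    reached_target: bool


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 frequency vs log10 mean connectivity per bin."""
    k = k[k > 0]
    if k.size < 3:
        raise ValueError("too few positive connectivities")
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    dk, freq = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            dk.append(k[mask].mean())
            freq.append(mask.sum() / k.size)
    if len(dk) < 3:
        raise ValueError(f"only {len(dk)} occupied connectivity bins; "
                         "scale-free fit needs at least 3")
    slope, _, r, _, _ = stats.linregress(np.log10(dk), np.log10(freq))
    r2 = float(r**2)
    return -r2 if slope > 0 else r2


def pick_soft_threshold(expr: pd.DataFrame,
                        powers: list[int] | None = None,
                        r2_target: float = 0.9,
                        n_bins: int = 10) -> SoftThresholdScan:
    """Scan candidate soft powers for scale-free topology.

    Connectivity at power beta is ``k_i = sum_j |bicor_ij|^beta`` (j != i);
    the chosen power is the smallest beta whose signed scale-free fit R^2
    reaches ``r2_target``, else the beta with the maximal fit (flagged via
    ``reached_target``).
    """
    if powers is None:
        powers = list(range(1, 21))
    if not powers:
        raise ValueError("powers must be nonempty")
    absC = np.abs(bicor_matrix(expr))
    np.fill_diagonal(absC, 0.0)
    fits, means = [], []
    for beta in powers:
        k = (absC**beta).sum(axis=1)
        fits.append(_scale_free_fit(k, n_bins=n_bins))
        means.append(float(k.mean()))
    fits_arr = np.array(fits)
    ok = np.where(fits_arr >= r2_target)[0]
    if ok.size:
        chosen, reached = powers[ok[0]], True
    else:
        chosen, reached = powers[int(np.argmax(fits_arr))], False
    return SoftThresholdScan(list(powers), fits, means, int(chosen), reached)


# ---------------------------------------------------------------------------
# adjacency / TOM / clustering
# ---------------------------------------------------------------------------

def adjacency(expr: pd.DataFrame, power: int,
              network_type: str = "unsigned") -> pd.DataFrame:
    """Soft-thresholded bicor adjacency; diagonal fixed at 1."""
    if power < 1:
        raise ValueError("power must be >= 1")
    C = bicor_matrix(expr)
    if network_type == "unsigned":
        A = np.abs(C) ** power
    elif network_type == "signed":
        A = ((1.0 + C) / 2.0) ** power
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=expr.index, columns=expr.index)


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbor similarity on top of adjacency.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj (u != i, j) and k_i the connectivity of i.
    """
    A = adj.to_numpy(float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    Ao = A.copy()
    np.fill_diagonal(Ao, 0.0)
    k = Ao.sum(axis=1)
    L = Ao @ Ao
    denom = np.minimum.outer(k, k) + 1.0 - Ao
    tom = (L + Ao) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(diss: np.ndarray | pd.DataFrame,
                   min_module_size: int = 30,
                   cut_height: float | None = None,
                   gene_ids: list[str] | None = None) -> pd.Series:
    """Static-cut average-linkage clustering of the TOM dissimilarity.

    ``cut_height=None`` places the cut in the middle of the largest gap
    among the upper half of the dendrogram merge heights: tight clusters
    finish merging well below the plateau where unrelated genes join, so
    the widest high gap separates real modules from that plateau. Clusters
    smaller than ``min_module_size`` become "grey". Labels are
    ``module_1, module_2, ...`` by decreasing size (ties broken by smallest
    member gene id).
    """
    D = diss.to_numpy(float) if isinstance(diss, pd.DataFrame) else np.asarray(diss, float)
    if gene_ids is None:
        gene_ids = (list(diss.index) if isinstance(diss, pd.DataFrame)
                    else [f"g{i}" for i in range(D.shape[0])])
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    if cut_height is None:
        heights = np.sort(Z[:, 2])
        upper = heights[heights >= np.quantile(heights, 0.5)]
        if upper.size >= 2:
            gaps = np.diff(upper)
            gi = int(np.argmax(gaps))
            cut_height = float((upper[gi] + upper[gi + 1]) / 2)
        else:
            cut_height = float(heights[-1])
    raw = fcluster(Z, t=cut_height, criterion="distance")
    out = pd.Series(GREY, index=pd.Index(gene_ids, name="gene"), name="module")
    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_module_size]
    clusters = []
    for c in keep:
        members = [g for g, lab in zip(gene_ids, raw) if lab == c]
        clusters.append((len(members), min(members), members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, _, members) in enumerate(clusters, start=1):
        out.loc[members] = f"module_{rank}"
    if not clusters:
        import warnings
        warnings.warn("static cut produced no module of the minimum size; "
                      "all genes labelled grey")
    return out


# ---------------------------------------------------------------------------
# eigengenes / kME / hubs
# ---------------------------------------------------------------------------

def module_eigengene(expr: pd.DataFrame, genes: list[str]) -> pd.Series:
    """First right-singular vector of the standardized module submatrix.

    Scaled to unit variance; sign chosen so the mean correlation with the
    module's genes is non-negative.
    """
    if not genes:
        raise ValueError("module gene list is empty")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"module genes absent from expression: {missing[:10]}")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sub = expr.loc[genes].to_numpy(float)
    sd = sub.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    e = e / e.std(ddof=1)
    cors = np.array([np.corrcoef(e, row)[0, 1] for row in z])
    if np.nanmean(cors) < 0:
        e = -e
    return pd.Series(e, index=expr.columns, name="eigengene")


def module_eigengenes(expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Samples x modules eigengene matrix for all non-grey modules."""
    mods = sorted(m for m in assignment.unique() if m != GREY)
    cols = {m: module_eigengene(expr, list(assignment.index[assignment == m]))
            for m in mods}
    return pd.DataFrame(cols, index=expr.columns)


def merge_close_modules(expr: pd.DataFrame, assignment: pd.Series,
                        merge_cut_height: float = 0.1) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity < cut.

    Dissimilarity is 1 - Pearson correlation of eigengenes; after each
    merge eigengenes are recomputed. Final labels are reassigned by
    decreasing module size.
    """
    assignment = assignment.copy()
    while True:
        mods = sorted(m for m in assignment.unique() if m != GREY)
        if len(mods) < 2:
            break
        eig = module_eigengenes(expr, assignment)
        corr = np.corrcoef(eig[mods].to_numpy().T)
        diss = 1.0 - corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut_height:
            break
        a, b = sorted((mods[i], mods[j]))
        assignment[assignment == b] = a
    # relabel by size, largest first
    mods = [m for m in assignment.unique() if m != GREY]
    sizes = [( -(assignment == m).sum(), assignment.index[assignment == m].min(), m)
             for m in mods]
    sizes.sort()
    rename = {old: f"module_{i}" for i, (_, _, old) in enumerate(sizes, start=1)}
    return assignment.map(lambda m: rename.get(m, GREY))


def drop_invalid_modules(assignment: pd.Series,
                         max_size: int = 1000) -> list[str]:
    """Retained-module list: grey and modules over ``max_size`` excluded.

    Genes keep their labels; only the retained list changes.
    """
    sizes = assignment.value_counts()
    return sorted(m for m in sizes.index
                  if m != GREY and sizes[m] <= max_size)


def module_trait_correlation(eigengenes: pd.DataFrame,
                             trait: pd.Series) -> pd.DataFrame:
    """Point-biserial correlation (and t-test p) of each eigengene vs trait."""
    t = trait.reindex(eigengenes.index)
    if t.isna().any():
        raise ValueError("trait is not aligned to eigengene samples")
    rows = {}
    for m in eigengenes.columns:
        e = eigengenes[m].to_numpy(float)
        if np.std(e) == 0:
            raise ValueError(f"eigengene of {m} is constant")
        r, p = stats.pearsonr(e, t.to_numpy(float))
        rows[m] = {"r": r, "p": p}
    return pd.DataFrame(rows).T.rename_axis("module")


def kme(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Gene x module table of Pearson correlations with eigengenes."""
    X = expr.to_numpy(float)
    E = eigengenes.to_numpy(float)
    Xz = X - X.mean(axis=1, keepdims=True)
    Ez = E - E.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xz, axis=1)
    en = np.linalg.norm(Ez, axis=0)
    xn[xn == 0] = np.inf
    table = (Xz @ Ez) / np.outer(xn, en)
    return pd.DataFrame(np.clip(table, -1, 1), index=expr.index,
                        columns=eigengenes.columns)


def hub_genes(kme_table: pd.DataFrame, assignment: pd.Series,
              module: str, n: int = 10) -> list[str]:
    """Top-n genes of a module by own-module kME (ties lexicographic)."""
    members = assignment.index[assignment == module]
    if len(members) == 0:
        raise KeyError(f"module {module!r} has no members")
    scores = kme_table.loc[members, module]
    order = sorted(zip(-scores.to_numpy(), scores.index))
    return [g for _, g in order[:n]]


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class CoexpressionModules(BaseEstimator):
    """End-to-end co-expression module discovery as an sklearn estimator.

    Parameters
    ----------
    top_variable : keep this many most-variable genes (None = all).
    power : soft-threshold power, or "auto" to scan for scale-free fit.
    network_type : "unsigned" or "signed" adjacency.
    min_module_size, cut_height, merge_cut_height, max_module_size, n_hubs :
        module detection and post-processing parameters.
    outlier_height : if set, remove outlier samples above this dendrogram
        height before anything else.

    ``fit(X, y)`` takes a samples x genes DataFrame and an optional binary
    trait; fitted attributes are ``labels_`` (per gene), ``power_``,
    ``eigengenes_``, ``kme_``, ``retained_modules_``, ``hubs_`` and, when a
    trait is given, ``trait_correlation_``.
    """

    def __init__(self, top_variable: int | None = None, power="auto",
                 r2_target: float = 0.9, network_type: str = "unsigned",
                 min_module_size: int = 30, cut_height: float | None = None,
                 merge_cut_height: float = 0.1, max_module_size: int = 1000,
                 n_hubs: int = 10, outlier_height: float | None = None,
                 min_cluster_size: int = 10):
        self.top_variable = top_variable
        self.power = power
        self.r2_target = r2_target
        self.network_type = network_type
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.merge_cut_height = merge_cut_height
        self.max_module_size = max_module_size
        self.n_hubs = n_hubs
        self.outlier_height = outlier_height
        self.min_cluster_size = min_cluster_size

    def fit(self, X: pd.DataFrame, y: pd.Series | None = None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame")
        if X.isna().any().any():
            raise ValueError("missing values are not accepted; impute upstream")
        expr = X.T  # internal convention: genes x samples
        self.dropped_samples_ = []
        if self.outlier_height is not None:
            expr, self.dropped_samples_ = remove_outlier_samples(
                expr, self.outlier_height, self.min_cluster_size)
        if self.top_variable is not None:
            expr = filter_variable_genes(expr, self.top_variable)
        if self.power == "auto":
            self.scan_ = pick_soft_threshold(expr, r2_target=self.r2_target)
            self.power_ = self.scan_.chosen_power
        else:
            self.scan_ = None
            self.power_ = int(self.power)
        A = adjacency(expr, self.power_, self.network_type)
        diss = 1.0 - tom_similarity(A)
        labels = detect_modules(diss, self.min_module_size, self.cut_height,
                                gene_ids=list(expr.index))
        labels = merge_close_modules(expr, labels, self.merge_cut_height)
        self.labels_ = labels
        self.eigengenes_ = module_eigengenes(expr, labels)
        self.retained_modules_ = drop_invalid_modules(labels, self.max_module_size)
        self.kme_ = kme(expr, self.eigengenes_[self.retained_modules_])
        self.hubs_ = {m: hub_genes(self.kme_, labels, m, self.n_hubs)
                      for m in self.retained_modules_}
        if y is not None:
            trait = pd.Series(y, index=expr.columns) if not isinstance(y, pd.Series) else y
            self.trait_correlation_ = module_trait_correlation(
                self.eigengenes_[self.retained_modules_], trait)
        self.expression_ = expr
        return self
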