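"""Reusable association statistics.

Spearman correlation, two-group Wilcoxon rank-sum tests, Fisher's-exact
gene-set overlap, over-representation (ORA) enrichment against GMT-style
pathway collections, Benjamini–Hochberg adjustment, and cluster marker-gene
calling for normalized single-cell matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def wilcoxon_two_group(values, groups) -> tuple[float, float]:
    """Two-sided Mann–Whitney/Wilcoxon rank-sum test between two groups.

    Exact enumeration when both groups have n <= 8 and there are no ties;
    otherwise the normal approximation with tie correction.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("one group is empty")
    if np.ptp(values) == 0:  # all observations tied: no evidence either way
        return float(a.size * b.size / 2.0), 1.0
    ties = np.unique(values).size < values.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ContingencySummary:
    universe: int
    size_a: int
    size_b: int
    overlap: int
    odds_ratio: float
    p: float
    degenerate: bool = False


def fisher_overlap(set_a, set_b, universe, alternative: str = "greater"
                   ) -> ContingencySummary:
    """Overlap of two gene sets under the hypergeometric null.

    One-sided ("greater", the default) asks for more overlap than chance,
    via the hypergeometric upper tail; "two-sided" uses Fisher's exact test.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A = set(set_a) & universe
    B = set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise ValueError("sets must be subsets of the universe")
    N, na, nb = len(universe), len(A), len(B)
    k = len(A & B)
    table = np.array([[k, na - k], [nb - k, N - na - nb + k]])
    degenerate = (table[0, 1] == 0 and table[1, 0] == 0) or na == 0 or nb == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0]) \
            if table[0, 1] * table[1, 0] > 0 else np.inf
    if alternative == "greater":
        p = float(stats.hypergeom.sf(k - 1, N, na, nb))
    elif alternative == "two-sided":
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return ContingencySummary(N, na, nb, k, float(odds), min(p, 1.0), degenerate)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def ora_enrichment(gene_list, pathways: dict[str, list[str]], universe,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of a gene list in each pathway of a collection.

    Hypergeometric (one-sided Fisher) p per pathway, BH-adjusted across the
    collection; pathways are clipped to the universe.
    """
    if not pathways:
        raise ValueError("empty pathway collection")
    universe = set(universe)
    genes = set(gene_list)
    if genes - universe:
        raise ValueError("gene_list must be a subset of the universe")
    rows = []
    for name in sorted(pathways):
        pw = set(pathways[name]) & universe
        summ = fisher_overlap(genes, pw, universe)
        rows.append({"pathway": name, "overlap": summ.overlap,
                     "list_size": summ.size_a, "pathway_size": summ.size_b,
                     "odds_ratio": summ.odds_ratio, "p": summ.p})
    out = pd.DataFrame(rows).set_index("pathway")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values(["p_adj", "p"])


def marker_genes(norm, clusters, gene_ids: list[str],
                 lfc_threshold: float = 0.5, alpha: float = 0.05
                 ) -> pd.DataFrame:
    """Cluster-vs-rest marker genes on a log-normalized genes x cells matrix.

    Per cluster, every gene is rank-sum tested cluster vs rest;
    avg_log2FC = log2(mean(expm1(in)) + 1) - log2(mean(expm1(out)) + 1);
    BH adjustment within cluster; pass requires avg_log2FC > lfc_threshold
    and adjusted p < alpha.
    """
    X = np.asarray(norm.todense(), dtype=float) if sp.issparse(norm) \
        else np.asarray(norm, dtype=float)
    clusters = pd.Series(np.asarray(clusters))
    labels = sorted(clusters.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    frames = []
    expm1 = np.expm1(X)
    for c in labels:
        mask = (clusters == c).to_numpy()
        if mask.sum() < 2:
            import warnings
            warnings.warn(f"cluster {c!r} is a singleton; approximation only")
        inside, outside = X[:, mask], X[:, ~mask]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(inside, outside, alternative="two-sided",
                                     axis=1, method="asymptotic")
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)  # all-tied genes
        lfc = (np.log2(expm1[:, mask].mean(axis=1) + 1.0)
               - np.log2(expm1[:, ~mask].mean(axis=1) + 1.0))
        padj = bh_adjust(pvals)
        frames.append(pd.DataFrame({
            "gene": gene_ids, "cluster": c, "avg_log2FC": lfc,
            "p": pvals, "p_adj": padj,
            "pass": (lfc > lfc_threshold) & (padj < alpha)}))
    return pd.concat(frames, ignore_index=True)
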