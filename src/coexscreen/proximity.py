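"""Drug screening by PPI network proximity to module hub genes.

For a drug with target set X and a module hub set Y, the proximity is the
average shortest-path distance over all pairs,

    D(X, Y) = sum_{x in X} sum_{y in Y} d(x, y) / (|X| |Y|),

where d is the unweighted hop distance on a score-thresholded PPI graph.
Significance comes from a pseudo-target background: D is recomputed for
1,000 uniformly random node sets of the same size, a Gaussian is fitted
(mean mu, unbiased SD sigma), and the drug's Z = (D - mu) / sigma is turned
into a one-sided lower-tail p (small D = closer than chance). p-values are
BH-adjusted across all screened drugs.

The graph is restricted to its largest connected component by default so
every pair distance is finite; backgrounds are cached per target-set size
with a size-derived sub-seed, so results do not depend on drug order.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .assoc import bh_adjust


@dataclass
class PPINetwork:
    graph: nx.Graph
    score_threshold: int
    restricted_to_lcc: bool
    n_nodes_raw: int

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())


@dataclass
class DrugTargetSet:
    drug_id: str
    drug_name: str
    targets: dict[str, float]  # target symbol -> pChEMBL


@dataclass
class BackgroundDistribution:
    size: int
    samples: np.ndarray
    mu: float
    sigma: float


@dataclass
class ProximityResult:
    table: pd.DataFrame
    skipped: pd.DataFrame
    top: pd.DataFrame


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

def load_string_edges(edges, score_threshold: int = 600,
                      restrict_to_lcc: bool = True,
                      strict: bool = False) -> PPINetwork:
    """Build an undirected simple graph from a STRING-dialect edge table.

    ``edges`` is a path to a TSV with columns (protein1, protein2,
    combined_score) or an equivalent DataFrame. Edges with score >=
    ``score_threshold`` are kept (strict ">" with ``strict=True``);
    self-loops are dropped and duplicate edges collapsed.
    """
    if isinstance(edges, (str, bytes)) or hasattr(edges, "__fspath__"):
        df = pd.read_csv(edges, sep="\t")
    else:
        df = edges.copy()
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    bad = df[df["combined_score"].isna()
             | df["protein1"].isna() | df["protein2"].isna()]
    if len(bad):
        raise ValueError(f"malformed edge rows at lines {list(bad.index[:10])}")
    n_raw = df.shape[0]
    keep = (df["combined_score"] > score_threshold if strict
            else df["combined_score"] >= score_threshold)
    df = df[keep]
    g = nx.Graph()
    for p1, p2 in zip(df["protein1"], df["protein2"]):
        if p1 != p2:
            g.add_edge(str(p1), str(p2))
    if restrict_to_lcc and g.number_of_nodes():
        lcc = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
        g = g.subgraph(lcc).copy()
    return PPINetwork(graph=g, score_threshold=score_threshold,
                      restricted_to_lcc=restrict_to_lcc, n_nodes_raw=n_raw)


def filter_effective_targets(drug_table: pd.DataFrame,
                             pchembl_min: float = 6.0,
                             missing: str = "drop"
                             ) -> tuple[list[DrugTargetSet], list[str]]:
    """Keep targets with potency strictly above ``pchembl_min``.

    Drugs left with zero effective targets are excluded and listed.
    ``missing`` controls rows without a potency value: "drop" or "error".
    """
    required = {"drug_id", "target_symbol", "pchembl"}
    if not required.issubset(drug_table.columns):
        raise ValueError(f"drug table needs columns {sorted(required)}")
    df = drug_table.copy()
    if df["pchembl"].isna().any():
        if missing == "error":
            raise ValueError("missing potency values present")
        df = df[df["pchembl"].notna()]
    df = df[df["pchembl"] > pchembl_min]
    names = (drug_table.groupby("drug_id")["drug_name"].first()
             if "drug_name" in drug_table.columns else None)
    kept, excluded = [], []
    for drug_id in sorted(drug_table["drug_id"].unique()):
        sub = df[df["drug_id"] == drug_id]
        if sub.empty:
            excluded.append(drug_id)
            continue
        targets = dict(sub.groupby("target_symbol")["pchembl"].max())
        name = str(names[drug_id]) if names is not None else drug_id
        kept.append(DrugTargetSet(drug_id, name, targets))
    return kept, excluded


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def shortest_distances(network: PPINetwork | nx.Graph,
                       sources) -> dict[str, dict[str, int]]:
    """BFS hop distances from each source to all reachable nodes."""
    g = network.graph if isinstance(network, PPINetwork) else network
    sources = [s for s in sources]
    mapped = [s for s in sources if s in g]
    if not mapped:
        raise KeyError(f"no source maps into the network: {sorted(sources)[:10]}")
    return {s: dict(nx.single_source_shortest_path_length(g, s))
            for s in mapped}


def proximity_D(network: PPINetwork | nx.Graph, X, Y
                ) -> tuple[float, dict]:
    """Average shortest-path distance between two node sets.

    Returns (D, report); the report lists symbols that failed to map.
    Unreachable pairs raise, which cannot occur on an LCC-restricted graph.
    """
    g = network.graph if isinstance(network, PPINetwork) else network
    Xm = sorted(set(x for x in X if x in g))
    Ym = sorted(set(y for y in Y if y in g))
    report = {"unmapped_targets": sorted(set(X) - set(Xm)),
              "unmapped_hubs": sorted(set(Y) - set(Ym)),
              "n_targets_mapped": len(Xm), "n_hubs_mapped": len(Ym)}
    if not Xm or not Ym:
        raise KeyError(f"no mapped members: targets={Xm}, hubs={Ym}")
    total = 0.0
    for y in Ym:
        dist = nx.single_source_shortest_path_length(g, y)
        for x in Xm:
            if x not in dist:
                raise ValueError(f"nodes {x!r} and {y!r} are disconnected; "
                                 "restrict the network to its LCC")
            total += dist[x]
    return total / (len(Xm) * len(Ym)), report


def _hub_mean_distance(g: nx.Graph, hubs: list[str]) -> tuple[list[str], np.ndarray]:
    """Per-node average hop distance to the hub set (nodes sorted)."""
    nodes = sorted(g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    acc = np.zeros(len(nodes))
    for y in hubs:
        dist = nx.single_source_shortest_path_length(g, y)
        if len(dist) != len(nodes):
            raise ValueError("hub cannot reach every node; use an "
                             "LCC-restricted network")
        for n, d in dist.items():
            acc[index[n]] += d
    return nodes, acc / len(hubs)


def sample_background(network: PPINetwork | nx.Graph, size: int,
                      Y, n_samples: int = 1000,
                      seed: int = 0) -> BackgroundDistribution:
    """Null distribution of D for uniformly random pseudo-target sets.

    Each draw picks ``size`` distinct nodes (hub overlap permitted) and
    computes D(draw, Y); mu and the unbiased sigma summarize the draws.
    Seeded per size, so cached backgrounds match per-drug sampling.
    """
    g = network.graph if isinstance(network, PPINetwork) else network
    n_nodes = g.number_of_nodes()
    if size < 1:
        raise ValueError("size must be >= 1")
    if size >= n_nodes:
        raise ValueError(f"size {size} must be below node count {n_nodes}")
    hubs = sorted(set(y for y in Y if y in g))
    if not hubs:
        raise KeyError("no hub maps into the network")
    _, mean_d = _hub_mean_distance(g, hubs)
    rng = np.random.default_rng([int(seed) % (2**31), size])
    draws = np.empty(n_samples)
    for i in range(n_samples):
        idx = rng.choice(n_nodes, size=size, replace=False)
        draws[i] = mean_d[idx].mean()
    sigma = float(draws.std(ddof=1))
    return BackgroundDistribution(size=size, samples=draws,
                                  mu=float(draws.mean()), sigma=sigma)


def gaussian_check(bg: BackgroundDistribution) -> dict:
    """Advisory normality report (QQ pairs + KS statistic) for a background."""
    s = np.sort(bg.samples)
    n = s.size
    if bg.sigma <= 0:
        return {"degenerate": True, "ks_stat": np.nan, "ks_p": np.nan,
                "qq": np.empty((0, 2))}
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n, bg.mu, bg.sigma)
    ks = stats.kstest(s, "norm", args=(bg.mu, bg.sigma))
    return {"degenerate": False, "ks_stat": float(ks.statistic),
            "ks_p": float(ks.pvalue), "qq": np.column_stack([theo, s])}


def z_and_p(D: float, mu: float, sigma: float,
            alternative: str = "less") -> tuple[float, float]:
    """Gaussian z-score of an observed proximity against its background.

    One-sided lower tail by default: a D far below mu (drug targets closer
    to the hubs than random) gives a small p.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    z = (D - mu) / sigma
    if alternative == "less":
        p = float(stats.norm.cdf(z))
    elif alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), p


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def screen_drugs(network: PPINetwork | nx.Graph,
                 drugs: list[DrugTargetSet], hubs,
                 n_background: int = 1000, seed: int = 0,
                 top_k: int = 20,
                 alternative: str = "less") -> ProximityResult:
    """Rank a drug collection by proximity significance to a hub set.

    Per drug: map targets, compute D, draw (or reuse the cached) background
    of matching mapped-target count, compute Z and one-sided p; BH-adjust
    across all screened drugs; rank ascending by (p_adj, Z, drug_id).
    """
    g = network.graph if isinstance(network, PPINetwork) else network
    hubs_mapped = sorted(set(h for h in hubs if h in g))
    if not hubs_mapped:
        raise KeyError("no hub gene maps into the network")
    nodes, mean_d = _hub_mean_distance(g, hubs_mapped)
    index = {n: i for i, n in enumerate(nodes)}

    backgrounds: dict[int, BackgroundDistribution] = {}
    rows, skipped = [], []
    for drug in drugs:
        mapped = sorted(set(drug.targets) & set(index))
        if not mapped:
            skipped.append({"drug_id": drug.drug_id, "reason": "no_mapped_targets"})
            continue
        if len(mapped) >= len(nodes):
            skipped.append({"drug_id": drug.drug_id, "reason": "targets_cover_network"})
            continue
        D = float(mean_d[[index[t] for t in mapped]].mean())
        size = len(mapped)
        if size not in backgrounds:
            backgrounds[size] = sample_background(
                g, size, hubs_mapped, n_samples=n_background, seed=seed)
        bg = backgrounds[size]
        z, p = z_and_p(D, bg.mu, bg.sigma, alternative=alternative)
        rows.append({"drug_id": drug.drug_id, "drug_name": drug.drug_name,
                     "n_targets": size, "mu": bg.mu, "sigma": bg.sigma,
                     "proximity": D, "Z": z, "p": p})
    if not rows:
        raise ValueError("no screenable drug (all failed target mapping)")
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(["p_adj", "Z", "drug_id"],
                              kind="stable").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    top = table.head(top_k).copy()
    top["background"] = [f"{r.n_targets}|{r.mu:.3f}|{r.sigma:.3f}"
                         for r in top.itertuples()]
    skipped_df = pd.DataFrame(skipped, columns=["drug_id", "reason"])
    return ProximityResult(table=table, skipped=skipped_df, top=top)


class ProximityScreen:
    """Estimator-style wrapper: fit on (edges, hubs), then screen drugs.

    Parameters mirror the functional layer: edge score threshold, potency
    cutoff, background size, master seed, report length.
    """

    def __init__(self, score_threshold: int = 600, pchembl_min: float = 6.0,
                 n_background: int = 1000, top_k: int = 20,
                 restrict_to_lcc: bool = True, seed: int = 0,
                 alternative: str = "less"):
        self.score_threshold = score_threshold
        self.pchembl_min = pchembl_min
        self.n_background = n_background
        self.top_k = top_k
        self.restrict_to_lcc = restrict_to_lcc
        self.seed = seed
        self.alternative = alternative

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("score_threshold", "pchembl_min", "n_background", "top_k",
                 "restrict_to_lcc", "seed", "alternative")}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, edges, hubs):
        self.network_ = load_string_edges(
            edges, score_threshold=self.score_threshold,
            restrict_to_lcc=self.restrict_to_lcc)
        self.hubs_ = list(hubs)
        return self

    def screen(self, drug_table: pd.DataFrame) -> ProximityResult:
        drugs, self.excluded_drugs_ = filter_effective_targets(
            drug_table, pchembl_min=self.pchembl_min)
        self.result_ = screen_drugs(
            self.network_, drugs, self.hubs_,
            n_background=self.n_background, seed=self.seed,
            top_k=self.top_k, alternative=self.alternative)
        return self.result_
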