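"""Synthetic data generators for every stage of the analysis.

The generators plant known structure — correlated gene modules with a
case/control effect, a scale-free protein interaction network, drug–target
tables with drugs placed near designated hub proteins, and cell-type
structured negative-binomial counts — so that module discovery, scoring,
discrimination and proximity screening can all be validated against ground
truth without any external accession.

Bulk expression follows a latent-factor model: every gene of module *m* is

    x_g = loading_g * f_m + noise_sd * eps_g,

with ``f_m`` standard normal per sample. For the single trait-associated
module, ``f_m`` is shifted by ``trait_effect`` (in SD units of the factor)
in case samples. Background genes are pure noise. Under this model the
within-module Pearson correlation has the closed form
``loading^2 / (loading^2 + noise_sd^2)`` and the module eigengene recovers
the factor, which makes hub/kME recovery analytically predictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp


class InvalidSpecError(ValueError):
    """Raised when a generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class ModulePlantSpec:
    """Case/control bulk expression with planted correlated modules.

    Exactly one module (``trait_module_index``) carries the trait effect.
    ``loading_spread`` > 0 draws per-gene loadings uniformly from
    ``within_module_loading ± loading_spread``, giving the modules a hub
    structure (highest-loading genes have the highest kME).
    """

    n_modules: int = 4
    genes_per_module: int = 50
    n_background_genes: int = 200
    n_cases: int = 100
    n_controls: int = 100
    within_module_loading: float = 0.8
    trait_effect: float = 0.8
    noise_sd: float = 0.6
    loading_spread: float = 0.0
    trait_module_index: int = 0
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_modules, self.genes_per_module, self.n_cases,
                  self.n_controls)
        if any(c < 1 for c in counts) or self.n_background_genes < 0:
            raise InvalidSpecError(f"non-positive dimensions in {self}")
        if not 0.0 < self.within_module_loading <= 1.0:
            raise InvalidSpecError("within_module_loading must be in (0, 1]")
        if self.noise_sd <= 0:
            raise InvalidSpecError("noise_sd must be > 0")
        if not 0 <= self.trait_module_index < self.n_modules:
            raise InvalidSpecError("trait_module_index out of range")


@dataclass
class NetworkPlantSpec:
    """Scale-free (preferential attachment) PPI stand-in with edge scores."""

    n_nodes: int = 500
    edges_per_new_node: int = 3
    score_low: int = 600
    score_high: int = 999
    seed: int = 0

    def validate(self) -> None:
        if self.edges_per_new_node < 1 or self.n_nodes <= self.edges_per_new_node:
            raise InvalidSpecError(
                "need n_nodes > edges_per_new_node >= 1, got "
                f"{self.n_nodes} / {self.edges_per_new_node}")
        if not (0 <= self.score_low <= self.score_high <= 1000):
            raise InvalidSpecError("score range must satisfy 0 <= low <= high <= 1000")


@dataclass
class DrugPlantSpec:
    """Drug→target tables containing null drugs and drugs planted near hubs."""

    n_null_drugs: int = 180
    n_planted_drugs: int = 20
    targets_per_drug: tuple[int, int] = (3, 10)
    planting_radius: int = 1
    pchembl_mean: float = 7.0
    pchembl_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_null_drugs < 0 or self.n_planted_drugs < 0:
            raise InvalidSpecError("drug counts must be >= 0")
        lo, hi = self.targets_per_drug
        if not 1 <= lo <= hi:
            raise InvalidSpecError("targets_per_drug must satisfy 1 <= min <= max")
        if self.planting_radius < 0:
            raise InvalidSpecError("planting_radius must be >= 0")


@dataclass
class CellPopulationSpec:
    """Cell-type structured NB counts with one module-active subtype.

    ``cell_types`` maps subtype label -> cells per sample. Cells are spread
    over ``n_samples`` samples, the first half labelled "case" and the rest
    "control". Genes of the planted module have their mean multiplied by
    ``module_shift`` in the designated ``active_subtype`` and, additionally,
    in cells from case samples.
    """

    cell_types: dict[str, int] = field(
        default_factory=lambda: {"Mic0": 50, "Mic1": 50, "Mic2": 50, "Mic3": 50})
    active_subtype: str = "Mic1"
    n_samples: int = 8
    nb_dispersion: float = 0.5
    library_size_log_mean: float = 0.0
    library_size_log_sd: float = 0.3
    module_shift: float = 4.0
    base_mean: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.cell_types) < 2:
            raise InvalidSpecError("need at least 2 cell types")
        if self.active_subtype not in self.cell_types:
            raise InvalidSpecError(
                f"active_subtype {self.active_subtype!r} not among cell types")
        if self.nb_dispersion <= 0:
            raise InvalidSpecError("nb_dispersion must be > 0")
        if self.module_shift <= 0:
            raise InvalidSpecError("module_shift must be > 0")
        if self.n_samples < 1:
            raise InvalidSpecError("n_samples must be >= 1")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class BulkDataset:
    expression: pd.DataFrame          # genes x samples
    trait: pd.Series                  # per sample, 1 = case
    gene_modules: dict[str, str]      # gene -> module label ("background" for noise)
    trait_module: str
    factors: pd.DataFrame             # samples x modules latent factors
    loadings: pd.Series               # per-gene planted loading (0 for background)


@dataclass
class CellDataset:
    counts: sp.csr_matrix             # genes x cells
    genes: list[str]
    cells: pd.DataFrame               # index = barcode; cell_type, sample, group


def _gene_symbols(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_bulk_expression(spec: ModulePlantSpec) -> BulkDataset:
    """Simulate genes x samples expression with planted co-expression modules."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_cases + spec.n_controls
    n_mod_genes = spec.n_modules * spec.genes_per_module
    n_genes = n_mod_genes + spec.n_background_genes

    trait = np.r_[np.ones(spec.n_cases, dtype=int),
                  np.zeros(spec.n_controls, dtype=int)]
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    genes = _gene_symbols(n_genes)

    factors = rng.standard_normal((n_samples, spec.n_modules))
    factors[:, spec.trait_module_index] += spec.trait_effect * trait

    if spec.loading_spread > 0:
        loadings = rng.uniform(spec.within_module_loading - spec.loading_spread,
                               spec.within_module_loading + spec.loading_spread,
                               size=n_mod_genes)
        loadings = np.clip(loadings, 1e-3, 1.0)
    else:
        loadings = np.full(n_mod_genes, spec.within_module_loading)

    X = np.empty((n_genes, n_samples))
    gene_modules: dict[str, str] = {}
    module_labels = [f"planted_{m + 1}" for m in range(spec.n_modules)]
    for m in range(spec.n_modules):
        lo = m * spec.genes_per_module
        hi = lo + spec.genes_per_module
        lam = loadings[lo:hi, None]
        X[lo:hi] = (lam * factors[:, m][None, :]
                    + spec.noise_sd * rng.standard_normal((spec.genes_per_module,
                                                           n_samples)))
        for g in genes[lo:hi]:
            gene_modules[g] = module_labels[m]
    X[n_mod_genes:] = spec.noise_sd * rng.standard_normal(
        (spec.n_background_genes, n_samples))
    for g in genes[n_mod_genes:]:
        gene_modules[g] = "background"

    all_loadings = np.r_[loadings, np.zeros(spec.n_background_genes)]
    return BulkDataset(
        expression=pd.DataFrame(X, index=genes, columns=sample_ids),
        trait=pd.Series(trait, index=sample_ids, name="trait"),
        gene_modules=gene_modules,
        trait_module=module_labels[spec.trait_module_index],
        factors=pd.DataFrame(factors, index=sample_ids, columns=module_labels),
        loadings=pd.Series(all_loadings, index=genes, name="loading"),
    )


def generate_ppi_network(spec: NetworkPlantSpec,
                         symbols: list[str] | None = None) -> pd.DataFrame:
    """Preferential-attachment edge table in STRING dialect.

    Each undirected edge is emitted once as (protein1, protein2,
    combined_score) with a synthetic score drawn uniformly from
    [score_low, score_high]. ``symbols`` lets the node universe share gene
    symbols with an expression matrix; extra nodes get fresh symbols.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = nx.barabasi_albert_graph(spec.n_nodes, spec.edges_per_new_node,
                                 seed=int(rng.integers(2**31)))
    if symbols is None:
        symbols = _gene_symbols(spec.n_nodes)
    elif len(symbols) < spec.n_nodes:
        extra = _gene_symbols(spec.n_nodes - len(symbols), prefix="NET")
        symbols = list(symbols) + extra
    mapping = dict(zip(range(spec.n_nodes), symbols))
    edges = sorted((min(mapping[u], mapping[v]), max(mapping[u], mapping[v]))
                   for u, v in g.edges())
    scores = rng.integers(spec.score_low, spec.score_high + 1, size=len(edges))
    return pd.DataFrame({
        "protein1": [e[0] for e in edges],
        "protein2": [e[1] for e in edges],
        "combined_score": scores,
    })


def choose_module_hubs(graph: nx.Graph, n: int = 10, seed: int = 0,
                       degree_cap_quantile: float = 0.9) -> list[str]:
    """Pick a connected cluster of ``n`` nodes to play the module hub set.

    Genes of one functional module cluster together in real interactomes
    and rarely coincide with the global high-degree core, so hubs are grown
    by breadth-first search from a random seed node, visiting neighbors in
    ascending degree order and skipping nodes above the
    ``degree_cap_quantile`` of the degree distribution (the cap is lifted
    only if growth stalls). The result is a tight, peripheral cluster.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes())
    if n > len(nodes):
        raise InvalidSpecError(f"cannot choose {n} hubs from {len(nodes)} nodes")
    degs = dict(graph.degree())
    cap = float(np.quantile(list(degs.values()), degree_cap_quantile))
    start = nodes[int(rng.integers(len(nodes)))]
    seen = {start}
    frontier = [start]
    order = [start]
    while frontier and len(order) < n:
        node = frontier.pop(0)
        for v in sorted(graph.neighbors(node), key=lambda v: (degs[v], v)):
            if v in seen or degs[v] > cap:
                continue
            seen.add(v)
            order.append(v)
            frontier.append(v)
            if len(order) == n:
                break
    if len(order) < n:  # stalled below the cap: allow high-degree nodes
        frontier = list(order)
        while frontier and len(order) < n:
            node = frontier.pop(0)
            for v in sorted(graph.neighbors(node), key=lambda v: (degs[v], v)):
                if v not in seen:
                    seen.add(v)
                    order.append(v)
                    frontier.append(v)
                    if len(order) == n:
                        break
    if len(order) < n:  # tiny component; fall back to lowest-degree rest
        rest = [v for v in sorted(nodes, key=lambda v: (degs[v], v))
                if v not in seen]
        order.extend(rest[: n - len(order)])
    return order[:n]


def generate_drug_table(spec: DrugPlantSpec, network: nx.Graph | pd.DataFrame,
                        hub_nodes: list[str]) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Drug→target table with potency values and per-drug planting truth.

    Null drugs draw targets uniformly from all network nodes; planted drugs
    draw only from nodes within ``planting_radius`` hops of the hub set.
    """
    spec.validate()
    if isinstance(network, pd.DataFrame):
        g = nx.from_pandas_edgelist(network, "protein1", "protein2")
    else:
        g = network
    missing = [h for h in hub_nodes if h not in g]
    if missing:
        raise InvalidSpecError(f"hub nodes absent from network: {missing}")

    eligible: set[str] = set()
    for h in hub_nodes:
        eligible.update(
            nx.single_source_shortest_path_length(g, h, cutoff=spec.planting_radius))
    if spec.n_planted_drugs and not eligible:
        raise InvalidSpecError(
            f"empty eligible neighborhood around hubs {sorted(hub_nodes)}")

    rng = np.random.default_rng(spec.seed)
    all_nodes = np.array(sorted(g.nodes()))
    eligible_nodes = np.array(sorted(eligible)) if eligible else all_nodes
    lo, hi = spec.targets_per_drug

    rows = []
    truth: dict[str, bool] = {}
    n_total = spec.n_null_drugs + spec.n_planted_drugs
    width = max(3, len(str(n_total)))
    for i in range(n_total):
        planted = i >= spec.n_null_drugs
        pool = eligible_nodes if planted else all_nodes
        drug_id = f"DRUG{i + 1:0{width}d}"
        name = ("planted_" if planted else "null_") + drug_id.lower()
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(pool))
        targets = rng.choice(pool, size=k, replace=False)
        pchembl = rng.normal(spec.pchembl_mean, spec.pchembl_sd, size=k)
        for t, v in zip(targets, pchembl):
            rows.append((drug_id, name, t, round(float(v), 3)))
        truth[drug_id] = planted
    table = pd.DataFrame(rows, columns=["drug_id", "drug_name",
                                        "target_symbol", "pchembl"])
    return table, truth


def generate_counts(spec: CellPopulationSpec,
                    module_genes: list[str],
                    n_genes: int = 500) -> CellDataset:
    """Negative-binomial counts for cell-type structured single-cell data.

    NB parameterized by mean mu and dispersion alpha (var = mu + alpha mu^2);
    per-cell library-size factors are log-normal. Module genes are up-shifted
    in the active subtype and in case-sample cells.
    """
    spec.validate()
    if not module_genes:
        raise InvalidSpecError("module_genes must be nonempty")
    rng = np.random.default_rng(spec.seed)

    genes = list(dict.fromkeys(list(module_genes) + _gene_symbols(n_genes, "SC")))
    genes = genes[:max(n_genes, len(module_genes))]
    module_idx = np.array([genes.index(g) for g in module_genes if g in genes])

    cell_rows = []
    for sample_i in range(spec.n_samples):
        sample = f"SAMP{sample_i + 1:02d}"
        group = "case" if sample_i < spec.n_samples // 2 else "control"
        for ctype, per_sample in sorted(spec.cell_types.items()):
            for j in range(per_sample):
                cell_rows.append((f"{sample}_{ctype}_{j:04d}", ctype, sample, group))
    cells = pd.DataFrame(cell_rows, columns=["barcode", "cell_type",
                                             "sample", "group"]).set_index("barcode")
    n_cells = len(cells)
    n_g = len(genes)

    base = rng.lognormal(mean=np.log(spec.base_mean), sigma=0.5, size=n_g)
    size_factor = rng.lognormal(spec.library_size_log_mean,
                                spec.library_size_log_sd, size=n_cells)
    shift = np.ones((n_g, n_cells))
    active = (cells["cell_type"] == spec.active_subtype).to_numpy()
    case = (cells["group"] == "case").to_numpy()
    shift[np.ix_(module_idx, active)] *= spec.module_shift
    shift[np.ix_(module_idx, case)] *= spec.module_shift

    mu = base[:, None] * size_factor[None, :] * shift
    r = 1.0 / spec.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    return CellDataset(counts=sp.csr_matrix(counts), genes=genes, cells=cells)
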