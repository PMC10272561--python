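"""End-to-end orchestration: simulate -> modules -> score -> classify ->
enrich/markers -> proximity, with a manifest recording parameters, seeds
and output hashes for reproducibility.

A single master seed is fanned out to per-stage sub-seeds derived from
stable stage labels, so each stage is reproducible in isolation and
independent of execution order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assoc, coexpression, discrimination, proximity, scoring, synthetic
from .io import write_expression_tsv, write_json, write_trait_tsv

log = logging.getLogger("coexscreen")


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable sub-seed for a named stage, below 2**31."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters with the study defaults."""

    out_dir: str = "coexscreen_run"
    seed: int = 0
    # simulate
    n_modules: int = 4
    genes_per_module: int = 50
    n_background_genes: int = 200
    n_cases: int = 100
    n_controls: int = 100
    within_module_loading: float = 0.8
    trait_effect: float = 0.8
    noise_sd: float = 0.6
    loading_spread: float = 0.15
    network_nodes: int = 500
    network_m: int = 3
    n_null_drugs: int = 180
    n_planted_drugs: int = 20
    planting_radius: int = 1
    # modules
    top_variable: int = 5000
    r2_target: float = 0.9
    min_module_size: int = 30
    cut_height: float | None = None
    merge_cut_height: float = 0.1
    max_module_size: int = 1000
    n_hubs: int = 10
    # classify
    cv_folds: int = 5
    cv_replicates: int = 3
    # proximity
    score_threshold: int = 600
    pchembl_min: float = 6.0
    n_background: int = 1000
    top_k: int = 20
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "modules", "score", "classify", "enrich", "proximity"])

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {},
                      "config": asdict(config)}
    t0 = time.time()
    state: dict = {}

    def record(stage: str, params: dict, files: list[Path]):
        manifest["stages"].append({"stage": stage, "params": params,
                                   "seconds": round(time.time() - t0, 2)})
        for f in files:
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)

    enabled = list(config.stages)
    if "simulate" in enabled:
        seed = stage_seed(config.seed, "simulate")
        spec = synthetic.ModulePlantSpec(
            n_modules=config.n_modules,
            genes_per_module=config.genes_per_module,
            n_background_genes=config.n_background_genes,
            n_cases=config.n_cases, n_controls=config.n_controls,
            within_module_loading=config.within_module_loading,
            trait_effect=config.trait_effect, noise_sd=config.noise_sd,
            loading_spread=config.loading_spread, seed=seed)
        bulk = synthetic.generate_bulk_expression(spec)
        net_spec = synthetic.NetworkPlantSpec(
            n_nodes=config.network_nodes, edges_per_new_node=config.network_m,
            seed=stage_seed(config.seed, "network"))
        edges = synthetic.generate_ppi_network(
            net_spec, symbols=list(bulk.expression.index))
        state.update(bulk=bulk, edges=edges)
        write_expression_tsv(bulk.expression, out / "expression.tsv")
        write_trait_tsv(bulk.trait, out / "trait.tsv")
        edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)
        write_json({"gene_modules": bulk.gene_modules,
                    "trait_module": bulk.trait_module}, out / "truth.json")
        record("simulate", {"seed": seed}, [out / "expression.tsv",
                                            out / "trait.tsv",
                                            out / "ppi_edges.tsv",
                                            out / "truth.json"])
        log.info("simulate: %d genes x %d samples, %d edges",
                 *bulk.expression.shape, len(edges))

    if "modules" in enabled:
        bulk = state["bulk"]
        est = coexpression.CoexpressionModules(
            top_variable=min(config.top_variable, bulk.expression.shape[0]),
            r2_target=config.r2_target,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_cut_height=config.merge_cut_height,
            max_module_size=config.max_module_size,
            n_hubs=config.n_hubs)
        est.fit(bulk.expression.T, bulk.trait)
        state["modules"] = est
        est.labels_.to_csv(out / "module_assignment.tsv", sep="\t")
        est.eigengenes_.to_csv(out / "eigengenes.tsv", sep="\t",
                               index_label="sample")
        est.kme_.to_csv(out / "kme.tsv", sep="\t", index_label="gene")
        est.trait_correlation_.to_csv(out / "module_trait.tsv", sep="\t")
        pd.DataFrame([(m, g) for m, gs in est.hubs_.items() for g in gs],
                     columns=["module", "gene"]).to_csv(
            out / "hub_genes.tsv", sep="\t", index=False)
        record("modules", {"power": est.power_}, [
            out / "module_assignment.tsv", out / "eigengenes.tsv",
            out / "kme.tsv", out / "module_trait.tsv", out / "hub_genes.tsv"])
        log.info("modules: %d retained, power %d",
                 len(est.retained_modules_), est.power_)

    if "score" in enabled:
        bulk, est = state["bulk"], state["modules"]
        target = est.trait_correlation_["r"].abs().idxmax()
        state["target_module"] = target
        genes = list(est.labels_.index[est.labels_ == target])
        score = scoring.ssgsea_score(bulk.expression, genes)
        score.rename("ssgsea").to_frame().join(bulk.trait).to_csv(
            out / "module_score.tsv", sep="\t", index_label="sample")
        record("score", {"module": target}, [out / "module_score.tsv"])

    if "classify" in enabled:
        bulk, est = state["bulk"], state["modules"]
        rows = {}
        for m in est.retained_modules_:
            feats = bulk.expression.loc[est.hubs_[m]].T.to_numpy()
            cv = discrimination.repeated_cv_auprc(
                feats, bulk.trait.to_numpy(), k=config.cv_folds,
                replicates=config.cv_replicates,
                seed=stage_seed(config.seed, f"classify:{m}"))
            rows[m] = {"median_auprc": cv.median_auprc,
                       **{f"rep{i}": v for i, v in
                          enumerate(cv.replicate_auprc)}}
        auprc_table = pd.DataFrame(rows).T.rename_axis("module")
        auprc_table.to_csv(out / "module_auprc.tsv", sep="\t")
        state["auprc"] = auprc_table
        record("classify", {"folds": config.cv_folds}, [out / "module_auprc.tsv"])

    if "enrich" in enabled:
        bulk, est = state["bulk"], state["modules"]
        target = state.get("target_module", est.retained_modules_[0])
        universe = list(est.labels_.index)
        # planted truth sets act as the pathway collection for the report
        pathways = {}
        for mod in sorted(set(bulk.gene_modules.values())):
            pathways[f"planted:{mod}"] = [
                g for g, m in bulk.gene_modules.items() if m == mod and
                g in set(universe)]
        genes = list(est.labels_.index[est.labels_ == target])
        enr = assoc.ora_enrichment(genes, pathways, universe)
        enr.to_csv(out / "enrichment.tsv", sep="\t")
        record("enrich", {"module": target}, [out / "enrichment.tsv"])

    if "proximity" in enabled:
        bulk, est = state["bulk"], state["modules"]
        target = state.get("target_module", est.retained_modules_[0])
        hubs = est.hubs_[target]
        edges = state["edges"]
        screen = proximity.ProximityScreen(
            score_threshold=config.score_threshold,
            pchembl_min=config.pchembl_min,
            n_background=config.n_background, top_k=config.top_k,
            seed=stage_seed(config.seed, "proximity"))
        screen.fit(edges, hubs)
        g = screen.network_.graph
        hubs_in = [h for h in hubs if h in g] or synthetic.choose_module_hubs(
            g, config.n_hubs, seed=stage_seed(config.seed, "hubs"))
        screen.hubs_ = hubs_in
        drug_spec = synthetic.DrugPlantSpec(
            n_null_drugs=config.n_null_drugs,
            n_planted_drugs=config.n_planted_drugs,
            planting_radius=config.planting_radius,
            seed=stage_seed(config.seed, "drugs"))
        drug_table, truth = synthetic.generate_drug_table(drug_spec, g, hubs_in)
        drug_table.to_csv(out / "drug_targets.tsv", sep="\t", index=False)
        result = screen.screen(drug_table)
        result.table.to_csv(out / "proximity_full.tsv", sep="\t", index=False)
        result.top.to_csv(out / "proximity_top.tsv", sep="\t", index=False)
        write_json({"planted": truth}, out / "drug_truth.json")
        record("proximity", {"hubs": hubs_in},
               [out / "drug_targets.tsv", out / "proximity_full.tsv",
                out / "proximity_top.tsv", out / "drug_truth.json"])
        top_ids = set(result.top["drug_id"])
        planted = {d for d, f in truth.items() if f}
        log.info("proximity: %d/%d planted drugs in top %d",
                 len(top_ids & planted), len(planted), config.top_k)

    for skipped in set(["simulate", "modules", "score", "classify", "enrich",
                        "proximity"]) - set(enabled):
        manifest["stages"].append({"stage": skipped, "skipped": True})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out
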