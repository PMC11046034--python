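"""End-to-end orchestration: SNP scoring through evaluation and maps.

``run_all`` chains the three prioritization steps (pleiotropic gene
identification, gene-level credit scoring, pathway-crosstalk
detection) and the evaluation analyses (negative simulation,
benchmarking AUC, LPA, PICT, disease relationships, module enrichment,
hexagonal prioritization map) over one input bundle, writing each
stage's output into a run directory together with the resolved config
and a provenance log. A re-run with ``resume=True`` skips stages whose
outputs already exist under an identical config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from pipetarget import (
    RWRConfig,
    benchmark_auc,
    build_matrix,
    build_network,
    define_poc_targets,
    disease_tree,
    expand_ld,
    find_crosstalk,
    lpa,
    load_drug_table,
    load_lead_snps,
    map_ngenes,
    permutation_significance,
    pict,
    propagate,
    score_linked_genes,
    simulate_negatives,
)
from pipetarget.credit_scoring import credit_table
from pipetarget.crosstalk_detection import merge_pathways
from pipetarget.evidence_mapping import read_eqtl_links, read_genes_bed, read_hic_links
from pipetarget.hexmap import (
    build_geometry,
    cluster_map,
    default_rings,
    overlay_targetability,
    train,
)
from pipetarget.module_analysis import (
    detect_modules,
    drug_target_categories,
    enrich,
    enrichment_frame,
)
from pipetarget.predictor_selection import assess_importance
from pipetarget.snp_scoring import snps_to_frame
from pipetarget.crosstalk_detection import read_gmt

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved inputs and parameters of one pipeline run."""

    genes_bed: str
    lead_snps: str
    ld: str
    network: str
    drugs: str
    pathways_gmt: str
    pathway_edges: str
    phylostrata_gmt: str = ""
    targetability: str = ""
    eqtl: list[str] = field(default_factory=list)
    hic: list[str] = field(default_factory=list)
    diseases: list[str] = field(default_factory=list)

    r2_min: float = 0.8
    window_bp: int = 20_000
    string_cutoff: int = 700
    restart: float = 0.75
    n_trees: int = 200
    n_reps: int = 5
    target_size: int = 20
    n_perm_crosstalk: int = 1000
    n_perm_lpa: int = 10_000
    hex_rings: int | None = None
    hex_k: int = 3
    seed: int = 0

    @classmethod
    def from_manifest(cls, manifest: dict, **overrides) -> "RunConfig":
        files = manifest["files"]
        cfg = cls(
            genes_bed=files["genes_bed"], lead_snps=files["lead_snps"],
            ld=files["ld"], network=files["network"], drugs=files["drugs"],
            pathways_gmt=files["pathways_gmt"], pathway_edges=files["pathway_edges"],
            phylostrata_gmt=files.get("phylostrata_gmt", ""),
            targetability=files.get("targetability", ""),
            eqtl=list(files.get("eqtl", [])), hic=list(files.get("hic", [])),
            diseases=sorted(manifest.get("disease_targets", {})),
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed stream derived from the master seed."""
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str, index=False):
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(config: RunConfig, run_dir, resume: bool = False) -> dict:
    """Execute the full pipeline; returns a results summary dict."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    with open(run_dir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
    provenance: dict = {"config_hash": cfg_hash, "stages": {}}
    results: dict = {}
    t_all = time.time()

    def done(stage, *outputs):
        provenance["stages"][stage] = {
            "outputs": [str(o) for o in outputs],
            "seconds": round(time.time() - t0, 3),
        }

    def fresh(path: Path) -> bool:
        """A stage output is reusable if it exists under the same config hash."""
        if not (resume and path.exists()):
            return False
        with open(path) as fh:
            return f"config={cfg_hash}" in fh.readline()

    # --- stage: snps ---
    t0 = time.time()
    snps_path = run_dir / "snps.tsv"
    if fresh(snps_path):
        from pipetarget.snp_scoring import frame_to_snps
        snps = frame_to_snps(pd.read_csv(snps_path, sep="\t", comment="#"))
        leads = [s for s in snps if s.rsid == s.lead_rsid]
        logger.info("resume: reusing %s", snps_path)
    else:
        leads = load_lead_snps(config.lead_snps)
        snps = expand_ld(leads, config.ld, r2_min=config.r2_min)
        _write_tsv(snps_to_frame(snps), snps_path, "snps", cfg_hash)
    results["n_lead_snps"] = len(leads)
    results["n_snps"] = len(snps)
    done("snps", snps_path)

    # --- stage: evidence ---
    t0 = time.time()
    genes = read_genes_bed(config.genes_bed)
    seed_sets = [map_ngenes(snps, genes, window_bp=config.window_bp)]
    for i, p in enumerate(config.hic):
        ds = f"hic_{i + 1:02d}"
        seed_sets.append(score_linked_genes(snps, read_hic_links(p, ds), ds))
    for i, p in enumerate(config.eqtl):
        ds = f"eqtl_{i + 1:02d}"
        seed_sets.append(score_linked_genes(snps, read_eqtl_links(p, ds), ds))
    results["n_seed_sets"] = len(seed_sets)
    done("evidence")

    # --- stage: propagation ---
    t0 = time.time()
    network = build_network(config.network, min_confidence=config.string_cutoff)
    rwr = RWRConfig(restart=config.restart)
    predictors = [propagate(network, s, rwr) for s in seed_sets if s.scores]
    results["n_network_genes"] = network.n_nodes
    done("propagation")

    # --- stage: labels + predictor selection ---
    t0 = time.time()
    drugs = load_drug_table(config.drugs)
    diseases = config.diseases or sorted(drugs["indication"].unique())
    diseases = [d for d in diseases if define_poc_targets(drugs, d)]
    positives = set().union(*(define_poc_targets(drugs, d) for d in diseases))
    ppi_graph = nx.Graph()
    ppi_graph.add_edges_from(
        (u, v) for u, v in _network_edges(network))
    negatives_all = set().union(*(
        simulate_negatives(drugs, d, [ppi_graph], seed=config.stage_seed("negatives"))
        for d in diseases))
    negatives_all -= positives
    labels = {g: "positive" for g in positives}
    labels.update({g: "negative" for g in negatives_all})
    report = assess_importance(
        predictors, labels, n_trees=config.n_trees, n_reps=config.n_reps,
        seed=config.stage_seed("importance"))
    imp_path = run_dir / "importance.tsv"
    _write_tsv(report.to_frame(), imp_path, "importance", cfg_hash)
    matrix = build_matrix(predictors, report)
    matrix_path = run_dir / "matrix.tsv"
    _write_tsv(matrix.to_frame(), matrix_path, "matrix", cfg_hash, index=True)
    results["n_predictors_retained"] = len(matrix.predictors)
    done("selection", imp_path, matrix_path)

    # --- stage: credit scoring ---
    t0 = time.time()
    credits = credit_table(matrix)
    prio_path = run_dir / "prioritization.tsv"
    _write_tsv(credits.table.rename_axis("gene"), prio_path, "prioritize",
               cfg_hash, index=True)
    done("prioritize", prio_path)

    # --- stage: crosstalk ---
    t0 = time.time()
    pathway_net = merge_pathways(config.pathways_gmt, config.pathway_edges)
    crosstalk = find_crosstalk(pathway_net, credits, target_size=config.target_size)
    crosstalk = permutation_significance(
        pathway_net, credits, crosstalk, n_perm=config.n_perm_crosstalk,
        seed=config.stage_seed("crosstalk"))
    ct_path = run_dir / "crosstalk.tsv"
    _write_tsv(
        pd.DataFrame({"gene": crosstalk.nodes,
                      "credit": [crosstalk.credits[g] for g in crosstalk.nodes]}),
        ct_path, "crosstalk", cfg_hash)
    results["crosstalk_size"] = crosstalk.size
    results["crosstalk_p_normal"] = crosstalk.p_normal
    results["crosstalk_p_empirical"] = crosstalk.p_empirical
    done("crosstalk", ct_path)

    # --- stage: evaluation ---
    t0 = time.time()
    eval_out = {}
    lpa_results = {}
    member_genes = {}
    for d in diseases:
        poc = define_poc_targets(drugs, d)
        neg = simulate_negatives(drugs, d, [ppi_graph],
                                 seed=config.stage_seed(f"neg:{d}"))
        auc = benchmark_auc(credits, poc - neg, neg - poc)
        r = lpa(credits, poc, n_perm=config.n_perm_lpa,
                seed=config.stage_seed(f"lpa:{d}"))
        lpa_results[d] = r
        member_genes[d] = poc & r.leading_edge
        eval_out[d] = {
            "n_poc": len(poc), "n_neg": len(neg), "auc": auc,
            "es": r.es, "nes": r.nes, "p": r.p, "coverage": r.coverage,
            "leading_edge_size": len(r.leading_edge),
        }
    for s in pict(lpa_results):
        eval_out[s.disease]["fdr"] = s.fdr
        eval_out[s.disease]["pict"] = s.pict
    tree = disease_tree(member_genes)
    eval_path = run_dir / "evaluation.json"
    with open(eval_path, "w") as fh:
        json.dump({"per_disease": eval_out,
                   "disease_tree_edges": [
                       {"a": u, "b": v, "shared": d["shared"]}
                       for u, v, d in tree.edges(data=True)]},
                  fh, indent=2, sort_keys=True)
    results["evaluation"] = eval_out
    done("evaluate", eval_path)

    # --- stage: modules + enrichment ---
    t0 = time.time()
    ct_graph = nx.Graph()
    ct_graph.add_nodes_from(crosstalk.nodes)
    ct_graph.add_edges_from(crosstalk.edges)
    partition = detect_modules(ct_graph, seed=config.stage_seed("modules"))
    universe = set(crosstalk.nodes)
    annotations: dict[str, set] = {
        k: set(v) for k, v in read_gmt(config.pathways_gmt).items()}
    annotations.update(drug_target_categories(drugs))
    if config.phylostrata_gmt:
        annotations.update({k: set(v) for k, v in read_gmt(config.phylostrata_gmt).items()})
    enrich_frames = []
    for m in range(1, partition.n_modules + 1):
        res = enrich(partition.members(m), annotations, universe)
        df = enrichment_frame(res)
        df.insert(0, "module", f"M{m}")
        enrich_frames.append(df)
    enr_path = run_dir / "module_enrichment.tsv"
    _write_tsv(pd.concat(enrich_frames, ignore_index=True) if enrich_frames
               else pd.DataFrame(), enr_path, "modules", cfg_hash)
    results["n_modules"] = partition.n_modules
    done("modules", enr_path)

    # --- stage: hexmap ---
    t0 = time.time()
    ct_credits = credits.table.loc[
        [g for g in crosstalk.nodes if g in credits.table.index], ["credit"]]
    rings = config.hex_rings if config.hex_rings is not None else default_rings(
        len(ct_credits))
    hexmap = build_geometry(rings)
    hexmap = train(hexmap, ct_credits, seed=config.stage_seed("hexmap"))
    hexmap = cluster_map(hexmap, k=min(config.hex_k, hexmap.n_hex))
    flags = {}
    if config.targetability:
        tdf = pd.read_csv(config.targetability, sep="\t")
        flags = dict(zip(tdf["gene_id"].astype(str), tdf["targetable"].astype(bool)))
    hexmap = overlay_targetability(hexmap, flags)
    hex_path = run_dir / "hexmap.json"
    with open(hex_path, "w") as fh:
        json.dump({
            "rings": hexmap.rings, "n_hex": hexmap.n_hex,
            "bmu": hexmap.bmu,
            "clusters": [int(c) for c in hexmap.clusters],
            "targetability": [None if np.isnan(x) else float(x)
                              for x in hexmap.targetability],
            "cluster_targetability": hexmap.cluster_targetability,
        }, fh, indent=2, sort_keys=True)
    results["hexmap_n_hex"] = hexmap.n_hex
    done("hexmap", hex_path)

    provenance["total_seconds"] = round(time.time() - t_all, 3)
    with open(run_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    results["run_dir"] = str(run_dir)
    return results


def _network_edges(network):
    adj = network.adjacency.tocoo()
    for i, j in zip(adj.row, adj.col):
        if i < j:
            yield network.nodes[i], network.nodes[j]
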