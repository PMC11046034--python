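"""Synthetic input bundles with a planted true-target signal.

Emulates every input class the pipeline consumes — lead-SNP and LD
tables, gene annotation, promoter-capture Hi-C and eQTL link tables, a
STRING-like interaction network, a ChEMBL-like drug-target table,
pathway and phylostratum gene sets and targetability flags — wiring a
configurable set of planted target genes into the signal: lead SNPs
land near them, their regulatory links are strengthened, they form a
network community and a dedicated pathway, and they carry phase->=2
drug records for the simulated diseases. ``signal_strength`` in [0, 1]
scales the planted/background contrast; at 0 the planted genes are
statistically indistinguishable from background.

Everything is driven by one seeded generator, so a config + seed pair
reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GENE_LEN = 5_000
GENE_SPACING = 100_000
N_CHROMS = 4


@dataclass
class FixtureConfig:
    """Parameters of the synthetic study.

    Defaults model a desk-scale study: 200 genes, 12 pleiotropic lead
    SNPs with 3 LD proxies each, 2 Hi-C + 2 eQTL evidence datasets, a
    preferential-attachment interaction network (m = 3) and 20 planted
    true targets shared across 3 simulated diseases.
    """

    n_genes: int = 200
    n_lead_snps: int = 12
    n_proxies_per_lead: int = 3
    n_hic_datasets: int = 2
    n_eqtl_datasets: int = 2
    pa_m: int = 3
    planted_target_count: int = 20
    signal_strength: float = 0.8
    n_diseases: int = 3
    n_decoy_druggable: int = 80
    n_background_pairs: int = 300
    seed: int = 0

    def __post_init__(self):
        for f in ("n_genes", "n_lead_snps", "n_proxies_per_lead", "n_hic_datasets",
                  "n_eqtl_datasets", "pa_m", "planted_target_count", "n_diseases"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.planted_target_count >= self.n_genes:
            raise ValueError("planted_target_count must be < n_genes")

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureConfig":
        return cls(**{k: v for k, v in d.items()
                      if k in {f.name for f in dataclasses.fields(cls)}})


def _gene_table(cfg: FixtureConfig) -> pd.DataFrame:
    ids = [f"gene{i + 1:04d}" for i in range(cfg.n_genes)]
    per = int(np.ceil(cfg.n_genes / N_CHROMS))
    rows = []
    for i, g in enumerate(ids):
        chrom = f"{i // per + 1}"
        k = i % per
        start = 100_000 + k * GENE_SPACING
        rows.append({"gene_id": g, "chrom": chrom, "start": start,
                     "end": start + GENE_LEN - 1})
    return pd.DataFrame(rows)


def _strength_exponent(signal: float) -> float:
    # planted eQTL p-values drawn as U(0,1)**(1+9s): identical to
    # background at s=0, sharply sub-uniform as s -> 1
    return 1.0 + 9.0 * signal


def generate(config: FixtureConfig, out_dir) -> dict:
    """Write the full fixture bundle under ``out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) that
    records the file paths, the planted target genes, the per-disease
    target assignments and every derived seed.
    """
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_table(cfg)
    gene_ids = list(genes["gene_id"])
    planted = sorted(rng.choice(gene_ids, size=cfg.planted_target_count, replace=False))
    planted_set = set(planted)
    background = [g for g in gene_ids if g not in planted_set]

    # --- gene annotation (BED6; 0-based half-open) ---
    bed = genes.assign(start0=genes["start"] - 1, score=0, strand="+")
    bed_path = out / "genes.bed"
    bed[["chrom", "start0", "end", "gene_id", "score", "strand"]].to_csv(
        bed_path, sep="\t", header=False, index=False)

    gene_pos = genes.set_index("gene_id")

    # --- lead SNPs anchored near planted (w.p. signal_strength) or background ---
    leads = []
    anchors = {}
    planted_cycle = list(planted)
    for i in range(cfg.n_lead_snps):
        rsid = f"rs{1000 + i}"
        if rng.random() < cfg.signal_strength and planted_cycle:
            anchor = planted_cycle.pop(int(rng.integers(len(planted_cycle))))
            p = 10.0 ** (-rng.uniform(8.0, 30.0))
            # half the signal loci are distal regulatory SNPs: outside
            # the proximity window, linked to their target gene only
            # through Hi-C / eQTL evidence
            distal = rng.random() < 0.5
        else:
            anchor = background[int(rng.integers(len(background)))]
            p = 10.0 ** (-rng.uniform(7.5, 10.0))
            distal = False
        row = gene_pos.loc[anchor]
        if distal:
            off = int(rng.integers(30_000, 70_000)) * (1 if rng.random() < 0.5 else -1)
            pos = int(row["start"]) + off
        else:
            pos = int(rng.integers(row["start"] - 10_000, row["end"] + 10_000))
        leads.append({"rsid": rsid, "chrom": row["chrom"], "pos": max(pos, 1),
                      "pvalue": p})
        anchors[rsid] = anchor
    leads_df = pd.DataFrame(leads)
    leads_path = out / "lead_snps.tsv"
    leads_df.to_csv(leads_path, sep="\t", index=False)

    # --- LD proxies (plus one sub-threshold decoy per lead) ---
    ld_rows = []
    for lead in leads:
        for j in range(cfg.n_proxies_per_lead):
            prsid = f"{lead['rsid']}p{j}"
            ld_rows.append({
                "lead_rsid": lead["rsid"], "proxy_rsid": prsid,
                "r2": round(float(rng.uniform(0.8, 1.0)), 4),
                "chrom": lead["chrom"],
                "pos": max(int(lead["pos"] + rng.integers(-5_000, 5_000)), 1),
            })
            anchors[prsid] = anchors[lead["rsid"]]
        ld_rows.append({
            "lead_rsid": lead["rsid"], "proxy_rsid": f"{lead['rsid']}x",
            "r2": round(float(rng.uniform(0.2, 0.79)), 4),
            "chrom": lead["chrom"], "pos": int(lead["pos"]) + 1_000,
        })
    ld_path = out / "ld.tsv"
    pd.DataFrame(ld_rows).to_csv(ld_path, sep="\t", index=False)

    pleio_rsids = [r for r in anchors]
    expo = _strength_exponent(cfg.signal_strength)

    # --- evidence link datasets ---
    # each dataset emulates one tissue/cell type: a planted gene shows
    # strengthened links only where it is "active" in that tissue
    def _link_rows(kind: str) -> pd.DataFrame:
        active = {g for g in planted if rng.random() < 0.7}
        rows = []
        # background pairs over non-pleiotropic SNPs: the eCDF substrate
        for k in range(cfg.n_background_pairs):
            g = gene_ids[int(rng.integers(len(gene_ids)))]
            u = float(rng.uniform())
            rows.append({"rsid": f"rs9{k:05d}", "gene_id": g, "val": u})
        # pleiotropic SNPs link their anchor gene and two random genes
        for rsid in pleio_rsids:
            targets = [anchors[rsid]] + [gene_ids[int(rng.integers(len(gene_ids)))]
                                         for _ in range(2)]
            for g in targets:
                u = float(rng.uniform())
                rows.append({"rsid": rsid, "gene_id": g,
                             "val": u ** expo if g in active else u})
        # every active planted gene gets two extra pleiotropic links
        for g in sorted(active):
            for rsid in rng.choice(pleio_rsids, size=2, replace=False):
                u = float(rng.uniform())
                rows.append({"rsid": str(rsid), "gene_id": g, "val": u ** expo})
        df = pd.DataFrame(rows)
        if kind == "eqtl":
            df["pvalue"] = df["val"].clip(lower=1e-300)
            return df[["rsid", "gene_id", "pvalue"]]
        # Hi-C: exponential interaction scores, inflated for planted links
        base = -np.log(df["val"].clip(lower=1e-300))
        df["score"] = base.round(6)
        return df[["rsid", "gene_id", "score"]]

    eqtl_paths, hic_paths = [], []
    for i in range(cfg.n_eqtl_datasets):
        p = out / f"eqtl_{i + 1:02d}.tsv"
        _link_rows("eqtl").to_csv(p, sep="\t", index=False)
        eqtl_paths.append(str(p))
    for i in range(cfg.n_hic_datasets):
        p = out / f"hic_{i + 1:02d}.tsv"
        _link_rows("hic").to_csv(p, sep="\t", index=False)
        hic_paths.append(str(p))

    # --- interaction network: preferential attachment + planted community ---
    import networkx as nx

    ba_seed = int(rng.integers(2**31 - 1))
    g_net = nx.barabasi_albert_graph(cfg.n_genes, cfg.pa_m, seed=ba_seed)
    relabel = dict(zip(range(cfg.n_genes), rng.permutation(gene_ids)))
    g_net = nx.relabel_nodes(g_net, relabel)
    for i, a in enumerate(planted):
        for b in planted[i + 1:]:
            if rng.random() < 0.4:
                g_net.add_edge(a, b)
    net_rows = [{"protein1": u, "protein2": v,
                 "combined_score": int(rng.integers(700, 1000))}
                for u, v in sorted(g_net.edges())]
    # sub-threshold decoy edges that the confidence filter must drop
    for _ in range(cfg.n_genes // 10):
        u, v = rng.choice(gene_ids, size=2, replace=False)
        net_rows.append({"protein1": str(u), "protein2": str(v),
                         "combined_score": int(rng.integers(150, 699))})
    net_path = out / "network.tsv"
    pd.DataFrame(net_rows).to_csv(net_path, sep="\t", index=False)

    # --- drug-target table ---
    diseases = [f"disease{i + 1:02d}" for i in range(cfg.n_diseases)]
    disease_targets = {}
    drug_rows = []
    for d in diseases:
        size = int(rng.integers(max(6, cfg.planted_target_count // 2),
                                cfg.planted_target_count + 1))
        tgts = sorted(rng.choice(planted, size=size, replace=False))
        disease_targets[d] = tgts
        for g in tgts:
            phase = int(rng.integers(2, 5))
            drug_rows.append({"gene_id": g, "drug": f"drug_{d}_{g}",
                              "phase": phase, "indication": d,
                              "approved": phase == 4})
    decoys = sorted(rng.choice(background, size=min(cfg.n_decoy_druggable,
                                                    len(background)), replace=False))
    for g in decoys:
        phase = int(rng.integers(1, 5))
        drug_rows.append({"gene_id": g, "drug": f"drug_other_{g}", "phase": phase,
                          "indication": f"other{int(rng.integers(1, 6)):02d}",
                          "approved": phase == 4})
    drugs_path = out / "drugs.tsv"
    pd.DataFrame(drug_rows).to_csv(drugs_path, sep="\t", index=False)

    # --- pathways: a ring of locally dense modules covering the genome ---
    # Every pathway (the planted one included) has the same local
    # topology — a member ring plus random chords — so node degree
    # carries no information about the planted signal; consecutive
    # pathways share one linker gene, which keeps the merged network
    # connected while leaving its diameter large.
    bg_perm = [background[i] for i in rng.permutation(len(background))]
    n_bg_pw = 13
    chunks = np.array_split(np.array(bg_perm), n_bg_pw)
    module_lists = [list(map(str, c)) for c in chunks] + [list(planted)]
    names = [f"pathway{k + 1:02d}" for k in range(n_bg_pw)] + ["planted_module"]
    pw_sets: dict[str, list[str]] = {}
    pw_edges = []
    chord_p = 0.25
    for k, (name, members) in enumerate(zip(names, module_lists)):
        prev = module_lists[k - 1]  # linker gene from the previous module
        linker = prev[int(rng.integers(len(prev)))]
        ext = members + [linker]
        pw_sets[name] = sorted(ext)
        ringm = [ext[i] for i in rng.permutation(len(ext))]
        for i in range(len(ringm)):
            pw_edges.append({"gene1": ringm[i], "gene2": ringm[(i + 1) % len(ringm)],
                             "pathway": name})
        for i, a in enumerate(ringm):
            for b in ringm[i + 2:]:
                if rng.random() < chord_p:
                    pw_edges.append({"gene1": a, "gene2": b, "pathway": name})
    gmt_path = out / "pathways.gmt"
    with open(gmt_path, "w") as fh:
        for name, members in pw_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
    pw_edges_path = out / "pathway_edges.tsv"
    pd.DataFrame(pw_edges).to_csv(pw_edges_path, sep="\t", index=False)

    # --- phylostrata: random partition into PSG01..PSG16 ---
    strata = rng.integers(1, 17, size=cfg.n_genes)
    psg_path = out / "phylostrata.gmt"
    with open(psg_path, "w") as fh:
        for s in range(1, 17):
            members = [g for g, x in zip(gene_ids, strata) if x == s]
            fh.write("\t".join([f"PSG{s:02d}", "synthetic"] + members) + "\n")

    # --- targetability flags ---
    tg_rows = []
    for g in gene_ids:
        p_t = 0.8 if g in planted_set else 0.3
        flag = bool(rng.random() < p_t)
        tg_rows.append({"gene_id": g, "targetable": flag,
                        "n_pockets": int(rng.integers(1, 6)) if flag else 0,
                        "pdb_ids": f"SYN{g[-4:]}" if flag else ""})
    targ_path = out / "targetability.tsv"
    pd.DataFrame(tg_rows).to_csv(targ_path, sep="\t", index=False)

    files = {
        "genes_bed": str(bed_path),
        "lead_snps": str(leads_path),
        "ld": str(ld_path),
        "eqtl": eqtl_paths,
        "hic": hic_paths,
        "network": str(net_path),
        "drugs": str(drugs_path),
        "pathways_gmt": str(gmt_path),
        "pathway_edges": str(pw_edges_path),
        "phylostrata_gmt": str(psg_path),
        "targetability": str(targ_path),
    }
    manifest = {
        "config": dataclasses.asdict(cfg),
        "planted_targets": planted,
        "disease_targets": disease_targets,
        "snp_anchors": anchors,
        "files": files,
    }
    # the on-disk manifest stores bundle-relative names so a bundle is
    # byte-reproducible and relocatable; the returned dict keeps full paths
    rel_files = {k: ([Path(p).name for p in v] if isinstance(v, list)
                     else Path(v).name) for k, v in files.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump({**manifest, "files": rel_files}, fh, indent=2, sort_keys=True)
    return manifest
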