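"""Evaluation analyses: benchmarking, leading prioritization, PICT.

* clinical proof-of-concept (PoC) targets: genes targeted by drugs at
  development phase >= 2 for the disease in question;
* simulated negative targets: the druggable landscape (any gene with a
  drug record at any phase for any indication) minus the disease's own
  targets and their direct interaction neighbors;
* benchmarking: rank-based AUC separating PoC targets from negatives;
* leading prioritization analysis (LPA): a GSEA-style running-score
  test of whether PoC targets concentrate at the top of the credit
  ranking, with NES, permutation p, coverage and the leading edge;
* PICT = log10(NES * Coverage / FDR), quantifying how much pleiotropy
  informs clinical therapeutics for a disease;
* target-level disease relationships: a maximum-sharing spanning tree
  over diseases connected by shared leading-edge PoC targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def load_drug_table(path) -> pd.DataFrame:
    """Read a drug-target table (TSV: gene_id, drug, phase, indication[, approved]).

    ``approved`` defaults to phase == 4 and must agree with it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "drug": str, "indication": str})
    df["phase"] = df["phase"].astype(int)
    if "approved" not in df.columns:
        df["approved"] = df["phase"] == 4
    else:
        df["approved"] = df["approved"].astype(bool)
        bad = df["approved"] != (df["phase"] == 4)
        if bad.any():
            raise ValueError(f"{bad.sum()} records with approved flag inconsistent with phase 4")
    return df


def define_poc_targets(records: pd.DataFrame, disease: str, min_phase: int = 2) -> set[str]:
    """Genes targeted at phase >= ``min_phase`` for ``disease``."""
    hit = records[(records["indication"] == disease) & (records["phase"] >= min_phase)]
    targets = set(hit["gene_id"])
    if not targets:
        logger.warning("no proof-of-concept target for disease %r", disease)
    return targets


def simulate_negatives(
    records: pd.DataFrame,
    disease: str,
    network_neighbors,
    seed: int = 0,
    n: int | None = None,
) -> set[str]:
    """Simulate negative control targets for ``disease``.

    The druggable landscape is every gene with any drug record at any
    phase for any indication; from it, genes indicated for the disease
    (at any phase) and their direct interaction neighbors are excluded.
    ``network_neighbors`` is an iterable of edge lists / graphs whose
    union supplies the neighbor relation. With ``n``, a seeded uniform
    subsample is returned.
    """
    landscape = set(records["gene_id"])
    disease_genes = set(records.loc[records["indication"] == disease, "gene_id"])
    neighbors: set[str] = set()
    for net in network_neighbors:
        edges = net.edges() if isinstance(net, nx.Graph) else net
        for u, v in edges:
            if u in disease_genes:
                neighbors.add(v)
            if v in disease_genes:
                neighbors.add(u)
    pool = sorted(landscape - disease_genes - neighbors)
    if not pool:
        raise ValueError(f"empty negative pool for disease {disease!r}")
    if n is not None and n < len(pool):
        rng = np.random.default_rng(seed)
        pool = sorted(rng.choice(pool, size=n, replace=False))
    return set(pool)


def benchmark_auc(credits, positives: set[str], negatives: set[str]) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    Probability that a random positive outscores a random negative.
    """
    if positives & negatives:
        raise ValueError("positive and negative sets overlap")
    if not positives or not negatives:
        raise ValueError("both sets must be non-empty")
    cred = _as_series(credits)
    scores = np.r_[cred.reindex(sorted(positives)).fillna(0.0).values,
                   cred.reindex(sorted(negatives)).fillna(0.0).values]
    n_pos, n_neg = len(positives), len(negatives)
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # midranks
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _as_series(credits) -> pd.Series:
    if isinstance(credits, pd.Series):
        return credits
    if isinstance(credits, dict):
        return pd.Series(credits)
    return credits.table["credit"]


@dataclass
class LPAResult:
    """Leading prioritization analysis outcome for one target set."""

    es: float
    nes: float
    p: float
    coverage: float
    leading_edge: set[str]
    peak_index: int  # 1-based rank of the running-score peak
    n_perm: int
    fdr: float | None = None
    set_size: int = 0


def _running_es(hit_pos: np.ndarray, hit_w: np.ndarray, n_total: int) -> tuple[float, int]:
    """Max positive deviation of the GSEA running score, evaluated at hits.

    ``hit_pos`` are 0-based ranks of set members (sorted ascending),
    ``hit_w`` their weights. Returns (ES, 0-based peak index).
    """
    m = len(hit_pos)
    miss_pen = 1.0 / (n_total - m)
    wsum = hit_w.sum()
    cum_w = np.cumsum(hit_w) / wsum
    # running value immediately after each hit
    vals = cum_w - (hit_pos + 1 - np.arange(1, m + 1)) * miss_pen
    k = int(np.argmax(vals))
    return float(vals[k]), int(hit_pos[k])


def lpa(
    credits,
    target_set: set[str],
    n_perm: int = 50_000,
    weight: float = 1.0,
    seed: int = 0,
) -> LPAResult:
    """GSEA-style leading prioritization analysis.

    Genes are ranked by credit (descending, ties by gene id); the
    running score rises by credit^weight at members and falls uniformly
    otherwise. ES is the maximum positive deviation; the leading edge
    is the set members at or before the peak, and coverage the fraction
    of the target set recovered there. The null is built from
    size-matched random gene sets; NES = ES / mean(positive null ES)
    and p = (1 + #{null >= ES}) / (1 + n_perm).
    """
    cred = _as_series(credits)
    order = cred.reset_index()
    order.columns = ["gene", "credit"]
    order = order.sort_values(["credit", "gene"], ascending=[False, True], kind="mergesort")
    genes = order["gene"].to_numpy()
    credvals = order["credit"].to_numpy(dtype=float)
    universe = set(genes)
    members = target_set & universe
    missing = target_set - universe
    if missing:
        logger.warning("%d target genes absent from the ranking, dropped", len(missing))
    m = len(members)
    if m == 0 or m >= len(genes):
        raise ValueError("target set empty (or exhausts the ranking) after filtering")
    n_total = len(genes)
    w_all = np.abs(credvals) ** weight
    w_all[w_all == 0] = np.finfo(float).tiny  # zero-credit hits still advance
    is_hit = np.isin(genes, sorted(members))
    hit_pos = np.nonzero(is_hit)[0]
    es, peak0 = _running_es(hit_pos, w_all[hit_pos], n_total)
    leading = set(genes[hit_pos[hit_pos <= peak0]])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n_total, size=m, replace=False))
        null[i], _ = _running_es(pos, w_all[pos], n_total)
    pos_null = null[null > 0]
    nes = float(es / pos_null.mean()) if len(pos_null) else float("nan")
    p = float((1 + np.sum(null >= es)) / (1 + n_perm))
    return LPAResult(
        es=es, nes=nes, p=p,
        coverage=len(leading) / len(target_set),
        leading_edge=leading, peak_index=peak0 + 1,
        n_perm=n_perm, set_size=m,
    )


@dataclass
class PICTScore:
    """Pleiotropy-informing-clinical-therapeutics score for one disease."""

    disease: str
    pict: float | None
    nes: float = float("nan")
    coverage: float = float("nan")
    fdr: float = float("nan")


def pict(results: dict[str, LPAResult]) -> list[PICTScore]:
    """PICT = log10(NES * Coverage / FDR) across diseases.

    FDR is Benjamini-Hochberg across the diseases' LPA p-values,
    floored at 1/n_perm so the score stays finite. Diseases with
    NES <= 0 or zero coverage get a missing PICT.
    """
    diseases = sorted(results)
    ps = np.array([results[d].p for d in diseases])
    _, fdrs, _, _ = multipletests(ps, method="fdr_bh")
    out = []
    for d, fdr in zip(diseases, fdrs):
        r = results[d]
        fdr = max(float(fdr), 1.0 / r.n_perm)
        r.fdr = fdr
        if not np.isfinite(r.nes) or r.nes <= 0 or r.coverage == 0:
            out.append(PICTScore(disease=d, pict=None, nes=r.nes,
                                 coverage=r.coverage, fdr=fdr))
        else:
            out.append(PICTScore(
                disease=d,
                pict=float(np.log10(r.nes * r.coverage / fdr)),
                nes=r.nes, coverage=r.coverage, fdr=fdr,
            ))
    return out


def disease_tree(member_genes: dict[str, set[str]]) -> nx.Graph:
    """Maximum-sharing spanning tree of target-level disease relations.

    Diseases sharing at least one member gene (PoC targets recovered in
    the leading edge) are joined with weight = shared count; a minimum
    spanning tree on cost 1/weight keeps the strongest-sharing backbone.
    Diseases sharing nothing remain isolated nodes.
    """
    g = nx.Graph()
    diseases = sorted(member_genes)
    g.add_nodes_from(diseases)
    for i, a in enumerate(diseases):
        for b in diseases[i + 1:]:
            shared = len(member_genes[a] & member_genes[b])
            if shared >= 1:
                g.add_edge(a, b, shared=shared, cost=1.0 / shared)
    tree_edges = set()
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        mst = nx.minimum_spanning_tree(sub, weight="cost")
        tree_edges.update(frozenset(e) for e in mst.edges())
    out = nx.Graph()
    out.add_nodes_from(diseases)
    for u, v, d in g.edges(data=True):
        if frozenset((u, v)) in tree_edges:
            out.add_edge(u, v, shared=d["shared"], thickness=float(d["shared"]))
    return out
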