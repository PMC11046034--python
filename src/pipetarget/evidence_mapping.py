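"""Mapping scored SNPs to candidate genes (genomic evidence).

Three classes of pleiotropic genes are produced, each as a per-dataset
seed-score set:

* **nGene** — genes within a fixed window (default +/-20 kb) of a lead
  or LD SNP; scored by the maximum SNP score among supporting SNPs.
* **cGene** — genes whose promoters physically contact SNP-harbouring
  regions in a promoter-capture Hi-C dataset.
* **eGene** — genes whose expression is associated with the SNP in an
  eQTL dataset.

For cGene/eGene the SNP score is attenuated by the empirical CDF of the
link strength, computed over *all* SNP-gene pairs of the dataset so the
attenuation is a rank within that dataset:

    S_gene = max over supporting SNPs of [ S_SNP * eCDF(x) ]

where x = -log10(p) for eQTL significance values and the raw interaction
strength for Hi-C scores (already "larger = stronger").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pipetarget.snp_scoring import PleioSNP, _norm_chrom

logger = logging.getLogger(__name__)

WINDOW_BP_DEFAULT = 20_000


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (1-based, inclusive)."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class EvidenceLink:
    """One SNP-to-gene link from a regulatory evidence dataset.

    ``strength`` is the dataset's native quantity (a p-value for eQTL,
    an interaction score for Hi-C); ``x_link`` is the monotone
    "larger = stronger" transform actually ranked by the eCDF.
    """

    rsid: str
    gene_id: str
    dataset_id: str
    evidence_type: str  # "cGene" | "eGene"
    strength: float
    x_link: float


@dataclass
class SeedScoreSet:
    """Per-dataset gene seed scores with their supporting SNPs."""

    dataset_id: str
    evidence_type: str  # "nGene" | "cGene" | "eGene"
    scores: dict[str, float] = field(default_factory=dict)
    snp_support: dict[str, set[str]] = field(default_factory=dict)


def read_genes_bed(path) -> list[GeneModel]:
    """Read gene models from BED6 (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    out = []
    for r in df.itertuples(index=False):
        out.append(GeneModel(
            gene_id=str(r.name), symbol=str(r.name), chrom=_norm_chrom(r.chrom),
            start=int(r.start) + 1, end=int(r.end), strand=str(r.strand),
        ))
    return out


def map_ngenes(
    snps: list[PleioSNP],
    genes: list[GeneModel],
    window_bp: int = WINDOW_BP_DEFAULT,
) -> SeedScoreSet:
    """Score genes with a SNP within ``window_bp`` of the gene body.

    A gene g gets the maximum ``s_snp`` over SNPs with position in
    ``[g.start - window_bp, g.end + window_bp]`` on the same chromosome.
    """
    out = SeedScoreSet(dataset_id="proximity", evidence_type="nGene")
    by_chrom: dict[str, list[PleioSNP]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for g in genes:
        lo, hi = g.start - window_bp, g.end + window_bp
        for s in by_chrom.get(g.chrom, ()):
            if lo <= s.pos <= hi:
                if s.s_snp > out.scores.get(g.gene_id, -math.inf):
                    out.scores[g.gene_id] = s.s_snp
                out.snp_support.setdefault(g.gene_id, set()).add(s.rsid)
    if not out.scores:
        logger.warning("no gene within %d bp of any SNP", window_bp)
    return out


def read_eqtl_links(path, dataset_id: str) -> list[EvidenceLink]:
    """Read eQTL links (TSV: rsid, gene_id, pvalue[, dataset_id]).

    Link strength is a significance p-value; x = -log10(p).
    """
    df = pd.read_csv(path, sep="\t")
    links = []
    for r in df.itertuples(index=False):
        p = float(r.pvalue)
        if not 0.0 < p <= 1.0:
            raise ValueError(f"{path}: eQTL p-value {p} outside (0, 1]")
        links.append(EvidenceLink(
            rsid=str(r.rsid), gene_id=str(r.gene_id), dataset_id=dataset_id,
            evidence_type="eGene", strength=p, x_link=-math.log10(p),
        ))
    return links


def read_hic_links(path, dataset_id: str) -> list[EvidenceLink]:
    """Read promoter-capture Hi-C links (TSV: rsid, gene_id, score).

    Interaction scores are already "larger = stronger": x = score.
    """
    df = pd.read_csv(path, sep="\t")
    return [
        EvidenceLink(
            rsid=str(r.rsid), gene_id=str(r.gene_id), dataset_id=dataset_id,
            evidence_type="cGene", strength=float(r.score), x_link=float(r.score),
        )
        for r in df.itertuples(index=False)
    ]


def score_linked_genes(
    snps: list[PleioSNP],
    links: list[EvidenceLink],
    dataset_id: str,
) -> SeedScoreSet:
    """Score genes linked to pleiotropic SNPs in one evidence dataset.

    The eCDF is estimated over ``x_link`` of every SNP-gene pair in the
    dataset (pleiotropic or not), with right-continuous "<=" counting so
    values lie in (0, 1]. Gene score is the max of ``s_snp * eCDF(x)``
    over links whose SNP is a retained pleiotropic SNP.
    """
    ds_links = [l for l in links if l.dataset_id == dataset_id]
    if len(ds_links) < 2:
        raise ValueError(f"dataset {dataset_id!r} has < 2 SNP-gene pairs; eCDF undefined")
    xs = np.sort(np.array([l.x_link for l in ds_links], dtype=float))
    n = len(xs)
    snp_score = {s.rsid: s.s_snp for s in snps}
    etype = ds_links[0].evidence_type
    out = SeedScoreSet(dataset_id=dataset_id, evidence_type=etype)
    for l in ds_links:
        s = snp_score.get(l.rsid)
        if s is None:
            continue
        ecdf = np.searchsorted(xs, l.x_link, side="right") / n
        val = s * ecdf
        if val > out.scores.get(l.gene_id, -math.inf):
            out.scores[l.gene_id] = val
        out.snp_support.setdefault(l.gene_id, set()).add(l.rsid)
    return out
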