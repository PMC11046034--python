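"""SNP-level scoring of pleiotropic association signals.

Lead SNPs reaching genome-wide significance across two or more diseases
are expanded by linkage disequilibrium (LD) and every retained SNP is
scored by combining its pleiotropic p-value with its LD strength:

    S_SNP = R^2 * ( log10((1-P)/P) - log10((1-T)/T) ),   T = 5e-8

so that a SNP exactly at the genome-wide threshold T scores zero and
stronger associations score higher, attenuated linearly by R^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: Genome-wide significance threshold used as the zero point of the SNP score.
GWAS_THRESHOLD: float = 5e-8

#: Default LD threshold for proxy expansion.
R2_MIN_DEFAULT: float = 0.8


@dataclass(frozen=True)
class PleioSNP:
    """One lead or LD-proxy SNP carrying a pleiotropic association signal.

    Attributes
    ----------
    rsid : str
        SNP identifier.
    chrom : str
        Chromosome name, normalized without a ``chr`` prefix.
    pos : int
        1-based basepair position.
    p_pleio : float
        Pleiotropic p-value combined across diseases. A proxy inherits
        the p-value of its lead SNP.
    r2 : float
        LD strength to the lead SNP (1.0 for a lead to itself).
    lead_rsid : str
        rsid of the lead SNP this record derives from.
    s_snp : float
        SNP score (see :func:`score_snp`).
    """

    rsid: str
    chrom: str
    pos: int
    p_pleio: float
    r2: float = 1.0
    lead_rsid: str = ""
    s_snp: float = field(default=0.0, compare=False)


def _norm_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


def score_snp(p_pleio: float, r2: float, threshold: float = GWAS_THRESHOLD) -> float:
    """Score a SNP from its pleiotropic p-value and LD strength.

    Returns ``r2 * (log10((1-p)/p) - log10((1-T)/T))``; zero when
    ``p == threshold``, positive for smaller p (given ``r2 > 0``).

    Raises
    ------
    ValueError
        If ``p_pleio`` is outside the open interval (0, 1) or ``r2``
        outside [0, 1].
    """
    if not 0.0 < p_pleio < 1.0:
        raise ValueError(f"p_pleio must be in (0, 1), got {p_pleio!r}")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must be in [0, 1], got {r2!r}")
    logit = math.log10((1.0 - p_pleio) / p_pleio)
    ref = math.log10((1.0 - threshold) / threshold)
    return r2 * (logit - ref)


def load_lead_snps(path, gwas_threshold: float = GWAS_THRESHOLD) -> list[PleioSNP]:
    """Read a lead-SNP TSV and keep genome-wide significant records.

    The file must be tab-separated with a header providing columns
    ``rsid``, ``chrom``, ``pos`` and ``pvalue`` (``p`` accepted).
    Only SNPs with p strictly below ``gwas_threshold`` are retained;
    duplicated rsids collapse to the record with the smallest p-value.

    Raises
    ------
    ValueError
        On malformed p-values / non-positive positions (with the
        offending line number) or if no SNP passes the threshold.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    pcol = cols.get("pvalue", cols.get("p"))
    if pcol is None or "rsid" not in cols:
        raise ValueError(f"{path}: expected columns rsid/chrom/pos/pvalue")
    out: dict[str, PleioSNP] = {}
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            p = float(row[pcol])
            pos = int(float(row[cols["pos"]]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line_no}: malformed record ({exc})") from exc
        if not 0.0 < p < 1.0:
            raise ValueError(f"{path}:{line_no}: p-value {p} outside (0, 1)")
        if pos <= 0:
            raise ValueError(f"{path}:{line_no}: non-positive position {pos}")
        if p >= gwas_threshold:
            continue
        rsid = str(row[cols["rsid"]]).strip()
        snp = PleioSNP(
            rsid=rsid,
            chrom=_norm_chrom(row[cols["chrom"]]),
            pos=pos,
            p_pleio=p,
            r2=1.0,
            lead_rsid=rsid,
            s_snp=score_snp(p, 1.0, gwas_threshold),
        )
        prev = out.get(rsid)
        if prev is None or p < prev.p_pleio:
            out[rsid] = snp
    if not out:
        raise ValueError(f"{path}: no SNP passes the threshold {gwas_threshold}")
    return list(out.values())


def expand_ld(
    leads: list[PleioSNP],
    ld_table,
    r2_min: float = R2_MIN_DEFAULT,
    gwas_threshold: float = GWAS_THRESHOLD,
) -> list[PleioSNP]:
    """Expand lead SNPs with LD proxies at ``R^2 >= r2_min``.

    Proxies inherit the combined p-value of their lead; LD attenuation
    enters only through R^2 in the score. A proxy reachable from several
    leads keeps the assignment maximizing its score. Proxies referencing
    an unknown lead are skipped with a warning.

    ``ld_table`` is a TSV path (columns ``lead_rsid``, ``proxy_rsid``,
    ``r2``, optional ``chrom``/``pos``) or an equivalent DataFrame.
    """
    by_rsid = {s.rsid: s for s in leads}
    df = ld_table if isinstance(ld_table, pd.DataFrame) else pd.read_csv(ld_table, sep="\t")
    out: dict[str, PleioSNP] = {s.rsid: s for s in leads}
    for _, row in df.iterrows():
        lead_id = str(row["lead_rsid"]).strip()
        proxy_id = str(row["proxy_rsid"]).strip()
        r2 = float(row["r2"])
        lead = by_rsid.get(lead_id)
        if lead is None:
            logger.warning("LD proxy %s references unknown lead %s; skipped", proxy_id, lead_id)
            continue
        if r2 < r2_min:
            continue
        if proxy_id in by_rsid:  # a lead keeps its own record
            continue
        s = score_snp(lead.p_pleio, r2, gwas_threshold)
        chrom = _norm_chrom(row["chrom"]) if "chrom" in df.columns else lead.chrom
        pos = int(row["pos"]) if "pos" in df.columns else lead.pos
        cand = PleioSNP(
            rsid=proxy_id, chrom=chrom, pos=pos,
            p_pleio=lead.p_pleio, r2=r2, lead_rsid=lead_id, s_snp=s,
        )
        prev = out.get(proxy_id)
        if prev is None or cand.s_snp > prev.s_snp:
            out[proxy_id] = cand
    return list(out.values())


def snps_to_frame(snps: list[PleioSNP]) -> pd.DataFrame:
    """Tabulate SNPs for writing as TSV."""
    return pd.DataFrame(
        [
            {
                "rsid": s.rsid, "chrom": s.chrom, "pos": s.pos,
                "pvalue": s.p_pleio, "r2": s.r2,
                "lead_rsid": s.lead_rsid, "s_snp": s.s_snp,
            }
            for s in snps
        ]
    )


def frame_to_snps(df: pd.DataFrame) -> list[PleioSNP]:
    """Inverse of :func:`snps_to_frame`."""
    return [
        PleioSNP(
            rsid=str(r.rsid), chrom=str(r.chrom), pos=int(r.pos),
            p_pleio=float(r.pvalue), r2=float(r.r2),
            lead_rsid=str(r.lead_rsid), s_snp=float(r.s_snp),
        )
        for r in df.itertuples(index=False)
    ]
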