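"""Gene-level credit scoring by eCDF conversion and Fisher-style combination.

Per retained predictor j, each gene's affinity AF_ij is converted into a
P-like value P_ij = eCDF_j(AF_ij) over all K genes (high affinity ->
P near 1). Per gene, the P-like values are combined in the style of
Fisher's method:

    x_i  = -2 * sum_j ln P_ij
    CP_i = lower-tail CDF of chi-squared(2J) at x_i
    CS_i = 10 * (-log CP_i - MIN) / (MAX - MIN)

Because P_ij are eCDF values (large for strong genes, unlike textbook
Fisher p-values), a top gene has x_i near 0 and hence CP_i near 0 —
the chain eCDF -> x -> lower-tail CDF -> -log is monotone end to end,
so larger affinities always mean larger credit. The lower tail is used
literally; no textbook upper-tail mode is offered. CP is floored at the
smallest positive double before taking logs, with a flag recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pipetarget.predictor_selection import GenePredictorMatrix

#: -log10 of the smallest positive double; floor for -log10(CP).
_NEGLOG_CP_CAP = -np.log10(np.nextafter(0, 1))

LN10 = np.log(10.0)


@dataclass
class CreditTable:
    """Per-gene combined evidence and 0-10 credit score.

    ``table`` columns: ``fisher_stat`` (x_i), ``neg_log_cp`` (-log10 of
    the combined p-like value, floored), ``cp_floored`` (flag),
    ``credit`` in [0, 10] and ``rank`` (1 = highest credit; ties broken
    by ascending gene_id). ``p_like`` holds the K x J matrix of P_ij.
    """

    genes: list[str]
    table: pd.DataFrame
    p_like: pd.DataFrame | None = None

    def credits(self) -> pd.Series:
        return self.table["credit"]

    def ranking(self) -> list[str]:
        """Gene ids ordered by rank (best first)."""
        return list(self.table.sort_values("rank").index)


def convert_to_plike(matrix: GenePredictorMatrix) -> pd.DataFrame:
    """Column-wise eCDF conversion of affinities into P-like values.

    P_ij = (# genes with AF_kj <= AF_ij) / K, right-continuous so
    values lie in [1/K, 1]. Constant columns are rejected: they carry
    no ranking information and should have been filtered upstream.
    """
    af = matrix.af
    K = af.shape[0]
    const = np.ptp(af, axis=0) == 0
    if const.any():
        bad = [matrix.predictors[j] for j in np.nonzero(const)[0]]
        raise ValueError(f"constant predictor column(s): {bad}")
    p = np.column_stack([
        stats.rankdata(af[:, j], method="max") / K for j in range(af.shape[1])
    ])
    return pd.DataFrame(p, index=matrix.genes,
                        columns=[f"{d}|{e}" for d, e in matrix.predictors])


def combine_fisher(p_like: pd.DataFrame) -> pd.DataFrame:
    """Combine P-like values per gene via the chi-squared chain.

    Returns a frame with ``fisher_stat``, ``neg_log_cp`` (log10 scale,
    computed through ``chi2.logcdf`` to dodge underflow and floored at
    the smallest positive double) and the ``cp_floored`` flag.
    """
    J = p_like.shape[1]
    x = -2.0 * np.log(p_like.values).sum(axis=1)
    with np.errstate(divide="ignore"):
        log_cp = stats.chi2.logcdf(x, df=2 * J)
    neg_log_cp = -log_cp / LN10
    floored = ~np.isfinite(neg_log_cp) | (neg_log_cp > _NEGLOG_CP_CAP)
    neg_log_cp = np.where(floored, _NEGLOG_CP_CAP, neg_log_cp)
    return pd.DataFrame(
        {"fisher_stat": x, "neg_log_cp": neg_log_cp, "cp_floored": floored},
        index=p_like.index,
    )


def rescale_credit(combined: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale -log10(CP) onto [0, 10] and attach ranks."""
    v = combined["neg_log_cp"].values.astype(float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("all combined p-like values equal; credit undefined")
    out = combined.copy()
    out["credit"] = 10.0 * (v - lo) / (hi - lo)
    # deterministic tie-break: descending credit, then ascending gene id
    tmp = out.reset_index(names="gene")
    tmp = tmp.sort_values(["credit", "gene"], ascending=[False, True], kind="mergesort")
    ranks = pd.Series(np.arange(1, len(tmp) + 1), index=tmp["gene"])
    out["rank"] = ranks.reindex(out.index).astype(int)
    return out


def credit_table(matrix: GenePredictorMatrix, keep_plike: bool = False) -> CreditTable:
    """Full chain: affinities -> P-like -> combined -> credit table."""
    p_like = convert_to_plike(matrix)
    combined = combine_fisher(p_like)
    table = rescale_credit(combined)
    return CreditTable(genes=matrix.genes, table=table,
                       p_like=p_like if keep_plike else None)
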