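"""Random walk with restart (RWR) over a protein-interaction network.

Each seed-score set is diffused over the interaction network to produce
an affinity predictor covering every network gene, thereby scoring
"peripheral" genes that carry no direct genomic evidence but are wired
to pleiotropic genes. The walk iterates

    P_t = (1 - gamma) * W * P_{t-1} + gamma * P_0

to its stationary vector, where gamma is the restart probability, P_0
the normalized seed vector and W the normalized adjacency. Two
normalizations are supported: symmetric ``D^-1/2 A D^-1/2`` (default)
and column-stochastic ``A D^-1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from pipetarget.evidence_mapping import SeedScoreSet

logger = logging.getLogger(__name__)

MIN_CONFIDENCE_DEFAULT = 700


@dataclass
class RWRConfig:
    """Random-walk parameters. ``restart`` is the probability gamma of
    jumping back to a seed node at each step."""

    restart: float = 0.75
    tol: float = 1e-10
    max_iter: int = 10_000
    normalization: str = "symmetric"  # "symmetric" | "stochastic"

    def __post_init__(self):
        if not 0.0 < self.restart <= 1.0:
            raise ValueError("restart probability must be in (0, 1]")


@dataclass
class PPINetwork:
    """Undirected protein-interaction network with normalized adjacency.

    ``nodes`` indexes the rows/columns of ``adjacency`` (sparse CSR).
    """

    nodes: list[str]
    adjacency: sp.csr_matrix
    node_index: dict[str, int]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _normalize(adj: sp.csr_matrix, mode: str) -> sp.csr_matrix:
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if mode == "symmetric":
        with np.errstate(divide="ignore"):
            d = 1.0 / np.sqrt(deg)
        d[~np.isfinite(d)] = 0.0
        D = sp.diags(d)
        return (D @ adj @ D).tocsr()
    if mode == "stochastic":
        with np.errstate(divide="ignore"):
            d = 1.0 / deg
        d[~np.isfinite(d)] = 0.0
        return (adj @ sp.diags(d)).tocsr()
    raise ValueError(f"unknown normalization {mode!r}")


def build_network(
    edge_file,
    min_confidence: int = MIN_CONFIDENCE_DEFAULT,
    normalization: str = "symmetric",
    weighted: bool = False,
) -> PPINetwork:
    """Build a PPI network from a STRING-like edge TSV.

    Accepts columns ``protein1``/``protein2``/``combined_score`` (or
    ``gene1``/``gene2``/``score``, or an unscored 2-column list). Edges
    below ``min_confidence`` are dropped, the graph is symmetrized and
    deduplicated, self-loops and isolated nodes removed. Confidence is
    by default only a filter (unweighted adjacency); with ``weighted``
    the scores become edge weights.
    """
    df = edge_file if isinstance(edge_file, pd.DataFrame) else pd.read_csv(
        edge_file, sep=None, engine="python")
    cols = list(df.columns)
    a, b = df[cols[0]].astype(str), df[cols[1]].astype(str)
    score = df[cols[2]].astype(float) if len(cols) >= 3 else pd.Series(
        np.full(len(df), 1000.0))
    keep = (score >= min_confidence) & (a != b)
    a, b, score = a[keep], b[keep], score[keep]
    if len(a) == 0:
        raise ValueError(f"no edge passes confidence >= {min_confidence}")
    # canonical orientation, keep max score across duplicates
    lo = np.minimum(a.values, b.values)
    hi = np.maximum(a.values, b.values)
    edges = pd.DataFrame({"u": lo, "v": hi, "w": score.values})
    edges = edges.groupby(["u", "v"], as_index=False)["w"].max()
    nodes = sorted(set(edges["u"]) | set(edges["v"]))
    idx = {g: i for i, g in enumerate(nodes)}
    iu = edges["u"].map(idx).values
    iv = edges["v"].map(idx).values
    w = edges["w"].values if weighted else np.ones(len(edges))
    n = len(nodes)
    adj = sp.coo_matrix((np.r_[w, w], (np.r_[iu, iv], np.r_[iv, iu])), shape=(n, n)).tocsr()
    return PPINetwork(nodes=nodes, adjacency=_normalize(adj, normalization), node_index=idx)


@dataclass
class AffinityPredictor:
    """Gene -> affinity vector: one predictor per evidence dataset."""

    dataset_id: str
    evidence_type: str
    affinity: dict[str, float]

    def vector(self, genes: list[str]) -> np.ndarray:
        return np.array([self.affinity.get(g, 0.0) for g in genes])


def propagate(
    network: PPINetwork,
    seeds: SeedScoreSet,
    cfg: RWRConfig | None = None,
) -> AffinityPredictor:
    """Diffuse a seed-score set over the network by RWR.

    The seed vector is the seed scores on network nodes, normalized to
    sum 1 (off-network seeds dropped with a warning). Iterates until the
    L1 change falls below ``cfg.tol``.

    Raises
    ------
    ValueError
        If every seed is off-network.
    RuntimeError
        If the iteration does not converge within ``cfg.max_iter``.
    """
    cfg = cfg or RWRConfig()
    n = network.n_nodes
    p0 = np.zeros(n)
    dropped = []
    for g, s in seeds.scores.items():
        i = network.node_index.get(g)
        if i is None:
            dropped.append(g)
        else:
            p0[i] += s
    if dropped:
        logger.warning("%d/%d seeds off-network, dropped (%s, ...)",
                       len(dropped), len(seeds.scores), dropped[0])
    total = p0.sum()
    if total <= 0:
        raise ValueError(f"all seeds of {seeds.dataset_id!r} are off-network")
    p0 /= total
    gamma = cfg.restart
    W = network.adjacency
    p = p0.copy()
    for _ in range(cfg.max_iter):
        p_new = (1.0 - gamma) * (W @ p) + gamma * p0
        resid = np.abs(p_new - p).sum()
        p = p_new
        if resid < cfg.tol:
            break
    else:
        raise RuntimeError(
            f"RWR did not converge in {cfg.max_iter} iterations (L1 residual {resid:.3e})")
    return AffinityPredictor(
        dataset_id=seeds.dataset_id,
        evidence_type=seeds.evidence_type,
        affinity={g: float(p[i]) for g, i in network.node_index.items()},
    )


def propagate_exact(network: PPINetwork, seeds: SeedScoreSet,
                    cfg: RWRConfig | None = None) -> np.ndarray:
    """Closed-form stationary vector gamma * (I - (1-gamma) W)^-1 P_0.

    Dense linear solve; intended as an independent cross-check of
    :func:`propagate` on small networks.
    """
    cfg = cfg or RWRConfig()
    n = network.n_nodes
    p0 = np.zeros(n)
    for g, s in seeds.scores.items():
        i = network.node_index.get(g)
        if i is not None:
            p0[i] += s
    if p0.sum() <= 0:
        raise ValueError("all seeds off-network")
    p0 /= p0.sum()
    A = np.eye(n) - (1.0 - cfg.restart) * network.adjacency.toarray()
    return cfg.restart * np.linalg.solve(A, p0)
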