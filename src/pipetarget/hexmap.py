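"""Supra-hexagonal self-organizing map of crosstalk gene credit profiles.

Genes are placed on a centered hexagonal lattice — r rings around a
central hexagon, 3r(r+1)+1 hexagons in total, indexed center-outward
and then clockwise around each ring — by training a batch SOM on the
genes' credit-score profiles across disorder systems. The trained map
is divided into edge-contiguous clusters (Ward on the codebook, with a
contiguity repair pass) and overlaid with the per-hexagon probability
of containing structurally targetable genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, ward
from scipy.spatial.distance import cdist

# axial-coordinate steps walked around a ring starting from (-k, k)
_AX_DIRS = [(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)]


@dataclass
class SupraHexMap:
    """Geometry, codebook and assignments of a supra-hexagonal map."""

    rings: int
    coords: np.ndarray  # (n, 2) axial coordinates, H1 = center
    codebook: np.ndarray | None = None  # (n, D)
    bmu: dict[str, int] = field(default_factory=dict)  # gene -> hexagon (0-based)
    clusters: np.ndarray | None = None  # (n,) 1-based cluster labels
    targetability: np.ndarray | None = None  # (n,) fraction or NaN
    cluster_targetability: dict[int, float] = field(default_factory=dict)

    @property
    def n_hex(self) -> int:
        return len(self.coords)

    def hexagon_genes(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {i: [] for i in range(self.n_hex)}
        for g, h in self.bmu.items():
            out[h].append(g)
        return out


def _axial_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hex grid distance between axial coordinate arrays."""
    dq = a[:, None, 0] - b[None, :, 0]
    dr = a[:, None, 1] - b[None, :, 1]
    return (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) / 2.0


def build_geometry(rings: int) -> SupraHexMap:
    """Centered hexagonal lattice with ``rings`` rings.

    H1 is the center; ring k holds 6k hexagons enumerated clockwise,
    so n = 3r(r+1)+1. Neighboring hexagons are at axial distance 1.
    """
    if rings < 0:
        raise ValueError("rings must be >= 0")
    coords = [(0, 0)]
    for k in range(1, rings + 1):
        q, r = -k, k  # start of ring k (south-west corner)
        for dq, dr in _AX_DIRS:
            for _ in range(k):
                coords.append((q, r))
                q, r = q + dq, r + dr
    return SupraHexMap(rings=rings, coords=np.array(coords, dtype=int))


def default_rings(n_genes: int) -> int:
    """Smallest r with 3r(r+1)+1 >= 5*sqrt(N) map units."""
    target = 5.0 * np.sqrt(max(n_genes, 1))
    r = 0
    while 3 * r * (r + 1) + 1 < target:
        r += 1
    return r


def train(
    hexmap: SupraHexMap,
    data: pd.DataFrame,
    seed: int = 0,
    epochs: tuple[int, int] = (50, 50),
) -> SupraHexMap:
    """Two-phase batch SOM training on a gene x system credit matrix.

    Rough phase shrinks the Gaussian neighborhood radius from the ring
    count to 1, the finetune phase from 1 to 0; codebook rows are
    updated as neighborhood-weighted means of their assigned data.
    Codebook initialized uniformly within the data range (seeded).
    """
    if len(data) < 1:
        raise ValueError("at least one gene is required")
    X = data.values.astype(float)
    genes = list(data.index)
    n, D = hexmap.n_hex, X.shape[1]
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    codebook = rng.uniform(lo, hi + 1e-12, size=(n, D))
    grid_d = _axial_distance(hexmap.coords, hexmap.coords)
    phases = [(float(max(hexmap.rings, 1)), 1.0, epochs[0]),
              (1.0, 0.0, epochs[1])]
    for r0, r1, n_ep in phases:
        for ep in range(n_ep):
            radius = r0 + (r1 - r0) * (ep / max(n_ep - 1, 1))
            d = cdist(X, codebook)
            bmu = np.argmin(d, axis=1)
            sigma = max(radius, 0.2)
            h = np.exp(-(grid_d[:, bmu] ** 2) / (2 * sigma**2))  # (n_hex, n_genes)
            wsum = h.sum(axis=1, keepdims=True)
            newcb = (h @ X) / np.where(wsum > 0, wsum, 1.0)
            codebook = np.where(wsum > 0, newcb, codebook)
    hexmap.codebook = codebook
    final_bmu = np.argmin(cdist(X, codebook), axis=1)
    hexmap.bmu = {g: int(b) for g, b in zip(genes, final_bmu)}
    return hexmap


def cluster_map(hexmap: SupraHexMap, k: int) -> SupraHexMap:
    """Partition the trained map into k edge-contiguous clusters.

    Ward clustering of codebook vectors, then a repair pass: any
    hexagon not edge-connected to its cluster's largest component is
    reassigned to an adjacent cluster (nearest codebook among adjacent
    clusters) until every cluster is contiguous.
    """
    if hexmap.codebook is None:
        raise ValueError("map must be trained before clustering")
    if not 1 <= k <= hexmap.n_hex:
        raise ValueError(f"k must be in [1, {hexmap.n_hex}]")
    labels = fcluster(ward(hexmap.codebook), t=k, criterion="maxclust")
    grid_d = _axial_distance(hexmap.coords, hexmap.coords)
    adj = grid_d == 1
    for _ in range(hexmap.n_hex):  # repair passes; converges quickly
        moved = False
        for lab in np.unique(labels):
            comp = _components(np.nonzero(labels == lab)[0], adj)
            if len(comp) <= 1:
                continue
            comp.sort(key=len, reverse=True)
            for stray in comp[1:]:
                for h in stray:
                    nbr_labs = labels[adj[h]]
                    nbr_labs = nbr_labs[nbr_labs != lab]
                    if len(nbr_labs) == 0:
                        continue
                    # nearest adjacent cluster by codebook distance
                    best, bestd = None, np.inf
                    for cand in np.unique(nbr_labs):
                        centroid = hexmap.codebook[labels == cand].mean(axis=0)
                        dd = np.linalg.norm(hexmap.codebook[h] - centroid)
                        if dd < bestd:
                            best, bestd = cand, dd
                    labels[h] = best
                    moved = True
        if not moved:
            break
    # relabel contiguously from 1
    uniq = {lab: i + 1 for i, lab in enumerate(np.unique(labels))}
    hexmap.clusters = np.array([uniq[l] for l in labels])
    return hexmap


def _components(nodes: np.ndarray, adj: np.ndarray) -> list[list[int]]:
    nodes_set = set(int(x) for x in nodes)
    comps = []
    seen: set[int] = set()
    for start in nodes:
        start = int(start)
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in np.nonzero(adj[v])[0]:
                u = int(u)
                if u in nodes_set and u not in seen:
                    seen.add(u)
                    stack.append(u)
        comps.append(comp)
    return comps


def overlay_targetability(hexmap: SupraHexMap, flags: dict[str, bool]) -> SupraHexMap:
    """Per-hexagon probability of containing structurally targetable genes.

    Each hexagon gets the fraction of its mapped genes flagged
    targetable (genes missing from ``flags`` count untargetable); empty
    hexagons are recorded as missing (NaN), not zero. Per-cluster
    percentages are gene-level fractions over the cluster's genes, not
    means of hexagon fractions.
    """
    frac = np.full(hexmap.n_hex, np.nan)
    for h, genes in hexmap.hexagon_genes().items():
        if genes:
            frac[h] = np.mean([bool(flags.get(g, False)) for g in genes])
    hexmap.targetability = frac
    if hexmap.clusters is not None:
        out = {}
        for lab in np.unique(hexmap.clusters):
            genes = [g for g, h in hexmap.bmu.items() if hexmap.clusters[h] == lab]
            out[int(lab)] = (
                float(np.mean([bool(flags.get(g, False)) for g in genes]))
                if genes else float("nan"))
        hexmap.cluster_targetability = out
    return hexmap
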