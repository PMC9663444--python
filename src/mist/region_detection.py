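"""Molecular region detection on the spot lattice.

The chain is: highly variable gene selection, PCA embedding, a lattice graph
weighted by PC-space Pearson correlation, pruning of low-weight edges,
connected-component extraction, and automatic threshold selection by
maximising intra-region similarity minus inter-region similarity plus a
coverage bonus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_st import STData
from .lattice import LAYOUTS, adjacent_pairs

ISOLATED = -1

__all__ = [
    "ISOLATED",
    "Embedding",
    "SpatialGraph",
    "RegionAssignment",
    "select_hvg",
    "embed_pca",
    "build_weighted_graph",
    "prune_and_components",
    "region_objective",
    "detect_regions",
    "default_min_region_size",
]


@dataclass
class Embedding:
    """Top principal components of the HVG-restricted expression matrix."""

    pcs: np.ndarray  # (M, p)
    p: int
    explained_variance: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class SpatialGraph:
    """Lattice adjacency with per-edge molecular-similarity weights."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) index pairs, i < j
    weights: np.ndarray  # (E,), in [-1, 1]

    def __post_init__(self):
        if self.edges.shape[0] != self.weights.shape[0]:
            raise ValueError("one weight required per edge")


@dataclass
class RegionAssignment:
    """Per-spot region labels (``ISOLATED`` = -1 for unassigned spots)."""

    labels: np.ndarray
    regions: list  # list of np.ndarray spot-index sets, size-descending
    threshold: float
    objective: float = np.nan

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def isolated(self) -> np.ndarray:
        return np.flatnonzero(self.labels == ISOLATED)


def select_hvg(data: STData, fraction: float = 0.8) -> np.ndarray:
    """Indices of the top ``ceil(fraction * N)`` genes by dispersion
    (variance over mean), ranked descending with a stable order."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    x = data.counts
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    order = np.argsort(-dispersion, kind="stable")
    k = int(np.ceil(fraction * data.n_genes))
    return order[:k]


def embed_pca(data: STData, genes: np.ndarray, p: int = 30, log1p: bool = True) -> Embedding:
    """Mean-centred PCA of the (optionally log1p-transformed) HVG sub-matrix.

    The sign of each component is fixed so that its largest-magnitude gene
    loading is positive, making the embedding bit-reproducible.
    """
    genes = np.asarray(genes)
    if p > min(data.n_spots, genes.size):
        raise ValueError(f"p={p} exceeds min(n_spots, n_genes)={min(data.n_spots, genes.size)}")
    x = data.counts[:, genes]
    if log1p:
        x = np.log1p(x)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for k in range(p):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    pcs = u[:, :p] * s[:p]
    expl = s[:p] ** 2 / max(data.n_spots - 1, 1)
    return Embedding(pcs=pcs, p=p, explained_variance=expl)


def _standardized_rows(pcs: np.ndarray) -> np.ndarray:
    mu = pcs.mean(axis=1, keepdims=True)
    sd = pcs.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} spot(s) have zero-variance PC vectors; "
                      "their similarities are set to 0")
    z = np.where(sd > 0, (pcs - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def pc_correlations(emb: Embedding) -> np.ndarray:
    """All-pairs Pearson correlation matrix of the spots' PC vectors."""
    z = _standardized_rows(emb.pcs)
    c = (z @ z.T) / emb.p
    return np.clip(c, -1.0, 1.0)


def build_weighted_graph(data: STData, emb: Embedding, layout: str = "square4") -> SpatialGraph:
    """One edge per lattice-adjacent spot pair, weighted by the Pearson
    correlation of the two spots' PC vectors."""
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    edges = adjacent_pairs(data.coords, layout)
    z = _standardized_rows(emb.pcs)
    if edges.shape[0]:
        w = (z[edges[:, 0]] * z[edges[:, 1]]).sum(axis=1) / emb.p
        w = np.clip(w, -1.0, 1.0)
    else:
        w = np.empty(0)
    return SpatialGraph(n_nodes=data.n_spots, edges=edges, weights=w)


def prune_and_components(graph: SpatialGraph, epsilon: float, q: int) -> RegionAssignment:
    """Drop edges with weight strictly below ``epsilon``, extract connected
    components by depth-first search, and keep components of size > ``q``
    as regions (ids in decreasing size order); the rest are ISOLATED."""
    if q < 1:
        raise ValueError("q must be >= 1")
    keep = graph.weights >= epsilon
    adj = [[] for _ in range(graph.n_nodes)]
    for i, j in graph.edges[keep]:
        adj[i].append(j)
        adj[j].append(i)

    seen = np.zeros(graph.n_nodes, dtype=bool)
    components = []
    for start in range(graph.n_nodes):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in adj[node]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        components.append(np.sort(np.asarray(comp, dtype=np.intp)))

    regions = [c for c in components if c.size > q]
    regions.sort(key=lambda c: (-c.size, int(c[0])))
    labels = np.full(graph.n_nodes, ISOLATED, dtype=int)
    for rid, comp in enumerate(regions):
        labels[comp] = rid
    return RegionAssignment(labels=labels, regions=regions, threshold=epsilon)


def region_objective(assignment: RegionAssignment, emb: Embedding, sigma: float = 0.1,
                     _corr: np.ndarray | None = None) -> float:
    """Threshold-selection score: mean intra-region similarity, minus mean
    inter-region similarity (averaged over region pairs), plus ``sigma``
    times the fraction of spots covered by regions.

    Similarity is the all-pairs Pearson correlation of PC vectors.  Returns
    ``-inf`` when there are no regions; with a single region the
    inter-region term is 0.
    """
    regions = assignment.regions
    if not regions:
        return -np.inf
    c = pc_correlations(emb) if _corr is None else _corr
    m = assignment.labels.size

    intra_terms = []
    for r in regions:
        if r.size < 2:
            intra_terms.append(0.0)
            continue
        block = c[np.ix_(r, r)]
        intra_terms.append((block.sum() - np.trace(block)) / (r.size * (r.size - 1)))
    intra = float(np.mean(intra_terms))

    inter = 0.0
    if len(regions) > 1:
        cross = [
            c[np.ix_(regions[a], regions[b])].mean()
            for a in range(len(regions))
            for b in range(a + 1, len(regions))
        ]
        inter = float(np.mean(cross))

    coverage = sum(r.size for r in regions) / m
    return intra - inter + sigma * coverage


def default_min_region_size(n_spots: int) -> int:
    """Platform default for the minimum region size ``q``: 40 for arrays
    with >= 500 spots (Visium scale), 20 for smaller samples."""
    return 40 if n_spots >= 500 else 20


def detect_regions(
    data: STData,
    sigma: float = 0.1,
    grid=None,
    q: int | None = None,
    p: int = 30,
    hvg_fraction: float = 0.8,
    layout: str = "square4",
    log1p: bool = True,
) -> RegionAssignment:
    """Run the full detection chain and return the assignment maximising the
    threshold-selection objective (ties broken toward the smaller threshold).
    """
    if not data.normalized:
        raise ValueError("detect_regions expects CPM-normalized data")
    if grid is None:
        grid = np.round(np.arange(0.10, 0.9001, 0.05), 10)
    if q is None:
        q = default_min_region_size(data.n_spots)

    genes = select_hvg(data, hvg_fraction)
    p_eff = min(p, data.n_spots, genes.size)
    emb = embed_pca(data, genes, p=p_eff, log1p=log1p)
    graph = build_weighted_graph(data, emb, layout)
    corr = pc_correlations(emb)

    best = None
    for eps in grid:
        cand = prune_and_components(graph, float(eps), q)
        cand.objective = region_objective(cand, emb, sigma, _corr=corr)
        if np.isfinite(cand.objective) and (best is None or cand.objective > best.objective):
            best = cand
    if best is None:
        w = graph.weights
        raise ValueError(
            "no threshold on the grid produced any region; edge-weight "
            f"distribution: min={w.min():.3f} median={np.median(w):.3f} max={w.max():.3f}"
        )
    return best
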