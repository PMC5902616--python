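"""Single-depth PPI network construction and MCODE-style complex detection.

The interaction source is a STRING-like edge list with combined scores in
[0, 1000]; only edges at or above a stringent threshold (default 900) are
kept. The single-depth network is the induced subgraph on the protein-coding
selected genes present in the source ("representors") together with their
first neighbours ("interactors").

Complex (cluster) detection follows the molecular-complex-detection scheme:
each vertex is weighted by the highest k-core of its closed neighbourhood
times that core's density; complexes grow outward from high-weight seeds
through vertices whose weight is within a percentage of the seed's, and are
post-processed by a k-core filter, an optional haircut (removal of
degree-<2 members) and an optional fluff step that adds dense boundary
neighbours, which is the only way complexes may overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SCORE_MIN = 900
DEFAULT_KCORE_FILTER = 10


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def threshold_edges(edges: pd.DataFrame, score_min: int = DEFAULT_SCORE_MIN) -> nx.Graph:
    """Thresholded undirected simple graph from a scored edge list.

    Keeps edges with ``combined_score >= score_min``; duplicate pairs are
    collapsed keeping the maximum score; self-loops are dropped.
    """
    g = nx.Graph()
    sub = edges[edges["combined_score"] >= score_min]
    for u, v, s in sub[["protein1", "protein2", "combined_score"]].itertuples(index=False):
        if u == v:
            continue
        if g.has_edge(u, v):
            if s > g[u][v]["score"]:
                g[u][v]["score"] = int(s)
        else:
            g.add_edge(u, v, score=int(s))
    return g


@dataclass
class PPINetwork:
    """Single-depth interaction network with node roles."""

    graph: nx.Graph = field(repr=False)
    representors: set[str]
    interactors: set[str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def components(self) -> list[set[str]]:
        return sorted(nx.connected_components(self.graph), key=len, reverse=True)


def build_single_depth(graph: nx.Graph, pcpsgs: set[str]) -> PPINetwork:
    """Induced subgraph on pcPSGs present in the source plus first neighbours.

    Representors are pcPSGs with at least one interaction in the thresholded
    source; interactors are their non-pcPSG neighbours. Edges among
    interactors are retained (network, not star-forest, semantics).
    """
    representors = {g for g in pcpsgs if g in graph and graph.degree(g) > 0}
    interactors: set[str] = set()
    for r in representors:
        interactors.update(graph.neighbors(r))
    interactors -= set(pcpsgs)
    nodes = representors | interactors
    sub = graph.subgraph(nodes).copy()
    return PPINetwork(graph=sub, representors=representors, interactors=interactors)


# ---------------------------------------------------------------------------
# vertex weighting
# ---------------------------------------------------------------------------

def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_kcore(g: nx.Graph) -> tuple[int, nx.Graph]:
    """The maximum k such that g has a non-empty k-core, and that core."""
    if g.number_of_edges() == 0:
        return 0, g.subgraph([])
    core_numbers = nx.core_number(g)
    k = max(core_numbers.values())
    core_nodes = [v for v, c in core_numbers.items() if c >= k]
    return k, g.subgraph(core_nodes)


def mcode_weights(graph: nx.Graph) -> pd.DataFrame:
    """Per-vertex core-based weights.

    For each vertex the subgraph induced by its closed neighbourhood is
    taken; the weight is the highest core number k of that subgraph times
    the density of that k-core. Isolated vertices weigh 0.
    """
    rows = []
    for v in graph.nodes:
        nb = list(graph.neighbors(v))
        if not nb:
            rows.append({"vertex": v, "core_k": 0, "core_density": 0.0, "weight": 0.0})
            continue
        sub = graph.subgraph([v, *nb])
        k, core = _highest_kcore(sub)
        d = _density(core)
        rows.append(
            {"vertex": v, "core_k": int(k), "core_density": d, "weight": float(k) * d}
        )
    return pd.DataFrame(
        rows, columns=["vertex", "core_k", "core_density", "weight"]
    ).set_index("vertex")


# ---------------------------------------------------------------------------
# complex detection
# ---------------------------------------------------------------------------

@dataclass
class Complex:
    """A detected dense subgraph: a disjoint core plus optional fluff."""

    seed: str
    core: frozenset[str]
    fluffed: frozenset[str]
    score: float
    kcore_k: int

    @property
    def members(self) -> frozenset[str]:
        return self.core | self.fluffed

    def __len__(self) -> int:
        return len(self.members)


def mcode_complexes(
    graph: nx.Graph,
    weights: pd.DataFrame | None = None,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = True,
    fluff_density: float = 0.1,
    kcore_filter: int = DEFAULT_KCORE_FILTER,
) -> list[Complex]:
    """Grow complexes from high-weight seeds and post-process them.

    Seeds are visited in decreasing weight order (ties by vertex id). From
    an unvisited seed, a breadth-first expansion includes unvisited vertices
    whose weight is at least ``w_seed * (1 - vwp)``; core vertices are
    marked visited globally, so cores are disjoint. Each candidate core is
    then (i) discarded unless it contains a k-core with k >= ``kcore_filter``,
    (ii) haircut by iteratively removing members with in-complex degree < 2,
    and (iii) fluffed by adding boundary neighbours whose closed
    neighbourhood density exceeds ``fluff_density`` (fluffed vertices may
    belong to several complexes). The score is the core density times the
    core size; complexes are returned by decreasing score.
    """
    if not 0 <= vwp <= 1:
        raise ValueError("vwp must lie in [0, 1]")
    if weights is None:
        weights = mcode_weights(graph)
    w = weights["weight"].to_dict()

    order = sorted(graph.nodes, key=lambda v: (-w.get(v, 0.0), v))
    visited: set[str] = set()
    complexes: list[Complex] = []
    for seed in order:
        if seed in visited or w.get(seed, 0.0) <= 0.0:
            continue
        threshold = w[seed] * (1.0 - vwp)
        core = {seed}
        visited.add(seed)
        queue = [seed]
        while queue:
            v = queue.pop(0)
            for u in graph.neighbors(v):
                if u in visited:
                    continue
                if w.get(u, 0.0) >= threshold:
                    visited.add(u)
                    core.add(u)
                    queue.append(u)

        sub = graph.subgraph(core)
        k, _ = _highest_kcore(sub)
        if k < kcore_filter:
            continue

        if haircut:
            core = set(core)
            while True:
                sub = graph.subgraph(core)
                low = [v for v in core if sub.degree(v) < 2]
                if not low:
                    break
                core -= set(low)
            if not core:
                continue

        fluffed: set[str] = set()
        if fluff:
            for v in sorted(core):
                for u in graph.neighbors(v):
                    if u in core or u in fluffed:
                        continue
                    nb_sub = graph.subgraph([u, *graph.neighbors(u)])
                    if _density(nb_sub) > fluff_density:
                        fluffed.add(u)

        core_sub = graph.subgraph(core)
        score = _density(core_sub) * len(core)
        complexes.append(
            Complex(
                seed=seed,
                core=frozenset(core),
                fluffed=frozenset(fluffed),
                score=score,
                kcore_k=int(k),
            )
        )
    complexes.sort(key=lambda c: (-c.score, c.seed))
    return complexes


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def degree_stats(graph: nx.Graph, n_bins: int = 10) -> dict:
    """Log-binned degree histogram with a descriptive log-log power-law fit."""
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    degrees = degrees[degrees > 0]
    if len(degrees) == 0:
        return {"bins": [], "freq": [], "slope": np.nan, "r2": np.nan}
    lo, hi = degrees.min(), degrees.max()
    if lo == hi:
        return {"bins": [float(lo)], "freq": [1.0], "slope": np.nan, "r2": np.nan}
    edges = np.logspace(np.log10(lo), np.log10(hi + 1), n_bins + 1)
    hist, _ = np.histogram(degrees, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    mask = hist > 0
    freq = hist[mask] / len(degrees) / np.diff(edges)[mask]
    res = stats.linregress(np.log10(centers[mask]), np.log10(freq))
    return {
        "bins": centers[mask].tolist(),
        "freq": freq.tolist(),
        "slope": float(res.slope),
        "r2": float(res.rvalue**2),
    }


def shared_gene_counts(complexes: list[Complex]) -> pd.DataFrame:
    """Symmetric matrix of pairwise shared member counts; diagonal = sizes."""
    n = len(complexes)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        mi = complexes[i].members
        mat[i, i] = len(mi)
        for j in range(i + 1, n):
            shared = len(mi & complexes[j].members)
            mat[i, j] = mat[j, i] = shared
    idx = [f"complex_{i + 1}" for i in range(n)]
    return pd.DataFrame(mat, index=idx, columns=idx)
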