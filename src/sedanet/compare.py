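"""Agreement between the Spearman and copula networks vs a rewiring null.

The observed statistic is the Jaccard index of the two (positive) edge
sets; the null distribution comes from degree-preserving double-edge
swaps applied to the copula network, repeated per lambda along the
shrinkage grid.  An observed overlap above the whole null distribution
indicates shared structure beyond what degree sequences alone produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .copula import CopulaGraph
from .io import InputError


def canonical_edges(edges) -> set[frozenset]:
    """Canonicalise an edge iterable to a set of unordered pairs."""
    out = set()
    for e in edges:
        u, v = tuple(e)[:2]
        if u == v:
            continue
        out.add(frozenset((u, v)))
    return out


def jaccard_edges(edges_a, edges_b) -> float:
    """|A n B| / |A u B| over canonicalised edge sets; 0 when both empty."""
    a = canonical_edges(edges_a)
    b = canonical_edges(edges_b)
    union = a | b
    if not union:
        warnings.warn("both edge sets empty; Jaccard defined as 0")
        return 0.0
    return len(a & b) / len(union)


def double_edge_swap(net: nx.Graph, n_swaps: int | None = None,
                     seed: int = 0) -> nx.Graph:
    """Degree-preserving rewiring by repeated double-edge swaps.

    Swaps (a-b, c-d) -> (a-d, c-b), rejecting self-loops and multi-edges.
    Defaults to 10x the edge count, enough to approach the
    configuration-model mixing regime.  Graphs admitting no valid swap
    are returned unchanged with a warning.
    """
    g = net.copy()
    m = g.number_of_edges()
    if n_swaps is None:
        n_swaps = 10 * m
    if m < 2 or g.number_of_nodes() < 4 or n_swaps == 0:
        if m >= 1:
            warnings.warn("graph admits no double-edge swap; returned unchanged")
        return g
    try:
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps,
                            seed=int(seed))
    except nx.NetworkXException as exc:
        warnings.warn(f"double-edge swap gave up ({exc}); "
                      "returning partially rewired graph")
    assert sorted(d for _, d in g.degree()) == \
        sorted(d for _, d in net.degree())
    return g


@dataclass
class ComparisonReport:
    """Observed vs null Jaccard overlap along the shrinkage grid."""

    lambdas: list[float]
    observed: list[float]
    nulls: list[list[float]]
    n_reps: int
    exceedance: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exceedance:
            self.exceedance = [
                float(np.mean([x >= obs for x in null])) if null else np.nan
                for obs, null in zip(self.observed, self.nulls)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lam, obs, null, exc in zip(self.lambdas, self.observed,
                                       self.nulls, self.exceedance):
            arr = np.asarray(null, dtype=float)
            rows.append({"lambda": lam, "observed_jaccard": obs,
                         "null_mean": arr.mean() if arr.size else np.nan,
                         "null_min": arr.min() if arr.size else np.nan,
                         "null_max": arr.max() if arr.size else np.nan,
                         "exceedance": exc})
        return pd.DataFrame(rows)


def null_overlap(spearman_edges, copula_graphs: list[CopulaGraph],
                 n_reps: int = 10, seed: int = 0,
                 n_swaps: int | None = None) -> ComparisonReport:
    """Observed Jaccard per lambda vs a swap-null on the copula network.

    Edge universes are restricted to the shared node set of the two
    networks; only positive copula edges are compared against the
    (positive) Spearman edges.  The null rewires the copula graph, as it
    is the model-based network whose degree structure we condition on.
    """
    sp_edges = canonical_edges(spearman_edges)
    sp_nodes = {n for e in sp_edges for n in e}
    rng = np.random.default_rng(seed)
    lambdas, observed, nulls = [], [], []
    for cg in copula_graphs:
        g = cg.to_graph(sign="positive")
        shared = sp_nodes & set(cg.families)
        g = g.subgraph(shared).copy()
        sp_sub = {e for e in sp_edges if e <= shared}
        obs = jaccard_edges(sp_sub, g.edges()) if g.number_of_edges() else 0.0
        null = []
        for _ in range(n_reps):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            rewired = double_edge_swap(g, n_swaps=n_swaps, seed=sub_seed)
            null.append(jaccard_edges(sp_sub, rewired.edges()))
        lambdas.append(cg.lam)
        observed.append(obs)
        nulls.append(null)
    return ComparisonReport(lambdas, observed, nulls, n_reps)
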