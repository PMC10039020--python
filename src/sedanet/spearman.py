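"""Thresholded positive Spearman co-occurrence network and node analyses.

The network has one node per family and an edge wherever the pairwise
Spearman rank correlation exceeds ``rho_min`` with a Benjamini-Hochberg
adjusted p value (over the full upper triangle of tested pairs) below
``alpha``.  Only positive correlations enter the headline network;
isolated nodes are pruned.  Modules default to connected components,
labelled in decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import InputError, TaxonAnnotation


def bh_adjust(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, returned in the
    input order.  ``m`` defaults to the number of tests supplied.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise InputError("p must be 1-D")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputError("p values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    m = n if m is None else int(m)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


@dataclass
class CorrelationResult:
    """All-pairs Spearman rho with raw and BH-adjusted p values."""

    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame

    @property
    def families(self) -> list[str]:
        return list(self.rho.columns)


def pairwise_spearman(matrix: pd.DataFrame) -> CorrelationResult:
    """Pairwise Spearman correlations with BH adjustment over the upper triangle.

    Rho is the Pearson correlation of average ranks; two-sided p values use
    the t approximation.  Constant columns yield NaN rho/p and are excluded
    from the multiple-testing battery (their p_adj stays NaN).
    """
    if matrix.shape[0] < 4:
        raise InputError("need at least 4 samples")
    if matrix.shape[1] < 2:
        raise InputError("need at least 2 families")
    X = matrix.to_numpy(dtype=float)
    n, f = X.shape
    ranks = stats.rankdata(X, axis=0)  # average ranks for ties
    const = np.ptp(X, axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0  # |rho| = 1: t approximation degenerates
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    p[const, :] = np.nan
    p[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices(f, k=1)
    flat_p = p[iu]
    tested = ~np.isnan(flat_p)
    adj_flat = np.full(flat_p.shape, np.nan)
    if tested.any():
        adj_flat[tested] = bh_adjust(flat_p[tested])
    p_adj = np.full((f, f), np.nan)
    p_adj[iu] = adj_flat
    p_adj.T[iu] = adj_flat
    np.fill_diagonal(p_adj, 0.0)
    idx = matrix.columns
    return CorrelationResult(
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(p_adj, index=idx, columns=idx))


def build_network(cr: CorrelationResult, rho_min: float = 0.4,
                  alpha: float = 0.1, sign: str = "positive") -> nx.Graph:
    """Threshold a correlation result into an undirected network.

    Edge (i, j) iff rho_ij > rho_min (or < -rho_min for the negative
    diagnostic variant) and adjusted p < alpha; edge weight = rho.
    Isolated nodes are removed, so every remaining node has degree >= 1.
    """
    if sign not in ("positive", "negative"):
        raise InputError("sign must be 'positive' or 'negative'")
    fams = cr.families
    rho = cr.rho.to_numpy()
    p_adj = cr.p_adj.to_numpy()
    g = nx.Graph()
    for i in range(len(fams)):
        for j in range(i + 1, len(fams)):
            r = rho[i, j]
            q = p_adj[i, j]
            if np.isnan(r) or np.isnan(q) or q >= alpha:
                continue
            if (sign == "positive" and r > rho_min) or \
               (sign == "negative" and r < -rho_min):
                g.add_edge(fams[i], fams[j], weight=float(r))
    return g


def annotate_nodes(net: nx.Graph, abundance: pd.Series | None = None,
                   ann: TaxonAnnotation | None = None,
                   env_tags: dict[str, str] | None = None,
                   modules: dict[str, int] | None = None) -> nx.Graph:
    """Attach abundance / functional group / env tag / module attributes."""
    for node in net.nodes:
        if abundance is not None:
            net.nodes[node]["abundance"] = float(abundance.get(node, 0.0))
        if ann is not None and node in ann.table.index:
            net.nodes[node]["functional_group"] = ann.group_of(node)
        if env_tags is not None:
            net.nodes[node]["env_tag"] = env_tags.get(node, "none")
        if modules is not None and node in modules:
            net.nodes[node]["module"] = int(modules[node])
    return net


def find_modules(net: nx.Graph, method: str = "components",
                 seed: int = 0) -> dict[str, int]:
    """Label network modules; default = connected components by size.

    ``greedy-modularity`` is available as an alternative community
    detection method (deterministic given the graph).
    """
    if net.number_of_nodes() == 0:
        return {}
    if method == "components":
        comps = sorted(nx.connected_components(net),
                       key=lambda c: (-len(c), sorted(c)[0]))
    elif method == "greedy-modularity":
        comps = list(nx.algorithms.community.greedy_modularity_communities(net))
        comps.sort(key=lambda c: (-len(c), sorted(c)[0]))
    else:
        raise InputError(f"unknown module method {method!r}")
    return {node: i for i, comp in enumerate(comps) for node in comp}


def fr_layout(net: nx.Graph, seed: int = 0) -> dict[str, np.ndarray]:
    """Fruchterman-Reingold force-directed layout, deterministic under seed."""
    return nx.spring_layout(net, seed=seed)


@dataclass
class NeighborReport:
    """Contingency of seed-node links tallied by neighbour functional group."""

    table: pd.Series            # functional group -> link count
    n_links: int
    n_neighbor_families: int
    n_groups: int

    def shares(self) -> pd.Series:
        """Percentage share of links per functional group (sums to 100)."""
        return 100.0 * self.table / self.table.sum()


def neighbor_composition(net: nx.Graph, seed_set, ann: TaxonAnnotation
                         ) -> NeighborReport:
    """Tally links from tagged seed families to their network neighbours.

    Mirrors the adjacent-vertices + contingency-table idiom: every
    (seed, neighbour) adjacency contributes one link, tallied under the
    neighbour's functional group.  Also reports the number of distinct
    neighbour families and functional groups.
    """
    seed_set = list(seed_set)
    unknown = [s for s in seed_set if s not in net]
    if unknown:
        raise InputError(f"seed families not in network: {unknown}")
    tally: dict[str, int] = {}
    neighbors: set[str] = set()
    n_links = 0
    for s in seed_set:
        for v in net.neighbors(s):
            grp = ann.group_of(v) if v in ann.table.index else "unknown"
            tally[grp] = tally.get(grp, 0) + 1
            neighbors.add(v)
            n_links += 1
    table = pd.Series(tally, dtype=int).sort_values(ascending=False)
    return NeighborReport(table, n_links, len(neighbors), len(table))


@dataclass
class DegreeTestReport:
    mean_a: float
    mean_b: float
    t: float
    p: float
    df: float


def compare_degrees(net: nx.Graph, set_a, set_b) -> DegreeTestReport:
    """Welch two-sample t-test on node degrees of two family sets."""
    set_a, set_b = list(set_a), list(set_b)
    for s in (set_a, set_b):
        if len(s) < 2:
            raise InputError("each set needs at least 2 families")
        missing = [f for f in s if f not in net]
        if missing:
            raise InputError(f"families not in network: {missing}")
    da = np.array([net.degree(f) for f in set_a], dtype=float)
    db = np.array([net.degree(f) for f in set_b], dtype=float)
    res = stats.ttest_ind(da, db, equal_var=False)
    df = getattr(res, "df", np.nan)
    return DegreeTestReport(float(da.mean()), float(db.mean()),
                            float(res.statistic), float(res.pvalue), float(df))
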