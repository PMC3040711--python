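"""Threshold networks, percolation analysis, topology statistics, null model.

Individuals are nodes; an undirected link joins two individuals whenever
their genetic distance is at or below a threshold.  Removing links in
decreasing distance order, the network stays in one giant component until
the percolation distance Dp, where it fragments into clusters.  Dp is
located as the peak of the mean cluster size excluding the largest,

    <S>* = (1/N) * sum_{s != largest} s^2 n_s,

with n_s the number of clusters of size s and N the number of nodes outside
the largest cluster (<S>* := 0 for a connected graph).  At Dp, the species
clusters and the bridge individuals connecting them become visible; bridge
("intermediate") individuals incident to inter-species links are the
putative hybrids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import _rewire
from .distances import DistanceMatrix
from .errors import ValidationError
from .genotype_io import NATURAL_SPECIES


def build_graph(matrix: DistanceMatrix, thr: float) -> nx.Graph:
    """Threshold graph: edge {i, j} iff D(i, j) <= thr (inclusive).

    All individuals appear as nodes, isolates included; node attributes are
    copied from the matrix metadata, edges carry their distance.
    """
    if thr < 0:
        raise ValidationError(f"threshold must be non-negative, got {thr}")
    g = nx.Graph(thr=float(thr), metric=matrix.metric)
    for ind_id in matrix.ids:
        g.add_node(ind_id, **matrix.node_meta.get(ind_id, {}))
    vals = matrix.values
    ii, jj = np.nonzero(np.triu(vals <= thr, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(matrix.ids[i], matrix.ids[j], distance=float(vals[i, j]))
    return g


# ---------------------------------------------------------------------------
# Percolation
# ---------------------------------------------------------------------------


@dataclass
class PercolationProfile:
    """<S>* and component counts over descending realized thresholds."""

    thresholds: np.ndarray  # strictly decreasing realized distance values
    mean_cluster_size: np.ndarray  # <S>* at each threshold
    n_components: np.ndarray
    largest_component_size: np.ndarray
    dp: float | None = None  # peak of <S>* (set by detect_percolation_threshold)
    dp_last_connected: float | None = None  # smallest thr at which graph is connected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "mean_cluster_size": self.mean_cluster_size,
                "n_components": self.n_components,
                "largest_size": self.largest_component_size,
            }
        )

    def to_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write(f"# dp={self.dp!r} dp_last_connected={self.dp_last_connected!r}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def threshold_below(self, value: float) -> float | None:
        """Largest realized threshold strictly below ``value`` (None if none)."""
        below = self.thresholds[self.thresholds < value]
        return float(below.max()) if below.size else None


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return True


def mean_cluster_size_excluding_largest(sizes: Iterable[int]) -> float:
    """<S>* from a multiset of component sizes; exactly one maximal component
    is excluded (the result only depends on sizes, so the choice among tied
    maxima is immaterial)."""
    sizes = sorted(sizes)
    if not sizes:
        return 0.0
    rest = sizes[:-1]  # drop one largest
    n_out = sum(rest)
    if n_out == 0:
        return 0.0
    return sum(s * s for s in rest) / n_out


def percolation_profile(matrix: DistanceMatrix) -> PercolationProfile:
    """Compute <S>*, component counts and largest-component size at every
    distinct realized distance (descending); equal-weight links are removed
    atomically."""
    n = len(matrix)
    if n < 3:
        raise ValidationError("percolation_profile needs at least 3 individuals")
    iu = np.triu_indices(n, k=1)
    w = matrix.values[iu]
    order = np.argsort(w, kind="stable")
    ei, ej, ew = iu[0][order], iu[1][order], w[order]
    uniq = np.unique(ew)
    if uniq.size == 1:
        warnings.warn(
            "degenerate matrix: all pairwise distances equal; profile has one point"
        )

    dsu = _DSU(n)
    from collections import Counter

    size_counts = Counter({1: n})
    thresholds, s_star, n_comp, largest = [], [], [], []
    pos = 0
    m = ew.size
    for value in uniq:
        while pos < m and ew[pos] == value:
            a, b = int(ei[pos]), int(ej[pos])
            ra, rb = dsu.find(a), dsu.find(b)
            if ra != rb:
                sa, sb = dsu.size[ra], dsu.size[rb]
                dsu.union(a, b)
                size_counts[sa] -= 1
                if size_counts[sa] == 0:
                    del size_counts[sa]
                size_counts[sb] -= 1
                if size_counts[sb] == 0:
                    del size_counts[sb]
                size_counts[sa + sb] += 1
            pos += 1
        smax = max(size_counts)
        ncomp = sum(size_counts.values())
        n_out = n - smax
        if n_out == 0:
            ss = 0.0
        else:
            ss = (
                sum(s * s * c for s, c in size_counts.items())
                - smax * smax
            ) / n_out
        thresholds.append(float(value))
        s_star.append(ss)
        n_comp.append(ncomp)
        largest.append(smax)

    # descending threshold order
    thresholds = np.array(thresholds[::-1])
    s_star = np.array(s_star[::-1])
    n_comp = np.array(n_comp[::-1], dtype=int)
    largest = np.array(largest[::-1], dtype=int)
    connected = n_comp == 1
    dp_last = float(thresholds[connected].min()) if connected.any() else None
    profile = PercolationProfile(
        thresholds=thresholds,
        mean_cluster_size=s_star,
        n_components=n_comp,
        largest_component_size=largest,
        dp_last_connected=dp_last,
    )
    profile.dp = detect_percolation_threshold(profile)
    return profile


def detect_percolation_threshold(profile: PercolationProfile) -> float:
    """Threshold at the global maximum of <S>*; ties break toward the larger
    threshold.  An all-zero profile (never fragmented) returns the minimum
    realized distance with a warning."""
    if profile.thresholds.size == 0:
        raise ValidationError("empty percolation profile")
    s = profile.mean_cluster_size
    if np.all(s == 0):
        warnings.warn("percolation profile never fragments; Dp set to min distance")
        return float(profile.thresholds.min())
    # thresholds are descending, argmax returns the first (largest) maximum
    return float(profile.thresholds[int(np.argmax(s))])


# ---------------------------------------------------------------------------
# Topology statistics
# ---------------------------------------------------------------------------


@dataclass
class NodeStats:
    """Per-node degree/clustering/betweenness plus global summaries."""

    table: pd.DataFrame  # columns: id, degree, clustering, betweenness
    degree_distribution: dict[int, float]  # P(k), sums to 1
    avg_clustering: float  # <CC> = mean of per-node C_i

    def get(self, node_id: str, column: str) -> float:
        return float(self.table.set_index("id").loc[node_id, column])


def node_statistics(graph: nx.Graph, normalized_betweenness: bool = False) -> NodeStats:
    """Degree k_i, clustering C_i = 2E_i/(k_i(k_i-1)) (0 when k_i < 2) and
    betweenness bc(i) = Σ_{s≠t≠i} σ_st(i)/σ_st over unordered pairs
    (unnormalized by default)."""
    nodes = list(graph.nodes)
    degree = dict(graph.degree())
    clustering = nx.clustering(graph)
    betweenness = nx.betweenness_centrality(graph, normalized=normalized_betweenness)
    table = pd.DataFrame(
        {
            "id": nodes,
            "degree": [degree[v] for v in nodes],
            "clustering": [clustering[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
        }
    )
    n = len(nodes)
    pk: dict[int, float] = {}
    for v in nodes:
        pk[degree[v]] = pk.get(degree[v], 0) + 1 / n
    avg_cc = float(table["clustering"].mean()) if n else 0.0
    return NodeStats(table=table, degree_distribution=pk, avg_clustering=avg_cc)


# ---------------------------------------------------------------------------
# Rewiring null model
# ---------------------------------------------------------------------------


@dataclass
class NullModelResult:
    n_iter: int
    mean_cc: float
    sd_cc: float
    observed_cc: float
    z_score: float | None
    seed: int
    method: str = "rewire"
    degenerate: bool = False  # no legal swap existed (e.g. star graph)

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "mean_cc": self.mean_cc,
            "sd_cc": self.sd_cc,
            "observed_cc": self.observed_cc,
            "z_score": self.z_score,
            "seed": self.seed,
            "method": self.method,
            "degenerate": self.degenerate,
        }


def rewiring_null_model(
    graph: nx.Graph,
    n_iter: int = 10_000,
    seed: int = 0,
    method: str = "rewire",
    swap_factor: int = 10,
) -> NullModelResult:
    """Null distribution of <CC> under link randomization.

    ``method="rewire"`` (default) applies >= ``swap_factor * |E|`` successful
    degree-preserving double-edge swaps per replicate; ``method="gnm"``
    resamples Erdos-Renyi G(n, m) graphs (same node and link counts, degrees
    free).  Reproducible under ``seed``.
    """
    if graph.number_of_edges() < 1:
        raise ValidationError("null model needs a graph with at least one edge")
    if n_iter < 100:
        raise ValidationError("n_iter must be >= 100 for a usable null distribution")
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n, m = len(nodes), graph.number_of_edges()
    observed = node_statistics(graph).avg_clustering

    if method == "rewire":
        adj = np.zeros((n, n), dtype=bool)
        edges = np.empty((m, 2), dtype=np.int64)
        for e, (u, v) in enumerate(graph.edges):
            iu, iv = index[u], index[v]
            adj[iu, iv] = adj[iv, iu] = True
            edges[e] = (iu, iv)
        samples = _rewire.rewired_cc_samples(adj, edges, n_iter, swap_factor * m, seed)
    elif method == "gnm":
        rng = np.random.default_rng(seed)
        samples = np.empty(n_iter)
        for r in range(n_iter):
            g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
            samples[r] = node_statistics(g).avg_clustering
    else:
        raise ValidationError(f"unknown null-model method {method!r}")

    mean_cc = float(np.mean(samples))
    sd_cc = float(np.std(samples))
    degenerate = sd_cc == 0.0
    z = None if degenerate else (observed - mean_cc) / sd_cc
    if degenerate:
        warnings.warn(
            "null distribution has zero variance (no legal rewiring?); z undefined"
        )
    return NullModelResult(
        n_iter=n_iter,
        mean_cc=mean_cc,
        sd_cc=sd_cc,
        observed_cc=observed,
        z_score=z,
        seed=seed,
        method=method,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Intermediate (putative hybrid) individuals
# ---------------------------------------------------------------------------


@dataclass
class IntermediateReport:
    """Nodes incident to at least one inter-species link."""

    ids: set[str]
    table: pd.DataFrame  # id, species, n_same_species, n_other_species, betweenness
    separates_species: bool  # removing the set disconnects the two species


def find_intermediates(graph: nx.Graph) -> IntermediateReport:
    """Individuals carrying inter-species links (putative hybrids).

    Inter-species links join a node labeled *spiralis* to one labeled
    *vesiculosus*; nodes labeled ``simulated_hybrid`` are outside both
    classes.  The report annotates each returned node with its same- and
    other-species neighbor counts and betweenness, and states whether
    removing the whole set severs every path between the two species.
    """
    species = nx.get_node_attributes(graph, "species")
    inter_nodes: set[str] = set()
    for u, v in graph.edges:
        su, sv = species.get(u), species.get(v)
        if {su, sv} == set(NATURAL_SPECIES):
            inter_nodes.update((u, v))

    stats = node_statistics(graph)
    bc = stats.table.set_index("id")["betweenness"]
    rows = []
    for node in sorted(inter_nodes):
        sp = species.get(node)
        same = other = 0
        for nb in graph.neighbors(node):
            sn = species.get(nb)
            if sn == sp:
                same += 1
            elif {sp, sn} == set(NATURAL_SPECIES):
                other += 1
        rows.append(
            {
                "id": node,
                "species": sp,
                "n_same_species": same,
                "n_other_species": other,
                "betweenness": float(bc[node]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["id", "species", "n_same_species", "n_other_species", "betweenness"]
    )

    # articulation check: do the two species still touch without the set?
    pruned = graph.copy()
    pruned.remove_nodes_from(inter_nodes)
    separates = True
    for comp in nx.connected_components(pruned):
        sp_in_comp = {species.get(v) for v in comp}
        if set(NATURAL_SPECIES) <= sp_in_comp:
            separates = False
            break
    return IntermediateReport(ids=inter_nodes, table=table, separates_species=separates)


DEFAULT_SAD_LADDER = (0.5, 0.39, 0.33, 0.28)


def detect_putative_hybrids(
    matrix: DistanceMatrix,
    ladder: Sequence[float] = DEFAULT_SAD_LADDER,
    profile: PercolationProfile | None = None,
) -> tuple[float, IntermediateReport, PercolationProfile]:
    """Canonical putative-hybrid detection on a SAD matrix.

    The screening threshold is the largest value of the standard SAD
    ``ladder`` at or below the network's collapse point (the smallest
    threshold at which the graph is still a single component) — the
    protocol of screening just under the percolation distance, where
    background inter-species links have dropped out but hybrid bridges
    persist; the 0.5 rung is the F1 half-genome sharing level.  Falls back
    to the largest realized distance below the <S>*-peak Dp when the whole
    ladder sits above the collapse point.
    Returns (threshold used, intermediate report, percolation profile).
    """
    if profile is None:
        profile = percolation_profile(matrix)
    collapse = profile.dp_last_connected
    anchor = collapse if collapse is not None else profile.dp
    candidates = [t for t in ladder if t <= anchor]
    if candidates:
        thr = max(candidates)
    else:
        thr = profile.threshold_below(profile.dp)
        if thr is None:
            thr = float(profile.thresholds.min())
    report = find_intermediates(build_graph(matrix, thr))
    return thr, report, profile


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


def threshold_sweep(matrix: DistanceMatrix, thresholds: Sequence[float]) -> pd.DataFrame:
    """Component report at each threshold: one tidy row per (threshold,
    component) with size, species composition, members, plus the per-threshold
    inter-species edge count and intermediates."""
    lo, hi = float(matrix.offdiag_values().min()), float(matrix.offdiag_values().max())
    rows = []
    for thr in thresholds:
        if not (lo <= thr <= hi):
            warnings.warn(
                f"threshold {thr} outside realized distance range [{lo}, {hi}]"
            )
        g = build_graph(matrix, thr)
        species = nx.get_node_attributes(g, "species")
        inter_edges = sum(
            1
            for u, v in g.edges
            if {species.get(u), species.get(v)} == set(NATURAL_SPECIES)
        )
        report = find_intermediates(g)
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        for c_idx, comp in enumerate(comps):
            labels = [species.get(v, "") for v in comp]
            rows.append(
                {
                    "threshold": thr,
                    "component": c_idx,
                    "size": len(comp),
                    "n_spiralis": labels.count("spiralis"),
                    "n_vesiculosus": labels.count("vesiculosus"),
                    "n_simulated_hybrid": labels.count("simulated_hybrid"),
                    "n_intermediates": len(report.ids & comp),
                    "inter_species_edges": inter_edges,
                    "members": ",".join(sorted(comp)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_graphml(
    graph: nx.Graph, path: str | Path, node_stats: NodeStats | None = None,
    intermediates: IntermediateReport | None = None, run_id: str = "",
) -> None:
    """GraphML export with per-node topology attributes and edge distances."""
    g = graph.copy()
    if run_id:
        g.graph["run_id"] = run_id
    if node_stats is not None:
        indexed = node_stats.table.set_index("id")
        for v in g.nodes:
            g.nodes[v]["degree"] = int(indexed.loc[v, "degree"])
            g.nodes[v]["cc"] = float(indexed.loc[v, "clustering"])
            g.nodes[v]["betweenness"] = float(indexed.loc[v, "betweenness"])
    if intermediates is not None:
        for v in g.nodes:
            g.nodes[v]["intermediate"] = v in intermediates.ids
    # GraphML cannot carry None attribute values
    for v in g.nodes:
        for key, val in list(g.nodes[v].items()):
            if val is None:
                g.nodes[v][key] = ""
    nx.write_graphml(g, path)


def write_edge_list(graph: nx.Graph, path: str | Path, run_id: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if run_id:
            fh.write(f"# run_id={run_id}\n")
        fh.write("id_a\tid_b\tdistance\n")
        for u, v, d in graph.edges(data="distance"):
            fh.write(f"{u}\t{v}\t{d!r}\n")
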