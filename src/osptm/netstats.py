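"""Coordinated-response detection over protein-normalized site profiles.

Sites whose Zq_qdna profiles correlate across samples (Pearson r above
a threshold) form a weighted graph; cohesive groups in that graph are
candidate response modules.  The clustering follows the cohesiveness
objective

    f(V) = W_in / (W_in + W_bound + penalty * |V|),

where W_in is the total edge weight inside V and W_bound the total
weight crossing its boundary: clusters are grown greedily from seeds,
merged in a single pass when they overlap strongly, and scored for
significance by a one-sided Mann-Whitney test of internal versus
boundary edge weights.  Cluster-level response distributions are
compared by the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

import logging

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """A detected response module."""

    members: frozenset
    cohesiveness: float
    p_value: float
    group_means: pd.DataFrame | None = None  # members x groups


def correlation_network(matrix: pd.DataFrame, r_min: float = 0.5) -> nx.Graph:
    """Pearson-correlation graph over row profiles.

    One node per row (site); an edge with weight r_ij wherever the
    correlation strictly exceeds ``r_min`` (negative correlations never
    create edges).  Zero-variance rows are excluded with a log message.
    """
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("%d zero-variance sites excluded from the network", int((~keep).sum()))
    labels = [l for l, k in zip(matrix.index, keep) if k]
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    if len(labels) >= 2:
        r = np.corrcoef(values[keep])
        iu, ju = np.triu_indices(len(labels), k=1)
        for i, j in zip(iu, ju):
            if r[i, j] > r_min:
                graph.add_edge(labels[i], labels[j], weight=float(r[i, j]))
    return graph


def cohesiveness(graph: nx.Graph, members: set, penalty: float = 2.0) -> float:
    """f(V) = W_in / (W_in + W_bound + penalty * |V|)."""
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        for v, data in graph[u].items():
            w = data.get("weight", 1.0)
            if v in members:
                w_in += w / 2.0
            else:
                w_bound += w
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def _grow(graph: nx.Graph, seed, penalty: float) -> set:
    """Greedy growth from a seed: repeatedly add the boundary node (or
    remove a member) that most increases cohesiveness."""
    members = {seed}
    f = cohesiveness(graph, members, penalty)
    while True:
        best_f, best_action = f, None
        boundary = {v for u in members for v in graph[u] if v not in members}
        for v in sorted(boundary, key=str):
            cand = members | {v}
            fc = cohesiveness(graph, cand, penalty)
            if fc > best_f:
                best_f, best_action = fc, ("add", v)
        if len(members) > 1:
            for v in sorted(members, key=str):
                cand = members - {v}
                fc = cohesiveness(graph, cand, penalty)
                if fc > best_f:
                    best_f, best_action = fc, ("remove", v)
        if best_action is None:
            return members
        kind, v = best_action
        members = members | {v} if kind == "add" else members - {v}
        f = best_f


def _overlap_score(a: set, b: set) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _edge_weight_split(graph: nx.Graph, members: set) -> tuple[list[float], list[float]]:
    internal, boundary = [], []
    for u in members:
        for v, data in graph[u].items():
            w = data.get("weight", 1.0)
            if v in members:
                if str(u) < str(v):
                    internal.append(w)
            else:
                boundary.append(w)
    return internal, boundary


def cluster_significance(graph: nx.Graph, members: set) -> float:
    """One-sided Mann-Whitney p: are internal edge weights larger than
    boundary edge weights?  A cluster with no boundary edges is
    maximally separated; its p is reported as 0."""
    internal, boundary = _edge_weight_split(graph, members)
    if not internal:
        return 1.0
    if not boundary:
        return 0.0
    return float(stats.mannwhitneyu(internal, boundary, alternative="greater").pvalue)


def cluster_density(graph: nx.Graph, members: set) -> float:
    """Weighted edge density: 2 W_in / (|V| (|V| - 1))."""
    n = len(members)
    if n < 2:
        return 0.0
    w_in = sum(
        d.get("weight", 1.0)
        for u, v, d in graph.edges(members, data=True)
        if u in members and v in members
    )
    return 2.0 * w_in / (n * (n - 1))


def cluster_cohesive(
    graph: nx.Graph,
    min_size: int = 5,
    penalty: float = 2.0,
    overlap: float = 0.8,
    min_density: float = 0.3,
    max_p: float | None = None,
) -> list[ClusterResult]:
    """Cohesiveness-based clustering of a weighted correlation graph.

    Seeds are processed by descending weighted degree (ties by label);
    a node already absorbed into a cluster does not seed again.  Grown
    clusters below ``min_size`` or with weighted density below
    ``min_density`` are discarded; cluster pairs with overlap score
    |A∩B|²/(|A||B|) >= ``overlap`` are merged in a single pass.  With
    ``max_p`` set, only clusters at or below that significance are
    reported.
    """
    if graph.number_of_nodes() == 0:
        return []
    degree = dict(graph.degree(weight="weight"))
    seeds = sorted(graph.nodes, key=lambda v: (-degree[v], str(v)))
    covered: set = set()
    raw: list[set] = []
    for seed in seeds:
        if seed in covered:
            continue
        members = _grow(graph, seed, penalty)
        covered |= members
        if len(members) >= min_size and cluster_density(graph, members) >= min_density:
            raw.append(members)

    # single-pass merging of strongly overlapping clusters
    merged: list[set] = []
    for members in raw:
        target = None
        for existing in merged:
            if _overlap_score(existing, members) >= overlap:
                target = existing
                break
        if target is None:
            merged.append(set(members))
        else:
            target |= members

    results = [
        ClusterResult(
            members=frozenset(m),
            cohesiveness=cohesiveness(graph, m, penalty),
            p_value=cluster_significance(graph, m),
        )
        for m in merged
    ]
    results.sort(key=lambda c: (c.p_value, -len(c.members), sorted(map(str, c.members))))
    if max_p is not None:
        results = [c for c in results if c.p_value <= max_p]
    return results


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the
    p-value is exact when n*m <= 10^4 and asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    method = "exact" if x.size * y.size <= 10_000 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def group_average(
    matrix: pd.DataFrame,
    design: dict[str, str],
    control: str | None = None,
) -> pd.DataFrame:
    """Per-group means of a sites x samples matrix.

    ``design`` maps sample to group.  With ``control`` given, the
    returned frame also carries ``<group>_vs_<control>`` contrast
    columns (group mean minus control mean).
    """
    groups: dict[str, list[str]] = {}
    for s in matrix.columns:
        if s in design:
            groups.setdefault(design[s], []).append(s)
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group needs at least one sample")
    out = pd.DataFrame(
        {g: matrix[cols].mean(axis=1) for g, cols in groups.items()}
    )
    if control is not None:
        if control not in out.columns:
            raise ValueError(f"control group {control!r} not in design")
        for g in groups:
            if g != control:
                out[f"{g}_vs_{control}"] = out[g] - out[control]
    return out
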