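"""Network complexity (simplified von Neumann entropy) and pairwise
network-similarity metrics.

The structural complexity of an HGT network H(V, E) is measured by the
simplified von Neumann entropy

    H_VN = 1 − 1/|V| − (1/|V|²) Σ_{(u,v)∈E} 1/(d_u d_v)

where d_u is the (unweighted) degree of node u and each undirected edge is
counted once. H_VN is 0 for a single isolated node and is bounded above by
1 − 1/|V|; denser, more evenly connected networks score higher, so rising
entropy along a time series indicates a growing, maturing network.

Similarity between two samples' networks is assessed from two complementary
angles: membership (Jaccard index of the node sets — which genomes
participate in HGT at all) and topology (Spearman rank correlation of a
per-node property — degree, PageRank, or local clustering coefficient —
computed in each network and compared over the shared nodes). The combined
score, Jaccard × degree correlation, summarizes both. Within-group versus
between-group similarity is compared with the classical two-sample
Student's t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import stats

from .data_model import HGTNetwork
from .errors import (
    InsufficientDataError,
    UndefinedMetricError,
)

TOPOLOGY_PROPERTIES = ("degree", "pagerank", "clustering_coefficient")

PAGERANK_DAMPING = 0.85
PAGERANK_TOL = 1e-9


@dataclass(frozen=True)
class EntropyValue:
    sample_id: str
    H_VN: float


def von_neumann_entropy(network: HGTNetwork) -> EntropyValue:
    """Exact evaluation of the simplified von Neumann entropy.

    Degrees are unweighted (edge multiplicity is ignored: E is the edge
    *set*). Undefined for an empty network.
    """
    g = network.graph
    n = g.number_of_nodes()
    if n == 0:
        raise UndefinedMetricError(
            f"entropy undefined for empty network {network.sample_id!r}"
        )
    deg = dict(g.degree())
    edge_sum = sum(1.0 / (deg[u] * deg[v]) for u, v in g.edges())
    h = 1.0 - 1.0 / n - edge_sum / (n * n)
    return EntropyValue(sample_id=network.sample_id, H_VN=h)


@dataclass(frozen=True)
class SimilarityScore:
    sample_a: str
    sample_b: str
    metric: str  # {jaccard, degree_corr, pagerank_corr, clustcoef_corr, combined}
    value: float
    correlation_undefined: bool = False  # set on combined when < 3 shared nodes


def node_jaccard(net_a: HGTNetwork, net_b: HGTNetwork) -> SimilarityScore:
    """Jaccard index of the two node (genome) sets."""
    a, b = net_a.nodes, net_b.nodes
    union = a | b
    if not union:
        raise UndefinedMetricError(
            "node Jaccard undefined: both networks are empty"
        )
    value = len(a & b) / len(union)
    return SimilarityScore(net_a.sample_id, net_b.sample_id, "jaccard", value)


def _node_property(network: HGTNetwork, prop: str) -> dict[str, float]:
    g = network.graph
    if prop == "degree":
        return {n: float(d) for n, d in g.degree()}
    if prop == "pagerank":
        return nx.pagerank(g, alpha=PAGERANK_DAMPING, tol=PAGERANK_TOL)
    if prop == "clustering_coefficient":
        return nx.clustering(g)
    from .errors import ParameterError

    raise ParameterError(
        f"unknown property {prop!r}; expected one of {TOPOLOGY_PROPERTIES}"
    )


_METRIC_NAME = {
    "degree": "degree_corr",
    "pagerank": "pagerank_corr",
    "clustering_coefficient": "clustcoef_corr",
}


def topology_correlation(
    net_a: HGTNetwork, net_b: HGTNetwork, property: str = "degree"
) -> SimilarityScore:
    """Spearman correlation of a per-node property over the shared nodes.

    The property is computed on each full network first, then restricted to
    the shared nodes; at least 3 shared nodes are required for the rank
    correlation to be non-degenerate.
    """
    shared = sorted(net_a.nodes & net_b.nodes)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"{len(shared)} shared nodes between {net_a.sample_id!r} and "
            f"{net_b.sample_id!r}; rank correlation needs >= 3"
        )
    pa = _node_property(net_a, property)
    pb = _node_property(net_b, property)
    xs = np.array([pa[n] for n in shared])
    ys = np.array([pb[n] for n in shared])
    if np.unique(xs).size == 1 or np.unique(ys).size == 1:
        raise UndefinedMetricError(
            "rank correlation undefined: zero variance in a ranking"
        )
    rho = float(stats.spearmanr(xs, ys).statistic)
    return SimilarityScore(
        net_a.sample_id, net_b.sample_id, _METRIC_NAME[property], rho
    )


def combined_similarity(net_a: HGTNetwork, net_b: HGTNetwork) -> SimilarityScore:
    """Jaccard × degree correlation; 0 (flagged) when the correlation is
    undefined because fewer than 3 nodes are shared.

    Defining the low-overlap case as 0 rather than dropping the pair keeps
    group sweeps complete: a pair of nearly node-disjoint networks *is*
    maximally dissimilar for this purpose.
    """
    jac = node_jaccard(net_a, net_b)
    try:
        corr = topology_correlation(net_a, net_b, "degree")
    except (InsufficientDataError, UndefinedMetricError):
        return SimilarityScore(
            net_a.sample_id, net_b.sample_id, "combined", 0.0,
            correlation_undefined=True,
        )
    return SimilarityScore(
        net_a.sample_id, net_b.sample_id, "combined", jac.value * corr.value
    )


@dataclass(frozen=True)
class GroupComparison:
    within: tuple[float, ...]
    between: tuple[float, ...]
    t_statistic: float
    p_value: float  # two-sided
    p_one_sided: float  # H1: within > between


def within_between_test(
    scores: Iterable[SimilarityScore],
    pairing: Mapping[tuple[str, str], str],
) -> GroupComparison:
    """Student's t-test of within-group vs between-group similarity values.

    ``pairing`` maps each (sample_a, sample_b) pair to ``"within"`` or
    ``"between"`` (pairs are looked up in either order). Returns the
    two-sided p-value and the one-sided p for within > between.
    """
    within: list[float] = []
    between: list[float] = []
    for s in scores:
        cls = pairing.get((s.sample_a, s.sample_b))
        if cls is None:
            cls = pairing.get((s.sample_b, s.sample_a))
        if cls == "within":
            within.append(s.value)
        elif cls == "between":
            between.append(s.value)
    if len(within) < 2 or len(between) < 2:
        raise InsufficientDataError(
            f"need >= 2 values per class; got {len(within)} within, "
            f"{len(between)} between"
        )
    w = np.asarray(within)
    b = np.asarray(between)
    if w.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if w.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, w.mean() - b.mean())
            p = 0.0
    else:
        res = stats.ttest_ind(w, b, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
    df = len(w) + len(b) - 2
    p_one = float(stats.t.sf(t, df)) if math.isfinite(t) else (0.0 if t > 0 else 1.0)
    return GroupComparison(
        within=tuple(within), between=tuple(between),
        t_statistic=t, p_value=p, p_one_sided=p_one,
    )


def all_pairwise_similarities(
    networks: Mapping[str, HGTNetwork],
    metrics: Iterable[str] = ("jaccard", "degree", "pagerank",
                              "clustering_coefficient", "combined"),
) -> list[SimilarityScore]:
    """Long-format table of every metric over every unordered sample pair.

    Pairs where a correlation metric is undefined (too little overlap or a
    flat ranking) are recorded with value NaN rather than dropped.
    """
    sids = sorted(networks)
    metrics = list(metrics)
    # node properties are pair-independent; compute once per network
    props_needed = [m for m in metrics if m in _METRIC_NAME] + (
        ["degree"] if "combined" in metrics else []
    )
    cache: dict[tuple[str, str], dict[str, float]] = {}
    for sid in sids:
        for prop in set(props_needed):
            cache[(sid, prop)] = _node_property(networks[sid], prop)

    def _corr(a: str, b: str, prop: str) -> SimilarityScore:
        shared = sorted(networks[a].nodes & networks[b].nodes)
        name = _METRIC_NAME[prop]
        if len(shared) < 3:
            return SimilarityScore(a, b, name, float("nan"), correlation_undefined=True)
        xs = np.array([cache[(a, prop)][n] for n in shared])
        ys = np.array([cache[(b, prop)][n] for n in shared])
        if np.unique(xs).size == 1 or np.unique(ys).size == 1:
            return SimilarityScore(a, b, name, float("nan"), correlation_undefined=True)
        rho = float(stats.spearmanr(xs, ys).statistic)
        return SimilarityScore(a, b, name, rho)

    out: list[SimilarityScore] = []
    for i, a in enumerate(sids):
        for b in sids[i + 1:]:
            jac = node_jaccard(networks[a], networks[b])
            for metric in metrics:
                if metric == "jaccard":
                    out.append(jac)
                elif metric == "combined":
                    corr = _corr(a, b, "degree")
                    if corr.correlation_undefined:
                        out.append(SimilarityScore(a, b, "combined", 0.0,
                                                   correlation_undefined=True))
                    else:
                        out.append(SimilarityScore(a, b, "combined",
                                                   jac.value * corr.value))
                else:
                    out.append(_corr(a, b, metric))
    return out
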