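"""Community detection within HGT networks and clustering of communities
across samples into HGT community clusters (HCCs).

Communities — densely connected groups of genomes exchanging genetic
material — are found per sample with the Leiden algorithm (modularity
optimization with a refinement step that guarantees well-connected
communities). Communities from all samples are then clustered by the
Jaccard distance between their genome sets (average-linkage hierarchical
clustering cut at a fixed height); each resulting HCC is a recurrent
community motif.

Because groups contribute unequal numbers of samples, labeling an HCC by the
raw majority of member labels is biased toward the larger group. The
bias-corrected rule assigns the label maximizing COUNT(label)/num(label) —
the number of member communities carrying the label relative to the number
of samples with that label in the dataset — with exact ties reported as
"ambiguous".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import igraph as ig
import leidenalg
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .data_model import HGTNetwork, TaxonomyTable
from .errors import (
    InsufficientDataError,
    ParameterError,
    UndefinedMetricError,
    ValidationError,
)

AMBIGUOUS = "ambiguous"

DEFAULT_HCC_CUT = 0.6
DEFAULT_HCC_MIN_SIZE = 2


@dataclass(frozen=True)
class Community:
    """One detected community: a set of genomes in one sample's network."""

    sample_id: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValidationError("community must have at least one member")

    @property
    def size(self) -> int:
        return len(self.members)


def detect_communities(
    network: HGTNetwork, resolution: float = 1.0, seed: int = 0
) -> list[Community]:
    """Partition a network into communities with the Leiden algorithm.

    Uses modularity-style quality (RB configuration null model) at the given
    resolution, with event multiplicities as edge weights. Deterministic for
    a fixed seed. The returned communities partition the node set.
    """
    if network.number_of_nodes() == 0:
        raise UndefinedMetricError(
            f"cannot detect communities in empty network {network.sample_id!r}"
        )
    nodes = sorted(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for (u, v) in network.edge_weights]
    weights = [float(w) for w in network.edge_weights.values()]
    g = ig.Graph(n=len(nodes), edges=edges)
    partition = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights or None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    out = []
    for block in partition:
        out.append(Community(
            sample_id=network.sample_id,
            members=frozenset(nodes[i] for i in block),
        ))
    # canonical order: largest first, ties by smallest member accession
    out.sort(key=lambda c: (-c.size, min(c.members)))
    return out


def community_jaccard(a: Community, b: Community) -> float:
    inter = len(a.members & b.members)
    union = len(a.members | b.members)
    return inter / union


@dataclass
class CompositionProfile:
    rank: str  # {"phylum", "genus"}
    fractions: dict[str, float]


@dataclass
class CommunityCluster:
    """One HCC: a group of similar communities recurring across samples."""

    cluster_id: int
    communities: list[Community]
    label: str | None = None
    composition: CompositionProfile | None = None

    @property
    def size(self) -> int:
        return len(self.communities)

    def genome_multiset(self) -> list[str]:
        """Concatenation of member genome sets, multiplicity preserved."""
        out: list[str] = []
        for c in self.communities:
            out.extend(sorted(c.members))
        return out


def _canonical_community_order(communities: Iterable[Community]) -> list[Community]:
    return sorted(communities, key=lambda c: (c.sample_id, tuple(sorted(c.members))))


def cluster_communities(
    communities: Iterable[Community],
    max_distance: float = DEFAULT_HCC_CUT,
    min_size: int = DEFAULT_HCC_MIN_SIZE,
) -> tuple[list[CommunityCluster], list[Community]]:
    """Cluster communities from all samples into HCCs.

    Distance between two communities is 1 − Jaccard(member sets);
    average-linkage hierarchical clustering is cut at ``max_distance``.
    Clusters smaller than ``min_size`` go to the returned unclustered pool.
    The assignment is order-invariant: communities are sorted canonically
    (by sample then members) before distances are computed.
    """
    comms = _canonical_community_order(communities)
    if len(comms) < 2:
        raise InsufficientDataError(
            f"{len(comms)} communities; clustering needs >= 2"
        )
    n = len(comms)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - community_jaccard(comms[i], comms[j])
            dist[i, j] = dist[j, i] = d
    z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(z, t=max_distance, criterion="distance")
    blocks: dict[int, list[Community]] = {}
    for comm, a in zip(comms, assignment):
        blocks.setdefault(int(a), []).append(comm)
    clusters: list[CommunityCluster] = []
    unclustered: list[Community] = []
    next_id = 1
    for a in sorted(blocks, key=lambda a: (-len(blocks[a]), a)):
        members = blocks[a]
        if len(members) >= min_size:
            clusters.append(CommunityCluster(cluster_id=next_id, communities=members))
            next_id += 1
        else:
            unclustered.extend(members)
    return clusters, unclustered


@dataclass(frozen=True)
class LabelCounts:
    """Per-label member counts within one cluster plus per-label sample counts."""

    counts: Mapping[str, int]  # COUNT_i(label)
    num_samples: Mapping[str, int]  # num(label): samples with that label in the dataset


def label_cluster(counts: LabelCounts) -> str:
    """Bias-corrected cluster label: argmax of COUNT(label)/num(label).

    Exact ties return "ambiguous". Scale-invariant: multiplying all COUNT
    and num values by one positive constant cannot change the result
    (ratios are compared exactly as rationals).
    """
    labels = sorted(counts.num_samples)
    if len(labels) < 2:
        raise ParameterError(f"need >= 2 labels, got {labels}")
    for lab in labels:
        if counts.num_samples[lab] < 1:
            raise ParameterError(f"num({lab!r}) must be >= 1")
    if all(counts.counts.get(lab, 0) == 0 for lab in labels):
        raise ValidationError("all COUNT values are zero; cluster has no labeled members")
    ratios = {
        lab: Fraction(counts.counts.get(lab, 0), counts.num_samples[lab])
        for lab in labels
    }
    best = max(ratios.values())
    winners = [lab for lab in labels if ratios[lab] == best]
    return winners[0] if len(winners) == 1 else AMBIGUOUS


def label_community_clusters(
    clusters: Sequence[CommunityCluster],
    sample_groups: Mapping[str, str],
) -> None:
    """Assign each HCC its bias-corrected label, in place.

    A community carries the group label of the sample it was detected in;
    num(label) is the number of samples per group in ``sample_groups``.
    """
    num = Counter(sample_groups.values())
    for cluster in clusters:
        member_labels = Counter(
            sample_groups[c.sample_id] for c in cluster.communities
        )
        cluster.label = label_cluster(LabelCounts(counts=member_labels, num_samples=num))


def cluster_composition(
    cluster: CommunityCluster, taxonomy: TaxonomyTable, rank: str = "phylum"
) -> CompositionProfile:
    """Taxonomic composition of an HCC's pooled genome multiset G_i.

    fraction(taxon) = multiplicity of the taxon among the genomes of all
    member communities (repeats across communities preserved) / |G_i|.
    Unresolvable accessions raise a lookup error naming the accession.
    """
    genomes = cluster.genome_multiset()
    taxa = Counter(taxonomy.rank_of(g, rank) for g in genomes)
    total = len(genomes)
    profile = CompositionProfile(
        rank=rank, fractions={t: c / total for t, c in sorted(taxa.items())}
    )
    cluster.composition = profile
    return profile


@dataclass(frozen=True)
class CompositionComparison:
    taxon: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float

    @property
    def direction(self) -> str:
        if self.mean_a > self.mean_b:
            return "a>b"
        if self.mean_a < self.mean_b:
            return "a<b"
        return "a=b"


def compare_compositions(
    profiles_a: Sequence[CompositionProfile],
    profiles_b: Sequence[CompositionProfile],
    taxon: str,
) -> CompositionComparison:
    """Two-sided Student's t-test on per-cluster fractions of one taxon.

    A cluster whose profile lacks the taxon contributes fraction 0 (the
    taxon genuinely makes up 0% of that cluster).
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise InsufficientDataError(
            f"need >= 2 clusters per side; got {len(profiles_a)} and {len(profiles_b)}"
        )
    fa = np.array([p.fractions.get(taxon, 0.0) for p in profiles_a])
    fb = np.array([p.fractions.get(taxon, 0.0) for p in profiles_b])
    if fa.var(ddof=1) == 0 and fb.var(ddof=1) == 0:
        if fa.mean() == fb.mean():
            t, p = 0.0, 1.0
        else:
            t = float("inf") if fa.mean() > fb.mean() else float("-inf")
            p = 0.0
    else:
        res = stats.ttest_ind(fa, fb, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
    return CompositionComparison(
        taxon=taxon, mean_a=float(fa.mean()), mean_b=float(fb.mean()),
        t_statistic=t, p_value=p,
    )
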