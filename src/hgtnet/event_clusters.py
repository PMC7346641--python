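"""Clustering of HGT events by their sample-presence profiles into HGT
event clusters (HECs).

Two HGT events that keep appearing in the same samples are likely carried
by the same mobile element or co-transferred segment. Each event (identified
by its cross-sample key) is summarized by the set of samples it occurs in;
events seen in fewer samples than a minimum-prevalence threshold are
filtered out, pairwise distances are 1 − Jaccard of the presence sets, and
average-linkage hierarchical clustering with a fixed-height tree cut plus a
minimum-class-size gate yields the HECs.

The two study designs use different thresholds, exposed as presets:
mother–child (minimum prevalence 5 samples, minimum class size 10) and
longitudinal IBD (minimum prevalence 4, minimum class size 20); the cut
height is 0.6 for both. HEC labels use the same bias-corrected rule as
community clusters, counting each member event once per sample it occurs
in; the genus composition counts both endpoint genomes of every member
event.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .communities import CompositionProfile, LabelCounts, label_cluster
from .data_model import EventKey, HGTEvent, SampleMetadata, TaxonomyTable, canonical_event_key
from .errors import InsufficientDataError, ParameterError, UndefinedMetricError

DEFAULT_HEC_CUT = 0.6

#: (min_samples, min_class_size) per study design
PRESETS = {
    "mother-child": (5, 10),
    "ibd": (4, 20),
}


@dataclass(frozen=True)
class EventPresence:
    """One distinct event (by key) and the set of samples it occurs in."""

    key: EventKey
    samples: frozenset[str]

    def __post_init__(self):
        if not self.samples:
            raise ParameterError("presence set must be non-empty")


def event_presences(
    events: Iterable[HGTEvent], bin_size: int = 100
) -> list[EventPresence]:
    """Collapse events to distinct keys with their sample-presence sets.

    An event occurring several times in one sample counts once (presence,
    not abundance).
    """
    by_key: dict[EventKey, set[str]] = {}
    for ev in events:
        by_key.setdefault(canonical_event_key(ev, bin_size), set()).add(ev.sample_id)
    return [
        EventPresence(key=k, samples=frozenset(s))
        for k, s in sorted(by_key.items(), key=lambda kv: kv[0])
    ]


def filter_events_by_prevalence(
    presences: Iterable[EventPresence], min_samples: int
) -> list[EventPresence]:
    """Keep events present in at least ``min_samples`` samples.

    Events in *fewer* than the threshold are filtered out, so an event in
    exactly ``min_samples`` samples is retained.
    """
    if min_samples < 1:
        raise ParameterError(f"min_samples must be >= 1, got {min_samples}")
    return [p for p in presences if len(p.samples) >= min_samples]


def event_presence_jaccard(a: EventPresence, b: EventPresence) -> float:
    """Jaccard similarity of the two sample-presence sets."""
    if not a.samples or not b.samples:
        raise UndefinedMetricError("presence Jaccard undefined on empty sample set")
    return len(a.samples & b.samples) / len(a.samples | b.samples)


@dataclass
class EventCluster:
    """One HEC: events co-occurring across a similar set of samples."""

    cluster_id: int
    members: list[EventPresence]
    label: str | None = None
    composition: CompositionProfile | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_events(
    presences: Iterable[EventPresence],
    max_distance: float = DEFAULT_HEC_CUT,
    min_class_size: int = 10,
) -> tuple[list[EventCluster], list[EventPresence]]:
    """Cluster event-presence profiles into HECs.

    Average-linkage hierarchical clustering on 1 − presence-Jaccard
    distances; the dendrogram is cut at ``max_distance`` and classes below
    ``min_class_size`` are moved to the unclustered pool. Every input event
    is assigned exactly once (to a cluster or the pool).
    """
    pres = sorted(presences, key=lambda p: p.key)
    if len(pres) < 2:
        raise InsufficientDataError(f"{len(pres)} presences; clustering needs >= 2")
    n = len(pres)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - event_presence_jaccard(pres[i], pres[j])
            dist[i, j] = dist[j, i] = d
    z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(z, t=max_distance, criterion="distance")
    blocks: dict[int, list[EventPresence]] = {}
    for p, a in zip(pres, assignment):
        blocks.setdefault(int(a), []).append(p)
    clusters: list[EventCluster] = []
    unclustered: list[EventPresence] = []
    next_id = 1
    for a in sorted(blocks, key=lambda a: (-len(blocks[a]), a)):
        members = blocks[a]
        if len(members) >= min_class_size:
            clusters.append(EventCluster(cluster_id=next_id, members=members))
            next_id += 1
        else:
            unclustered.extend(members)
    return clusters, unclustered


def label_event_clusters(
    clusters: Sequence[EventCluster],
    metadata: Mapping[str, SampleMetadata],
) -> None:
    """Assign each HEC its bias-corrected label, in place.

    An event contributes the label of *each* sample it occurs in (counted
    per occurrence), so COUNT(label) = Σ over member events of the number of
    label-group samples in its presence set; num(label) = samples per group
    in the dataset.
    """
    num = Counter(m.group for m in metadata.values())
    for cluster in clusters:
        label_counts: Counter[str] = Counter()
        for p in cluster.members:
            for sid in p.samples:
                label_counts[metadata[sid].group] += 1
        cluster.label = label_cluster(LabelCounts(counts=label_counts, num_samples=num))


def event_cluster_composition(
    cluster: EventCluster, taxonomy: TaxonomyTable, rank: str = "genus"
) -> CompositionProfile:
    """Taxonomic composition of an HEC: both endpoint genomes of every
    member event contribute one observation each."""
    taxa: Counter[str] = Counter()
    for p in cluster.members:
        taxa[taxonomy.rank_of(p.key.genome_a, rank)] += 1
        taxa[taxonomy.rank_of(p.key.genome_b, rank)] += 1
    total = sum(taxa.values())
    profile = CompositionProfile(
        rank=rank, fractions={t: c / total for t, c in sorted(taxa.items())}
    )
    cluster.composition = profile
    return profile


def run_hec_analysis(
    events: Iterable[HGTEvent],
    metadata: Mapping[str, SampleMetadata],
    taxonomy: TaxonomyTable | None = None,
    *,
    preset: str | None = None,
    min_samples: int | None = None,
    min_class_size: int | None = None,
    max_distance: float = DEFAULT_HEC_CUT,
    bin_size: int = 100,
) -> tuple[list[EventCluster], list[EventPresence]]:
    """Full HEC stage: presence profiles → prevalence filter → clustering →
    labeling (→ genus composition when a taxonomy is given)."""
    if preset is not None:
        if preset not in PRESETS:
            raise ParameterError(f"unknown preset {preset!r}; expected {sorted(PRESETS)}")
        p_min_samples, p_min_class = PRESETS[preset]
        min_samples = p_min_samples if min_samples is None else min_samples
        min_class_size = p_min_class if min_class_size is None else min_class_size
    if min_samples is None or min_class_size is None:
        raise ParameterError("min_samples and min_class_size (or a preset) are required")
    presences = filter_events_by_prevalence(event_presences(events, bin_size), min_samples)
    if len(presences) < 2:
        raise InsufficientDataError(
            f"{len(presences)} events pass the prevalence filter; clustering needs >= 2"
        )
    clusters, unclustered = cluster_events(presences, max_distance, min_class_size)
    label_event_clusters(clusters, metadata)
    if taxonomy is not None:
        for c in clusters:
            event_cluster_composition(c, taxonomy, rank="genus")
    return clusters, unclustered
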