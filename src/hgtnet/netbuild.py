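"""Per-sample HGT network construction, event-rate normalization, and
cross-group event overlap.

The network of one sample has reference genomes as nodes; two genomes are
linked if at least one HGT event joins them, and the edge weight is the
number of such events. The raw event count of a sample depends on sequencing
effort, so comparisons across samples use the *HGT event rate*

    H̄ = ln( H / (Σ r_i / Σ l_i) )

where H is the sample's event count and Σr_i/Σl_i (uniquely mapped reads
over genome lengths, summed over the genomes linked by events) approximates
the average read depth.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx

from .data_model import DepthSummary, EventKey, HGTEvent, HGTNetwork, canonical_event_key
from .errors import ParameterError, UndefinedMetricError, ValidationError


def build_network(events: Iterable[HGTEvent]) -> HGTNetwork:
    """Build the weighted undirected genome graph of one sample.

    All events must share one sample_id; an empty event list yields an empty
    network (sample_id ``""``). Edge weight = number of events linking the
    two genomes; no isolated nodes are produced.
    """
    events = list(events)
    sample_ids = {ev.sample_id for ev in events}
    if len(sample_ids) > 1:
        raise ValidationError(
            f"events from multiple samples passed to build_network: {sorted(sample_ids)}"
        )
    sample_id = sample_ids.pop() if sample_ids else ""
    weights = Counter(ev.genome_pair for ev in events)
    g = nx.Graph()
    for (u, v), w in weights.items():
        g.add_edge(u, v, weight=w)
    return HGTNetwork(sample_id=sample_id, graph=g)


def build_networks_by_sample(events: Iterable[HGTEvent]) -> dict[str, HGTNetwork]:
    """Group events by sample and build one network per sample."""
    by_sample: dict[str, list[HGTEvent]] = {}
    for ev in events:
        by_sample.setdefault(ev.sample_id, []).append(ev)
    return {sid: build_network(evs) for sid, evs in sorted(by_sample.items())}


def network_size(network: HGTNetwork) -> int:
    """Number of nodes (genomes linked by HGT events) in the network."""
    return network.number_of_nodes()


@dataclass(frozen=True)
class EventRate:
    """Depth-normalized HGT event count of one sample (natural-log scale)."""

    sample_id: str
    H: int
    depth: float
    rate: float


def hgt_event_rate(H: int, depth_summary: DepthSummary) -> EventRate:
    """Compute H̄ = ln(H / depth) with depth = Σr_i / Σl_i.

    Undefined when H = 0 or when no reads mapped (depth 0).
    """
    if H < 1:
        raise UndefinedMetricError(
            f"event rate undefined for H={H} (sample {depth_summary.sample_id!r})"
        )
    depth = depth_summary.average_depth()
    if depth <= 0:
        raise UndefinedMetricError(
            f"event rate undefined: zero mapped reads in sample "
            f"{depth_summary.sample_id!r}"
        )
    return EventRate(
        sample_id=depth_summary.sample_id,
        H=H,
        depth=depth,
        rate=math.log(H / depth),
    )


@dataclass
class OverlapSummary:
    """Venn-cell counts of distinct event keys over two or more groups.

    ``cells`` maps a frozenset of group names to the number of event keys
    found in exactly those groups. ``group_keys`` retains the per-group key
    sets for downstream use.
    """

    groups: tuple[str, ...]
    cells: dict[frozenset[str], int]
    group_keys: dict[str, frozenset[EventKey]]

    def cell(self, *groups: str) -> int:
        """Count of keys present in exactly the named groups."""
        return self.cells.get(frozenset(groups), 0)

    def shared_by_all(self) -> int:
        return self.cell(*self.groups)

    def exclusive_to(self, group: str) -> int:
        return self.cell(group)

    def total_distinct(self) -> int:
        return sum(self.cells.values())


def group_event_overlap(
    events_by_group: Mapping[str, Iterable[HGTEvent]], bin_size: int = 100
) -> OverlapSummary:
    """Exact Venn-cell counts of distinct event keys across groups.

    Each group's key set is the union of :func:`canonical_event_key` over its
    events (deduplicated within the group: the cells count distinct events,
    not occurrences).
    """
    groups = tuple(sorted(events_by_group))
    if len(groups) < 2:
        raise ParameterError(
            f"event overlap requires >= 2 groups, got {len(groups)}"
        )
    key_sets = {
        g: frozenset(canonical_event_key(ev, bin_size) for ev in events_by_group[g])
        for g in groups
    }
    cells: dict[frozenset[str], int] = {}
    for r in range(1, len(groups) + 1):
        for subset in combinations(groups, r):
            inside = frozenset(subset)
            region = set.intersection(*(set(key_sets[g]) for g in subset))
            for g in groups:
                if g not in inside:
                    region -= key_sets[g]
            if region:
                cells[inside] = len(region)
    return OverlapSummary(groups=groups, cells=cells, group_keys=key_sets)
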