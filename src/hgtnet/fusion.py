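"""Fusion-gene calling at HGT breakpoints.

When both breakpoints of an HGT event fall inside annotated genes — one on
each of the two linked genomes — the transferred junction joins parts of
the two genes into a candidate fusion gene. This module intersects event
breakpoints with gene intervals (1-based inclusive on both ends; strand is
recorded but ignored, a breakpoint being strandless) and summarizes the
functional annotations of the fused genes.

Events with either breakpoint intergenic yield nothing; where several genes
overlap a breakpoint, every (gene_a, gene_b) pair is reported, while
event-level summaries count each event once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from intervaltree import IntervalTree

from .data_model import GeneAnnotation, HGTEvent


@dataclass(frozen=True)
class FusionGene:
    """One candidate fusion: an event whose breakpoints lie inside two genes."""

    event: HGTEvent
    gene_a: GeneAnnotation
    gene_b: GeneAnnotation

    def __post_init__(self):
        assert self.gene_a.genome_id == self.event.genome_a
        assert self.gene_b.genome_id == self.event.genome_b
        assert self.gene_a.contains(self.event.pos_a)
        assert self.gene_b.contains(self.event.pos_b)


def _build_gene_index(annotations: Iterable[GeneAnnotation]) -> dict[str, IntervalTree]:
    """Per-genome interval trees over gene bodies.

    Interval ends are half-open internally; +1 makes containment inclusive
    of the annotated end coordinate.
    """
    index: dict[str, IntervalTree] = {}
    for ann in annotations:
        tree = index.setdefault(ann.genome_id, IntervalTree())
        tree[ann.start: ann.end + 1] = ann
    return index


def detect_fusions(
    events: Iterable[HGTEvent], annotations: Iterable[GeneAnnotation]
) -> list[FusionGene]:
    """Find every (event, gene_a, gene_b) combination where both breakpoints
    fall inside gene bodies on their respective genomes.

    Output order is canonical (by event, then gene ids) and therefore
    invariant to the ordering of the annotation input. Genomes without any
    annotation are simply intergenic everywhere.
    """
    index = _build_gene_index(annotations)
    fusions: list[FusionGene] = []
    for ev in sorted(set(events)):
        trees_a = index.get(ev.genome_a)
        trees_b = index.get(ev.genome_b)
        if trees_a is None or trees_b is None:
            continue
        hits_a = sorted((iv.data for iv in trees_a[ev.pos_a]))
        if not hits_a:
            continue
        hits_b = sorted((iv.data for iv in trees_b[ev.pos_b]))
        for ga in hits_a:
            for gb in hits_b:
                fusions.append(FusionGene(event=ev, gene_a=ga, gene_b=gb))
    return fusions


@dataclass
class FunctionSummary:
    """Counts of fusion *events* per gene-product description.

    An event increments every distinct product among its fused genes once
    (an event whose two genes share a product increments it once), so the
    counts sum to at least the number of fusion events.
    """

    product_counts: dict[str, int]
    total_fusions: int

    def most_common(self, n: int | None = None) -> list[tuple[str, int]]:
        items = sorted(self.product_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return items if n is None else items[:n]


def summarize_fusion_functions(fusions: Iterable[FusionGene]) -> FunctionSummary:
    """Aggregate fused-gene products over distinct fusion events."""
    products_by_event: dict[HGTEvent, set[str]] = {}
    for f in fusions:
        s = products_by_event.setdefault(f.event, set())
        s.add(f.gene_a.product)
        s.add(f.gene_b.product)
    counts: Counter[str] = Counter()
    for prods in products_by_event.values():
        counts.update(prods)
    return FunctionSummary(
        product_counts=dict(counts), total_fusions=len(products_by_event)
    )
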