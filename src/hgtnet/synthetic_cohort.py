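"""Seeded synthetic-cohort generator with truth tables.

Generates cohorts with the statistical structure the downstream analyses
assume, standing in for sequencing data processed through read alignment
and breakpoint calling:

* per-sample HGT networks with scale-free degree structure (preferential
  attachment with tunable target exponent α in (2, 3));
* a mother–child family design (children sampled longitudinally with
  growing networks, mothers large and flat) or an IBD patient design
  (CD / UC / Non-IBD groups);
* family sharing — a fraction ρ of each child's events copied from its
  mother's event pool;
* group-specific event pools (driving Venn overlap structure and HEC
  labels), planted co-occurrence blocks, planted community motifs with a
  taxon bias, and planted in-gene / intergenic events for fusion calling;
* per-genome read counts and lengths for the event-rate normalization.

All randomness flows from one root seed through named substreams so each
component is independently reproducible; every planted structure is
recorded in :class:`TruthTables` for cross-checking by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .communities import Community
from .data_model import (
    DepthRecord,
    DepthSummary,
    EventKey,
    GeneAnnotation,
    HGTEvent,
    HGTNetwork,
    SampleMetadata,
    TaxonomyTable,
    TaxonRecord,
    canonical_event_key,
    write_events,
    write_gene_annotations,
    write_metadata,
)
from .errors import ParameterError
from .event_clusters import EventPresence

DEFAULT_PHYLUM_WEIGHTS = {
    "Firmicutes": 0.5,
    "Bacteroidetes": 0.25,
    "Proteobacteria": 0.15,
    "Actinobacteria": 0.10,
}

_PRODUCT_POOL = (
    "hypothetical protein",
    "ABC transporter ATP-binding protein",
    "transposase",
    "IS110 family transposase",
    "recombinase family protein",
    "site-specific integrase",
    "plasmid mobilization relaxosome protein Mob",
    "conjugal transfer protein Tra",
    "multidrug SMR transporter",
    "multidrug efflux RND transporter permease subunit",
    "DNA polymerase III subunit",
    "elongation factor Tu",
)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream of the root seed."""
    h = int(np.frombuffer(name.encode(), dtype=np.uint8).sum())
    return np.random.default_rng([seed, h])


# ---------------------------------------------------------------------------
# taxonomy + annotations
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyBundle:
    taxonomy: TaxonomyTable
    annotations: list[GeneAnnotation]
    genome_lengths: dict[str, int]

    def genomes(self) -> list[str]:
        return sorted(g for g, _ in self.taxonomy.items())

    def genomes_of_phylum(self, phylum: str) -> list[str]:
        return sorted(g for g, rec in self.taxonomy.items() if rec.phylum == phylum)


def generate_taxonomy(
    n_genomes: int,
    phylum_weights: dict[str, float] | None = None,
    seed: int = 0,
    *,
    genome_length: int = 500_000,
    genes_per_genome: int = 40,
    gene_length: int = 900,
    intergenic_gap: int = 300,
) -> TaxonomyBundle:
    """Generate genome accessions with taxonomy and tiled gene annotations.

    Each genome is assigned a phylum by weighted draw (genus and species
    nested under it) and carries ``genes_per_genome`` non-overlapping gene
    intervals of ``gene_length`` bp separated by ``intergenic_gap`` bp gaps,
    starting after an initial gap. Deterministic per seed.
    """
    if n_genomes < 2:
        raise ParameterError(f"n_genomes must be >= 2, got {n_genomes}")
    weights = dict(phylum_weights or DEFAULT_PHYLUM_WEIGHTS)
    total = sum(weights.values())
    if not np.isclose(total, 1.0):
        raise ParameterError(f"phylum weights must sum to 1, got {total}")
    span = genes_per_genome * (gene_length + intergenic_gap) + intergenic_gap
    if span > genome_length:
        raise ParameterError(
            f"{genes_per_genome} genes of {gene_length} bp with {intergenic_gap} bp "
            f"gaps need {span} bp > genome_length {genome_length}"
        )
    rng = _rng(seed, "taxonomy")
    phyla = sorted(weights)
    probs = np.array([weights[p] for p in phyla])
    records: dict[str, TaxonRecord] = {}
    annotations: list[GeneAnnotation] = []
    lengths: dict[str, int] = {}
    for i in range(n_genomes):
        acc = f"G{i:05d}"
        phylum = phyla[int(rng.choice(len(phyla), p=probs))]
        genus = f"{phylum[:4]}_genus{int(rng.integers(1, 6))}"
        records[acc] = TaxonRecord(
            species=f"{genus} sp. {acc}", genus=genus, phylum=phylum
        )
        lengths[acc] = genome_length
        for k in range(genes_per_genome):
            start = intergenic_gap + k * (gene_length + intergenic_gap) + 1
            annotations.append(GeneAnnotation(
                genome_id=acc,
                gene_id=f"{acc}_g{k:03d}",
                start=start,
                end=start + gene_length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                product=str(rng.choice(_PRODUCT_POOL)),
            ))
    return TaxonomyBundle(
        taxonomy=TaxonomyTable(records),
        annotations=annotations,
        genome_lengths=lengths,
    )


# ---------------------------------------------------------------------------
# scale-free backbone
# ---------------------------------------------------------------------------


def preferential_attachment_graph(
    n: int, m: int = 2, alpha_target: float = 3.0,
    rng: np.random.Generator | None = None,
) -> nx.Graph:
    """Growing network with attachment kernel (degree + a).

    Initial attractiveness a = m·(α_target − 3) tunes the asymptotic degree
    exponent to α_target (a = 0 recovers classic preferential attachment
    with α = 3); α_target must exceed 2 so the kernel stays positive.
    Nodes are integers 0..n−1 in arrival order.
    """
    if n < m + 1:
        raise ParameterError(f"n must be > m, got n={n}, m={m}")
    if alpha_target <= 2.0:
        raise ParameterError(f"alpha_target must be > 2, got {alpha_target}")
    rng = rng if rng is not None else np.random.default_rng()
    a = m * (alpha_target - 3.0)
    g = nx.complete_graph(m + 1)
    deg = np.zeros(n)
    deg[: m + 1] = m
    for new in range(m + 1, n):
        w = deg[:new] + a
        w = np.clip(w, 1e-9, None)
        targets = rng.choice(new, size=m, replace=False, p=w / w.sum())
        for t in targets:
            g.add_edge(new, int(t))
            deg[int(t)] += 1
        deg[new] = m
    return g


def growth_snapshots(g: nx.Graph, sizes: Sequence[int]) -> list[nx.Graph]:
    """Nested prefix subgraphs of a grown network at the given sizes."""
    return [g.subgraph(range(s)).copy() for s in sizes]


# ---------------------------------------------------------------------------
# cohort configuration and truth
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic cohort (desk-scale defaults).

    The mother–child design follows families with a mother sampled at three
    time points (sizes flat) and a child at five (sizes growing); the IBD
    design follows CD/UC/Non-IBD patients sampled longitudinally with flat
    sizes. Degree exponents default inside the ultra-small-world band (2,3),
    mothers above children.
    """

    design: str = "mother_child"  # or "ibd"
    seed: int = 0
    n_genomes: int = 600

    # mother-child design
    n_families: int = 10
    child_sizes: tuple[int, ...] = (40, 65, 100, 145, 200)
    child_time_points: tuple[str, ...] = ("birth", "2w", "1mo", "2mo", "3mo")
    mother_size: int = 350
    mother_time_points: tuple[str, ...] = ("gest", "birth", "3mo")
    alpha_mother: float = 2.8
    alpha_child: float = 2.4
    rho: float = 0.5  # family-sharing fraction
    mother_persistence: float = 0.85  # per-time-point event retention

    # ibd design
    ibd_group_sizes: dict[str, int] = field(
        default_factory=lambda: {"CD": 6, "UC": 4, "Non-IBD": 3}
    )
    ibd_time_points: tuple[str, ...] = ("t1", "t2", "t3", "t4")
    ibd_size: int = 200
    ibd_alphas: dict[str, float] = field(
        default_factory=lambda: {"CD": 2.5, "UC": 2.7, "Non-IBD": 2.3}
    )

    # planted structure
    group_pool_size: int = 60
    pool_injection_rate: float = 0.5
    n_motifs: int = 4
    motif_size: int = 12
    motif_phylum: dict[str, str] = field(default_factory=dict)  # group -> biased phylum
    motif_bias: float = 0.6
    motif_injection_rate: float = 0.6
    n_blocks: int = 4
    block_size: int = 12
    block_n_samples: int = 8
    n_fusion_ingene: int = 25
    n_fusion_intergenic: int = 25

    # depth model
    depth_mean: float = 0.05
    depth_cv: float = 0.3

    # event multiplicity ~ 1 + Geometric(p)
    multiplicity_p: float = 0.6

    def __post_init__(self):
        if not (0.0 <= self.rho <= 1.0):
            raise ParameterError(f"rho must be in [0, 1], got {self.rho}")
        if self.design not in ("mother_child", "ibd"):
            raise ParameterError(f"unknown design {self.design!r}")


def ibd_config(**overrides) -> CohortConfig:
    return CohortConfig(design="ibd", **overrides)


@dataclass
class TruthTables:
    """Every planted structure, recorded for recovery checks."""

    edge_multiplicity: dict[str, dict[tuple[str, str], int]] = field(default_factory=dict)
    family_shared_keys: dict[str, set[EventKey]] = field(default_factory=dict)
    group_pools: dict[str, set[EventKey]] = field(default_factory=dict)
    motifs: list[dict] = field(default_factory=list)
    blocks: list[dict] = field(default_factory=list)
    fusion_events: list[dict] = field(default_factory=list)  # {"event":, "in_gene": bool}
    depth: dict[str, DepthSummary] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    bundle: TaxonomyBundle
    events: list[HGTEvent]
    metadata: dict[str, SampleMetadata]
    depth: dict[str, DepthSummary]
    truth: TruthTables

    def write(self, out_dir: str | Path) -> None:
        """Emit the cohort as the plain-text exchange files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_events(self.events, out / "events.tsv")
        write_metadata(self.metadata.values(), out / "metadata.tsv")
        with (out / "taxonomy.tsv").open("w") as fh:
            fh.write("genome\tspecies\tgenus\tphylum\n")
            for g, rec in sorted(self.bundle.taxonomy.items()):
                fh.write(f"{g}\t{rec.species}\t{rec.genus}\t{rec.phylum}\n")
        with (out / "depth.tsv").open("w") as fh:
            fh.write("sample_id\tgenome\treads\tlength\n")
            for sid in sorted(self.depth):
                for rec in self.depth[sid].records:
                    fh.write(f"{sid}\t{rec.genome}\t{rec.reads}\t{rec.length}\n")
        write_gene_annotations(self.bundle.annotations, out / "annotations.gff3")


# ---------------------------------------------------------------------------
# event materialization helpers
# ---------------------------------------------------------------------------


def _random_position(rng: np.random.Generator, length: int) -> int:
    return int(rng.integers(1, length + 1))


def _gene_interior_position(rng: np.random.Generator, genes: list[GeneAnnotation]) -> int:
    g = genes[int(rng.integers(len(genes)))]
    return int(rng.integers(g.start, g.end + 1))


def _intergenic_position(rng, genes: list[GeneAnnotation], length: int) -> int:
    """A position in a gap between consecutive genes (genes are tiled with
    gaps by construction)."""
    starts = sorted(g.start for g in genes)
    ends = sorted(g.end for g in genes)
    # gap before the first gene is guaranteed by the tiling
    first = starts[0]
    if first > 1:
        return int(rng.integers(1, first))
    # otherwise use the gap after a random gene
    i = int(rng.integers(len(ends) - 1))
    lo, hi = ends[i] + 1, starts[i + 1] - 1
    return int(rng.integers(lo, hi + 1))


def _materialize_edge(
    rng: np.random.Generator,
    genome_u: str,
    genome_v: str,
    lengths: dict[str, int],
) -> tuple[str, int, str, int]:
    return (
        genome_u,
        _random_position(rng, lengths[genome_u]),
        genome_v,
        _random_position(rng, lengths[genome_v]),
    )


@dataclass(frozen=True)
class _PoolEvent:
    """An un-sampled event template: fixed genome pair and positions."""

    genome_a: str
    pos_a: int
    genome_b: str
    pos_b: int
    order: int  # arrival index of the later backbone endpoint (drives growth)

    def to_event(self, sample_id: str) -> HGTEvent:
        return HGTEvent(sample_id, self.genome_a, self.pos_a, self.genome_b, self.pos_b)

    def key(self, bin_size: int = 100) -> EventKey:
        return canonical_event_key(self.to_event(""), bin_size)


def _individual_pool(
    rng: np.random.Generator,
    size: int,
    alpha: float,
    genomes: Sequence[str],
    lengths: dict[str, int],
    multiplicity_p: float,
) -> list[_PoolEvent]:
    """Backbone → event templates for one individual.

    Nodes are mapped to a random genome subset; each backbone edge becomes
    1 + Geometric(p) event templates sharing the genome pair (distinct
    positions), tagged with the arrival order of the newer endpoint so
    growing subsets of the pool correspond to growing networks.
    """
    g = preferential_attachment_graph(size, m=2, alpha_target=alpha, rng=rng)
    node_map = {i: genomes[j] for i, j in
                enumerate(rng.choice(len(genomes), size=size, replace=False))}
    pool: list[_PoolEvent] = []
    for u, v in g.edges():
        gu, gv = node_map[u], node_map[v]
        mult = 1 + int(rng.geometric(multiplicity_p)) - 1
        for _ in range(max(1, mult)):
            ga, pa, gb, pb = _materialize_edge(rng, gu, gv, lengths)
            pool.append(_PoolEvent(ga, pa, gb, pb, order=max(u, v)))
    return pool


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    config: CohortConfig, bundle: TaxonomyBundle | None = None
) -> SyntheticCohort:
    """Generate a full cohort (events, metadata, depth, truth tables)."""
    if bundle is None:
        bundle = generate_taxonomy(config.n_genomes, seed=config.seed)
    genomes = bundle.genomes()
    lengths = bundle.genome_lengths
    truth = TruthTables()
    events: list[HGTEvent] = []
    metadata: dict[str, SampleMetadata] = {}

    if config.design == "mother_child":
        _generate_mother_child(config, bundle, genomes, lengths, truth, events, metadata)
    else:
        _generate_ibd(config, bundle, genomes, lengths, truth, events, metadata)

    _inject_group_pools(config, genomes, lengths, truth, events, metadata)
    _inject_blocks(config, genomes, lengths, truth, events, metadata)
    _inject_motifs(config, bundle, lengths, truth, events, metadata)
    _plant_fusion_events(config, bundle, truth, events, metadata)
    _draw_depth(config, lengths, truth, events, metadata)

    events.sort()
    for ev in events:
        pair = ev.genome_pair
        per_sample = truth.edge_multiplicity.setdefault(ev.sample_id, {})
        per_sample[pair] = per_sample.get(pair, 0) + 1
    return SyntheticCohort(
        config=config, bundle=bundle, events=events, metadata=metadata,
        depth=truth.depth, truth=truth,
    )


def _generate_mother_child(config, bundle, genomes, lengths, truth, events, metadata):
    rng = _rng(config.seed, "backbone")
    if config.mother_size + max(config.child_sizes) > len(genomes):
        pass  # pools draw independently; overlap across individuals is fine
    if max(config.child_sizes) > len(genomes) or config.mother_size > len(genomes):
        raise ParameterError("network size trajectory exceeds available genomes")
    if list(config.child_sizes) != sorted(set(config.child_sizes)):
        raise ParameterError("child size trajectory must be strictly increasing")
    for f in range(config.n_families):
        fam = f"F{f:02d}"
        mother_pool = _individual_pool(
            rng, config.mother_size, config.alpha_mother, genomes, lengths,
            config.multiplicity_p,
        )
        child_pool = _individual_pool(
            rng, max(config.child_sizes), config.alpha_child, genomes, lengths,
            config.multiplicity_p,
        )
        # family sharing: a fraction rho of the child's templates is replaced
        # by draws from the mother's pool (same key => shared event)
        n_share = int(round(config.rho * len(child_pool)))
        shared_keys: set[EventKey] = set()
        if n_share > 0 and mother_pool:
            replace_idx = rng.choice(len(child_pool), size=n_share, replace=False)
            for idx in replace_idx:
                src = mother_pool[int(rng.integers(len(mother_pool)))]
                old = child_pool[int(idx)]
                child_pool[int(idx)] = _PoolEvent(
                    src.genome_a, src.pos_a, src.genome_b, src.pos_b, order=old.order
                )
                shared_keys.add(src.key())
        truth.family_shared_keys[fam] = shared_keys

        for tp in config.mother_time_points:
            sid = f"{fam}_M_{tp}"
            metadata[sid] = SampleMetadata(sid, f"{fam}_M", "Mother", tp)
            keep = rng.random(len(mother_pool)) < config.mother_persistence
            events.extend(p.to_event(sid) for p, k in zip(mother_pool, keep) if k)
        for tp, size in zip(config.child_time_points, config.child_sizes):
            sid = f"{fam}_C_{tp}"
            metadata[sid] = SampleMetadata(sid, f"{fam}_C", "Child", tp)
            events.extend(p.to_event(sid) for p in child_pool if p.order < size)


def _generate_ibd(config, bundle, genomes, lengths, truth, events, metadata):
    rng = _rng(config.seed, "backbone")
    if config.ibd_size > len(genomes):
        raise ParameterError("network size exceeds available genomes")
    i = 0
    for group in sorted(config.ibd_group_sizes):
        for _ in range(config.ibd_group_sizes[group]):
            ind = f"P{i:02d}"
            i += 1
            pool = _individual_pool(
                rng, config.ibd_size, config.ibd_alphas[group], genomes, lengths,
                config.multiplicity_p,
            )
            for tp in config.ibd_time_points:
                sid = f"{ind}_{tp}"
                metadata[sid] = SampleMetadata(sid, ind, group, tp)
                keep = rng.random(len(pool)) < config.mother_persistence
                events.extend(p.to_event(sid) for p, k in zip(pool, keep) if k)


def _inject_group_pools(config, genomes, lengths, truth, events, metadata):
    if config.group_pool_size <= 0:
        return
    rng = _rng(config.seed, "pools")
    groups = sorted({m.group for m in metadata.values()})
    for group in groups:
        pool: list[_PoolEvent] = []
        for _ in range(config.group_pool_size):
            u, v = rng.choice(len(genomes), size=2, replace=False)
            ga, pa, gb, pb = _materialize_edge(rng, genomes[int(u)], genomes[int(v)], lengths)
            pool.append(_PoolEvent(ga, pa, gb, pb, order=0))
        truth.group_pools[group] = {p.key() for p in pool}
        for sid, meta in sorted(metadata.items()):
            if meta.group != group:
                continue
            keep = rng.random(len(pool)) < config.pool_injection_rate
            events.extend(p.to_event(sid) for p, k in zip(pool, keep) if k)


def _inject_blocks(config, genomes, lengths, truth, events, metadata):
    if config.n_blocks <= 0:
        return
    rng = _rng(config.seed, "blocks")
    sids = sorted(metadata)
    for b in range(config.n_blocks):
        block_events: list[_PoolEvent] = []
        for _ in range(config.block_size):
            u, v = rng.choice(len(genomes), size=2, replace=False)
            ga, pa, gb, pb = _materialize_edge(rng, genomes[int(u)], genomes[int(v)], lengths)
            block_events.append(_PoolEvent(ga, pa, gb, pb, order=0))
        n_s = min(config.block_n_samples, len(sids))
        block_sids = sorted(
            sids[int(i)] for i in rng.choice(len(sids), size=n_s, replace=False)
        )
        truth.blocks.append({
            "keys": {p.key() for p in block_events},
            "samples": set(block_sids),
        })
        for sid in block_sids:
            events.extend(p.to_event(sid) for p in block_events)


def _inject_motifs(config, bundle, lengths, truth, events, metadata):
    if config.n_motifs <= 0:
        return
    rng = _rng(config.seed, "motifs")
    groups = sorted({m.group for m in metadata.values()})
    for k in range(config.n_motifs):
        group = groups[k % len(groups)]
        biased_phylum = config.motif_phylum.get(group)
        pool = bundle.genomes()
        if biased_phylum:
            biased = bundle.genomes_of_phylum(biased_phylum)
            n_biased = int(round(config.motif_bias * config.motif_size))
            chosen = list(rng.choice(biased, size=min(n_biased, len(biased)), replace=False))
            rest = [g for g in pool if g not in set(chosen)]
            chosen += list(rng.choice(rest, size=config.motif_size - len(chosen),
                                      replace=False))
        else:
            chosen = list(rng.choice(pool, size=config.motif_size, replace=False))
        chosen = sorted(str(g) for g in chosen)
        clique: list[_PoolEvent] = []
        for i in range(len(chosen)):
            for j in range(i + 1, len(chosen)):
                ga, pa, gb, pb = _materialize_edge(rng, chosen[i], chosen[j], lengths)
                clique.append(_PoolEvent(ga, pa, gb, pb, order=0))
        injected: list[str] = []
        for sid, meta in sorted(metadata.items()):
            if meta.group != group or rng.random() > config.motif_injection_rate:
                continue
            injected.append(sid)
            events.extend(p.to_event(sid) for p in clique)
        truth.motifs.append({
            "genomes": set(chosen), "group": group, "samples": injected,
        })


def _plant_fusion_events(config, bundle, truth, events, metadata):
    rng = _rng(config.seed, "fusion")
    sids = sorted(metadata)
    genes_by_genome: dict[str, list[GeneAnnotation]] = {}
    for ann in bundle.annotations:
        genes_by_genome.setdefault(ann.genome_id, []).append(ann)
    genomes = sorted(genes_by_genome)
    lengths = bundle.genome_lengths
    for in_gene, count in ((True, config.n_fusion_ingene),
                           (False, config.n_fusion_intergenic)):
        for _ in range(count):
            u, v = rng.choice(len(genomes), size=2, replace=False)
            gu, gv = genomes[int(u)], genomes[int(v)]
            if in_gene:
                pa = _gene_interior_position(rng, genes_by_genome[gu])
                pb = _gene_interior_position(rng, genes_by_genome[gv])
            else:
                pa = _intergenic_position(rng, genes_by_genome[gu], lengths[gu])
                pb = _intergenic_position(rng, genes_by_genome[gv], lengths[gv])
            sid = sids[int(rng.integers(len(sids)))]
            ev = HGTEvent(sid, gu, pa, gv, pb)
            events.append(ev)
            truth.fusion_events.append({"event": ev, "in_gene": in_gene})


def _draw_depth(config, lengths, truth, events, metadata):
    rng = _rng(config.seed, "depth")
    by_sample: dict[str, set[str]] = {sid: set() for sid in metadata}
    for ev in events:
        by_sample[ev.sample_id].add(ev.genome_a)
        by_sample[ev.sample_id].add(ev.genome_b)
    sigma = np.sqrt(np.log(1 + config.depth_cv ** 2))
    mu = np.log(config.depth_mean) - sigma ** 2 / 2
    for sid in sorted(by_sample):
        records = []
        for g in sorted(by_sample[sid]):
            depth_g = float(rng.lognormal(mean=mu, sigma=sigma))
            reads = max(1, int(round(depth_g * lengths[g])))
            records.append(DepthRecord(genome=g, reads=reads, length=lengths[g]))
        truth.depth[sid] = DepthSummary(sample_id=sid, records=records)


# ---------------------------------------------------------------------------
# growth series (nested networks for one child + its mother)
# ---------------------------------------------------------------------------


def generate_growth_series(
    sizes: Sequence[int] = (50, 100, 200, 400, 800),
    mother_size: int = 1000,
    alpha: float = 2.5,
    seed: int = 0,
) -> tuple[list[HGTNetwork], HGTNetwork]:
    """Nested child networks at the given sizes plus a larger mother network.

    Each time point's network is a prefix subgraph of one growing
    preferential-attachment backbone, so node and edge sets are strictly
    nested. The mother network must be larger than every child snapshot.
    """
    sizes = list(sizes)
    if sizes != sorted(set(sizes)):
        raise ParameterError("size trajectory must be strictly increasing")
    if mother_size <= max(sizes):
        raise ParameterError("mother network must be larger than all child snapshots")
    rng = _rng(seed, "growth")
    child = preferential_attachment_graph(max(sizes), m=2, alpha_target=alpha, rng=rng)
    nets = []
    for t, g in enumerate(growth_snapshots(child, sizes)):
        relabeled = nx.relabel_nodes(g, {i: f"G{i:05d}" for i in g.nodes})
        nx.set_edge_attributes(relabeled, 1, "weight")
        nets.append(HGTNetwork(sample_id=f"child_t{t}", graph=relabeled))
    mg = preferential_attachment_graph(mother_size, m=2, alpha_target=alpha, rng=rng)
    mg = nx.relabel_nodes(mg, {i: f"G{i:05d}" for i in mg.nodes})
    nx.set_edge_attributes(mg, 1, "weight")
    return nets, HGTNetwork(sample_id="mother", graph=mg)


# ---------------------------------------------------------------------------
# direct generators for planted clustering structure
# ---------------------------------------------------------------------------


def generate_community_motif_set(
    n_motifs: int = 5,
    communities_per_motif: int = 20,
    motif_size: int = 30,
    keep_prob: float = 0.9,
    seed: int = 0,
) -> tuple[list[Community], list[int]]:
    """Communities drawn around disjoint motif cores, with truth labels.

    Each community keeps every core genome independently with ``keep_prob``
    (expected within-motif Jaccard = keep/(2−keep), ≈ 0.82 at the default);
    cores are disjoint so across-motif Jaccard is 0.
    """
    rng = _rng(seed, "motif-set")
    comms: list[Community] = []
    labels: list[int] = []
    for m in range(n_motifs):
        core = [f"M{m:02d}_G{i:03d}" for i in range(motif_size)]
        for c in range(communities_per_motif):
            keep = rng.random(motif_size) < keep_prob
            members = [g for g, k in zip(core, keep) if k]
            if not members:  # degenerate draw; keep one core genome
                members = [core[0]]
            comms.append(Community(sample_id=f"s{m:02d}_{c:02d}",
                                   members=frozenset(members)))
            labels.append(m)
    return comms, labels


def generate_cooccurrence_blocks(
    n_blocks: int = 4,
    events_per_block: int = 15,
    samples_per_block: int = 10,
    n_samples: int = 60,
    keep_prob: float = 0.9,
    seed: int = 0,
) -> tuple[list[EventPresence], list[int]]:
    """Event-presence profiles drawn around per-block sample cores.

    Block cores are random ``samples_per_block``-subsets of the sample pool
    (pairwise overlap is small when n_samples ≫ samples_per_block); each
    event keeps core samples independently with ``keep_prob``.
    """
    rng = _rng(seed, "block-set")
    sids = [f"s{i:03d}" for i in range(n_samples)]
    presences: list[EventPresence] = []
    labels: list[int] = []
    for b in range(n_blocks):
        core = [sids[int(i)] for i in
                rng.choice(n_samples, size=samples_per_block, replace=False)]
        for e in range(events_per_block):
            keep = rng.random(samples_per_block) < keep_prob
            samples = [s for s, k in zip(core, keep) if k]
            if not samples:
                samples = [core[0]]
            key = EventKey(genome_a=f"B{b:02d}a_{e:03d}", genome_b=f"B{b:02d}b_{e:03d}",
                           bin_a=0, bin_b=0)
            presences.append(EventPresence(key=key, samples=frozenset(samples)))
            labels.append(b)
    return presences, labels
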