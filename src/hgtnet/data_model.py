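"""Domain types and readers/writers for HGT-network analysis.

An *HGT event* is the linkage of two segments of two different reference
genomes inferred from a pair of breakpoints in one metagenomic sample; it is
the atomic edge contribution of the per-sample HGT network. This module
defines the event/network/taxonomy/annotation containers used throughout the
package and the readers for the plain-text exchange formats:

* event TSV     — ``sample_id  genome_a  pos_a  genome_b  pos_b``
* taxonomy TSV  — ``genome  species  genus  phylum``
* depth TSV     — ``sample_id  genome  reads  length``
* metadata TSV  — ``sample_id  individual  group  time_point``
* GFF3 for gene annotations; GraphML or a 3-column weighted edge list for
  networks.

Coordinates are 1-based inclusive throughout (GFF3 convention). Events are
stored canonically with ``genome_a < genome_b`` lexicographically so that the
same biological linkage always has one representation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils
import networkx as nx
import pandas as pd

from .errors import (
    FormatError,
    ParameterError,
    ParseError,
    UndefinedMetricError,
    ValidationError,
)

EVENT_COLUMNS = ("sample_id", "genome_a", "pos_a", "genome_b", "pos_b")


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class HGTEvent:
    """One breakpoint-pair linkage between two genomes in one sample.

    Instances are canonical: the side with the lexicographically smaller
    genome accession is always side *a* (sides are swapped on construction
    when needed). Positions are 1-based base-pair coordinates.
    """

    sample_id: str
    genome_a: str
    pos_a: int
    genome_b: str
    pos_b: int

    def __post_init__(self):
        if self.genome_a == self.genome_b:
            raise ValidationError(
                f"HGT event links a genome to itself: {self.genome_a!r}"
            )
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValidationError(
                f"breakpoint positions must be >= 1, got ({self.pos_a}, {self.pos_b})"
            )
        if self.genome_b < self.genome_a:  # canonicalize: smaller accession on side a
            ga, gb = self.genome_a, self.genome_b
            pa, pb = self.pos_a, self.pos_b
            object.__setattr__(self, "genome_a", gb)
            object.__setattr__(self, "genome_b", ga)
            object.__setattr__(self, "pos_a", pb)
            object.__setattr__(self, "pos_b", pa)

    @property
    def genome_pair(self) -> tuple[str, str]:
        return (self.genome_a, self.genome_b)


@dataclass(frozen=True, order=True)
class EventKey:
    """Binned identity of an HGT event, comparable across samples.

    Two events in different samples are "the same" event iff they link the
    same genome pair and both breakpoints fall in the same fixed-width
    coordinate bin. Bin width absorbs the few-bp jitter of split-read
    breakpoint calls.
    """

    genome_a: str
    genome_b: str
    bin_a: int
    bin_b: int

    def __post_init__(self):
        if self.genome_a >= self.genome_b:
            raise ValidationError("EventKey requires genome_a < genome_b")
        if self.bin_a < 0 or self.bin_b < 0:
            raise ValidationError("EventKey bins must be >= 0")


def canonical_event_key(event: HGTEvent, bin_size: int = 100) -> EventKey:
    """Map an event to its cross-sample identity key.

    Binning is ``floor((pos - 1) / bin_size)`` so position 1 falls in bin 0.
    The result is invariant under swapping the two sides of the event
    (events are already stored canonically).
    """
    if bin_size < 1:
        raise ParameterError(f"bin_size must be >= 1, got {bin_size}")
    return EventKey(
        genome_a=event.genome_a,
        genome_b=event.genome_b,
        bin_a=(event.pos_a - 1) // bin_size,
        bin_b=(event.pos_b - 1) // bin_size,
    )


class HGTNetwork:
    """Weighted undirected genome graph for one sample.

    Nodes are reference-genome accessions; the weight of an edge is the
    number of HGT events linking the two genomes in this sample. Backed by a
    :class:`networkx.Graph` (exposed as :attr:`graph`); no self-loops, and
    every node participates in at least zero edges (isolated nodes are legal
    in principle but never produced by event ingestion).
    """

    def __init__(self, sample_id: str, graph: nx.Graph | None = None):
        self.sample_id = sample_id
        self.graph = graph if graph is not None else nx.Graph()
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            w = data.get("weight", 1)
            if int(w) != w or w < 1:
                raise ValidationError(f"edge ({u},{v}) weight {w!r} is not an integer >= 1")

    # -- container views ---------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edge_weights(self) -> dict[tuple[str, str], int]:
        """Edge-weight map with canonically ordered (min, max) node pairs."""
        return {
            (min(u, v), max(u, v)): int(d.get("weight", 1))
            for u, v, d in self.graph.edges(data=True)
        }

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def total_events(self) -> int:
        return sum(self.edge_weights.values())

    def degrees(self) -> dict[str, int]:
        """Unweighted degrees (edge multiplicity ignored)."""
        return dict(self.graph.degree())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HGTNetwork)
            and self.sample_id == other.sample_id
            and self.nodes == other.nodes
            and self.edge_weights == other.edge_weights
        )

    def __repr__(self) -> str:
        return (
            f"HGTNetwork(sample_id={self.sample_id!r}, "
            f"|V|={self.number_of_nodes()}, |E|={self.number_of_edges()})"
        )


@dataclass(frozen=True)
class TaxonRecord:
    species: str
    genus: str
    phylum: str


class TaxonomyTable:
    """Genome accession → (species, genus, phylum) lookups that fail loudly."""

    RANKS = ("species", "genus", "phylum")

    def __init__(self, records: Mapping[str, TaxonRecord]):
        for acc, rec in records.items():
            for rank in self.RANKS:
                if not getattr(rec, rank):
                    raise ValidationError(
                        f"empty {rank} for genome {acc!r}; use 'unclassified'"
                    )
        self._records = dict(records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __getitem__(self, accession: str) -> TaxonRecord:
        try:
            return self._records[accession]
        except KeyError:
            from .errors import TaxonomyLookupError

            raise TaxonomyLookupError(
                f"genome accession {accession!r} not in taxonomy table"
            ) from None

    def rank_of(self, accession: str, rank: str) -> str:
        if rank not in self.RANKS:
            raise ParameterError(f"unknown rank {rank!r}; expected one of {self.RANKS}")
        return getattr(self[accession], rank)

    def items(self):
        return self._records.items()


@dataclass(frozen=True)
class DepthRecord:
    genome: str
    reads: int  # uniquely mapped read count r_i
    length: int  # genome length l_i in bp

    def __post_init__(self):
        if self.reads < 0:
            raise ValidationError(f"read count must be >= 0, got {self.reads}")
        if self.length < 1:
            raise ValidationError(f"genome length must be >= 1, got {self.length}")


@dataclass
class DepthSummary:
    """Per-sample read-mapping summary over the genomes linked by HGT events."""

    sample_id: str
    records: list[DepthRecord] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(r.reads for r in self.records)

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    def average_depth(self) -> float:
        """Σ r_i / Σ l_i — approximately the sample's average read depth."""
        if not self.records:
            raise UndefinedMetricError(f"no depth records for sample {self.sample_id!r}")
        return self.total_reads / self.total_length


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    individual_id: str
    group: str
    time_point: str


@dataclass(frozen=True, order=True)
class GeneAnnotation:
    """One annotated gene: 1-based inclusive interval on a genome."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    product: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end}]"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_events(path: str | Path, bin_size: int = 100) -> list[HGTEvent]:
    """Read an HGT event table, canonicalizing each row.

    ``bin_size`` is accepted for interface symmetry with
    :func:`canonical_event_key` (events themselves are stored at base-pair
    resolution). Malformed rows raise :class:`ParseError` naming the 1-based
    file line (header = line 1).
    """
    if bin_size < 1:
        raise ParameterError(f"bin_size must be >= 1, got {bin_size}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, EVENT_COLUMNS, path)
    events: list[HGTEvent] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        try:
            pos_a = int(row.pos_a)
            pos_b = int(row.pos_b)
        except ValueError:
            raise ParseError(
                f"breakpoint position is not an integer "
                f"(pos_a={row.pos_a!r}, pos_b={row.pos_b!r})",
                line=line,
            ) from None
        if pos_a < 1 or pos_b < 1:
            raise ParseError(
                f"breakpoint positions must be >= 1, got ({pos_a}, {pos_b})", line=line
            )
        if row.genome_a == row.genome_b:
            raise ValidationError(
                f"line {line}: event links genome {row.genome_a!r} to itself"
            )
        events.append(
            HGTEvent(
                sample_id=row.sample_id,
                genome_a=row.genome_a,
                pos_a=pos_a,
                genome_b=row.genome_b,
                pos_b=pos_b,
            )
        )
    return events


def write_events(events: Iterable[HGTEvent], path: str | Path) -> None:
    """Write events as a canonical tab-separated table."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EVENT_COLUMNS)
        for ev in events:
            writer.writerow([ev.sample_id, ev.genome_a, ev.pos_a, ev.genome_b, ev.pos_b])


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a genome → species/genus/phylum table.

    Duplicate identical rows are deduplicated; duplicate rows with
    conflicting ranks raise :class:`ValidationError` listing the accessions.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("genome", "species", "genus", "phylum"), path)
    records: dict[str, TaxonRecord] = {}
    conflicts: list[str] = []
    for row in df.itertuples(index=False):
        rec = TaxonRecord(species=row.species, genus=row.genus, phylum=row.phylum)
        prev = records.get(row.genome)
        if prev is not None and prev != rec:
            conflicts.append(row.genome)
        records[row.genome] = rec
    if conflicts:
        raise ValidationError(
            f"{path}: conflicting taxonomy for accession(s) {sorted(set(conflicts))}"
        )
    return TaxonomyTable(records)


def read_depth(path: str | Path) -> dict[str, DepthSummary]:
    """Read per-sample read-depth summaries, keyed by sample_id."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genome": str})
    _require_columns(df, ("sample_id", "genome", "reads", "length"), path)
    out: dict[str, DepthSummary] = {}
    for row in df.itertuples(index=False):
        summ = out.setdefault(row.sample_id, DepthSummary(sample_id=row.sample_id))
        summ.records.append(
            DepthRecord(genome=row.genome, reads=int(row.reads), length=int(row.length))
        )
    return out


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read sample metadata; sample_id must be unique."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("sample_id", "individual", "group", "time_point"), path)
    out: dict[str, SampleMetadata] = {}
    for row in df.itertuples(index=False):
        if row.sample_id in out:
            raise ValidationError(f"{path}: duplicate sample_id {row.sample_id!r}")
        out[row.sample_id] = SampleMetadata(
            sample_id=row.sample_id,
            individual_id=row.individual,
            group=row.group,
            time_point=row.time_point,
        )
    return out


def write_metadata(records: Iterable[SampleMetadata], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "individual", "group", "time_point"])
        for rec in records:
            writer.writerow([rec.sample_id, rec.individual_id, rec.group, rec.time_point])


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file.

    Only features of type ``gene`` are kept; product is taken from the
    ``product`` attribute, falling back to ``"NA"`` when absent. Coordinates
    are 1-based inclusive per the GFF3 standard.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    annotations: list[GeneAnnotation] = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", ["NA"])[0] or "NA"
        annotations.append(
            GeneAnnotation(
                genome_id=feat.seqid,
                gene_id=gene_id,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                product=product,
            )
        )
    return annotations


def write_gene_annotations(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write gene annotations as minimal standard GFF3."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for ann in sorted(annotations):
            attrs = f"ID={ann.gene_id};product={ann.product}"
            fh.write(
                f"{ann.genome_id}\thgtnet\tgene\t{ann.start}\t{ann.end}\t.\t"
                f"{ann.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# network serialization
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "weighted-edge-list")


def write_network(network: HGTNetwork, path: str | Path, format: str = "graphml") -> None:
    """Serialize a network; round-trip safe for both supported formats."""
    path = Path(path)
    if format == "graphml":
        g = network.graph.copy()
        g.graph["sample_id"] = network.sample_id
        nx.write_graphml(g, path)
    elif format == "weighted-edge-list":
        with path.open("w") as fh:
            fh.write(f"# sample_id\t{network.sample_id}\n")
            for (u, v), w in sorted(network.edge_weights.items()):
                fh.write(f"{u}\t{v}\t{w}\n")
    else:
        raise ParameterError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}"
        )


def read_network(path: str | Path, format: str = "graphml") -> HGTNetwork:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        sample_id = g.graph.pop("sample_id", path.stem)
        clean = nx.Graph()
        clean.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            clean.add_edge(u, v, weight=int(d.get("weight", 1)))
        return HGTNetwork(sample_id=str(sample_id), graph=clean)
    elif format == "weighted-edge-list":
        g = nx.Graph()
        sample_id = path.stem
        with path.open() as fh:
            for raw in fh:
                raw = raw.rstrip("\n")
                if not raw:
                    continue
                if raw.startswith("#"):
                    parts = raw[1:].strip().split("\t")
                    if len(parts) == 2 and parts[0] == "sample_id":
                        sample_id = parts[1]
                    continue
                u, v, w = raw.split("\t")
                g.add_edge(u, v, weight=int(w))
        return HGTNetwork(sample_id=sample_id, graph=g)
    else:
        raise ParameterError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}"
        )


def iter_network_files(directory: str | Path) -> Iterator[HGTNetwork]:
    """Yield networks from every .graphml / .edges file in a directory."""
    directory = Path(directory)
    for p in sorted(directory.iterdir()):
        if p.suffix == ".graphml":
            yield read_network(p, "graphml")
        elif p.suffix in (".edges", ".wel"):
            yield read_network(p, "weighted-edge-list")
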