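"""Core in-memory containers shared across the pipeline.

All coordinates are 0-based half-open (BED convention). Single-nucleotide
features are width-1 intervals. "Upstream"/"downstream" and profile offsets
are always in transcript orientation: negative offsets are 5' of the anchor
on the anchor's strand.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

REGIONS = ("5UTR", "CDS", "intron", "3UTR")
#: precedence used when a position overlaps segments of several transcripts
REGION_PRECEDENCE = ("5UTR", "3UTR", "CDS", "intron")

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicPosition:
    """A single stranded genomic coordinate (0-based)."""

    contig: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative coordinate: {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand: {self.strand!r}")


def orient(strand: str) -> int:
    """+1 on the plus strand, -1 on the minus strand."""
    return 1 if strand == "+" else -1


class TagTrack:
    """Per-position 5'-tag (or crosslink) counts for one sample/replicate.

    Counts are keyed by (contig, strand) -> {pos: count}; zero counts are
    never stored. Strands are kept strictly separate.
    """

    def __init__(self, sample: str = "", replicate: str = ""):
        self.sample = sample
        self.replicate = replicate
        self._counts: dict[tuple[str, str], dict[int, int]] = defaultdict(dict)

    def add(self, contig: str, pos: int, strand: str, count: int = 1) -> None:
        if count <= 0:
            raise ValueError("tag counts must be positive")
        d = self._counts[(contig, strand)]
        d[pos] = d.get(pos, 0) + count

    def counts(self, contig: str, strand: str) -> dict[int, int]:
        return self._counts.get((contig, strand), {})

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._counts)

    def positions(self) -> Iterator[tuple[GenomicPosition, int]]:
        for (contig, strand), d in sorted(self._counts.items()):
            for pos in sorted(d):
                yield GenomicPosition(contig, pos, strand), d[pos]

    def total(self) -> int:
        return sum(sum(d.values()) for d in self._counts.values())

    def count_at(self, pos: GenomicPosition) -> int:
        return self._counts.get((pos.contig, pos.strand), {}).get(pos.pos, 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TagTrack):
            return NotImplemented
        return dict(self._counts) == dict(other._counts)

    def __len__(self) -> int:
        return sum(len(d) for d in self._counts.values())


def pool_tracks(tracks: Iterable[TagTrack], sample: str = "pooled") -> TagTrack:
    """Sum several tracks position-wise into one pooled track."""
    pooled = TagTrack(sample=sample)
    for t in tracks:
        for gp, c in t.positions():
            pooled.add(gp.contig, gp.pos, gp.strand, c)
    return pooled


@dataclass
class Segment:
    region: str  # one of REGIONS
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


@dataclass
class Transcript:
    """One transcript decomposed into 5'UTR/CDS/intron/3'UTR segments.

    ``segments`` are ordered 5'->3' in transcript orientation and must not
    overlap.
    """

    gene: str
    contig: str
    strand: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        spans = sorted((s.start, s.end) for s in self.segments)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping segments in {self.gene}")

    @property
    def start(self) -> int:
        return min(s.start for s in self.segments)

    @property
    def end(self) -> int:
        return max(s.end for s in self.segments)

    def tss(self) -> GenomicPosition:
        pos = self.start if self.strand == "+" else self.end - 1
        return GenomicPosition(self.contig, pos, self.strand)

    def region_segments(self, region: str) -> list[Segment]:
        return [s for s in self.segments if s.region == region]

    def utr3_interval(self) -> tuple[int, int] | None:
        segs = self.region_segments("3UTR")
        if not segs:
            return None
        return min(s.start for s in segs), max(s.end for s in segs)


class AnnotationModel:
    """Transcript models with fast region lookup."""

    def __init__(self, transcripts: Iterable[Transcript] = ()):
        self.transcripts: list[Transcript] = list(transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def by_gene(self, gene: str) -> Transcript:
        for t in self.transcripts:
            if t.gene == gene:
                return t
        raise KeyError(gene)

    def assign_region(self, pos: GenomicPosition) -> str:
        """Label a position by overlapping segment, 'intergenic' if none.

        Overlaps across transcripts are resolved with the precedence
        5UTR > 3UTR > CDS > intron.
        """
        hit: set[str] = set()
        for t in self.transcripts:
            if t.contig != pos.contig or t.strand != pos.strand:
                continue
            for s in t.segments:
                if s.start <= pos.pos < s.end:
                    hit.add(s.region)
        for region in REGION_PRECEDENCE:
            if region in hit:
                return region
        return "intergenic"

    def gene_of(self, pos: GenomicPosition) -> str | None:
        for t in self.transcripts:
            if (t.contig == pos.contig and t.strand == pos.strand
                    and t.start <= pos.pos < t.end):
                return t.gene
        return None


@dataclass
class Cluster:
    """A tag cluster: interval plus counts and the dominant position.

    ``min_density``/``max_density`` are populated by density-stability
    clustering only (tags per nt; density of a multi-site interval is
    total / (last_pos - first_pos); single positions get infinite density).
    """

    contig: str
    strand: str
    start: int
    end: int
    total: int
    per_replicate_totals: dict[str, int] = field(default_factory=dict)
    min_density: float | None = None
    max_density: float | None = None
    dominant: GenomicPosition | None = None
    dominant_count: int = 0
    region: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("cluster end must exceed start")

    @property
    def span(self) -> int:
        """Inclusive-coordinate length (last_pos - first_pos) of the cluster."""
        return self.end - self.start - 1

    def contains(self, other: "Cluster") -> bool:
        return (self.contig == other.contig and self.strand == other.strand
                and self.start <= other.start and other.end <= self.end
                and (self.start, self.end) != (other.start, other.end))
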