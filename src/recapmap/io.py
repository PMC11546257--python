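"""Readers and writers for the plain-text formats the pipeline touches.

One fixed coordinate convention: everything is 0-based half-open in memory
(BED convention); conversion, where a format requires it, happens only at
the file boundary. All writers sort records by (contig, start, strand) so
that write-then-read round-trips are stable.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import AnnotationModel, Segment, TagTrack, Transcript

SPOT_COLUMNS = ["image", "replicate", "cell", "channel", "x_px", "y_px", "brightness"]
BED6_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


class ParseError(ValueError):
    """Malformed input file; message carries the path and line number."""


# ---------------------------------------------------------------- BEDgraph

def read_bedgraph_tags(path: str | Path, sample: str = "", replicate: str = "",
                       strand: str = "+") -> TagTrack:
    """Read a stranded single-nucleotide BEDgraph into a :class:`TagTrack`.

    Tag tracks are single-nt by construction (each record is one 5' end
    position), so any record wider than 1 nt is rejected rather than
    expanded.
    """
    track = TagTrack(sample=sample, replicate=replicate)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                count = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if end - start != 1:
                raise ParseError(
                    f"{path}:{lineno}: record spans {end - start} nt; "
                    "tag tracks are single-nucleotide")
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative count {count}")
            if count != int(count):
                raise ParseError(f"{path}:{lineno}: non-integer count {count}")
            if count > 0:
                track.add(contig, start, strand, int(count))
    return track


def write_bedgraph_tags(track: TagTrack, path: str | Path, strand: str) -> None:
    """Write one strand of a tag track as single-nt BEDgraph records."""
    with open(path, "w") as fh:
        for contig, s in track.keys():
            if s != strand:
                continue
            counts = track.counts(contig, s)
            for pos in sorted(counts):
                fh.write(f"{contig}\t{pos}\t{pos + 1}\t{counts[pos]}\n")


# ------------------------------------------------------------- bedgraph score

def read_bedgraph_scores(path: str | Path) -> dict[str, dict[int, float]]:
    """Read a per-base score track (e.g. conservation); wide records expand."""
    scores: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from None
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            d = scores.setdefault(fields[0], {})
            for p in range(start, end):
                d[p] = value
    return scores


def write_bedgraph_scores(scores: dict[str, dict[int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(scores):
            d = scores[contig]
            for pos in sorted(d):
                fh.write(f"{contig}\t{pos}\t{pos + 1}\t{d[pos]:g}\n")


# ------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(genome.items())]
    SeqIO.write(records, str(path), "fasta")


# -------------------------------------------------------------------- BED6

def read_bed6(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS,
                         dtype={"contig": str, "name": str, "strand": str},
                         comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED6_COLUMNS)
    if df.isna().any().any():
        raise ParseError(f"{path}: inconsistent column counts (expected 6)")
    bad = df.index[df.end <= df.start]
    if len(bad):
        raise ParseError(f"{path}: record {bad[0] + 1} has end <= start")
    if not df.strand.isin(["+", "-"]).all():
        raise ParseError(f"{path}: invalid strand value")
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df = df.loc[:, BED6_COLUMNS].sort_values(["contig", "start", "strand"])
    df.to_csv(path, sep="\t", header=False, index=False)


def intervals_to_bed6(intervals: Iterable[tuple[str, int, int, str, float, str]]) -> pd.DataFrame:
    return pd.DataFrame(list(intervals), columns=BED6_COLUMNS)


# -------------------------------------------------------------- annotation

def write_annotation(ann: AnnotationModel, path: str | Path) -> None:
    """Annotation as BED6; the name column carries ``gene:region``."""
    rows = []
    for t in ann.transcripts:
        for seg in t.segments:
            rows.append((t.contig, seg.start, seg.end,
                         f"{t.gene}:{seg.region}", 0, t.strand))
    write_bed6(intervals_to_bed6(rows), path)


def read_annotation(path: str | Path) -> AnnotationModel:
    df = read_bed6(path)
    transcripts: dict[str, Transcript] = {}
    for row in df.itertuples():
        if ":" not in row.name:
            raise ParseError(f"{path}: annotation name {row.name!r} lacks gene:region")
        gene, region = row.name.rsplit(":", 1)
        t = transcripts.get(gene)
        if t is None:
            t = transcripts[gene] = Transcript(gene, row.contig, row.strand, [])
        t.segments.append(Segment(region, int(row.start), int(row.end)))
    for t in transcripts.values():
        t.segments.sort(key=lambda s: s.start, reverse=(t.strand == "-"))
    return AnnotationModel(transcripts.values())


# --------------------------------------------------------------- spot TSV

def read_spots(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing spot column(s) {missing}")
    if (df.brightness <= 0).any():
        raise ParseError(f"{path}: brightness must be positive")
    if (df.x_px < 0).any() or (df.y_px < 0).any():
        raise ParseError(f"{path}: negative pixel coordinate")
    return df


def write_spots(df: pd.DataFrame, path: str | Path) -> None:
    extra = [c for c in df.columns if c not in SPOT_COLUMNS]
    df.loc[:, SPOT_COLUMNS + extra].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------- ground truth JSON

def write_ground_truth(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)


def read_ground_truth(path: str | Path):
    from .simulate import GroundTruth  # local import avoids a cycle
    with open(path) as fh:
        d = json.load(fh)
    d["recap_sites"] = [tuple(x) for x in d["recap_sites"]]
    d["sirna_cleavage_positions"] = [tuple(x) for x in d["sirna_cleavage_positions"]]
    return GroundTruth(**d)


# ---------------------------------------------------- published cluster tables

def read_cluster_table(path: str | Path) -> pd.DataFrame:
    """Read a published 3'UTR CAGE cluster table (BED-like, >=6 columns).

    Returns one row per unique cluster keyed by (contig, start, end, strand);
    extra per-sample columns are preserved.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 6:
        raise ParseError(f"{path}: expected at least 6 BED columns")
    df = df.rename(columns={0: "contig", 1: "start", 2: "end", 3: "name",
                            4: "score", 5: "strand"})
    return df.drop_duplicates(subset=["contig", "start", "end", "strand"])


def count_unique_clusters(path: str | Path) -> int:
    return len(read_cluster_table(path))


# ------------------------------------------------------------------ validate

_VALIDATORS = {
    ".fasta": read_fasta, ".fa": read_fasta,
    ".bed": read_bed6,
    ".bedgraph": read_bedgraph_scores, ".bg": read_bedgraph_scores,
    ".tsv": read_spots,
    ".json": lambda p: json.load(open(p)),
}


def validate_file(path: str | Path) -> str:
    """Parse a file according to its extension; returns the detected kind."""
    suffix = Path(path).suffix.lower()
    if suffix not in _VALIDATORS:
        raise ParseError(f"{path}: unrecognised extension {suffix!r}")
    _VALIDATORS[suffix](path)
    return suffix.lstrip(".")
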