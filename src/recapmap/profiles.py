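"""Anchor-relative signal profiles (RNA-maps) and their derivatives.

Offsets are in anchor (transcript) orientation: negative offsets are 5' of
the anchor on its own strand. Signal at anchor position + offset *
orientation is accumulated per anchor; curves are per-anchor normalised
(sum of the unsmoothed curve = total in-window signal / number of anchors).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import AnnotationModel, GenomicPosition, TagTrack, orient


@dataclass
class ProfileMatrix:
    """anchors x offsets signal matrix with normalisation metadata."""

    anchors: list[GenomicPosition]
    offsets: np.ndarray                  # [-W .. +W]
    values: np.ndarray                   # shape (n_anchors, 2W+1)
    normalisation: str = "raw"           # raw | per_anchor | log2_mean200
    smoothing_window: int = 1

    def mean_curve(self, smoothing: int | None = None) -> np.ndarray:
        """Per-anchor-normalised mean curve, optionally smoothed."""
        curve = self.values.sum(axis=0) / max(1, len(self.anchors))
        w = self.smoothing_window if smoothing is None else smoothing
        return smooth_curve(curve, w)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets,
                             "value": self.mean_curve(),
                             "n_anchors": len(self.anchors)})


def smooth_curve(curve: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling mean that conserves the curve sum.

    Each input bin spreads its mass uniformly over its own window, clipped
    at the curve boundaries, so edge bins shrink their window instead of
    borrowing mass from outside; interior bins equal the plain centred
    rolling mean.
    """
    if window <= 1:
        return curve.astype(float)
    h = (window - 1) // 2
    n = len(curve)
    out = np.zeros(n)
    for i, x in enumerate(curve):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out[lo:hi] += x / (hi - lo)
    return out


def anchor_profile(track: TagTrack, anchors: Sequence[GenomicPosition],
                   W: int, smoothing: int = 1) -> ProfileMatrix:
    """Signal density around anchors: values[a, o] = count at
    anchor_a + o * orientation_a."""
    if W <= 0:
        raise ValueError("profile half-width W must be positive")
    if not anchors:
        raise ValueError("no anchors given")
    offsets = np.arange(-W, W + 1)
    values = np.zeros((len(anchors), 2 * W + 1))
    for a, anchor in enumerate(anchors):
        counts = track.counts(anchor.contig, anchor.strand)
        sgn = orient(anchor.strand)
        for o in offsets:
            p = anchor.pos + int(o) * sgn
            if p in counts:
                values[a, o + W] = counts[p]
    return ProfileMatrix(list(anchors), offsets, values,
                         normalisation="per_anchor", smoothing_window=smoothing)


def control_anchors(anchors: Sequence[GenomicPosition], ann: AnnotationModel,
                    mode: str = "same_region", seed: int = 0
                    ) -> list[GenomicPosition]:
    """Randomised control anchors.

    ``same_region``: uniform random position within the 3'UTR containing
    each anchor (the anchor itself if no 3'UTR is found). ``window150``:
    uniform within +-150 nt of each anchor.
    """
    rng = np.random.default_rng(seed)
    out = []
    for anchor in anchors:
        if mode == "window150":
            p = anchor.pos + int(rng.integers(-150, 151))
            out.append(GenomicPosition(anchor.contig, max(0, p), anchor.strand))
            continue
        if mode != "same_region":
            raise ValueError(f"unknown control mode {mode!r}")
        placed = False
        for t in ann.transcripts:
            if t.contig != anchor.contig or t.strand != anchor.strand:
                continue
            iv = t.utr3_interval()
            if iv and iv[0] <= anchor.pos < iv[1]:
                p = int(rng.integers(iv[0], iv[1]))
                out.append(GenomicPosition(anchor.contig, p, anchor.strand))
                placed = True
                break
        if not placed:
            out.append(anchor)
    return out


def profile_heatmap(track: TagTrack, anchors: Sequence[GenomicPosition],
                    W: int = 100, norm_halfwidth: int = 200, top_n: int = 500
                    ) -> ProfileMatrix:
    """log2 count heatmap around the ``top_n`` strongest anchors.

    Anchors are ranked by total signal within +-``norm_halfwidth``; each
    row is log2((c + 1) / mean(c + 1)) with the mean over the same
    +-``norm_halfwidth`` span, reported for the central +-W offsets.
    """
    wide = anchor_profile(track, anchors, norm_halfwidth)
    totals = wide.values.sum(axis=1)
    order = np.argsort(-totals, kind="stable")[:top_n]
    c1 = wide.values[order] + 1.0
    vals = np.log2(c1 / c1.mean(axis=1, keepdims=True))
    lo = norm_halfwidth - W
    return ProfileMatrix([wide.anchors[i] for i in order],
                         np.arange(-W, W + 1),
                         vals[:, lo:lo + 2 * W + 1],
                         normalisation="log2_mean200")


# ------------------------------------------------------------- read ends

def fragment_end_positions(fragments: pd.DataFrame
                           ) -> tuple[TagTrack, TagTrack]:
    """5' and 3' end tracks of stranded fragments (BED6 DataFrame).

    Convention: the 3' end is the coordinate one past the last covered
    nucleotide in transcript orientation (half-open), so a fragment
    abutting a downstream capping site registers at offset 0.
    """
    starts, ends = TagTrack("starts"), TagTrack("ends")
    for row in fragments.itertuples():
        if row.strand == "+":
            p5, p3 = row.start, row.end
        else:
            p5, p3 = row.end - 1, row.start - 1
        starts.add(row.contig, p5, row.strand)
        if p3 >= 0:
            ends.add(row.contig, p3, row.strand)
    return starts, ends


def readend_profile(fragments: pd.DataFrame, anchors: Sequence[GenomicPosition],
                    W: int, smoothing: int = 1
                    ) -> tuple[ProfileMatrix, ProfileMatrix]:
    """Profiles of fragment 5' starts and 3' ends around anchors."""
    starts, ends = fragment_end_positions(fragments)
    return (anchor_profile(starts, anchors, W, smoothing),
            anchor_profile(ends, anchors, W, smoothing))


# ------------------------------------------------------------ score curves

def score_profile(scores: dict[str, dict[int, float]],
                  anchors: Sequence[GenomicPosition], W: int
                  ) -> pd.DataFrame:
    """Mean per-offset score (e.g. conservation) over anchors.

    Positions without a score are treated as absent: the mean is over
    covered anchors only, and per-offset coverage is reported.
    """
    if not anchors:
        raise ValueError("no anchors given")
    offsets = np.arange(-W, W + 1)
    total = np.zeros(2 * W + 1)
    cover = np.zeros(2 * W + 1, dtype=int)
    for anchor in anchors:
        d = scores.get(anchor.contig, {})
        sgn = orient(anchor.strand)
        for o in offsets:
            v = d.get(anchor.pos + int(o) * sgn)
            if v is not None:
                total[o + W] += v
                cover[o + W] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cover > 0, total / np.maximum(cover, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "mean_score": mean, "coverage": cover})


# ---------------------------------------------------------- siRNA detection

def sirna_capping_detect(tracks: Sequence[TagTrack],
                         target: tuple[str, int, int, str],
                         min_replicates: int = 2) -> dict:
    """Detect cleavage-derived capping at an siRNA target interval.

    Detected iff at least ``min_replicates`` replicate tracks place >= 1
    tag with its 5' end inside the (half-open) target interval. The
    dominant offset is the pooled-maximum position relative to the target
    5' end in transcript orientation.
    """
    contig, start, end, strand = target
    if end - start < 1:
        raise ValueError("target interval must span at least 1 nt")
    per_rep = []
    pooled: dict[int, int] = {}
    for track in tracks:
        counts = track.counts(contig, strand)
        inside = {p: c for p, c in counts.items() if start <= p < end}
        per_rep.append(sum(inside.values()))
        for p, c in inside.items():
            pooled[p] = pooled.get(p, 0) + c
    detected = sum(1 for n in per_rep if n >= 1) >= min_replicates
    dominant_offset = None
    if pooled:
        best = max(sorted(pooled), key=lambda p: pooled[p])
        dominant_offset = (best - start) if strand == "+" else (end - 1 - best)
    return {"detected": detected, "per_replicate_counts": per_rep,
            "dominant_offset": dominant_offset}


# ------------------------------------------------------ long-read classes

def classify_read_starts(read_starts: Sequence[GenomicPosition],
                         tss_anchors: Sequence[GenomicPosition],
                         utr_anchors: Sequence[GenomicPosition],
                         window: int = 50) -> list[str]:
    """Classify read 5' starts as TSS / UTR / OTHER by proximity (+-window)
    to TSS anchors, then 3'UTR CAGE anchors (TSS has precedence)."""

    def near(pos: GenomicPosition, anchors: Sequence[GenomicPosition]) -> bool:
        return any(a.contig == pos.contig and a.strand == pos.strand
                   and abs(a.pos - pos.pos) <= window for a in anchors)

    out = []
    for rs in read_starts:
        if near(rs, tss_anchors):
            out.append("TSS")
        elif near(rs, utr_anchors):
            out.append("UTR")
        else:
            out.append("OTHER")
    return out
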