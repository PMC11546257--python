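"""CAGE 5'-tag clustering: reproducibility-filtered window clusters,
density-stability (paraclu-style) clusters, dominant peaks, region labels
and library-size normalisation.

Density of a multi-site interval is total count / (last_pos - first_pos);
single positions have infinite density. A density-stability cluster is an
interval of tag sites that, for some density threshold d, is maximal among
intervals whose every anchored prefix and anchored suffix (including the
interval itself) has density >= d. Each reported cluster carries
``min_density`` (the threshold at which it becomes maximal, i.e. at which
its smallest enclosing stable interval breaks) and ``max_density`` (the
threshold at which it breaks up itself).
"""
from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (AnnotationModel, Cluster, GenomicPosition, TagTrack,
                    REGIONS, orient, pool_tracks)

# ------------------------------------------------------------ window clusters


def window_cluster(tracks: Sequence[TagTrack], gap: int = 20,
                   min_per_replicate: int = 2, min_replicates: int = 2
                   ) -> list[Cluster]:
    """Merge tag positions whose inter-position gap is <= ``gap`` nt and
    keep clusters supported by at least ``min_replicates`` replicates with
    >= ``min_per_replicate`` tags each.

    The gap is measured between width-1 intervals: positions 100 and 121
    (gap 20) merge at the default; 100 and 122 do not.
    """
    if len(tracks) < 2:
        raise ValueError("window clustering needs >= 2 replicate tracks")
    reps = [t.replicate or f"rep{i + 1}" for i, t in enumerate(tracks)]
    keys = sorted({k for t in tracks for k in t.keys()})
    out: list[Cluster] = []
    for contig, strand in keys:
        per_rep = [t.counts(contig, strand) for t in tracks]
        positions = sorted(set().union(*per_rep))
        if not positions:
            continue
        runs: list[list[int]] = [[positions[0]]]
        for p in positions[1:]:
            if p - runs[-1][-1] - 1 <= gap:
                runs[-1].append(p)
            else:
                runs.append([p])
        for run in runs:
            rep_totals = {rep: sum(d.get(p, 0) for p in run)
                          for rep, d in zip(reps, per_rep)}
            support = sum(1 for v in rep_totals.values() if v >= min_per_replicate)
            if support < min_replicates:
                continue
            pooled = {p: sum(d.get(p, 0) for d in per_rep) for p in run}
            cl = Cluster(contig, strand, run[0], run[-1] + 1,
                         total=sum(pooled.values()),
                         per_replicate_totals=rep_totals)
            _set_dominant(cl, pooled)
            out.append(cl)
    return out


def _set_dominant(cluster: Cluster, pooled: dict[int, int]) -> None:
    best = _dominant_position(pooled, cluster.strand)
    cluster.dominant = GenomicPosition(cluster.contig, best, cluster.strand)
    cluster.dominant_count = pooled[best]


def _dominant_position(pooled: dict[int, int], strand: str) -> int:
    """Position of maximal count; ties go to the 5'-most position in
    transcript orientation (smallest coordinate on '+', largest on '-')."""
    best_count = max(pooled.values())
    tied = [p for p, c in pooled.items() if c == best_count]
    return min(tied) if strand == "+" else max(tied)


def dominant_peak(cluster: Cluster, track: TagTrack) -> GenomicPosition:
    """Dominant peak of a cluster under a pooled track (tie rule as above)."""
    counts = track.counts(cluster.contig, cluster.strand)
    pooled = {p: c for p, c in counts.items() if cluster.start <= p < cluster.end}
    if not pooled:
        raise ValueError("cluster has no tags in the given track")
    pos = _dominant_position(pooled, cluster.strand)
    return GenomicPosition(cluster.contig, pos, cluster.strand)


# ----------------------------------------------------- density-stability

def _stability_bounds(pos: np.ndarray, cnt: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """U and M matrices for all site intervals [i..j].

    U[i, j] = min density over anchored prefixes/suffixes of [i..j]
    (the break threshold); M[i, j] = max U over strict superintervals
    (the formation threshold). Entries with j < i are meaningless.
    """
    m = len(pos)
    cum = np.concatenate([[0], np.cumsum(cnt)])
    U = np.full((m, m), math.inf)
    # prefix minima: density of [i..k] anchored at i, running min over k
    for i in range(m):
        k = np.arange(i + 1, m)
        if len(k):
            dens = (cum[k + 1] - cum[i]) / (pos[k] - pos[i])
            U[i, i + 1:] = np.minimum.accumulate(dens)
    # suffix minima: density of [k..j] anchored at j, running min over k
    for j in range(m):
        k = np.arange(0, j)
        if len(k):
            dens = (cum[j + 1] - cum[k]) / (pos[j] - pos[k])
            U[:j, j] = np.minimum(U[:j, j], np.minimum.accumulate(dens[::-1])[::-1])
    M = np.zeros((m, m))
    # sweep by decreasing span; a superinterval extends one site left or right
    for span in range(m - 2, -1, -1):
        i = np.arange(0, m - span)
        j = i + span
        left = np.full(len(i), -math.inf)
        right = np.full(len(i), -math.inf)
        mask = i > 0
        left[mask] = np.maximum(U[i[mask] - 1, j[mask]], M[i[mask] - 1, j[mask]])
        mask = j < m - 1
        right[mask] = np.maximum(U[i[mask], j[mask] + 1], M[i[mask], j[mask] + 1])
        M[i, j] = np.maximum(np.maximum(left, right), 0.0)
    return U, M


def paraclu_cluster(track: TagTrack) -> list[Cluster]:
    """Density-stability clustering of a pooled tag track.

    Emits the full nested hierarchy per contig/strand: every interval whose
    break threshold exceeds its formation threshold, including every single
    tag position (infinite break density). Quadratic in the number of
    distinct tag positions per contig/strand.
    """
    out: list[Cluster] = []
    for contig, strand in track.keys():
        counts = track.counts(contig, strand)
        pos = np.array(sorted(counts))
        cnt = np.array([counts[p] for p in pos])
        U, M = _stability_bounds(pos, cnt)
        cum = np.concatenate([[0], np.cumsum(cnt)])
        ii, jj = np.nonzero(np.triu(U > M))
        for i, j in zip(ii, jj):
            pooled = {int(p): int(c) for p, c in zip(pos[i:j + 1], cnt[i:j + 1])}
            cl = Cluster(contig, strand, int(pos[i]), int(pos[j]) + 1,
                         total=int(cum[j + 1] - cum[i]),
                         min_density=float(M[i, j]), max_density=float(U[i, j]))
            _set_dominant(cl, pooled)
            out.append(cl)
    return out


def paraclu_filter(clusters: Iterable[Cluster], min_total: int = 5,
                   max_len: int = 200, min_ratio: float = 2.0,
                   readd_singles: bool = True, drop_nested: bool = True
                   ) -> list[Cluster]:
    """Post-filter a density-stability hierarchy into a flat peak set.

    In order: drop clusters with total < ``min_total``; drop single-position
    clusters; drop clusters whose inclusive length (last - first position)
    exceeds ``max_len``; drop clusters with max/min density ratio below
    ``min_ratio``; re-add single-position clusters passing ``min_total``;
    finally drop any cluster contained in a retained larger one.
    """
    clusters = list(clusters)
    singles = [c for c in clusters if c.span == 0]
    kept = [c for c in clusters if c.span != 0]
    kept = [c for c in kept if c.total >= min_total]
    kept = [c for c in kept if c.span <= max_len]

    def ratio(c: Cluster) -> float:
        if not c.min_density:  # hierarchy root forms at threshold 0
            return math.inf
        return c.max_density / c.min_density

    kept = [c for c in kept if ratio(c) >= min_ratio]
    if readd_singles:
        seen = {(c.contig, c.strand, c.start, c.end) for c in kept}
        for c in singles:
            if c.total >= min_total and (c.contig, c.strand, c.start, c.end) not in seen:
                kept.append(c)
    if drop_nested:
        kept = [c for c in kept
                if not any(other.contains(c) for other in kept)]
    return sorted(kept, key=lambda c: (c.contig, c.start, c.strand))


# ------------------------------------------------------------ region labels

def assign_region(pos: GenomicPosition, ann: AnnotationModel) -> str:
    """Region label of a position (precedence 5UTR > 3UTR > CDS > intron;
    'intergenic' when no segment overlaps)."""
    return ann.assign_region(pos)


def region_proportions(tracks: Sequence[TagTrack], ann: AnnotationModel
                       ) -> dict[str, float]:
    """Tag-weighted fraction of 5' positions per transcript region,
    normalised over the four annotated regions."""
    totals = dict.fromkeys(REGIONS, 0)
    for track in tracks:
        for gp, c in track.positions():
            label = ann.assign_region(gp)
            if label in totals:
                totals[label] += c
    grand = sum(totals.values())
    if grand == 0:
        return {r: 0.0 for r in REGIONS}
    return {r: totals[r] / grand for r in REGIONS}


# -------------------------------------------------------- count-matrix stats

def size_factor_normalize(counts: pd.DataFrame
                          ) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios library size factors (clusters x samples matrix).

    factor_s = median over clusters (restricted to clusters with nonzero
    counts in every sample) of count_cs / geometric-mean_c; the normalised
    matrix is counts / factors.
    """
    mat = counts.to_numpy(float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no cluster has nonzero counts in all samples")
    sub = mat[usable]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    # median taken in log space (geometric interpolation on even counts),
    # matching the DESeq2 convention
    log_ratios = np.log(sub) - log_geo
    factors = pd.Series(np.exp(np.median(log_ratios, axis=0)),
                        index=counts.columns, name="size_factor")
    return factors, counts / factors


def replicate_correlation(counts: pd.DataFrame, log: bool = True
                          ) -> tuple[pd.DataFrame, dict]:
    """Pairwise Pearson correlation between samples on cluster counts.

    ``log`` applies log2(1 + x) first; the choice is recorded in the
    returned metadata.
    """
    mat = counts.to_numpy(float)
    if log:
        mat = np.log2(1.0 + mat)
    r = np.corrcoef(mat, rowvar=False)
    df = pd.DataFrame(r, index=counts.columns, columns=counts.columns)
    return df, {"log2_1p": log, "n_clusters": len(counts)}


# ------------------------------------------------------------- inner peaks

def inner_3utr_peaks(peaks: Sequence[GenomicPosition], ann: AnnotationModel,
                     margin: int = 150) -> list[GenomicPosition]:
    """Keep 3'UTR peaks >= ``margin`` nt from both 3'UTR boundaries
    (distance to the CDS side and to the transcript termination side, in
    transcript orientation; the boundary case is inclusive)."""
    kept = []
    for pk in peaks:
        for t in ann.transcripts:
            if t.contig != pk.contig or t.strand != pk.strand:
                continue
            iv = t.utr3_interval()
            if iv is None:
                continue
            start, end = iv
            if start <= pk.pos < end and min(pk.pos - start, end - 1 - pk.pos) >= margin:
                kept.append(pk)
                break
    return kept


# ----------------------------------------------------------- convenience

def cluster_count_matrix(clusters: Sequence[Cluster],
                         tracks: dict[str, TagTrack]) -> pd.DataFrame:
    """Tag totals of each cluster (rows) under each named track (columns)."""
    data = {}
    for name, track in tracks.items():
        col = []
        for c in clusters:
            counts = track.counts(c.contig, c.strand)
            col.append(sum(v for p, v in counts.items() if c.start <= p < c.end))
        data[name] = col
    return pd.DataFrame(data)


def label_clusters(clusters: Sequence[Cluster], ann: AnnotationModel) -> None:
    """Annotate each cluster in place with the region of its dominant peak."""
    for c in clusters:
        anchor = c.dominant or GenomicPosition(c.contig, c.start, c.strand)
        c.region = ann.assign_region(anchor)
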