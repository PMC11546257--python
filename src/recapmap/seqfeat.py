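"""Sequence and structure features around genomic anchors.

Covers position frequency matrices (sequence logos), k-mer/hexamer offset
profiles, G4Hunter G-quadruplex scoring, equilibrium base-pairing
probabilities from a uniform-weight partition function, and miRNA
complementarity/seed matching. All matching is done in the DNA alphabet
(U mapped to T); anchor windows are extracted strand-oriented, so minus
strand anchors read the reverse complement.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import GenomicPosition

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
ALPHABET = "ACGT"

#: canonical base pairs (DNA alphabet; GT encodes the GU wobble)
_CANONICAL = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_MIN_LOOP = 3          # minimum unpaired nucleotides inside a hairpin
_PAIR_WEIGHT = float(np.e)  # Boltzmann factor per pair: energy -1 at kT = 1


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def extract_window(genome: Mapping[str, str], anchor: GenomicPosition,
                   upstream: int, downstream: int) -> tuple[str, int]:
    """Strand-oriented sequence from offset -upstream to +downstream
    (inclusive) around an anchor; truncated at contig edges.

    Returns (sequence, offset_of_first_base) so callers can align
    truncated windows; for a full window the first offset is -upstream.
    """
    contig = genome[anchor.contig]
    if anchor.strand == "+":
        lo = anchor.pos - upstream
        hi = anchor.pos + downstream + 1
    else:
        lo = anchor.pos - downstream
        hi = anchor.pos + upstream + 1
    clipped_lo, clipped_hi = max(0, lo), min(len(contig), hi)
    seq = contig[clipped_lo:clipped_hi]
    if anchor.strand == "+":
        first = clipped_lo - anchor.pos
    else:
        seq = revcomp(seq)
        first = anchor.pos - (clipped_hi - 1)
    return _dna(seq), first


# ----------------------------------------------------------------- PFM

@dataclass
class PositionFrequencyMatrix:
    offsets: np.ndarray
    counts: pd.DataFrame      # offsets x ACGT
    n_sequences: int

    def fractions(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=1)
        return self.counts.div(tot.where(tot > 0, 1), axis=0)


def pfm_around(anchors: Sequence[GenomicPosition], genome: Mapping[str, str],
               flank: int) -> PositionFrequencyMatrix:
    """Base counts per offset in strand-oriented +-flank windows."""
    offsets = np.arange(-flank, flank + 1)
    counts = pd.DataFrame(0, index=offsets, columns=list(ALPHABET))
    for anchor in anchors:
        seq, first = extract_window(genome, anchor, flank, flank)
        for i, base in enumerate(seq):
            o = first + i
            if -flank <= o <= flank and base in ALPHABET:
                counts.loc[o, base] += 1
    return PositionFrequencyMatrix(offsets, counts, len(anchors))


# ---------------------------------------------------------------- k-mers

def kmer_profile(anchors: Sequence[GenomicPosition], genome: Mapping[str, str],
                 kmers: Sequence[str], flank: int, mode: str = "coverage"
                 ) -> pd.DataFrame:
    """Per-offset k-mer occurrence profile in +-flank windows.

    ``coverage``: every occurrence increments all offsets it covers
    (hexamer coverage per nucleotide); ``start``: only the occurrence
    start offset is incremented (GGG-style profiles).
    """
    if mode not in ("coverage", "start"):
        raise ValueError(f"unknown mode {mode!r}")
    kmers = [_dna(k) for k in kmers]
    kmax = max(len(k) for k in kmers)
    offsets = np.arange(-flank, flank + 1)
    profile = np.zeros(2 * flank + 1)
    for anchor in anchors:
        seq, first = extract_window(genome, anchor, flank + kmax, flank + kmax)
        for k in kmers:
            for i in range(len(seq) - len(k) + 1):
                if seq[i:i + len(k)] != k:
                    continue
                o = first + i
                if mode == "start":
                    if -flank <= o <= flank:
                        profile[o + flank] += 1
                else:
                    lo = max(-flank, o)
                    hi = min(flank, o + len(k) - 1)
                    if hi >= lo:
                        profile[lo + flank:hi + flank + 1] += 1
    return pd.DataFrame({"offset": offsets, "count": profile})


# -------------------------------------------------------------- G4Hunter

def g4hunter_basescores(sequence: str) -> np.ndarray:
    """Per-base G4Hunter scores: each base in a G-run of length L scores
    +min(L, 4), in a C-run -min(L, 4), other bases 0."""
    seq = _dna(sequence)
    scores = np.zeros(len(seq))
    i = 0
    while i < len(seq):
        b = seq[i]
        j = i
        while j < len(seq) and seq[j] == b:
            j += 1
        if b == "G":
            scores[i:j] = min(j - i, 4)
        elif b == "C":
            scores[i:j] = -min(j - i, 4)
        i = j
    return scores


def g4hunter_score(sequence: str, window: int = 25) -> np.ndarray:
    """Sliding-window mean of per-base scores (window start positions);
    sequences shorter than the window are scored whole."""
    base = g4hunter_basescores(sequence)
    if len(base) == 0:
        return np.array([])
    if len(base) < window:
        return np.array([base.mean()])
    kernel = np.ones(window) / window
    return np.convolve(base, kernel, mode="valid")


def g4_hits(sequence: str, window: int = 25, threshold: float = 1.2
            ) -> list[tuple[int, int, int, float]]:
    """Maximal regions of overlapping windows whose |mean| >= threshold.

    Returns (start, end, sign, max_abs_mean); sign -1 flags the
    minus-strand (C-run) motif.
    """
    means = g4hunter_score(sequence, window)
    w = min(window, len(_dna(sequence)))
    hits = []
    for sign in (1, -1):
        idx = np.nonzero(sign * means >= threshold)[0]
        if not len(idx):
            continue
        run_start = idx[0]
        prev = idx[0]
        for i in list(idx[1:]) + [None]:
            if i is not None and i <= prev + w:  # windows overlap or abut
                prev = i
                continue
            region = (int(run_start), int(prev) + w, sign,
                      float(np.max(sign * means[run_start:prev + 1])))
            hits.append(region)
            if i is not None:
                run_start = prev = i
    return sorted(hits)


# ----------------------------------------------- partition function folding

def _pairable(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL


def pair_probabilities(sequence: str, pair_weight: float = _PAIR_WEIGHT,
                       min_loop: int = _MIN_LOOP) -> np.ndarray:
    """Equilibrium base-pair probability matrix over all nested structures.

    Uniform-weight model: every canonical pair (AT/TA, GC/CG, GT/TG in DNA
    alphabet, i.e. AU/GC/GU wobble on RNA) contributes a Boltzmann factor
    ``pair_weight`` (default e, energy -1 per pair at kT = 1); hairpin
    loops enclose at least ``min_loop`` unpaired bases. Returns the
    symmetric n x n matrix P with P[i, j] = Pr(i pairs j).
    """
    seq = _dna(sequence)
    n = len(seq)
    if n == 0:
        return np.zeros((0, 0))
    can = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            can[i, j] = _pairable(seq[i], seq[j])

    # inside: Z[i, j] = partition function of subsequence i..j (1 if empty)
    Z = np.ones((n + 2, n + 2))

    def z(i: int, j: int) -> float:
        return Z[i + 1, j + 1] if i <= j else 1.0

    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            tot = z(i + 1, j)  # i unpaired
            ks = np.nonzero(can[i, i:j + 1])[0] + i
            for k in ks:
                tot += pair_weight * z(i + 1, k - 1) * z(k + 1, j)
            Z[i + 1, j + 1] = tot

    # outside: X[i, j] = weight of configurations on the rest of the
    # sequence given that (i, j) is paired (enclosing pairs allowed)
    X = np.zeros((n, n))
    order = sorted(zip(*np.nonzero(can)), key=lambda ij: ij[0] - ij[1])
    for i, j in order:  # decreasing span
        tot = z(0, i - 1) * z(j + 1, n - 1)
        for a in range(i):
            for b in range(j + 1, n):
                if can[a, b] and X[a, b] > 0:
                    tot += pair_weight * z(a + 1, i - 1) * z(j + 1, b - 1) * X[a, b]
        X[i, j] = tot

    P = np.zeros((n, n))
    total = z(0, n - 1)
    for i, j in zip(*np.nonzero(can)):
        P[i, j] = pair_weight * z(i + 1, j - 1) * X[i, j] / total
    return P + P.T


def prob_paired(sequence: str, **kwargs) -> np.ndarray:
    """Per-position probability of being base-paired."""
    return pair_probabilities(sequence, **kwargs).sum(axis=1)


@dataclass
class PairProbabilityProfile:
    offsets: np.ndarray
    p_paired: np.ndarray
    n_anchors: int


def pair_probability_profile(anchors: Sequence[GenomicPosition],
                             genome: Mapping[str, str], window: int = 75,
                             report_span: int = 50,
                             pair_probs=None) -> PairProbabilityProfile:
    """Mean pairing probability per offset around anchors.

    Each anchor contributes the ``window``-nt centred sequence (truncated
    with a warning at contig edges); the mean over anchors is reported for
    the central ``report_span`` offsets. ``pair_probs`` may supply an
    externally computed callable seq -> per-position probabilities to
    replace the built-in uniform-weight model.
    """
    if not anchors:
        raise ValueError("no anchors given")
    fold = pair_probs or prob_paired
    up = (window - 1) // 2
    down = window - 1 - up
    acc = np.zeros(window)
    cov = np.zeros(window)
    for anchor in anchors:
        seq, first = extract_window(genome, anchor, up, down)
        if len(seq) < window:
            warnings.warn(f"window truncated at contig edge for {anchor}",
                          stacklevel=2)
        p = fold(seq)
        idx = np.arange(first + up, first + up + len(seq))
        acc[idx] += p
        cov[idx] += 1
    mean = np.where(cov > 0, acc / np.maximum(cov, 1), np.nan)
    offsets = np.arange(-up, down + 1)
    lo = (window - report_span) // 2
    return PairProbabilityProfile(offsets[lo:lo + report_span],
                                  mean[lo:lo + report_span], len(anchors))


# ------------------------------------------------------------------ miRNA

def mirna_complementarity_scan(sequences: Mapping[str, str],
                               mirnas: Mapping[str, str],
                               max_mismatch: int = 1
                               ) -> pd.DataFrame:
    """Ungapped full-length scan for reverse-complement miRNA matches.

    Reports every position where the reverse complement of a miRNA aligns
    to a target sequence with <= ``max_mismatch`` mismatches.
    """
    rows = []
    for mname, mseq in sorted(mirnas.items()):
        pat = np.frombuffer(revcomp(_dna(mseq)).encode(), dtype="S1")
        m = len(pat)
        for sname, seq in sorted(sequences.items()):
            arr = np.frombuffer(_dna(seq).encode(), dtype="S1")
            n = len(arr)
            if n < m:
                continue
            mm = np.zeros(n - m + 1, dtype=int)
            for k in range(m):
                mm += arr[k:n - m + 1 + k] != pat[k]
            for start in np.nonzero(mm <= max_mismatch)[0]:
                rows.append((sname, int(start), int(start) + m, mname,
                             int(mm[start])))
    return pd.DataFrame(rows, columns=["sequence", "start", "end",
                                       "mirna", "mismatches"])


def expressed_mirnas(table: pd.DataFrame, min_reads: int = 10,
                     min_reps: int = 2) -> pd.DataFrame:
    """Filter a miRNA table (columns: name, seq, rep1..repN) to miRNAs with
    strictly more than ``min_reads`` reads in >= ``min_reps`` replicates."""
    rep_cols = [c for c in table.columns if c not in ("name", "seq")]
    ok = (table[rep_cols] > min_reads).sum(axis=1) >= min_reps
    return table.loc[ok].reset_index(drop=True)


def mirna_seed_profile(anchors: Sequence[GenomicPosition],
                       genome: Mapping[str, str], table: pd.DataFrame,
                       min_reads: int = 10, min_reps: int = 2,
                       flank: int = 30) -> pd.DataFrame:
    """Seed-match occurrence heatmap around anchors.

    The seed is miRNA positions 2-8; occurrences of its reverse complement
    are counted per start offset in +-flank windows, one row per expressed
    miRNA.
    """
    expressed = expressed_mirnas(table, min_reads, min_reps)
    offsets = np.arange(-flank, flank + 1)
    mat = {}
    for row in expressed.itertuples():
        seed = _dna(row.seq)[1:8]
        site = revcomp(seed)
        profile = np.zeros(2 * flank + 1)
        for anchor in anchors:
            seq, first = extract_window(genome, anchor,
                                        flank + len(site), flank + len(site))
            for i in range(len(seq) - len(site) + 1):
                o = first + i
                if seq[i:i + len(site)] == site and -flank <= o <= flank:
                    profile[o + flank] += 1
        mat[row.name] = profile
    return pd.DataFrame(mat, index=offsets).T
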