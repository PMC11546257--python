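"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive enumeration (explicit loops over all
intervals / all nested structures / all alignment offsets) so they share
no code path with the implementations they check.
"""
from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pytest

from recapmap import simulate
from recapmap.types import TagTrack


# ------------------------------------------------------ paraclu oracle

def paraclu_oracle(positions, counts):
    """Exhaustive density-stability clustering.

    For every site interval, the break threshold U is the minimum density
    over all anchored prefixes and suffixes (single sites are infinitely
    dense); the formation threshold M is the maximum U over all strict
    superintervals (0 for the outermost interval). An interval is a
    cluster iff U > M. Returns sorted (start, end, total, min_d, max_d).
    """
    pos, cnt = list(positions), list(counts)
    m = len(pos)

    def dens(i, j):
        if i == j:
            return math.inf
        return sum(cnt[i:j + 1]) / (pos[j] - pos[i])

    U = {}
    for i in range(m):
        for j in range(i, m):
            vals = [dens(i, k) for k in range(i, j + 1)]
            vals += [dens(k, j) for k in range(i, j + 1)]
            U[(i, j)] = min(vals)
    out = []
    for (i, j), u in U.items():
        supers = [U[(a, b)] for a in range(i + 1) for b in range(j, m)
                  if (a, b) != (i, j)]
        M = max(supers + [0.0])
        if u > M:
            out.append((pos[i], pos[j] + 1, sum(cnt[i:j + 1]), M, u))
    return sorted(out)


def random_sites(rng, max_sites=12, max_pos=60, max_count=9):
    m = int(rng.integers(1, max_sites + 1))
    pos = sorted(rng.choice(max_pos, size=m, replace=False).tolist())
    cnt = rng.integers(1, max_count + 1, size=m).tolist()
    return pos, cnt


def track_from_sites(pos, cnt, contig="c", strand="+"):
    t = TagTrack()
    for p, c in zip(pos, cnt):
        t.add(contig, int(p), strand, int(c))
    return t


# ------------------------------------------------- window-merge oracle

def window_merge_oracle(positions, gap=20):
    """Transitive closure of 'within gap' via pairwise union-find."""
    pos = sorted(set(positions))
    parent = list(range(len(pos)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, p in enumerate(pos):
        for j, q in enumerate(pos):
            if i < j and q - p - 1 <= gap:
                parent[find(j)] = find(i)
    groups = {}
    for i, p in enumerate(pos):
        groups.setdefault(find(i), []).append(p)
    return sorted((min(g), max(g) + 1) for g in groups.values())


# ------------------------------------------- structure-enumeration oracle

_CANON = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def enumerate_pair_probs(seq, pair_weight=math.e, min_loop=3):
    """Base-pair probabilities by explicit enumeration of every nested
    structure (Boltzmann weight pair_weight ** n_pairs)."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)

    @lru_cache(maxsize=None)
    def structures(i, j):
        if j < i:
            return (frozenset(),)
        out = list(structures(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _CANON:
                for inner in structures(i + 1, k - 1):
                    for outer in structures(k + 1, j):
                        out.append(inner | outer | {(i, k)})
        return tuple(out)

    P = np.zeros((n, n))
    Z = 0.0
    for s in structures(0, n - 1):
        w = pair_weight ** len(s)
        Z += w
        for (i, j) in s:
            P[i, j] += w
    structures.cache_clear()
    P /= Z
    return P + P.T


# ----------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_sim():
    """A 30-gene synthetic study shared by read-only tests."""
    cfg = simulate.SimConfig(seed=7, n_genes=30)
    genome, ann, truth = simulate.simulate_genome_annotation(cfg)
    tracks = simulate.simulate_cage(cfg, ann, truth)
    return cfg, genome, ann, truth, tracks


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions (100 genes) used for recovery checks."""
    cfg = simulate.SimConfig(seed=11)
    genome, ann, truth = simulate.simulate_genome_annotation(cfg)
    tracks = simulate.simulate_cage(cfg, ann, truth)
    return cfg, genome, ann, truth, tracks
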