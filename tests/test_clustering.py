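"""Window clustering, density-stability clustering, filters, dominant
peaks, region labels and count-matrix statistics."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from recapmap import clustering
from recapmap.clustering import (dominant_peak, inner_3utr_peaks,
                                 paraclu_cluster, paraclu_filter,
                                 region_proportions, replicate_correlation,
                                 size_factor_normalize, window_cluster)
from recapmap.types import (AnnotationModel, Cluster, GenomicPosition,
                            Segment, TagTrack, Transcript, pool_tracks)
from conftest import paraclu_oracle, random_sites, track_from_sites, \
    window_merge_oracle


def _two_reps(pairs1, pairs2, strand="+"):
    t1, t2 = TagTrack("s", "rep1"), TagTrack("s", "rep2")
    for p, c in pairs1:
        t1.add("c", p, strand, c)
    for p, c in pairs2:
        t2.add("c", p, strand, c)
    return [t1, t2]


class TestWindowCluster:
    def test_gap_20_merges(self):
        clusters = window_cluster(_two_reps([(100, 2)], [(121, 2)]))
        assert [(c.start, c.end) for c in clusters] == [(100, 122)]

    def test_gap_21_splits(self):
        clusters = window_cluster(_two_reps([(100, 2), (122, 2)],
                                            [(100, 2), (122, 2)]))
        assert [(c.start, c.end) for c in clusters] == [(100, 101), (122, 123)]

    def test_replicate_support_2_1_rejected(self):
        assert window_cluster(_two_reps([(100, 2)], [(100, 1)])) == []

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError, match="replicate"):
            window_cluster([TagTrack()])

    def test_strands_kept_separate(self):
        t1, t2 = TagTrack("s", "rep1"), TagTrack("s", "rep2")
        for t in (t1, t2):
            t.add("c", 100, "+", 2)
            t.add("c", 105, "-", 2)
        clusters = window_cluster([t1, t2])
        assert sorted(c.strand for c in clusters) == ["+", "-"]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_interval_merge_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = sorted(rng.choice(300, size=rng.integers(1, 30), replace=False))
        tracks = _two_reps([(int(p), 2) for p in pos], [(int(p), 2) for p in pos])
        got = [(c.start, c.end) for c in window_cluster(tracks)]
        assert got == window_merge_oracle(pos)


class TestParaclu:
    def test_single_site(self):
        t = track_from_sites([5], [7])
        cl = paraclu_cluster(t)
        assert [(c.start, c.end, c.total, c.min_density, c.max_density)
                for c in cl] == [(5, 6, 7, 0.0, math.inf)]

    def test_adjacent_pair_hierarchy(self):
        cl = paraclu_cluster(track_from_sites([10, 11], [5, 5]))
        got = sorted((c.start, c.end, c.total, c.min_density, c.max_density)
                     for c in cl)
        assert got == [(10, 11, 5, 10.0, math.inf),
                       (10, 12, 10, 0.0, 10.0),
                       (11, 12, 5, 10.0, math.inf)]

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_enumeration_oracle(self, seed):
        """Implementation equals exhaustive enumeration for <= 12 sites."""
        rng = np.random.default_rng(seed)
        pos, cnt = random_sites(rng)
        got = sorted((c.start, c.end, c.total, c.min_density, c.max_density)
                     for c in paraclu_cluster(track_from_sites(pos, cnt)))
        assert got == paraclu_oracle(pos, cnt)

    def test_dominant_and_totals_consistent(self):
        cl = paraclu_cluster(track_from_sites([1, 3, 10], [2, 9, 4]))
        for c in cl:
            assert c.start <= c.dominant.pos < c.end
            assert c.dominant_count <= c.total


def _mk(start, end, total, min_d=1.0, max_d=10.0):
    return Cluster("c", "+", start, end, total, min_density=min_d,
                   max_density=max_d)


class TestParacluFilter:
    def test_length_201_removed(self):
        # inclusive length end - start - 1 = 201 > 200
        assert paraclu_filter([_mk(0, 202, 50)]) == []

    def test_length_200_kept(self):
        assert len(paraclu_filter([_mk(0, 201, 50)])) == 1

    def test_density_ratio_below_2_removed(self):
        assert paraclu_filter([_mk(0, 50, 50, min_d=10.0, max_d=19.0)]) == []
        assert len(paraclu_filter([_mk(0, 50, 50, min_d=10.0, max_d=20.0)])) == 1

    def test_low_total_removed(self):
        assert paraclu_filter([_mk(0, 50, 4)]) == []

    def test_single_position_readded(self):
        single = _mk(7, 8, 6, min_d=3.0, max_d=math.inf)
        assert paraclu_filter([single]) == [single]
        weak = _mk(7, 8, 4, min_d=3.0, max_d=math.inf)
        assert paraclu_filter([weak]) == []

    def test_nested_cluster_removed(self):
        outer = _mk(0, 100, 80)
        inner = _mk(10, 40, 40)
        kept = paraclu_filter([outer, inner])
        assert kept == [outer]

    def test_retained_set_mutually_non_nested(self):
        rng = np.random.default_rng(0)
        pos, cnt = random_sites(rng, max_sites=12, max_pos=400, max_count=30)
        kept = paraclu_filter(paraclu_cluster(track_from_sites(pos, cnt)))
        for a in kept:
            assert not any(b.contains(a) for b in kept)


class TestDominantPeak:
    def _track(self, pairs, strand="+"):
        t = TagTrack()
        for p, c in pairs:
            t.add("c", p, strand, c)
        return t

    def test_unique_maximum(self):
        t = self._track([(100, 3), (101, 7)])
        c = Cluster("c", "+", 100, 102, 10)
        assert dominant_peak(c, t).pos == 101

    def test_tie_plus_strand_5prime(self):
        t = self._track([(101, 5), (102, 5)])
        assert dominant_peak(Cluster("c", "+", 101, 103, 10), t).pos == 101

    def test_tie_minus_strand_5prime(self):
        t = self._track([(101, 5), (102, 5)], strand="-")
        assert dominant_peak(Cluster("c", "-", 101, 103, 10), t).pos == 102


@pytest.fixture
def tiny_ann():
    ta = Transcript("gA", "c", "+", [Segment("5UTR", 0, 100),
                                     Segment("CDS", 100, 300),
                                     Segment("intron", 300, 400),
                                     Segment("CDS", 400, 500),
                                     Segment("3UTR", 500, 1100)])
    tb = Transcript("gB", "c", "+", [Segment("5UTR", 1050, 1060),
                                     Segment("CDS", 1060, 1200)])
    return AnnotationModel([ta, tb])


class TestRegions:
    def test_sole_3utr(self, tiny_ann):
        assert tiny_ann.assign_region(GenomicPosition("c", 600, "+")) == "3UTR"

    def test_precedence_3utr_over_cds(self, tiny_ann):
        # inside gA 3'UTR and gB CDS simultaneously
        assert tiny_ann.assign_region(GenomicPosition("c", 1070, "+")) == "3UTR"

    def test_intergenic(self, tiny_ann):
        assert tiny_ann.assign_region(GenomicPosition("c", 5000, "+")) == "intergenic"

    def test_wrong_strand_is_intergenic(self, tiny_ann):
        assert tiny_ann.assign_region(GenomicPosition("c", 600, "-")) == "intergenic"

    def test_proportions(self, tiny_ann):
        t = TagTrack()
        t.add("c", 50, "+", 5)   # 5UTR
        t.add("c", 600, "+", 5)  # 3UTR
        props = region_proportions([t], tiny_ann)
        assert props["5UTR"] == props["3UTR"] == 0.5
        assert sum(props.values()) == 1.0

    def test_3utr_fraction_grows_with_recap_rate(self):
        from recapmap import simulate
        fracs = []
        for rate in (0.0, 10.0, 40.0):
            cfg = simulate.SimConfig(seed=3, n_genes=20, recap_rate=rate)
            genome, ann, truth = simulate.simulate_genome_annotation(cfg)
            tracks = simulate.simulate_cage(cfg, ann, truth)
            fracs.append(region_proportions(list(tracks.values()), ann)["3UTR"])
        assert fracs[0] < fracs[1] < fracs[2]


class TestSizeFactors:
    def test_identical_samples(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        f, norm = size_factor_normalize(m)
        assert np.allclose(f, [1.0, 1.0])

    def test_doubled_sample_closed_form(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f, norm = size_factor_normalize(m)
        assert np.allclose(f, [1 / math.sqrt(2), math.sqrt(2)])
        assert np.allclose(norm["a"], norm["b"])

    def test_scale_equivariance(self):
        """Scaling one library by k scales its factor, relative to the
        other sample's, by k; the geometric mean of factors stays 1."""
        m = pd.DataFrame({"a": [3, 8, 13], "b": [5, 9, 2]})
        f1, _ = size_factor_normalize(m)
        f2, _ = size_factor_normalize(m.assign(b=m.b * 7))
        assert np.isclose((f2["b"] / f2["a"]) / (f1["b"] / f1["a"]), 7.0)
        assert np.isclose(np.prod(f1) ** 0.5, np.prod(f2) ** 0.5)

    def test_row_order_invariance(self):
        m = pd.DataFrame({"a": [3, 8, 13], "b": [5, 9, 2]})
        f1, _ = size_factor_normalize(m)
        f2, _ = size_factor_normalize(m.iloc[[2, 0, 1]])
        assert np.allclose(f1, f2)

    def test_error_when_no_common_nonzero(self):
        m = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="nonzero"):
            size_factor_normalize(m)

    def test_matches_pydeseq2_size_factors(self):
        """Independent cross-check against the DESeq2 reimplementation."""
        deseq = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson([50, 100, 25], size=(40, 3)),
                              columns=list("abc"))
        ours, _ = size_factor_normalize(counts)
        _, theirs = deseq.deseq2_norm(counts.to_numpy().T)  # samples x genes
        assert np.allclose(ours.to_numpy(), theirs)


class TestCorrelation:
    def test_identical_and_antiproportional(self):
        m = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3], "c": [3, 2, 1]})
        r, meta = replicate_correlation(m, log=False)
        assert np.isclose(r.loc["a", "b"], 1.0)
        assert np.isclose(r.loc["a", "c"], -1.0)

    def test_synthetic_replicates_correlate(self, default_sim):
        cfg, genome, ann, truth, tracks = default_sim
        reps = list(tracks.values())
        clusters = window_cluster(reps)
        mat = clustering.cluster_count_matrix(
            clusters, {t.replicate: t for t in reps})
        r, _ = replicate_correlation(mat)
        assert r.loc["rep1", "rep2"] > 0.9


class TestInnerPeaks:
    def _ann(self):
        # '+' gene with 3'UTR [500, 1100)
        t = Transcript("g", "c", "+", [Segment("CDS", 0, 500),
                                       Segment("3UTR", 500, 1100)])
        return AnnotationModel([t])

    def test_peak_149_from_cds_dropped(self):
        ann = self._ann()
        assert inner_3utr_peaks([GenomicPosition("c", 649, "+")], ann) == []

    def test_peak_150_from_both_kept(self):
        ann = self._ann()
        pk = GenomicPosition("c", 650, "+")
        assert inner_3utr_peaks([pk], ann) == [pk]
        pk2 = GenomicPosition("c", 949, "+")  # 150 nt from end (end-1=1099)
        assert inner_3utr_peaks([pk2], ann) == [pk2]
        assert inner_3utr_peaks([GenomicPosition("c", 950, "+")], ann) == []

    def test_short_3utr_keeps_nothing(self):
        t = Transcript("g", "c", "+", [Segment("3UTR", 0, 299)])
        ann = AnnotationModel([t])
        peaks = [GenomicPosition("c", p, "+") for p in range(0, 299, 10)]
        assert inner_3utr_peaks(peaks, ann) == []


def test_planted_recap_recovery(default_sim):
    """At default rates >= 90% of planted capping sites are recovered with
    a retained 3'UTR cluster whose dominant peak is within +-5 nt."""
    from recapmap.pipeline import recap_recall
    cfg, genome, ann, truth, tracks = default_sim
    pooled = pool_tracks(list(tracks.values()))
    retained = paraclu_filter(paraclu_cluster(pooled))
    clustering.label_clusters(retained, ann)
    recall, offsets = recap_recall(retained, truth, tolerance=5)
    assert recall >= 0.9
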