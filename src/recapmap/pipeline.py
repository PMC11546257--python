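"""End-to-end orchestration: simulate -> cluster -> profile -> rank ->
siRNA -> FISH, from a single flat config, with a machine-readable report.

The run report records the package version, the seed, every parameter as
used, per-stage record counts, SHA-256 hashes of written files, and
recovery metrics against the planted ground truth.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, clustering, fish, io, profiles, rbp, simulate
from .simulate import GroundTruth, SimConfig
from .types import GenomicPosition, pool_tracks

log = logging.getLogger("recapmap")

ALL_STAGES = ("simulate", "cluster", "profile", "rbp", "sirna", "fish")


@dataclass
class RunConfig:
    outdir: str = "recapmap_run"
    seed: int = 0
    log_level: str = "INFO"
    stages: tuple[str, ...] = ALL_STAGES
    sim: dict = field(default_factory=dict)      # SimConfig overrides
    gap: int = 20
    min_per_replicate: int = 2
    min_total: int = 5
    max_len: int = 200
    min_ratio: float = 2.0
    profile_window: int = 100
    smoothing: int = 5
    rbp_fdr: float = 0.05
    rbp_n_perm: int = 100
    rbp_window: int = 100
    sirna_min_replicates: int = 2
    fish_threshold_px: float = 3.0
    recovery_tolerance_nt: int = 5

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        cfg = SimConfig(seed=self.seed)
        for k, v in self.sim.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown SimConfig field {k!r}")
            setattr(cfg, k, v)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def recap_recall(clusters, truth: GroundTruth, tolerance: int = 5
                 ) -> tuple[float, list[int]]:
    """Fraction of planted recap sites with a retained 3'UTR cluster whose
    dominant peak lies within +-tolerance nt; also the per-site offsets."""
    offsets = []
    hit = 0
    for _, contig, pos, strand in truth.recap_sites:
        best = None
        for c in clusters:
            if (c.contig == contig and c.strand == strand and c.dominant
                    and c.region in (None, "3UTR")):
                d = c.dominant.pos - pos
                if best is None or abs(d) < abs(best):
                    best = d
        if best is not None and abs(best) <= tolerance:
            hit += 1
            offsets.append(best)
    recall = hit / len(truth.recap_sites) if truth.recap_sites else float("nan")
    return recall, offsets


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns (and
    writes) the run report. A stage failure is recorded and later stages
    that depend on it are skipped; partial outputs are retained."""
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed,
                    "parameters": dataclasses.asdict(cfg),
                    "stages": {}, "files": {}}
    state: dict = {}

    def record(name: str, **info) -> None:
        report["stages"][name] = {"status": "ok", **info}

    def write(name: str, path: Path) -> None:
        report["files"][path.name] = _sha256(path)

    order = [s for s in ALL_STAGES if s in cfg.stages]
    for stage in order:
        try:
            _STAGE_FUNCS[stage](cfg, state, outdir, record, write)
        except Exception as exc:  # noqa: BLE001 - report and continue
            log.exception("stage %s failed", stage)
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report


# ----------------------------------------------------------------- stages

def _stage_simulate(cfg, state, outdir, record, write):
    sim = cfg.sim_config()
    genome, ann, truth = simulate.simulate_genome_annotation(sim)
    tracks = simulate.simulate_cage(sim, ann, truth)
    xlinks = simulate.simulate_crosslinks(sim, ann, truth)
    frags = simulate.simulate_fragments(sim, ann, truth)
    cons = simulate.simulate_conservation(sim, ann, truth)
    state.update(sim=sim, genome=genome, ann=ann, truth=truth,
                 tracks=tracks, xlinks=xlinks, frags=frags, cons=cons)
    io.write_fasta(genome, outdir / "genome.fasta")
    io.write_annotation(ann, outdir / "annotation.bed")
    for (sample, rep), track in tracks.items():
        for strand, tag in (("+", "plus"), ("-", "minus")):
            p = outdir / f"cage_{sample}_{rep}_{tag}.bedgraph"
            io.write_bedgraph_tags(track, p, strand)
            write("cage", p)
    io.write_ground_truth(truth, outdir / "ground_truth.json")
    for p in ("genome.fasta", "annotation.bed", "ground_truth.json"):
        write("sim", outdir / p)
    record("simulate", n_genes=len(ann), n_recap_sites=len(truth.recap_sites),
           n_cage_tracks=len(tracks), n_fragments=len(frags))


def _stage_cluster(cfg, state, outdir, record, write):
    tracks = list(state["tracks"].values())
    ann = state["ann"]
    window = clustering.window_cluster(tracks, gap=cfg.gap,
                                       min_per_replicate=cfg.min_per_replicate)
    pooled = pool_tracks(tracks)
    hierarchy = clustering.paraclu_cluster(pooled)
    retained = clustering.paraclu_filter(hierarchy, min_total=cfg.min_total,
                                         max_len=cfg.max_len,
                                         min_ratio=cfg.min_ratio)
    clustering.label_clusters(retained, ann)
    clustering.label_clusters(window, ann)
    utr3_peaks = [c.dominant for c in retained if c.region == "3UTR"]
    inner = clustering.inner_3utr_peaks(utr3_peaks, ann)
    state.update(window_clusters=window, retained=retained,
                 utr3_peaks=utr3_peaks, inner_peaks=inner, pooled=pooled)
    rows = [(c.contig, c.start, c.end, f"{c.region}|dom={c.dominant.pos}",
             c.total, c.strand) for c in retained]
    io.write_bed6(io.intervals_to_bed6(rows), outdir / "clusters.bed")
    write("cluster", outdir / "clusters.bed")
    info = dict(n_window_clusters=len(window), n_retained=len(retained),
                n_3utr_peaks=len(utr3_peaks), n_inner_peaks=len(inner))
    truth = state.get("truth")
    if truth and truth.recap_sites:
        recall, offsets = recap_recall(retained, truth,
                                       cfg.recovery_tolerance_nt)
        info["recap_recall"] = recall
        info["median_dominant_offset"] = float(np.median(offsets)) if offsets else None
    props = clustering.region_proportions(tracks, ann)
    info["region_proportions"] = props
    record("cluster", **info)


def _stage_profile(cfg, state, outdir, record, write):
    anchors = state["inner_peaks"] or state["utr3_peaks"]
    truth = state["truth"]
    xl = state["xlinks"][truth.enriched_rbp]
    prof = profiles.anchor_profile(xl, anchors, cfg.profile_window,
                                   smoothing=cfg.smoothing)
    curve = prof.mean_curve()
    peak_offset = int(prof.offsets[int(np.argmax(curve))])
    prof.to_frame().to_csv(outdir / "rbp_profile.tsv", sep="\t", index=False)
    starts, ends = profiles.readend_profile(state["frags"], anchors,
                                            cfg.profile_window)
    ends.to_frame().to_csv(outdir / "readends_profile.tsv", sep="\t", index=False)
    cons = profiles.score_profile(state["cons"], anchors, cfg.profile_window)
    cons.to_csv(outdir / "conservation_profile.tsv", sep="\t", index=False)
    for name in ("rbp_profile.tsv", "readends_profile.tsv",
                 "conservation_profile.tsv"):
        write("profile", outdir / name)
    ends_curve = ends.mean_curve()
    record("profile", n_anchors=len(anchors),
           rbp_profile_peak_offset=peak_offset,
           readend_peak_offset=int(ends.offsets[int(np.argmax(ends_curve))]))


def _stage_rbp(cfg, state, outdir, record, write):
    order, sites = rbp.rank_rbps_around_peaks(
        state["xlinks"], state["ann"], state["inner_peaks"],
        W=cfg.rbp_window, fdr=cfg.rbp_fdr, n_perm=cfg.rbp_n_perm,
        seed=cfg.seed)
    with open(outdir / "rbp_ranking.tsv", "w") as fh:
        fh.write("rbp\tscore\trank\n")
        for i, (name, score) in enumerate(order, 1):
            fh.write(f"{name}\t{score:.4f}\t{i}\n")
    write("rbp", outdir / "rbp_ranking.tsv")
    enriched = state["truth"].enriched_rbp
    rank = next(i for i, (n, _) in enumerate(order, 1) if n == enriched)
    state["rbp_order"] = order
    record("rbp", n_sites=len(sites), enriched_rbp=enriched,
           enriched_rank=rank)


def _stage_sirna(cfg, state, outdir, record, write):
    sim, ann, truth = state["sim"], state["ann"], state["truth"]
    targets, tracks = simulate.simulate_sirna(sim, ann, truth)
    results = {}
    for row in targets.itertuples():
        reps = [tracks[(row.name, f"rep{r + 1}")]
                for r in range(sim.sirna_replicates)]
        res = profiles.sirna_capping_detect(
            reps, (row.contig, row.start, row.end, row.strand),
            min_replicates=cfg.sirna_min_replicates)
        results[row.name] = res
    n_det = sum(r["detected"] for r in results.values())
    mid_offsets = [r["dominant_offset"] for r in results.values()
                   if r["dominant_offset"] is not None]
    state["sirna_results"] = results
    io.write_bed6(targets, outdir / "sirna_targets.bed")
    write("sirna", outdir / "sirna_targets.bed")
    record("sirna", n_targets=len(results), n_detected=n_det,
           dominant_offsets=mid_offsets)


def _stage_fish(cfg, state, outdir, record, write):
    sim, truth = state["sim"], state["truth"]
    spots = simulate.simulate_fish(sim, truth)
    io.write_spots(spots, outdir / "fish_spots.tsv")
    write("fish", outdir / "fish_spots.tsv")
    fracs = fish.independent_fraction(spots,
                                      dist_threshold_px=cfg.fish_threshold_px)
    tests = fish.compare_groups(fracs, control="control")
    fracs.to_csv(outdir / "fish_fractions.tsv", sep="\t", index=False)
    tests.to_csv(outdir / "fish_tests.tsv", sep="\t", index=False)
    down = fracs[fracs.channel == "downstream"]
    est = {g: float(grp.fraction_independent.mean())
           for g, grp in down.groupby("gene")}
    record("fish", n_spots=len(spots), downstream_fraction_by_gene=est,
           truth_fraction_by_gene=truth.cleaved_fraction_per_gene)


_STAGE_FUNCS = {"simulate": _stage_simulate, "cluster": _stage_cluster,
                "profile": _stage_profile, "rbp": _stage_rbp,
                "sirna": _stage_sirna, "fish": _stage_fish}
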