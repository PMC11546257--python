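"""Synthetic genomes, annotations and signal tracks with planted ground truth.

The generator emulates the signal structure the pipeline is built to detect:

* promoter CAGE tag clusters at annotated TSSs;
* planted intra-3'UTR capping ("recap") sites with a G-run ending at the
  site, carrying their own CAGE tag clusters;
* one RNA-binding protein whose crosslinks sit a few nucleotides upstream
  (mean -10 nt, sd 5) of the recap sites, against a shared uniform
  background for all RBPs;
* RNA-seq fragments whose 3' ends coincide with recap sites (the upstream
  cleavage product);
* per-base conservation elevated downstream of recap sites;
* siRNA-knockdown CAGE samples with cleavage-derived 5' tags at target
  midpoints in a configurable subset of replicates;
* two-channel FISH spot tables in which a planted fraction of downstream
  spots is spatially independent of the upstream channel.

Every output is reproducible byte-for-byte from (SimConfig, seed): each
artifact draws from its own child of ``numpy.random.SeedSequence(seed)``
(spawn keys: 0 genome, 1 CAGE per sample/replicate, 2 crosslinks, 3
fragments, 4 conservation, 5 siRNA, 6 FISH, 7 per-gene expression field),
so regenerating one file never perturbs another.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import AnnotationModel, Segment, TagTrack, Transcript, orient

_GAP = 500          # intergenic gap between simulated genes, nt
_INNER_MARGIN = 160  # recap sites keep this distance from 3'UTR boundaries


def _default_region_lengths() -> dict[str, int]:
    return {"5UTR": 200, "CDS": 1000, "intron": 500, "3UTR": 800}


def _default_rbp_offsets() -> tuple[float, float]:
    # upstream enrichment: mean -10 nt, sd 5 (negative = 5' of the site)
    return (-10.0, 5.0)


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the defaults used throughout."""

    seed: int = 0
    n_genes: int = 100
    genome_length: int | None = None           # None: auto-sized
    region_lengths: dict[str, int] = field(default_factory=_default_region_lengths)
    frac_genes_with_recap: float = 0.5
    promoter_rate: float = 50.0                # expected tags per TSS per replicate
    recap_rate: float = 20.0                   # expected tags per recap site per replicate
    expression_sd: float = 0.75                # sd of per-gene log expression multiplier
    noise_rate: float = 1.0                    # expected background tags per kb
    g_rich_len: int = 8
    rbp_offsets: tuple[float, float] = field(default_factory=_default_rbp_offsets)
    enriched_rbp: str = "UPF1"
    n_rbps: int = 10
    rbp_site_rate: float = 15.0                # crosslinks per recap site (enriched RBP)
    rbp_background_per_gene: float = 3.0       # uniform crosslinks per gene, all RBPs
    n_replicates: int = 2
    n_samples: int = 1
    frag_len: tuple[float, float] = (250.0, 30.0)   # fragment length mean, sd
    frags_per_gene: float = 30.0
    frac_frag_at_recap: float = 0.5
    sirna_targets: int = 5
    sirna_rate: float = 30.0
    sirna_replicates: int = 3
    sirna_replicates_with_signal: int = 3
    fish_cleaved_frac: float = 0.5
    fish_jitter_sd: float = 0.5                # px
    fish_spots_per_cell: int = 12
    fish_n_cells: int = 200                    # per probed gene, across replicates
    fish_cell_size: float = 200.0              # px, cells laid out on a grid

    def validate(self) -> None:
        for name in ("frac_genes_with_recap", "fish_cleaved_frac", "frac_frag_at_recap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("promoter_rate", "recap_rate", "rbp_site_rate", "sirna_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if set(self.region_lengths) != {"5UTR", "CDS", "intron", "3UTR"}:
            raise ValueError("region_lengths must cover 5UTR/CDS/intron/3UTR")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the synthetic data."""

    recap_sites: list[tuple[str, str, int, str]] = field(default_factory=list)
    enriched_rbp: str = ""
    cleaved_fraction_per_gene: dict[str, float] = field(default_factory=dict)
    sirna_cleavage_positions: list[tuple[str, str, int, str]] = field(default_factory=list)


def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


# ------------------------------------------------------- genome & annotation

def simulate_genome_annotation(cfg: SimConfig) -> tuple[dict[str, str], AnnotationModel, GroundTruth]:
    """Lay out non-overlapping genes on both strands and plant recap sites.

    Each gene is 5'UTR -> CDS (split by one intron) -> 3'UTR in transcript
    orientation. Recap genes carry a G-run of ``g_rich_len`` ending at the
    planted site (on the transcript strand) and an AATAAA hexamer near the
    annotated 3'UTR end.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    L = cfg.region_lengths
    gene_len = sum(L.values())
    needed = cfg.n_genes * (gene_len + _GAP) + _GAP
    if cfg.genome_length is not None and cfg.genome_length < needed:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small for {cfg.n_genes} "
            f"genes (need >= {needed})")
    glen = cfg.genome_length if cfg.genome_length is not None else needed

    seq = rng.choice(list("ACGT"), size=glen, p=[0.3, 0.2, 0.2, 0.3])
    truth = GroundTruth(enriched_rbp=cfg.enriched_rbp)
    transcripts: list[Transcript] = []
    n_recap = int(round(cfg.frac_genes_with_recap * cfg.n_genes))
    recap_flags = np.zeros(cfg.n_genes, bool)
    if cfg.n_genes:
        recap_flags[rng.choice(cfg.n_genes, size=n_recap, replace=False)] = True

    cursor = _GAP
    contig = "chr1"
    for i in range(cfg.n_genes):
        gene = f"gene{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor
        cursor += gene_len + _GAP
        # genomic order of regions depends on strand
        order = ["5UTR", "CDS1", "intron", "CDS2", "3UTR"]
        half = L["CDS"] // 2
        sizes = {"5UTR": L["5UTR"], "CDS1": half, "intron": L["intron"],
                 "CDS2": L["CDS"] - half, "3UTR": L["3UTR"]}
        if strand == "-":
            order = order[::-1]
        segs, pos = [], start
        for part in order:
            region = "CDS" if part.startswith("CDS") else part
            segs.append(Segment(region, pos, pos + sizes[part]))
            pos += sizes[part]
        if strand == "-":
            segs = segs[::-1]  # 5'->3' in transcript orientation
        transcripts.append(Transcript(gene, contig, strand, segs))

        u3 = [s for s in segs if s.region == "3UTR"][0]
        if recap_flags[i]:
            lo, hi = u3.start + _INNER_MARGIN, u3.end - _INNER_MARGIN
            if hi <= lo:  # 3'UTR too short for inner placement: use middle
                site = (u3.start + u3.end) // 2
            else:
                site = int(rng.integers(lo, hi))
            truth.recap_sites.append((gene, contig, site, strand))
            # G-run ending at the site, in transcript orientation
            g = min(cfg.g_rich_len, site + 1)
            if strand == "+":
                seq[site - g + 1:site + 1] = "G"
            else:
                seq[site:site + g] = "C"
        # canonical polyA hexamer ~25 nt upstream of the 3'UTR end
        if strand == "+":
            hx = u3.end - 25
            seq[hx:hx + 6] = list("AATAAA")
        else:
            hx = u3.start + 19
            seq[hx:hx + 6] = list("TTTATT")

    genome = {contig: "".join(seq)} if cfg.n_genes else {contig: "".join(seq)}
    return genome, AnnotationModel(transcripts), truth


# -------------------------------------------------------------------- CAGE

_PROM_JITTER = np.array([-2, -1, -1, 0, 0, 0, 0, 1, 1, 2])


def simulate_cage(cfg: SimConfig, ann: AnnotationModel, truth: GroundTruth
                  ) -> dict[tuple[str, str], TagTrack]:
    """Poisson 5'-tag tracks per sample x replicate.

    Promoter tags at the TSS (rate ``promoter_rate``, small positional
    jitter), recap tags exactly at the planted sites (rate ``recap_rate``),
    and a homogeneous background of ``noise_rate`` tags/kb painted
    uniformly along each gene. Promoter and recap rates are modulated by a
    per-gene lognormal expression multiplier (sd ``expression_sd`` in log
    space) shared by all samples and replicates -- one rate field, many
    Poisson draws -- emulating the dynamic range of real libraries.
    """
    recap_by_gene = {g: (c, p, s) for g, c, p, s in truth.recap_sites}
    expr = _rng(cfg, 7).lognormal(0.0, cfg.expression_sd,
                                  size=len(ann.transcripts))
    tracks: dict[tuple[str, str], TagTrack] = {}
    for si in range(cfg.n_samples):
        for ri in range(cfg.n_replicates):
            sample, rep = f"sample{si + 1}", f"rep{ri + 1}"
            rng = _rng(cfg, 1, si, ri)
            track = TagTrack(sample=sample, replicate=rep)
            for gi, t in enumerate(ann.transcripts):
                tss = t.tss()
                n = rng.poisson(cfg.promoter_rate * expr[gi])
                if n:
                    for j in rng.choice(_PROM_JITTER, size=n):
                        track.add(t.contig, max(0, tss.pos + int(j) * orient(t.strand)),
                                  t.strand)
                if t.gene in recap_by_gene:
                    contig, p, s = recap_by_gene[t.gene]
                    n = rng.poisson(cfg.recap_rate * expr[gi])
                    if n:
                        track.add(contig, p, s, int(n))
                span = t.end - t.start
                nbg = rng.poisson(cfg.noise_rate * span / 1000.0)
                for p in rng.integers(t.start, t.end, size=nbg):
                    track.add(t.contig, int(p), t.strand)
            tracks[(sample, rep)] = track
    return tracks


# -------------------------------------------------------------- crosslinks

def rbp_names(cfg: SimConfig) -> list[str]:
    others = [f"RBP{i:02d}" for i in range(1, cfg.n_rbps)]
    return [cfg.enriched_rbp] + others


def simulate_crosslinks(cfg: SimConfig, ann: AnnotationModel, truth: GroundTruth
                        ) -> dict[str, TagTrack]:
    """Per-RBP crosslink tracks: common uniform background for every RBP,
    plus recap-site-proximal crosslinks for the enriched RBP at offsets
    drawn from ``rbp_offsets`` (transcript orientation, upstream negative)."""
    mean, sd = cfg.rbp_offsets
    tracks: dict[str, TagTrack] = {}
    for k, rbp in enumerate(rbp_names(cfg)):
        rng = _rng(cfg, 2, k)
        track = TagTrack(sample=rbp)
        for t in ann.transcripts:
            n = rng.poisson(cfg.rbp_background_per_gene)
            for p in rng.integers(t.start, t.end, size=n):
                track.add(t.contig, int(p), t.strand)
        if rbp == cfg.enriched_rbp:
            for _, contig, pos, strand in truth.recap_sites:
                n = rng.poisson(cfg.rbp_site_rate)
                offs = np.rint(rng.normal(mean, sd, size=n)).astype(int)
                for o in offs:
                    p = pos + int(o) * orient(strand)
                    if p >= 0:
                        track.add(contig, p, strand)
        tracks[rbp] = track
    return tracks


# -------------------------------------------------------------- fragments

def simulate_fragments(cfg: SimConfig, ann: AnnotationModel, truth: GroundTruth
                       ) -> pd.DataFrame:
    """RNA-seq-like fragment intervals (BED6 columns; name = replicate).

    In recap genes a fraction ``frac_frag_at_recap`` of fragments are the
    upstream cleavage product: their transcript 3' end abuts the recap site
    (half-open end == site position on '+', start == site + 1 on '-')."""
    recap_by_gene = {g: p for g, _, p, _ in truth.recap_sites}
    mean, sd = cfg.frag_len
    rows = []
    for ri in range(cfg.n_replicates):
        rng = _rng(cfg, 3, ri)
        rep = f"rep{ri + 1}"
        for t in ann.transcripts:
            n = rng.poisson(cfg.frags_per_gene)
            for _ in range(n):
                flen = max(30, int(rng.normal(mean, sd)))
                at_recap = (t.gene in recap_by_gene
                            and rng.random() < cfg.frac_frag_at_recap)
                if at_recap:
                    site = recap_by_gene[t.gene]
                    if t.strand == "+":
                        end = site
                        start = max(t.start, end - flen)
                    else:
                        start = site + 1
                        end = min(t.end, start + flen)
                else:
                    start = int(rng.integers(t.start, max(t.start + 1, t.end - flen)))
                    end = min(t.end, start + flen)
                if end > start:
                    rows.append((t.contig, start, end, rep, 0, t.strand))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name", "score", "strand"])


# ------------------------------------------------------------ conservation

def simulate_conservation(cfg: SimConfig, ann: AnnotationModel, truth: GroundTruth,
                          elevated_span: int = 150, elevation: float = 0.3,
                          baseline: float = 0.3) -> dict[str, dict[int, float]]:
    """Per-base conservation scores over gene bodies: noisy baseline,
    elevated for ``elevated_span`` nt immediately downstream of each recap
    site (the body of the 3'UTR-derived RNA)."""
    rng = _rng(cfg, 4)
    scores: dict[str, dict[int, float]] = {}
    for t in ann.transcripts:
        d = scores.setdefault(t.contig, {})
        vals = np.clip(rng.normal(baseline, 0.05, size=t.end - t.start), 0.0, 1.0)
        for p, v in zip(range(t.start, t.end), vals):
            d[p] = round(float(v), 4)
    for _, contig, pos, strand in truth.recap_sites:
        d = scores[contig]
        step = orient(strand)
        for k in range(1, elevated_span + 1):
            p = pos + k * step
            if p in d:
                d[p] = round(min(1.0, d[p] + elevation), 4)
    return scores


# ------------------------------------------------------------------- siRNA

def simulate_sirna(cfg: SimConfig, ann: AnnotationModel, truth: GroundTruth,
                   target_len: int = 21
                   ) -> tuple[pd.DataFrame, dict[tuple[str, str], TagTrack]]:
    """siRNA-knockdown CAGE experiments.

    Returns (targets BED6 DataFrame, tracks keyed by (target_name, rep)).
    Cleavage-derived 5' tags appear exactly at the target midpoint in the
    first ``sirna_replicates_with_signal`` replicates; all replicates carry
    uniform background along the gene.
    """
    rng = _rng(cfg, 5)
    genes = ann.transcripts[:cfg.sirna_targets]
    rows = []
    tracks: dict[tuple[str, str], TagTrack] = {}
    truth.sirna_cleavage_positions.clear()
    for t in genes:
        cds = t.region_segments("CDS")[0]
        start = int(rng.integers(cds.start, cds.end - target_len))
        mid = start + target_len // 2
        name = f"si_{t.gene}"
        rows.append((t.contig, start, start + target_len, name, 0, t.strand))
        truth.sirna_cleavage_positions.append((name, t.contig, mid, t.strand))
        for ri in range(cfg.sirna_replicates):
            rep_rng = _rng(cfg, 5, ri, genes.index(t))
            track = TagTrack(sample=name, replicate=f"rep{ri + 1}")
            if ri < cfg.sirna_replicates_with_signal:
                n = max(1, rep_rng.poisson(cfg.sirna_rate))
                track.add(t.contig, mid, t.strand, int(n))
            nbg = rep_rng.poisson(cfg.noise_rate * (t.end - t.start) / 1000.0)
            for p in rep_rng.integers(t.start, t.end, size=nbg):
                track.add(t.contig, int(p), t.strand)
            tracks[(name, f"rep{ri + 1}")] = track
    targets = pd.DataFrame(rows, columns=["contig", "start", "end", "name", "score", "strand"])
    return targets, tracks


# -------------------------------------------------------------------- FISH

def simulate_fish(cfg: SimConfig, truth: GroundTruth,
                  genes: Sequence[str] | None = None,
                  n_replicates: int = 2, fields_per_replicate: int = 3
                  ) -> pd.DataFrame:
    """Two-channel FISH spot tables with a planted cleaved fraction.

    Each cell holds ``fish_spots_per_cell`` transcripts; every transcript
    produces one upstream and one downstream spot. Intact transcripts put
    the two spots at the same location up to Gaussian jitter
    (``fish_jitter_sd`` px per channel); cleaved transcripts (probability =
    the gene's cleaved fraction) place the downstream spot at an
    independent uniform position in the cell, so the expected independent
    downstream fraction equals the planted fraction.
    """
    if genes is None:
        recap_genes = [g for g, _, _, _ in truth.recap_sites][:2]
        genes = recap_genes + ["control"]
    fracs = {g: truth.cleaved_fraction_per_gene.get(
        g, 0.0 if g == "control" else cfg.fish_cleaved_frac) for g in genes}
    truth.cleaved_fraction_per_gene.update(fracs)

    cells_per_field = max(1, math.ceil(cfg.fish_n_cells / (n_replicates * fields_per_replicate)))
    grid = math.ceil(math.sqrt(cells_per_field))
    size = cfg.fish_cell_size
    rows = []
    for gi, gene in enumerate(genes):
        rng = _rng(cfg, 6, gi)
        f = fracs[gene]
        for ri in range(n_replicates):
            for fi in range(fields_per_replicate):
                image = f"{gene}_r{ri + 1}_f{fi + 1}"
                for ci in range(cells_per_field):
                    ox = (ci % grid) * size
                    oy = (ci // grid) * size
                    cell = f"cell{ci + 1}"
                    for _ in range(cfg.fish_spots_per_cell):
                        ux, uy = rng.uniform(0, size, size=2)
                        if rng.random() < f:
                            dx, dy = rng.uniform(0, size, size=2)
                        else:
                            dx, dy = ux, uy
                        jux, juy = rng.normal(0, cfg.fish_jitter_sd, size=2)
                        jdx, jdy = rng.normal(0, cfg.fish_jitter_sd, size=2)
                        bu, bd = rng.lognormal(0.0, 0.5, size=2)
                        rows.append((image, f"rep{ri + 1}", cell, "upstream",
                                     ox + ux + jux, oy + uy + juy, bu))
                        rows.append((image, f"rep{ri + 1}", cell, "downstream",
                                     ox + dx + jdx, oy + dy + jdy, bd))
    df = pd.DataFrame(rows, columns=["image", "replicate", "cell", "channel",
                                     "x_px", "y_px", "brightness"])
    df[["x_px", "y_px"]] = df[["x_px", "y_px"]].clip(lower=0.0).round(3)
    df["brightness"] = df["brightness"].round(4)
    df.insert(0, "gene", df["image"].str.rsplit("_", n=2).str[0])
    return df
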