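# recapmap

Genome-wide detection and characterisation of **capped 3′UTR-derived RNAs**
from CAGE 5′-end data.

CAGE (cap analysis of gene expression) sequences the 5′ ends of capped
transcripts, so most signal marks transcription start sites — yet a
reproducible ~10–15% of 5′ tags falls inside 3′UTRs, far from any promoter.
These tags mark capped RNA species generated *post-transcriptionally*:
an mRNA is cleaved in the cytoplasm and the newly exposed downstream 5′ end
re-acquires an m⁷G cap ("recapping"). `recapmap` packages the computational
machinery needed to find and characterise these events:

* **Tag clustering** — reproducibility-filtered window clustering
  (gap ≤ 20 nt, ≥ 2 tags from each of ≥ 2 replicates) and density-stability
  clustering: for tag sites with counts, the density of an interval is
  Σcounts / (last − first position), and a reported cluster is an interval
  that, for some density threshold *d*, is maximal among intervals whose
  every anchored prefix and suffix has density ≥ *d*. Clusters carry the
  thresholds at which they form and break (min/max density), are filtered
  (total ≥ 5, length ≤ 200 nt, density ratio ≥ 2, non-nested, single-nt
  peaks re-added), and the position of maximal pooled count is the
  **dominant peak**.
* **RNA-maps** — per-anchor-normalised signal density as a function of the
  offset from anchor positions (crosslink sites, RNA-seq fragment
  starts/ends, conservation scores), with randomised-control anchors,
  log₂ ratio-to-window-mean heatmaps, and siRNA cleavage-capping detection
  (CAGE signal inside the target interval in ≥ 2 replicates).
* **RBP enrichment ranking** — per-gene permutation-FDR crosslink peak
  calling (3-nt windows against uniform shuffles), union-merged binding
  sites split to ≤ 50 nt, and per-RBP scores
  Σ log₂((c + 1)/(max c + 1)) over sites near 3′UTR CAGE peaks.
* **Sequence & structure features** — sequence logos (PFMs), polyA-hexamer
  and GGG offset profiles, G4Hunter G-quadruplex scoring (G-runs score
  +min(run, 4) per base, C-runs the negative, 25-nt window means,
  threshold 1.2), base-pairing probability profiles from a McCaskill-style
  partition function (uniform pair weight e, minimum hairpin loop 3), and
  miRNA complementarity / seed-match scanning.
* **smFISH colocalisation** — brightness top-half filtering, 3-px
  nearest-neighbour colocalisation between upstream/downstream probe
  channels, independent-signal fractions per replicate, pairwise Welch
  *t*-tests with Benjamini–Hochberg correction.
* **Synthetic data** — a seeded generator that plants every signal the
  pipeline detects (promoter + intra-3′UTR capping-site tag clusters with a
  G-run at the site, upstream-shifted crosslinks for one enriched RBP,
  fragment 3′ ends abutting the sites, downstream-elevated conservation,
  siRNA cleavage tags at target midpoints, FISH spot tables with a planted
  cleaved fraction), so every stage is testable offline against ground
  truth.

## Worked example

Run the full synthetic study (40 genes, half with a planted 3′UTR capping
site) and inspect the run report:

```python
from recapmap.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(outdir="demo", seed=1,
                                sim={"n_genes": 40}, rbp_n_perm=50))
for stage in ("cluster", "profile", "rbp", "sirna"):
    print(stage, report["stages"][stage])
```

prints (abridged):

```
cluster  n_retained=60  n_3utr_peaks=20  recap_recall=1.0
         region_proportions={'5UTR': 0.752, 'CDS': 0.016, 'intron': 0.010, '3UTR': 0.222}
profile  rbp_profile_peak_offset=-11  readend_peak_offset=0
rbp      enriched_rbp='UPF1'  enriched_rank=1
sirna    n_detected=5  dominant_offsets=[10, 10, 10, 10, 10]
```

Read: every planted capping site was recovered by a retained 3′UTR cluster
whose dominant peak is exact (`recap_recall=1.0`); ~22% of 5′ tags fall in
3′UTRs under these simulation settings; the enriched RBP's crosslinks peak
11 nt *upstream* of the capping sites and it ranks first of 10 RBPs;
RNA-seq fragment 3′ ends pile up exactly at the sites (offset 0); and all
five siRNA targets show capped 5′ ends at the target midpoint (offset 10 of
a 21-nt target). The same stages are available from the shell:

```bash
recapmap simulate --seed 1 --n-genes 40 --outdir demo_sim
recapmap cluster --method paraclu \
    --in demo_sim/cage_sample1_rep1_plus.bedgraph:+ \
    --in demo_sim/cage_sample1_rep2_plus.bedgraph:+ \
    --ann demo_sim/annotation.bed --out clusters.bed
recapmap run --config run.yaml     # full pipeline from a flat YAML config
```

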