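# Methods

This note documents the models implemented in `recapmap`, the parameter
defaults and why they were chosen, what the synthetic data generator does
and does not emulate, and the numerical conventions that keep results
reproducible.

## Coordinates and orientation

Everything in memory is 0-based half-open (BED convention); conversion
happens only at file boundaries. Single-nucleotide features (5′-tag
positions, crosslink sites, dominant peaks) are width-1 intervals.
"Upstream"/"downstream" and all profile offsets are in *transcript*
orientation: negative offsets are 5′ of the anchor on the anchor's own
strand. Fragment 3′ ends use the half-open convention — the end coordinate
is one past the last covered nucleotide in transcript orientation — so a
fragment abutting a capping site registers at offset 0.

## Tag clustering

**Window clustering.** Tag positions on one strand whose inter-position gap
is ≤ 20 nt (measured between width-1 intervals, i.e. positions 100 and 121
merge) are merged transitively. A cluster is retained when at least two
replicates each contribute ≥ 2 tags inside it; both thresholds are
configurable. With the standard two-replicate design this equals requiring
support from every replicate.

**Density-stability clustering.** For sorted tag sites with counts, the
density of a multi-site interval is total count / (last − first position);
single positions are infinitely dense. For an interval *I*, let *U(I)* be
the minimum density over all anchored prefixes and suffixes of *I*
(including *I* itself) — the threshold at which *I* stops qualifying — and
*M(I)* the maximum *U* over all strict superintervals (0 for the outermost
interval) — the threshold at which *I* becomes maximal. The emitted
hierarchy is exactly the set { *I* : *U(I)* > *M(I)* }, each cluster
carrying `min_density = M` and `max_density = U`. This is computed with an
O(n²) dynamic programme per contig/strand (running prefix/suffix minima,
then a decreasing-span sweep for *M*); a brute-force enumeration oracle in
the test suite pins the semantics exactly for all instances of ≤ 12 sites.
The quadratic cost is acceptable at the tag densities this pipeline sees
(thousands of distinct positions per contig/strand); extremely dense
genome-wide tracks would need pre-splitting.

**Post-filter.** In order: drop clusters with total < 5; drop the
hierarchy's single-position members; drop clusters whose inclusive length
(last − first position) exceeds 200 nt; drop clusters with
max_density/min_density < 2 (the outermost cluster, min_density 0, is
treated as ratio ∞); re-add single positions with ≥ 5 tags as standalone
clusters; finally remove any cluster contained in a retained larger one, so
the retained set is mutually non-nested. The single-position drop/re-add
pair mirrors the two-stage convention of the clustering tool this pipeline
reimplements; both steps are flag-controlled.

**Dominant peak.** The position of maximal pooled count within a cluster;
ties break to the 5′-most position in transcript orientation, a
deterministic and orientation-consistent rule.

**Region labels.** A position overlapping segments of several transcripts
is resolved with precedence 5UTR > 3UTR > CDS > intron; no overlap →
intergenic. *Inner* 3′UTR peaks keep ≥ 150 nt to both the CDS-side and the
termination-side 3′UTR boundary (inclusive at 150), avoiding boundary
effects in conservation profiles.

**Size factors.** Median-of-ratios library normalisation: for clusters
with nonzero counts in every sample, each count is divided by the
cluster's geometric mean across samples and the per-sample factor is
exp(median(log ratios)) — the median taken in log space, matching the
DESeq2 convention (verified against pydeseq2 in the test suite). Replicate
correlations are Pearson on log2(1 + count) by default; the transform is
recorded in the result metadata.

## RNA-maps (metaprofiles)

`density[o] = (Σ_anchors count at anchor + o·orientation) / n_anchors`,
optionally smoothed with a 5-nt centred rolling mean (figure smoothing
widths are rarely published; 5 nt is narrow enough not to displace a
±20 nt feature). The smoother conserves the curve sum by spreading each
bin's mass over its own boundary-clipped window rather than averaging over
clipped windows, which would leak mass at the edges; bins further than one
window from an edge equal the plain rolling mean. Unsmoothed, the curve
sums to (total in-window signal)/n_anchors by construction.

Controls: `same_region` redraws each anchor uniformly within its own
3′UTR; `window150` within ±150 nt of the anchor; both seeded.

Heatmaps: rows are the top-N anchors by total signal within ±200 nt;
values are log₂((c + 1)/mean(c + 1)) with the mean over the same ±200-nt
span and a +1 pseudocount (the source material is silent on zeros; the
pseudocount's effect vanishes as counts grow), reported for the central
±100 nt.

siRNA cleavage-capping detection: a target is *detected* when ≥ 2
replicates place ≥ 1 CAGE 5′ tag inside the (21-nt) target interval
itself — the strictest reading of "the exact position targeted" — and the
dominant offset is the pooled-maximum position relative to the target 5′
end in transcript orientation. Long-read start classification: TSS if
within ±50 nt of a TSS anchor, else UTR if within ±50 nt of a 3′UTR CAGE
anchor, else OTHER; TSS takes precedence when both match (window and
precedence were design choices; both are parameters).

## RBP enrichment

Crosslink peak calling is a per-gene permutation test: the gene's
crosslinks are re-drawn uniformly within the gene n_perm times (default
100), windowed counts use a centred 3-nt window, and the significance
threshold is the smallest count *x* whose empirical FDR — mean permuted
windows ≥ *x* divided by observed windows ≥ *x* — is ≤ 0.05. Genes with
fewer than two crosslinks are skipped. This reproduces the *behaviour* of
the published FDR peak caller, not its internals bit-for-bit.

Significant windows from all RBPs are union-merged; merged regions of
length L are split into ⌈L/50⌉ near-equal pieces (sizes differ ≤ 1 nt),
conserving per-RBP counts. Each RBP is scored over sites whose centre lies
within ±100 nt of a 3′UTR CAGE peak:
`score = Σ_sites log₂((c_rbp + 1)/(max_RBP c + 1))`. The dominant RBP
contributes 0 per site and every other RBP a negative term, so the summed
score ranks RBPs by how consistently they dominate peak-proximal sites.
The published description ("sum of log2 ratios of crosslink enrichments")
does not pin a formula; this per-site ratio-to-max with pseudocount 1 is
our concrete reading, isolated in one function so alternatives can be
plugged in. Whether input/mock controls should enter the ratio is likewise
unspecified; they do not, here.

## Sequence and structure features

**G4Hunter.** Each base in a G-run of length L scores +min(L, 4), in a
C-run −min(L, 4), otherwise 0; windowed scores are 25-nt sliding means and
hits are maximal regions of overlapping windows with |mean| ≥ 1.2 (sign
flags the minus-strand motif). Scores are antisymmetric under
complementation by construction.

**Pairing probabilities.** A McCaskill-style partition function over all
nested secondary structures with canonical pairs {AU, GC, GU} (DNA
alphabet after U→T), minimum hairpin loop 3, and a uniform Boltzmann
factor e per pair (energy −1 at kT = 1). Inside weights Z(i,j) follow the
standard "first base unpaired or paired to k" recursion; outside weights
X(i,j) condition on the innermost enclosing pair; P(i,j) =
w·Z(i+1,j−1)·X(i,j)/Z. The uniform-weight model was chosen over a full
nearest-neighbour thermodynamic model because it is self-contained and
exactly verifiable against structure enumeration (the suite checks all
sequences ≤ 12 nt to 10⁻⁹), while preserving the qualitative claim the
profile supports — G/C-rich contexts pair more. A hook accepts externally
computed probability vectors for users who want the full thermodynamic
model. Probabilities (not MFE pair indicators) are reported; profiles use
75-nt windows centred on anchors with the central 50 nt reported.

**miRNA matching.** Complementarity scanning reports every ungapped
full-length alignment of a miRNA's reverse complement with ≤ 1 mismatch
("fewer than 2" read strictly; the threshold is a parameter). Expressed
miRNAs require strictly more than 10 reads in ≥ 2 replicates; the seed is
miRNA positions 2–8 and seed-site occurrences are counted per start offset
within ±30 nt of the anchors.

**polyA profiles.** Canonical A[A/U]UAAA hexamer occurrences increment
every offset they cover (coverage per nucleotide); GGG profiles increment
the start offset only.

## FISH colocalisation

Spots arrive cell-assigned with z-projected 2-D pixel coordinates. Within
each channel × image group only the top half by brightness is *scored*
(≥ the group median; ties kept), suppressing dim false positives, but
nearest-neighbour candidates come from the opposite channel's full
pre-filter set — the filter restricts which spots are scored, not which
can witness colocalisation (both behaviours are flag-controlled; the
source description is ambiguous). A scored spot is independent when its
nearest opposite-channel neighbour in the same image is > 3 px away.
Fractions pool all fields of a replicate; Welch t-tests compare
per-replicate fractions for every gene pair per channel (all pairs, with
the control contrast flagged) and Benjamini–Hochberg adjustment runs over
the whole table.

## Synthetic data generator

The generator emulates the *structure* of the real signals: localised
promoter tag clusters (Poisson rate 50/replicate with ±2 nt jitter);
planted intra-3′UTR capping sites ≥ 160 nt from both 3′UTR boundaries,
carrying exact-position tag clusters (rate 20/replicate) and an 8-nt G-run
ending at the site; homogeneous "exon painting" background (1 tag/kb); a
per-gene lognormal expression field (log-sd 0.75) shared by all replicates
so replicate correlations reflect a common rate field, as in real
libraries; one RBP with crosslinks at recap + N(−10, 5²) nt against a
uniform background common to all 10 RBPs; RNA-seq fragments half of which
(in recap genes) end exactly at the site; conservation elevated for 150 nt
downstream of sites; siRNA cleavage tags at 21-nt target midpoints in a
configurable subset of 3 replicates; and FISH cells in which each
transcript yields an upstream and a downstream spot, colocalised up to
0.5 px Gaussian jitter per channel unless cleaved (probability =
`fish_cleaved_frac`), in which case the downstream spot is placed
independently and uniformly in the 200×200 px cell.

Everything derives from one seed through named `SeedSequence` sub-streams
(genome 0, CAGE 1, crosslinks 2, fragments 3, conservation 4, siRNA 5,
FISH 6, expression field 7), so identical configs reproduce byte-identical
files and regenerating one artifact never perturbs another.

**What it does not emulate** — and hence what passing tests do not show
about real data: mapping artefacts and multimappers, sequencing errors,
promoter shape diversity, alternative polyadenylation, overlapping genes
and antisense transcription, RBP binding-site sequence specificity beyond
position, chromatin-level signals, and optical artefacts beyond a
brightness-independent dim-spot population. Recovery rates measured here
are upper bounds for equivalently parameterised real data.

## Problem sizes and numerics

Default verification sizes: 100 genes (≈ 315-kb genome) for recovery
checks; 500 random instances (≤ 12 sites) for the clustering oracle; 200
random sequences (≤ 12 nt) for the folding oracle; 100 seeds × 20 genes ×
10 RBPs for ranking recovery; 200 cells per planted FISH fraction. These
sizes give comfortable statistical margins for every threshold tested
(binomial s.e. ≤ 0.035 for the FISH fractions, ≥ 10⁴ tags behind each
recall estimate) while a full test run stays in the tens of seconds.
Degenerate inputs are defined rather than special-cased: empty tracks
cluster to empty lists, a single tag site is an infinitely dense cluster,
zero anchors raise errors, missing FISH channels flag all scored spots
independent. Ties are always broken deterministically (5′-most dominant
positions, alphabetical RBP ranking).

## Known limitations

The density-stability DP is quadratic in distinct tag positions per
contig/strand; the partition function is cubic-to-quartic in window length
(fine at the 75-nt analysis window, not meant for kilobase folds). The
permutation FDR uses a uniform within-gene null, ignoring sequence
composition biases of crosslinking. FISH distances are 2-D on z-projected
coordinates, as in the imaging protocol this mirrors; true 3-D
colocalisation would need the z-stack. Real-data ingestion expects
pre-aligned, pre-quantified tracks (BEDgraph/BED/TSV); alignment and spot
detection are upstream of this package.
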