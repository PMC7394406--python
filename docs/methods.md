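# Methods

## Coordinates and construct geometry

All internal coordinates are 0-based half-open on the forward genomic
strand, matching the rMATS `exonStart_0base` convention; GTF I/O converts
to/from 1-based inclusive. Transcript exon lists are ordered 5′→3′ in
transcript orientation. An E-I-E-I-E construct is three consecutive exons
plus the two intervening introns; its parts are stored as genomic
intervals keyed by transcript-orientation role (`exon_up` … `exon_down`),
so on the minus strand `exon_up` is the genomically rightmost part.
Sequence extraction reverse-complements each part on the minus strand; the
concatenation of part sequences always equals the strand-corrected span
substring (this symmetry is property-tested against a mirrored genome).

rMATS flanking-exon columns (`upstreamES/EE`, `downstreamES/EE`) are read
as genomic (upstream = leftmost); roles are reassigned from the strand when
the construct is built. Events with a zero-length gap between exons are
rejected.

## Reference transcripts and controls

The reference transcript of a gene is the longest protein-coding
transcript that carries a transcript support level (TSL). "Has a TSL" means
the attribute is present and not "NA"; any level 1–5 qualifies, with an
optional `max_tsl` cut-off for stricter policies. "Longest" is spliced
(exonic) length, configurable to genomic span; ties break to the
lexicographically smallest transcript ID for determinism.

Internal controls: the candidate pool is every 3-exon window of the
reference transcript whose genomic span intersects no event construct span
of the gene (an exon-only overlap test is available); one member is drawn
uniformly. Genes whose pool is empty — typical for low exon counts when the
event window covers most of the transcript — contribute nothing, and the
count is reported. Internal controls are grouped by the direction
(more/less skipped) of their gene's events, so each direction set is
compared against controls from its own genes; pooling them instead is a
one-line change and does not alter the planted-effect results.

External controls: genes are ranked by mean abundance across all samples
(median/max configurable), excluding mitochondrial contigs (by contig name,
default {chrM, MT}), genes present in any of the five filtered event sets
(gene identity = gene_id with any ".version" suffix stripped), and genes
without a transcript whose (ID, version) matches the curated set. Fewer
eligible genes than requested is a hard error unless explicitly allowed.

All sampling uses per-gene random streams: the global seed is mixed with a
CRC32 hash of the gene ID (never Python's salted `hash`), so results are
identical across platforms and independent of gene processing order.

## Feature definitions

| feature | definition |
| --- | --- |
| part lengths (5) | interval lengths, nt |
| GC content (3) | (G+C)/(A+C+G+T) of central exon and both introns; ambiguity codes excluded from numerator and denominator; all-ambiguous → absent |
| BPS-3′SS distance (2) | 1-based offset of the called branch adenosine from the intron's 3′ end |
| splice-site strength (4) | additive log-odds of the 9-mer donor (last 3 exonic + first 6 intronic nt) or 23-mer acceptor (last 20 intronic + first 3 exonic nt) |

Splice-site scoring is a pluggable position-weight interface. The shipped
default is a first-order log-odds table (log2 of position frequency over a
uniform 0.25 background, pseudocount 1) trained on every annotated
donor/acceptor window of the loaded annotation. This is deliberately not a
maximum-entropy model: those tables are external artifacts, and every
downstream statistic depends only on the rank ordering of scores, which a
first-order table preserves for the planted strong/weak classes (asserted
by test). Any table with the same shape can be dropped in. Non-canonical
(non-GT/AG) boundaries are scored, not rejected. Windows containing
ambiguity codes, or truncated by short parts, yield absent values.

Branch points: every adenosine whose distance d from the intron's 3′ end
satisfies 15 ≤ d ≤ 500 is scored over the heptamer (5 nt upstream, the A,
1 nt downstream; the branch A is heptamer position 6); the argmax is
reported with ties resolved toward the 3′SS, and no candidate → absent.
The default model is a sharp consensus table around a TACTAAC-like box
(consensus probability 0.85 per position). This replaces an SVM-based
caller whose model is not reconstructible; the measured quantity — the
BPS-3′SS distance — is preserved exactly on synthetic data where the truth
is planted, which is the property the statistics need.

## Statistics

Each feature × contrast cell is a two-sided Mann–Whitney U test: exact
enumeration when both samples have ≤ 8 observations and the pooled data are
tie-free, otherwise the normal approximation with tie correction and
continuity correction (via `scipy.stats.mannwhitneyu`; the test suite
checks the exact path against full rank-assignment enumeration for all
n, m ≤ 7). Direction words come from comparing medians — Shorter/Longer for
lengths and distances, Lower/Higher for GC, Weaker/Stronger for scores —
and a cell is NS when p ≥ α (default 0.05) or the medians are equal. Stars
follow the strict ladder * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001.
No multiple-testing correction is applied to the starred grid (it reports
raw p, as the source analysis does); Benjamini–Hochberg q-values are
emitted alongside in the long-format table. Whether to use one-sided tests
was considered and rejected: the direction is read off the medians, and the
two-sided p keeps the grid symmetric under swapping event and control sets
(property-tested).

## Expression summaries

DEG direction: rows with adjusted p < α split by the sign of log2 fold
change (zero log2FC counts in neither direction); percentages are of the
significant total, rounded to the nearest integer. A `use_raw_p` switch
covers tables where the significance column is a raw p.

qPCR: fold = 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference) within a sample
and ΔΔCt = ΔCt(test) − ΔCt(calibrator). Invariance to a common cycle shift
is property-tested.

EMT score: per sample group, the number of mesenchymal panel genes whose
group-mean abundance strictly exceeds that gene's all-sample median, minus
the same count for epithelial genes — an integer in [−|E|, +|M|], ties
count as not exceeding. The published scoring scheme this mirrors is not
specified to reproducible detail, so the scheme is a pluggable callable;
the default reproduces the qualitative contract (integer score, negative =
epithelial) and the published values are *not* claimed reproducible by it.
Default panels: epithelial {CDH1, DSP, OCLN, ESRP1}, mesenchymal {CDH2,
VIM, FOXC2, ZEB1, SOX10}; DSP denotes desmoplakin.

## The synthetic generator

`skipfeat.simulate` emulates the complete input bundle. Per gene: 5–9 exons
(lognormal lengths, median 150 nt exons / 1000 nt introns, floors 30/120
nt), alternating strands, four nuclear contigs plus a mitochondrial contig.
Each junction carries a donor/acceptor motif sampled around the canonical
consensus (GT/AG invariant; consensus probability 0.85 for "strong"
junctions, flattened for "weak" ones — the strength shift parameter maps
each table unit to a 2^−0.25 factor on the consensus probability, floored
at uniform). Each intron carries the exact branch consensus heptamer at a
planted offset (background 22–45 nt, kept clear of the 20-nt acceptor
window); other exact occurrences inside the search window are scrubbed by
mutating their branch A, so the planted adenosine is the unique top-scoring
candidate and planted offsets are exactly recoverable — an idealization
that makes the BPS-3′SS feature noise-free on synthetic data.

Event genes get one planted 3-exon window: central exon length ×0.5,
flanking introns ×3, branch offsets ×2, weak central donor/acceptor, and
an optional GC shift (0 by default). Event SE rows reuse the real window
coordinates of the gene's transcript, so the internal-control non-overlap
constraint is non-trivially exercised. p and FDR are sampled (< 0.05 for
planted rows, ≥ 0.05 for background, including rows that pass p but fail
FDR), never computed from counts — the pipeline consumes, and must not
re-derive, upstream statistics. Small A3SS/A5SS/MXE/RI tables mark decoy
genes significant, and mitochondrial, MANE-less and event genes are given
the highest expression baselines so each external-control filter excludes
at least one top-ranked gene. The DEG plan (default 346 up / 835 down /
2000 null, the scale of the source iPSC contrast) is realized exactly in
the DEG table; when the plan exceeds the simulated gene count the table is
padded with synthetic filler IDs, since the direction summary is a pure
table computation. Marker-panel genes get epithelial-high profiles in the
patient group and mesenchymal-high in controls; qPCR records plant ΔΔCt =
+2 (fold 0.25) and −1 (fold 2) targets against a stable reference.

What the generator does **not** emulate: read-level noise (no FASTQ/BAM),
codon or splicing-regulatory element structure, correlated features (each
feature is planted independently), inter-gene expression correlation, and
realistic branch-point degeneracy (one exact consensus per intron). Passing
the recovery suite therefore shows the pipeline's bookkeeping and
statistics are correct under known truth — not that the default scoring
models match any particular organism's splicing code.

## Problem sizes and numerical choices

The shipped study conditions: 340 nuclear genes with 200 event genes
(planted-effect recovery, 20 seeds, 100 external controls), 130 genes with
50 event genes and all effects off (null calibration, 50 seeds, 40 external
controls), and 2160 genes (external-control contract at the full n = 2000).
Recovery requires the complete 7-feature × 4-contrast planted pattern at
p < 0.0001; null calibration requires the significant-cell fraction of the
full grid in [0.01, 0.12]. Oracle suites compare the branch-point caller
(1000 random introns), internal-control pools (500 random geometries) and
exact Mann–Whitney p-values (all n, m ≤ 7) against brute-force
enumerations kept free of package code.

Degenerate inputs are handled as: empty sequence → error for GC; absent
feature values dropped per cell with sample sizes reported; a cell with an
entirely absent side is marked "insufficient data"; an empty significant
DEG set returns zeros with a warning. Known limitations: no effect-size or
covariate modelling in the comparisons; the GC features on synthetic data
show a mild length-coupled shift (fixed-length boundary motifs are diluted
in longer introns), visible as occasional borderline GC cells in planted
runs but absent under the null, where lengths are exchangeable.
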