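# Methods

## Coordinates and strand conventions

All internal coordinates are 0-based, half-open, matching BED and
bedGraph. Strand-aware quantities are expressed as signed offsets along
the direction of transcription and converted to genomic intervals in
one place (`GeneAnnotation.offset_window`), so a window "[TSS−150,
TSS+150]" in the inclusive notation common in the literature is
normalised to the half-open transcription-space window [−150, +150) of
width 300; the one-base difference from a 301-base inclusive reading is
immaterial at these window sizes and the widths are configurable.
Minus-strand bedGraphs that store negated values are handled by a
reader flag (`negated_minus`, default off); values are always returned
as non-negative magnitudes. Queries on contigs a track has never seen
return zero with a logged warning rather than erroring, because
annotations and tracks routinely come from different sources.

## Pausing index

For a gene of length L the pause window is [−150, +150) around the
TSS and the body window [300, L−300), both in transcription space on
the sense strand of a 3′-end-mapped track; the pausing index is the
ratio of per-base densities. Genes shorter than 300 bp are excluded
(`too_short`); genes of 300–600 bp have no body window
(`empty_body_window`); genes with zero body reads are flagged
(`zero_body_reads`) and excluded from distributions rather than patched
with a pseudocount, which would manufacture arbitrary finite indexes.
Because indexes span orders of magnitude across species, species
summaries average log₁₀ PI and report the geometric mean; the
regression below uses mean log₁₀ PI as its response. RPM normalisation
(scale to 10⁶ total reads) cancels in the index — an invariance the
tests check to 1e−9 — but is applied in the pipeline so emitted tracks
are comparable across libraries.

## TSS refinement

Windows of 10 bp slide at step 1 (a step-10 tiling is available by
config) over ±500 bp around the annotated start of a 5′-end-mapped
track; the refined TSS is the strand-aware 5′-most base of the window
with the maximal read sum. "Sliding" is read as step < width because
that is what sliding windows mean; both behaviours are exposed. Ties
are broken by the window whose centre is nearest the original TSS,
then by the more upstream window — an invented but deterministic rule
chosen to minimise displacement. Genes whose search region holds fewer
than `min_reads` (default 1) reads keep their annotation and are
flagged. Only the TSS-side boundary moves; the TES is fixed. Note the
refined start is the *window* start, so even noiseless data shifts the
call a few bases upstream of a single-base peak; accuracy criteria are
therefore stated as "within 10 bases".

## Pause sites and motif enrichment

The pause site is the argmax of sense-strand 3′-end counts in
[TSS, TSS+100), ties to the 5′-most base, no call for empty windows.
"Strongest positioned" pause is quantified as peak_count/window_total
(1.0 = perfectly focused); the top ceil(n/4) genes by this score form
the quartile used for PWM construction. PWMs are column frequencies
with an additive pseudocount (default 0.25), N bases excluded per
column, scored as log₂ odds against a uniform background (genome-wide
frequencies can be supplied); scoring is sense-strand by default.

Enrichment at the pause is the mean best-match score of the 20 bp
pause-centred sequence minus the mean score of flanking DNA in
[−500, −100) and [100, 500) from the pause. Flanks are scored as the
mean of best-match scores over 20 bp tiles rather than one max over
the whole 400 bp window: the maximum of many alignment offsets grows
with window length, so a whole-window max would be biased above the
20 bp pause score on motif-free sequence, whereas tile means give the
same window-length statistics on both sides and an enrichment that is
zero-centred under the null (verified against simulation) and monotone
in the fraction of sites carrying a planted motif. The ±100 bp
exclusion keeps initiation-region sequence out of the flank estimate.
Published pause-motif matrices are inputs (plain-text 4×L files), not
hard-coded.

## Orthology

Presence of a query protein in a target proteome is decided by a
two-pass reciprocal search over a pluggable pairwise aligner; the
bundled aligner is Smith–Waterman (BLOSUM62, gap open 11, extend 1)
with Karlin–Altschul E-values, E = mn·2^(−S′), S′ = (λS − ln K)/ln 2,
using the standard gapped constants λ = 0.267, K = 0.041 and a per-pair
m·n search space with no database-length correction — at desk scale
this reproduces threshold behaviour deterministically. Both reciprocity
readings are implemented: lenient (any reciprocal hit below 10⁻⁶
confirms presence — the literal two-pass rule) and strict (the
candidate's best reciprocal hit must be the original query, classical
RBH). Lenient is the default; the two differ exactly on paralog-only
fixtures, which is itself a tested property.

## Cross-species statistics

The enrichment–pausing relationship is ordinary least squares of mean
log₁₀ pausing index on motif enrichment; p-values come from the t
statistic for a zero slope with n−2 degrees of freedom. No
phylogenetic correction is attempted (deliberately: the method under
study is a plain regression). Species are grouped by the number of
query subunits called present; group comparisons use a two-sided
Mann–Whitney U, computed exactly when n_a+n_b ≤ 12 without ties and by
the tie- and continuity-corrected normal approximation otherwise.

## Perturbation analysis

Samples are scaled by spike-in factors, factor_i = count_i /
mean(counts), signal divided by the factor so factors average to 1.
Fold-change tracks are per-base log₂((t+0.1)/(c+0.1)). Response
matrices tile [−upstream, downstream) from a per-gene anchor in
fixed-width bins ((1000+50000)/1000 = 51 columns at the defaults,
matching the reference-point heatmap geometry); bins past contig ends
are missing (NaN + mask) and are zero-imputed, flagged, for
clustering. Clustering is Lloyd's k-means, k = 3, best of 10 restarts,
deterministic under a seed, with labels renumbered by descending
pause-proximal response so cluster numbering is stable. The
heat-shock analysis classifies genes by differential results
(up/down at padj < 0.05), restricts to genes stable under depletion
alone (dtag padj ≥ 0.05), and compares conditions' log₂ fold changes
at up- and down-regulated genes separately by Mann–Whitney; gene-body
counts exclude the first 3 kb downstream of the TSS ([TSS+3000, TES],
no 3′ trim — a 3′ trim is a config option) so pause loss cannot
masquerade as a body-level change. The bundled differential engine
(spike-scaled counts, per-gene Mann–Whitney across replicates,
Benjamini–Hochberg) is a deliberately simple pluggable default; tables
from external engines can be substituted wherever (gene, log2fc, padj)
records are consumed.

## Synthetic data

The generator is this package's own stand-in for nascent-transcription
data; no generative model is claimed by the analyses themselves. Each
gene is a two-component occupancy mixture: a narrow pause footprint
(halfwidth 2, i.e. 5 bp) at an offset drawn uniformly from 30–60 bp
downstream of the TSS (configurable to 30–100 for dispersed
proto-pause scenarios) and a uniform body from the footprint end to the
TES. Reads are allocated multinomially — totals are exact, so depth
normalisation is exactly invertible in tests — with the 3′ track
recording sampled positions and the 5′ track recording the TSS plus
rounded Gaussian jitter (default sd 1 base; refinement must be
challenged but recoverable). The planted pausing index is defined as
the value the standard window estimator converges to; since the 300 bp
pause window also contains body signal, the generator calibrates the
footprint density accordingly (footprint density exceeds
PI × body density). Depletion courses multiply pause mass by a
per-archetype retention at 30 min and restore a fraction of the lost
mass at a configurable downstream shift at 60 min
(localized_recovery: retention 0.2, shift 0, recovery 0.9;
no_recovery: 0.15/–/0; downstream_recovery: 0.15/2000 bp/0.9). Library
totals scale with expected occupancy at constant spike-in counts,
emulating constant cell input — the situation spike-ins exist to
calibrate. Synthetic proteomes mutate query families to 60% identity
for orthologs; paralog-only entries are 85%-identity copies of a
different family that is itself a diverged (55% identity) duplicate of
the target family, so forward searches find the paralog but reciprocal
best hits do not return the query.

Not emulated: mappability and sequencing error, antisense and enhancer
transcription, initiation/elongation kinetics, nucleosome structure,
multi-isoform genes, and phylogenetic covariance among species.
Passing tests therefore demonstrate correctness of the estimators and
workflows under the stated occupancy model, not robustness to these
real-data complications.

## Problem sizes and numerical choices

Validation runs use sizes chosen to make sampling noise small relative
to the tested tolerances while keeping the full suite fast: 100 genes
per planted-index stratum at ~3000 reads/gene (body-window counts are
the precision bottleneck at high PI), 1000 genes at ~60 reads/gene for
TSS refinement, 500 sites × 100 replicates for null-enrichment
calibration, 300 genes at 2000 reads/gene for response clustering, and
10 species × 80 genes for the planted cross-species regression.
Floating-point invariances (RPM, spike scaling, PWM column sums) are
asserted at 1e−9 relative; exact assertions (read conservation,
bedGraph round trips, alignment scores vs a brute-force dynamic
program, Mann–Whitney vs full enumeration) are asserted with no
tolerance. K-means determinism comes from a fixed seed and explicit
restart count; cluster label order is fixed by the pause-proximal
response so outputs are byte-stable across reruns.
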