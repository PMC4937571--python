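# Methods

This note documents the models and procedures implemented in
`tp53cistrome`, the assumptions behind them, the parameters that matter,
and the choices made where the design was genuinely open.

## The measurement model

A barcoded enhancer-reporter screen couples each candidate region to one
or more random 17-nt barcodes; plasmid DNA counts measure a barcode's
abundance in the library, and cDNA counts in matched p53-high and
p53-off conditions measure its transcriptional output. The package
models counts as negative binomial, NB(mean m, dispersion α) with
variance m + αm², the standard over-dispersed model for sequencing
counts. Enhancer activity is treated as binary: a responsive region
multiplies its cDNA mean by a single `activity_fold` in the p53-high
condition only. A graded mode (log-normal jitter of the fold) exists but
is off by default, matching the observed on/off behaviour of
TP53-responsive elements.

## Reporter quantification

**Coupling.** A barcode is assigned to the region holding the majority
of its long-read support, retained only when total support ≥
`min_support` (default 3 reads) and majority fraction ≥ `purity`
(default 0.9). Chimeric couplings typically fail the purity filter and
are excluded rather than mis-assigned; chance barcode collisions are
recorded, never merged (4¹⁷ ≈ 1.7 × 10¹⁰ possible barcodes make them
negligible at library scale).

**Normalisation.** Counts receive pseudocount 1, are scaled to CPM of
the raw library size, and each cDNA CPM is divided by the unit's mean
plasmid CPM. A unit with zero plasmid counts everywhere is flagged
`low_coverage` and excluded.

**Composition offset.** CPM scaling is not composition-robust: when a
sizeable fraction of units is strongly induced, the p53-high library
total inflates and every raw log2FC shifts down by a common offset
(about −1.9 log₂ units at 40% positives with an 8-fold effect). The
caller therefore centres fold changes on the across-region median raw
log2FC — the unresponsive bulk — and tests against that offset
(`Thresholds.center_lfc`, default on). This assumes responsive regions
are a minority (< 50%); with a responsive majority the centring would
shrink true effects.

**Differential test.** Because NB counts share one dispersion, log-scale
noise is near-homoscedastic across regions. The default test
(`var_mode="pooled"`) is a two-sided t statistic whose variance is the
within-group residual variance pooled over *all* regions, with the
pooled degrees of freedom — a moderated test in the spirit of shrunken-
variance approaches used throughout genomics. This matters because most
regions carry one or two barcodes (barcodes per fragment ≈ 1.2), giving
as few as two observations per condition; an unpooled Welch test
(`var_mode="welch"`, available) has essentially no power there.
Classification thresholds are adj. P < 0.05 with |log2FC| ≥ 1.5
(positive/down), a grayzone for significant-but-small (0.5 ≤ |log2FC| <
1.5) or large-but-nonsignificant calls, and negative otherwise.

**Peak collapse.** A peak counts as covered when a retained region
overlaps ≥ 60% of it; the peak inherits the class of the overlapping
region with the most barcodes (ties → larger |log2FC|).

## Motif model

Scores are log₂ likelihood ratios against a zero-order background
(uniform by default), maximised over all offsets and both strands;
N-containing windows are skipped; ties break toward the smaller offset,
then the + strand, for determinism. The homotypic CRM score accepts
positive-scoring hits greedily by score, skipping overlaps, and sums the
chain minus `gap_penalty` per 100 bp of inter-hit gap; with one positive
hit it reduces exactly to the best single-site score. AUC uses midranks,
so ties contribute ½ exactly as in the pairwise-concordance definition.

The shipped tetramer PWM is a consensus-derived stand-in for the
duplicated RRRCWWGYYY element (zero spacer): degenerate R/W/Y positions
carry 0.40–0.57 on their two admissible bases with 1–2% soft counts
elsewhere, while the C/G anchors of the CWWG core are near-invariant
(0.985). The anchor sharpness is deliberate: functional response
elements essentially never tolerate core substitutions, and a softer
core would plant "functional" sites indistinguishable from background,
misrepresenting the class structure the classifier is meant to learn.
Users supply their own matrices for real analyses.

## Direct/indirect classifier and genome scan

The forest follows the published configuration: 151 trees,
max_features = √p, Gini importances (non-negative, summing to 1),
stratified fivefold CV, fully seeded. Features are per-PWM best-window
LLRs. The genome scan anchors on every position where any PWM reaches
`llr_threshold`, evaluates the forest on a 500-bp window centred on the
anchor, keeps windows with P(direct) ≥ 0.5, and merges calls within
100 bp keeping the max-probability representative. The anchor threshold
for clean-recovery analyses is 21 bits — between the empirical background
maximum over a megabase (≈ 18 bits) and the consensus site score
(25.6 bits); for exploratory scans a background-quantile helper
(`background_llr_threshold`) estimates thresholds from shuffled sequence.

## Cistrome structure

Coverage is summed per base over site midpoint ± 2000 bp from bedGraph
tracks (missing bases count 0, absent chromosomes warn). Clustering is
k-means (k = 3, k-means++, 10 restarts, seeded) on log1p coverage;
clusters are relabelled strong/weak/unbound by descending mean so labels
never depend on initialisation. A constant matrix returns one label with
a degeneracy flag. Rank aggregation is mean-rank (Borda): descending
per-experiment ranks with midrank ties, averaged, final order breaking
ties by site id — a permutation of 1..n invariant to experiment order
and to any strictly monotone per-experiment transform of coverage.

## Flanking profiles

Offset 0 is the site midpoint; a dinucleotide at offset k spans
[k, k+2). Frequencies exclude N-containing dinucleotides from the
denominator and sum to 1 per offset otherwise. DNA shape is a centred-
pentamer lookup from a user-supplied (strand-symmetrised) table, with
the outermost 2 bp trimmed; conservation profiles read per-base values
from a bedGraph with configurable handling of uncovered bases.

## The simulator: what it does and does not emulate

The generator reproduces the structures the analysis depends on: planted
20-bp full sites at uniform interior offsets on random strands
(`frac_positive`, default 0.4), Poisson-distributed barcodes per region
(mean 1.2, matching reporter-library practice), chimeric couplings
(5%), NB counts (depth 1000, dispersion 0.05, 2 replicates per
condition), an 8-fold binary activity effect, and a sites × experiments
coverage matrix with shared strong/weak/unbound tiers (means 100/20/2,
fractions 0.2/0.3/0.5 of 300 sites) plus experiment-private strong sites
(`indirect_rate`). An optional flag GC-shifts responsive flanks 50–150 bp
from the site to create the A/T-dinucleotide depletion used to test the
profile code.

It does **not** emulate fragment-capture bias, barcode abundance
heterogeneity in the plasmid pool, sequencing error beyond optional
barcode substitutions, mappability or repeat structure, or correlated
noise across experiments. Passing tests therefore demonstrate that the
algorithms recover planted structure under the stated noise model — not
that real screens are free of the artefacts listed above.

Problem sizes used in tests and in the acceptance script (500 regions,
300 training peaks, 1-Mb scan genome, 300 coverage sites) are the
package's choice of a regime large enough for stable statistics while
keeping any run to seconds.

## Numerical and degenerate-input conventions

Zero-probability PWM cells map to −∞ log-odds (never matched); empty
coupling input returns an empty table with a warning; regions whose
barcodes all fail filters are classed `low_coverage`; a t test with
fewer than two observations per side (unpooled mode) returns P = 1 for
a zero difference and NaN otherwise; correlation of a zero-variance
vector is reported NaN rather than raising. All stochastic routines
take explicit seeds and are byte-reproducible.

## Known limitations

- The moderated test assumes a shared dispersion; strongly
  heteroscedastic real data would call for per-region shrinkage instead.
- Median centring assumes responsive regions are a minority.
- The genome scan is windowed and greedy; two genuine sites closer than
  the merge distance report as one call.
- k-means on summed coverage ignores profile shape; a profile mode would
  be needed to separate sites with equal totals but different footprints.
- The shipped PWM is a stand-in; conclusions about real TP53 sites
  require empirically derived matrices.
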