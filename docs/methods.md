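# Methods

This note records the statistical models, conventions and design choices
behind `regumirror`, and what its synthetic-data validation does and does
not establish about real data.

## Conventions

All genomic coordinates are 0-based half-open internally (the BED /
narrowPeak convention); GTF input (1-based closed) is converted on
ingestion, so a gene on the + strand at GTF `start..end` has TSS `start−1`
and on the − strand `end−1`. Gene symbols are harmonized by trimming and
uppercasing, which merges mouse title-case symbols (`Spp1`) with human
uppercase symbols (`SPP1`) into one namespace; cross-species identity still
flows through an explicit ortholog map, never through string equality.
When a table contains the same harmonized symbol twice, the record with the
smallest adjusted p is kept (missing p sorts last) — a deterministic rule
favoring the strongest evidence. A missing adjusted p is treated as
non-significant everywhere.

## Overlap, concordance, correlation

Significance means Padj < α strictly (default α = 0.05). The overlap of two
significant sets is tested with the upper-tail hypergeometric probability
P(X ≥ k) *including* the observed k, the standard enrichment convention;
`k = 0` therefore always yields p = 1. The background N is a required
argument of any overlap test: for a pairwise comparison the natural choice
is the union of genes analyzed (tested, not merely significant) in both
datasets, and the pipeline's `compare` stage defaults to that union when no
explicit N is configured. Direction concordance counts shared significant
genes whose log₂FC signs agree; genes with a fold change of exactly zero in
either table are excluded from numerator and denominator (the sign is
undefined). Spearman ρ uses average ranks for ties and the large-sample
t-approximation for its p-value — every real use has dozens to thousands of
shared genes, where the approximation is indistinguishable from exact
permutation.

Benjamini–Hochberg adjustment is the classic step-up with cumulative-minimum
monotone repair (delegated to `statsmodels`, cross-checked in the tests
against a from-the-definition oracle). One property worth recording: the
adjusted-value map is *not* idempotent. Re-adjusting an already adjusted
vector re-applies the m/rank inflation, e.g. (0, 0.5, 1) → (0, 0.75, 1) →
(0, 1, 1). What is stable is the rejection decision at any level, not the
adjusted values themselves.

## Enrichment and GSEA

ORA restricts each catalog term to the background before applying the size
filter (default 10 ≤ K ≤ 500) and corrects across retained terms only.
Redundant-term simplification clusters significant terms by single-linkage
on Jaccard similarity of member sets at cutoff 0.7 and keeps the
smallest-padj representative per cluster. Jaccard on member sets was chosen
over ontology-graph semantic similarity deliberately: it needs no ontology
input, is exactly testable, and at the 0.7 cutoff behaves very similarly on
flat catalogs; it will merge less aggressively than a semantic measure for
terms related through the GO graph but sharing few genes.

GSEA uses the weighted KS running sum (weight 1 by default, weight 0 giving
the classic unweighted statistic). Significance comes from a *gene
permutation* null: membership labels are redrawn uniformly, `n_perm` times
per distinct set size, under a mandatory seed. The p-value is the add-one
estimator conditioned on sign, p = (1 + #{same-sign |null| ≥ |ES|}) /
(1 + #same-sign nulls), and NES divides ES by the mean |null ES| of the same
sign — the canonical normalization. This estimator is exactly uniform under
the null (the validation measures a 5% rejection rate within binomial
error), at the cost that its floor for any single set is 1/(1 + #same-sign
nulls), roughly 2/n_perm, not 1/n_perm; an adaptive multilevel scheme could
go lower but is deliberately out of scope. If all in-set metrics are exactly
zero under positive weight, hit increments fall back to equal weights so the
statistic stays defined.

## Motif machinery

PFM counts become probabilities with a background-weighted pseudocount
(default 1), then log₂-odds scores against the background (uniform by
default). The match threshold is the smallest *attainable* score whose
upper-tail probability under i.i.d. background sequence is ≤ the p-value
cutoff (default 5 × 10⁻⁵, the convention of promoter motif scanners). The
tail distribution is computed by exact dynamic-programming convolution of
per-column score distributions on a 10⁻⁴-bit grid; the returned threshold
shaves the worst-case rounding margin (w·grid/2, ≤ ~10⁻³ bits) so a
sequence at the chosen score level always passes. Consequence: scores
within that margin *below* the level can also pass; the acceptance bound on
the empirical hit rate (≤ 1.5 × cutoff at 10⁶ positions) absorbs this
granularity. Scanning evaluates every offset on both strands (the minus
strand via the reverse-complemented matrix); windows containing N never
match. If even the maximum attainable score is too probable for the cutoff
(very short or flat motifs), the threshold is +∞ and nothing matches — a
real behavior worth knowing when supplying short PFMs.

## The target funnel

Promoter windows are symmetric [TSS − 2 kb, TSS + 2 kb), strand-independent
(only the TSS position itself is strand-aware), clipped at the chromosome
start; a gene with several TSSs contributes several windows. A peak is
promoter-bound on ≥1 bp overlap. Peak strength is the narrowPeak score
column; a zeroed score with a present q-value is repaired as
round(−log₁₀ q × 10), the score's own definition. Ties between equal-score
peaks break by smaller start, then chromosome name, making outputs
deterministic. The five-tier color scale (blue < 200, cyan 200–499, green
500–749, yellow 750–999, red ≥ 1000) is a total, stepwise non-decreasing
function of the score.

The occupancy gate requires a YAP1 best peak AND at least one TEAD1–4 best
peak, per species; the consensus gate requires both species to pass, linked
by the ortholog map (a human gene with several mouse orthologs qualifies if
any pairing passes; the lexicographically first qualifying mouse symbol
represents it, with multiplicity logged). The motif gate scans the retained
best promoter peaks of all five factors in either species; an alternative
mode scans the whole ±2 kb window instead (`scan_full_window`). The final
gate intersects with genes at Padj < 0.05 and log₂FC < 0 in *both* knockout
time-point tables. Every gate can be disabled independently, which is how
the tests verify that each synthetic decoy dies at exactly its intended
stage.

## Synthetic data: what it emulates, and what it does not

`gen_deg_pair` constructs the shared-significant overlap *exactly*
(round(overlap · n_B) genes), draws sign agreement per shared gene as a
Bernoulli(concordance), and couples fold-change magnitudes (b's magnitude =
0.25 + |0.7·(a − 0.25) + 0.3·noise|) so Spearman ρ rises monotonically with
the concordance target. Magnitudes are |Normal(0, σ)| + 0.25, the offset
avoiding zero-sign ambiguity. Significant genes get Padj ~ U(10⁻⁸, 0.049),
others U(0.05, 1).

`gen_regulatory_fixture` writes two pseudo-species (one chromosome each,
5 kb promoter spacing to keep windows disjoint, ~250 kb per genome at the
default 48 genes) with 19 planted targets and 3 decoys per funnel stage.
Peaks are 200 bp around the TSS with scores sampled across all five tiers
(a quarter of them emitted with a zeroed score column and a q-value, to
exercise the repair path). The planted TEAD-like PFM is 9 bp wide
(consensus AGGAATGTC around the GGAATG MCAT core) with sharply peaked
columns, so at the default cutoff only the exact consensus matches — planted
consensus instances pass, and the one-mismatch near-consensus planted in
`no_motif` decoys fails. `no_motif` promoter windows are additionally
scrubbed of chance consensus occurrences so a lucky background 9-mer cannot
leak a decoy through. Every decoy satisfies all gates except its own, which
is what makes gate-level attribution testable.

What passing these tests shows: the statistics match exact oracles, the
funnel logic implements its gates precisely, and the whole pipeline is
deterministic under seeds. What it does not show: robustness to the
messiness of real data — overlapping promoters, one-to-many orthology at
scale, ChIP peak-caller artifacts, motif thresholds on genomes with
non-uniform base composition, or batch structure in DEG tables. The
generators emulate the *interfaces* and the planted signal, not read-level
noise, fragment-length models, or GC bias.

## Problem sizes and numerics

Validation sizes were chosen so the full suite runs in well under a minute
per component on one CPU: exact-oracle checks at N ≤ 60 (hypergeometric) and
table totals ≤ 40 (Fisher) over 1000 random configurations; GSEA calibration
with 500 replicates at n_perm = 2000 on 100-gene lists; motif enumeration at
w ≤ 8; fixtures of 48 genes over 10 seeds. The permutation null is
vectorized over permutations in memory-bounded blocks. All tolerances are
stated in the tests themselves: 10⁻¹² relative for counting statistics
against big-integer oracles, 10⁻¹² absolute for running-sum equivalence,
0.01 bits for thresholds against enumeration.

## Known limitations

- The ortholog gate keys on symbols, not stable gene IDs; symbol drift
  between annotation releases is the caller's responsibility.
- GSEA p-values cannot go below ~2/n_perm (see above); use more
  permutations when very small p-values matter.
- Term simplification is catalog-agnostic Jaccard, not ontology-aware.
- The funnel treats pooled peaks per factor as one evidence set; per-cell-
  type resolution is lost by design (callers may pass any subset of peak
  files).
- No liftover: all inputs for one species must share a genome build.
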