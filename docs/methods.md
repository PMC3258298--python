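# Methods

`coldmir` asks one question of a paired small-RNA / expression-array
experiment with two conditions: **does the miRNAome drive the observed
transcriptome-wide expression change?** It answers with a battery of
statistics that probe the question at increasing levels of organisation —
single miRNAs, seed sequences, and the miRNA–mRNA network as a whole. This
note records the models, the defaults, and the design choices, in that
order.

## Differential-miRNA screen

Each miRNA has one raw read count per library (NC = control, WC =
treatment). Libraries differ in depth, so WC counts are divided by a
scaling factor *f* before comparison:

* default estimator: total-count ratio, `f = ΣWC / ΣNC`;
* robust alternative: `median_ratio`, the median per-miRNA WC/NC ratio over
  rows with both counts positive;
* `calibrate_norm_factor`: when a table already carries reported normalized
  folds (as the bundled zebrafish example does), each row implies a factor
  — `(WC/NC)/fold` for up-regulated rows, `(WC/NC)·fold` for down — and the
  (optionally leave-one-out) median of these recovers the scaling that was
  used. On the bundled table the per-row implied factors cluster within
  ±0.04% of 1.979, and the leave-one-out calibration reproduces every
  reported fold to better than 0.05%.

The fold change is directional and ≥ 1: `(WC/f)/NC` when the miRNA is
higher in WC, `NC/(WC/f)` otherwise. Zero counts are replaced by a
pseudocount (default 1) so folds remain defined.

A miRNA is called differential when `fold > 2` **and** mean expression
`> 64` (both strict). The abundance cut exists because low-count miRNAs
show far larger relative noise than abundant ones. The mean is computed on
**raw counts** by default. On the bundled 25-miRNA example, averaging raw
counts (or, equivalently in outcome, scaling NC up to the deeper library
before averaging — the `mean_on="normalized"` option) passes all 25 rows,
whereas averaging after scaling WC *down* would drop four borderline rows;
the down-scaling convention discards information about the deeper library
and is not offered.

## Target-set enrichment

For each miRNA, a two-sided Fisher exact test on the 2×2 partition of the
assayed gene universe by (predicted target) × (differentially expressed),
run separately against the up- and down-regulated sets, with
Benjamini–Hochberg FDR across miRNAs. Direction (enrichment/depletion) is
read off the observed overlap relative to its hypergeometric expectation.
The same machinery serves the TF-representation test below. Fisher,
hypergeometric tails and BH are delegated to scipy/statsmodels; the test
suite cross-checks them against exact rational enumeration.

## Regulatory-effect (RE) score

Per sample, all genes are ranked by expression (average ranks on ties); a
miRNA's RE score is

    RE = (mean rank of non-targets − mean rank of targets) / N_genes

so RE ∈ (−1, 1), positive when targets sit low — i.e. look repressed. The
score is invariant to any strictly monotone transform of the intensities
and exactly antisymmetric under swapping the target/non-target roles. Per
miRNA, the per-sample scores of the two conditions are compared with a
Welch two-sample t-test (safer than pooled variance at n = 3 per group,
and nearly identical there), BH-corrected across miRNAs, flagged at
FDR < 0.05.

A caution that matters for calibration: the RE statistic responds to *any*
between-condition expression change that touches a target set, not only to
miRNA-driven change. If a simulation plants differential genes at random
(uncorrelated with the miRNAs), target sets randomly absorb shifted genes
and RE genuinely differs between conditions for many miRNAs. The
uniform-p null of the RE test is therefore checked on data with no
expression change at all; under that null the Welch test at n = 3 is
slightly conservative (≈3% of p-values below 0.05 in our suite).

## Seed-word enrichment landscape

A miRNA recognises targets through its 5' seed: the 7-mers at positions
1–7 and 2–8 are reverse-complemented into DNA to give the UTR words a seed
match would contain. Genes are ranked from most up- to most down-regulated;
for each word and each leading-bin cutoff *c* (20 evenly spaced cutoffs by
default), the number of word-bearing genes among the leading *c* is tested
against a hypergeometric null (N genes, K carriers, c drawn). The signed
score is −log10 of the one-sided tail, positive for enrichment, negative
for depletion; at the full-list cutoff every word scores exactly 0.

Choices: word occurrence is binarized per gene because the hypergeometric
sampling unit is the gene (occurrence counts are retained for
diagnostics); landscape p-values are not multiplicity-corrected (a
Bonferroni-over-words threshold is trivial to draw when plotting); no
Markov background correction for sequence composition is applied — on the
uniform-composition synthetic UTRs it would be a no-op, on real UTRs its
absence means low-complexity words can score spuriously.

## Regulatory density and its permutation null

The differential miRNAs and differential genes form a bipartite network
with an edge per predicted targeting relation between them. An edge is
**coherent** when its endpoints changed in opposite directions (consistent
with repression), **incoherent** when parallel. The network-level polarity
statistic is the regulatory density

    RD = (#coherent − #incoherent) / (#coherent + #incoherent) ∈ [−1, 1],

which lives on the lattice {(2c − E)/E}. Its null distribution comes from
degree-preserving randomization: repeated bipartite double-edge swaps —
pick edges (m1,g1), (m2,g2), rewire to (m1,g2), (m2,g1) unless a duplicate
edge would arise — leaving every node's degree and direction intact. Each
null replicate runs a fresh chain of 100·E attempted swaps from the
observed network (comparing against 10·E on test fixtures showed
indistinguishable null distributions, so 100·E is comfortably past
mixing); the test suite also verifies on an exhaustively enumerable 3×4
graph that the chain samples the degree class uniformly. Networks
admitting no valid swap (e.g. complete bipartite) are returned unchanged
with a warning, collapsing the null onto the observed value — the
honest answer for a rigid graph.

With n replicates the one-sided empirical p-value is
`(1 + #{null ≥ observed})/(n + 1)` — never zero, and ties (common on a
discrete lattice) count toward the null, making the test slightly
conservative. Significance is declared when the observed RD exceeds the
null 95th percentile; n = 1000 by default.

## TF layer

Putative transcription factors are genes annotated with any of four GO
term labels: "DNA binding", "transcription factor activity",
"transcription activator activity", "transcription repressor activity".
Matching is by exact label; the GO graph is not traversed (ancestor
closure would sweep in far more genes than the plain labels intend).
TF representation among differential genes is tested with the same
two-sided Fisher machinery; miRNA→TF edges of the coherence network are
extracted with their labels; and a Mann–Whitney rank-sum comparison of TF
vs non-TF mean expression is provided to judge whether low TF abundance
could mask differential TFs.

## Synthetic data

The generators produce exactly the inputs above, with defaults mirroring
the motivating zebrafish cold-acclimation experiment: 700 miRNAs, 7356
arrayed genes, library depths 6,473,829 (NC) and 10,799,032 (WC), 25/700
truly changed miRNAs, 626/7356 differential genes, 3 replicates per
condition, ~80 targets per miRNA (≈7.6 regulating miRNAs per gene), and
`coupling_beta = 0` — no miRNA-driven coherence, the regime the method is
designed to rule in or out.

* **Counts**: per-miRNA abundances are log-normal (σ = 2, a heavy-tailed
  expression spectrum); counts are negative binomial with dispersion 0.1
  (overdispersion is a property of small-RNA libraries; the exact noise
  family of real libraries is unknowable from two libraries, so this is a
  modelling stand-in). Changed miRNAs shift their WC mean by ±`mirna_lfc`
  log2 units, half up, half down. Totals are not renormalized after
  planting, so realized library totals deviate slightly from the nominal
  depths when planted effects are large or unbalanced.
* **Expression**: baseline log2 intensities Normal(8, 1.5); within-
  condition noise Normal(0, 0.25) — the replicate-level spread of a
  well-behaved array experiment; planted genes shift by ±`gene_lfc` (1.0
  ≙ 2-fold). With `coupling_beta > 0`, each gene targeted by ≥1 changed
  miRNA is, with that probability, forced differential opposite to one of
  its changed regulators (chosen uniformly when they conflict).
* **Target map**: per-miRNA out-degree Poisson(`targets_per_mirna`),
  targets uniform without replacement, no duplicate pairs.
* **UTRs**: uniform-random A/C/G/T of length `utr_len` (500 nt default);
  planted (gene, word) sites overwrite a random window.

One root seed drives per-generator substreams, so outputs are reproducible
individually and jointly. What the generators do **not** emulate: GC/
composition bias and repeat structure in UTRs, correlated expression
between genes, probe-level array artifacts, sequencing adapter/length
effects, and target-prediction bias. Passing recovery tests on this
synthetic world therefore demonstrates the statistics' correctness and
calibration, not robustness to those real-data pathologies.

## Problem sizes in the test suite

The Monte-Carlo suites run at reduced scale chosen to keep the binomial
error of each checked proportion well inside its acceptance band: null
calibration uses 200 datasets (40 miRNAs × 1000 genes, ~120-edge networks,
200 shuffles each); RD power uses 100 datasets at `coupling_beta = 0.9`;
seed-word recovery plants a word in the 50 most down-regulated of 1000
UTRs across 60 datasets; the RE-test uniformity check pools 1500 p-values
from 15 no-change datasets.

## Known limitations

* The RD test conditions on node directions and degrees; it does not model
  uncertainty in the upstream differential calls or in target prediction.
* The empirical p cannot go below 1/(n+1); rare-event resolution is bounded
  by the replicate budget.
* The seed-word scan has no composition correction (above).
* With one count library per condition, the screen has no within-condition
  replication; the fold/abundance rule is a filter, not a calibrated test.
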