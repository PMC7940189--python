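# Methods

This note documents the models, parameter choices and numerical
conventions behind `motifcircuit`, and what the synthetic data can and
cannot establish about behaviour on real data.

## Problem and model

The package addresses a regulator-prioritization problem in single-cell
transcriptomics: given the marker genes of one cell cluster, which
transcription-factor binding motifs best distinguish the regulatory
sequences of those markers from the regulatory sequences of non-marker
genes? The unit of analysis is the gene; the feature vector of a gene
is its motif hit-count profile over a motif database; and the two
competing selectors are a per-motif chi-squared enrichment test (CT)
and a guided regularized random forest (RF/GRRF) that scores motifs
jointly.

### Gene sets

Positives are up-regulated cluster markers (linear fold change >= 1.5,
BH-adjusted p < 0.05, expressed in >= 10% of the cluster's cells) with
at least one ATAC-seq peak annotated to their promoter. Negatives are
non-markers (adjusted p > 0.1, absolute fold change strictly inside
(1/1.5, 1.5), same 10% expression floor), split into negative set 1
(no promoter peak; regulatory sequence = fixed TSS window) and negative
set 2 (promoter peak present; regulatory sequence = the peak itself).
Genes with 0.05 <= adjusted p <= 0.1 sit in a deliberate buffer zone
between the two significance thresholds and belong to neither set, so
the sets are disjoint by construction.

Interpretation choices where the protocol is ambiguous:

* "equal to or >1.5-fold" is read as an inclusive, upward-only bound
  for positives; the negatives' fold condition is read as a bound on
  the *absolute* (bidirectional) fold change, i.e. the open interval
  (1/1.5, 1.5) on the linear scale.
* Non-marker status is evaluated against the focal cluster only, not
  against every cluster.
* The promoter window is [TSS-1000, TSS+100) on the gene's strand (the
  HOMER convention). When a peak overlaps several promoter windows the
  gene with the TSS nearest the peak midpoint wins; remaining ties go
  to the lexicographically smallest gene id.
* The representative TSS of a gene is its longest protein-coding
  transcript (falling back to the longest transcript of any biotype);
  length ties break on transcript id when present, else TSS position.

### Sequence extraction

Coordinates are 0-based half-open (BED convention) throughout, and the
TSS is a 0-based position. The negative-set-1 window spans 1,000 bp
upstream to 220 bp downstream of the TSS (1,220 bp total); both values
are configurable. On the minus strand the interval endpoints are
mirrored — [TSS-downstream, TSS+upstream) — and the sequence is reverse
complemented, so all sequences are gene-strand oriented. Windows are
truncated at contig edges rather than discarded (synthetic contigs are
short), with the truncation flagged on the record.

### Motif scanning and exact p-values

A motif's position probability matrix (PPM) is converted to an integer
log-odds matrix in centibits:

    score(i, b) = round(100 * log2((ppm[i,b]*(1-eps) + eps*bg[b]) / bg[b]))

with pseudo-probability fraction eps = 0.01 shrinking the PPM toward
the background to avoid infinities. Integer discretization buys an
*exact* null: the distribution of the total window score under an
i.i.d. background follows from convolving the per-position score
distributions, and p(s) = P(S >= s) is read off the survival function.
The 100x granularity is configurable through the scoring function.

The scanning background defaults to uniform and is always symmetrized
with its reverse complement (A with T, C with G), so one null
distribution serves both strands; minus-strand windows are scored with
the reverse-complement score matrix and reported on the forward axis.
Windows containing N are skipped. The emission threshold is p <= 1e-4
(the common default for this kind of scanner). Within one scan run —
one cluster and one gene set — hits receive Benjamini-Hochberg
q-values, and hits with q <= 0.05 are counted per (gene, motif),
pooling a gene's multiple peaks and both strands. The source protocol
prints the filter in the opposite direction (keep q > 0.05), which
would retain only non-significant hits; the default corrects the
apparent typo, and `mode="keep_gt"` (CLI `--q-mode gt`) reproduces the
literal behaviour for faithful comparison. Genes whose total retained
count is zero are dropped from the final sets, since they carry no
feature information.

The exact-null DP applies an order-0 background even when sequences
were generated from an order-1 model; higher-order scoring nulls are
out of scope.

### Chi-squared enrichment (CT)

Per motif, genes are dichotomized into with/without at least one
retained hit (raw counts have no natural 2x2 form) and cross-tabulated
against the positive/negative labels. The statistic is Yates-corrected:

    chi2 = N * max(|ad - bc| - N/2, 0)^2 / ((a+b)(c+d)(a+c)(b+d)),

with an upper-tail p on 1 degree of freedom. A motif is testable when
at least 5 genes carry a hit — a proxy for the test's expected-count
validity requirement — and all margins are positive; other motifs are
reported untested. Ranking is by descending -log10 p with ties broken
by larger statistic, then motif id; no cross-motif multiplicity
correction is applied because the method consumes ranks, not p-value
cutoffs.

### Guided regularized random forest (RF/GRRF)

The forest is written from scratch (a numba-compiled CART kernel):
binary Gini-impurity trees on numeric thresholds, bootstrap sampling,
`mtry` random candidate features per node (default ceil(sqrt(p))),
grown to purity (min_leaf = 1), 500 trees by default. Importance is
mean decrease in Gini: the bootstrap-share-weighted impurity decrease
summed over a feature's splits, averaged over trees.

Guidance: an ordinary forest is fitted first and its importances are
max-normalized to imp in [0,1]^p. For a regularization weight
gamma in [0,1] each feature receives

    lambda_i = (1 - gamma) * lambda0 + gamma * imp_i,   lambda0 = 1,

and the regularized forest is grown *sequentially* with a shared
selected-feature set F: a candidate i not in F competes with
gain * lambda_i, a member of F with its raw gain; the winning feature
enters F and never leaves; zero-gain splits become leaves. lambda0 = 1
is the standard choice and is exposed in the API. At gamma = 0 the
procedure reduces exactly — same seed, same RNG consumption, same
trees — to the ordinary forest, which the tests assert. Features
outside F have importance exactly 0.

Determinism conventions: per-tree seeds derive from the forest seed;
candidate-gain ties break toward the lowest feature index; threshold
ties within a feature break toward the lowest threshold; tree build
order is part of the seeded contract (GRRF trees are not independent).
Splits depend only on value ranks, so any strictly increasing
relabeling of counts leaves tree structure unchanged.

### Nested evaluation protocol

Stratified 5-fold CV (per-class round-robin deal after a seeded
shuffle; per-fold class counts differ by at most 1). Each fold is the
test set once; each remaining fold is the validation set once with the
other three merged for training — 4 runs per test fold, 20 runs total.
Per run: ordinary RF on the training split supplies guidance; GRRF
models over the gamma grid (default 0.0, 0.1, ..., 1.0) are compared
by validation *accuracy* (ties toward larger gamma — stronger
regularization, fewer features); the tuned model is then scored by
ACC, MCC and F1. Per test fold the best of the four runs by the
product ACC x MCC x F1 predicts the held-out fold (auROC and auPRC);
the cluster's best model is the test-fold winner by auROC, and its F
and importances provide the RF ranking. Validation accuracy is used
for tuning and the triple product for model selection because the
protocol sequences them that way; degenerate (single-class) validation
folds are skipped with a warning.

Metric conventions: MCC with a zero denominator is defined as 0 (keeps
the product defined); auROC uses average-rank tie handling; auPRC is
step-interpolated average precision; hard predictions threshold the
forest probability at 0.5.

Top-N curves retrain a plain forest on the top-N motifs (N = 1..10) of
each method's ranking per test fold — masking features inside a fitted
ensemble is ill-defined, so retraining operationalizes "predict with
the top N motifs". The coverage curve is the cumulative fraction of
positive genes with at least one retained hit of any top-N motif.

## Synthetic data

The generator emulates the statistical structure the method assumes,
not single-cell data itself. Each gene gets its own contig: background
DNA (order-0 i.i.d. with configurable GC, or an order-1 chain that
repeats the previous base with probability `markov_persistence` and
otherwise redraws from the stationary distribution, preserving GC); a
TSS placed so the 1,220 bp window fits (alternating strands); an OCR
peak of the same length, jittered by up to ±100 bp, for positive and
negative-set-2 genes; and motif instances planted at uniform positions
and strands, Poisson-distributed per sequence with mean
`plant_rate_positive` (default 1.0) in positives and 0 in negatives.
Planted motifs are high-information (one base at probability 0.95 per
column, ~13 bits at width 8); decoys are Dirichlet-random. The DE
table straddles the selection thresholds by construction, optionally
with five distractor genes violating exactly one criterion each. The
truth file records gene sets *and* per-site coordinates, enabling
site-level recovery tests beyond the gene-level need. Two extensions
support specific experiments: `plant_rate_negative2` leaks signal into
the OCR-bearing negatives (negative-mode contrast), and `plant_groups`
plants different motifs in disjoint positive subsets (redundant-family
contrast). A fixed seed makes the bundle byte-identical.

What passing on this generator does **not** show: real promoters have
repeats, CpG islands and higher-order composition the background model
lacks; real DE tables have correlated fold changes and p-values; real
peaks vary in length and can be distal; motif databases contain
correlated families far messier than the jittered ones here. Results
on the bundle certify the machinery (filters, coordinates, exact
p-values, selection and evaluation logic), not biological performance.

## Problem sizes used

Tests and the acceptance script run the pipeline at reduced but
faithful sizes chosen once: the planted-recovery condition keeps the
full 200+200 genes, 1,220 bp and 5-of-100 motifs with 100-tree forests
and a gamma grid of 5; the redundancy, null and negative-mode
experiments use 60-100 genes per class, 30-60 motifs and 25-50 trees.
These are the package's own study conditions for its synthetic
benchmarks; all forest and grid sizes remain configurable.

## Known limitations

* Binary classification only; multi-class clusters are handled one
  cluster at a time against the rest.
* The scanner's exact null assumes order-0 backgrounds; q-values are
  computed per scan run rather than FIMO's position-count convention.
* CT uses gene-level presence/absence; pooled-count variants of the
  2x2 table are not implemented.
* The GRRF kernel targets dense integer-like count matrices of
  moderate width (hundreds of motifs); it is not tuned for
  high-dimensional sparse inputs.
* No repeat masking or CpG classification of promoters; no motif
  discovery.
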