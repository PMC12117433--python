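# Methods

This note records the model, the conventions, the tunable parameters, what
the synthetic benchmark does and does not emulate, and the numerical
choices that were genuinely open.

## Coordinates and input normalization

All intervals are 0-based half-open internally. GTF (1-based closed) and
BED/bedGraph (already 0-based half-open) are converted at the reader
boundary, so feature code never mixes conventions. One transcript
represents each gene: the one with maximal total exonic length, ties
broken by the lexicographically smallest transcript id (the tie-break is a
deterministic convention, nothing more). Genes are filtered to
`gene_biotype/gene_type == protein_coding` when the attribute is present
in the GTF; otherwise all genes are kept.

Conservation tracks are sparse: positions without a record are *no data*
and are excluded from aggregates — they are never treated as zero. A
region whose coverage is below 10% of its bases yields missing aggregates
rather than an estimate dominated by a handful of covered bases.

## Sequence features

Per gene the package emits (default configuration, 222 columns):

| group | columns | notes |
|---|---|---|
| architecture | 9 | element lengths, exon/intron counts, intron:exon ratio |
| composition | 86 | overlapping 1/2/3-mer frequencies of the strand-oriented gene body, AT content, CDS AT content |
| codon bias | 84 | per amino-acid group (incl. stop): total proportion, mean, median, CV of member-codon frequencies |
| TF motifs | 9 | aggregate hit density (hits/kb, both strands) per region |
| RBP sites | 4 | overlapping records/kb over 5'UTR, exons, introns, 3'UTR |
| miRNA sites | 3 | 5'UTR, CDS, 3'UTR |
| conservation | 20 | mean and median per region |
| TSS distance | 1 | bp to the nearest other TSS on the chromosome |

Regions: symmetric promoter windows [TSS−w, TSS+w) for w ∈ {500, 1000,
2000, 5000} (configurable; the window is centred on the TSS for both
strands), gene body, 5'UTR, exons, introns, 3'UTR, CDS. A PWM hit is a
window whose log-odds score (uniform background, pseudocount 1e-6) reaches
`score_fraction` (default 0.8) of the motif's maximal achievable score;
consensus motifs are matched exactly; windows containing N never match;
windows never span the gap between two intervals of a region. Motif counts
are aggregated over the whole motif set by default (per-motif columns are
available behind a flag) — the feature is "how motif-dense is this
region", not a motif-by-motif profile.

Composition is computed on the unspliced, strand-oriented gene-body
sequence; codon statistics on the spliced CDS. The coefficient of
variation uses the population standard deviation throughout.

## Expression and specificity

TPM_g = (c_g/L_g)/Σ_j(c_j/L_j) × 10⁶ with L the exonic (default) or
gene-span length in bp; the model's expression feature is log2(TPM+1) of
the profiled sample. Per-cell scoring swaps in log2(CP10K+1) of each
cell's UMI column; all other features stay fixed, so a gene×cell score
matrix costs one logistic evaluation per cell.

The five specificity indices are computed once from a multi-tissue
reference atlas on log2(TPM+1) and joined to genes as constants (they are
properties of the gene, not of the profiled sample). Definitions, for a
vector x over n tissues with p = x/Σx:

- tau = Σᵢ(1 − xᵢ/max x)/(n − 1)
- Gini = ΣᵢΣⱼ|xᵢ−xⱼ| / (2n²·mean x) — the plain relative mean absolute
  difference halved (range [0, (n−1)/n]), not rescaled by n/(n−1)
- Simpson = Σ pᵢ²
- Shannon specificity = 1 − H(p)/log₂ n
- ROKU = 1 − H(p′)/log₂ n, where p′ normalizes |x − T(x)| and T is a
  one-step Tukey biweight location (c = 5, eps = 1e-4, median/MAD start)

An all-zero gene scores 0 on every index. The log transform matters: tau
of a uniformly expressed gene under realistic count noise is ≈ 0.5 on the
raw scale but ≈ 0.1 on the log scale, which is the regime in which the
index is conventionally interpreted. ROKU is scale-invariant only up to
O(eps/MAD) because of the eps guard; the other four are exactly invariant.

## Feature selection

1. **Screen** — two-sided Wilcoxon rank-sum per feature, CIG vs control
   and CIG vs housekeeping; kept iff p ≤ 0.05 in *both* (the stricter
   reading; `screen_rule="any"` is available). Exact enumeration when both
   groups have ≤ 8 tie-free values, otherwise the tie-corrected normal
   approximation with continuity correction. A feature constant in the
   pooled sample gets p = 1.
2. **Prune** — pairs with |Pearson r| > 0.9 (pairwise-complete) processed
   in descending |r|; in each live pair the feature with the larger
   CIG-vs-control p is dropped (ties: the lexicographically larger name).
3. **Triple search** — every 3-feature combination, scored by mean 10-fold
   CV MCC of the L1-logistic model. One stratified fold assignment, fixed
   by the seed, is shared across all candidates so comparisons are paired.
   The pipeline caps the pool entering this stage at the `max_pool` = 12
   features with the smallest screen p-values so that the search stays
   exhaustive at interactive cost; the cap is a configuration choice and
   can be lifted for wider searches.
4. **Forward extension** — greedily add the pool feature with the best
   MCC gain; stop when the gain is ≤ 1e-4 ("no further enhancement"). By
   default only the best triple is extended; `n_seeds > 1` extends the
   top-k triples and keeps the best final set.

## Classifier, evaluation, significance

The L1-logistic fit maximizes Σ log-lik − (1/C)Σ|βⱼ| with C = 1 by
default, via liblinear (`l1_ratio=1`). liblinear nominally includes the
intercept in the penalty; `intercept_scaling=10` reduces that contribution
to |β₀|/10, a negligible bias accepted in exchange for speed and exact
determinism across the thousands of fits the selection stage performs.
Standardization (median imputation, then z-scoring with the population sd)
is always refit on training rows only — inside every CV fold, every
bootstrap split, and stored in the serialized model for scoring time.

Evaluation: stratified 10-fold CV with pooled out-of-fold predictions
(per-fold metrics reported alongside) and 500 stratified 80/20 bootstrap
splits (mean ± sd per metric). Metrics: sensitivity, specificity,
accuracy, MCC and F1 at the 0.5 cut; AUROC by the Mann–Whitney rank
formula with half-credit ties.

Significance is the package's one invented contract (the source procedure
reports FDR calls without defining the p-value): p(g) = (#{reference
control genes with score ≥ s(g)} + 1)/(n_controls + 1), BH-adjusted across
all scored genes, significant at FDR < 0.05. Consequences worth knowing:
the p-value floor is 1/(n_controls+1), so with few controls (e.g. 60) the
BH adjustment across a large gene set cannot reach FDR < 0.05 even for a
perfect ranking — resolution is set by the control-set size, and the
score *ranking* is informative below that resolution.

## SCIGNet

Edge lists are collapsed by distinct-source votes; edges with < 2 votes
are discarded (`min_votes` configurable); duplicate rows within one source
count once; self-loops are kept but flagged. The 23 TF features decompose
as 3 counts + 2 self values + 3 groups × 2 quantities × 3 statistics;
"neighbors" concatenates the children and parent lists, so the combined
mean equals (Σchildren + Σparents)/(n_children + n_parents). CV is
missing for sets smaller than 2 or with zero mean; genes without a
score/expression value are excluded from aggregates.

SMOTE: minority rows are oversampled by xᵢ + u·(x_nn − xᵢ), u ~ U(0,1),
with the neighbour drawn from the k = 5 nearest minority points (Euclidean
on standardized features, interpolation in the original space); the
majority is subsampled without replacement. The default per-class target
is min(majority size, 221). Selection and fitting then reuse the CIG
machinery on the 23 columns (the screen's housekeeping reference is a
held-aside slice of the balanced controls; the fold count adapts to the
balanced class sizes).

## The synthetic benchmark

The generator plants, for CIG-labeled genes: motif instances in the
promoter (±1 kb) and gene body at `base_motif_rate` × 3 (vs × 1 for other
genes), a +1.5 conservation shift in promoter bins, 3× longer 3'UTRs, 2×
RBP/miRNA site rates, high home-tissue and near-silent away-tissue
expression (negative binomial, dispersion 0.3, home mean 300 vs away 0.5
counts), and bulk expression elevated to the home-tissue level.
Housekeeping genes are uniformly high (mean 200) with short introns;
controls are uniformly moderate (mean 30). Single-cell UMIs are Poisson
thinnings of the first three tissue profiles at ~3000 counts/cell. Master
TFs draw child counts at 3× the control mean, attach preferentially to
high-score genes, and are regulated by other masters; every true GRN edge
appears in ≥ 2 of 3 source files, decoys in exactly 1. All randomness
derives from one seed; identical configs write byte-identical files.

What this does **not** emulate: realistic sequence evolution (the
background genome is i.i.d. uniform), correlated motif grammar, GC
isochores, mappability or batch structure in expression, dropout patterns
beyond Poisson thinning, or the heterogeneity of real identity-gene
signatures (every planted CIG carries every effect). Passing tests
therefore demonstrate that the *machinery* recovers planted signal of the
stated sizes — near-ceiling AUROC on the fixture is a property of the
strong planted effects, not a claim about real-genome performance, where
the corresponding published-scale analyses report AUROC ≈ 0.9–0.95 with
far larger training resources.

Problem sizes used by the test-suite and the acceptance script — the
default fixture (1000 genes, 60/60/100 labels, 4 contigs, 12 tissues, 150
cells, 150 TFs / 20 masters), a 12-feature / 300-gene table for the
selection-recovery checks (20 seeds), n = 4000 for coefficient recovery
(20 seeds), 8 label permutations and 20 noise-sweep repetitions — were
chosen so every property is measured with useful Monte-Carlo precision at
interactive cost.

## Numerical conventions and edge cases

- Zero-length regions, genes without a UTR/CDS, lone genes on a contig,
  and sub-coverage conservation regions yield missing features, never 0.
- Missing values are median-imputed from the fitting rows at
  standardization time; a feature constant on the fitting rows is an
  error naming the feature.
- The "sign pattern recovered" check for L1 recovery counts |β̂| < 0.15 as
  zero — 3 sd of the null estimate at n = 4000 and half the ±0.3 accuracy
  band used for the nonzero coefficients.
- Model files are versioned JSON; loading any other schema version is
  refused. Save→load round-trips reproduce scores to < 1e-12.
- Pipeline stage seeds derive from the run seed as
  (seed·1000003 + stage) mod 2³¹−1, so stages rerun standalone
  reproducibly; identical config + inputs give bit-identical outputs.

## Known limitations

- The empirical-null resolution issue described above.
- The exhaustive triple search is O(|pool|³); the pipeline's `max_pool`
  cap trades completeness of the candidate pool for tractability.
- Per-cell scoring treats specificity indices as gene-level constants from
  the reference atlas; a cell type absent from the atlas inherits
  atlas-derived specificity.
- bigWig conservation input is not implemented; bedGraph covers the same
  contract.
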