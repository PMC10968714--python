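# Methods

This note documents the models, conventions and numerical choices
behind `tsrnakit`, in the spirit of a statistical-software methods
appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Reference spaces and coordinates

Fragments are classified against three per-gene sequence spaces: the
mature tRNA, a 5′-leader window and a 3′-trailer window.  All
coordinates are 1-based inclusive throughout, matching the
`tDR-<start>:<end>` span convention, so a 76-nt His mature tRNA ends at
position 76 and its CCA-terminal fragments end there too.

The mature sequence is the spliced gene body with `CCA` appended
unconditionally — eukaryotic tRNA genes do not encode it — and, for
histidine tRNAs, a post-transcriptional `G−1` prepended as mature
position 1.  No deduplication of a genomically encoded CCA is
attempted.  The coordinate map sends post-transcriptional positions to
`None`; it is injective on templated positions, and excising
CCA (and G−1) and re-inserting introns reproduces the gene sequence
exactly (tested as a round trip).

Window defaults: trailer 35 nt (the tRF-1 mapping space), leader 50 nt.
The leader length is a generous configurable default — tRF-1 biology
pins the trailer at ~35 nt, but no comparable convention exists for the
leader.  Flanks shorter than the window (contig edges) are truncated
with a warning, never padded.  Minus-strand genes are stored
coding-strand 5′→3′ on load; trailer extraction is strand-aware
(downstream in transcription direction).

## Classification rules

Matching is exact — no mismatches or indels.  This keeps the
identification deterministic and exhaustive; modification-tolerant
alignment is deliberately out of scope.  Per placement:

* mature: end at the mature terminus → `3p_trf` (regardless of start,
  CCA-inclusive); start within the 5′ tolerance and end short of the
  terminus → `5p_trf`; otherwise `i_trf`;
* trailer: start at position 1 (abutting the mature 3′ end) → `trf1`;
* leader: end at the leader's last base (abutting the mature start) →
  `5pU_trf`.

The 5′ start tolerance is 1, or 2 for His genes: the His `G−1` is not
genomically templated, so a genomically-derived 5′ fragment begins at
mature position 2; without the His exception such fragments would be
misclassified as internal.  When placements span classes the highest
precedence class wins — mature (3p > 5p > i) > trailer > leader,
mature-space identity being biologically primary — and conflicting
placements are dropped with a log message.

A 5′ fragment is flagged as a 5′ half (tiRNA) when it is ≥ 30 nt; if
the anticodon position is annotated in the metadata, ending within
[anticodon_start − 2, anticodon_start + 4] overrides the length
heuristic, approximating anticodon-loop cleavage.

Names follow `tDR-<start>:<end>-<Isotype>-<Anticodon>-<family>[-M<k>]`,
with the span taken from the lexicographically smallest (gene, start)
mature placement and `k` the number of *distinct mature sequences*
containing the fragment (isodecoders with identical bodies collapse).
Leader/trailer fragments keep their signature ids — a mature-span name
does not apply.

## Quantification

A read supports a signature iff it equals the signature sequence over
its full length (case-insensitive, U→T).  Full-length equality keeps
assignment unambiguous even when one signature is a suffix of another
(as with nested 3′ fragments such as spans 60:76 vs 55:76 of the same
mature tRNA); prefix/suffix matching would double-count.  Expression is
log2(count/denominator × 10⁶ + 1) with the denominator either the
total library reads (default, the TCGA miRNA-seq convention) or the
catalog-assigned total.  The detection filter keeps signatures with a
nonzero count in ≥ 50% of samples by default (configurable) — a stated
stand-in for "available expression abundance", which has no canonical
definition.

## Differential expression

Per signature, a tumor-vs-normal contrast on log2 expression: paired
(one-sample t on pair differences) when pair ids completely match one
tumor to one normal, otherwise unpaired with pooled variance; auto mode
degrades to unpaired with a warning when pairing is incomplete, which
is the usual situation with unequal group sizes.  Shrinkage follows the
standard empirical-Bayes treatment: sample variances are modeled as
s² ~ s₀²·F(d, d₀); (d₀, s₀²) are moment-matched on log s² via digamma/
trigamma identities (Newton inversion of the trigamma function); the
posterior variance is s̃² = (d₀s₀² + d·s²)/(d₀ + d) and the moderated t
has d₀ + d degrees of freedom, capped at the pooled residual df.  When
the log-variance spread is no wider than chi-square sampling alone
explains, d₀ = ∞ and s₀² is the arithmetic mean of the variances.  Two
implementation details matter for parity with the reference
implementation (limma's eBayes, against which the test suite checks
agreement at ~1e−15 via Rscript): the infinite-d₀ scale rule and the
pooled-df cap.  Zero-variance signatures are excluded from the prior
fit but still shrunk.

The significance gate is strict: |log2FC| > 1 AND p < 0.05 on the raw
p-value.  BH q-values are reported alongside but not used for the gate.
A Welch-t fallback (`method="welch"`) exists purely for
cross-validation of the moderated path.

## Survival analysis

Tumor samples are dichotomized at the median of the signature's
expression; ties go to the "low" group (a choice that must be stated —
conventions differ), and an all-identical vector is a degenerate-split
error.  The Kaplan–Meier estimator is the textbook product-limit with
right censoring; the two-group log-rank test sums hypergeometric O−E
and variance over distinct event times (chi-square, 1 df).

Cox regression maximizes the Breslow partial likelihood by
Newton–Raphson with analytic gradient and information matrix
(cumulative-sum formulation over descending times), tolerance 1e−8 on
the score norm, 50 iterations maximum.  Breslow tie handling is the
simplest correct choice; with continuous (untied) times it coincides
with Efron, which is how the lifelines cross-check in the tests is
arranged.  Covariates are centered for numerical stability (the
estimate is invariant); categorical covariates are dummy-encoded
against a stated reference level.  Monotone likelihood (perfect
separation) is detected as a vanished score at an extreme coefficient
(|β| > 10) and reported as non-convergence with no estimates — a plain
gradient criterion alone would silently "converge" on separated data.
Wald tests and CIs are exp(β ± 1.96·SE).  Univariate sweep mode fits
one model per original covariate, keeping a categorical covariate's
dummies together, mirroring the usual forest-plot layout.

The chi-square association test is Pearson's without continuity
correction; a zero expected count is an error advising category
merging.  Spearman correlation is Pearson on average ranks with the
t approximation for p; the top-k table (default k = 500) is ordered by
|ρ| descending, then ρ, then gene id.

## Enrichment

ORA: hypergeometric upper tail P[X ≥ k] with BH correction across
sets; the universe defaults to the expression matrix's genes and query
genes outside it are dropped with a warning.  GSEA: weighted KS running
sum (hit steps |score|^w normalized over the set, default w = 1; miss
steps 1/(N−K)); ES is the extremum by absolute value.  The null
permutes gene labels — appropriate because the module receives a
ranked list, not raw expression, so phenotype permutation is
unavailable; this is a documented deviation from the classic
phenotype-permutation scheme.  NES divides ES by the mean |permuted
ES| of matching sign and the p-value carries a +1 pseudo-count.
Gene-set content is always user-supplied GMT; no database is fetched.

## Target scanning

The seed is fragment positions 2–8 (5′→3′).  A site is the UTR
occurrence of the reverse complement of positions 2–7, upgraded by a
match to position 8 (m8) and/or an adenosine opposite position 1 (A1):
8mer > 7mer-m8 > 7mer-A1 > 6mer, each site reported once at its best
type, overlaps allowed.  Duplex support is a Smith–Waterman-style local
alignment of the fragment against the reversed UTR window (≤ 60 nt):
Watson–Crick +1, G:U wobble +0.5, mismatch −1, gap open/extend −2/−1.
A prediction passes with ≥ 1 seed site and best window score ≥ half the
fragment length (configurable).  This scorer is deliberately
transparent — no thermodynamics, no AGO-CLIP evidence — so the stage is
fully testable against enumeration oracles.  One symmetry caveat: a
wobble-aware pairing score is symmetric under argument swap but not
under reverse-complementing both inputs (G:T maps to C:A), so the swap
symmetry is what the property tests assert.

## Synthetic data

The generators emulate the statistical structure of a tumor/normal
small-RNA cohort at desk scale.  Defaults are the study conditions the
analyses assume: 16 tumors vs 9 controls; negative-binomial counts
(variance μ + φμ², φ = 0.3, a typical bulk small-RNA overdispersion;
no count model is canonical here and NB is the field standard) around
a baseline mean of 200 with planted log2 fold changes; exponential
survival with hazard λ₀·exp(β·z) on the standardized log2 expression
of designated biomarkers plus independent uniform censoring; a binary
pathology covariate with logistic dependence on the biomarker; an mRNA
matrix tied to the biomarker through a Gaussian copula (latent Pearson
r = 2·sin(πρ_s/6) for a target Spearman ρ_s, monotone-mapped so ranks
are preserved; |ρ_s| > 0.99 rejected as infeasible); FASTQ reads that
reproduce the count matrix exactly at zero error rate, with optional
per-base substitution noise and background reads rejected-sampled to
match no signature; and UTRs with one planted seed site each,
background-checked to contain no spurious core.

The reference generator always plants one His-GTG isodecoder pair
sharing its 3′ end so that 3′ fragments multimap and exercise the
`-M<k>` naming path.

What the simulations do *not* model: RNA modifications and alignment
artifacts, adapter/quality issues, sequencing-depth heterogeneity
beyond library size, batch effects, and non-proportional hazards.
Passing parameter-recovery tests therefore demonstrates correctness of
the estimators under their own assumptions, not robustness to real
TCGA-grade data.

## Problem sizes and calibration checks

The validation suites run at sizes chosen to keep Monte-Carlo noise
inside the tolerance being checked: the DE type-I error uses one
2000-signature null at 16 vs 9; DE power uses 200 replicates of a
4-fold effect at σ = 0.3; Cox recovery uses 200 replicates of n = 500
with a unit log-hazard and a U(0, 7) censoring horizon calibrated to
censor ~20% of subjects (200 replicates put the coverage estimator's
sd near 0.015, well inside the ±0.04 band asserted); the classifier
oracle draws 1000 random fragments; target recall uses 100 planted
UTRs.  `scripts/acceptance.py` re-runs the same computations from a
single command-line seed.

## Known limitations

* Exact matching misclassifies fragments carrying sequencing errors or
  modifications-induced misreads; they simply fail to place.
* tRFdb/tRFexplorer accession numbering is treated as input ids, never
  derived.
* The duplex scorer's threshold (half the fragment length) is a
  screening heuristic, not an affinity model.
* The Cox implementation handles ties by Breslow only; heavy ties with
  small risk sets would favor Efron or exact methods.
* Mitochondrial tRNAs and tRNA gene prediction are out of scope; the
  reference gene set is entirely user-supplied.
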