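# tsrnakit

Identification, quantification and cohort biomarker statistics for
tRNA-derived small RNAs (tsRNAs / tRFs).

tsRNAs are 16–35 nt fragments cleaved from mature or precursor tRNAs.
They fall into five positional classes relative to the parental gene:
5′-tRFs, 3′-tRFs (CCA-inclusive) and internal i-tRFs from the mature
tRNA, plus 5′U-tRFs from the 5′ leader and tRF-1 fragments from the 3′
trailer of the primary transcript.  Several of them behave as
tumor-associated small RNAs: their abundance in small-RNA-seq separates
tumors from matched controls, stratifies survival, and — because a tRF
loaded into Argonaute can seed-pair with 3′UTRs like a microRNA —
suggests direct mRNA targets.  `tsrnakit` packages that entire desk-side
workflow for bioinformaticians analyzing small-RNA-seq cohorts:

* **reference** — build the mature-tRNA / leader / trailer sequence
  spaces (intron excision, unconditional 3′ CCA, His G−1; trailer
  window 35 nt, leader window 50 nt);
* **classify** — place candidate fragments by exhaustive exact matching,
  assign the five tRF classes, count multimapping across isodecoders,
  and parse/format tDRnamer-style names such as `tDR-60:76-His-GTG-1-M2`
  (mature span 60–76, His-GTG family 1, found in 2 distinct mature
  sequences);
* **quantify** — exact full-length read counting per signature,
  log2(reads-per-million + 1) normalization, detection filtering;
* **cohort** — moderated-t differential expression (empirical-Bayes
  variance shrinkage, gate |log2FC| > 1 and p < 0.05), median-split
  Kaplan–Meier with the log-rank test, univariate/multivariate Cox
  proportional hazards (Breslow ties, Newton–Raphson), chi-square
  pathology association, Spearman top-k correlated mRNAs;
* **enrichment** — hypergeometric over-representation and permutation
  GSEA against user-supplied GMT gene sets;
* **targets** — miRNA-like seed-site scanning (6mer/7mer-A1/7mer-m8/8mer,
  seed = fragment positions 2–8) plus a local anti-parallel duplex
  alignment score;
* **simulate** — seeded generators for every input (tRNA-like genes,
  negative-binomial counts with planted fold changes, exponential
  survival with expression-dependent hazard, Gaussian-copula mRNA
  correlation, FASTQ reads, UTRs with planted sites) so the whole
  pipeline is testable by parameter recovery.

The statistics follow the standard formulations.  The moderated t for
signature *g* is t_g = log2FC_g / (s̃_g·c) with posterior variance
s̃²_g = (d₀s₀² + d·s²_g)/(d₀+d), the prior (d₀, s₀²) moment-matched on
log-variances (it reproduces limma's eBayes to machine precision — see
the test suite).  The log-rank statistic is (ΣO−E)²/V with
hypergeometric variance per event time; Cox models maximize the Breslow
partial likelihood; GSEA uses the weighted Kolmogorov–Smirnov running
sum with a gene-label permutation null.

## Worked example

Everything is driven by one seeded command (also available stage by
stage: `build-ref`, `classify`, `quantify`, `de`, `survival`, `cox`,
`chisq`, `correlate`, `ora`, `gsea`, `targets`, `simulate`):

```bash
tsrnakit run-all --seed 3 --outdir runall
```

which simulates a 16-tumor / 9-control cohort, designates one 3′-tRF as
a biomarker (4-fold down in tumors, unit log-hazard per SD), runs every
stage, and prints:

```json
{
 "seed": 3,
 "n_catalog": 14,
 "n_detected": 14,
 "n_de_significant": 2,
 "biomarker": "sig-3p-004",
 "logrank_p": 0.05029257779352792,
 "cox_converged": true,
 "chisq": {"statistic": 2.2857142857142856, "df": 1, "p": 0.13057001811573693},
 "gsea_es": 0.9799999999999993,
 "n_target_pass": 3
}
```

Reading: all 14 simulated signatures were detected from the FASTQ reads;
2 passed the strict DE gate (the planted biomarker among them); the
median split of the biomarker's expression gives a log-rank p of 0.050
on 16 tumors (small-n survival is noisy by design — the Cox recovery
suites characterize the estimator properly); the GSEA enrichment score
of the planted correlated gene set is 0.98; 3 of 20 synthetic UTRs pass
the combined seed + duplex threshold.  Full tables (DE, KM curves, Cox
forest, correlations, ORA, targets) are written under `runall/`.

The library surface mirrors the CLI, e.g.:

```python
>>> import tsrnakit as tk
>>> tk.parse_tdr_id("tDR-60:76-His-GTG-1-M2")
TDRName(start=60, end=76, isotype='His', anticodon='GTG', family_index=1, multimap_count=2)
```

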