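# Methods

## Count model and differential expression

Counts are modeled as negative binomial with variance μ + αμ². The stages
are deliberately analytic so every number can be re-derived by hand or by a
brute-force oracle:

- **Normalization.** Median-of-ratios size factors: for sample *j*,
  s<sub>j</sub> = median over features with positive geometric mean of
  K<sub>ij</sub>/geomean<sub>i</sub>. If no feature is expressed in every
  sample this is undefined and the estimator raises (advising a
  pseudo-reference fallback) rather than guessing.
- **Dispersion.** Genewise α̂ by method of moments on normalized counts,
  using the pooled within-genotype variance so planted or real DE does not
  inflate it, and correcting the Poisson term for the size factors
  (E[s²] = μ·mean(1/s) + αμ²): α̂ = max(0, (s² − μ·mean(1/s))/μ²). A trend
  α(μ) = a/μ + b is fit by non-negative least squares on features with
  μ > 1 (genewise values capped at their 95th percentile so outliers do not
  drive the fit), and the final dispersion is a fixed 50/50 blend of
  genewise and trend, floored at 1e-8. The fixed-weight blend replaces an
  empirical-Bayes posterior on purpose: it has no tuning parameters and its
  behavior is provable in tests (Poisson data yields median final α below
  0.01; α = 0.2 data is recovered within a factor of two).
- **Wald test with a fold-change-threshold null.** Group means are taken on
  normalized counts with a pseudo-mean floor of 0.5 when forming the log
  ratio, so features seen in only one group get a large but finite LFC; an
  exactly zero LFC has sign 0 and is therefore never canonical downstream.
  The standard error follows from Var(mean of K/s) = μ·Σ(1/s)/n² + αμ²/n by
  the delta method on log μ. The statistic max(0, |lfc| − θ)/se with
  two-sided normal tails implements the composite null |LFC| ≤ θ: inside
  the band p = 1 exactly, and p is monotone non-decreasing in θ. mRNA
  contrasts use θ = 1, miRNA contrasts θ = 0. LFCs are reported unshrunk
  (an optional normal-prior shrinkage toward zero is available via
  `run_contrast(..., shrink=True)` for plotting, but sign and threshold
  calls always use the MLE); the adaptive-mixture posterior shrinkage some
  DE tools apply for reporting is intentionally out of scope.
- **Design.** Genotype effects are fit as pairwise two-group contrasts
  against WT, not a joint three-level GLM — only mutant-vs-WT comparisons
  are ever consumed. Contrasts whose two genotypes share no sequencing
  batch are refused as confounded; this is what makes a KO-vs-KI request on
  the two-batch miRNA design an error by construction. Features with
  all-zero counts in the used samples are excluded from testing and from
  the BH denominator; no further independent filtering, outlier handling or
  multi-factor modeling is done.
- **Multiple testing.** Benjamini–Hochberg step-up (via statsmodels) with
  NaN passthrough; DE is called at padj < 0.1.

## Pair compilation and network

miRNA identifiers are canonicalized before any matching: species prefix
stripped, the implied-default `-5p` suffix dropped, the distinguishing
`-3p` kept, the stem normalized to `miR`/`let` without a following dash.
Gene symbols match case-insensitively after trimming; database identifiers
with no counterpart in the DE results are reported via a warning, never
silently dropped. The supported set is the tri-database intersection
restricted to pairs whose miRNA and mRNA are both DE in the contrast;
direction is not constrained and many-to-many structure is preserved.

The graph is a pure function of the two supported-pair lists: nodes and
edges are inserted in lexicographic order, so exports are byte-reproducible
under input permutation. "Shared" on a node means it appears in supported
pairs of both contrasts (pair lists are the only input, and a feature only
enters one if it is DE there); "concordant" on an edge means present in
both contrasts with the same canonical status — the weakest consistent
reading of "the two mutants behave similarly", and it is stored as a flag
rather than hidden in the rendering. GraphML and edge-TSV exports round-trip
losslessly (floats are written with 17 significant digits and re-parsed in
round-trip mode); DOT is one-way. Rendering is best-effort matplotlib and
carries no quantitative claims; the magnitude→color intensity scale clips at
|LFC| = 4 by default, a display choice only.

## Enrichment and qPCR

Over-representation is the upper-tail hypergeometric P(X ≥ k) for a query
of size n against a set of size K in a universe of N, with BH across the
collection as the q-value (Storey-style estimators would need tuning; BH is
conservative and closed-form) and a 0.1 threshold. The universe defaults to
the expressed features supplied by the caller; ontology structure, term
redundancy and real annotations are out of scope — the module operates on
arbitrary named sets (GMT in/out).

Relative quantification is 2^−ΔΔCt with ΔCt = target − reference per sample
and ΔΔCt the difference of group means. The SEM is computed on
per-replicate folds 2^−(ΔCt_test,i − mean ΔCt_control) — the common
per-replicate-fold convention; with a single replicate it is NaN rather
than a fabricated zero. Amplification-efficiency correction is out of
scope.

## What the generator emulates — and what it cannot show

`synthetic` draws NB counts with log-normal baseline means (meanlog
log 100, sdlog 1.5), shared dispersion 0.05, per-sample size factors
uniform in [0.5, 2], and planted DE at exactly ±2^LFC in expectation, split
between KO-only, KI-only and both-mutant features (default ¼/¼/½, with
both-mutant features sharing one sign, so shared/concordant logic is
exercised). Defaults follow the study design where it is stated — six
mRNA-seq and five miRNA-seq replicates per genotype, ~15,000 genes, ~1,000
miRNAs, two miRNA batches with KI+WT in batch 1 and KO+WT in batch 2 (WT
replicates alternate between batches) — and conventional simulation values
elsewhere, since library sizes and dispersions of the real data are not
published. Target databases contain every planted pair plus decoys, a
controlled fraction of which is shared by all three; the remainder are
disjoint by construction, so the intersection is known exactly.

Passing tests therefore demonstrate statistical correctness of the
machinery — calibration under the null, recovery of planted effects,
exact set logic — on idealized data. They do not show robustness to what
real sequencing adds: per-gene dispersion variation, outlier samples,
GC/length biases, mappability artifacts, isomiR ambiguity, or annotation
mismatches beyond the name dialects the generator plants. The study's
published DE gene counts depend on its deposited raw reads and alignment
stack and are not reproduced here.

## Problem sizes used in checks

The automated checks run the DE calibration at 2,000 features × 6 vs 6
replicates over 10 seeds, planted-recovery at 100 strong signals
(|LFC| = 3, μ ≥ 200), the end-to-end run at 4,000 genes / 600 miRNAs, and
the acceptance script's study-scale pass at the full 15,000 × 1,000 — sizes
chosen so the whole suite completes in well under a minute on one core
while keeping Monte-Carlo noise far from the asserted bounds.
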