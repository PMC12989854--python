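# Methods

## Model and procedure

`genepace` treats the collection of per-gene pairwise distance
matrices as draws from a multivariate distribution over taxon pairs.
For genes g = 1..i on a fixed panel of N taxa, the pipeline is:

1. **Imputation.** Missing off-diagonal cells (taxa absent from a
   gene, or pairs below the shared-site threshold) are filled with the
   arithmetic mean of two components: the mean of the gene's observed
   off-diagonal values, and the mean of that taxon pair's observed
   values across genes. If only one component is defined it is used
   alone; if neither is, the gene or pair is dropped with a log entry.
   Imputation happens on the raw distance scale, before any transform,
   so imputed cells sit at the centre of the distribution and cannot
   masquerade as outliers. For the taxon-level pass the diagonal is
   additionally set to the taxon's row mean within the gene.
2. **Log transform.** x → ln(x + ε) with ε = 1e-6 (additive,
   configurable, recorded in report headers). The transform is
   strictly order-preserving; ε only matters for exact zeros (e.g.
   dN = 0), which map to ln ε rather than −∞.
3. **Gene scoring.** Upper triangles are stacked into an i × P matrix
   (P = N(N−1)/2, columns in lexicographic panel-pair order). Squared
   Mahalanobis distances use the column means and the sample
   covariance (denominator i−1): the exact inverse when full rank,
   otherwise the Moore–Penrose pseudo-inverse with relative tolerance
   1e-10 and a warning. An optional shrinkage intensity λ blends the
   covariance with its own diagonal (default 0).
4. **Flagging.** Outliers are *defined* as genes with D² strictly
   above the empirical 0.95 quantile (linear interpolation, numpy
   default). Ties at the threshold are excluded, so at most 5% of
   genes are flagged and reruns are deterministic. χ² upper-tail
   p-values (df = P) with Bonferroni multiplication by i are
   annotations, not the selection rule; when the covariance rank is
   below the nominal df a warning notes that the χ² reference is
   conservative.
5. **Driver taxa.** The tensor restricted to flagged genes is
   collapsed to an (i_outlier × N) × N matrix of full per-taxon rows
   (diagonal included) and scored the same way, with df = N and
   Bonferroni over the row count. Rows strictly above the 0.95
   quantile mark the (gene, taxon) pairs driving the outlier signal.

The key assumption is approximate multivariate normality of
log-distances within the bulk of genes; the covariance across taxon
pairs absorbs relatedness, shared branches, and gene-tree discordance
without a phylogeny being specified. Normality matters least exactly
where the method looks — the extreme tail is flagged by an empirical
quantile, not a parametric cutoff.

## Distances

* **Hamming** distances are proportions (mismatches over compared
  sites), not raw counts: counts confound alignment length across
  genes. Sites count as compared only when both taxa carry an
  unambiguous base; pairs sharing fewer than `min_shared_sites` (30)
  sites are missing.
* **dN/dS** uses Nei–Gojobori (1986) counting with Jukes–Cantor
  correction. Synonymous site fractions are computed per codon
  position over the non-stop single-nucleotide neighbours, so
  N + S = 3 × (compared codons) exactly; substitution paths through
  stop codons are excluded and differences averaged over the remaining
  shortest paths. These are known NG86 variants and are stated
  explicitly because implementations differ. Codons with gaps or
  ambiguity in either sequence are skipped; pairs under
  `min_shared_codons` (10) clean codons are missing; the correction is
  undefined (missing) at proportions ≥ 3/4. ω = dN/dS is missing
  wherever dS is zero or missing. NG86 was chosen over maximum
  likelihood codon models because it is closed-form, fast, and
  testable against exhaustive enumeration; an import path (square
  PHYLIP matrices or long TSV) accepts externally computed ML or
  cophenetic matrices when exact replication of an ML workflow is
  needed.

## Alignment preprocessing

Filters run per gene, in a fixed order: taxon count (default ≥ 9
taxa), reading-frame detection, internal-stop masking, codon-column
filters, information content (default ≥ 10 parsimony-informative
sites). Decisions the data forced:

* **Frame detection** trims 0–2 leading bases so that the final codon
  is a stop in every taxon whose terminal codon is free of gaps and
  ambiguity; if no offset satisfies all such taxa, the offset
  maximizing the ungapped-terminal-stop fraction is accepted when that
  fraction is at least one half. Alignments with no evaluable terminal
  codon at an offset do not satisfy the rule vacuously.
* **Internal stops** are masked to `---` (only when every IUPAC
  expansion of the codon is a stop), preserving matrix dimensions
  rather than discarding the gene. The terminal codon triplet is
  removed only when at least one unambiguous terminal codon actually
  is a stop — this makes the cascade idempotent: re-running
  preprocessing on its own output changes nothing.
* **Column filters**: a codon column is dropped when the gapped-taxon
  fraction exceeds 0.5 (over all taxa) or the heterozygous fraction
  exceeds 0.5 (over non-gapped taxa only, avoiding double-penalty).
  Both comparisons are strict. "Heterozygous" is operationalized as a
  codon whose IUPAC-ambiguity expansions translate to more than one
  amino acid — the natural reading for alignments derived from diploid
  genome calls, though other operationalizations exist.
* **Parsimony-informative site**: a nucleotide column with at least
  two distinct unambiguous bases each carried by at least two taxa;
  gaps and ambiguity codes never count as states.

## The simulator

`simulate_tensor` emulates the structure of a real ortholog panel:
dated pure-birth (Yule) trees; per-gene lognormal rate multipliers
ρ_g (σ = 0.3); multiplicative lognormal pairwise noise (σ = 0.1) drawn
independently for dS and dN, so the observed ω = dN/dS is itself noisy
— as it is when both distances are estimated from finite alignments;
taxon-wise missingness (5% — a missing taxon loses its whole
row/column in that gene, mirroring orthologs absent from some
assemblies); and ω accelerations (×5) implanted in 5% of genes.

Two design choices deserve emphasis:

* **Per-gene focal clades (default).** Each accelerated gene draws its
  own focal clade uniformly from the tree's internal clades, matching
  the empirical picture in which different clades share different
  accelerated-gene sets. Fixing one clade for all outlier genes (via
  `focal_clade=...`) is supported but is a much harder regime for any
  covariance-based detector: fifty genes deviating along one shared
  direction inflate the covariance along exactly that direction, and a
  classical-Mahalanobis breakdown bound caps their scores near
  (1−p)/p for outlier fraction p, regardless of effect size.
* **Both-endpoint acceleration (default).** ω is multiplied only for
  pairs with *both* endpoints inside the gene's focal clade, because
  only those pairwise paths lie entirely on accelerated branches; a
  cross pair's path is mostly outside the clade and its elevation
  would be diluted. The either-endpoint variant remains available, but
  note that it elevates every row touching the clade uniformly, and
  the taxon-level pass then singles out the *boundary* rows as most
  distinctive rather than the clade members.

The codon simulator evolves sequences codon-by-codon with exact
stochastic (Gillespie) simulation: proposal rates proportional to the
target-base frequency at the position, times κ for transitions and ω
for non-synonymous changes, stops forbidden; branch lengths are read
as expected substitutions per codon on the neutral scale. Estimator
consistency of NG86 is checked at κ = 1, the counting model's own
assumption; at κ = 2 NG86's well-known downward ω bias (~12% in our
measurements) reflects model mismatch, not estimator error, so the
data-generation default κ = 2 is deliberately not used for the
consistency check.

What the simulator does **not** emulate: alignment error, paralogy and
contamination, indels, codon-usage bias, coalescent gene-tree
discordance, among-site rate variation, and partial (branch-fraction)
acceleration of cross-clade pairs. Passing recovery tests therefore
demonstrate correctness of the machinery under a clean generative
model, not performance guarantees on real alignments.

## Numerical choices and degenerate inputs

* Quantile thresholds use numpy's default (linear) empirical quantile;
  flags are strict (`>`), so a vector of identical scores flags
  nothing, and ties at the threshold are excluded.
* Covariance rank is assessed against 1e-10 times the spectral norm;
  rank-deficient panels fall back to the pseudo-inverse with a
  warning. All-identical rows raise `DegenerateMatrix`.
* Pearson correlations use the product-moment formula with a two-sided
  t-transform p-value (n−2 df); a seeded permutation p-value is
  available. Zero-variance inputs raise `ConstantInput`; the CLI
  skips the correlation (with a log line) rather than aborting a run.
* Fisher's exact overlap test computes the hypergeometric upper tail
  directly; empty sets return odds ratio 0 and p = 1 by convention.
* Distance matrices are validated symmetric; imports average the two
  triangles when they disagree beyond 1e-8 (error in strict mode).
* Report writers emit deterministic ordering (sorted gene ids, panel
  order) and `#` headers with the resolved configuration, so reruns on
  identical inputs are byte-identical.

## Problem sizes

The test suite and `scripts/acceptance.py` run entirely on synthetic
data at desk scale, chosen to finish in seconds while leaving the
statistics well-resolved: recovery experiments use 20 replicates of
1000 genes × 16 taxa; null calibration uses 2000 genes at P = 45;
NG86 validation uses 500 random codon pairs against exhaustive
enumeration and 200 neutral two-taxon simulations of 500 codons; the
committed toy FASTA fixture is 12 genes × 10 taxa × 61 codons.

## Known limitations

* Distance matrices lose sequence-level information; the method
  cannot localize accelerations to ancient branches or separate a deep
  hybridization signature from a rate shift.
* The taxon-pair dimensions are highly non-independent; χ² p-values
  with df = P are heuristic annotations (the covariance rank is often
  below P), which is why outlier status is defined by the empirical
  quantile instead.
* With a single shared deviation pattern across many outlier genes,
  classical Mahalanobis scores saturate (see the breakdown bound
  above); a robust covariance estimator would be the natural
  extension.
* The quantile rule always flags ~5% of genes, even in data with no
  genuine outliers; the Bonferroni-adjusted p-values are the guard
  against over-interpreting flags in well-behaved panels.
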