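# Methods

## Model and procedure

`mrmr-eqtl` treats each genetic marker as an independent three-class
classification problem: the F2 genotype (1 = homozygous first parental
allele, 2 = heterozygous, 3 = homozygous second parental allele) is the
class label, and gene-expression profiles are the features. The mapping
workflow per SNP is:

1. Discretize every gene's expression to three states at mean ± t·SD
   (estimation only; classification uses the continuous values).
2. Rank genes by maximum relevance (MaxRel: mutual information with the
   genotype, in bits) and by greedy mRMR (relevance minus mean redundancy
   against the already-selected genes).
3. Score every prefix of the chosen ranking by leave-one-out
   nearest-neighbor accuracy under cosine distance (the IFS curve); the
   optimal affected-gene set is the shortest prefix attaining the curve's
   maximum.
4. Report the optimal set if its accuracy reaches the cutoff, annotating
   each SNP–gene pair as cis/trans/ambiguous by genomic distance.

All information quantities use the plug-in (maximum-likelihood) estimator
on empirical contingency counts, log base 2, no bias correction. The
estimator is deliberately simple: only the relative order of scores matters
for ranking, and the plug-in form is exactly reproducible by independent
contingency-table evaluation, which the test suite exploits. Conditional
mutual information (for covariate adjustment) uses the entropy identity
I(x;y|z) = H(x,z) + H(y,z) − H(z) − H(x,y,z), equivalently a stratified sum
over condition states.

Assumptions worth stating: markers are analysed independently (no joint
multi-locus model); samples with a missing call at a marker are dropped for
that marker only; markers with fewer than two observed genotype classes are
skipped; expression values are finite reals on a roughly comparable scale
(the cosine distance is scale-invariant per sample but not per gene).

## Parameters

| Parameter | Default | Units / range | Why |
|---|---|---|---|
| `discretize_t` | 1.0 | SD of each gene | Historical default of discrete-MI feature-selection software; 3 bins keep contingency tables well-populated at n≈100–250. |
| `k_rank` | 50 | genes | Depth of the mRMR list carried into IFS; bounds LOOCV cost (O(K·n²) per SNP) while exceeding plausible affected-set sizes. |
| `mrmr_scheme` | `mid` | {mid, miq} | Difference criterion is the canonical default; quotient available. |
| `ifs_list` | `mrmr` | {mrmr, maxrel} | Which ranking IFS consumes; user-selectable by design. |
| `accuracy_cutoff` | 0.90 | LOOCV accuracy | Reporting threshold on the optimal set's overall (not per-class) accuracy. |
| `cis_window_bp` | 5,000,000 | bp | Same-chromosome SNP-to-gene-start distance, inclusive, under which a pair is cis. |
| `threads` | 1 | — | Per-SNP parallelism (joblib); results are independent of the thread count. |

Coordinate conventions: 1-based base pairs; the gene anchor is its
transcription start; the cis window is inclusive ("within 5 Mb").

## Numerical choices

- **Exact MI symmetry.** Contingency cell terms are summed in sorted order
  and the two marginal sums are grouped before subtraction, so
  I(x;y) and I(y;x) are bitwise identical and genes whose tables are
  permutations of one another receive bitwise-equal scores.
- **Tie-breaking.** Greedy mRMR breaks ties by input gene order, treating
  scores within 1e-12 of the round maximum as tied. The tolerance is needed
  because two genes can have mathematically equal scores (permuted
  contingency tables) that differ in the last float ulp; without it the
  winner would depend on summation order rather than on anything
  scientifically meaningful. IFS ties on maximum accuracy go to the
  smallest prefix (parsimony). Nearest-neighbor distance ties go to the
  smallest sample index.
- **Degenerate inputs.** A constant gene discretizes to all zeros (zero MI
  with everything). A zero-norm feature vector in classification is an
  error, not silently handled — it indicates degenerate gene selection
  upstream. The quotient mRMR scheme floors redundancy at 1e-12. The Welch
  t-test falls back to a sign comparison of means when both groups have
  zero variance.
- **IFS cost.** The Gram matrix of the prefix features is grown one gene at
  a time, so a full K-point curve costs O(K n²) rather than O(K² n²); each
  curve point still equals an independent jackknife on that prefix (tested
  per-point).
- **Covariate adjustment** replaces relevance MI with conditional MI given
  the joint covariate state; redundancy between genes remains unconditional,
  since it models co-expression rather than genotype association. With no
  covariates the two code paths are bit-identical.

## Synthetic data generator

The generator emulates the statistical structure of an F2 intercross eQTL
study, not any particular organism's biology:

- **Genotypes**: per sample, two gamete haplotypes are two-state Markov
  chains along each chromosome with switch probability r (default 0.1)
  between adjacent markers; genotype = allele sum. Unlinked markers
  segregate 1:2:1; adjacent-marker genotype concordance follows
  (1 − 2r(1−r))². Markers sit on a uniform grid (default 1 Mb spacing,
  5 chromosomes).
- **Expression**: e_g = μ_g + a·(geno − 2) + d·1(geno = 2) + Σ_parents
  w·e_parent + N(0, σ²), evaluated in one pass over a directed acyclic
  small-world network (Watts–Strogatz ring, mean degree 10, edges oriented
  from lower to higher gene index, weight ±0.3). Effects a and d are in
  units of the noise SD (default σ = 1).
- **Planted structure**: planted genes are grouped into per-SNP blocks
  (`pleiotropy`, default 5; `trans_pleiotropy` optionally larger). An eQTL
  that regulates a small module of genes is both what hotspot-style real
  data look like and what a network-propagation benchmark generator
  produces; it is also what makes a ≥ 0.90 LOOCV accuracy attainable — a
  marker whose genotype moves a single gene cannot be predicted that
  reliably from expression, however strong the effect, because one
  informative feature among noise carries too little geometry for a
  cosine nearest-neighbor classifier. Cis genes are placed within the cis
  window of their SNP; trans genes are forced outside it (other chromosome
  or beyond the window). Ground truth records only the direct SNP → gene
  plantings.
- **Defaults** follow the published benchmark conditions where stated
  (population 250, 1000 genes and SNPs, small-world topology, mean degree
  10); everything else is this generator's own choice of a realistic
  design.

What the generator does **not** model: steady-state regulatory dynamics
(one propagation pass only), epistasis, sex effects, genotyping error,
probe-level artefacts, or heavy-tailed expression noise. Passing tests on
this generator therefore demonstrate correctness of the algorithms and
qualitative behaviors (non-linear detection, cis > trans score ordering),
not performance on any real dataset.

## Evaluation harness

Precision–recall is computed tie-aware over an explicitly supplied candidate
universe (unscored pairs count as lowest-scored, so the recall denominator
is always the full truth set); AUPR is the average-precision step integral,
not a trapezoid, which avoids the optimistic interpolation bias of
trapezoidal PR areas. RAUPR rescales a set of AUPRs by their maximum.
Consensus counting reports the fraction of a reference table's (snp, gene)
pairs confirmed by at least k other tables.

The hypergeometric enrichment test is the exact upper tail P(X ≥ k)
(scipy's survival function); no multiple-testing correction is applied by
default, with a Bonferroni option. The calibration check in the test suite
uses a (N, K, n) configuration whose discrete null rejection probability at
α = 0.05 is ≈ 0.047 — for coarser configurations the exact test is
conservative and the rejection rate drops well below nominal, which is a
property of the discreteness, not an implementation artefact.

## Study conditions used by tests and the acceptance script

Simulation-backed checks run at desk scale, chosen once: planted-effect
recovery uses 250 samples, 50 SNPs × 200 genes, additive effects of 3 SD;
the cis-versus-trans comparison uses 200 samples, 16 SNPs × 84 genes on a
4 × 40 Mb genome with cis blocks of 5 genes at a = 3.5 and trans hotspots
of 8 genes at a = 2.0 (stronger-but-fewer cis, weaker-but-more trans — the
ordering the method is expected to recover); the non-linearity contrast
uses dominance-only effects (a = 0, d = 3). The 10 Mb marker spacing in the
cis/trans setting keeps the 5 Mb cis window from covering entire
chromosomes, so chance same-chromosome pairs are not all called cis.

## Known limitations

- Per-SNP independence means linked markers produce largely duplicated
  affected-gene sets; no peak-collapsing across markers is attempted.
- The plug-in MI estimator is biased upward at small n; since every gene is
  scored on the same samples the ranking is unaffected, but absolute bit
  values should not be compared across sample sizes.
- The accuracy cutoff is a hard threshold, not a significance level; no
  genome-wide error-rate control is provided.
- Cosine distance ignores per-gene scale differences; expression should be
  normalized upstream if genes live on wildly different scales.
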