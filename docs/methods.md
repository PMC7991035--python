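# Methods

## Statistical model of the association scan

For one trait × treatment × experiment combination, the phenotype
vector `y` over `n` genotypes is modelled as

    y = μ + P β + x_j b_j + u + e,
    u ~ N(0, K σ²_g),   e ~ N(0, I σ²_e),

where `x_j` is the minor-allele dosage of marker `j`, `P` holds the
leading principal components of the centred dosage matrix, and `K` is
the VanRaden genomic relationship matrix

    K = Z_c Z_cᵀ / (2 Σ_j p_j (1 − p_j)),

with `Z_c` the mean-imputed dosages centred at `2p_j`. Monomorphic
markers are excluded from `K`; with Hardy–Weinberg proportions the
diagonal averages ≈ 1 + inbreeding.

Variance components are estimated once by REML on the **null** model
(no marker term) — the P3D/EMMAX approximation — and held fixed for
the per-marker tests. The restricted likelihood is profiled in the
variance ratio δ = σ²_e/σ²_g on the eigenbasis of `K`: a 41-point
log-scale grid over δ ∈ [e⁻¹⁰, e¹⁰] brackets the optimum, refined by
bounded 1-D minimization to an `xatol` of 1e−8 in log δ (well below
1e−6 in restricted log-likelihood near the optimum). Eigenvalues are
clipped at zero; a kinship whose smallest eigenvalue is below −1e−8
(relative) is rejected as non-PSD.

Given δ̂, every marker is tested by generalized least squares in the
whitened basis: covariates are projected out by QR, the marker slope
`b̂_j` gets a Wald t-test with `n − q − 1` degrees of freedom (q =
intercept + PCs), and the residual variance is re-estimated per
marker. Setting σ²_g = 0 makes the whitening the identity, so the scan
reduces *exactly* to ordinary least squares — this limit is an oracle
in the test suite, as is a dense explicit-inverse GLS implementation.

Compressed mixed models additionally cluster individuals into kinship
groups before fitting. The group count used by the original tooling is
not fixed by any principle, and the uncompressed model is the exact
special case of one group per individual, so this package fits the
uncompressed model; at the panel sizes involved the scan is a
per-marker vectorized weighted regression and compression would buy
nothing.

Reported per marker: MAF, `b̂` (trait units per minor-allele copy),
p, −log₁₀ p, and `r²_model` — defined here as the squared correlation
between the fixed-effect fitted values (intercept + PCs + marker) and
the phenotype, since the quantity printed in association summaries of
this kind is rarely given a formula.

**Marker-based heritability** is `σ²_g / (σ²_g + σ²_e)` from the same
null REML fit.

## Relative traits

`relative = value(HNT) / value(CNT)` per genotype, trait and
experiment. Genotypes missing either arm are excluded (logged);
`CNT = 0` is excluded with a warning since the ratio is undefined.

## Locus calling

Markers with −log₁₀ p ≥ 3.5 (configurable) are visited in ascending p,
ties broken by chromosome then position (the source analysis is silent
on ties; determinism requires a rule). A marker is accepted unless an
accepted peak on the same chromosome lies within 100 kb. For the
chained case (A–B and B–C within the window, A–C not), greedy-by-p
resolution is the interpretation adopted for "lowest p within
100 kb": the best peak wins and suppresses both neighbours. The greedy
result equals the lexicographically minimal maximal independent set of
the conflict graph, which the tests verify by exhaustive enumeration.

**Allelic effect** = mean(phenotype | dosage ≥ 1) − mean(phenotype |
dosage = 0). Heterozygotes count as minor-allele carriers; in the
inbred panels this analysis targets, heterozygotes are rare and the
choice is immaterial, but it must be fixed for the simulated
outbred-like genotypes. The favorable allele is the carrier group in
the beneficial direction, per a configurable trait-direction map
(yield, seed weight, harvest index, grain dimensions: higher is
favorable; chalkiness: lower). Equal group means yield effect 0 and an
indeterminate ('?') favorable allele.

**Locus comparison** classifies pairs from different contexts as
`identical_snp` (same peak name) or `proximal` (same chromosome,
≤ 100 kb, configurable); a second, wider distance tier
(`region_group_bp`, default 0.49 Mb) is exposed for LD-region-level
grouping. Both relations are reported because shared-locus statements
in this literature mix exact identity and proximity.

## Candidate-gene windows

The window is the 1-based closed interval
`[max(1, peak − 50 kb), peak + 50 kb]`; *any* overlap of a gene's
interval with the window counts (the alternative — gene start inside
the window — silently drops boundary-spanning genes). Only GFF3
features of type `gene` are used; strand is carried but never
filters. Windows are peak-centred. Pooling across loci partitions
candidates into absolute-only / relative-only / shared, which always
sums to the pool size.

## Differential-expression channel

The published analysis used edgeR on an HNT time course; the
prioritization consumes only the binary "DE at any time point at
FDR < 0.05" flag, so this package re-implements the minimal pipeline:

* **TMM normalization** — reference library = closest upper-quartile
  rate to the mean; gene-wise log2 ratios trimmed 30% (two-sided) by M
  and 5% by abundance, averaged with inverse asymptotic-variance
  weights; factors rescaled to geometric mean 1. Agrees with edgeR's
  `calcNormFactors` within 2% on a composition-shifted matrix (tested
  against `Rscript`/edgeR as an independent reference).
* **Common dispersion** — method of moments, `(s² − m)/m²` pooled by
  median over replicate groups with positive means, floored at 1e−4.
  Tagwise/trended dispersion and the GLM framework are deliberately
  out of scope.
* **Exact test per time point** — counts are rescaled to a common
  effective library size (rounded), replicate-group totals are NB with
  size n/φ, and the two-sided p sums conditional split probabilities
  no more likely than observed. Totals above 50,000 switch to a normal
  approximation of the conditional split.
* **BH correction within each time point**; a time point missing
  either condition is skipped with a warning.

Flags: *untestable* if the gene's total count across libraries is
below the number of libraries (the "no detectable expression" state;
the source analysis names the state without a cutoff, so the floor is
one expected read per library); *supported* if FDR < 0.05 at ≥ 1 time
point; *failed* otherwise.

## Network and rank channels

Network: only edges where the candidate is the **target** of a
transcription factor count — a candidate that is itself a TF with
outgoing edges is not thereby supported. Scores are integers in
[0, 871]; the strong subset is score ≥ 200 (inclusive). A gene absent
from the full network (no edge touches it) is untestable; present with
no strong incoming edge is failed. "Could not be tested" is modelled
as node absence rather than absence of strong edges, the reading that
keeps failure meaningful.

Rank: supported if ranked ≤ 2 (configurable) in **any** containing
locus, matching the per-locus phrasing of the rank tool's output; a
gene with no rank row in any of its loci (locus never ranked, or gene
dropped) is untestable. Duplicate ranks within a locus are a
validation error.

## Voting

With flags (DE, network, rank) ∈ {supported, failed, untestable}³:

    high  ⇔  n_supported ≥ 2,  or  (n_supported ≥ 1 and n_failed = 0)

i.e. a failure in any *testable* channel blocks single-channel
promotion, and untestability is never penalized. All 27 combinations
are enumerated in the tests. Output is sorted by (supports desc,
failures asc, gene id) and is input-order independent.

## Synthetic data

The generators emulate the statistical structure of the study inputs,
not the inputs themselves:

* **Genotypes** — ancestral frequencies uniform on (0.1, 0.9);
  subpopulation frequencies Beta-distributed around them with
  Balding–Nichols concentration (1 − F)/F, F = `fst_like_divergence`
  (default 0.1; F = 0 is the exchangeable limit). LD: haplotypes share
  a latent Gaussian factor per block (default span 20 kb) whose
  loading decays exponentially with the marker's offset into the
  block, so adjacent-marker r² decays with distance and vanishes
  across blocks; the Gaussian copula preserves marginal frequencies.
  Dosages are re-oriented to the minor allele on *observed* calls
  (after any missingness mask) so that file round trips are exact.
  Marker names follow the `Chr{c}pos{p}.1` convention of the study's
  tables.
* **Phenotypes** — value = baseline (10 SD units, so ratios are
  well-behaved) + scoped QTL effects (SD units per minor-allele copy)
  + polygenic term `Z_c α` with `cov = h² K` exactly + iid noise of
  variance 1 − h². HNT-only/CNT-only scoping *is* the planted
  G×treatment component; both arms share the polygenic term.
* **Expression** — NB counts (dispersion 0.1) over control/HNT ×
  3 time points × 3 replicates; library sizes geometrically spaced
  over a 2.5-fold range to exercise normalization; planted genes get a
  fixed baseline mean of 100 so the planted log2FC is identifiable.
* **Annotation / network / ranks** — one gene per equal-width slot per
  chromosome (guaranteed non-overlap and window coverage); TF fraction
  0.1 with uniform integer scores on [0, 871]; per-locus rank
  permutations with configurable missing fraction and unranked loci.

One master seed derives a fixed-key child stream per stage, so outputs
are bit-reproducible and adding, say, a DE spec never perturbs the
genotype stream.

What the generator does **not** emulate: realistic rice LD maps or
allele-frequency spectra, ascertainment of the study's 45,200 SNP
panel, shared-nursery phenotype correlations, count over-dispersion
heterogeneity, or network topology beyond density. Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical assumptions, not performance on real rice data.

## Problem sizes and numerical choices

Replicated experiments (in `hntgwas.experiments`) use panels of 500
genotypes with 200–1000 markers and 50–100 replicates — large enough
for stable empirical rates while keeping a full run to about a minute
on one CPU; the end-to-end causal-recovery experiment uses 400
genotypes × 20 replicates of the entire pipeline. Numerical guards:
eigenvalue clipping at 0 for PSD kinships, p-values clipped away from
0, zero-variance markers dropped with a logged count, mean imputation
of missing dosages, and phenotype-missing samples dropped per trait.

## Known limitations

* Dispersion is common across genes; strongly heterogeneous
  over-dispersion will mis-calibrate the DE channel at the tails.
* The exact test rounds rescaled pseudo-counts; with very small counts
  and very unequal libraries this loses a little information relative
  to quantile-adjusted conditioning.
* The scan assumes a single variance-component structure (no
  dominance, epistasis, or multi-trait modelling), and p-values use
  the P3D approximation rather than per-marker REML.
* Significance uses the fixed −log₁₀ p = 3.5 convention, not
  Bonferroni; the threshold is configuration, not inference.
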