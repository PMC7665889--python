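# Methods

## Imprinting classification

For each candidate gene (curated known-imprinted list ∩ autosomes ∩
expressed genes ∖ exclusions), allelic reads pooled over the wild-type
samples define the log-ratio λ = ln(Σm) − ln(Σp). Treating each haplotyped
read as a Bernoulli trial, λ is the maximum-likelihood intercept of an
intercept-only binomial logistic regression, so the closed form replaces
an iterative fit; the two agree to better than 10⁻⁸ (checked against the
IRLS fit in the tests). The pooled form weights samples by their allelic
depth — the literal optimum of the binomial model. A gene is imprinted
when |λ| ≥ ln 1.5; the silent allele is paternal when λ > 0. When exactly
one pooled sum is zero a Haldane–Anscombe pseudocount of 0.5 enters both
sums; both zero gives NA.

Expression is defined on the non-haplotyped totals: CPM ≥ 1 in at least a
third of libraries, compared as a real number (2 of 6 libraries passes,
2 of 7 does not). Library size is the per-sample sum of gene totals; no
between-sample normalization factors enter the filter. Genes whose mean
haplotyped coverage over informative samples drops below 10 in any
genotype are kept in the call table but flagged non-testable. *Gatm* is
excluded by default (its maternal bias in placenta reflects decidual
contamination, not imprinting).

## Differential imprinting

The quantity of interest is the silent-allele proportion
p_s = silent/(m+p) per gene and sample (NA at zero informative depth).
The silent-allele direction is fixed from wild type and reused for every
genotype.

**Paired negative-binomial engine** (complete designs). Each sample
contributes its (maternal, paternal) pair as two NB observations with log
link. The design holds one indicator per sample — the pairing factor,
absorbing total expression so that the totals are ancillary — plus an
allele main effect, allele × genotype interactions, and allele × Cre
interactions when both Cre lines are present (config `cre_in_model`; the
calling rule evaluates per-Cre effects either way). The likelihood-ratio
statistic 2(ℓ_full − ℓ_null) for dropping the allele × genotype columns is
referred to χ² with df = number of dropped columns. In the dispersion → 0
limit this reproduces the binomial logistic LRT on the allelic proportions
exactly (tested). Samples with zero paired counts are dropped; a genotype
left without usable samples makes the design non-identifiable and yields
an NA result with the reason recorded.

**Dispersion.** NB2 parametrization (variance μ + φμ²). The Cox–Reid
adjusted profile likelihood APL_g(φ) = ℓ_g(φ; β̂) − ½ log det(XᵀWX) is
evaluated on a fixed 25-point log-spaced grid over [10⁻⁴, 3] and the
maximizer refined by quadratic interpolation in log φ. *Common* mode
maximizes the mean APL across genes; *tagwise* maximizes
APL_g + w · mean-APL with prior weight w = 10 equivalent genes, shrinking
gene-wise values toward the common one. This is a deliberate, documented
approximation to weighted-likelihood empirical Bayes; common mode is exact
and available wherever strict reproducibility matters (it is the default
for methylation and intended for sparse single-embryo data). Recovery is
validated by simulation (true φ = 0.1 estimated within [0.07, 0.13] over
200 genes; Poisson data estimated ≤ 0.01).

**Beta-binomial engine** (mosaic designs). When informativeness varies
across samples — N1 backcrosses lose about half of the allelic matrix —
per-gene dispersion cannot be estimated, so the maternal count given the
informative depth is modelled beta-binomial with logit-linear mean
(intercept + genotype) and intraclass correlation fixed at φ = 0.01
(variance nπ(1−π)(1+(n−1)φ), matching the generator's parametrization so
simulated and fitted dispersions are commensurable). Maximization is BFGS
with analytic gradient from empirical-logit starts, gradient tolerance
10⁻⁸, linear predictor clipped to ±30 to tame boundary fits; no random
restarts, so fits are deterministic. The LRT of the genotype terms against
the intercept-only null uses χ² df = groups − 1.

**Calling rule.** BH adjustment runs within one experiment's tested-gene
family. A gene is called when p_adj < 0.05 and |Δ| > 0.05, where Δ is the
difference of unweighted per-sample means of p_s (test − wt); for
placental designs with both Cre lines, Δ is computed per Cre stratum and
the guard may be met by either. Mean-of-proportions (rather than pooled
counts) matches per-sample visualization and is exactly unbiased given
depth; its bias is re-measured by the acceptance script (|bias| ≤ 0.01 at
n = 8/group, depth 100).

Under each engine's own null model the empirical rejection rate at
α = 0.05 over 2000 simulated genes stays within [0.035, 0.065]
(re-measured by the acceptance script for the beta-binomial, the paired NB
and the DMR test).

## Informativeness segmentation

Per sample and chromosome, the Cast-read proportion in 100 kb bins is fit
by a binary regression tree on bin index: splits minimize within-segment
SSE, require ≥ minsplit (4) observations in the node, and are accepted
only when they reduce SSE by ≥ cp (0.05) × that chromosome's root SSE —
the documented meaning of the rpart parameters. Equally good splits take
the leftmost index. Bins with fewer than 5 allelic reads (config
`min_bin_depth`) are treated as missing: skipped by the fit, spanned by
the enclosing segment. Leaves become segments; a segment is heterozygous
when its fitted proportion ≥ 0.25 (config `zygosity_threshold`, the
midpoint between the expected 0.5 and ≈0; the source protocol does not
state the leaf→zygosity rule, so it is config-exposed). A gene is
informative for a sample when its midpoint falls in a heterozygous
segment; F1 samples bypass segmentation entirely.

The greedy fit equals exhaustive optimal recursive splitting (verified
against a brute-force splitter on fixtures up to 64 bins). A structural
limitation follows from the cost-complexity rule: an interior block much
shorter than its flanks cannot be isolated, because a single split's SSE
reduction falls below cp × root SSE. Real first-generation backcrosses
rarely produce such blocks (about one crossover per chromosome per
meiosis, and crossover interference suppresses close double crossovers),
but segmentations of data with megabase-scale conversion tracts would
miss them.

## Methylation

Per-CpG methylated/unmethylated counts (0-based positions) are summed
over half-open regions; overlapping regions each receive a CpG. Testable
germline DMRs require mean haplotyped coverage ≥ 10 per sample in both
wild-type and tested genotypes and a wild-type allelic methylation
difference ≥ 10 points; the hypermethylated allele is the wild-type-higher
one. Its methylated and unmethylated counts enter the paired NB engine
(pairing within sample mirrors the allelic design; the protocol names only
"paired-sample design") with the common dispersion estimated across tested
regions — capped at the first 500 regions for large panels, well past
where the estimate stabilizes. Calls at BH-adjusted p < 0.05.

Genome-wide tests (CpG islands, promoters, 10 kb bins) use the unsplit
counts: regions with < 10 total counts are excluded, each remaining
region gets a binomial logistic LRT of genotype, BH correction, and a
call requires p_adj < 0.05 plus ≥ 10 points of mean methylation
difference. Regions are annotated with the nearest gene within 2 kb
(interval distance, 0 when overlapping; ties to the smaller start
coordinate).

Single-embryo QC: in a cross with a Cast sire, a female embryo carries a
paternal X, so a paternal-X fraction of X-linked bisulfite reads ≥ 0.25
(config `sex_threshold`) calls female and 0 X coverage is unsexable and
dropped; a genome-wide maternal-allele fraction ≥ 0.65 (config
`contamination_threshold`) flags maternal-tissue contamination. The
source protocol gives no numeric thresholds ("much higher proportion"),
so both are config-exposed choices.

## Synthetic data generator

`simulate_expression` draws per-gene totals NB(μ_g, φ) with log-normal
μ_g (default mean 200, σ = 1, φ = 0.05), thins them binomially at the
haplotyping efficiency h = 0.8 (unassignable reads stay in the total
only, reproducing m + p < total), and splits assignable reads
beta-binomially (ρ = 0.01) around the gene's maternal fraction. Imprinted
archetypes start at silent proportion p0 = 0.02; loss-of-imprinting
genotypes add Δ at affected genes. One in ten genes is an imprinted
archetype and one in ten biallelic genes still sits on the known-imprinted
candidate list, emulating a curated list that includes genes not imprinted
in the assayed tissue. Defaults (2000 genes, 8 samples per genotype) run
the full pipeline in well under a minute.

`simulate_backcross_bins` alternates heterozygous/homozygous blocks with
geometric lengths (mean 25 Mb, floor 10 Mb — the interference argument
above), Poisson bin depth (default 80) and beta-binomial Cast proportions
around 0.5 (het) or 0.01 (homozygous-B6 mis-assignment).
`simulate_methylation` gives germline-DMR archetypes ~95%/5% allelic
methylation with a random hyper allele, secondary DMRs 75%/25%,
unmethylated islands 5%, and erodes the hyper allele by a genotype shift
at affected regions.

All generators are pure functions of (scenario, seed): a fixed seed gives
byte-identical output. What the generator does **not** emulate: mapping
bias between strains, SNP-density variation along genes (haplotyping
efficiency is uniform), gene-length and GC effects, correlated expression
between clustered imprinted genes, read-level errors, and bisulfite
conversion failure. Passing tests therefore demonstrate the statistical
machinery under the model's own assumptions, not robustness to those
artefacts.

## Numerical and design notes

* Coordinates are 0-based half-open throughout; TSVs are UTF-8 with `.`
  for missing values; writers emit fixed column orders and `%.6g` floats
  so identical runs are byte-identical.
* GLM fits: IRLS with tolerance 10⁻¹⁰, max 200 iterations; dispersions
  below 10⁻⁸ degenerate to Poisson.
* LRT statistics are clamped at 0; NA p-values (non-identifiable designs)
  pass through BH untouched and never count toward the family size.
* BH adjustment preserves input order, caps at 1, and propagates NA.
* Problem sizes in the reproduction script (2000 genes/regions for null
  calibrations, 200 genes for bias, 8 backcross samples × 5 chromosomes
  for breakpoint recovery) are chosen so each quantity has a Monte-Carlo
  error well inside the tolerance being checked while the full script
  completes in minutes on one CPU.
* The per-gene silent-allele Δ uses unweighted per-sample means, not
  pooled counts: the estimator drawn in per-sample dot plots, unbiased
  given depth, at a small efficiency cost for very uneven depths.
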