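# Methods

This note documents the statistical procedures implemented in `deltapop`,
the conventions chosen where several are in circulation, and what the
synthetic-data generator does and does not emulate.

## Data model

Genotypes are unordered diploid allele pairs (integer codes, semantically
PCR fragment lengths) at `L ≥ 1` loci. A call with either allele missing is
treated as wholly missing; the completeness filter removes every individual
with a missing call at any locus, mirroring the field practice of excluding
individuals that fail to amplify in one or more primer sets. The filter is
idempotent, so already-filtered input passes through unchanged. Genepop
files with 2- or 3-digit allele codes are read (width auto-detected per
file); files are always written with 3-digit codes, which bounds
representable allele codes at 999.

## Diversity battery

* **Allele frequencies** are gene-copy proportions, `p_a = N_a / 2n`.
* **Heterozygosity.** `Ho` is the heterozygote fraction; `He = 1 − Σ p²`
  without small-sample correction. The uncorrected form is used because the
  fixation index is defined from it (below); the Nei-style `2n/(2n−1)`
  correction is available behind `DiversityConfig.unbiased_he`. Population
  means of Ho/He average over **all** loci, monomorphic ones included.
* **PIC** per locus on pooled frequencies, Botstein form:
  `1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²`; always ≤ He.
* **Fixation index** `F = (He − Ho)/He` per locus, averaged over loci with
  `He > 0`; undefined (NaN) for fully monomorphic populations.
* **F_IS** is the Weir–Cockerham (1984) small-sample within-population
  estimator: per allele `c = h/2` and
  `b = n/(n−1) · [p(1−p) − (2n−1)/(4n) · h]` with `h` the share of
  individuals heterozygous *for that allele*; components are summed over
  alleles and loci before the final ratio (`f̂ = 1 − Σc / Σ(b+c)`,
  ratio-of-sums). Positive values mean homozygote excess. `f̂ → 1 − Ho/He`
  as `n → ∞`; the test suite checks agreement with `F` at `n = 10⁴` to
  0.01.
* **Hardy–Weinberg test.** Monte-Carlo exact test: the statistic is the
  conditional probability of the observed genotype array given the allele
  counts (`n! · Π N_a! · 2^h / ((2n)! · Π n_g!)`); the null shuffles the 2n
  gene copies within the population×locus and re-pairs them;
  `p = (1 + #{null ≤ observed}) / (1 + B)` with ties counted toward the
  null (the valid, slightly conservative convention). Monomorphic cells and
  `n < 2` are not testable. Because the statistic is discrete, the
  realized type-I rate sits a little under the nominal level; measured over
  2,000 Hardy–Weinberg replicates (n = 100, two equifrequent alleles,
  B = 400) it is ≈ 0.043 at α = 0.05. The 2,000-replicate design was chosen
  for estimator precision (the ±2 SE width at 500 replicates is comparable
  to the acceptance band itself).
* **Allelic richness** is rarefied on gene copies: per locus
  `A_r = Σ_a [1 − C(2n − N_a, G) / C(2n, G)]` with `G = 2g`; the default
  `g` is the smallest population size in the data set (the published survey
  uses g = 14). Values are averaged over loci. `A_r` is non-decreasing in
  `G`, equals the observed allele count at `G = 2n`, and equals exactly 1
  for a monomorphic locus.
* **Rare and private alleles.** Rare = pooled frequency ≤ 0.05 (threshold
  configurable); private = present in exactly one population. Both are
  reported per population as counts and per-individual rates (`count/n_j`).
  Judging rarity on the pooled data set (not per population) matches the
  convention of reporting one rare-allele set for the whole survey.
* **SLG/MLG.** SLG counts distinct unordered single-locus genotypes,
  summed over loci for the per-population figure; MLG counts distinct full
  genotype tuples. The duplication spectrum (copy number → cases) is the
  raw signal of clonality.
* **Region comparison** uses the two-sided Wilcoxon rank-sum test in its
  normal approximation with tie correction (no continuity correction, so
  identical samples give p = 1 exactly).

## Differentiation at levels of integration

`Δ_j` is the total-variation distance (`d0 = ½ Σ|p−q|`) between population
j's type distribution and its pooled complement, where pooling weights every
individual equally; `Δ_SD = Σ (n_j/n) Δ_j` (an equal-weight variant is
available, as the subpopulation weighting is a convention). At the
gene-pool and SLG levels the per-locus `d0` values are averaged with equal
locus weight ("mean SLG"); an alternative mode pools the per-locus type
spaces into one distribution before measuring, since published aggregates
do not always state which convention was used. The level ordering

    Δ_SD(gene pool) ≤ Δ_SD(mean SLG) ≤ Δ_SD(MLG)

is a theorem (marginalization never increases total variation) and is
asserted property-style on random data.

**Permutation analysis 1** re-pairs the 2n_j gene copies within every
population×locus independently, per replicate; allele counts — hence the
gene-pool level — are invariant by construction (asserted), so any
exceedance at SLG/MLG isolates genotypic association (selfing-driven
homozygote excess, clonal duplication, inter-locus linkage).
**Permutation analysis 2** permutes whole individuals among populations
with sample sizes fixed. Verdicts use the published criterion "observed
higher than 95% of all null values" with strict inequality and ties counted
against significance; the one-sided p-value is
`(1 + #{null ≥ observed}) / (1 + B)`. Replicate b draws its RNG stream from
`(seed, analysis-id, b)`, so results are independent of evaluation order
and parallelization. Under label exchangeability the verdict-true rate of
analysis 2 measures ≤ 7% over 300 calibration runs (test suite).

## Cluster inference

Individuals are encoded as 0/1/2 allele-copy counts (one column per
locus×allele), centered, scaled, and projected on principal components
retaining ≥ 95% variance (the retained-variance cutoff is a design choice;
the DAPC step chooses its own PC count by a-score instead). For each K in
the range, R independent best-of-5-starts Lloyd K-means fits record the
between-group inertia L(K);

    ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K))

is the Evanno-style second difference applied to inertia as a clustering-
accuracy proxy. `L(1) = 0` identically (one group has no between-group
inertia), which anchors the second difference so ΔK is defined at the lower
end of the K range; an exactly reproducible optimum (sd = 0) is floored at
1e-12 and therefore dominates, which is the intended reading. `BIC(K) =
n·ln(WSS_K/n) + K·ln n` is reported as a diagnostic only — on weakly
structured data it is typically monotone and inconclusive. A flat ΔK
profile (maximum < 5× median) raises a `no_clear_k` flag rather than a
confident choice. The default R = 100 replicate runs per K keeps desk-scale
runtimes; larger replication is a flag away and changes only the precision
of sd(L).

DAPC is PCA followed by linear discriminant analysis with shared
within-group covariance; memberships are the Gaussian posteriors in
discriminant space. The number of retained PCs is chosen by the a-score
(group-mean reassignment rate minus its label-permuted expectation, 10
permutations), ties resolved toward the smallest candidate; `n_pca` is
capped at `n − K − 1` and shrunk automatically if the within-group scatter
is singular. Population×cluster tables attribute each individual to its
argmax-membership cluster; majority ties break toward the lowest cluster
index with a warning.

## Reserve selection (MAWP rule engine)

The engine is deterministic, order-independent and lexicographic — it
argues by dominance, not weighted sums, because the underlying survey
arguments are dominance statements ("X is the best representative within
the EGU"). Rules, in order: (1) seed the portfolio with the Δ_j minimum
(best single representative of the whole set) and maximum (most distinct
composition); (2) exclude populations with a recorded immediate threat —
including sole EGU representatives, whose EGU is then reported uncovered;
(3) select all large populations (size is the primary long-term viability
criterion); (4) select populations inside protected areas or with existing
management plans (conservation infrastructure already in place); (5) cover
every remaining eco-geographic unit with its best eligible population by
the quality order size class → protected area → management plan → vitality
→ collaboration, ties toward the smaller label; (6) flag selected sole EGU
representatives that are critically small or introduced as complementary-
but-suboptimal. Every decision carries the list of rules that fired.

Treating "large size" and "protected/managed" as absolute selection rules
(not merely tie-breakers within EGU coverage) is the design choice that
lets one eco-geographic unit legitimately contribute two reserves — a large
population *and* a protected one — which is exactly the configuration in
the bundled survey table. On that table (27 German *H. repens* populations
with their published gene-pool Δ_j and site attributes) the engine selects
14 populations, two suboptimal, with no population-specific special cases.

## Synthetic data generator

Allele frequencies drift down a Dirichlet hierarchy — ancestral
`Dirichlet(α·1)`, regional `Dirichlet(θ_region · p_ancestral)`, population
`Dirichlet(θ_pop · p_region)` — so the concentrations directly control the
quantities the statistics measure (smaller θ = more drift = larger Δ).
Individuals are exact clones of an earlier population member with
probability c, otherwise fresh draws at the partial-selfing equilibrium
`F_eq = s/(2−s)` (homozygote aa with probability `p² + F_eq·p(1−p)`).
Defaults reproduce the published survey design: 27 populations with the
published per-site sample sizes (Σ = 715; 13 Northern, 14 Southern), six
loci with allele counts (4, 5, 6, 7, 7, 9) spanning the published per-locus
range and total of 38 alleles. Where the survey pins no value the defaults
are one-time choices at realistic magnitudes: α = 1 (uninformative
ancestral frequencies), θ_region = 30 and θ_pop = 10 (regional split
detectable by clustering, gene-pool Δ_SD ≈ 0.3, near the published 0.35),
s = 0.5 and c = 0.3 (mixed homozygote excess and MLG duplication), missing
rate 0 (the analyzed data set is complete after filtering).

What the generator does **not** emulate: genuinely shared multi-locus
genotypes *across* populations (with six multi-allelic loci the MLG spaces
of drifted populations are near-disjoint, so simulated Δ_SD(MLG) saturates
near 1, unlike the published 0.37 — MLG-level comparisons against real data
should use few-locus configurations); mutation on clonal lineages; spatial
or stepping-stone structure; linkage between loci; temporal sampling.
Passing tests on synthetic data therefore validate estimator correctness
and calibration, not the field realism of any particular parameter value.

## Numerical conventions and edge cases

Unordered pairs are stored sorted, so (a,b) ≡ (b,a) everywhere. Monomorphic
population×locus cells: He = Ho = 0, PIC = 0, richness 1, F/F_IS excluded
from (or undefined for) ratio statistics, HWE not testable. Empty
complements (single-population input) are errors. Rarefaction with G
exceeding a population's gene-copy count raises an error naming the
population. All Monte-Carlo p-values use the add-one convention and count
ties conservatively. The pipeline derives one seed per stage from the
master seed and the stage name (CRC-based), so adding or reordering stages
does not silently change another stage's stream; re-running an identical
configuration is bit-identical.

## Problem sizes used in the test suite

Property suites run on matrices of ≤ 40 individuals × ≤ 3 loci (exhaustive
rarefaction oracles on 8 gene copies); calibration studies use 100–2,000
replicates with B = 99–400 permutations; parameter recovery uses n = 200 ×
50 replicates (F_IS) and the full 715-individual survey design × 30
replicates (cluster recovery). These sizes make the whole suite run in a
few minutes on one core while keeping every Monte-Carlo band at least ±2
SE wide.

## Known limitations

The genepop dialect parser targets the common fixed-width two-allele form
(no haploid or mixed-ploidy rows). The bootstrap CIs on Ho/He are optional
and off by default; no published result depends on them. Null-allele
correction, linkage-disequilibrium statistics and F_ST-family estimators
beyond the Δ machinery are out of scope. DAPC membership probabilities are
in-sample posteriors, not cross-validated assignment rates.
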