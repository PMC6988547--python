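# deltapop

Population-genetics analysis of microsatellite (SSR) surveys for
conservation planning, built around the workflow used to characterize the
German populations of *Helosciadium repens* (creeping marshwort), a crop
wild relative of celery: per-population diversity statistics, compositional
genetic differentiation at three levels of genetic integration with
permutation nulls, cluster inference, and a deterministic rule engine that
turns genetics plus site metadata into a portfolio of **most appropriate
wild populations (MAWPs)** — candidate sites for genetic reserves.

## The statistics at the core

For diploid individuals typed at *L* SSR loci, each population *j* is
described by a relative-frequency distribution over "types" at one of three
**levels of genetic integration**:

* **gene pool** — the 2*n<sub>j</sub>* allele copies at a locus,
* **SLG** — unordered single-locus genotypes,
* **MLG** — whole multi-locus genotypes.

Its differentiation is the total-variation distance to the pooled remainder
of the data set (its *complement*):

```
Δ_j = d0(pop_j, complement_j),      d0(p, q) = ½ Σ_t |p_t − q_t| ∈ [0, 1]
Δ_SD = Σ_j (n_j / n) · Δ_j
```

At the gene-pool and SLG levels the per-locus distances are averaged with
equal locus weight. Because alleles are a marginalization of genotypes,
`Δ_SD(gene pool) ≤ Δ_SD(mean SLG) ≤ Δ_SD(MLG)` on every data set. Two
permutation analyses separate the sources of differentiation: (1) permuting
gene copies among individuals *within* populations destroys genotypic
associations (Hardy–Weinberg departure, inter-locus linkage) while leaving
the gene pools untouched; (2) permuting individuals *among* populations
(sample sizes fixed) destroys the population–type association at any level.

Around this sit the standard SSR battery (allele frequencies, H<sub>o</sub>,
H<sub>e</sub> = 1 − Σp², Botstein PIC, Monte-Carlo exact Hardy–Weinberg
tests, fixation index F, Weir–Cockerham F<sub>IS</sub>, rarefied allelic
richness, private/rare alleles, SLG/MLG counts), cluster-number selection by
replicated K-means with the Evanno-style ΔK on between-group inertia, DAPC
membership probabilities, and the MAWP rule engine (Δ extremes, threat
exclusion, size and protection/management priority, eco-geographic-unit
coverage).

## Worked example

```python
import deltapop as dp

# synthetic survey with the study's sampling design (27 populations, 715
# individuals, 6 loci), two regions, partial selfing and clonality
gm, pf, truth = dp.simulate(dp.SimulationParams(seed=7))

summary = dp.diversity_summary(gm, pf)
results = dp.differentiation_analysis(gm, pf, B=200, seed=7)
for lvl, r in results.items():
    print(lvl, f"delta_sd={r.delta_sd:.4f}", f"perm2_p={r.perm2_p:.4f}")
```

prints

```
genepool delta_sd=0.3027 perm2_p=0.0050
slg delta_sd=0.4653 perm2_p=0.0050
mlg delta_sd=1.0000 perm2_p=0.0050
```

— the level ordering gene pool ≤ SLG ≤ MLG, and a second-permutation
p-value of 1/(B+1): no permutation of individuals among populations reaches
the observed subdivision, i.e. populations differ far more than exchangeable
sampling would allow. The per-population table gives the usual columns
(`n, MLG, SLG, A, rare, private, all_rich, mean_Ho, mean_He, F, FIS`), e.g.

```
             n  MLG  SLG   A   rare  private  all_rich  mean_Ho  mean_He      F    FIS cat  form
P01         27   21   52  27  0.111      0.0     3.655    0.370    0.617  0.419  0.416   N  terr
P04          7    4   19  22  0.143      0.0     3.667    0.262    0.461  0.491  0.492   N  terr
```

(positive F/F<sub>IS</sub> = homozygote excess, here induced by the
generator's selfing rate). Selecting reserve candidates from the bundled
27-population survey table:

```python
meta = dp.bundled_population_metadata()
frame = dp.decisions_frame(dp.select_mawps(meta["delta_j"], meta))
print(int(frame.selected.sum()), sorted(frame.index[frame.suboptimal]))
# 14 ['10R', '14R']
```

selects 14 populations, two of them flagged complementary-but-suboptimal
(sole representatives of their eco-geographic unit that are critically
small or introduced). Each row of the decisions frame lists every rule that
fired for that population.

The same stages are available from the shell:

```
deltapop simulate --out sim --seed 7
deltapop run --genotypes sim/genotypes.gen --metadata sim/metadata.csv \
             --out report --seed 7 --permutations 1000
deltapop mawp            # bundled survey table
```

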