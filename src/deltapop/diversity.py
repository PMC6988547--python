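"""Per-population and per-locus diversity statistics for diploid SSR data.

Implements the classical microsatellite summary battery: allele frequencies,
observed/expected heterozygosity, polymorphic information content (PIC),
a Monte-Carlo exact Hardy-Weinberg test, the fixation index F = (He-Ho)/He,
the Weir & Cockerham (1984) within-population inbreeding estimator FIS,
rarefied allelic richness, private/rare allele rates, single- and multi-locus
genotype (SLG/MLG) counts, and a North-vs-South rank-sum comparison.

All functions expect a complete (filtered) :class:`~deltapop.genotypes.GenotypeMatrix`;
statistics that divide by He skip monomorphic loci and report NaN where no
polymorphic locus exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix, PopulationFrame


@dataclass
class DiversityConfig:
    """Tunable parameters of the diversity battery.

    rare_threshold
        Pooled-frequency cutoff at or below which an allele counts as rare.
    rarefaction_individuals
        Standardized subsample size g (individuals) for allelic richness;
        ``None`` uses the smallest population size in the data set. Richness
        is rarefied on gene copies, G = 2g.
    hwe_permutations
        Monte-Carlo replicates for the Hardy-Weinberg exact test.
    bootstrap_reps
        Optional percentile-bootstrap replicates for Ho/He CIs (0 = off).
    unbiased_he
        Apply the 2n/(2n-1) small-sample correction to He. Off by default;
        the uncorrected 1 - sum(p^2) matches the F column convention.
    rng_seed
        Seed for every stochastic step in this module.
    """

    rare_threshold: float = 0.05
    rarefaction_individuals: int | None = None
    hwe_permutations: int = 10_000
    bootstrap_reps: int = 0
    unbiased_he: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rare_threshold < 1:
            raise ValueError("rare_threshold must be in (0, 1)")
        if self.rarefaction_individuals is not None and self.rarefaction_individuals < 1:
            raise ValueError("rarefaction_individuals must be >= 1")
        if self.hwe_permutations < 1:
            raise ValueError("hwe_permutations must be >= 1")


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(
    gm: GenotypeMatrix, pf: PopulationFrame | None = None, scope: str = "pooled"
) -> pd.DataFrame:
    """Tidy allele-count/frequency table.

    Returns columns ``unit`` (population label, or ``"pooled"``), ``locus``,
    ``allele``, ``count`` and ``freq`` with p_a = count / (2 n_unit) so that
    frequencies sum to 1 within each (unit, locus). Empty units are absent.
    """
    if scope not in ("pooled", "population"):
        raise ValueError("scope must be 'pooled' or 'population'")
    if scope == "population" and pf is None:
        raise ValueError("population scope requires a PopulationFrame")
    units: list[tuple[str, np.ndarray]]
    if scope == "pooled":
        units = [("pooled", np.arange(gm.n_individuals))]
    else:
        idx = {ind: i for i, ind in enumerate(gm.individual_ids)}
        units = [
            (pop, np.array([idx[i] for i in pf.individuals_of(pop)], dtype=int))
            for pop in pf.population_labels
        ]
    rows = []
    for unit, sel in units:
        if sel.size == 0:
            continue
        for l, locus in enumerate(gm.locus_ids):
            copies = gm.calls[sel, l, :].ravel()
            copies = copies[copies != MISSING]
            if copies.size == 0:
                continue
            alleles, counts = np.unique(copies, return_counts=True)
            for a, c in zip(alleles, counts):
                rows.append(
                    {
                        "unit": unit,
                        "locus": locus,
                        "allele": int(a),
                        "count": int(c),
                        "freq": c / copies.size,
                    }
                )
    return pd.DataFrame(rows, columns=["unit", "locus", "allele", "count", "freq"])


def _pop_indices(gm: GenotypeMatrix, pf: PopulationFrame) -> dict[str, np.ndarray]:
    idx = {ind: i for i, ind in enumerate(gm.individual_ids)}
    return {
        pop: np.array([idx[i] for i in pf.individuals_of(pop)], dtype=int)
        for pop in pf.population_labels
    }


# ---------------------------------------------------------------------------
# heterozygosity, PIC, F
# ---------------------------------------------------------------------------


def heterozygosity(
    gm: GenotypeMatrix, pf: PopulationFrame, unbiased_he: bool = False
) -> pd.DataFrame:
    """Per population x locus observed and expected heterozygosity.

    Ho is the fraction of heterozygous individuals; He = 1 - sum(p^2)
    (optionally with the 2n/(2n-1) correction). Monomorphic loci yield
    Ho = He = 0 and are included in per-population means.
    """
    rows = []
    for pop, sel in _pop_indices(gm, pf).items():
        for l, locus in enumerate(gm.locus_ids):
            pairs = gm.calls[sel, l, :]
            pairs = pairs[(pairs != MISSING).all(axis=1)]
            n = len(pairs)
            if n == 0:
                continue
            ho = float(np.mean(pairs[:, 0] != pairs[:, 1]))
            _, counts = np.unique(pairs.ravel(), return_counts=True)
            p = counts / counts.sum()
            he = 1.0 - float(np.sum(p**2))
            if unbiased_he:
                he *= 2 * n / (2 * n - 1) if n > 0 else 1.0
            rows.append({"population": pop, "locus": locus, "n": n, "Ho": ho, "He": he})
    return pd.DataFrame(rows, columns=["population", "locus", "n", "Ho", "He"])


def mean_heterozygosity(het: pd.DataFrame) -> pd.DataFrame:
    """Per-population mean Ho/He over all loci (monomorphic included)."""
    out = het.groupby("population", sort=False)[["Ho", "He"]].mean()
    return out.rename(columns={"Ho": "mean_Ho", "He": "mean_He"})


def pic(gm: GenotypeMatrix) -> pd.Series:
    """Polymorphic information content per locus from pooled frequencies.

    Botstein-type: PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.
    Monomorphic loci score 0; PIC <= He always.
    """
    freqs = allele_frequencies(gm, scope="pooled")
    values = {}
    for locus in gm.locus_ids:
        p = freqs.loc[freqs["locus"] == locus, "freq"].to_numpy()
        if p.size == 0:
            values[locus] = np.nan
            continue
        s2 = np.sum(p**2)
        s4 = np.sum(p**4)
        # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
        values[locus] = float(1.0 - s2 - (s2**2 - s4))
    return pd.Series(values, name="PIC")


def pooled_locus_summary(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus pooled table: allele count A, PIC, Ho, He."""
    whole = PopulationFrame(
        pd.Series(["all"] * gm.n_individuals, index=gm.individual_ids)
    )
    het = heterozygosity(gm, whole).set_index("locus")
    freqs = allele_frequencies(gm, scope="pooled")
    a_locus = freqs.groupby("locus", sort=False)["allele"].nunique()
    out = pd.DataFrame(
        {
            "A": a_locus.reindex(gm.locus_ids),
            "PIC": pic(gm).reindex(gm.locus_ids),
            "Ho": het["Ho"].reindex(gm.locus_ids),
            "He": het["He"].reindex(gm.locus_ids),
        }
    )
    out.index.name = "locus"
    return out


def fixation_index_F(gm: GenotypeMatrix, pf: PopulationFrame) -> pd.Series:
    """Per-population fixation index F = mean over polymorphic loci of (He-Ho)/He.

    Populations with no polymorphic locus are undefined (NaN).
    """
    het = heterozygosity(gm, pf)
    values = {}
    for pop, grp in het.groupby("population", sort=False):
        poly = grp[grp["He"] > 0]
        if poly.empty:
            values[pop] = np.nan
        else:
            values[pop] = float(((poly["He"] - poly["Ho"]) / poly["He"]).mean())
    return pd.Series(values, name="F").reindex(pf.population_labels)


def fis_weir_cockerham(gm: GenotypeMatrix, pf: PopulationFrame) -> pd.Series:
    """Weir & Cockerham (1984) within-population inbreeding estimator f-hat.

    Variance components are summed over alleles and loci before the final
    ratio (ratio-of-sums). Positive values indicate homozygote excess. For a
    single population the components reduce, per allele a with frequency p,
    observed-heterozygote share h (fraction of individuals heterozygous for
    a) and sample size n, to::

        b_a = n/(n-1) * [p(1-p) - (2n-1)/(4n) * h]
        c_a = h/2
        f-hat = 1 - sum(c) / sum(b + c)

    which tends to 1 - Ho/He as n grows. Populations where every locus is
    monomorphic (or n < 2) are NaN.
    """
    values = {}
    for pop, sel in _pop_indices(gm, pf).items():
        num = 0.0  # sum of c
        den = 0.0  # sum of b + c
        for l in range(gm.n_loci):
            pairs = gm.calls[sel, l, :]
            pairs = pairs[(pairs != MISSING).all(axis=1)]
            n = len(pairs)
            if n < 2:
                continue
            alleles, counts = np.unique(pairs.ravel(), return_counts=True)
            if alleles.size < 2:
                continue
            p = counts / (2 * n)
            het_mask = pairs[:, 0] != pairs[:, 1]
            for a, pa in zip(alleles, p):
                h = float(np.mean(het_mask & ((pairs == a).any(axis=1))))
                b = n / (n - 1) * (pa * (1 - pa) - (2 * n - 1) / (4 * n) * h)
                c = h / 2
                num += c
                den += b + c
        values[pop] = 1.0 - num / den if den > 0 else np.nan
    return pd.Series(values, name="FIS").reindex(pf.population_labels)


# ---------------------------------------------------------------------------
# Hardy-Weinberg Monte-Carlo exact test
# ---------------------------------------------------------------------------


def _log_genotype_array_prob(pairs: np.ndarray) -> float:
    """Log conditional probability of a genotype array given allele counts.

    P = n! * prod_a N_a! * 2^h / ((2n)! * prod_g n_g!)  (Levene's conditional
    distribution, the statistic of the Guo-Thompson exact test).
    """
    n = len(pairs)
    _, allele_counts = np.unique(pairs.ravel(), return_counts=True)
    _, geno_counts = np.unique(pairs, axis=0, return_counts=True)
    h = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    return float(
        gammaln(n + 1)
        + np.sum(gammaln(allele_counts + 1))
        + h * np.log(2.0)
        - gammaln(2 * n + 1)
        - np.sum(gammaln(geno_counts + 1))
    )


def _hwe_mc_pvalue(pairs: np.ndarray, b: int, rng: np.random.Generator) -> float:
    """Monte-Carlo p-value for one population x locus sample (complete pairs)."""
    n = len(pairs)
    alleles = np.unique(pairs.ravel())
    n_alleles = alleles.size
    obs = _log_genotype_array_prob(pairs)
    copies = pairs.ravel()
    # re-pair shuffled gene copies, all replicates at once
    perm = rng.permuted(np.tile(copies, (b, 1)), axis=1)
    a = perm[:, 0::2]
    bb = perm[:, 1::2]
    lo = np.minimum(a, bb)
    hi = np.maximum(a, bb)
    # canonical small codes for bincount
    remap = {int(al): k for k, al in enumerate(alleles)}
    lo_k = np.vectorize(remap.__getitem__, otypes=[np.int64])(lo)
    hi_k = np.vectorize(remap.__getitem__, otypes=[np.int64])(hi)
    codes = lo_k * n_alleles + hi_k
    ncodes = n_alleles * n_alleles
    counts = np.zeros((b, ncodes), dtype=np.int64)
    np.add.at(counts, (np.repeat(np.arange(b), n), codes.ravel()), 1)
    h = np.sum(lo != hi, axis=1)
    # allele counts are invariant under the shuffle; those terms are shared
    const = float(
        gammaln(n + 1)
        + np.sum(gammaln(np.unique(copies, return_counts=True)[1] + 1))
        - gammaln(2 * n + 1)
    )
    null = const + h * np.log(2.0) - np.sum(gammaln(counts + 1), axis=1)
    return float((1 + np.sum(null <= obs + 1e-9)) / (1 + b))


def hwe_test(
    gm: GenotypeMatrix, pf: PopulationFrame, cfg: DiversityConfig | None = None
) -> pd.DataFrame:
    """Monte-Carlo exact Hardy-Weinberg test per population x locus.

    The statistic is the conditional probability of the observed genotype
    array given the allele counts; the null resamples by shuffling the 2n
    gene copies within the population x locus and re-pairing them. The
    p-value is (1 + #{null <= observed}) / (1 + B). Monomorphic cells and
    n < 2 are reported as not testable (NaN).
    """
    cfg = cfg or DiversityConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    rows = []
    for pop, sel in _pop_indices(gm, pf).items():
        for l, locus in enumerate(gm.locus_ids):
            pairs = gm.calls[sel, l, :]
            pairs = pairs[(pairs != MISSING).all(axis=1)]
            n = len(pairs)
            testable = n >= 2 and np.unique(pairs.ravel()).size >= 2
            p = (
                _hwe_mc_pvalue(pairs, cfg.hwe_permutations, rng)
                if testable
                else np.nan
            )
            rows.append(
                {"population": pop, "locus": locus, "n": n, "p_value": p,
                 "testable": bool(testable)}
            )
    return pd.DataFrame(rows, columns=["population", "locus", "n", "p_value", "testable"])


# ---------------------------------------------------------------------------
# rarefaction, private & rare alleles, genotype classes
# ---------------------------------------------------------------------------


def allelic_richness(
    gm: GenotypeMatrix, pf: PopulationFrame, cfg: DiversityConfig | None = None
) -> pd.Series:
    """Rarefied allelic richness per population (mean over loci).

    Per locus, the expected number of distinct alleles in a random subsample
    of G = 2g gene copies: A_r = sum_a [1 - C(2n - N_a, G) / C(2n, G)].
    With G = 2n this is the observed allele count; a monomorphic locus gives
    exactly 1 for any g.
    """
    cfg = cfg or DiversityConfig()
    pops = _pop_indices(gm, pf)
    g = cfg.rarefaction_individuals
    if g is None:
        g = int(min(len(sel) for sel in pops.values()))
    G = 2 * g
    values = {}
    for pop, sel in pops.items():
        per_locus = []
        for l in range(gm.n_loci):
            pairs = gm.calls[sel, l, :]
            pairs = pairs[(pairs != MISSING).all(axis=1)]
            ngenes = 2 * len(pairs)
            if ngenes == 0:
                continue
            if G > ngenes:
                raise ValueError(
                    f"rarefaction size G={G} exceeds {ngenes} gene copies in "
                    f"population {pop}"
                )
            _, counts = np.unique(pairs.ravel(), return_counts=True)
            ar = 0.0
            for na in counts:
                # 1 - C(ngenes-na, G)/C(ngenes, G), computed in log space
                if ngenes - na < G:
                    ar += 1.0
                else:
                    lr = (
                        gammaln(ngenes - na + 1)
                        - gammaln(G + 1)
                        - gammaln(ngenes - na - G + 1)
                        - gammaln(ngenes + 1)
                        + gammaln(G + 1)
                        + gammaln(ngenes - G + 1)
                    )
                    ar += 1.0 - float(np.exp(lr))
            per_locus.append(ar)
        values[pop] = float(np.mean(per_locus)) if per_locus else np.nan
    return pd.Series(values, name="allelic_richness").reindex(pf.population_labels)


def private_and_rare(
    gm: GenotypeMatrix, pf: PopulationFrame, cfg: DiversityConfig | None = None
) -> pd.DataFrame:
    """Private and rare allele counts and per-individual rates per population.

    Private: alleles occurring in exactly one population. Rare: alleles with
    POOLED frequency <= the configured threshold; a population's rare count
    is the number of such alleles present in it. Rates divide by n_j.
    """
    cfg = cfg or DiversityConfig()
    pooled = allele_frequencies(gm, scope="pooled")
    perpop = allele_frequencies(gm, pf, scope="population")
    rare_keys = {
        (r.locus, r.allele)
        for r in pooled.itertuples()
        if r.freq <= cfg.rare_threshold
    }
    presence = perpop.groupby(["locus", "allele"])["unit"].nunique()
    private_keys = set(presence[presence == 1].index)
    sizes = pf.sizes()
    rows = []
    for pop in pf.population_labels:
        mine = perpop[perpop["unit"] == pop]
        keys = {(r.locus, r.allele) for r in mine.itertuples()}
        n_priv = len(keys & private_keys)
        n_rare = len(keys & rare_keys)
        nj = int(sizes[pop])
        rows.append(
            {
                "population": pop,
                "n": nj,
                "private": n_priv,
                "rare": n_rare,
                "private_per_ind": n_priv / nj,
                "rare_per_ind": n_rare / nj,
            }
        )
    return pd.DataFrame(rows).set_index("population")


def genotype_classes(
    gm: GenotypeMatrix, pf: PopulationFrame
) -> tuple[pd.DataFrame, dict]:
    """SLG and MLG counts per population and pooled, plus duplication spectrum.

    SLG counts distinct unordered single-locus genotypes per locus, summed
    over loci for the per-population figure; MLG counts distinct full
    multi-locus tuples. The pooled spectrum maps MLG copy number (within
    populations) to how many (population, MLG) cases show it.
    """
    pops = _pop_indices(gm, pf)
    rows = []
    spectrum: dict[int, int] = {}
    for pop, sel in pops.items():
        slg = 0
        for l in range(gm.n_loci):
            pairs = gm.calls[sel, l, :]
            pairs = pairs[(pairs != MISSING).all(axis=1)]
            if len(pairs):
                slg += np.unique(pairs, axis=0).shape[0]
        tuples = gm.calls[sel].reshape(len(sel), -1)
        _, counts = np.unique(tuples, axis=0, return_counts=True)
        for c in counts:
            spectrum[int(c)] = spectrum.get(int(c), 0) + 1
        rows.append({"population": pop, "MLG": int(counts.size), "SLG": int(slg)})
    per_pop = pd.DataFrame(rows).set_index("population")
    pooled_slg = 0
    for l in range(gm.n_loci):
        pairs = gm.calls[:, l, :]
        pairs = pairs[(pairs != MISSING).all(axis=1)]
        if len(pairs):
            pooled_slg += np.unique(pairs, axis=0).shape[0]
    pooled_mlg = np.unique(gm.calls.reshape(gm.n_individuals, -1), axis=0).shape[0]
    pooled = {"SLG": int(pooled_slg), "MLG": int(pooled_mlg), "spectrum": spectrum}
    return per_pop, pooled


def per_population_allele_counts(gm: GenotypeMatrix, pf: PopulationFrame) -> pd.Series:
    """Distinct allele count A per population, summed implicitly over loci."""
    perpop = allele_frequencies(gm, pf, scope="population")
    counts = perpop.groupby("unit", sort=False).size()
    return counts.reindex(pf.population_labels).fillna(0).astype(int).rename("A")


# ---------------------------------------------------------------------------
# region comparison and the full summary table
# ---------------------------------------------------------------------------


def region_compare(
    values: pd.Series, pf: PopulationFrame, metadata: pd.DataFrame | None = None
) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing N vs S population values.

    Uses the normal approximation with tie correction. ``values`` is indexed
    by population label; the region comes from ``metadata`` (or
    ``pf.populations``).
    """
    meta = metadata if metadata is not None else pf.populations
    if meta is None or "region" not in meta.columns:
        raise ValueError("population metadata with a 'region' column is required")
    region = meta["region"]
    x = values[region.reindex(values.index) == "N"].dropna()
    y = values[region.reindex(values.index) == "S"].dropna()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both regions must be non-empty")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.pvalue)


def diversity_summary(
    gm: GenotypeMatrix,
    pf: PopulationFrame,
    cfg: DiversityConfig | None = None,
    hwe: bool = False,
) -> pd.DataFrame:
    """One row per population with the full diversity battery.

    Columns: n, MLG, SLG, A, rare (per individual), private (per individual),
    all_rich, mean_Ho, mean_He, F, FIS — plus cat/form when metadata is
    attached.
    """
    cfg = cfg or DiversityConfig()
    per_pop, _ = genotype_classes(gm, pf)
    het = heterozygosity(gm, pf, unbiased_he=cfg.unbiased_he)
    means = mean_heterozygosity(het)
    pr = private_and_rare(gm, pf, cfg)
    out = pd.DataFrame(index=pd.Index(pf.population_labels, name="population"))
    out["n"] = pf.sizes()
    out["MLG"] = per_pop["MLG"]
    out["SLG"] = per_pop["SLG"]
    out["A"] = per_population_allele_counts(gm, pf)
    out["rare"] = pr["rare_per_ind"]
    out["private"] = pr["private_per_ind"]
    out["all_rich"] = allelic_richness(gm, pf, cfg)
    out["mean_Ho"] = means["mean_Ho"]
    out["mean_He"] = means["mean_He"]
    out["F"] = fixation_index_F(gm, pf)
    out["FIS"] = fis_weir_cockerham(gm, pf)
    if hwe:
        hw = hwe_test(gm, pf, cfg)
        out["HWE_dev"] = hw.groupby("population", sort=False)["p_value"].apply(
            lambda p: int((p.dropna() < 0.05).sum())
        )
    meta = pf.populations
    if meta is not None:
        for col, name in (("region", "cat"), ("form", "form")):
            if col in meta.columns:
                out[name] = meta[col].reindex(out.index)
    return out
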