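"""Diversity statistics against brute-force oracles and closed forms."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import deltapop as dp
from deltapop.diversity import DiversityConfig

from conftest import matrix_from_pairs, random_dataset


def brute_allele_freqs(gm, sel, locus):
    """Independent tally of the 2n gene copies."""
    tally = {}
    for i in sel:
        for a in gm.calls[i, locus]:
            tally[a] = tally.get(a, 0) + 1
    total = sum(tally.values())
    return {a: c / total for a, c in tally.items()}


class TestAlleleFrequencies:
    def test_counting_example(self):
        gm, pf = matrix_from_pairs({"P": [[(1, 1)], [(1, 2)]]}, ["L1"])
        f = dp.allele_frequencies(gm, scope="pooled").set_index("allele")["freq"]
        assert f[1] == 0.75 and f[2] == 0.25

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_copy_tally_and_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        gm, pf = random_dataset(rng, [5, 5], n_loci=3, n_alleles=4)
        table = dp.allele_frequencies(gm, pf, scope="population")
        for (unit, locus), grp in table.groupby(["unit", "locus"]):
            assert np.isclose(grp["freq"].sum(), 1.0, atol=1e-12)
            sel = [
                i for i, ind in enumerate(gm.individual_ids)
                if pf.assignment[ind] == unit
            ]
            expected = brute_allele_freqs(gm, sel, gm.locus_ids.index(locus))
            got = dict(zip(grp["allele"], grp["freq"]))
            assert got.keys() == expected.keys()
            for a in got:
                assert np.isclose(got[a], expected[a])


class TestHeterozygosity:
    def test_all_heterozygous(self):
        gm, pf = matrix_from_pairs({"P": [[(1, 2)]] * 6}, ["L1"])
        het = dp.heterozygosity(gm, pf)
        assert het["Ho"].iloc[0] == 1.0
        assert het["He"].iloc[0] == 0.5

    def test_monomorphic_and_mean_over_all_loci(self):
        gm, pf = matrix_from_pairs(
            {"P": [[(1, 2), (3, 3)]] * 4}, ["L1", "L2"]
        )
        het = dp.heterozygosity(gm, pf)
        assert het.set_index("locus").loc["L2", ["Ho", "He"]].tolist() == [0, 0]
        from deltapop.diversity import mean_heterozygosity
        means = mean_heterozygosity(het)
        assert means.loc["P", "mean_He"] == pytest.approx(0.25)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_direct_count(self, seed):
        rng = np.random.default_rng(seed)
        gm, pf = random_dataset(rng, [8], n_loci=2, n_alleles=3)
        het = dp.heterozygosity(gm, pf)
        for row in het.itertuples():
            l = gm.locus_ids.index(row.locus)
            pairs = gm.calls[:, l, :]
            ho = np.mean(pairs[:, 0] != pairs[:, 1])
            p = np.array(list(brute_allele_freqs(gm, range(8), l).values()))
            assert np.isclose(row.Ho, ho)
            assert np.isclose(row.He, 1 - (p**2).sum())


class TestPic:
    def test_monomorphic_zero(self):
        gm, _ = matrix_from_pairs({"P": [[(1, 1)]] * 3}, ["L1"])
        assert dp.pic(gm)["L1"] == 0.0

    def test_biallelic_half(self):
        gm, _ = matrix_from_pairs({"P": [[(1, 1)], [(2, 2)]]}, ["L1"])
        assert dp.pic(gm)["L1"] == pytest.approx(0.375)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_pic_never_exceeds_he(self, seed):
        rng = np.random.default_rng(seed)
        gm, pf = random_dataset(rng, [10], n_loci=3, n_alleles=5)
        whole = dp.PopulationFrame(
            pd.Series(["all"] * gm.n_individuals, index=gm.individual_ids)
        )
        het = dp.heterozygosity(gm, whole).set_index("locus")["He"]
        p = dp.pic(gm)
        assert (p <= het.reindex(p.index) + 1e-12).all()


class TestFixationIndices:
    def test_f_zero_when_ho_equals_he(self):
        # p = q = 0.5 with Ho = 0.5 = He
        gm, pf = matrix_from_pairs(
            {"P": [[(1, 2)], [(1, 2)], [(1, 1)], [(2, 2)]]}, ["L1"]
        )
        assert dp.fixation_index_F(gm, pf)["P"] == pytest.approx(0.0)

    def test_f_minus_one_all_heterozygous(self):
        gm, pf = matrix_from_pairs({"P": [[(1, 2)]] * 10}, ["L1"])
        assert dp.fixation_index_F(gm, pf)["P"] == pytest.approx(-1.0)

    def test_monomorphic_population_undefined(self):
        gm, pf = matrix_from_pairs({"P": [[(1, 1)]] * 10}, ["L1"])
        assert np.isnan(dp.fixation_index_F(gm, pf)["P"])
        assert np.isnan(dp.fis_weir_cockerham(gm, pf)["P"])

    def test_fis_consistent_under_hwe(self):
        gm, pf, _ = dp.simulate(
            dp.SimulationParams(
                pop_sizes=[1000], n_north=1, allele_counts=[4, 4],
                selfing=0.0, clonality=0.0, theta_pop=1e6, theta_region=1e6,
                seed=99,
            )
        )
        assert abs(dp.fis_weir_cockerham(gm, pf)["P01"]) < 0.05

    def test_fis_approaches_minus_one_all_het(self):
        gm, pf = matrix_from_pairs({"P": [[(1, 2)]] * 2000}, ["L1"])
        assert dp.fis_weir_cockerham(gm, pf)["P"] == pytest.approx(-1.0, abs=1e-3)

    def test_fis_converges_to_f_for_large_n(self):
        rng = np.random.default_rng(3)
        gm, pf = random_dataset(rng, [10_000], n_loci=2, n_alleles=4)
        f = dp.fixation_index_F(gm, pf)["P0"]
        fis = dp.fis_weir_cockerham(gm, pf)["P0"]
        assert abs(f - fis) < 0.01


class TestHweTest:
    def test_monomorphic_not_testable(self):
        gm, pf = matrix_from_pairs({"P": [[(1, 1)]] * 10}, ["L1"])
        res = dp.hwe_test(gm, pf, DiversityConfig(hwe_permutations=50))
        assert not res["testable"].iloc[0]
        assert np.isnan(res["p_value"].iloc[0])

    def test_extreme_heterozygote_excess_rejected(self):
        gm, pf = matrix_from_pairs({"P": [[(1, 2)]] * 50}, ["L1"])
        res = dp.hwe_test(gm, pf, DiversityConfig(hwe_permutations=999, rng_seed=1))
        assert res["p_value"].iloc[0] < 0.01


class TestAllelicRichness:
    def test_monomorphic_is_one(self):
        gm, pf = matrix_from_pairs({"P": [[(1, 1)]] * 8}, ["L1"])
        ar = dp.allelic_richness(gm, pf, DiversityConfig(rarefaction_individuals=3))
        assert ar["P"] == pytest.approx(1.0)

    def test_full_sample_recovers_observed_count(self):
        gm, pf = matrix_from_pairs(
            {"P": [[(1, 2)], [(3, 3)], [(1, 4)]]}, ["L1"]
        )
        ar = dp.allelic_richness(gm, pf, DiversityConfig(rarefaction_individuals=3))
        assert ar["P"] == pytest.approx(4.0)

    def test_two_gene_subsample_of_skewed_pair(self):
        # copies {3, 1} among 4 genes; all C(4,2)=6 subsamples average 1.5
        gm, pf = matrix_from_pairs({"P": [[(1, 1)], [(1, 2)]]}, ["L1"])
        ar = dp.allelic_richness(gm, pf, DiversityConfig(rarefaction_individuals=1))
        assert ar["P"] == pytest.approx(1.5)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), g=st.integers(1, 4))
    def test_matches_exhaustive_enumeration(self, seed, g):
        rng = np.random.default_rng(seed)
        gm, pf = random_dataset(rng, [4], n_loci=1, n_alleles=3)  # 8 gene copies
        copies = gm.calls[:, 0, :].ravel()
        G = 2 * g
        exact = np.mean(
            [len(set(sub)) for sub in itertools.combinations(copies, G)]
        )
        ar = dp.allelic_richness(gm, pf, DiversityConfig(rarefaction_individuals=g))
        assert ar["P0"] == pytest.approx(exact, abs=1e-12)

    def test_oversized_subsample_names_population(self):
        gm, pf = matrix_from_pairs({"Ptiny": [[(1, 2)]] * 2}, ["L1"])
        with pytest.raises(ValueError, match="Ptiny"):
            dp.allelic_richness(gm, pf, DiversityConfig(rarefaction_individuals=5))

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_g_and_bounded_by_observed(self, seed):
        rng = np.random.default_rng(seed)
        gm, pf = random_dataset(rng, [6], n_loci=2, n_alleles=4)
        values = [
            dp.allelic_richness(gm, pf, DiversityConfig(rarefaction_individuals=g))["P0"]
            for g in (1, 3, 6)
        ]
        assert values[0] <= values[1] + 1e-12 <= values[2] + 2e-12
        observed = dp.allele_frequencies(gm, pf, "population")
        a_mean = observed.groupby("locus")["allele"].nunique().mean()
        assert values[2] <= a_mean + 1e-12


class TestPrivateAndRare:
    def test_single_population_all_private(self, rng):
        gm, pf = random_dataset(rng, [6], n_loci=2, n_alleles=3)
        pr = dp.private_and_rare(gm, pf)
        total = dp.allele_frequencies(gm, scope="pooled").shape[0]
        assert pr.loc["P0", "private"] == total

    def test_rare_threshold_boundary(self):
        # 50 pooled copies: allele 2 once (0.02 <= 0.05, rare), allele 3
        # four times (0.08 > 0.05, not rare)
        rows = [[(1, 1)]] * 10 + [[(1, 2)]] + [[(3, 3)]] * 2
        gm, pf = matrix_from_pairs({"P": rows, "Q": [[(1, 1)]] * 12}, ["L1"])
        pr = dp.private_and_rare(gm, pf)
        freqs = dp.allele_frequencies(gm, scope="pooled").set_index("allele")["freq"]
        assert freqs[2] <= 0.05 < freqs[3]
        assert pr.loc["P", "rare"] == 1

    def test_rate_divides_by_sample_size(self):
        rows = {"A": [[(1, 2)]] * 9, "B": [[(1, 1)]] * 9}
        gm, pf = matrix_from_pairs(rows, ["L1"])
        pr = dp.private_and_rare(gm, pf)
        assert pr.loc["A", "private"] == 1  # allele 2 only in A
        assert pr.loc["A", "private_per_ind"] == pytest.approx(1 / 9)


class TestGenotypeClasses:
    def test_duplicates_collapse(self):
        gm, pf = matrix_from_pairs({"P": [[(1, 2)], [(1, 2)]]}, ["L1"])
        per_pop, pooled = dp.genotype_classes(gm, pf)
        assert per_pop.loc["P", "MLG"] == 1
        assert pooled["spectrum"] == {2: 1}

    def test_clonal_population_single_mlg(self):
        gm, pf = matrix_from_pairs({"P": [[(1, 2), (3, 3)]] * 30}, ["L1", "L2"])
        per_pop, _ = dp.genotype_classes(gm, pf)
        assert per_pop.loc["P", "MLG"] == 1
        assert per_pop.loc["P", "SLG"] == 2  # one distinct SLG per locus

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_set_of_tuples_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gm, pf = random_dataset(rng, [10, 10], n_loci=6, n_alleles=3)
        per_pop, pooled = dp.genotype_classes(gm, pf)
        for pop in pf.population_labels:
            sel = [i for i, ind in enumerate(gm.individual_ids)
                   if pf.assignment[ind] == pop]
            mlg = len({tuple(gm.calls[i].ravel()) for i in sel})
            slg = sum(
                len({tuple(gm.calls[i, l]) for i in sel})
                for l in range(gm.n_loci)
            )
            assert per_pop.loc[pop, "MLG"] == mlg
            assert per_pop.loc[pop, "SLG"] == slg
        assert pooled["MLG"] == len(
            {tuple(r.ravel()) for r in gm.calls}
        )


class TestRegionCompare:
    def _pf(self, n_north, n_south):
        pops = [f"N{i}" for i in range(n_north)] + [f"S{i}" for i in range(n_south)]
        meta = pd.DataFrame(
            {"region": ["N"] * n_north + ["S"] * n_south}, index=pops
        )
        return pops, meta

    def test_identical_multisets_p_one(self):
        pops, meta = self._pf(4, 4)
        values = pd.Series([1, 2, 3, 4, 1, 2, 3, 4], index=pops, dtype=float)
        pf = dp.PopulationFrame(pd.Series(dtype=object), meta)
        assert dp.region_compare(values, pf) == pytest.approx(1.0)

    def test_extreme_shift_significant(self):
        pops, meta = self._pf(14, 13)
        values = pd.Series([0.0] * 14 + [1.0] * 13, index=pops)
        pf = dp.PopulationFrame(pd.Series(dtype=object), meta)
        assert dp.region_compare(values, pf) < 0.001

    def test_empty_region_errors(self):
        pops, meta = self._pf(3, 0)
        values = pd.Series([1.0, 2.0, 3.0], index=pops)
        pf = dp.PopulationFrame(pd.Series(dtype=object), meta)
        with pytest.raises(ValueError):
            dp.region_compare(values, pf)

    def test_null_p_values_roughly_uniform(self):
        from scipy.stats import kstest
        rng = np.random.default_rng(0)
        pops, meta = self._pf(14, 13)
        base = rng.normal(size=27)
        ps = []
        for _ in range(1000):
            perm = rng.permutation(base)
            values = pd.Series(perm, index=pops)
            pf = dp.PopulationFrame(pd.Series(dtype=object), meta)
            ps.append(dp.region_compare(values, pf))
        assert kstest(ps, "uniform").statistic < 0.1


def test_summary_has_table_shape(rng):
    gm, pf, _ = dp.simulate(
        dp.SimulationParams(pop_sizes=[10, 12, 9], n_north=2,
                            allele_counts=[3, 4], seed=4)
    )
    summary = dp.diversity_summary(gm, pf)
    assert list(summary.index) == pf.population_labels
    for col in ("n", "MLG", "SLG", "A", "rare", "private", "all_rich",
                "mean_Ho", "mean_He", "F", "FIS"):
        assert col in summary.columns
    assert (summary["MLG"] <= summary["n"]).all()
    assert summary[["mean_Ho", "mean_He"]].min().min() >= 0
    assert summary[["mean_Ho", "mean_He"]].max().max() <= 1
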