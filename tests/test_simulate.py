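"""Synthetic admixed populations: founders, meiosis, breeding, traits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admixgs import simulate as sim
from admixgs._rng import stream


class TestFounderModel:
    def test_contributions_default_and_validation(self):
        m = sim.FounderModel(n_subpops=3)
        assert np.allclose(m.contributions, 1 / 3)
        with pytest.raises(ValueError):
            sim.FounderModel(divergence=1.0)
        with pytest.raises(ValueError):
            sim.FounderModel(divergence=-0.1)
        with pytest.raises(ValueError):
            sim.FounderModel(n_subpops=2, contributions=(0.7, 0.7))

    def test_zero_divergence_identical_frequencies(self, small_map):
        f = sim.simulate_founders(sim.FounderModel(2, 0.0), small_map, 40, seed=1)
        assert np.allclose(f.allele_freqs[0], f.allele_freqs[1])

    def test_balding_nichols_frequency_variance(self):
        """E[kappa^2] between two subpops is 2 F p(1-p) per marker; check the
        average over many markers against a brute-force frequency draw."""
        gmap = sim.GeneticMap.uniform(1, 8000, 100)
        F = 0.2
        f = sim.simulate_founders(sim.FounderModel(2, F, (0.3, 0.7)),
                                  gmap, 2, seed=3)
        kappa = 0.5 * (f.allele_freqs[0] - f.allele_freqs[1])
        # brute-force oracle: draw Beta pairs around the same ancestral law
        rng = np.random.default_rng(99)
        p = rng.uniform(0.3, 0.7, 200_000)
        a = (1 - F) / F
        q1 = rng.beta(a * p, a * (1 - p))
        q2 = rng.beta(a * p, a * (1 - p))
        oracle = np.mean((0.5 * (q1 - q2)) ** 2)
        got = np.mean((2 * kappa) ** 2) / 4
        assert got == pytest.approx(oracle, rel=0.08)

    def test_founders_in_linkage_equilibrium(self, founders):
        haps = founders.hapset.haps[founders.subpops == 0].reshape(-1, founders.hapset.n_markers)
        rng = np.random.default_rng(0)
        ds = []
        for _ in range(300):
            i, j = rng.choice(haps.shape[1], 2, replace=False)
            ds.append(np.mean(haps[:, i] * haps[:, j])
                      - haps[:, i].mean() * haps[:, j].mean())
        assert abs(np.mean(ds)) < 0.01

    def test_unique_descent_labels(self, founders):
        d = founders.hapset.descent
        first = d[:, :, 0].ravel()
        assert len(np.unique(first)) == len(first)
        assert (d == d[:, :, [0]]).all()


class TestDropGamete:
    def test_zero_length_chromosome(self):
        rng = stream(0, "x")
        haps = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        desc = np.array([[5, 5], [6, 6]], dtype=np.int32)
        for _ in range(50):
            h, d, nc = sim.drop_gamete(haps, desc, np.array([0.0, 0.0]), rng)
            assert nc == 0
            assert (d == d[0]).all()

    def test_poisson_one_per_morgan(self):
        """Mean crossover count on a 1-Morgan chromosome is 1."""
        rng = stream(1, "meiosis")
        pos = np.linspace(0, 100, 50)
        haps = np.zeros((2, 50), dtype=np.uint8)
        desc = np.stack([np.zeros(50, np.int32), np.ones(50, np.int32)])
        counts = [sim.drop_gamete(haps, desc, pos, rng)[2] for _ in range(10_000)]
        m = np.mean(counts)
        assert abs(m - 1.0) < 3 * np.std(counts) / np.sqrt(len(counts))

    def test_crossover_counts_poisson_gof(self):
        """Chi-square goodness of fit of crossover counts to Poisson(2)."""
        rng = stream(7, "gof")
        pos = np.linspace(0, 200, 30)
        haps = np.zeros((2, 30), dtype=np.uint8)
        desc = np.stack([np.zeros(30, np.int32), np.ones(30, np.int32)])
        counts = np.array([sim.drop_gamete(haps, desc, pos, rng)[2]
                           for _ in range(10_000)])
        kmax = 7
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), 2.0)
        probs = np.append(pmf, 1 - pmf.sum())
        chi2, p = stats.chisquare(obs, probs * len(counts))
        assert p > 0.001

    def test_haldane_recombination_fraction(self):
        """Two markers 1 Morgan apart recombine with frequency
        (1 - exp(-2))/2 ~ 0.432."""
        rng = stream(3, "haldane")
        pos = np.array([0.0, 100.0])
        haps = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        desc = np.array([[0, 0], [1, 1]], dtype=np.int32)
        rec = 0
        n = 20_000
        for _ in range(n):
            h, _, _ = sim.drop_gamete(haps, desc, pos, rng)
            rec += h[0] != h[1]
        expect = 0.5 * (1 - np.exp(-2))
        assert rec / n == pytest.approx(expect, abs=3 * np.sqrt(expect * (1 - expect) / n))


class TestBreedPopulation:
    def test_minimal_design_bookkeeping(self, founders, small_map):
        d = sim.BreedingDesign(n_generations=1, n_sires=1, n_dams=1,
                               n_families=1, offspring_per_family=2,
                               mating="monogamous")
        pop = sim.breed_population(founders, d, small_map, seed=5)
        kids = pop.pedigree[pop.pedigree["generation"] == 1]
        assert len(kids) == 2
        assert kids["sire"].nunique() == 1 and kids["dam"].nunique() == 1

    def test_full_sib_counts(self, small_pop):
        fin = small_pop.pedigree[small_pop.pedigree["generation"] == 2]
        sizes = fin.groupby(["sire", "dam"]).size()
        assert (sizes == 6).all()

    def test_infeasible_design_rejected(self):
        with pytest.raises(ValueError):
            sim.BreedingDesign(n_sires=2, n_dams=2, n_families=5)

    def test_mendelian_consistency(self, small_pop):
        """Every transmitted allele exists in the transmitting parent."""
        ped = small_pop.pedigree
        hs = small_pop.hapset
        idx = {i: k for k, i in enumerate(ped["id"])}
        rng = np.random.default_rng(0)
        nonf = ped[ped["sire"] != 0]
        for r in nonf.sample(min(len(nonf), 40), random_state=1).itertuples():
            k = idx[r.id]
            for side, parent in ((0, r.sire), (1, r.dam)):
                p = idx[parent]
                child = hs.haps[k, side]
                ok = (child == hs.haps[p, 0]) | (child == hs.haps[p, 1])
                assert ok.all()

    def test_descent_labels_trace_founder_gametes(self, small_pop):
        founder_labels = set(range(2 * (small_pop.pedigree["generation"] == 0).sum()))
        assert set(np.unique(small_pop.hapset.descent)) <= founder_labels

    def test_true_ibd_parent_offspring_exact_half(self, sib_pop):
        """A parent passes exactly one gamete: true fraction 0.5, variance 0."""
        M = sim.true_ibd_matrix(sib_pop.hapset)
        ped = sib_pop.pedigree
        idx = {i: k for k, i in enumerate(ped["id"])}
        vals = [M[idx[r.id], idx[r.sire]]
                for r in ped[ped["sire"] != 0].itertuples()]
        assert np.allclose(vals, 0.5)

    def test_true_ibd_fullsib_mean_half_with_spread(self, sib_pop):
        M = sim.true_ibd_matrix(sib_pop.hapset)
        ped = sib_pop.pedigree
        idx = {i: k for k, i in enumerate(ped["id"])}
        fin = ped[ped["generation"] == 1]
        vals = []
        for (s, d), grp in fin.groupby(["sire", "dam"]):
            ids = grp["id"].tolist()
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    vals.append(M[idx[ids[a]], idx[ids[b]]])
        vals = np.asarray(vals)
        assert abs(vals.mean() - 0.5) < 0.02
        assert vals.std() > 0.01


class TestTraits:
    def test_h2_rescaling_exact(self, small_pop):
        tv = sim.assign_trait(small_pop, sim.TraitModel(60, 0.43), seed=9)
        base = (small_pop.pedigree["generation"] == 0).to_numpy()
        ratio = tv.tbv[base].var() / (tv.tbv[base].var() + tv.sigma_e2)
        assert ratio == pytest.approx(0.43, abs=1e-10)

    def test_zero_qtl_rejected(self):
        with pytest.raises(ValueError):
            sim.TraitModel(n_qtl=0, h2=0.3)

    def test_correlated_traits_hit_target(self, small_pop):
        t1 = sim.TraitModel(60, 0.14)
        t2 = sim.TraitModel(60, 0.14)
        tv1, tv2 = sim.assign_correlated_traits(small_pop, t1, t2, 0.72, seed=4)
        base = (small_pop.pedigree["generation"] == 0).to_numpy()
        got = np.corrcoef(tv1.tbv[base], tv2.tbv[base])[0, 1]
        assert got == pytest.approx(0.72, abs=1e-10)

    def test_noise_free_phenotype_equals_tbv(self, small_pop):
        tv = sim.assign_trait(small_pop, sim.TraitModel(60, 0.43, mean=5.0), seed=2)
        tv.sigma_e2 = 0.0
        design = sim.FixedEffectDesign(n_tests=1, person_day_sd=0.0,
                                       gender_effect=0.0, test_effect_sd=0.0)
        ph = sim.generate_phenotypes(small_pop, {"color": tv}, seed=3,
                                     design=design)
        rows = small_pop.index_of(ph["id"])
        assert np.allclose(ph["fc"], 5.0 + tv.tbv[rows], atol=1e-12)

    def test_count_trait_roundtrip_and_skewness(self, small_pop):
        """Counts are skewed; the log-density recomputed from (LC, BW)
        recovers the latent value up to rounding."""
        from admixgs import traits as tr
        tv = sim.assign_trait(small_pop, sim.TraitModel(
            60, 0.14, "log-density-count", mean=-1.7, phen_var=0.53), seed=6)
        ph = tr.derive(sim.generate_phenotypes(small_pop, {"lice": tv}, seed=7))
        ok = ph["lc"] > 0
        err = (ph.loc[ok, "logld"] - ph.loc[ok, "logld_latent"]).abs()
        assert (err < 1 / (ph.loc[ok, "lc"])).all()
        assert stats.skew(ph["lc"]) > stats.skew(ph["logld"])
        assert abs(stats.skew(ph["logld"])) < 1.0

    def test_phenotype_rejects_empty_generation(self, small_pop):
        tv = sim.assign_trait(small_pop, sim.TraitModel(60, 0.43), seed=2)
        with pytest.raises(ValueError):
            sim.generate_phenotypes(small_pop, {"color": tv}, seed=3,
                                    generation=9)


class TestSelectGenotyped:
    @pytest.fixture()
    def pheno(self, small_pop):
        rng = np.random.default_rng(0)
        ids = small_pop.generation_ids(2)
        return pd.DataFrame({"id": ids, "logld": rng.normal(size=len(ids))})

    def test_fraction_one_returns_all(self, pheno, small_pop):
        got = sim.select_genotyped(pheno, small_pop.pedigree, 1.0, "random", 1)
        assert set(got) == set(pheno["id"])

    def test_extreme_mode_takes_both_tails(self, pheno, small_pop):
        got = sim.select_genotyped(pheno, small_pop.pedigree, 0.5,
                                   "extreme-families", 1)
        ped = small_pop.pedigree.set_index("id")
        fam = pheno.assign(f=[(ped.loc[i, "sire"], ped.loc[i, "dam"])
                              for i in pheno["id"]])
        means = fam.groupby("f")["logld"].mean().sort_values()
        chosen_fams = set(fam[fam["id"].isin(got)]["f"])
        ranks = {f: r for r, f in enumerate(means.index)}
        mid = len(means) / 2
        # chosen families are more extreme in rank than unchosen ones
        chosen_dev = np.mean([abs(ranks[f] - mid) for f in chosen_fams])
        other_dev = np.mean([abs(ranks[f] - mid) for f in means.index
                             if f not in chosen_fams])
        assert chosen_dev > other_dev

    def test_extreme_mode_inflates_between_family_variance(self, pheno, small_pop):
        got = sim.select_genotyped(pheno, small_pop.pedigree, 0.4,
                                   "extreme-families", 1)
        ped = small_pop.pedigree.set_index("id")
        fam = pheno.assign(f=[(ped.loc[i, "sire"], ped.loc[i, "dam"])
                              for i in pheno["id"]])
        var_all = fam.groupby("f")["logld"].mean().var()
        var_sel = fam[fam["id"].isin(got)].groupby("f")["logld"].mean().var()
        assert var_sel > var_all

    def test_invalid_inputs(self, pheno, small_pop):
        with pytest.raises(ValueError):
            sim.select_genotyped(pheno.iloc[:0], small_pop.pedigree, 0.5)
        with pytest.raises(ValueError):
            sim.select_genotyped(pheno, small_pop.pedigree, 1.5)
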