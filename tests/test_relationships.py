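"""Pedigree A, VanRaden-2 GRM, marker subsets, ADJUST rescale, single-step H."""

import numpy as np
import pandas as pd
import pytest

from admixgs import simulate as sim
from admixgs.relationships import (RelationshipMatrix,
                                   adjust_to_pedigree, grm_vanraden2,
                                   make_marker_subsets, numerator_relationship,
                                   paper_density_scheme, single_step_h,
                                   topological_order)


class TestNumeratorRelationship:
    def test_founder_diagonal_one(self, toy_pedigree):
        A = numerator_relationship(toy_pedigree)
        d = dict(zip(A.ids, np.diag(A.values)))
        assert d[1] == 1.0 and d[2] == 1.0

    def test_full_sibs_half(self, toy_pedigree):
        A = numerator_relationship(toy_pedigree)
        i, j = A.index_of([3, 4])
        assert A.values[i, j] == pytest.approx(0.5)

    def test_full_sib_mating_inbreeding(self, toy_pedigree):
        """Offspring of a full-sib pair have F = 0.25."""
        A = numerator_relationship(toy_pedigree)
        i = A.index_of([5])[0]
        assert A.values[i, i] == pytest.approx(1.25)

    def test_half_sib_mating_inbreeding(self):
        ped = pd.DataFrame({
            "id": [1, 2, 3, 4, 5, 6],
            "sire": [0, 0, 0, 1, 1, 4],
            "dam": [0, 0, 0, 2, 3, 5],
        })
        A = numerator_relationship(ped)
        i = A.index_of([6])[0]
        assert A.values[i, i] == pytest.approx(1.125)

    def test_matches_path_counting_on_random_pedigrees(self):
        """Tabular method vs recursive-kinship oracle on all pedigrees of
        up to 8 individuals drawn at random."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = rng.integers(3, 9)
            sire, dam = [0], [0]
            for i in range(1, n):
                pool = list(range(1, i + 1))
                s = rng.choice(pool + [0, 0])
                d = rng.choice([x for x in pool + [0, 0] if x != s or x == 0])
                sire.append(int(s))
                dam.append(int(d))
            ped = pd.DataFrame({"id": range(1, n + 1), "sire": sire, "dam": dam})
            A = numerator_relationship(ped)
            oracle = _kinship_oracle(ped)
            got = A.restrict(ped["id"].to_numpy()).values
            assert np.allclose(got, oracle, atol=1e-12)

    def test_unsorted_pedigree_handled(self, toy_pedigree):
        shuffled = toy_pedigree.sample(frac=1.0, random_state=5)
        A1 = numerator_relationship(toy_pedigree)
        A2 = numerator_relationship(shuffled)
        assert np.allclose(A1.values, A2.restrict(A1.ids).values)

    def test_cycle_rejected(self):
        ped = pd.DataFrame({"id": [1, 2], "sire": [2, 1], "dam": [0, 0]})
        with pytest.raises(ValueError, match="cycle"):
            topological_order(ped)

    def test_own_parent_rejected(self):
        ped = pd.DataFrame({"id": [1], "sire": [1], "dam": [0]})
        with pytest.raises(ValueError, match="own parent"):
            topological_order(ped)


def _kinship_oracle(ped: pd.DataFrame) -> np.ndarray:
    """Recursive kinship coefficients, independent of the tabular code."""
    parents = {r.id: (r.sire, r.dam) for r in ped.itertuples()}
    ids = ped["id"].tolist()
    born = {i: k for k, i in enumerate(ids)}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i, j):
        if i == 0 or j == 0:
            return 0.0
        if i == j:
            s, d = parents[i]
            return 0.5 * (1.0 + f(s, d))
        if born[i] < born[j]:
            i, j = j, i
        s, d = parents[i]
        return 0.5 * (f(s, j) + f(d, j))

    A = np.empty((len(ids), len(ids)))
    for a, i in enumerate(ids):
        for b, j in enumerate(ids):
            A[a, b] = 2 * f(i, j)   # diagonal: 2 f(i,i) = 1 + F_i
    return A


class TestGRM:
    def test_all_heterozygous_gives_zero(self):
        X = np.ones((4, 10))
        G = grm_vanraden2(X)
        assert np.allclose(G.values, 0.0)

    def test_duplicate_individual_rows_equal(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, (6, 200)).astype(float)
        X[5] = X[0]
        G = grm_vanraden2(X)
        assert G.values[0, 0] == pytest.approx(G.values[5, 5])
        assert G.values[0, 5] == pytest.approx(G.values[0, 0])

    def test_matches_definition(self):
        """Entry-wise against the literal sum over markers."""
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, (8, 50)).astype(float)
        G = grm_vanraden2(X)
        p = X.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        Xc = X[:, keep] - 2 * p[keep]
        expect = np.zeros((8, 8))
        for j in range(keep.sum()):
            pj = p[keep][j]
            expect += np.outer(Xc[:, j], Xc[:, j]) / (2 * pj * (1 - pj))
        expect /= keep.sum()
        assert np.allclose(G.values, expect, atol=1e-10)

    def test_expected_grm_equals_A_by_gene_dropping(self, sib_pop):
        """With base-population frequencies, E[G] = A: class means of G
        match pedigree values under gene dropping."""
        gmap10 = sim.GeneticMap.uniform(5, 500, 100)
        f = sim.simulate_founders(sim.FounderModel(1, 0.0, (0.2, 0.8)),
                                  gmap10, 30, seed=51)
        d = sim.BreedingDesign(n_generations=1, n_sires=15, n_dams=15,
                               n_families=15, offspring_per_family=6,
                               mating="monogamous")
        pop = sim.breed_population(f, d, gmap10, seed=52)
        base = pop.pedigree["generation"] == 0
        # true generating frequencies, not the realized founder sample
        # (sample frequencies induce the familiar -1/N centring bias)
        G = grm_vanraden2(pop.hapset.dosages().astype(float),
                          ids=pop.ids, freqs=f.allele_freqs[0])
        A = numerator_relationship(pop.pedigree).restrict(G.ids)
        for target in (0.5, 0.0):
            mask = np.isclose(A.values, target) & ~np.eye(A.n, dtype=bool)
            assert G.values[mask].mean() == pytest.approx(target, abs=0.03)
        diag_nonf = np.diag(G.values)[~base.to_numpy()]
        assert diag_nonf.mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            grm_vanraden2(np.zeros((3, 5)))


class TestMarkerSubsets:
    def test_three_disjoint_pairs_cover_six(self):
        subs = make_marker_subsets(6, [2], [3], seed=0)
        all_idx = np.concatenate([s.indices for s in subs])
        assert sorted(all_idx) == list(range(6))

    def test_disjoint_and_sized(self):
        subs = make_marker_subsets(1000, [50, 100], [4, 2], seed=1)
        by_d = {}
        for s in subs:
            by_d.setdefault(s.density, []).append(s.indices)
        for d, parts in by_d.items():
            union = np.concatenate(parts)
            assert len(union) == len(set(union)) == d * len(parts)

    def test_paper_scheme_scaled(self):
        scheme = paper_density_scheme(220_000)
        assert scheme[22_000] == 10 and scheme[55_000] == 4
        assert scheme[220_000] == 1
        small = paper_density_scheme(2200)
        assert all(d * r <= 2200 for d, r in small.items())

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            make_marker_subsets(10, [4], [3], seed=0)

    def test_seed_changes_membership_not_shape(self):
        a = make_marker_subsets(100, [10], [3], seed=1)
        b = make_marker_subsets(100, [10], [3], seed=2)
        assert [len(s.indices) for s in a] == [len(s.indices) for s in b]
        assert any(not np.array_equal(x.indices, y.indices)
                   for x, y in zip(a, b))


class TestAdjust:
    def _toy(self):
        ids = np.array([1, 2, 3])
        G = RelationshipMatrix(ids, np.array([[1.2, 0.3, 0.1],
                                              [0.3, 1.4, 0.2],
                                              [0.1, 0.2, 1.0]]), "GRM-VR2")
        A = RelationshipMatrix(ids, np.array([[1.0, 0.5, 0.25],
                                              [0.5, 1.0, 0.25],
                                              [0.25, 0.25, 1.0]]), "PED-A")
        return G, A

    def test_fixed_point(self):
        _, A = self._toy()
        out = adjust_to_pedigree(A, A)
        assert np.allclose(out.values, A.values, atol=1e-12)

    def test_means_matched(self):
        G, A = self._toy()
        out = adjust_to_pedigree(G, A)
        off = ~np.eye(3, dtype=bool)
        assert np.diag(out.values).mean() == pytest.approx(
            np.diag(A.values).mean(), abs=1e-10)
        assert out.values[off].mean() == pytest.approx(
            A.values[off].mean(), abs=1e-10)

    def test_coefficients_match_hand_solved_system(self):
        G, A = self._toy()
        out = adjust_to_pedigree(G, A)
        off = ~np.eye(3, dtype=bool)
        md_g, mo_g = np.diag(G.values).mean(), G.values[off].mean()
        md_a, mo_a = np.diag(A.values).mean(), A.values[off].mean()
        beta = np.linalg.solve([[1, md_g], [1, mo_g]], [md_a, mo_a])
        assert out.meta["adjust_alpha"] == pytest.approx(beta[0], abs=1e-10)
        assert out.meta["adjust_beta"] == pytest.approx(beta[1], abs=1e-10)

    def test_constant_matrix_rejected(self):
        ids = np.array([1, 2])
        C = RelationshipMatrix(ids, np.full((2, 2), 0.5))
        A = RelationshipMatrix(ids, np.eye(2))
        with pytest.raises(ValueError, match="degenerate"):
            adjust_to_pedigree(C, A)


class TestSingleStepH:
    @pytest.fixture()
    def setup(self, toy_pedigree):
        A = numerator_relationship(toy_pedigree)
        rng = np.random.default_rng(3)
        geno = np.array([5, 6])
        A22 = A.restrict(geno).values
        noise = rng.normal(0, 0.05, (2, 2))
        G = RelationshipMatrix(geno, A22 + 0.5 * (noise + noise.T), "GRM-VR2")
        return A, G, geno

    def test_all_genotyped_gives_G(self, setup):
        A, _, _ = setup
        rng = np.random.default_rng(0)
        n = A.n
        E = rng.normal(0, 0.03, (n, n))
        G = RelationshipMatrix(A.ids, A.values + E + E.T, "GRM-VR2")
        H, Hi = single_step_h(A, G, A.ids)
        assert np.allclose(H.restrict(A.ids).values, G.values, atol=1e-10)

    def test_none_genotyped_gives_A(self, setup):
        A, _, _ = setup
        H, Hi = single_step_h(A, None, [])
        assert np.allclose(H.values, A.values)
        assert np.allclose(Hi, np.linalg.inv(A.values), atol=1e-8)

    def test_direct_formula_oracle(self, setup):
        """Dense H against a literal evaluation of the block identity."""
        A, G, geno = setup
        H, Hi = single_step_h(A, G, geno)
        order = H.ids
        Av = A.restrict(order).values
        n1 = A.n - len(geno)
        A11, A12 = Av[:n1, :n1], Av[:n1, n1:]
        A22 = Av[n1:, n1:]
        Gv = G.restrict(order[n1:]).values
        A22i = np.linalg.inv(A22)
        D = Gv - A22
        expect = Av.copy()
        expect[:n1, :n1] = A11 + A12 @ A22i @ D @ A22i @ A12.T
        expect[:n1, n1:] = A12 + A12 @ A22i @ D
        expect[n1:, :n1] = expect[:n1, n1:].T
        expect[n1:, n1:] = Gv
        assert np.allclose(H.values, expect, atol=1e-10)

    def test_inverse_identity(self, setup):
        A, G, geno = setup
        H, Hi = single_step_h(A, G, geno)
        assert np.allclose(H.values @ Hi, np.eye(H.n), atol=1e-8)

    def test_unknown_genotyped_id_rejected(self, setup):
        A, G, _ = setup
        with pytest.raises(ValueError):
            single_step_h(A, G, [99])


class TestRelationshipMatrixIO:
    def test_tsv_roundtrip(self, toy_pedigree, tmp_path):
        A = numerator_relationship(toy_pedigree)
        path = tmp_path / "a.tsv"
        A.to_tsv(path)
        back = RelationshipMatrix.from_tsv(path)
        assert np.allclose(back.values, A.values, atol=1e-9)
        assert list(back.ids) == list(A.ids)

    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            RelationshipMatrix(np.array([1, 2]),
                               np.array([[1.0, 0.2], [0.4, 1.0]]))
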