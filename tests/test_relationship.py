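import numpy as np
import pandas as pd
import pytest

from bdsmap.io import GenotypeDataset, Pedigree
from bdsmap.relationship import (InbreedingVector, RelationshipMatrix,
                                 balding_nichols_kinship, base_allele_freqs,
                                 earliest_cohort, genomic_inbreeding,
                                 grm_principal_components, grm_vanraden,
                                 pedigree_inbreeding)
from bdsmap.simulate import simulate_confounded_families
from conftest import make_dataset


def _tiny(calls, birth=None):
    n, m = calls.shape
    loci = pd.DataFrame({"snp": [f"s{j}" for j in range(m)], "chrom": "1",
                         "pos": np.arange(1, m + 1)})
    return GenotypeDataset([f"A{i}" for i in range(n)],
                           birth if birth is not None else np.full(n, 1970.0),
                           loci, np.asarray(calls, dtype=np.int8))


class TestBaseFreqs:
    def test_mean_dosage_over_base(self):
        g = _tiny(np.array([[0], [1], [2], [2]]))
        p = base_allele_freqs(g, ["A0", "A1", "A2"])
        assert p[0] == pytest.approx(0.5)

    def test_monomorphic_base_clamped_with_warning(self):
        g = _tiny(np.array([[2], [2], [2], [0]]))
        with pytest.warns(UserWarning, match="clamped"):
            p = base_allele_freqs(g, ["A0", "A1", "A2"])
        assert p[0] == pytest.approx(1 - 1 / 12)

    def test_empty_base_errors(self):
        g = _tiny(np.array([[0], [2]]))
        with pytest.raises(ValueError):
            base_allele_freqs(g, [])

    def test_founder_freqs_match_truth(self):
        rng = np.random.default_rng(2)
        truth = rng.uniform(0.2, 0.8, 300)
        calls = rng.binomial(2, truth, size=(400, 300)).astype(np.int8)
        g = _tiny(calls)
        p = base_allele_freqs(g, g.animals)
        se = np.sqrt(truth * (1 - truth) / (2 * 400))
        assert (np.abs(p - truth) < 3.5 * se).mean() > 0.98

    def test_earliest_cohort_rule(self):
        g = _tiny(np.array([[0], [1], [2]]), birth=[1990.0, 1950.0, 1970.0])
        assert earliest_cohort(g, 2) == ["A1", "A2"]


class TestVanRadenGRM:
    def test_hand_example_single_snp(self):
        g = _tiny(np.array([[0], [2]]))
        G = grm_vanraden(g, np.array([0.5]))
        np.testing.assert_allclose(G.matrix, [[2, -2], [-2, 2]])

    def test_dosages_at_reference_give_zero_matrix(self):
        g = _tiny(np.array([[1, 2], [1, 2]]))
        G = grm_vanraden(g, np.array([0.5, 1 - 1e-3]))
        assert np.abs(G.matrix).max() < 0.02

    def test_founder_diagonal_near_one(self):
        rng = np.random.default_rng(3)
        truth = rng.uniform(0.1, 0.9, 500)
        calls = rng.binomial(2, truth, size=(100, 500)).astype(np.int8)
        g = _tiny(calls)
        G = grm_vanraden(g, truth)
        assert abs(np.diag(G.matrix).mean() - 1.0) < 0.05

    def test_locus_permutation_invariance(self, small_dataset):
        g = small_dataset
        p = g.dosages().mean(axis=0) / 2
        G1 = grm_vanraden(g, p).matrix
        perm = np.random.default_rng(0).permutation(g.n_snps)
        G2 = grm_vanraden(g.subset(snp_idx=perm), p[perm]).matrix
        np.testing.assert_allclose(G1, G2, atol=1e-10)

    def test_zero_denominator_errors(self):
        g = _tiny(np.array([[0], [2]]))
        with pytest.raises(ValueError, match="denominator"):
            grm_vanraden(g, np.array([1.0]))


class TestBaldingNichols:
    def test_identical_rows_match_diagonal(self):
        g = _tiny(np.array([[2, 0, 1, 2], [2, 0, 1, 2], [0, 2, 1, 0],
                            [1, 1, 2, 1]]))
        K = balding_nichols_kinship(g).matrix
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_opposite_homozygotes_minimal(self):
        g = _tiny(np.array([[2, 0, 1, 2], [2, 0, 1, 2], [0, 2, 1, 0],
                            [1, 1, 2, 1]]))
        K = balding_nichols_kinship(g).matrix
        assert K[0, 2] == pytest.approx(K.min())

    def test_monomorphic_rejected(self):
        g = _tiny(np.array([[2, 1], [2, 0]]))
        with pytest.raises(ValueError, match="monomorphic"):
            balding_nichols_kinship(g)

    def test_family_structure_resolved(self):
        g = simulate_confounded_families(n_animals=120, m_snps=400,
                                         n_families=2, fst=0.1,
                                         family_time_concentration=1.0, seed=5)
        K = balding_nichols_kinship(g).matrix
        fam = g.birth_date > 1975
        within = np.concatenate([K[np.ix_(fam, fam)].ravel(),
                                 K[np.ix_(~fam, ~fam)].ravel()])
        between = K[np.ix_(fam, ~fam)].ravel()
        assert within.mean() > between.mean()


class TestPedigreeInbreeding:
    @staticmethod
    def _ped(rows):
        df = pd.DataFrame(rows, columns=["animal", "sire", "dam",
                                         "birth_date"])
        return Pedigree(df)

    def test_unrelated_parents_give_zero(self):
        ped = self._ped([("s", "0", "0", 1.0), ("d", "0", "0", 1.0),
                         ("x", "s", "d", 2.0)])
        assert pedigree_inbreeding(ped).F["x"] == pytest.approx(0.0)

    def test_full_sib_mating(self):
        ped = self._ped([("a", "0", "0", 1.0), ("b", "0", "0", 1.0),
                         ("s", "a", "b", 2.0), ("d", "a", "b", 2.0),
                         ("x", "s", "d", 3.0)])
        assert pedigree_inbreeding(ped).F["x"] == pytest.approx(0.25)

    def test_half_sib_mating(self):
        ped = self._ped([("a", "0", "0", 1.0), ("b", "0", "0", 1.0),
                         ("c", "0", "0", 1.0),
                         ("s", "a", "b", 2.0), ("d", "a", "c", 2.0),
                         ("x", "s", "d", 3.0)])
        assert pedigree_inbreeding(ped).F["x"] == pytest.approx(0.125)

    def test_founders_zero(self):
        ped = self._ped([("a", "0", "0", 1.0), ("b", "0", "0", 1.0)])
        assert (pedigree_inbreeding(ped).F == 0).all()


class TestGenomicInbreeding:
    def test_diagonal_minus_one(self):
        G = RelationshipMatrix(np.array([[1.05, 0.2], [0.2, 1.0]]),
                               kind="grm_vanraden", ids=["a", "b"])
        F = genomic_inbreeding(G).F
        assert F["a"] == pytest.approx(0.05)
        assert F["b"] == pytest.approx(0.0)

    def test_requires_vanraden(self):
        K = RelationshipMatrix(np.eye(2), kind="balding_nichols")
        with pytest.raises(TypeError):
            genomic_inbreeding(K)


class TestPCA:
    def test_identity_equal_eigenvalues(self):
        G = RelationshipMatrix(np.eye(6), kind="grm_vanraden")
        scores, w = grm_principal_components(G, 3)
        np.testing.assert_allclose(w, 1.0)
        np.testing.assert_allclose(scores.T @ scores, np.eye(3), atol=1e-10)

    def test_low_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        B = rng.normal(size=(8, 3))
        G = RelationshipMatrix(B @ B.T, kind="grm_vanraden")
        scores, w = grm_principal_components(G, 5)
        np.testing.assert_allclose(scores @ scores.T, G.matrix, atol=1e-8)

    def test_diverged_subpopulations_separate_on_pc1(self):
        g = simulate_confounded_families(n_animals=100, m_snps=400,
                                         n_families=2, fst=0.15,
                                         family_time_concentration=1.0, seed=2)
        G = grm_vanraden(g, g.dosages().mean(axis=0) / 2)
        scores, _ = grm_principal_components(G, 2)
        fam = g.birth_date > 1975
        lo, hi = scores[fam, 0], scores[~fam, 0]
        assert lo.max() < hi.min() or hi.max() < lo.min()

    def test_k_validation(self):
        G = RelationshipMatrix(np.eye(4), kind="grm_vanraden")
        with pytest.raises(ValueError):
            grm_principal_components(G, 0)
        with pytest.raises(ValueError):
            grm_principal_components(G, 4)


class TestSimulationLinkedProperties:
    def test_parent_offspring_grm_near_half(self):
        from bdsmap.simulate import SimConfig, simulate_selected_population

        cfg = SimConfig(n_founders=80, births_per_year=80, start_year=1950,
                        end_year=1960, n_chromosomes=5,
                        n_snps_per_chromosome=80, n_qtl=5, n_traits=1,
                        heritabilities=(0.4,), ebv_accuracy_r2=(0.7,),
                        index_eras=[(1950, np.array([0.0]))],
                        sire_usage_skew=0.0, seed=8)
        pop = simulate_selected_population(cfg)
        g = pop.genotypes
        p = base_allele_freqs(g, earliest_cohort(g, 80))
        G = grm_vanraden(g, p).matrix
        idx = {a: i for i, a in enumerate(g.animals)}
        vals = []
        for _, r in pop.pedigree.records.iterrows():
            if r["sire"] in idx and r["animal"] in idx:
                vals.append(G[idx[r["animal"]], idx[r["sire"]]])
        assert len(vals) > 100
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_selection_spreads_genomic_f_beyond_pedigree_f(self):
        from bdsmap.simulate import SimConfig, simulate_selected_population

        cfg = SimConfig(n_founders=150, births_per_year=150, start_year=1950,
                        end_year=1985, discrete_generations=True,
                        n_chromosomes=5, n_snps_per_chromosome=60,
                        n_qtl=30, n_traits=1, heritabilities=(0.4,),
                        ebv_accuracy_r2=(0.7,),
                        index_eras=[(1950, np.array([1.0]))],
                        proportion_sires=0.15, proportion_dams=0.6, seed=8)
        pop = simulate_selected_population(cfg)
        g = pop.genotypes
        p = base_allele_freqs(g, earliest_cohort(g, 100))
        Fg = genomic_inbreeding(grm_vanraden(g, p)).F
        Fp = pedigree_inbreeding(pop.pedigree).F[g.animals]
        assert Fg.var() > Fp.var()
        # deeper-pedigree animals: genomic and pedigree F positively related
        slope = np.polyfit(Fg.to_numpy(), Fp.to_numpy(), 1)[0]
        assert slope > 0
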