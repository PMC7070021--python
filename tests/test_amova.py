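"""AMOVA variance partitioning, pairwise Fst and gene-flow tests."""

import numpy as np
import pytest

from firsurvey import amova as am
from firsurvey.containers import GenotypeMatrix
from firsurvey.synthetic import PopSimTruth, gen_population_genotypes


def _uniform_matrix(n, L, allele=1):
    calls = np.empty((n, L, 2), dtype=object)
    calls[:] = allele
    return GenotypeMatrix([f"i{j}" for j in range(n)], [f"L{j}" for j in range(L)], calls)


class TestAmova:
    def test_identical_individuals_zero_components(self):
        G = _uniform_matrix(6, 4)
        table = am.amova(G, ["x"] * 3 + ["y"] * 3, n_permutations=0)
        assert all(r.variance == 0 for r in table.rows)
        assert table.phi_st == 0.0

    def test_fixed_differences_full_partition(self):
        calls = np.empty((8, 5, 2), dtype=object)
        calls[:4] = 1
        calls[4:] = 2
        G = GenotypeMatrix([f"i{j}" for j in range(8)], [f"L{j}" for j in range(5)], calls)
        table = am.amova(G, ["x"] * 4 + ["y"] * 4, n_permutations=99, seed=0)
        assert table.phi_st == pytest.approx(1.0)
        assert table["among groups"].percent == pytest.approx(100.0)
        assert table["among groups"].p_value <= 0.05

    def test_fst_recovery_balding_nichols(self, three_group_sim):
        table = am.amova(
            three_group_sim.genotypes, three_group_sim.group_labels, n_permutations=0
        )
        assert abs(table.phi_st - 0.2) < 0.05

    def test_no_structure_k1_split(self):
        sim = gen_population_genotypes(
            PopSimTruth(n_groups=1, fst=0.2, group_sizes=(40,), n_loci=30, seed=5)
        )
        # arbitrary split of one panmictic group: among-group percent ~ 0
        labels = ["a"] * 20 + ["b"] * 20
        table = am.amova(sim.genotypes, labels, n_permutations=99, seed=1)
        assert table["among groups"].percent < 5.0
        assert table["among groups"].p_value > 0.05

    def test_percentages_sum_to_100(self, three_group_sim):
        table = am.amova(
            three_group_sim.genotypes, three_group_sim.group_labels, n_permutations=0
        )
        assert sum(r.percent for r in table.rows) == pytest.approx(100.0)

    def test_total_ss_invariant_under_relabeling(self, three_group_sim):
        G = three_group_sim.genotypes
        labels = three_group_sim.group_labels
        rng = np.random.default_rng(3)
        t1 = am.amova(G, labels, n_permutations=0)
        shuffled = [labels[i] for i in rng.permutation(len(labels))]
        t2 = am.amova(G, shuffled, n_permutations=0)
        ss1 = sum(r.ss for r in t1.rows)
        ss2 = sum(r.ss for r in t2.rows)
        assert ss1 == pytest.approx(ss2)

    def test_small_group_rejected(self):
        G = _uniform_matrix(3, 2)
        with pytest.raises(ValueError):
            am.amova(G, ["x", "x", "y"], n_permutations=0)

    def test_two_level_design(self):
        sim = gen_population_genotypes(
            PopSimTruth(n_groups=4, fst=0.2, group_sizes=(20, 20, 20, 20), n_loci=30, seed=8)
        )
        groups = ["A"] * 40 + ["B"] * 40
        table = am.amova(
            sim.genotypes, groups, subgroup_labels=sim.group_labels,
            n_permutations=49, seed=2,
        )
        assert len(table.rows) == 3
        assert sum(r.percent for r in table.rows) == pytest.approx(100.0)
        # real divergence sits among subgroups, not between the arbitrary
        # A/B supergroups
        assert table["among subgroups within groups"].percent > 10
        assert table["among groups"].percent < 10


class TestPairwiseFst:
    def test_matrix_structure(self, three_group_sim):
        names, fst, p = am.pairwise_fst(
            three_group_sim.genotypes, three_group_sim.group_labels, n_permutations=0
        )
        assert np.allclose(fst, fst.T)
        assert np.all(np.diag(fst) == 0)

    def test_matches_two_group_amova_exactly(self, three_group_sim):
        G = three_group_sim.genotypes
        labels = three_group_sim.group_labels
        names, fst, _ = am.pairwise_fst(G, labels, n_permutations=0)
        idx = [i for i, lab in enumerate(labels) if lab in ("G1", "G2")]
        sub = GenotypeMatrix([G.individuals[i] for i in idx], G.loci, G.calls[idx])
        table = am.amova(sub, [labels[i] for i in idx], n_permutations=0)
        assert fst[names.index("G1"), names.index("G2")] == pytest.approx(table.phi_st)

    def test_null_pair_near_zero(self):
        sim = gen_population_genotypes(
            PopSimTruth(n_groups=1, fst=0.2, group_sizes=(50,), n_loci=40, seed=4)
        )
        labels = ["a"] * 25 + ["b"] * 25
        _, fst, p = am.pairwise_fst(sim.genotypes, labels, n_permutations=99, seed=3)
        assert abs(fst[0, 1]) < 0.05
        assert p[0, 1] > 0.05

    def test_recovery_at_fst_025(self):
        sim = gen_population_genotypes(
            PopSimTruth(n_groups=2, fst=0.25, group_sizes=(60, 60), n_loci=40, seed=6)
        )
        _, fst, _ = am.pairwise_fst(sim.genotypes, sim.group_labels, n_permutations=0)
        assert 0.20 <= fst[0, 1] <= 0.30

    def test_near_fixed_groups(self):
        sim = gen_population_genotypes(
            PopSimTruth(
                n_groups=2, fst=0.99, group_sizes=(20, 20), n_loci=20,
                alleles_per_locus=2, seed=7,
            )
        )
        _, fst, _ = am.pairwise_fst(sim.genotypes, sim.group_labels, n_permutations=0)
        assert fst[0, 1] > 0.9


class TestNmFromFst:
    def test_published_value(self):
        assert am.nm_from_fst(0.2133) == pytest.approx(0.92, abs=0.005)

    def test_complete_differentiation(self):
        assert am.nm_from_fst(1.0) == 0.0

    def test_hand_arithmetic(self):
        assert am.nm_from_fst(0.25) == pytest.approx(0.75)

    def test_monotone_decreasing_and_invertible(self):
        grid = np.linspace(0.01, 1.0, 25)
        values = [am.nm_from_fst(f) for f in grid]
        assert all(a > b for a, b in zip(values, values[1:]))
        for f in grid:
            nm = am.nm_from_fst(f)
            assert 1.0 / (4 * nm + 1) == pytest.approx(f, rel=1e-12)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            am.nm_from_fst(0.0)
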