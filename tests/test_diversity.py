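"""Allele-frequency, diversity-statistic and Nei-distance tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firsurvey import diversity
from firsurvey.containers import GenotypeMatrix


def _matrix(calls_list, loci=None):
    calls = np.empty((len(calls_list), len(calls_list[0]), 2), dtype=object)
    for i, row in enumerate(calls_list):
        for l, pair in enumerate(row):
            calls[i, l] = pair
    names = [f"i{j}" for j in range(len(calls_list))]
    loci = loci or [f"L{j}" for j in range(len(calls_list[0]))]
    return GenotypeMatrix(names, loci, calls)


class TestAlleleFrequencies:
    def test_monomorphic(self):
        G = _matrix([[("A", "A")]] * 10)
        freqs, n = diversity.allele_frequencies(G, 0)
        assert freqs == {"A": 1.0}
        assert n == 10

    def test_hand_count(self):
        G = _matrix([[("A", "B")], [("A", "A")]])
        freqs, n = diversity.allele_frequencies(G, 0)
        assert freqs == {"A": 0.75, "B": 0.25}
        assert n == 2

    def test_missing_excluded(self):
        G = _matrix([[("A", "B")], [(None, None)]])
        _, n = diversity.allele_frequencies(G, 0)
        assert n == 1

    def test_all_missing_raises(self):
        G = _matrix([[(None, None)]])
        with pytest.raises(ValueError):
            diversity.allele_frequencies(G, 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_frequencies_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n, J = rng.integers(2, 12), rng.integers(2, 6)
        calls = [[tuple(rng.integers(1, J + 1, size=2).tolist())] for _ in range(n)]
        G = _matrix(calls)
        freqs, _ = diversity.allele_frequencies(G, 0)
        assert sum(freqs.values()) == pytest.approx(1.0)


class TestLocusStats:
    def test_monomorphic_locus(self):
        G = _matrix([[("A", "A")]] * 8)
        s = diversity.locus_stats(G, 0)
        assert (s.na, s.ne, s.ho, s.he, s.shannon_i, s.pic) == (1, 1.0, 0.0, 0.0, 0.0, 0.0)

    def test_even_biallelic_frequencies(self):
        # p = (0.5, 0.5): ne=2, he_raw=0.5, I=ln2, pic=0.375
        G = _matrix([[("A", "B")], [("A", "B")]])
        s = diversity.locus_stats(G, 0, he_correction="none")
        assert s.ne == pytest.approx(2.0)
        assert s.he == pytest.approx(0.5)
        assert s.shannon_i == pytest.approx(math.log(2))
        assert s.pic == pytest.approx(0.375)
        assert s.ho == 1.0

    def test_pic_three_allele_brute_force(self):
        # p = (0.5, 0.25, 0.25) -> PIC via explicit double sum
        p = [0.5, 0.25, 0.25]
        expected = 1 - sum(x**2 for x in p) - sum(
            2 * p[i] ** 2 * p[j] ** 2
            for i in range(len(p))
            for j in range(i + 1, len(p))
        )
        assert expected == pytest.approx(0.5546875)
        assert diversity.pic_from_frequencies(p) == pytest.approx(expected)

    def test_unbiased_correction_factor(self):
        G = _matrix([[("A", "B")], [("A", "B")]])
        raw = diversity.locus_stats(G, 0, he_correction="none").he
        unb = diversity.locus_stats(G, 0, he_correction="unbiased").he
        assert unb == pytest.approx(raw * 4 / 3)  # 2n/(2n-1) with n=2

    def test_ho_excludes_missing(self):
        G = _matrix([[("A", "B")], [(None, None)], [("A", "A")]])
        s = diversity.locus_stats(G, 0)
        assert s.ho == pytest.approx(0.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_identities_on_random_frequencies(self, seed):
        """He_raw = 1 - 1/Ne exactly; PIC <= He_raw."""
        rng = np.random.default_rng(seed)
        n, J = int(rng.integers(3, 20)), int(rng.integers(2, 8))
        calls = [
            [tuple(rng.integers(1, J + 1, size=2).tolist())] for _ in range(n)
        ]
        s = diversity.locus_stats(_matrix(calls), 0, he_correction="none")
        assert s.he == pytest.approx(1 - 1 / s.ne, rel=1e-12)
        assert s.pic <= s.he + 1e-12
        assert 1 <= s.ne <= s.na


class TestPublishedTable:
    def test_aggregation_reproduces_printed_means(self):
        df = diversity.load_clgssr_table()
        assert len(df) == 46
        assert df["na"].sum() == 298
        assert df["na"].mean() == pytest.approx(6.478, abs=0.001)
        assert df["ne"].mean() == pytest.approx(2.718, abs=0.001)
        assert df["ho"].mean() == pytest.approx(0.254, abs=0.001)
        assert df["he"].mean() == pytest.approx(0.573, abs=0.001)
        assert df["pic"].mean() == pytest.approx(0.526, abs=0.001)
        assert df["shannon_i"].mean() == pytest.approx(1.125, abs=0.001)

    def test_ne_he_identity_consistent_with_small_sample_correction(self):
        # printed He sits between the raw 1 - 1/Ne and the unbiased
        # (2n/(2n-1))-corrected value at n = 199
        df = diversity.load_clgssr_table()
        raw = 1 - 1 / df["ne"]
        corrected = raw * (2 * 199) / (2 * 199 - 1)
        # allow printed rounding at 3 decimals
        assert ((df["he"] - corrected).abs() < 0.015).mean() > 0.9

    def test_pic_classification_counts(self):
        df = diversity.load_clgssr_table()
        assert (df["pic"] > 0.5).sum() == 29


class TestNeiDistance:
    def test_identical_profiles(self):
        prof = {"L1": {"A": 0.5, "B": 0.5}}
        assert diversity.nei_da_distance(prof, prof) == pytest.approx(0.0)

    def test_disjoint_profiles(self):
        a = {"L1": {"A": 1.0}, "L2": {"C": 1.0}}
        b = {"L1": {"B": 1.0}, "L2": {"D": 1.0}}
        assert diversity.nei_da_distance(a, b) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        a = {"L1": {"A": 1.0, "B": 0.0}}
        b = {"L1": {"A": 0.5, "B": 0.5}}
        assert diversity.nei_da_distance(a, b) == pytest.approx(1 - math.sqrt(0.5))

    def test_no_shared_loci_raises(self):
        with pytest.raises(ValueError):
            diversity.nei_da_distance({"L1": {"A": 1.0}}, {"L2": {"A": 1.0}})

    def test_symmetry_and_zero_iff_identical(self, two_group_sim):
        G = two_group_sim.genotypes
        pa = diversity.frequency_profile(G, list(range(0, 10)))
        pb = diversity.frequency_profile(G, list(range(30, 40)))
        dab = diversity.nei_da_distance(pa, pb)
        dba = diversity.nei_da_distance(pb, pa)
        assert dab == pytest.approx(dba)
        assert dab > 0

    def test_individual_matrix_properties(self, two_group_sim):
        G = two_group_sim.genotypes
        D = diversity.individual_distance_matrix(G)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)
        assert np.all((0 <= D) & (D <= 1))
        # same-group pairs closer on average than cross-group pairs
        within = D[:25, :25][np.triu_indices(25, 1)].mean()
        between = D[:25, 25:].mean()
        assert between > within
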