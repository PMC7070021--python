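"""K-mer counting and genome-survey estimator tests."""

import numpy as np
import pytest

from firsurvey import kmer
from firsurvey.containers import KmerHistogram
from firsurvey.synthetic import SpectrumTruth, gen_kmer_spectrum


class TestCountKmers:
    def test_sequence_shorter_than_k_gives_empty_histogram(self):
        hist = kmer.count_kmers("ACGTACG", k=17)
        assert hist.counts == {}

    def test_homopolymer_multiplicity(self):
        # "AAAA" has three overlapping "AA" windows -> one k-mer seen 3x
        hist = kmer.count_kmers("AAAA", k=2, canonical=False)
        assert hist.counts == {3: 1}

    def test_canonical_merges_reverse_complements(self):
        # ACG windows: AC, CG; canonical(GT) would also be AC
        hist = kmer.count_kmers("ACG", k=2, canonical=True)
        assert hist.counts == {1: 2}
        # GT counted together with AC when canonical
        h2 = kmer.count_kmers(["AC", "GT"], k=2, canonical=True)
        assert h2.counts == {2: 1}

    def test_n_windows_skipped(self):
        hist = kmer.count_kmers("ACNGT", k=2, canonical=False)
        assert sum(hist.counts.values()) == 2  # AC and GT only

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            kmer.count_kmers("ACGT", k=0)

    def test_total_mass_matches_window_count_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            for canonical in (False, True):
                hist = kmer.count_kmers(seq, k=5, canonical=canonical)
                # total mass = number of windows regardless of key identity
                assert hist.total_kmers() == len(seq) - 5 + 1


class TestFindPeaks:
    def test_bimodal_spectrum_with_prior_picks_main(self):
        truth = SpectrumTruth(
            genome_size_bp=500_000, heterozygosity=0.02, mean_depth=30
        )
        hist = gen_kmer_spectrum(truth, seed=2)
        peaks, main = kmer.find_peaks(hist, prior_depth=30)
        depths = [d for d, _ in peaks]
        assert any(abs(d - 15) <= 2 for d in depths)
        assert any(abs(d - 30) <= 2 for d in depths)
        assert abs(main - 30) <= 2

    def test_unimodal_poisson_peak_at_mode(self):
        rng = np.random.default_rng(0)
        draws = rng.poisson(25, size=200_000)
        draws = draws[draws >= 1]
        vals, counts = np.unique(draws, return_counts=True)
        hist = KmerHistogram(17, dict(zip(vals.tolist(), counts.tolist())))
        _, main = kmer.find_peaks(hist)
        assert abs(main - 25) <= 1

    def test_error_only_histogram_raises(self):
        with pytest.raises(ValueError):
            kmer.find_peaks(KmerHistogram(17, {1: 10**6}), error_depth_cutoff=3)


class TestGenomeSize:
    def test_published_survey_division(self):
        # total 17-mer count / peak depth, at the printed magnitudes
        total = 347_935_256_501
        hist = KmerHistogram(17, {30: total // 30, 2: total // 30})
        # construct so filtered mass is exactly divisible contribution
        est = kmer.estimate_genome_size(hist, 30, error_depth_cutoff=3)
        assert est == (total // 30) * 30 // 30

    def test_simple_arithmetic(self):
        hist = KmerHistogram(17, {10: 100})
        assert kmer.estimate_genome_size(hist, 10, error_depth_cutoff=3) == 100

    def test_homogeneity_doubling_counts_doubles_estimate(self):
        hist = KmerHistogram(17, {10: 50, 20: 25, 30: 10})
        doubled = KmerHistogram(17, {d: 2 * c for d, c in hist.counts.items()})
        e1 = kmer.estimate_genome_size(hist, 10, 3)
        e2 = kmer.estimate_genome_size(doubled, 10, 3)
        assert e2 == 2 * e1

    def test_recovery_on_simulated_spectrum(self):
        truth = SpectrumTruth(genome_size_bp=10**6, mean_depth=30)
        hist = gen_kmer_spectrum(truth, seed=3)
        _, main = kmer.find_peaks(hist)
        est = kmer.estimate_genome_size(hist, main)
        assert abs(est - 10**6) / 10**6 < 0.05

    def test_zero_mass_raises(self):
        with pytest.raises(ValueError):
            kmer.estimate_genome_size(KmerHistogram(17, {1: 5}), 30, 3)


class TestHeterozygosity:
    def test_no_heterozygosity_gives_near_zero_signal(self):
        truth = SpectrumTruth(genome_size_bp=300_000, heterozygosity=0.0, mean_depth=30)
        hist = gen_kmer_spectrum(truth, seed=4)
        _, main = kmer.find_peaks(hist)
        assert kmer.estimate_heterozygous_signal(hist, main) < 0.02

    def test_calibrated_rate_recovers_simulated_rate(self):
        truth = SpectrumTruth(genome_size_bp=200_000, heterozygosity=0.02, mean_depth=30)
        hist = gen_kmer_spectrum(truth, seed=5)
        _, main = kmer.find_peaks(hist, prior_depth=30)
        signal = kmer.estimate_heterozygous_signal(hist, main)
        rate = kmer.calibrate_heterozygosity(signal)
        assert 0.015 <= rate <= 0.025

    def test_signal_monotone_in_rate(self):
        signals = []
        for rate in (0.01, 0.02, 0.04):
            truth = SpectrumTruth(
                genome_size_bp=200_000, heterozygosity=rate, mean_depth=30
            )
            hist = gen_kmer_spectrum(truth, seed=6)
            _, main = kmer.find_peaks(hist, prior_depth=30)
            signals.append(kmer.estimate_heterozygous_signal(hist, main))
        assert signals[0] < signals[1] < signals[2]


class TestRepeatFraction:
    def test_no_repeats_gives_near_zero(self):
        truth = SpectrumTruth(genome_size_bp=300_000, mean_depth=30)
        hist = gen_kmer_spectrum(truth, seed=7)
        _, main = kmer.find_peaks(hist)
        assert kmer.estimate_repeat_fraction(hist, main) < 0.02

    @pytest.mark.parametrize("frac,lo,hi", [(0.5, 0.4, 0.6), (0.75, 0.6, 0.9)])
    def test_recovery(self, frac, lo, hi):
        truth = SpectrumTruth(genome_size_bp=400_000, repeat_fraction=frac, mean_depth=30)
        hist = gen_kmer_spectrum(truth, seed=8)
        _, main = kmer.find_peaks(hist, prior_depth=30)
        assert lo <= kmer.estimate_repeat_fraction(hist, main) <= hi

    def test_monotone_in_truth(self):
        ests = []
        for frac in (0.25, 0.75):
            truth = SpectrumTruth(
                genome_size_bp=400_000, repeat_fraction=frac, mean_depth=30
            )
            hist = gen_kmer_spectrum(truth, seed=9)
            _, main = kmer.find_peaks(hist, prior_depth=30)
            ests.append(kmer.estimate_repeat_fraction(hist, main))
        assert ests[0] < ests[1]


class TestGcWindows:
    def test_pure_gc_window(self):
        rows = kmer.gc_depth_windows("GC" * 5_000, window_bp=10_000)
        assert len(rows) == 1
        assert rows[0][3] == 1.0

    def test_n_excluded_from_denominator(self):
        rows = kmer.gc_depth_windows("ATGCN" * 2_000, window_bp=10_000)
        assert rows[0][3] == pytest.approx(0.5)
        assert kmer.gc_content("ATGCN" * 2_000) == pytest.approx(0.5)

    def test_window_tiling_and_mean_gc(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=1_000_000))
        rows = kmer.gc_depth_windows(seq, window_bp=10_000)
        assert len(rows) == 100
        mean_gc = np.mean([r[3] for r in rows])
        assert abs(mean_gc - 0.5) < 0.01

    def test_short_trailing_window_dropped_half_kept(self):
        # 14 kb -> second window is 4 kb (< half) and dropped
        rows = kmer.gc_depth_windows("A" * 14_000, window_bp=10_000)
        assert len(rows) == 1
        # 16 kb -> 6 kb trailing window (>= half) kept
        rows = kmer.gc_depth_windows("A" * 16_000, window_bp=10_000)
        assert len(rows) == 2
        assert rows[1][2] - rows[1][1] == 6_000
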