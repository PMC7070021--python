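"""SSR scanner, motif classification, summaries and primer screening tests.

The scanner is checked against an independent brute-force oracle that
enumerates every (start, period) maximal perfect run, keeps primitive
units, collapses phase-shifted duplicates by left-maximality, and applies
the same documented leftmost-wins overlap rule.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firsurvey import ssr
from firsurvey.kmer import reverse_complement
from firsurvey.ssr import PrimerConstraints, canonical_motif_class, find_ssrs

MIN_REPEATS = dict(ssr.DEFAULT_MIN_REPEATS)


def _primitive(unit: str) -> bool:
    n = len(unit)
    return not any(n % d == 0 and unit == unit[:d] * (n // d) for d in range(1, n))


def brute_force_ssrs(seq: str, min_repeats=None):
    """Independent enumerator of maximal perfect repeats (oracle)."""
    min_repeats = min_repeats or MIN_REPEATS
    n = len(seq)
    found = []
    for p, min_rep in min_repeats.items():
        for start in range(n - p * min_rep + 1):
            unit = seq[start : start + p]
            if "N" in unit or not _primitive(unit):
                continue
            count = 1
            while seq[start + count * p : start + (count + 1) * p] == unit:
                count += 1
            if count < min_rep:
                continue
            # left-maximality: a phase-shifted copy would start earlier
            if start >= 1 and seq[start - 1] != "N" and seq[start - 1] == seq[start - 1 + p]:
                continue
            found.append((start, start + count * p, unit, count))
    # same documented overlap rule as the scanner: leftmost wins, then longer
    found.sort(key=lambda t: (t[0], -(t[1] - t[0]), len(t[2])))
    out, last_end = [], -1
    for t in found:
        if t[0] >= last_end:
            out.append(t)
            last_end = t[1]
    return out


class TestScanner:
    def test_minimum_repeat_thresholds(self):
        assert [(l.motif, l.repeat_count) for l in find_ssrs("ACACACACACAC")] == [("AC", 6)]
        assert find_ssrs("ACACACACAC") == []  # (AC)x5 below the minimum
        assert [(l.motif, l.repeat_count) for l in find_ssrs("AATAATAATAATAAT")] == [
            ("AAT", 5)
        ]
        assert [(l.motif, l.repeat_count) for l in find_ssrs("ACGTACGTACGTACGT")] == [
            ("ACGT", 4)
        ]

    def test_locus_invariants(self):
        for locus in find_ssrs("TTACACACACACACGG"):
            assert locus.end - locus.start == locus.unit_size * locus.repeat_count

    def test_mononucleotide_runs_never_reported(self):
        assert find_ssrs("A" * 50) == []

    def test_run_broken_at_n(self):
        # 6 + 6 repeats of AC separated by N: neither side reaches 6+6
        seq = "ACACACACACAC" + "N" + "ACACACACACAC"
        loci = find_ssrs(seq)
        assert [(l.start, l.repeat_count) for l in loci] == [(0, 6), (13, 6)]

    def test_non_primitive_unit_reported_at_smallest_period(self):
        loci = find_ssrs("AC" * 8)
        assert len(loci) == 1
        assert loci[0].motif == "AC"
        assert loci[0].repeat_count == 8

    def test_partial_trailing_unit_not_counted(self):
        loci = find_ssrs("ACACACACACACA")  # (AC)x6 + "A"
        assert [(l.repeat_count, l.end - l.start) for l in loci] == [(6, 12)]

    def test_loci_never_overlap_on_random_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGTN"), size=500, p=[0.24] * 4 + [0.04]))
            loci = find_ssrs(seq)
            for a, b in zip(loci, loci[1:]):
                assert a.end <= b.start

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # AT-rich backgrounds produce more near-repeats than uniform ones
        probs = [[0.25] * 4, [0.35, 0.15, 0.15, 0.35]][seed % 2]
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=2_000, p=probs))
            got = [(l.start, l.end, l.motif, l.repeat_count) for l in find_ssrs(seq)]
            assert got == brute_force_ssrs(seq)

    def test_oracle_agreement_with_ns(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), size=1_000, p=[0.23] * 4 + [0.08]))
            got = [(l.start, l.end, l.motif, l.repeat_count) for l in find_ssrs(seq)]
            assert got == brute_force_ssrs(seq)


class TestCanonicalClass:
    @pytest.mark.parametrize(
        "motif,expected",
        [("CTT", "AAG/CTT"), ("GTT", "AAC/GTT"), ("AAT", "AAT/ATT"), ("CG", "CG/CG")],
    )
    def test_published_class_labels(self, motif, expected):
        assert canonical_motif_class(motif) == expected

    def test_rotation_and_revcomp_closure(self):
        assert canonical_motif_class("TA") == canonical_motif_class("AT")
        assert canonical_motif_class("TA") == canonical_motif_class(
            reverse_complement("TA")
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=6))
    def test_invariance_property(self, motif):
        label = canonical_motif_class(motif)
        # idempotent on its own representative
        x = label.split("/")[0]
        assert canonical_motif_class(x) == label
        # invariant under rotation and reverse complement
        for i in range(len(motif)):
            assert canonical_motif_class(motif[i:] + motif[:i]) == label
        assert canonical_motif_class(reverse_complement(motif)) == label

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif_class("AXT")


class TestSummary:
    def test_published_unit_size_proportions(self):
        # the printed unit-size census: di 266,593 / tri 48,138 / tetra
        # 36,732 / penta 6,791 / hexa 3,939
        counts = {2: 266_593, 3: 48_138, 4: 36_732, 5: 6_791, 6: 3_939}
        summary = ssr.SSRSummary(
            total=sum(counts.values()),
            by_unit_size=counts,
            by_repeat_count={},
            by_class={},
            density_bp_per_locus=None,
        )
        props = summary.unit_size_proportions()
        assert props[2] == pytest.approx(0.736, abs=0.0005)
        assert props[3] == pytest.approx(0.133, abs=0.0005)
        assert props[4] == pytest.approx(0.101, abs=0.0005)
        assert props[5] == pytest.approx(0.019, abs=0.0005)
        assert props[6] == pytest.approx(0.011, abs=0.0005)

    def test_density_arithmetic(self):
        loci = find_ssrs("ACACACACACAC")
        summary = ssr.summarize_ssrs(loci * 1, non_n_length=13_184)
        assert summary.density_bp_per_locus == pytest.approx(13_184)

    def test_zero_loci_density_absent(self):
        summary = ssr.summarize_ssrs([], non_n_length=1_000)
        assert summary.density_bp_per_locus is None
        assert summary.total == 0

    def test_compound_report_clusters_nearby_loci(self):
        seq = "AC" * 8 + "T" * 20 + "AAG" * 6 + "T" * 200 + "AG" * 7
        loci = find_ssrs(seq)
        assert len(loci) == 3
        clusters = ssr.merge_compound_loci(loci, max_gap=100)
        assert len(clusters) == 2
        assert len(clusters[0][3]) == 2  # the two loci 20 bp apart
        assert len(clusters[1][3]) == 1


class TestPrimerDesign:
    def _seq_with_locus(self, flank):
        seq = flank + "AC" * 10 + flank
        locus = find_ssrs(seq)[0]
        return seq, locus

    def test_locus_near_sequence_end_yields_nothing(self):
        seq = "ACGTACGTGC" + "AC" * 8  # locus 10 bp from the start, no right flank
        locus = find_ssrs(seq)[0]
        assert ssr.design_primer_sites(seq, locus) == []

    def test_engineered_flanks_yield_valid_pair(self):
        rng = np.random.default_rng(21)
        flank = "".join(rng.choice(list("ACGT"), size=120, p=[0.25] * 4))
        seq, locus = self._seq_with_locus(flank)
        pairs = ssr.design_primer_sites(seq, locus)
        assert pairs
        best = pairs[0]
        cons = PrimerConstraints()
        assert cons.product_min <= best.product_size <= cons.product_max
        assert best.left_end <= locus.start and best.right_start >= locus.end
        for gc, tm, ln in [
            (best.left_gc, best.left_tm, best.left_end - best.left_start),
            (best.right_gc, best.right_tm, best.right_end - best.right_start),
        ]:
            assert cons.gc_min <= gc <= cons.gc_max
            assert cons.tm_min <= tm <= cons.tm_max
            assert cons.primer_min <= ln <= cons.primer_max

    def test_pure_at_flanks_rejected_by_gc_window(self):
        seq, locus = self._seq_with_locus("AT" * 60)
        assert ssr.design_primer_sites(seq, locus) == []

    def test_constraint_triple_validation(self):
        with pytest.raises(ValueError):
            PrimerConstraints(product_min=300, product_opt=150, product_max=100)

    def test_tm_formula_on_known_composition(self):
        # 20-mer with 10 GC: Tm = 64.9 + 41*(10-16.4)/20
        primer = "G" * 10 + "A" * 10
        assert ssr.primer_tm(primer) == pytest.approx(64.9 + 41 * (10 - 16.4) / 20)
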