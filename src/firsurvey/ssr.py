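"""Perfect microsatellite (SSR) mining, classification and primer screening.

The scanner reports maximal perfect tandem repeats of primitive 2-6 bp
units, with per-unit-size minimum repeat counts defaulting to the MISA
convention used for conifer genome surveys: {2: 6, 3: 5, 4: 4, 5: 4,
6: 4}.  Mononucleotide runs are never reported (a poly-A tract is not a
dinucleotide SSR: its unit is not primitive).  Runs are broken at N.
When two detected runs overlap (possible at run boundaries, by up to
unit_size - 1 bases), the leftmost one is kept — a documented, rare
tie-break that keeps reported loci non-overlapping.

Primer-site screening scans both flanks of a locus exhaustively under
BatchPrimer3-style constraints (product 100-300 bp, primer 18-23 nt,
GC 40-70%, Tm 50-70 C via the basic GC formula).
"""

from __future__ import annotations

from dataclasses import dataclass

from .containers import SSRLocus
from .kmer import reverse_complement

DEFAULT_MIN_REPEATS = {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}


def is_primitive(unit: str) -> bool:
    """True when the unit is not a whole-number repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def _rotations(motif: str):
    return (motif[i:] + motif[:i] for i in range(len(motif)))


def canonical_motif_class(motif: str) -> str:
    """Strand- and phase-independent motif class label "X/Y".

    X is the lexicographically smallest rotation over the motif and its
    reverse complement; Y is the smallest rotation of X's reverse
    complement (the complementary-strand representative).  All motifs in
    one rotation/reverse-complement equivalence class share one label,
    e.g. CTT -> "AAG/CTT", GTT -> "AAC/GTT", TA -> "AT/AT".
    """
    motif = motif.upper()
    if not (2 <= len(motif) <= 6):
        raise ValueError("motif length must be 2-6")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    x = min(min(_rotations(motif)), min(_rotations(reverse_complement(motif))))
    y = min(_rotations(reverse_complement(x)))
    return f"{x}/{y}"


def _segment_runs(seq: str, offset: int, seq_id: str, min_repeats):
    """Maximal perfect runs with primitive units inside an N-free segment."""
    found = []
    n = len(seq)
    for p, min_rep in sorted(min_repeats.items()):
        if n < p * min_rep:
            continue
        x = 0
        limit = n - p
        while x <= limit - 1:
            if seq[x] != seq[x + p]:
                x += 1
                continue
            run_start = x
            while x < limit and seq[x] == seq[x + p]:
                x += 1
            # equality stretch [run_start, x) -> run [run_start, x + p)
            run_len = x + p - run_start
            count = run_len // p
            if count >= min_rep:
                unit = seq[run_start : run_start + p]
                if is_primitive(unit):
                    found.append(
                        SSRLocus(
                            sequence_id=seq_id,
                            start=offset + run_start,
                            end=offset + run_start + count * p,
                            motif=unit,
                            repeat_count=count,
                            canonical_class=canonical_motif_class(unit),
                        )
                    )
            x += 1
    return found


def _drop_overlaps(loci):
    """Keep a left-to-right non-overlapping subset (leftmost wins, then longer)."""
    out = []
    last_end = -1
    for loc in sorted(loci, key=lambda s: (s.start, -(s.end - s.start), s.unit_size)):
        if loc.start >= last_end:
            out.append(loc)
            last_end = loc.end
    return out


def find_ssrs(sequence: str, seq_id: str = "seq1", min_repeats=None):
    """Detect perfect SSR loci in one sequence.

    Returns non-overlapping :class:`SSRLocus` records sorted by start.
    ``min_repeats`` maps unit size -> minimum repeat count (defaults to
    {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}).
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    sequence = sequence.upper()
    if set(sequence) - set("ACGTN"):
        raise ValueError("sequence must be over {A,C,G,T,N}")
    loci = []
    # break at N: scan each N-free segment independently
    start = 0
    n = len(sequence)
    while start < n:
        if sequence[start] == "N":
            start += 1
            continue
        end = sequence.find("N", start)
        if end == -1:
            end = n
        loci.extend(_segment_runs(sequence[start:end], start, seq_id, min_repeats))
        start = end
    return _drop_overlaps(loci)


def find_ssrs_many(sequences, min_repeats=None):
    """Scan a list of (id, sequence) records; concatenation of per-record scans."""
    out = []
    for seq_id, seq in sequences:
        out.extend(find_ssrs(seq, seq_id=seq_id, min_repeats=min_repeats))
    return out


@dataclass
class SSRSummary:
    total: int
    by_unit_size: dict
    by_repeat_count: dict  # (unit_size, repeat_count) -> n
    by_class: dict
    density_bp_per_locus: float | None  # non-N bp per locus; None when no loci

    def unit_size_proportions(self) -> dict:
        if self.total == 0:
            return {}
        return {u: n / self.total for u, n in self.by_unit_size.items()}

    def class_proportions(self, unit_size: int | None = None) -> dict:
        pool = {
            c: n
            for c, n in self.by_class.items()
            if unit_size is None or len(c.split("/")[0]) == unit_size
        }
        tot = sum(pool.values())
        return {c: n / tot for c, n in pool.items()} if tot else {}


def summarize_ssrs(loci, non_n_length: int) -> SSRSummary:
    """Tabulate loci by unit size, repeat count and canonical class.

    ``density_bp_per_locus`` is non-N length / locus count ("one SSR locus
    every D bp, not counting unknown bases"); absent when there are no loci.
    """
    if non_n_length <= 0:
        raise ValueError("non_n_length must be positive")
    by_unit: dict[int, int] = {}
    by_rep: dict[tuple[int, int], int] = {}
    by_class: dict[str, int] = {}
    for loc in loci:
        by_unit[loc.unit_size] = by_unit.get(loc.unit_size, 0) + 1
        key = (loc.unit_size, loc.repeat_count)
        by_rep[key] = by_rep.get(key, 0) + 1
        cls = loc.canonical_class or canonical_motif_class(loc.motif)
        by_class[cls] = by_class.get(cls, 0) + 1
    total = sum(by_unit.values())
    density = non_n_length / total if total else None
    return SSRSummary(
        total=total,
        by_unit_size=by_unit,
        by_repeat_count=by_rep,
        by_class=by_class,
        density_bp_per_locus=density,
    )


def merge_compound_loci(loci, max_gap: int = 100):
    """Optional compound report: cluster perfect loci within ``max_gap`` bp.

    Mirrors the interruption-distance convention of MISA-style compound
    SSRs.  Returns a list of ``(sequence_id, start, end, members)`` with
    members the perfect loci in the cluster; headline counts elsewhere
    always use the perfect loci themselves.
    """
    out = []
    current = []
    for loc in sorted(loci, key=lambda s: (s.sequence_id, s.start)):
        if current and (
            loc.sequence_id != current[-1].sequence_id
            or loc.start - current[-1].end > max_gap
        ):
            out.append(
                (current[0].sequence_id, current[0].start, current[-1].end, list(current))
            )
            current = []
        current.append(loc)
    if current:
        out.append(
            (current[0].sequence_id, current[0].start, current[-1].end, list(current))
        )
    return out


# --- primer-site screening -------------------------------------------------


@dataclass(frozen=True)
class PrimerConstraints:
    """BatchPrimer3-style screening constraints (min, opt, max triples)."""

    product_min: int = 100
    product_opt: int = 150
    product_max: int = 300
    primer_min: int = 18
    primer_opt: int = 21
    primer_max: int = 23
    gc_min: float = 0.40
    gc_opt: float = 0.50
    gc_max: float = 0.70
    tm_min: float = 50.0
    tm_opt: float = 55.0
    tm_max: float = 70.0

    def __post_init__(self) -> None:
        for lo, opt, hi in (
            (self.product_min, self.product_opt, self.product_max),
            (self.primer_min, self.primer_opt, self.primer_max),
            (self.gc_min, self.gc_opt, self.gc_max),
            (self.tm_min, self.tm_opt, self.tm_max),
        ):
            if not lo <= opt <= hi:
                raise ValueError("constraint triples must satisfy min <= opt <= max")


@dataclass(frozen=True)
class PrimerPair:
    left_start: int
    left_end: int
    right_start: int
    right_end: int  # right primer anneals to the reverse strand over this span
    product_size: int
    left_gc: float
    right_gc: float
    left_tm: float
    right_tm: float
    penalty: float


def primer_tm(primer: str) -> float:
    """Basic GC-content melting temperature, valid for primers >= 14 nt."""
    if len(primer) < 14:
        raise ValueError("GC Tm formula requires >= 14 nt")
    gc = primer.count("G") + primer.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(primer)


def _windows(seq, lo, hi, cons):
    """Valid primer windows [i, j) with start in [lo, hi)."""
    out = []
    for i in range(lo, hi):
        for length in range(cons.primer_min, cons.primer_max + 1):
            j = i + length
            if j > len(seq):
                break
            word = seq[i:j]
            if "N" in word:
                continue
            gc = (word.count("G") + word.count("C")) / length
            if not cons.gc_min <= gc <= cons.gc_max:
                continue
            tm = primer_tm(word)
            if not cons.tm_min <= tm <= cons.tm_max:
                continue
            out.append((i, j, gc, tm))
    return out


def design_primer_sites(sequence: str, locus: SSRLocus, constraints=None):
    """Candidate primer pairs bracketing an SSR locus.

    Exhaustive scan of left-flank forward primers and right-flank reverse
    primers; a pair is emitted iff both primers pass the length/GC/Tm
    windows and the product (left start to right end) lies within the
    product-size range.  Candidates are ranked by summed |value - optimum|
    penalties (lengths and Tm in their native units, GC in percent,
    product size included), ties broken by coordinates.  Returns [] when
    the locus sits too close to a sequence end.
    """
    cons = constraints or PrimerConstraints()
    sequence = sequence.upper()
    n = len(sequence)
    # left primers must end at or before the locus start, right primers
    # must start at or after the locus end; product must cover the locus.
    left_lo = max(0, locus.start - (cons.product_max - (locus.end - locus.start)))
    lefts = [
        w for w in _windows(sequence, left_lo, max(left_lo, locus.start), cons) if w[1] <= locus.start
    ]
    rights = [
        w
        for w in _windows(sequence, locus.end, min(n, locus.end + cons.product_max), cons)
        if w[0] >= locus.end
    ]
    pairs = []
    for li, lj, lgc, ltm in lefts:
        for ri, rj, rgc, rtm in rights:
            product = rj - li
            if not cons.product_min <= product <= cons.product_max:
                continue
            penalty = (
                abs(product - cons.product_opt)
                + abs((lj - li) - cons.primer_opt)
                + abs((rj - ri) - cons.primer_opt)
                + abs(lgc - cons.gc_opt) * 100
                + abs(rgc - cons.gc_opt) * 100
                + abs(ltm - cons.tm_opt)
                + abs(rtm - cons.tm_opt)
            )
            pairs.append(
                PrimerPair(
                    left_start=li,
                    left_end=lj,
                    right_start=ri,
                    right_end=rj,
                    product_size=product,
                    left_gc=lgc,
                    right_gc=rgc,
                    left_tm=ltm,
                    right_tm=rtm,
                    penalty=penalty,
                )
            )
    pairs.sort(key=lambda p: (p.penalty, p.left_start, p.right_end))
    return pairs
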