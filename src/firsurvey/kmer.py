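"""K-mer spectrum construction and genome-survey estimators.

The genome-survey chain is: count k-mers (default k = 17) in the read or
scaffold set, locate the main (homozygous) peak of the depth spectrum,
and estimate

* genome size      = total k-mer number / main peak depth,
* heterozygous signal = k-mer mass under the half-depth peak as a fraction
  of non-error mass, with an optional simulation-calibrated conversion to
  a per-base heterozygosity rate,
* repeat fraction  = k-mer mass beyond a multiple (default 2x) of the main
  peak over non-error mass,
* GC content in non-overlapping windows (default 10 kb).

The "total k-mer number" excludes the sequencing-error spike: depths below
``error_depth_cutoff`` (default max(3, main_peak/4)) are dropped before the
division, since error k-mers inflate the raw total without representing
genomic sequence.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .containers import KmerHistogram

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def default_error_cutoff(main_peak_depth: int) -> int:
    """Depth below which k-mers are treated as sequencing errors."""
    return max(3, main_peak_depth // 4)


def count_kmers(sequences, k: int = 17, canonical: bool = True) -> KmerHistogram:
    """Histogram of k-mer multiplicities over a set of sequences.

    Windows containing ``N`` are skipped.  With ``canonical`` a k-mer and
    its reverse complement are counted under one key (the lexicographic
    minimum of the pair), matching the convention of standard k-mer
    counters on unstranded reads.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(sequences, str):
        sequences = [sequences]
    table: dict[str, int] = {}
    for seq in sequences:
        seq = seq.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)} in sequence")
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if "N" in word:
                continue
            if canonical:
                rc = reverse_complement(word)
                if rc < word:
                    word = rc
            table[word] = table.get(word, 0) + 1
    hist: dict[int, int] = {}
    for mult in table.values():
        hist[mult] = hist.get(mult, 0) + 1
    return KmerHistogram(k=k, counts=hist)


def find_peaks(
    hist: KmerHistogram,
    error_depth_cutoff: int = 3,
    prior_depth: float | None = None,
    smooth_width: int = 3,
):
    """Local maxima of the depth spectrum and the designated main peak.

    The count-vs-depth curve (depths >= ``error_depth_cutoff``) is smoothed
    with a centered moving average of ``smooth_width`` bins before peak
    picking.  The main peak is the candidate closest to ``prior_depth``
    when one is supplied (an external expectation, e.g. implied by a flow
    cytometry genome size); otherwise the candidate carrying the largest
    k-mer mass, ties broken toward higher depth.

    Returns ``(peaks, main_depth)`` with ``peaks`` a list of
    ``(depth, smoothed_height)`` tuples.
    """
    depths, counts = hist.as_arrays()
    keep = depths >= error_depth_cutoff
    depths, counts = depths[keep], counts[keep].astype(float)
    if depths.size == 0 or counts.sum() == 0:
        raise ValueError("empty histogram after error-depth filtering")
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        smoothed = np.convolve(counts, kernel, mode="same")
    else:
        smoothed = counts
    idx, _ = _signal.find_peaks(smoothed)
    if idx.size == 0:
        # monotone or single-bin spectrum: fall back to the global maximum
        idx = np.array([int(np.argmax(smoothed))])
    peaks = [(int(depths[i]), float(smoothed[i])) for i in idx]
    if prior_depth is not None:
        main = min(peaks, key=lambda p: (abs(p[0] - prior_depth), -p[0]))[0]
    else:
        # mass at the peak depth, tie -> higher depth
        main = max(peaks, key=lambda p: (p[0] * p[1], p[0]))[0]
    return peaks, int(main)


def estimate_genome_size(
    hist: KmerHistogram, main_peak_depth: int, error_depth_cutoff: int | None = None
) -> int:
    """Genome size (bp) = total filtered k-mer number / main peak depth."""
    if main_peak_depth < 1:
        raise ValueError("main_peak_depth must be >= 1")
    if error_depth_cutoff is None:
        error_depth_cutoff = default_error_cutoff(main_peak_depth)
    total = hist.total_kmers(min_depth=error_depth_cutoff)
    if total == 0:
        raise ValueError("zero total k-mers after filtering")
    return total // main_peak_depth


def estimate_heterozygous_signal(
    hist: KmerHistogram, main_peak_depth: int, error_depth_cutoff: int | None = None
) -> float:
    """Fraction of non-error k-mer mass under the half-depth peak.

    Mass at depths in ``[cutoff, 0.75 * main_peak_depth)`` — the midpoint
    between the half-depth and full-depth components — is attributed to
    heterozygous k-mers, after subtracting the left tail that the
    homozygous component itself places below the split (a Poisson at the
    main peak depth, scaled to the observed height at the mode).  Returns
    0 when there is no half-depth component.
    """
    if error_depth_cutoff is None:
        error_depth_cutoff = default_error_cutoff(main_peak_depth)
    split = 0.75 * main_peak_depth
    total = hist.total_kmers(min_depth=error_depth_cutoff)
    if total == 0:
        return 0.0
    half_mass = sum(
        d * c for d, c in hist.counts.items() if error_depth_cutoff <= d < split
    )
    # main-component left tail below the split: Poisson(main) scaled so
    # its pmf at the mode matches the smoothed observed height there
    height = np.mean(
        [hist.counts.get(main_peak_depth + o, 0) for o in (-1, 0, 1)]
    )
    scale = height / max(_stats.poisson.pmf(main_peak_depth, main_peak_depth), 1e-300)
    depths = np.arange(error_depth_cutoff, int(np.ceil(split)))
    depths = depths[depths < split]
    leak = float(
        (depths * scale * _stats.poisson.pmf(depths, main_peak_depth)).sum()
    )
    return max(half_mass - leak, 0.0) / total


def estimate_repeat_fraction(
    hist: KmerHistogram,
    main_peak_depth: int,
    multiplier: float = 2.0,
    error_depth_cutoff: int | None = None,
) -> float:
    """Fraction of non-error k-mer mass at depths beyond multiplier x peak."""
    if multiplier <= 1:
        raise ValueError("multiplier must be > 1")
    if error_depth_cutoff is None:
        error_depth_cutoff = default_error_cutoff(main_peak_depth)
    total = hist.total_kmers(min_depth=error_depth_cutoff)
    if total == 0:
        return 0.0
    tail = sum(
        d * c
        for d, c in hist.counts.items()
        if d >= error_depth_cutoff and d > multiplier * main_peak_depth
    )
    return tail / total


def calibrate_heterozygosity(
    signal: float,
    mean_depth: float = 30.0,
    k: int = 17,
    genome_size_bp: int = 200_000,
    rate_grid=None,
    seed: int = 7,
    repeat_fraction: float = 0.0,
) -> float:
    """Convert a half-peak mass signal into a heterozygosity rate.

    The conversion is empirical: spectra are simulated on a grid of known
    per-base rates with the package's own generator (same depth and k),
    the signal is measured on each, and the observed signal is inverted by
    monotone linear interpolation.  Signals above the grid are clipped to
    the top grid rate.

    The calibration grid is built on repeat-free spectra; when the target
    spectrum has an estimated ``repeat_fraction`` the observed signal is
    divided by (1 - repeat_fraction) first, undoing the dilution of the
    half-depth component by repeat k-mer mass.
    """
    from .synthetic import SpectrumTruth, gen_kmer_spectrum

    if not 0 <= repeat_fraction < 1:
        raise ValueError("repeat_fraction must lie in [0, 1)")
    signal = signal / (1.0 - repeat_fraction)
    if rate_grid is None:
        rate_grid = np.array([0.0, 0.005, 0.01, 0.02, 0.03, 0.04, 0.05])
    rate_grid = np.asarray(rate_grid, float)
    sigs = []
    for r, rate in enumerate(rate_grid):
        truth = SpectrumTruth(
            genome_size_bp=genome_size_bp,
            heterozygosity=float(rate),
            repeat_fraction=0.0,
            mean_depth=mean_depth,
            error_rate=0.0,
        )
        h = gen_kmer_spectrum(truth, seed=seed + r, k=k)
        _, main = find_peaks(h, prior_depth=mean_depth)
        sigs.append(estimate_heterozygous_signal(h, main))
    sigs = np.asarray(sigs)
    order = np.argsort(sigs)
    return float(np.interp(signal, sigs[order], rate_grid[order]))


def gc_content(sequences) -> float:
    """Overall GC fraction, (G+C)/(A+C+G+T); N excluded from the denominator."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = at = 0
    for seq in sequences:
        seq = seq.upper()
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("no non-N bases")
    return gc / (gc + at)


def gc_depth_windows(sequences, window_bp: int = 10_000, depth_track=None):
    """Per-window (gc_fraction, mean_depth) over non-overlapping windows.

    A trailing partial window is kept when it covers at least half of
    ``window_bp``, otherwise dropped.  ``depth_track``, when given, maps a
    sequence id to a per-base depth array; without it mean depth is NaN.
    Returns a list of ``(sequence_id, start, end, gc_fraction, mean_depth)``.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if isinstance(sequences, str):
        sequences = [("seq1", sequences)]
    rows = []
    for seq_id, seq in sequences:
        seq = seq.upper()
        n = len(seq)
        start = 0
        while start < n:
            end = min(start + window_bp, n)
            if end - start < window_bp and (end - start) < window_bp / 2:
                break
            win = seq[start:end]
            gc = win.count("G") + win.count("C")
            at = win.count("A") + win.count("T")
            frac = gc / (gc + at) if gc + at else float("nan")
            if depth_track is not None and seq_id in depth_track:
                mean_depth = float(np.mean(depth_track[seq_id][start:end]))
            else:
                mean_depth = float("nan")
            rows.append((seq_id, start, end, frac, mean_depth))
            start += window_bp
    return rows
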