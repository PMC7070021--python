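"""Seeded generators for every input the survey pipeline consumes.

Four generators emulate the statistical structure of the study inputs:

* SSR-free background genomes with microsatellites planted at known
  coordinates (scanner ground truth);
* diploid 17-mer depth spectra as Poisson depth mixtures — an error spike
  at depth 1-2, a heterozygous component at half the mean depth, the
  homozygous main peak at the mean depth, and a high-copy repeat tail —
  without simulating reads, since the estimators only consume histograms;
* multi-group diploid genotype matrices under the Balding-Nichols model,
  in which per-group allele frequencies are drawn around a common base
  frequency with variance Fst * p * (1 - p), so the divergence parameter
  doubles as a recovery oracle for the AMOVA/Fst estimators;
* replicate flow-cytometry peak intensities with a controlled
  coefficient of variation.

Every generator is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix, KmerHistogram, SSRLocus
from .ssr import DEFAULT_MIN_REPEATS, canonical_motif_class, find_ssrs

BASES = np.array(list("ACGT"))


# --- SSR genomes -----------------------------------------------------------


@dataclass
class SsrGenomeTruth:
    sequences: list  # list of (id, sequence)
    planted_loci: list  # list of SSRLocus ground truth
    non_n_length: int


def _ssr_free_background(rng, length, min_repeats, max_tries=200):
    """Random sequence rejected until the scanner finds nothing in it."""
    for _ in range(max_tries):
        seq = "".join(rng.choice(BASES, size=length))
        if not find_ssrs(seq, min_repeats=min_repeats):
            return seq
    raise RuntimeError("could not draw an SSR-free background")


def gen_ssr_genome(
    n_sequences: int = 1,
    length: int = 10_000,
    planted_spec=None,
    seed: int = 0,
    min_repeats=None,
) -> SsrGenomeTruth:
    """Genome with SSRs planted at known spans on an SSR-free background.

    ``planted_spec`` lists (motif, repeat_count, approximate_position)
    per plant, optionally with a leading sequence index for multi-record
    genomes: (seq_index, motif, repeat_count, position).  The background
    is rejection-sampled until the scanner itself (with the same minimum
    thresholds) finds nothing, so the planted loci are the complete truth.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    rng = np.random.default_rng(seed)
    planted_spec = planted_spec or []
    per_seq: dict[int, list] = {i: [] for i in range(n_sequences)}
    for spec in planted_spec:
        if len(spec) == 4:
            si, motif, count, pos = spec
        else:
            motif, count, pos = spec
            si = 0
        motif = motif.upper()
        if set(motif) - set("ACGT"):
            raise ValueError(f"motif {motif!r} must be over ACGT")
        if not 2 <= len(motif) <= 6:
            raise ValueError("motif length must be 2-6")
        from .ssr import is_primitive

        if not is_primitive(motif):
            raise ValueError(
                f"motif {motif!r} is a repetition of a shorter unit; "
                "plant the primitive unit instead"
            )
        per_seq[si].append((int(pos), motif, int(count)))
    sequences = []
    planted: list[SSRLocus] = []
    total = 0
    for si in range(n_sequences):
        seq_id = f"synth{si + 1}"
        bg = list(_ssr_free_background(rng, length, min_repeats))
        occupied: list[tuple[int, int]] = []
        for pos, motif, count in sorted(per_seq[si]):
            span = len(motif) * count
            start = min(max(0, pos), length - span)
            end = start + span
            # one background base either side kept clear of the motif's
            # alphabet so the planted run cannot extend
            for a, b in occupied:
                if start < b + 1 and a - 1 < end:
                    raise ValueError("planted loci overlap")
            bg[start:end] = list(motif * count)
            for edge in (start - 1, end):
                if 0 <= edge < length:
                    choices = [c for c in "ACGT" if c not in set(motif)] or ["N"]
                    bg[edge] = str(rng.choice(choices))
            occupied.append((start, end))
            planted.append(
                SSRLocus(
                    sequence_id=seq_id,
                    start=start,
                    end=end,
                    motif=motif,
                    repeat_count=count,
                    canonical_class=canonical_motif_class(motif),
                )
            )
        seq = "".join(bg)
        sequences.append((seq_id, seq))
        total += len(seq) - seq.count("N")
    planted.sort(key=lambda s: (s.sequence_id, s.start))
    return SsrGenomeTruth(sequences=sequences, planted_loci=planted, non_n_length=total)


# --- k-mer spectra ---------------------------------------------------------


@dataclass
class SpectrumTruth:
    """Ground-truth parameters behind a simulated diploid k-mer spectrum."""

    genome_size_bp: int
    heterozygosity: float = 0.0  # per-base rate in [0, 1]
    repeat_fraction: float = 0.0
    mean_depth: float = 30.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValueError("genome size must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        for name in ("heterozygosity", "repeat_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def gen_kmer_spectrum(truth: SpectrumTruth, seed: int = 0, k: int = 17) -> KmerHistogram:
    """Simulate a diploid k-mer depth histogram as a Poisson mixture.

    The genome's k-mer positions split into a unique homozygous pool
    (depth ~ Poisson(D)), a heterozygous pool — a fraction
    1 - (1 - h)^k of unique positions, each contributing two distinct
    k-mers at Poisson(D/2) — and a repeat pool carrying ``repeat_fraction``
    of the total mass at copy numbers >= 3 (depth ~ Poisson(c * D)).
    Sequencing errors add distinct k-mers at depth 1-2.  Total
    depth-weighted mass stays ~ genome_size_bp * mean_depth.
    """
    rng = np.random.default_rng(seed)
    G, D = truth.genome_size_bp, truth.mean_depth
    p_het = 1.0 - (1.0 - truth.heterozygosity) ** k
    n_unique = int(round(G * (1 - truth.repeat_fraction)))
    n_het_pos = rng.binomial(n_unique, p_het)
    n_hom = n_unique - n_het_pos
    depths = []
    if n_hom:
        depths.append(rng.poisson(D, size=n_hom))
    if n_het_pos:
        depths.append(rng.poisson(D / 2.0, size=2 * n_het_pos))
    # repeat tail: copy numbers 3 + Geometric, distinct k-mers until the
    # repeat mass budget (repeat_fraction * G positions) is spent
    repeat_mass = G - n_unique
    if repeat_mass > 0:
        mean_extra = 4.0
        # copy numbers are >= 4, so at most budget/4 + 1 distinct k-mers
        draw = 3 + rng.geometric(1.0 / (1 + mean_extra), size=repeat_mass // 4 + 2)
        cum = np.cumsum(draw)
        take = int(np.searchsorted(cum, repeat_mass)) + 1
        copies = draw[: min(take, len(draw))]
        depths.append(rng.poisson(np.minimum(copies, 10_000) * D))
    if truth.error_rate > 0:
        n_err = int(round(truth.error_rate * G * D / 2.0))
        if n_err:
            depths.append(rng.integers(1, 3, size=n_err))
    alld = np.concatenate(depths) if depths else np.array([], dtype=int)
    alld = alld[alld >= 1]
    vals, counts = np.unique(alld, return_counts=True)
    return KmerHistogram(k=k, counts={int(v): int(c) for v, c in zip(vals, counts)})


# --- population genotypes --------------------------------------------------


@dataclass
class PopSimTruth:
    """Parameters of a Balding-Nichols multi-group genotype simulation."""

    n_groups: int = 3
    fst: float = 0.2
    group_sizes: tuple = (60, 60, 60)
    n_loci: int = 40
    alleles_per_locus: int = 5
    admixture_alpha: float | None = None  # None -> pure group membership
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if len(self.group_sizes) != self.n_groups:
            raise ValueError("one size per group required")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class PopSimResult:
    genotypes: GenotypeMatrix
    group_labels: list
    q_truth: np.ndarray  # (n, K) generating ancestry proportions
    group_freqs: np.ndarray  # (K, L, J) generating allele frequencies


def gen_population_genotypes(truth: PopSimTruth) -> PopSimResult:
    """Diploid genotypes for K divergent groups under Balding-Nichols.

    Base frequencies per locus are drawn from a flat Dirichlet; group
    frequencies from Dirichlet(p0 * (1 - Fst) / Fst), which has mean p0
    and variance Fst * p0 * (1 - p0).  Each individual draws two alleles
    per locus from its group's frequencies (or, with ``admixture_alpha``,
    from group frequencies mixed by an individual Dirichlet(alpha) Q).
    Missing calls are masked at ``missing_rate`` on whole genotypes.
    """
    rng = np.random.default_rng(truth.seed)
    K, L, J = truth.n_groups, truth.n_loci, truth.alleles_per_locus
    n = int(sum(truth.group_sizes))
    base = rng.dirichlet(np.ones(J), size=L)  # (L, J)
    scale = (1.0 - truth.fst) / truth.fst
    freqs = np.empty((K, L, J))
    for l in range(L):
        alpha = np.maximum(base[l] * scale, 1e-9)
        freqs[:, l, :] = rng.dirichlet(alpha, size=K)
    group_labels = []
    for g, size in enumerate(truth.group_sizes):
        group_labels.extend([f"G{g + 1}"] * size)
    q = np.zeros((n, K))
    if truth.admixture_alpha is None:
        for i, lab in enumerate(group_labels):
            q[i, int(lab[1:]) - 1] = 1.0
    else:
        q[:] = rng.dirichlet(np.full(K, truth.admixture_alpha), size=n)
    calls = np.empty((n, L, 2), dtype=object)
    for i in range(n):
        mix = q[i] @ freqs.reshape(K, L * J)
        mix = mix.reshape(L, J)
        for l in range(L):
            a, b = rng.choice(J, size=2, p=mix[l] / mix[l].sum())
            calls[i, l, 0] = int(a) + 1
            calls[i, l, 1] = int(b) + 1
    if truth.missing_rate > 0:
        mask = rng.random((n, L)) < truth.missing_rate
        for i, l in zip(*np.nonzero(mask)):
            calls[i, l, 0] = None
            calls[i, l, 1] = None
    G = GenotypeMatrix(
        individuals=[f"ind{i + 1}" for i in range(n)],
        loci=[f"L{l + 1}" for l in range(L)],
        calls=calls,
        labels=group_labels,
    )
    return PopSimResult(genotypes=G, group_labels=group_labels, q_truth=q, group_freqs=freqs)


# --- flow cytometry --------------------------------------------------------


def gen_flow_cytometry_run(
    true_ratio: float,
    cv: float = 0.03,
    n_replicates: int = 10,
    seed: int = 0,
    standard_name: str = "standard",
    standard_2c_pg: float = 10.43,
    sample_mean: float = 1e6,
):
    """Replicate peak-intensity table with a controlled CV.

    Sample and standard peak means are drawn lognormally around means
    whose ratio is ``true_ratio``; the per-replicate ``peak_cv`` column
    records the generating CV (so a replicate generated above a quality
    threshold is flagged by the estimator's filter).  Returns a
    :class:`firsurvey.cytometry.CytometryRun`.
    """
    from .cytometry import CytometryRun

    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    std_mean = sample_mean / true_ratio
    reps = []
    for _ in range(n_replicates):
        if cv == 0:
            s, t = sample_mean, std_mean
        else:
            sigma = np.sqrt(np.log(1 + cv**2))
            s = sample_mean * np.exp(rng.normal(-sigma**2 / 2, sigma))
            t = std_mean * np.exp(rng.normal(-sigma**2 / 2, sigma))
        reps.append((float(s), float(t), float(cv)))
    return CytometryRun(
        standard_name=standard_name, standard_2c_pg=standard_2c_pg, replicates=reps
    )
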