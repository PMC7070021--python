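"""Shared in-memory containers for the survey pipeline.

The pipeline passes three kinds of data between stages: k-mer depth
histograms (genome survey), SSR loci (marker mining), and diploid
codominant genotype matrices (diversity / structure / AMOVA).  They are
deliberately thin dataclasses over plain Python and numpy objects so that
every stage can be exercised on synthetic inputs without file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = None  # sentinel for a missing diploid call (both alleles at once)


@dataclass
class KmerHistogram:
    """Depth spectrum of distinct k-mers.

    ``counts`` maps sequencing depth (multiplicity, >= 1) to the number of
    distinct k-mers observed at that depth.  The k-mer *mass* at depth d is
    ``d * counts[d]``; summing mass over depths gives the total k-mer
    number that the genome-size formula divides by the peak depth.
    """

    k: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for depth, n in self.counts.items():
            if depth < 1:
                raise ValueError(f"depth must be >= 1, got {depth}")
            if n < 0:
                raise ValueError(f"count must be >= 0, got {n}")

    def total_kmers(self, min_depth: int = 1) -> int:
        """Total k-mer number: sum of depth x count over depths >= min_depth."""
        return int(sum(d * c for d, c in self.counts.items() if d >= min_depth))

    def n_distinct(self, min_depth: int = 1) -> int:
        return int(sum(c for d, c in self.counts.items() if d >= min_depth))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (depth, count) arrays covering 1..max depth."""
        if not self.counts:
            return np.array([], dtype=int), np.array([], dtype=int)
        dmax = max(self.counts)
        depths = np.arange(1, dmax + 1)
        counts = np.zeros(dmax, dtype=np.int64)
        for d, c in self.counts.items():
            counts[d - 1] = c
        return depths, counts


@dataclass(frozen=True)
class SSRLocus:
    """One perfect microsatellite locus.

    Coordinates are 0-based half-open; ``end - start`` always equals
    ``unit_size * repeat_count`` and the spanned substring is the motif
    tiled ``repeat_count`` times.
    """

    sequence_id: str
    start: int
    end: int
    motif: str
    repeat_count: int
    canonical_class: str = ""

    @property
    def unit_size(self) -> int:
        return len(self.motif)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.repeat_count:
            raise ValueError(
                f"span {self.end - self.start} != unit {len(self.motif)} x "
                f"{self.repeat_count} repeats"
            )


class GenotypeMatrix:
    """Individuals x loci diploid codominant calls.

    ``calls`` is an (n_individuals, n_loci, 2) object array of allele
    labels; a missing genotype has ``None`` in both slots (calls are
    missing all-or-nothing).  Allele labels are opaque — SSR fragment
    sizes, integers, or strings — and are only ever compared for equality.
    """

    def __init__(self, individuals, loci, calls, labels=None):
        self.individuals = list(individuals)
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=object)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        half = (calls[:, :, 0] == None) != (calls[:, :, 1] == None)  # noqa: E711
        if half.any():
            raise ValueError("half-missing calls are not allowed")
        self.calls = calls
        self.labels = None if labels is None else list(labels)
        if self.labels is not None and len(self.labels) != len(self.individuals):
            raise ValueError("one label per individual required")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """(n_individuals, n_loci) boolean mask of missing calls."""
        return self.calls[:, :, 0] == None  # noqa: E711

    def locus_index(self, locus) -> int:
        return self.loci.index(locus)

    def subset_loci(self, idx) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            self.individuals,
            [self.loci[i] for i in idx],
            self.calls[:, idx, :],
            labels=self.labels,
        )

    def allele_codes(self) -> tuple[np.ndarray, list[list]]:
        """Integer-coded alleles for numeric kernels.

        Returns ``(codes, alleles)`` where ``codes`` is (n, L, 2) int with
        -1 for missing and ``alleles[l]`` lists the labels at locus l in
        code order (sorted by string representation for determinism).
        """
        n, L = self.n_individuals, self.n_loci
        codes = np.full((n, L, 2), -1, dtype=np.int64)
        alleles: list[list] = []
        for l in range(L):
            col = self.calls[:, l, :]
            labels = sorted(
                {a for a in col.ravel() if a is not None}, key=lambda x: (str(x))
            )
            lookup = {a: j for j, a in enumerate(labels)}
            for i in range(n):
                a, b = col[i]
                if a is not None:
                    codes[i, l, 0] = lookup[a]
                    codes[i, l, 1] = lookup[b]
            alleles.append(labels)
        return codes, alleles

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.individuals != other.individuals or self.loci != other.loci:
            return False
        a, b = self.calls, other.calls
        for i in range(a.shape[0]):
            for l in range(a.shape[1]):
                if set(a[i, l]) != set(b[i, l]):
                    return False
        return True
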