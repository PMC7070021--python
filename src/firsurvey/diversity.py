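"""Per-locus codominant diversity statistics and Nei's D_A distance.

For allele frequencies p_1..p_n at a locus (each diploid call contributes
two allele observations):

* Na  — observed allele count
* Ne  — effective allele count, 1 / sum p_i^2
* Ho  — observed heterozygosity, het calls / non-missing calls
* He  — expected heterozygosity (Nei gene diversity) 1 - sum p_i^2,
        optionally with the unbiased small-sample factor 2n/(2n-1)
* I   — Shannon information index, -sum p_i ln p_i (natural log)
* PIC — polymorphism information content,
        1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

He defaults to the unbiased form, the convention of the classic
codominant-diversity packages this mirrors; pass ``he_correction="none"``
for the raw gene diversity.  The uncorrected He and Ne are tied by the
identity He = 1 - 1/Ne.

Nei's (1983) D_A distance between two allele-frequency profiles x, y over
L shared loci is D_A = 1 - (1/L) sum_l sum_a sqrt(x_la * y_la).
Individual-level distances treat each individual as a population of two
alleles per locus; loci missing in either individual are dropped from L
for that pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


def load_clgssr_table() -> "pd.DataFrame":
    """Published per-locus diversity table for the 46 CLgSSR markers.

    Columns: locus, size_min_bp, size_max_bp, na, ne, ho, he, pic,
    shannon_i — the genotyping summary of 46 polymorphic genomic SSR
    markers scored on 199 Chinese fir clones, shipped with the package
    as reference input for aggregation and benchmarking.
    """
    with resources.files("firsurvey.data").joinpath("clgssr_diversity.csv").open() as fh:
        return pd.read_csv(fh)


def allele_frequencies(G: GenotypeMatrix, locus) -> tuple[dict, int]:
    """Allele frequency table and sample size (non-missing individuals)."""
    l = G.locus_index(locus) if not isinstance(locus, int) else locus
    counts: dict = {}
    n = 0
    for i in range(G.n_individuals):
        a, b = G.calls[i, l]
        if a is None:
            continue
        n += 1
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    if n == 0:
        raise ValueError(f"locus {locus!r} has no non-missing calls")
    total = 2 * n
    return {a: c / total for a, c in counts.items()}, n


def pic_from_frequencies(freqs) -> float:
    """Polymorphism information content from a frequency vector."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, float)
    s2 = float(np.sum(p**2))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    cross = s2**2 - float(np.sum(p**4))
    return 1.0 - s2 - cross


def shannon_index(freqs) -> float:
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, float)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


@dataclass(frozen=True)
class LocusStats:
    locus: object
    n: int
    na: int
    ne: float
    ho: float
    he: float
    shannon_i: float
    pic: float


def locus_stats(G: GenotypeMatrix, locus, he_correction: str = "unbiased") -> LocusStats:
    """All per-locus diversity statistics for one locus."""
    if he_correction not in ("none", "unbiased"):
        raise ValueError("he_correction must be 'none' or 'unbiased'")
    freqs, n = allele_frequencies(G, locus)
    l = G.locus_index(locus) if not isinstance(locus, int) else locus
    het = sum(
        1
        for i in range(G.n_individuals)
        if G.calls[i, l, 0] is not None and G.calls[i, l, 0] != G.calls[i, l, 1]
    )
    p = np.asarray(list(freqs.values()), float)
    s2 = float(np.sum(p**2))
    he = 1.0 - s2
    if he_correction == "unbiased":
        he *= 2 * n / (2 * n - 1)
    return LocusStats(
        locus=locus if not isinstance(locus, int) else G.loci[locus],
        n=n,
        na=int(np.sum(p > 0)),
        ne=1.0 / s2,
        ho=het / n,
        he=he,
        shannon_i=shannon_index(freqs),
        pic=pic_from_frequencies(freqs),
    )


def all_locus_stats(G: GenotypeMatrix, he_correction: str = "unbiased"):
    return [locus_stats(G, l, he_correction) for l in range(G.n_loci)]


def frequency_profile(G: GenotypeMatrix, individuals=None) -> dict:
    """Per-locus allele frequencies over a subset of individuals.

    Returns {locus: {allele: freq}}; loci with no non-missing call in the
    subset are omitted.
    """
    idx = (
        range(G.n_individuals)
        if individuals is None
        else [G.individuals.index(i) if not isinstance(i, int) else i for i in individuals]
    )
    idx = list(idx)
    profile = {}
    for l, locus in enumerate(G.loci):
        counts: dict = {}
        tot = 0
        for i in idx:
            a, b = G.calls[i, l]
            if a is None:
                continue
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
            tot += 2
        if tot:
            profile[locus] = {a: c / tot for a, c in counts.items()}
    return profile


def nei_da_distance(profile_a: dict, profile_b: dict) -> float:
    """Nei's 1983 D_A distance between two allele-frequency profiles."""
    shared = [l for l in profile_a if l in profile_b]
    if not shared:
        raise ValueError("profiles share no loci")
    acc = 0.0
    for l in shared:
        xa, xb = profile_a[l], profile_b[l]
        acc += sum(math.sqrt(xa[al] * xb[al]) for al in xa if al in xb)
    return 1.0 - acc / len(shared)


def individual_distance_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Pairwise Nei D_A over individuals (each a 2-allele population)."""
    n, L = G.n_individuals, G.n_loci
    codes, alleles = G.allele_codes()
    D = np.zeros((n, n))
    # per-individual frequency arrays per locus: 0, 0.5, or 1
    freq = [np.zeros((n, len(alleles[l]))) for l in range(L)]
    missing = G.missing_mask()
    for l in range(L):
        for i in range(n):
            if missing[i, l]:
                continue
            freq[l][i, codes[i, l, 0]] += 0.5
            freq[l][i, codes[i, l, 1]] += 0.5
    sq = [np.sqrt(f) for f in freq]
    shared = (~missing).astype(float)
    # sum over loci of sum_a sqrt(x_a y_a), and count of shared loci
    bc = np.zeros((n, n))
    for l in range(L):
        bc += sq[l] @ sq[l].T * np.outer(shared[:, l], shared[:, l])
    n_shared = shared @ shared.T
    if (n_shared == 0).any():
        raise ValueError("some individual pair shares no loci")
    D = 1.0 - bc / n_shared
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 1.0)
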