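"""Model-based ancestry inference (admixture model) and K selection.

A Gibbs sampler over the standard admixture model: each individual i has
ancestry proportions q_i over K groups (Dirichlet(alpha) prior), each
group k has allele frequencies p_kl per locus (symmetric
Dirichlet(lambda) prior), and every allele copy carries a latent origin
group z.  Sweeps alternate

    z | q, p   (categorical per allele copy)
    p | z      (Dirichlet with allele counts)
    q | z      (Dirichlet with origin counts)

and the observed-data log likelihood sum log(sum_k q_ik p_k,l,x) is
recorded every sweep.  Reported q and p are posterior means over
post-burn-in sweeps.  alpha is fixed (default 1.0) rather than updated.

K is selected with the Evanno second-difference statistic over replicate
runs:  dK(K) = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd_r(L(K)),
undefined at the endpoints of the K grid.  L(K) per run is the
harmonic-style estimator mean(trace) - var(trace)/2.

Replicate Q matrices are aligned CLUMPP-style (exact search over column
permutations, greedy against an incrementally built reference) before
averaging, and individuals are assigned to the argmax group when their
top membership reaches a threshold (default Q >= 0.6), else "mixed".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .containers import GenotypeMatrix


@njit(cache=True)
def _gibbs_core(obs, lidx, n_alleles, k, burn_in, iterations, seed, alpha, lam):
    """Compiled Gibbs chain; returns (q_mean, p_mean, loglik_trace).

    obs: (n, 2L) allele codes, -1 missing, locus-major copy order.
    """
    np.random.seed(seed)
    n, m = obs.shape
    L = m // 2
    j_max = int(n_alleles.max())
    q = np.full((n, k), 1.0 / k)
    p = np.zeros((k, L, j_max))
    for kk in range(k):
        for l in range(L):
            for j in range(n_alleles[l]):
                p[kk, l, j] = 1.0 / n_alleles[l]
    q_acc = np.zeros((n, k))
    p_acc = np.zeros((k, L, j_max))
    trace = np.empty(iterations - burn_in)
    wk = np.empty(k)
    counts_p = np.zeros((k, L, j_max))
    counts_q = np.zeros((n, k))
    kept = 0
    for sweep in range(iterations):
        counts_p[:] = 0.0
        counts_q[:] = 0.0
        ll = 0.0
        for i in range(n):
            for c in range(m):
                a = obs[i, c]
                if a < 0:
                    continue
                l = lidx[c]
                tot = 0.0
                for kk in range(k):
                    wk[kk] = q[i, kk] * p[kk, l, a]
                    tot += wk[kk]
                ll += np.log(max(tot, 1e-300))
                u = np.random.random() * tot
                acc = 0.0
                zz = k - 1
                for kk in range(k):
                    acc += wk[kk]
                    if u < acc:
                        zz = kk
                        break
                counts_p[zz, l, a] += 1.0
                counts_q[i, zz] += 1.0
        for kk in range(k):
            for l in range(L):
                s = 0.0
                for j in range(n_alleles[l]):
                    g = np.random.gamma(lam + counts_p[kk, l, j], 1.0)
                    p[kk, l, j] = g
                    s += g
                for j in range(n_alleles[l]):
                    p[kk, l, j] /= s
        for i in range(n):
            s = 0.0
            for kk in range(k):
                g = np.random.gamma(alpha + counts_q[i, kk], 1.0)
                q[i, kk] = g
                s += g
            for kk in range(k):
                q[i, kk] /= s
        if sweep >= burn_in:
            trace[kept] = ll
            kept += 1
            q_acc += q
            p_acc += p
    return q_acc / kept, p_acc / kept, trace


@dataclass
class AdmixtureResult:
    k: int
    q: np.ndarray  # (n_individuals, k) posterior-mean ancestry
    p: np.ndarray  # (k, n_loci, max_alleles) posterior-mean frequencies
    loglik_trace: np.ndarray  # post-burn-in observed-data log likelihood
    lk: float = field(init=False)

    def __post_init__(self) -> None:
        self.lk = estimate_lk(self.loglik_trace) if len(self.loglik_trace) >= 2 else float(
            self.loglik_trace[0]
        )


def _coded_alleles(G: GenotypeMatrix):
    codes, alleles = G.allele_codes()
    j_max = max((len(a) for a in alleles), default=0)
    if j_max == 0 or G.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    n_alleles = np.array([len(a) for a in alleles], dtype=np.int64)
    return codes, n_alleles, j_max


def fit_admixture(
    G: GenotypeMatrix,
    k: int,
    burn_in: int = 2_000,
    iterations: int = 10_000,
    seed: int = 0,
    alpha: float = 1.0,
    lam: float = 1.0,
) -> AdmixtureResult:
    """Gibbs sampler for the admixture model.

    ``iterations`` counts total sweeps; the first ``burn_in`` are
    discarded.  The same seed on the same inputs yields a bit-identical
    trace.  Missing genotypes are skipped in both the likelihood and the
    origin updates.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not iterations > burn_in >= 0:
        raise ValueError("need iterations > burn_in >= 0")
    codes, n_alleles, j_max = _coded_alleles(G)
    n, L = G.n_individuals, G.n_loci
    lidx = np.repeat(np.arange(L), 2)  # locus of each of the 2L allele copies
    obs = codes.reshape(n, 2 * L)  # (n, 2L) in locus-major (locus, copy) order
    q_mean, p_mean, trace = _gibbs_core(
        np.ascontiguousarray(obs),
        np.ascontiguousarray(lidx),
        np.ascontiguousarray(n_alleles),
        k,
        burn_in,
        iterations,
        int(seed) % (2**32),
        float(alpha),
        float(lam),
    )
    q_mean = q_mean / q_mean.sum(axis=1, keepdims=True)
    slot_ok = np.arange(j_max)[None, :] < n_alleles[:, None]
    with np.errstate(invalid="ignore"):
        p_mean = np.where(slot_ok, p_mean / p_mean.sum(axis=2, keepdims=True), 0.0)
    return AdmixtureResult(k=k, q=q_mean, p=p_mean, loglik_trace=trace)


def estimate_lk(loglik_trace) -> float:
    """STRUCTURE-style L(K): mean minus half the sample variance of the trace."""
    trace = np.asarray(loglik_trace, float)
    if trace.size < 2:
        raise ValueError("trace must hold at least 2 samples")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


@dataclass
class EvannoRow:
    k: int
    mean_lk: float
    sd_lk: float
    delta_k: float | None  # None at grid endpoints


def evanno_delta_k(lk_by_k: dict, sd_floor: float = 1e-6):
    """Evanno table from replicate L(K) values.

    ``lk_by_k`` maps K -> sequence of L(K) values over replicate runs
    (same replicate count for all K).  dK is the mean over replicates of
    |L(K+1) - 2 L(K) + L(K-1)| divided by the replicate standard
    deviation of L(K); undefined at the smallest and largest K.  A zero
    standard deviation is floored at ``sd_floor`` with a warning.
    """
    ks = sorted(lk_by_k)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K grid must be consecutive")
    reps = {len(lk_by_k[k]) for k in ks}
    if len(reps) != 1 or min(reps) < 2:
        raise ValueError("need the same number (>= 2) of replicates per K")
    arr = np.array([lk_by_k[k] for k in ks], float)  # (nK, reps)
    rows = []
    for idx, k in enumerate(ks):
        mean = float(arr[idx].mean())
        sd = float(arr[idx].std(ddof=1))
        if idx == 0 or idx == len(ks) - 1:
            rows.append(EvannoRow(k=k, mean_lk=mean, sd_lk=sd, delta_k=None))
            continue
        sd_used = sd
        if sd_used < sd_floor:
            warnings.warn(
                f"sd of L(K={k}) is {sd:g}; floored at {sd_floor:g} for deltaK",
                stacklevel=2,
            )
            sd_used = sd_floor
        second = np.abs(arr[idx + 1] - 2 * arr[idx] + arr[idx - 1]).mean()
        rows.append(EvannoRow(k=k, mean_lk=mean, sd_lk=sd, delta_k=float(second / sd_used)))
    return rows


def best_k(evanno_rows) -> int:
    """K maximizing deltaK (interior K only)."""
    interior = [r for r in evanno_rows if r.delta_k is not None]
    if not interior:
        raise ValueError("no interior K with a defined deltaK")
    return max(interior, key=lambda r: r.delta_k).k


def align_replicates(q_list) -> np.ndarray:
    """CLUMPP-style consensus of replicate Q matrices.

    Each replicate's columns are permuted to maximize the sum of
    elementwise products with the incrementally built running mean
    (exact search over the k! permutations, k <= 8); the consensus is the
    mean of aligned replicates with rows renormalized.
    """
    q_list = [np.asarray(q, float) for q in q_list]
    shape = q_list[0].shape
    if any(q.shape != shape for q in q_list):
        raise ValueError("all Q matrices must share one shape")
    k = shape[1]
    if k > 8:
        raise ValueError("exact permutation search supports k <= 8")
    ref = q_list[0].copy()
    total = q_list[0].copy()
    for idx, q in enumerate(q_list[1:], start=2):
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(k)):
            score = float((ref * q[:, perm]).sum())
            if score > best_score:
                best_score, best_perm = score, perm
        total += q[:, best_perm]
        ref = total / idx
    consensus = total / len(q_list)
    return consensus / consensus.sum(axis=1, keepdims=True)


def assign_groups(q, threshold: float = 0.6):
    """Group label per individual: argmax group iff max Q >= threshold, else 'mixed'."""
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    q = np.asarray(q, float)
    out = []
    for row in q:
        j = int(np.argmax(row))
        out.append(j + 1 if row[j] >= threshold else "mixed")
    return out


def run_k_grid(
    G: GenotypeMatrix,
    k_values,
    n_replicates: int = 10,
    burn_in: int = 2_000,
    iterations: int = 10_000,
    seed: int = 0,
    alpha: float = 1.0,
):
    """Replicated admixture runs over a K grid.

    Returns ``(lk_by_k, results)`` where ``lk_by_k[k]`` lists L(K) per
    replicate and ``results[k]`` the corresponding AdmixtureResults.
    Sub-seeds are derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    lk_by_k: dict[int, list[float]] = {}
    results: dict[int, list[AdmixtureResult]] = {}
    for k in sorted(k_values):
        lk_by_k[k] = []
        results[k] = []
        for rep in range(n_replicates):
            sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            res = fit_admixture(
                G, k, burn_in=burn_in, iterations=iterations, seed=sub, alpha=alpha
            )
            lk_by_k[k].append(res.lk)
            results[k].append(res)
    return lk_by_k, results
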