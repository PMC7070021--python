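"""Analysis of molecular variance (AMOVA), pairwise Fst and gene flow.

Genetic variance in codominant diploid genotypes is partitioned across a
one- or two-level hierarchy (groups, optionally subgroups nested in
groups).  The analysis works at the allele-copy level: each diploid
individual contributes two haploid units per locus, the squared distance
between two units is the number of loci at which their alleles differ,
and the classical sums-of-squares decomposition over the pairwise
squared-distance matrix yields the variance components and the Phi
statistics.  With allele copies as units, PhiST is a direct estimate of
the fixation index Fst: under an island model with divergence Fst the
among-group component of allele-frequency variance is Fst of the total,
which a genotype-as-unit analysis would overstate (the two copies of an
individual are independent draws given its group, so the among-group
signal doubles relative to the within-individual spread).

Significance is assessed by permutation (default 999) with +1 smoothing.
Individuals are the permutation unit (their two copies travel together):
whole subgroups are permuted across groups for the among-group test when
a nested design is supplied, else individuals across groups; individuals
are permuted across subgroups within their group for the among-subgroup
test.

Gene flow is derived from the fixation index by the island-model formula
Nm = (1/4)(1/Fst - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix


def genotype_distance_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Pairwise allele-difference counts between diploid individuals.

    Per locus the distance between two calls is the minimum number of
    allele substitutions turning one multiset into the other (0, 1 or 2);
    loci missing in either individual contribute 0.  Used for reporting
    and for quick dissimilarity summaries; the AMOVA itself works on
    allele copies (see :func:`unit_distance_matrix`).
    """
    n, L = G.n_individuals, G.n_loci
    codes, alleles = G.allele_codes()
    missing = G.missing_mask()
    D = np.zeros((n, n))
    for l in range(L):
        j = len(alleles[l])
        C = np.zeros((n, j))
        ok = ~missing[:, l]
        for i in np.where(ok)[0]:
            C[i, codes[i, l, 0]] += 1
            C[i, codes[i, l, 1]] += 1
        diff = np.abs(C[:, None, :] - C[None, :, :]).sum(axis=2) / 2.0
        D += np.where(np.outer(ok, ok), diff, 0.0)
    return D


def unit_distance_matrix(G: GenotypeMatrix) -> np.ndarray:
    """(2n x 2n) squared distances between allele copies.

    Unit 2i and 2i+1 are the two allele copies of individual i; the
    squared distance between two units counts the loci at which their
    alleles differ (loci missing in either unit are skipped).
    """
    n, L = G.n_individuals, G.n_loci
    codes, _ = G.allele_codes()
    units = codes.transpose(0, 2, 1).reshape(2 * n, L)  # rows: i0, i1 copies
    D = np.zeros((2 * n, 2 * n))
    for l in range(L):
        col = units[:, l]
        ok = col >= 0
        diff = (col[:, None] != col[None, :]) & np.outer(ok, ok)
        D += diff
    return D


@dataclass
class AmovaRow:
    source: str
    df: int
    ss: float
    variance: float  # raw moment estimate (may be negative)
    percent: float  # computed with negative components floored at 0
    phi: float | None
    p_value: float | None
    truncated: bool = False  # True when a negative component was floored


@dataclass
class AmovaTable:
    rows: list
    phi_st: float

    def __getitem__(self, source: str) -> AmovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)


def _ss_within(D2: np.ndarray, parts) -> float:
    """Sum over partitions of (within-partition pair sums) / partition size."""
    ss = 0.0
    for idx in parts:
        if len(idx) == 0:
            continue
        sub = D2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * len(idx))
    return ss


def _groups(labels) -> dict:
    out: dict = {}
    for i, lab in enumerate(labels):
        out.setdefault(lab, []).append(i)
    return out


def _expand(ind_parts) -> list:
    """Individual-index partitions -> allele-copy-index partitions."""
    return [[u for i in idx for u in (2 * i, 2 * i + 1)] for idx in ind_parts]


def _one_level_components(D2_units, ind_groups):
    groups = _expand(ind_groups)
    n = D2_units.shape[0]
    g = len(groups)
    ss_total = D2_units.sum() / (2.0 * n)
    ss_within = _ss_within(D2_units, groups)
    ss_among = ss_total - ss_within
    df_among, df_within = g - 1, n - g
    sizes = np.array([len(idx) for idx in groups], float)
    n_c = (n - (sizes**2).sum() / n) / df_among
    ms_within = ss_within / df_within
    sigma_w = ms_within
    sigma_a = (ss_among / df_among - ms_within) / n_c
    return ss_total, ss_among, ss_within, df_among, df_within, sigma_a, sigma_w


def amova(
    G: GenotypeMatrix,
    group_labels,
    subgroup_labels=None,
    n_permutations: int = 999,
    seed: int = 0,
) -> AmovaTable:
    """Hierarchical AMOVA over groups (and optional nested subgroups).

    Every individual must carry a group label (and a subgroup label in
    the nested design); each terminal stratum needs >= 2 members.
    """
    group_labels = list(group_labels)
    if len(group_labels) != G.n_individuals:
        raise ValueError("one group label per individual required")
    if len(set(group_labels)) < 2:
        raise ValueError("need >= 2 groups")
    D2 = unit_distance_matrix(G)
    rng = np.random.default_rng(seed)
    if subgroup_labels is None:
        return _amova_one_level(D2, group_labels, n_permutations, rng)
    subgroup_labels = list(subgroup_labels)
    if len(subgroup_labels) != G.n_individuals:
        raise ValueError("one subgroup label per individual required")
    return _amova_two_level(D2, group_labels, subgroup_labels, n_permutations, rng)


def _amova_one_level(D2, labels, n_perm, rng) -> AmovaTable:
    ind_groups = list(_groups(labels).values())
    for idx in ind_groups:
        if len(idx) < 2:
            raise ValueError("every group needs >= 2 members")
    (ss_total, ss_among, ss_within, df_a, df_w, sigma_a, sigma_w) = _one_level_components(
        D2, ind_groups
    )
    sa, sw = max(sigma_a, 0.0), max(sigma_w, 0.0)
    total = sa + sw
    phi_st = sa / total if total > 0 else 0.0
    p = None
    if n_perm > 0:
        n_ind = len(labels)
        sizes = [len(idx) for idx in ind_groups]
        hits = 0
        for _ in range(n_perm):
            order = rng.permutation(n_ind)
            pos = 0
            perm_groups = []
            for sz in sizes:
                perm_groups.append(list(order[pos : pos + sz]))
                pos += sz
            comp = _one_level_components(D2, perm_groups)[5]
            if comp >= sigma_a - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    rows = [
        AmovaRow(
            "among groups", df_a, ss_among, sigma_a,
            100 * sa / total if total else 0.0, phi_st, p, truncated=sigma_a < 0,
        ),
        AmovaRow(
            "within groups", df_w, ss_within, sigma_w,
            100 * sw / total if total else 0.0, None, None,
        ),
    ]
    return AmovaTable(rows=rows, phi_st=phi_st)


def _two_level_components(D2_units, ind_groups, ind_subs_by_group):
    """Variance components for groups / subgroups-in-groups / within-subgroups."""
    groups = _expand(ind_groups)
    subs_by_group = [_expand(subs) for subs in ind_subs_by_group]
    n = D2_units.shape[0]
    g = len(groups)
    all_subs = [idx for subs in subs_by_group for idx in subs]
    p_tot = len(all_subs)
    ss_total = D2_units.sum() / (2.0 * n)
    ss_wp = _ss_within(D2_units, all_subs)
    ss_wg = _ss_within(D2_units, groups)
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg
    df_ag, df_ap, df_wp = g - 1, p_tot - g, n - p_tot
    sizes_g = np.array([len(idx) for idx in groups], float)
    sq_by_group = [
        sum(len(idx) ** 2 for idx in subs) / len(grp)
        for grp, subs in zip(groups, subs_by_group)
    ]
    sum_sq_over_ng = float(np.sum(sq_by_group))
    sum_sq_over_n = sum(len(idx) ** 2 for idx in all_subs) / n
    n1 = (n - sum_sq_over_ng) / df_ap
    n2 = (sum_sq_over_ng - sum_sq_over_n) / df_ag
    n3 = (n - (sizes_g**2).sum() / n) / df_ag
    sigma_c = ss_wp / df_wp
    sigma_b = (ss_ap / df_ap - sigma_c) / n1
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    return (ss_total, ss_ag, ss_ap, ss_wp, df_ag, df_ap, df_wp, sigma_a, sigma_b, sigma_c)


def _amova_two_level(D2, group_labels, sub_labels, n_perm, rng) -> AmovaTable:
    group_map = _groups(group_labels)
    ind_groups = list(group_map.values())
    ind_subs_by_group = []
    for glab, gidx in group_map.items():
        sub_map = _groups([sub_labels[i] for i in gidx])
        subs = [[gidx[j] for j in idx] for idx in sub_map.values()]
        for idx in subs:
            if len(idx) < 2:
                raise ValueError("every subgroup needs >= 2 members")
        ind_subs_by_group.append(subs)
    (ss_total, ss_ag, ss_ap, ss_wp, df_ag, df_ap, df_wp, sig_a, sig_b, sig_c) = (
        _two_level_components(D2, ind_groups, ind_subs_by_group)
    )
    fa, fb, fc = max(sig_a, 0.0), max(sig_b, 0.0), max(sig_c, 0.0)
    total = fa + fb + fc
    phi_st = (fa + fb) / total if total else 0.0
    phi_ct = fa / total if total else 0.0
    p_ag = None
    p_ap = None
    if n_perm > 0:
        # among groups: permute whole subgroups across groups
        all_subs = [idx for subs in ind_subs_by_group for idx in subs]
        n_subs_per_group = [len(subs) for subs in ind_subs_by_group]
        hits_ag = 0
        for _ in range(n_perm):
            order = rng.permutation(len(all_subs))
            perm_groups, perm_subs, pos = [], [], 0
            for cnt in n_subs_per_group:
                chunk = [all_subs[j] for j in order[pos : pos + cnt]]
                pos += cnt
                perm_subs.append(chunk)
                perm_groups.append([i for idx in chunk for i in idx])
            comp = _two_level_components(D2, perm_groups, perm_subs)[7]
            if comp >= sig_a - 1e-12:
                hits_ag += 1
        p_ag = (hits_ag + 1) / (n_perm + 1)
        # among subgroups: permute individuals within their group
        hits_ap = 0
        for _ in range(n_perm):
            perm_subs_by_group = []
            for grp, subs in zip(ind_groups, ind_subs_by_group):
                order = rng.permutation(grp)
                chunks, pos = [], 0
                for idx in subs:
                    chunks.append(list(order[pos : pos + len(idx)]))
                    pos += len(idx)
                perm_subs_by_group.append(chunks)
            comp = _two_level_components(D2, ind_groups, perm_subs_by_group)[8]
            if comp >= sig_b - 1e-12:
                hits_ap += 1
        p_ap = (hits_ap + 1) / (n_perm + 1)
    rows = [
        AmovaRow(
            "among groups", df_ag, ss_ag, sig_a,
            100 * fa / total if total else 0.0, phi_ct, p_ag, truncated=sig_a < 0,
        ),
        AmovaRow(
            "among subgroups within groups", df_ap, ss_ap, sig_b,
            100 * fb / total if total else 0.0, phi_st, p_ap, truncated=sig_b < 0,
        ),
        AmovaRow(
            "within subgroups", df_wp, ss_wp, sig_c,
            100 * fc / total if total else 0.0, None, None,
        ),
    ]
    return AmovaTable(rows=rows, phi_st=phi_st)


def pairwise_fst(
    G: GenotypeMatrix, group_labels, n_permutations: int = 999, seed: int = 0
):
    """Pairwise PhiST matrix with permutation p-values.

    Each pair of groups is analyzed as a two-group AMOVA on the subset of
    individuals belonging to the pair.  Returns ``(group_names, fst,
    p_values)`` with symmetric matrices and zero diagonals.
    """
    group_labels = list(group_labels)
    names = sorted(set(group_labels), key=str)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    g = len(names)
    fst = np.zeros((g, g))
    pvals = np.zeros((g, g))
    ss = np.random.SeedSequence(seed)
    for a in range(g):
        for b in range(a + 1, g):
            idx = [i for i, lab in enumerate(group_labels) if lab in (names[a], names[b])]
            sub = GenotypeMatrix(
                [G.individuals[i] for i in idx], G.loci, G.calls[idx]
            )
            labs = [group_labels[i] for i in idx]
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            table = amova(sub, labs, n_permutations=n_permutations, seed=sub_seed)
            fst[a, b] = fst[b, a] = table.phi_st
            row = table["among groups"]
            pvals[a, b] = pvals[b, a] = row.p_value if row.p_value is not None else np.nan
    return names, fst, pvals


def nm_from_fst(fst: float) -> float:
    """Island-model gene flow Nm = (1/4)(1/Fst - 1); requires Fst in (0, 1]."""
    if not 0 < fst <= 1:
        raise ValueError("Fst must lie in (0, 1]")
    return 0.25 * (1.0 / fst - 1.0)
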