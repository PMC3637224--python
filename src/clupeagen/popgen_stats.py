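"""Population-genetic summary statistics and structure analyses.

Haplotype and nucleotide diversity, mismatch distributions, AMOVA with
Phi_ST-type fixation indices and permutation tests, pairwise Phi_ST
matrices, and classical (Torgerson) multidimensional scaling of the
resulting distance matrices.

The AMOVA follows the standard molecular-variance framework: the matrix of
pairwise nucleotide differences between individuals plays the role of
squared Euclidean distances, sums of squares are decomposed into
hierarchical levels, and variance components are obtained by equating
observed mean squares to their expectations. Phi_ST is the inter-population
component of nucleotide diversity; its null distribution is obtained by
permuting individuals among populations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .seq_io import MISSING, HaplotypeTable, PartitionedAlignment, PopulationMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    n: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    S: int

    @property
    def pi_percent(self) -> float:
        return 100.0 * self.pi


def haplotype_diversity(counts) -> tuple[float, float]:
    """Haplotype (gene) diversity h = n(1 - sum p_i^2)/(n-1), with Nei's SD.

    ``counts`` is an iterable of haplotype frequencies (absolute counts).
    """
    c = np.asarray(list(counts), dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = c / n
    sum_p2 = float(np.sum(p**2))
    sum_p3 = float(np.sum(p**3))
    h = n * (1.0 - sum_p2) / (n - 1.0)
    # Nei (1987) eq. 8.12 sampling variance of heterozygosity
    var = (
        2.0
        / (n * (n - 1.0))
        * (2.0 * (n - 2.0) * (sum_p3 - sum_p2**2) + sum_p2 - sum_p2**2)
    )
    return float(h), math.sqrt(max(var, 0.0))


def _pairwise_diff_count(a: str, b: str) -> tuple[int, int]:
    """(differences, comparable sites) with pairwise deletion of N/-."""
    diffs = comparable = 0
    for x, y in zip(a, b):
        if x in MISSING or y in MISSING:
            continue
        comparable += 1
        if x != y:
            diffs += 1
    return diffs, comparable


def nucleotide_diversity(source, population: str | None = None, popmap: PopulationMap | None = None) -> tuple[float, float]:
    """Nucleotide diversity: mean per-site pairwise difference, with SD.

    ``source`` may be a :class:`PartitionedAlignment` (optionally subset to
    one population via ``population`` + ``popmap``), a plain list of
    sequences, or a :class:`HaplotypeTable` (frequency-weighted over
    haplotype pairs).
    """
    if isinstance(source, HaplotypeTable):
        ids = source.haplotype_ids
        if population is not None:
            freqs = source.counts[population].to_numpy(dtype=float)
        else:
            freqs = source.counts.sum(axis=1).to_numpy(dtype=float)
        keep = freqs > 0
        seqs = [source.sequences[h] for h, k in zip(ids, keep) if k]
        freqs = freqs[keep]
        n = freqs.sum()
        if n < 2:
            raise ValueError("nucleotide diversity needs n >= 2")
        total = 0.0
        n_pairs = n * (n - 1) / 2.0
        L = len(seqs[0]) if seqs else 0
        for i in range(len(seqs)):
            for j in range(i, len(seqs)):
                if i == j:
                    w = freqs[i] * (freqs[i] - 1) / 2.0
                    if w == 0:
                        continue
                    d = 0.0
                else:
                    w = freqs[i] * freqs[j]
                    diffs, comp = _pairwise_diff_count(seqs[i], seqs[j])
                    if comp == 0:
                        raise ValueError("haplotype pair with no comparable sites")
                    d = diffs / comp
                total += w * d
        pi = total / n_pairs
        n_eff = int(n)
    else:
        if isinstance(source, PartitionedAlignment):
            if population is not None:
                if popmap is None:
                    raise ValueError("population subsetting requires a popmap")
                samples = [
                    s for s in source.sample_ids if popmap.population_of(s) == population
                ]
                source = source.subset(samples)
            seqs = source.sequences
        else:
            seqs = list(source)
        if len(seqs) < 2:
            raise ValueError("nucleotide diversity needs n >= 2")
        dists = []
        for a, b in itertools.combinations(seqs, 2):
            diffs, comp = _pairwise_diff_count(a, b)
            if comp == 0:
                raise ValueError("sequence pair with no comparable sites")
            dists.append(diffs / comp)
        pi = float(np.mean(dists))
        n_eff = len(seqs)
        L = len(seqs[0])

    # Nei (1987) eq. 10.7 approximate sampling variance (no-recombination form)
    n = n_eff
    L = max(L, 1)
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return float(pi), math.sqrt(max(var, 0.0))


def segregating_sites(seqs: list[str]) -> int:
    """Number of sites with >= 2 distinct resolved states."""
    if not seqs:
        return 0
    S = 0
    for col in zip(*seqs):
        states = {c for c in col if c not in MISSING}
        if len(states) > 1:
            S += 1
    return S


def diversity_stats(seqs: list[str]) -> DiversityStats:
    """Bundle n, h, pi and S for a list of sequences."""
    from collections import Counter

    counter = Counter(seqs)
    h, h_sd = haplotype_diversity(counter.values())
    pi, pi_sd = nucleotide_diversity(seqs)
    return DiversityStats(
        n=len(seqs), h=h, h_sd=h_sd, pi=pi, pi_sd=pi_sd, S=segregating_sites(seqs)
    )


# ---------------------------------------------------------------------------
# mismatch distributions
# ---------------------------------------------------------------------------


@dataclass
class MismatchDistribution:
    """Histogram of pairwise difference counts k = 0, 1, 2, ..."""

    counts: np.ndarray
    n_pairs: int
    excluded_pairs: int = 0

    @property
    def modal_k(self) -> list[int]:
        peak = self.counts.max()
        return [int(k) for k in np.flatnonzero(self.counts == peak)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(len(self.counts)), "count": self.counts.astype(int)}
        )


def mismatch_distribution(
    seqs: list[str], min_comparable_fraction: float = 0.5
) -> MismatchDistribution:
    """Distribution of raw pairwise difference counts (pairwise deletion).

    Pairs with fewer than ``min_comparable_fraction`` of sites comparable
    are excluded; the exclusion count is logged and recorded.
    """
    if len(seqs) < 2:
        raise ValueError("mismatch distribution needs n >= 2")
    L = len(seqs[0])
    ks = []
    excluded = 0
    for a, b in itertools.combinations(seqs, 2):
        diffs, comp = _pairwise_diff_count(a, b)
        if comp < min_comparable_fraction * L:
            excluded += 1
            continue
        ks.append(diffs)
    if excluded:
        logger.info("mismatch distribution: excluded %d low-coverage pairs", excluded)
    if not ks:
        raise ValueError("all pairs excluded for missing data")
    counts = np.bincount(ks)
    return MismatchDistribution(counts=counts, n_pairs=len(ks), excluded_pairs=excluded)


def peak_to_lineage_divergence(k: float, L: int) -> float:
    """Per-lineage uncorrected divergence (%) for a mismatch peak at k.

    A pair separated by k differences has accumulated k/2 changes per
    lineage, i.e. 100*k/(2L) percent per site.
    """
    if L <= 0:
        raise ValueError("sequence length must be positive")
    if k < 0:
        raise ValueError("difference count must be >= 0")
    return 100.0 * k / (2.0 * L)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Variance components and Phi statistics from an AMOVA decomposition."""

    sigma_within: float
    sigma_among_pops: float
    sigma_among_groups: float | None
    phi_st: float
    phi_sc: float | None
    phi_ct: float | None
    p_phi_st: float | None
    p_phi_sc: float | None
    p_phi_ct: float | None
    n_permutations: int
    seed: int | None
    df: dict = field(default_factory=dict)

    @property
    def total_variance(self) -> float:
        return (
            self.sigma_within
            + self.sigma_among_pops
            + (self.sigma_among_groups or 0.0)
        )


def pairwise_difference_matrix(seqs: list[str]) -> np.ndarray:
    """Matrix of raw pairwise difference counts between individuals."""
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diffs, comp = _pairwise_diff_count(seqs[i], seqs[j])
            if comp == 0:
                raise ValueError("pair with no comparable sites")
            d[i, j] = d[j, i] = diffs
    return d


def _one_level_components(d2: np.ndarray, pop_of: np.ndarray, n_pops: int):
    """Variance components for a single-level AMOVA.

    ``d2`` holds squared distances (pairwise difference counts); ``pop_of``
    maps each individual to a population index.
    """
    N = d2.shape[0]
    ssd_total = d2[np.triu_indices(N, k=1)].sum() / N
    ssd_within = 0.0
    sizes = np.zeros(n_pops)
    for k in range(n_pops):
        members = np.flatnonzero(pop_of == k)
        sizes[k] = members.size
        if members.size > 1:
            sub = d2[np.ix_(members, members)]
            ssd_within += sub[np.triu_indices(members.size, k=1)].sum() / members.size
    ssd_among = ssd_total - ssd_within
    df_among = n_pops - 1
    df_within = N - n_pops
    if df_within <= 0 or df_among <= 0:
        raise ValueError("AMOVA needs >=2 populations and N > number of populations")
    sigma_w = ssd_within / df_within
    n_prime = (N - (sizes**2).sum() / N) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / n_prime
    return sigma_a, sigma_w


def _two_level_components(d2, pop_of, n_pops, group_of_pop, n_groups):
    """Excoffier-style two-level decomposition (groups / pops / individuals)."""
    N = d2.shape[0]
    sizes = np.array([(pop_of == k).sum() for k in range(n_pops)], dtype=float)
    group_of_ind = np.array([group_of_pop[p] for p in pop_of])
    group_sizes = np.array([(group_of_ind == g).sum() for g in range(n_groups)], dtype=float)

    ssd_total = d2[np.triu_indices(N, k=1)].sum() / N
    ssd_within_pop = 0.0
    for k in range(n_pops):
        members = np.flatnonzero(pop_of == k)
        if members.size > 1:
            sub = d2[np.ix_(members, members)]
            ssd_within_pop += sub[np.triu_indices(members.size, k=1)].sum() / members.size
    ssd_within_group = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(group_of_ind == g)
        if members.size > 1:
            sub = d2[np.ix_(members, members)]
            ssd_within_group += sub[np.triu_indices(members.size, k=1)].sum() / members.size
    ssd_among_groups = ssd_total - ssd_within_group
    ssd_among_pops_within = ssd_within_group - ssd_within_pop

    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = N - n_pops
    if min(df_ag, df_ap, df_wp) <= 0:
        raise ValueError("degenerate design for two-level AMOVA")

    # coefficients (Excoffier, Smouse & Quattro 1992)
    sum_n2_over_group = 0.0
    for g in range(n_groups):
        pops = [k for k in range(n_pops) if group_of_pop[k] == g]
        sum_n2_over_group += sum(sizes[k] ** 2 for k in pops) / group_sizes[g]
    n_1 = (N - sum_n2_over_group) / df_ap
    n_2 = (sum_n2_over_group - (sizes**2).sum() / N) / df_ag
    n_3 = (N - (group_sizes**2).sum() / N) / df_ag

    sigma_w = ssd_within_pop / df_wp
    sigma_b = (ssd_among_pops_within / df_ap - sigma_w) / n_1
    sigma_a = (ssd_among_groups / df_ag - sigma_w - n_2 * sigma_b) / n_3
    return sigma_a, sigma_b, sigma_w


def _extract_sequences(aln: PartitionedAlignment, popmap: PopulationMap):
    missing = [s for s in aln.sample_ids if s not in popmap.assignments]
    if missing:
        raise ValueError(f"samples missing from popmap: {missing}")
    return aln.sequences, [popmap.population_of(s) for s in aln.sample_ids]


def amova(
    aln: PartitionedAlignment,
    popmap: PopulationMap,
    grouping: dict[str, list[str]] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    populations: list[str] | None = None,
) -> AmovaResult:
    """AMOVA over pairwise nucleotide differences, with permutation tests.

    With ``grouping`` (group -> list of population codes) a two-level
    design is fitted (Phi_CT, Phi_SC, Phi_ST); otherwise a single level
    (Phi_ST only). P-values use the (b+1)/(n_perm+1) convention and include
    the observed arrangement. Negative components are reported as computed.
    """
    seqs_all, pops_all = _extract_sequences(aln, popmap)
    if populations is not None:
        keep = [i for i, p in enumerate(pops_all) if p in populations]
        seqs_all = [seqs_all[i] for i in keep]
        pops_all = [pops_all[i] for i in keep]
    pop_labels = list(dict.fromkeys(pops_all))
    if len(pop_labels) < 2:
        raise ValueError("AMOVA needs at least two populations")
    sizes = {p: pops_all.count(p) for p in pop_labels}
    empty = [p for p, n in sizes.items() if n == 0]
    if empty:
        raise ValueError(f"empty populations: {empty}")
    pop_index = {p: i for i, p in enumerate(pop_labels)}
    pop_of = np.array([pop_index[p] for p in pops_all])
    d2 = pairwise_difference_matrix(seqs_all)
    rng = np.random.default_rng(seed)

    if grouping is None:
        sigma_a, sigma_w = _one_level_components(d2, pop_of, len(pop_labels))
        total = sigma_a + sigma_w
        phi_st = sigma_a / total if total != 0 else 0.0

        b = 0
        for _ in range(n_perm):
            perm = rng.permutation(pop_of)
            pa, pw = _one_level_components(d2, perm, len(pop_labels))
            tot = pa + pw
            phi_perm = pa / tot if tot != 0 else 0.0
            if phi_perm >= phi_st - 1e-12:
                b += 1
        p_st = (b + 1) / (n_perm + 1) if n_perm > 0 else None
        return AmovaResult(
            sigma_within=float(sigma_w),
            sigma_among_pops=float(sigma_a),
            sigma_among_groups=None,
            phi_st=float(phi_st),
            phi_sc=None,
            phi_ct=None,
            p_phi_st=p_st,
            p_phi_sc=None,
            p_phi_ct=None,
            n_permutations=n_perm,
            seed=seed,
            df={"among": len(pop_labels) - 1, "within": len(pops_all) - len(pop_labels)},
        )

    # two-level design
    group_labels = list(grouping)
    group_of_pop = np.zeros(len(pop_labels), dtype=int)
    assigned = set()
    for gi, g in enumerate(group_labels):
        for p in grouping[g]:
            if p in pop_index:
                group_of_pop[pop_index[p]] = gi
                assigned.add(p)
    unassigned = set(pop_labels) - assigned
    if unassigned:
        raise ValueError(f"populations not assigned to any group: {sorted(unassigned)}")

    sigma_a, sigma_b, sigma_w = _two_level_components(
        d2, pop_of, len(pop_labels), group_of_pop, len(group_labels)
    )
    total = sigma_a + sigma_b + sigma_w
    phi_st = (sigma_a + sigma_b) / total if total != 0 else 0.0
    phi_ct = sigma_a / total if total != 0 else 0.0
    denom_sc = sigma_b + sigma_w
    phi_sc = sigma_b / denom_sc if denom_sc != 0 else 0.0

    b_st = b_sc = b_ct = 0
    group_of_ind = np.array([group_of_pop[p] for p in pop_of])
    for _ in range(n_perm):
        # Phi_ST: individuals permuted among all populations
        perm = rng.permutation(pop_of)
        pa, pb, pw = _two_level_components(
            d2, perm, len(pop_labels), group_of_pop, len(group_labels)
        )
        tot = pa + pb + pw
        if tot != 0 and (pa + pb) / tot >= phi_st - 1e-12:
            b_st += 1
        # Phi_SC: individuals permuted among populations within their group
        perm_sc = pop_of.copy()
        for gi in range(len(group_labels)):
            members = np.flatnonzero(group_of_ind == gi)
            perm_sc[members] = rng.permutation(pop_of[members])
        pa, pb, pw = _two_level_components(
            d2, perm_sc, len(pop_labels), group_of_pop, len(group_labels)
        )
        if pb + pw != 0 and pb / (pb + pw) >= phi_sc - 1e-12:
            b_sc += 1
        # Phi_CT: whole populations permuted among groups
        perm_gop = rng.permutation(group_of_pop)
        pa, pb, pw = _two_level_components(
            d2, pop_of, len(pop_labels), perm_gop, len(group_labels)
        )
        tot = pa + pb + pw
        if tot != 0 and pa / tot >= phi_ct - 1e-12:
            b_ct += 1

    denom = n_perm + 1
    return AmovaResult(
        sigma_within=float(sigma_w),
        sigma_among_pops=float(sigma_b),
        sigma_among_groups=float(sigma_a),
        phi_st=float(phi_st),
        phi_sc=float(phi_sc),
        phi_ct=float(phi_ct),
        p_phi_st=(b_st + 1) / denom if n_perm else None,
        p_phi_sc=(b_sc + 1) / denom if n_perm else None,
        p_phi_ct=(b_ct + 1) / denom if n_perm else None,
        n_permutations=n_perm,
        seed=seed,
        df={
            "among_groups": len(group_labels) - 1,
            "among_pops": len(pop_labels) - len(group_labels),
            "within": len(pops_all) - len(pop_labels),
        },
    )


def pairwise_phist(
    aln: PartitionedAlignment,
    popmap: PopulationMap,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Pairwise Phi_ST between all population pairs, with P-value matrix.

    Each entry is a two-population AMOVA; the permutation seed is derived
    per pair from ``seed`` so results do not depend on pair order.
    """
    _, pops_all = _extract_sequences(aln, popmap)
    pop_labels = list(dict.fromkeys(pops_all))
    k = len(pop_labels)
    phi = np.zeros((k, k))
    pvals = np.zeros((k, k))
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(k * (k - 1) // 2)
    pair_idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            res = amova(
                aln,
                popmap,
                n_perm=n_perm,
                seed=int(child_seeds[pair_idx].generate_state(1)[0] % (2**31)),
                populations=[pop_labels[i], pop_labels[j]],
            )
            phi[i, j] = phi[j, i] = res.phi_st
            pvals[i, j] = pvals[j, i] = res.p_phi_st if res.p_phi_st is not None else np.nan
            pair_idx += 1
    # Phi matrices may contain small negatives; DistanceMatrix allows them
    return (
        DistanceMatrix(pop_labels, phi),
        DistanceMatrix(pop_labels, pvals * (1 - np.eye(k))),
    )


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------


def classical_mds(
    dm: DistanceMatrix, dims: int = 2, floor_negative: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson metric MDS: double-centering + eigendecomposition.

    Returns ``(coordinates, eigenvalues)``. Negative input entries (as can
    arise in Phi_ST matrices) are floored at 0 when ``floor_negative`` is
    set. If fewer than ``dims`` positive eigenvalues exist, fewer axes are
    returned with a warning.
    """
    D = dm.values.copy()
    if floor_negative:
        D = np.maximum(D, 0.0)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    positive = vals > 1e-12
    n_pos = int(positive.sum())
    if n_pos < dims:
        logger.warning(
            "only %d positive eigenvalues; returning %d axes instead of %d",
            n_pos,
            n_pos,
            dims,
        )
        dims = n_pos
    coords = vecs[:, :dims] * np.sqrt(np.maximum(vals[:dims], 0.0))
    return coords, vals
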