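"""Founder-haplotype inference from allele counts.

An 8-state hidden Markov model decoded with the Viterbi algorithm. States
are the eight founder haplotypes; emissions treat each read as an
independent Bernoulli trial reporting the founder's allele with
probability 0.99 (1% error); transitions between adjacent markers combine
the per-meiosis recombinant fraction R (Haldane's mapping function applied
to the physical distance) with the funnel-cross topology:

    P(i -> i)                      = (1-R)^3      (no crossover in 3 meioses)
    P(i -> level-1 partner of i)   = R(1-R)^2     (crossover at level 1 only)
    P(i -> other pair, same quartet) = R(1-R)/2 each of 2 states
    P(i -> other quartet)            = R/4     each of 4 states

Disomic chromosomes are decoded over the 36 unordered haplotype pairs:
each homolog follows an independent funnel chain and a read draws one
homolog uniformly before reporting its allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cross import level1_partner
from .tables import HaplotypeMatrix, MarkerTable, AlleleCountMatrix, PloidyTable


@dataclass(frozen=True)
class LinkageParams:
    """Physical-to-genetic conversion and emission error model.

    ``crossover_rate`` is in crossovers per Mb per meiosis (genetic
    distance m = c * d / 1e6 Morgans for physical distance d in bp);
    ``error_rate`` is the per-read probability of reporting the wrong
    allele (the expected allele is emitted with probability 1 - error).
    """

    crossover_rate: float = 3.0
    error_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.crossover_rate < 0:
            raise ValueError("crossover rate must be >= 0")
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error rate must be in (0, 0.5)")

    def recombinant_fraction(self, distance_bp) -> np.ndarray:
        return haldane_r(self.crossover_rate * np.asarray(distance_bp, float) / 1e6)


def haldane_r(m) -> np.ndarray | float:
    """Haldane's mapping function R = 0.5 * (1 - exp(-2m)), m in Morgans."""
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0):
        raise ValueError("genetic distance must be >= 0")
    r = 0.5 * (1.0 - np.exp(-2.0 * m_arr))
    return float(r) if np.isscalar(m) else r


def funnel_transition_matrix(r: float) -> np.ndarray:
    """8x8 haplotype transition matrix for one marker interval.

    Derived from the funnel topology: staying requires no crossover in any
    of the three meioses; switching to the level-1 partner requires a
    crossover at level 1 only, etc. Rows sum to 1 for any R in [0, 0.5].
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombinant fraction must be in [0, 0.5]")
    t = np.empty((8, 8))
    stay = (1 - r) ** 3
    partner = r * (1 - r) ** 2
    cousin = 0.5 * r * (1 - r)
    far = 0.25 * r
    for i in range(1, 9):
        quartet = {1, 2, 3, 4} if i <= 4 else {5, 6, 7, 8}
        for j in range(1, 9):
            if j == i:
                p = stay
            elif j == level1_partner(i):
                p = partner
            elif j in quartet:
                p = cousin
            else:
                p = far
            t[i - 1, j - 1] = p
    return t


def emission_loglik(
    n_ref: np.ndarray, n_alt: np.ndarray, founder_alleles: np.ndarray,
    params: LinkageParams,
) -> np.ndarray:
    """Log-likelihood of counts at one marker under each of the 8 states.

    Parameters
    ----------
    n_ref, n_alt : arrays broadcastable to (n_strains,)
    founder_alleles : (8,) array of 0/1 — each founder's allele here.

    Returns (n_strains, 8). Zero coverage contributes 0 to every state.
    """
    e = params.error_rate
    log_hit, log_miss = np.log1p(-e), np.log(e)
    n_ref = np.atleast_1d(np.asarray(n_ref))[:, None]
    n_alt = np.atleast_1d(np.asarray(n_alt))[:, None]
    is_alt = (np.asarray(founder_alleles) == 1)[None, :]
    match = np.where(is_alt, n_alt, n_ref)
    mismatch = np.where(is_alt, n_ref, n_alt)
    return match * log_hit + mismatch * log_miss


def _interval_logts(pos: np.ndarray, params: LinkageParams, builder) -> list[np.ndarray]:
    rs = params.recombinant_fraction(np.diff(pos.astype(np.int64)))
    out = []
    with np.errstate(divide="ignore"):
        for r in rs:
            out.append(np.log(builder(float(r))))
    return out


def _viterbi(emis: list[np.ndarray], logts: list[np.ndarray], log_init: np.ndarray) -> np.ndarray:
    """Generic vectorized Viterbi. emis[t]: (n, K); logts[t]: (K, K).

    Ties break toward the smallest state index (argmax first occurrence).
    Returns (n, L) state indices.
    """
    n = emis[0].shape[0]
    L = len(emis)
    score = log_init[None, :] + emis[0]
    back = np.empty((L - 1, n, emis[0].shape[1]), dtype=np.int16)
    for t in range(1, L):
        cand = score[:, :, None] + logts[t - 1][None, :, :]
        back[t - 1] = np.argmax(cand, axis=1)
        score = np.max(cand, axis=1) + emis[t]
    path = np.empty((n, L), dtype=np.int16)
    path[:, -1] = np.argmax(score, axis=1)
    for t in range(L - 2, -1, -1):
        path[:, t] = back[t, np.arange(n), path[:, t + 1]]
    return path


def viterbi_chromosome(
    n_ref: np.ndarray,
    n_alt: np.ndarray,
    markers: MarkerTable,
    chromosome: str,
    params: LinkageParams = LinkageParams(),
) -> np.ndarray:
    """Decode monosomic haplotype paths for one chromosome.

    ``n_ref`` / ``n_alt`` are (n_strains, n_chrom_markers) count slices
    aligned to the chromosome's markers. Returns codes 1..8, (n_strains, L).
    """
    sl = markers.chromosome_slices().get(chromosome)
    if sl is None or sl.stop == sl.start:
        raise ValueError(f"no markers on chromosome {chromosome!r}")
    fa = markers.founder_alleles[sl]
    pos = markers.pos[sl]
    n_ref = np.atleast_2d(n_ref)
    n_alt = np.atleast_2d(n_alt)
    emis = [
        emission_loglik(n_ref[:, t], n_alt[:, t], fa[t], params)
        for t in range(fa.shape[0])
    ]
    logts = _interval_logts(pos, params, funnel_transition_matrix)
    path = _viterbi(emis, logts, np.full(8, -np.log(8.0)))
    return (path + 1).astype(np.int8)


# --- disome model ----------------------------------------------------------

# unordered pairs (i, j), 1 <= i <= j <= 8, in lexicographic order
PAIR_STATES: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(1, 9) for j in range(i, 9)
)
_PI = np.array([p[0] - 1 for p in PAIR_STATES])
_PJ = np.array([p[1] - 1 for p in PAIR_STATES])


def disome_transition_matrix(r: float) -> np.ndarray:
    """36x36 unordered-pair transition matrix: two independent funnel
    chains collapsed to unordered pairs."""
    t = funnel_transition_matrix(r)
    same = t[_PI[:, None], _PI[None, :]] * t[_PJ[:, None], _PJ[None, :]]
    cross = t[_PI[:, None], _PJ[None, :]] * t[_PJ[:, None], _PI[None, :]]
    return same + cross * (_PI[None, :] != _PJ[None, :])


def disome_emission_loglik(
    n_ref: np.ndarray, n_alt: np.ndarray, founder_alleles: np.ndarray,
    params: LinkageParams,
) -> np.ndarray:
    """Pair-state emissions: each read picks a homolog uniformly, then
    reports that homolog's allele with probability 1 - error."""
    e = params.error_rate
    p_alt_single = np.where(np.asarray(founder_alleles) == 1, 1 - e, e)
    p_alt = 0.5 * (p_alt_single[_PI] + p_alt_single[_PJ])  # (36,)
    n_ref = np.atleast_1d(np.asarray(n_ref))[:, None]
    n_alt = np.atleast_1d(np.asarray(n_alt))[:, None]
    return n_alt * np.log(p_alt)[None, :] + n_ref * np.log1p(-p_alt)[None, :]


def viterbi_disome(
    n_ref: np.ndarray,
    n_alt: np.ndarray,
    markers: MarkerTable,
    chromosome: str,
    params: LinkageParams = LinkageParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Decode a disomic chromosome over unordered haplotype pairs.

    Returns (first, second) code arrays, each (n_strains, L), first <= second.
    """
    sl = markers.chromosome_slices().get(chromosome)
    if sl is None or sl.stop == sl.start:
        raise ValueError(f"no markers on chromosome {chromosome!r}")
    fa = markers.founder_alleles[sl]
    pos = markers.pos[sl]
    n_ref = np.atleast_2d(n_ref)
    n_alt = np.atleast_2d(n_alt)
    emis = [
        disome_emission_loglik(n_ref[:, t], n_alt[:, t], fa[t], params)
        for t in range(fa.shape[0])
    ]
    # uniform over ordered pairs -> {i,i} gets 1/64, {i,j} gets 2/64
    init = np.where(_PI == _PJ, 1.0, 2.0)
    log_init = np.log(init / 64.0)
    logts = _interval_logts(pos, params, disome_transition_matrix)
    path = _viterbi(emis, logts, log_init)
    first = (_PI[path] + 1).astype(np.int8)
    second = (_PJ[path] + 1).astype(np.int8)
    return first, second


DEFAULT_READ_CUTOFF = 12_000


def infer_haplotypes(
    counts: AlleleCountMatrix,
    markers: MarkerTable,
    ploidy: PloidyTable | None = None,
    params: LinkageParams = LinkageParams(),
    read_cutoff: int = DEFAULT_READ_CUTOFF,
) -> tuple[HaplotypeMatrix, list[str]]:
    """Infer the full haplotype matrix for a population.

    Strains with total reads <= ``read_cutoff`` are dropped (and returned
    as the second element). Chromosomes called copy-number 2 in ``ploidy``
    are decoded with the disome model; all others with the 8-state model.
    """
    if counts.n_markers != markers.n_markers:
        raise ValueError("count matrix and marker table dimensions differ")
    keep = counts.total_reads() > read_cutoff
    excluded = [s for s, k in zip(counts.strains, keep) if not k]
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size == 0:
        warnings.warn("all strains fall below the read-count cutoff")
        empty = np.zeros((0, markers.n_markers), dtype=np.int8)
        return HaplotypeMatrix([], empty, empty.copy()), excluded

    strains = [counts.strains[i] for i in kept_idx]
    ref = counts.ref_counts[kept_idx]
    alt = counts.alt_counts[kept_idx]
    first = np.zeros((len(strains), markers.n_markers), dtype=np.int8)
    second = np.zeros_like(first)

    for chrom, sl in markers.chromosome_slices().items():
        if ploidy is not None:
            ci = ploidy.chromosomes.index(chrom)
            cn = np.array(
                [ploidy.copy_number[ploidy.strains.index(s), ci] for s in strains]
            )
        else:
            cn = np.ones(len(strains), dtype=np.int8)
        mono = np.flatnonzero(cn == 1)
        dis = np.flatnonzero(cn == 2)
        if mono.size:
            first[mono, sl] = viterbi_chromosome(
                ref[mono, sl], alt[mono, sl], markers, chrom, params
            )
        if dis.size:
            f, s2 = viterbi_disome(ref[dis, sl], alt[dis, sl], markers, chrom, params)
            first[dis, sl] = f
            second[dis, sl] = s2
    return HaplotypeMatrix(strains, first, second), excluded
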