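"""Selection scans: deviations from expected haplotype frequencies.

Single-marker scan: chi-square goodness-of-fit of per-marker haplotype
counts against the design expectation (1/8 per haplotype; region-specific
weights on a trisomic chromosome). Because the final population is much
larger than the intermediate pools, null counts are overdispersed
relative to Poisson; the scan therefore first estimates a count divisor D
such that counts/D match a same-mean Poisson (Q-Q slope closest to 1) and
tests the adjusted counts.

Pairwise scan: chi-square test of independence (8x8 table, df 49) for all
scaffold marker pairs. The cross structure inflates null statistics, so
the bottom 95% of inter-chromosomal statistics are Q-Q regressed
log-log against simulated chi-square(49) quantiles and the inverse map
transforms every statistic back to the theoretical null scale before
Holm correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cross import TrisomyEvent
from .linkage import expected_haplotype_freqs
from .tables import MISSING, MarkerTable

PAIR_DF = 49  # (8 - 1)^2


def haplotype_counts(codes: np.ndarray) -> np.ndarray:
    """Per-marker 8-vector of strain counts, (n_markers, 8).

    ``codes`` is (n_strains, n_markers), 1..8 with 0 = missing; counts sum
    to the number of non-missing strains at each marker.
    """
    codes = np.asarray(codes)
    m = codes.shape[1]
    idx = codes.astype(np.int64) + 9 * np.arange(m)[None, :]
    counts = np.bincount(idx.ravel(), minlength=9 * m).reshape(m, 9)
    return counts[:, 1:]


def expected_frequency_table(
    markers: MarkerTable, trisomy: TrisomyEvent | None = None
) -> np.ndarray:
    """(n_markers, 8) expected haplotype frequencies.

    1/8 everywhere except the trisomic chromosome, where copy weights give
    1/9 for uninvolved haplotypes and 0, 1/9, 2/9 or 3/9 for the carrier
    pair depending on the LOH region.
    """
    freqs = np.tile(expected_haplotype_freqs(), (markers.n_markers, 1))
    if trisomy is None:
        return freqs
    sl = markers.chromosome_slices().get(trisomy.chromosome)
    if sl is None:
        return freqs
    pos = markers.pos[sl]
    base = np.ones(8)
    base[trisomy.extra_copy_of - 1] += 1
    w = np.tile(base, (len(pos), 1))
    other = [h for h in trisomy.g1_pair if h != trisomy.extra_copy_of][0]
    for start, end, hap in trisomy.loh_intervals:
        inside = (pos >= start) & (pos <= end)
        lost = other if hap == trisomy.extra_copy_of else trisomy.extra_copy_of
        w[inside, hap - 1] = 3.0
        w[inside, lost - 1] = 0.0
    freqs[sl] = w / w.sum(axis=1, keepdims=True)
    return freqs


# ---------------------------------------------------------------------------
# overdispersion calibration


@dataclass(frozen=True)
class InflationCalibration:
    """Fitted count divisor restoring Poisson-like dispersion."""

    divisor: int
    central_fraction: float
    slope: float  # Q-Q slope of adjusted counts vs Poisson at the fitted D
    grid_slopes: np.ndarray


def _central(sorted_vals: np.ndarray, fraction: float) -> np.ndarray:
    n = len(sorted_vals)
    drop = int(round(n * (1 - fraction) / 2))
    return sorted_vals[drop : n - drop] if drop else sorted_vals


def estimate_inflation_divisor(
    counts: np.ndarray,
    central_fraction: float = 0.95,
    divisor_grid=range(1, 101),
    comparator_seed: int = 0,
    comparator_factor: int = 10,
) -> InflationCalibration:
    """Find the integer divisor D whose divided central-95% ordered counts
    Q-Q regress on same-mean simulated Poisson quantiles with slope
    closest to 1."""
    obs = np.sort(np.asarray(counts, dtype=float).ravel())
    if len(obs) < 100:
        raise ValueError("need at least 100 count observations")
    if np.ptp(obs) == 0:
        raise ValueError("all counts equal; divisor undefined")
    rng = np.random.default_rng(comparator_seed)
    central_obs = _central(obs, central_fraction)
    ranks = (np.arange(len(central_obs)) + 0.5) / len(central_obs)
    slopes = []
    grid = list(divisor_grid)
    for d in grid:
        adj = central_obs / d
        lam = adj.mean()
        sim = rng.poisson(lam, size=comparator_factor * len(obs))
        q = np.quantile(np.sort(sim), 0.025 + ranks * central_fraction)
        # Q-Q regression slope of adjusted observed on comparator quantiles
        qc = q - q.mean()
        denom = np.dot(qc, qc)
        slopes.append(np.dot(qc, adj - adj.mean()) / denom if denom else np.inf)
    slopes_arr = np.asarray(slopes)
    best = int(np.argmin(np.abs(slopes_arr - 1.0)))
    return InflationCalibration(
        int(grid[best]), central_fraction, float(slopes_arr[best]), slopes_arr
    )


# ---------------------------------------------------------------------------
# single-marker scan


@dataclass(frozen=True)
class SingleMarkerScan:
    statistic: np.ndarray  # per marker
    p_value: np.ndarray
    df: np.ndarray
    holm_cutoff_p: float
    significant: np.ndarray  # boolean


def single_marker_scan(
    counts: np.ndarray,
    expected_freqs: np.ndarray,
    divisor: float = 1.0,
    alpha: float = 0.05,
) -> SingleMarkerScan:
    """Goodness-of-fit scan on divisor-adjusted counts.

    Categories with zero expected frequency are excluded with df
    reduction; the Holm-corrected cutoff is computed over all markers.
    """
    counts = np.asarray(counts, dtype=float)
    exp_f = np.asarray(expected_freqs, dtype=float)
    n = counts.sum(axis=1, keepdims=True)
    expected = exp_f * n
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = (counts / divisor - expected / divisor) ** 2 / (expected / divisor)
    live = exp_f > 0
    cells[~live] = 0.0
    stat = cells.sum(axis=1)
    df = live.sum(axis=1) - 1
    p = sps.chi2.sf(stat, df)
    cutoff = holm_cutoff(p, alpha)
    return SingleMarkerScan(stat, p, df, cutoff, p <= cutoff)


# ---------------------------------------------------------------------------
# pairwise independence scan


def pairwise_chisq(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Pearson chi-square of independence on the 8x8 joint haplotype table
    (df 49). Strains missing at either marker are excluded."""
    table = _joint_tables(
        np.asarray(codes_a)[:, None], np.asarray(codes_b)[:, None]
    )[0]
    return float(_pearson_stats(table[None])[0])


def _joint_tables(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(C, 8, 8) joint count tables for C pairs of code columns."""
    c = a.shape[1]
    idx = (a.astype(np.int64) * 9 + b) + 81 * np.arange(c)[None, :]
    t = np.bincount(idx.ravel(), minlength=81 * c).reshape(c, 9, 9)
    return t[:, 1:, 1:]


def _pearson_stats(tables: np.ndarray) -> np.ndarray:
    rows = tables.sum(axis=2, dtype=float)
    cols = tables.sum(axis=1, dtype=float)
    n = rows.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = rows[:, :, None] * cols[:, None, :] / n[:, None, None]
        cells = (tables - e) ** 2 / e
    cells[~np.isfinite(cells)] = 0.0
    return cells.sum(axis=(1, 2))


@dataclass(frozen=True)
class PairwiseCalibration:
    """Log-linear map from observed null statistics to chi-square(49)."""

    intercept: float  # log(observed) = intercept + slope * log(quantile)
    slope: float
    bottom_fraction: float

    def transform(self, statistic) -> np.ndarray:
        """Map raw statistics back to the theoretical null scale."""
        s = np.maximum(np.asarray(statistic, dtype=float), 1e-12)
        return np.exp((np.log(s) - self.intercept) / self.slope)


def calibrate_pairwise_null(
    inter_chrom_stats: np.ndarray,
    bottom_fraction: float = 0.95,
    comparator_seed: int = 0,
    comparator_factor: int = 10,
    df: int = PAIR_DF,
) -> PairwiseCalibration:
    """Fit the log-linear Q-Q relation of observed inter-chromosomal
    statistics (bottom 95%, presumed null) to chi-square(df) quantiles."""
    obs = np.sort(np.asarray(inter_chrom_stats, dtype=float))
    if len(obs) < 100:
        raise ValueError("need at least 100 inter-chromosomal statistics")
    keep = obs[: int(np.ceil(len(obs) * bottom_fraction))]
    rng = np.random.default_rng(comparator_seed)
    sim = rng.chisquare(df, size=comparator_factor * len(obs))
    ranks = (np.arange(len(keep)) + 0.5) / len(obs)
    q = np.quantile(sim, ranks)
    lx = np.log(np.maximum(q, 1e-12))
    ly = np.log(np.maximum(keep, 1e-12))
    slope, intercept = np.polyfit(lx, ly, 1)
    return PairwiseCalibration(float(intercept), float(slope), bottom_fraction)


@dataclass(frozen=True)
class PairwiseScan:
    pairs: np.ndarray  # (n_pairs, 2) marker indices
    statistic: np.ndarray  # raw chi-square
    transformed: np.ndarray  # on the chi-square(49) null scale
    inter_chromosomal: np.ndarray  # boolean; intra pairs are linkage-confounded
    holm_cutoff_p: float
    significant: np.ndarray


def pairwise_scan(
    codes: np.ndarray,
    chrom: np.ndarray,
    calibration: PairwiseCalibration | None = None,
    alpha: float = 0.05,
    chunk: int = 512,
) -> PairwiseScan:
    """Score all marker pairs for haplotype non-independence.

    The Holm cutoff and significance calls use inter-chromosomal pairs
    only (intra-chromosomal pairs are scored but flagged: linkage itself
    violates independence). If no calibration is given it is fitted from
    this scan's inter-chromosomal statistics.
    """
    codes = np.asarray(codes)
    m = codes.shape[1]
    ii, jj = np.triu_indices(m, k=1)
    pairs = np.column_stack([ii, jj])
    stat = np.empty(len(pairs))
    for k0 in range(0, len(pairs), chunk):
        p = pairs[k0 : k0 + chunk]
        tables = _joint_tables(codes[:, p[:, 0]], codes[:, p[:, 1]])
        stat[k0 : k0 + chunk] = _pearson_stats(tables)
    inter = np.asarray(chrom)[pairs[:, 0]] != np.asarray(chrom)[pairs[:, 1]]
    if calibration is None:
        calibration = calibrate_pairwise_null(stat[inter])
    transformed = calibration.transform(stat)
    p_inter = sps.chi2.sf(transformed[inter], PAIR_DF)
    cutoff = holm_cutoff(p_inter, alpha)
    p_all = sps.chi2.sf(transformed, PAIR_DF)
    significant = (p_all <= cutoff) & inter
    return PairwiseScan(pairs, stat, transformed, inter, cutoff, significant)


# ---------------------------------------------------------------------------
# multiple testing


def holm_cutoff(p_values: np.ndarray, alpha: float = 0.05) -> float:
    """Step-down Holm nominal-p cutoff.

    Sort p ascending; the largest k with p(i) <= alpha/(m-i+1) for all
    i <= k determines the cutoff: the bound of the first failing test,
    alpha/(m-k), or alpha when everything is rejected; 0 when nothing is."""
    p = np.sort(np.asarray(p_values, dtype=float))
    m = len(p)
    if m == 0:
        return 0.0
    bounds = alpha / (m - np.arange(m))
    failing = np.flatnonzero(p > bounds)
    k = m if failing.size == 0 else int(failing[0])
    if k == 0:
        return 0.0
    if k == m:
        return alpha
    return alpha / (m - k)
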