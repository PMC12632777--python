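"""Genetic-map behavior of the funnel population.

Two markers share a haplotype in a final strain only if no net crossover
separated them in any of the three meioses, so the expected identity is
I = (1 - R)^3 with R from Haldane's function, R = 0.5(1 - exp(-2 c d / 1e6))
for physical distance d bp and conversion coefficient c (crossovers per Mb
per meiosis). Fitting c to observed identity-vs-distance therefore
measures the effective post-funnel crossover density 3c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm import haldane_r
from .tables import MISSING, HaplotypeMatrix


def predicted_identity(distance_bp, c: float) -> np.ndarray:
    """I(d; c) = (1 - R)^3, decreasing from 1 at d=0 to 1/8 as d -> inf."""
    r = haldane_r(c * np.asarray(distance_bp, dtype=float) / 1e6)
    return (1.0 - r) ** 3


def pairwise_identity(
    haplotypes: HaplotypeMatrix, pairs: np.ndarray
) -> np.ndarray:
    """Proportion of strains with matching codes for each (i, j) marker pair.

    ``pairs`` is (n_pairs, 2) of column indices. Cells that are missing or
    disomic in either member are excluded pairwise.
    """
    codes = haplotypes.monosomic_codes()
    pairs = np.asarray(pairs)
    out = np.empty(len(pairs))
    chunk = 2048
    for k0 in range(0, len(pairs), chunk):
        p = pairs[k0 : k0 + chunk]
        a = codes[:, p[:, 0]]
        b = codes[:, p[:, 1]]
        valid = (a != MISSING) & (b != MISSING)
        n = valid.sum(axis=0)
        match = ((a == b) & valid).sum(axis=0)
        with np.errstate(invalid="ignore"):
            out[k0 : k0 + chunk] = np.where(n > 0, match / np.maximum(n, 1), np.nan)
    return out


def same_chromosome_pairs(
    chrom: np.ndarray,
    pos: np.ndarray,
    max_pairs: int | None = 20_000,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """All (or a seeded subsample of) same-chromosome marker index pairs,
    with their physical distances in bp."""
    rng = np.random.default_rng(seed)
    idx_pairs = []
    for name in np.unique(chrom):
        rows = np.flatnonzero(chrom == name)
        if len(rows) < 2:
            continue
        i, j = np.triu_indices(len(rows), k=1)
        idx_pairs.append(np.column_stack([rows[i], rows[j]]))
    pairs = np.concatenate(idx_pairs)
    if max_pairs is not None and len(pairs) > max_pairs:
        pairs = pairs[rng.choice(len(pairs), size=max_pairs, replace=False)]
    dist = np.abs(pos[pairs[:, 0]].astype(np.int64) - pos[pairs[:, 1]])
    return pairs, dist


@dataclass(frozen=True)
class ConversionFit:
    """Result of the identity-decay fit."""

    c_per_meiosis: float
    residual_variance: float
    grid: np.ndarray
    grid_residuals: np.ndarray

    @property
    def post_funnel_rate(self) -> float:
        """Effective crossovers per Mb after the 3 rounds of meiosis."""
        return 3.0 * self.c_per_meiosis


def fit_conversion_coefficient(
    identities: np.ndarray,
    distances_bp: np.ndarray,
    grid: np.ndarray | None = None,
) -> ConversionFit:
    """Grid search for the conversion coefficient c.

    For each candidate c, observed identity is regressed (OLS, with
    intercept) on the predicted identity I(d; c); the c minimizing the
    residual variance wins.
    """
    if grid is None:
        grid = np.arange(0.5, 6.0 + 1e-9, 0.01)
    identities = np.asarray(identities, dtype=float)
    distances_bp = np.asarray(distances_bp, dtype=float)
    ok = np.isfinite(identities)
    y = identities[ok]
    d = distances_bp[ok]
    if len(np.unique(d)) < 2:
        raise ValueError("need at least two distinct distances to fit")
    resid = np.empty(len(grid))
    for k, c in enumerate(grid):
        x = predicted_identity(d, float(c))
        if np.ptp(x) == 0:
            raise ValueError("degenerate (constant) predicted identities")
        xm, ym = x.mean(), y.mean()
        slope = np.dot(x - xm, y - ym) / np.dot(x - xm, x - xm)
        r = y - (ym + slope * (x - xm))
        resid[k] = np.var(r)
    best = int(np.argmin(resid))
    return ConversionFit(float(grid[best]), float(resid[best]), np.asarray(grid), resid)


def expected_haplotype_freqs(copy_weights=None) -> np.ndarray:
    """Design-expected per-haplotype frequencies.

    With all weights 1 (the default), every haplotype is expected at 1/8.
    On a chromosome carrying extra copies (e.g. the trisomic chromosome IX,
    weight 2 for the duplicated haplotype), the expectation is w_i / sum(w):
    1/9 for the six uninvolved haplotypes, and 1/9, 2/9, 3/9 or 0 for the
    carriers depending on the LOH region.
    """
    if copy_weights is None:
        copy_weights = np.ones(8)
    w = np.asarray(copy_weights, dtype=float)
    if w.shape != (8,) or (w < 0).any() or w.sum() == 0:
        raise ValueError("copy weights must be 8 non-negative values, not all zero")
    return w / w.sum()
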