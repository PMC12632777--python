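"""Population structure: shared intermediate-pool ancestry.

A marker with haplotype h was inherited through specific intermediate
pools (h in {1,2} came via the G1_12 pool, h in {1..4} via the G2_14 pool,
and so on). For a pair of strains, discordance is the proportion of
non-matching haplotypes within the regions both strains inherited from
the same intermediate pool: 0 if they descend from the same pool member,
otherwise ~0.5 (two-founder G1 pools) or ~0.75 (four-founder G2 pools).
Complete-linkage clustering of the discordance distances reveals
bottlenecked groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cross import G1_SETS, G2_SETS
from .tables import MISSING, HaplotypeMatrix

POPULATIONS: dict[str, frozenset[int]] = {
    "G1_12": G1_SETS[0],
    "G1_34": G1_SETS[1],
    "G1_56": G1_SETS[2],
    "G1_78": G1_SETS[3],
    "G2_14": G2_SETS[0],
    "G2_58": G2_SETS[1],
}

DEFAULT_MIN_JOINT_MARKERS = 50
DEFAULT_CLUSTER_CUTOFF = 0.25


def null_discordance(population: str) -> float:
    """Expected discordance for unrelated strains: 1 - 1/|founder set|."""
    k = len(POPULATIONS[population])
    return 1.0 - 1.0 / k


def ancestry_mask(codes: np.ndarray, population: str) -> np.ndarray:
    """Boolean mask of markers a strain inherited via the named pool.

    ``codes`` are monosomic haplotype codes (0 = missing / excluded;
    aneuploid chromosomes should already be masked out).
    """
    members = POPULATIONS[population]
    return np.isin(codes, list(members))


def pairwise_discordance(
    codes_a: np.ndarray, codes_b: np.ndarray, population: str
) -> tuple[float, int]:
    """Discordance of two strains over their joint ancestry mask.

    Returns (proportion non-matching, number of jointly masked markers);
    the proportion is NaN when the joint mask is empty.
    """
    joint = ancestry_mask(codes_a, population) & ancestry_mask(codes_b, population)
    n = int(joint.sum())
    if n == 0:
        return float("nan"), 0
    return float((codes_a[joint] != codes_b[joint]).mean()), n


def discordance_matrix(
    haplotypes: HaplotypeMatrix,
    population: str,
    min_joint_markers: int = DEFAULT_MIN_JOINT_MARKERS,
) -> np.ndarray:
    """Symmetric strain x strain discordance for one intermediate pool.

    Pairs with fewer than ``min_joint_markers`` jointly masked markers are
    NaN. Disomic cells are treated as missing.
    """
    codes = haplotypes.monosomic_codes()
    members = POPULATIONS[population]
    in_pop = np.isin(codes, list(members)) & (codes != MISSING)
    n = haplotypes.n_strains
    d = np.zeros((n, n))
    # vectorized over the second strain
    for i in range(n):
        joint = in_pop[i][None, :] & in_pop
        counts = joint.sum(axis=1)
        mism = ((codes[i][None, :] != codes) & joint).sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = mism / counts
        row[counts < min_joint_markers] = np.nan
        d[i] = row
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class AncestryClusters:
    """Shared-ancestor groups for one intermediate pool."""

    population: str
    labels: np.ndarray  # cluster id per strain
    groups: tuple[tuple[int, ...], ...]  # strain indices, clusters of size >= 2


def cluster_shared_ancestry(
    dist: np.ndarray,
    population: str,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF,
) -> AncestryClusters:
    """Complete-linkage clustering of a discordance matrix, cut at
    ``cutoff`` (default 0.25 — far from both the 0 shared-ancestor mode
    and the 0.5 / 0.75 unrelated modes).

    NaN entries (insufficient joint markers) are imputed at the unrelated
    expectation so they never drive a merge.
    """
    d = np.array(dist, dtype=float)
    nan = ~np.isfinite(d)
    d[nan] = null_discordance(population)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    z = linkage(squareform(d, checks=False), method="complete")
    labels = fcluster(z, t=cutoff, criterion="distance")
    groups = []
    for cid in np.unique(labels):
        members = tuple(int(i) for i in np.flatnonzero(labels == cid))
        if len(members) >= 2:
            groups.append(members)
    return AncestryClusters(population, labels, tuple(groups))
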