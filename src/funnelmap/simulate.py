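"""Synthetic funnel-cross generator.

Produces an 8-founder biallelic SNV panel, progeny of the 3-level funnel
cross with known truth (lineage, haplotype mosaics, ploidy), and
low-coverage allele read counts with the error structure the downstream
haplotype inference assumes.

Genomes are represented as segment mosaics: per chromosome copy, an array
of 1-based segment start positions (first element 1) and a parallel array
of founder codes. Crossovers follow a Poisson process along the physical
sequence (no interference), at ``crossover_rate`` expected crossovers per
Mb per meiosis, so Haldane's mapping function with m = c*d/1e6 Morgans is
exact for this simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross import G1_PAIRS, CrossDesign, LethalPair, TrisomyEvent
from .layout import GenomeLayout
from .tables import (
    AlleleCountMatrix,
    HaplotypeMatrix,
    MarkerTable,
    PloidyTable,
)

# A chromosome copy: (segment start positions, founder codes).
Copy = tuple[np.ndarray, np.ndarray]
# A (possibly aneuploid) haploid genome: chromosome -> list of copies.
Genome = dict[str, list[Copy]]

DEFAULT_SHARING_SPECTRUM = (0.774, 0.130, 0.0673, 0.028)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimOptions:
    """Statistical parameters of the synthetic panel and sequencing.

    Defaults reproduce the study conditions of the real population:
    ~1 SNV per 44 bp, the observed minor-allele sharing spectrum
    (77.4 / 13.0 / 6.73 / 2.8 % of markers with the minor allele carried
    by 1-4 founders), mean sequencing depth 3.8x, and a 1% per-read
    allele error rate.
    """

    bp_per_marker: float = 44.0
    sharing_spectrum: tuple[float, float, float, float] = DEFAULT_SHARING_SPECTRUM
    mean_depth: float = 3.8
    error_rate: float = 0.01
    missegregation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.bp_per_marker <= 0:
            raise ValueError("marker density must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")
        s = float(sum(self.sharing_spectrum))
        if s > 1 + 1e-9 or any(p < 0 for p in self.sharing_spectrum):
            raise ValueError("sharing spectrum must be non-negative and sum to <= 1")
        if not 0 <= self.missegregation_rate <= 1:
            raise ValueError("missegregation rate must be in [0, 1]")

    def spectrum_probs(self) -> np.ndarray:
        """Carrier-count probabilities for 1..4 founders, remainder to 1."""
        p = np.asarray(self.sharing_spectrum, dtype=float)
        p = p.copy()
        p[0] += max(0.0, 1.0 - p.sum())
        return p / p.sum()


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# founder marker panel


def simulate_founder_markers(
    layout: GenomeLayout, options: SimOptions = SimOptions(), seed=0
) -> MarkerTable:
    """Draw a biallelic SNV panel segregating among the 8 founders.

    Marker count per chromosome is Poisson(length / density), at least 1;
    positions are uniform (then sorted, deduplicated); each marker's
    minor-allele carrier count is drawn from the sharing spectrum and the
    carriers chosen uniformly among the founders. The minor allele is
    written as the alternative allele (founder indicator 1).
    """
    rng = _rng(seed)
    probs = options.spectrum_probs()
    chroms, poss = [], []
    for name, length in zip(layout.names, layout.lengths):
        n = max(1, int(rng.poisson(length / options.bp_per_marker)))
        n = min(n, length)  # positions are distinct integers in [1, length]
        pos = np.sort(rng.choice(length, size=n, replace=False) + 1)
        chroms.append(np.full(n, name, dtype=object))
        poss.append(pos.astype(np.int64))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    m = len(pos)

    carriers = rng.choice(np.arange(1, 5), size=m, p=probs)
    # choose `carriers[i]` founders uniformly: rank a random matrix per row
    order = np.argsort(rng.random((m, 8)), axis=1)
    alleles = np.zeros((m, 8), dtype=np.uint8)
    rows = np.repeat(np.arange(m), carriers)
    cols = np.concatenate([order[i, : carriers[i]] for i in range(m)])
    alleles[rows, cols] = 1

    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    return MarkerTable(chrom, pos, _BASES[ref_idx], _BASES[alt_idx], alleles)


# ---------------------------------------------------------------------------
# meiosis on segment mosaics


def _compress(bounds: np.ndarray, codes: np.ndarray) -> Copy:
    if len(codes) <= 1:
        return bounds, codes
    keep = np.empty(len(codes), dtype=bool)
    keep[0] = True
    keep[1:] = codes[1:] != codes[:-1]
    return bounds[keep], codes[keep]


def _splice(parents: list[Copy], cuts: np.ndarray, phase: int, length: int) -> Copy:
    """Alternate between the two parental copies at each cut position."""
    edges = np.concatenate(([1], cuts, [length + 1]))
    b_parts, c_parts = [], []
    for i in range(len(edges) - 1):
        s, e = int(edges[i]), int(edges[i + 1])
        bounds, codes = parents[(phase + i) % 2]
        j0 = np.searchsorted(bounds, s, side="right") - 1
        j1 = np.searchsorted(bounds, e - 1, side="right")
        seg_b = bounds[j0:j1].copy()
        seg_b[0] = s
        b_parts.append(seg_b)
        c_parts.append(codes[j0:j1])
    return _compress(np.concatenate(b_parts), np.concatenate(c_parts))


def recombine_copies(
    a: Copy, b: Copy, length: int, c: float, rng: np.random.Generator
) -> Copy:
    """One meiotic product of two homologs: Poisson(c*L/1e6) crossovers,
    uniform breakpoints, fair-coin starting parent."""
    k = int(rng.poisson(c * length / 1e6))
    phase = int(rng.integers(2))
    if k == 0:
        return (a, b)[phase]
    cuts = np.unique(rng.integers(2, length + 1, size=k))
    return _splice([a, b], cuts, phase, length)


def meiosis(
    diploid: Genome, layout: GenomeLayout, c: float, rng: np.random.Generator,
    p_disome: float = 0.5, missegregation_rate: float = 0.0,
) -> Genome:
    """Sample one gamete genome from a diploid (chromosome -> copies).

    Chromosomes with 2 copies recombine normally. Chromosomes with >= 3
    copies (a trisomic/tetrasomic diploid) follow unbiased multivalent
    segregation: the gamete receives 2 intact copies (a uniform pair) with
    probability ``p_disome``, else 1 intact copy (uniform) — each copy of a
    trivalent then has marginal transmission probability 1/2.
    """
    missegregate = -1
    if missegregation_rate > 0 and rng.random() < missegregation_rate:
        missegregate = int(rng.integers(layout.n_chromosomes))

    gamete: Genome = {}
    for ci, (name, length) in enumerate(zip(layout.names, layout.lengths)):
        copies = diploid[name]
        if len(copies) == 1:
            gamete[name] = [copies[0]]
        elif len(copies) == 2:
            if ci == missegregate:
                gamete[name] = [copies[0], copies[1]]
            else:
                gamete[name] = [recombine_copies(copies[0], copies[1], length, c, rng)]
        else:
            if rng.random() < p_disome:
                i, j = rng.choice(len(copies), size=2, replace=False)
                gamete[name] = [copies[int(i)], copies[int(j)]]
            else:
                gamete[name] = [copies[int(rng.integers(len(copies)))]]
    return gamete


def founder_genome(founder: int, layout: GenomeLayout) -> Genome:
    return {
        name: [(np.array([1], dtype=np.int64), np.array([founder], dtype=np.int8))]
        for name in layout.names
    }


def mate(a: Genome, b: Genome) -> Genome:
    """Fuse two gametes into a diploid (copies concatenate per chromosome)."""
    return {name: a[name] + b[name] for name in a}


def _apply_loh(copy: Copy, intervals, length: int) -> Copy:
    """Override [start, end] intervals of a chromosome copy with a fixed code."""
    bounds, codes = copy
    for start, end, hap in intervals:
        end = min(end, length)
        pts = np.unique(np.concatenate([bounds, [start, end + 1]]))
        pts = pts[pts <= length]
        orig = codes[np.searchsorted(bounds, pts, side="right") - 1]
        new = np.where((pts >= start) & (pts <= end), np.int8(hap), orig)
        bounds, codes = _compress(pts.astype(np.int64), new.astype(np.int8))
    return bounds, codes


def default_trisomy_ix() -> TrisomyEvent:
    """Trisomy-IX event emulating the observed pattern: an extra haplotype-6
    copy in the (5,6) level-1 diploid with two left-arm LOH intervals, one
    erasing haplotype 5 (all copies 6) and one erasing haplotype 6 (all
    copies 5). Interval coordinates are a package choice; the real event's
    breakpoints are not published."""
    return TrisomyEvent(
        chromosome="chrIX",
        g1_pair=(5, 6),
        extra_copy_of=6,
        loh_intervals=((1, 40_000, 6), (80_000, 130_000, 5)),
        p_disome_gamete=0.5,
    )


# ---------------------------------------------------------------------------
# the funnel


@dataclass
class FunnelPopulation:
    """Final mapping strains with full truth.

    ``lineage`` columns are the pool indices of each strain's ancestors in
    the G1_12, G1_34, G1_56, G1_78, G2_14 and G2_58 intermediate pools.
    """

    layout: GenomeLayout
    design: CrossDesign
    strains: list[str]
    genomes: list[Genome]
    lineage: np.ndarray  # (n, 6) int32
    copy_number: np.ndarray  # (n, n_chrom) int8

    LINEAGE_COLS = ("G1_12", "G1_34", "G1_56", "G1_78", "G2_14", "G2_58")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def haplotypes_at(self, markers: MarkerTable) -> HaplotypeMatrix:
        """True founder codes at the given marker positions."""
        first = np.zeros((self.n_strains, markers.n_markers), dtype=np.int8)
        second = np.zeros_like(first)
        for name, sl in markers.chromosome_slices().items():
            pos = markers.pos[sl]
            for i, g in enumerate(self.genomes):
                copies = g[name]
                vals = [_codes_at(cp, pos) for cp in copies]
                first[i, sl] = vals[0]
                if len(vals) > 1:
                    second[i, sl] = vals[1]
        return HaplotypeMatrix(list(self.strains), first, second)

    def ploidy_table(self) -> PloidyTable:
        return PloidyTable(
            list(self.strains),
            list(self.layout.names),
            self.copy_number,
            self.copy_number.astype(float),
        )

    def truth_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.lineage, columns=list(self.LINEAGE_COLS))
        df.insert(0, "strain", self.strains)
        for j, name in enumerate(self.layout.names):
            df[f"cn_{name}"] = self.copy_number[:, j]
        return df

    def subset(self, idx: np.ndarray) -> "FunnelPopulation":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FunnelPopulation(
            self.layout,
            self.design,
            [self.strains[i] for i in idx],
            [self.genomes[i] for i in idx],
            self.lineage[idx],
            self.copy_number[idx],
        )

    def euploid(self) -> "FunnelPopulation":
        return self.subset(np.all(self.copy_number == 1, axis=1))


def _codes_at(copy: Copy, pos: np.ndarray) -> np.ndarray:
    bounds, codes = copy
    return codes[np.searchsorted(bounds, pos, side="right") - 1]


def _draw(pool_n: int, restrict: int | None, rng) -> int:
    n = pool_n if restrict is None else min(restrict, pool_n)
    return int(rng.integers(n))


def simulate_funnel(
    design: CrossDesign,
    layout: GenomeLayout,
    options: SimOptions = SimOptions(),
    seed=0,
) -> FunnelPopulation:
    """Run the 3-level funnel and return the final population with truth.

    Level 1 crosses the fixed founder pairs; levels 2 and 3 mate random
    pairs drawn (with replacement) from the opposite-mating-type pools of
    the stated size. If a trisomy event is configured, the designated
    level-1 diploid carries the extra chromosome copy (with LOH applied)
    and transmission follows unbiased multivalent segregation, emitting
    disomic gametes that propagate through later levels.
    """
    rng = _rng(seed)
    c = design.crossover_rate
    tri = design.trisomy
    miss = options.missegregation_rate

    # level 1: four fixed founder crosses
    g1_diploids = []
    for pair in G1_PAIRS:
        dip = mate(founder_genome(pair[0], layout), founder_genome(pair[1], layout))
        if tri is not None and pair == tri.g1_pair:
            name = tri.chromosome
            length = layout.length_of(name)
            copies = list(dip[name])
            extra = copies[pair.index(tri.extra_copy_of)]
            copies.append(extra)
            dip[name] = [_apply_loh(cp, tri.loh_intervals, length) for cp in copies]
        g1_diploids.append(dip)

    p_dis = tri.p_disome_gamete if tri is not None else 0.5

    def gamete_of(dip: Genome) -> Genome:
        return meiosis(dip, layout, c, rng, p_disome=p_dis, missegregation_rate=miss)

    # G1 pools: gametes of the level-1 diploids
    g1_pools = [
        [gamete_of(dip) for _ in range(design.pool_size)] for dip in g1_diploids
    ]

    # G2 pools: random G1 x G1 matings, one gamete each
    g2_pools: list[list[Genome]] = []
    g2_parents: list[np.ndarray] = []
    for pool_a, pool_b, name_a, name_b in (
        (g1_pools[0], g1_pools[1], "G1_12", "G1_34"),
        (g1_pools[2], g1_pools[3], "G1_56", "G1_78"),
    ):
        ra = design.bottleneck_for(name_a)
        rb = design.bottleneck_for(name_b)
        members, parents = [], []
        for _ in range(design.pool_size):
            ia = _draw(len(pool_a), ra, rng)
            ib = _draw(len(pool_b), rb, rng)
            members.append(gamete_of(mate(pool_a[ia], pool_b[ib])))
            parents.append((ia, ib))
        g2_pools.append(members)
        g2_parents.append(np.asarray(parents, dtype=np.int32))

    # level 3: final strains
    r14 = design.bottleneck_for("G2_14")
    r58 = design.bottleneck_for("G2_58")
    genomes: list[Genome] = []
    lineage = np.zeros((design.final_size, 6), dtype=np.int32)
    for s in range(design.final_size):
        i14 = _draw(len(g2_pools[0]), r14, rng)
        i58 = _draw(len(g2_pools[1]), r58, rng)
        genomes.append(gamete_of(mate(g2_pools[0][i14], g2_pools[1][i58])))
        lineage[s] = (
            g2_parents[0][i14, 0],
            g2_parents[0][i14, 1],
            g2_parents[1][i58, 0],
            g2_parents[1][i58, 1],
            i14,
            i58,
        )

    cn = np.ones((design.final_size, layout.n_chromosomes), dtype=np.int8)
    for s, g in enumerate(genomes):
        for j, name in enumerate(layout.names):
            cn[s, j] = min(len(g[name]), 2)

    strains = [f"S{s:05d}" for s in range(design.final_size)]
    return FunnelPopulation(layout, design, strains, genomes, lineage, cn)


# ---------------------------------------------------------------------------
# viability filtering and read counts


def apply_viability_filter(
    population: FunnelPopulation, lethal: LethalPair
) -> tuple[FunnelPopulation, int]:
    """Remove strains violating a two-locus survival rule.

    Haplotypes at the two loci are read from the first chromosome copy.
    Returns the surviving population and the number of strains removed.
    """
    h1 = np.array(
        [
            int(_codes_at(g[lethal.chromosome_1][0], np.array([lethal.position_1]))[0])
            for g in population.genomes
        ]
    )
    h2 = np.array(
        [
            int(_codes_at(g[lethal.chromosome_2][0], np.array([lethal.position_2]))[0])
            for g in population.genomes
        ]
    )
    keep = np.array([lethal.survives(a, b) for a, b in zip(h1, h2)])
    if not keep.any():
        raise ValueError("viability rule removed the entire population")
    return population.subset(keep), int((~keep).sum())


def simulate_read_counts(
    haplotypes: HaplotypeMatrix,
    markers: MarkerTable,
    options: SimOptions = SimOptions(),
    seed=0,
    ploidy: PloidyTable | None = None,
) -> AlleleCountMatrix:
    """Low-coverage allele counts given true haplotypes.

    Depth per strain x marker is Poisson(mean_depth); each read reports the
    allele implied by the strain's haplotype with probability 1 - error.
    For disomic cells each read first picks one homolog uniformly. Cells
    with missing haplotype get zero depth.
    """
    rng = _rng(seed)
    e = options.error_rate
    fa = markers.founder_alleles  # (M, 8)
    cols = np.arange(markers.n_markers)

    def p_alt_of(codes: np.ndarray) -> np.ndarray:
        # P(read reports alt) per cell for one homolog; 0-coded cells unused
        safe = (np.maximum(codes, 1) - 1).astype(np.int64)
        a = fa[cols[None, :], safe]
        return np.where(a == 1, 1 - e, e)

    p_alt = p_alt_of(haplotypes.first)
    dis = haplotypes.second > 0
    if dis.any():
        p2 = p_alt_of(haplotypes.second)
        p_alt = np.where(dis, 0.5 * (p_alt + p2), p_alt)

    depth = rng.poisson(options.mean_depth, size=p_alt.shape)
    depth[haplotypes.first == 0] = 0
    alt = rng.binomial(depth, p_alt)
    return AlleleCountMatrix(
        list(haplotypes.strains), (depth - alt).astype(np.int32), alt.astype(np.int32)
    )
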