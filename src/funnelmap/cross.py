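"""The 8-parent funnel-cross design.

Eight founders (coded 1..8) are combined through three levels of mating:
level 1 crosses the fixed pairs (1,2), (3,4), (5,6), (7,8); level 2 crosses
random members of the (1,2)x(3,4) and (5,6)x(7,8) gamete pools; level 3
crosses the two resulting four-founder pools. Every final segregant is a
recombinant mosaic of all eight founder haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

N_FOUNDERS = 8
G1_PAIRS: tuple[tuple[int, int], ...] = ((1, 2), (3, 4), (5, 6), (7, 8))
G2_QUARTETS: tuple[tuple[int, ...], ...] = ((1, 2, 3, 4), (5, 6, 7, 8))

# Founder set identifying each intermediate haploid population.
G1_SETS: tuple[frozenset[int], ...] = tuple(frozenset(p) for p in G1_PAIRS)
G2_SETS: tuple[frozenset[int], ...] = tuple(frozenset(q) for q in G2_QUARTETS)


def level1_partner(h: int) -> int:
    """The founder mated with ``h`` at level 1 (1<->2, 3<->4, ...)."""
    return h + 1 if h % 2 == 1 else h - 1


def level2_quartet(h: int) -> tuple[int, ...]:
    """The four-founder group containing ``h`` after level 2."""
    return G2_QUARTETS[0] if h <= 4 else G2_QUARTETS[1]


@dataclass(frozen=True)
class TrisomyEvent:
    """An extra chromosome copy carried by one level-1 diploid.

    Models the observed trisomy of chromosome IX in the (5,6) level-1
    diploid: a duplication of the haplotype-6 copy accompanied by loss-of-
    heterozygosity (LOH) intervals in which all three copies carry a single
    haplotype.

    ``loh_intervals`` maps (start, end) 1-based inclusive intervals to the
    haplotype that all copies carry there.
    """

    chromosome: str = "chrIX"
    g1_pair: tuple[int, int] = (5, 6)
    extra_copy_of: int = 6
    loh_intervals: tuple[tuple[int, int, int], ...] = ()
    # Probability that a meiosis of a trisomic diploid emits a 2-copy gamete
    # (unbiased 2:1 trivalent segregation -> 0.5).
    p_disome_gamete: float = 0.5

    def __post_init__(self) -> None:
        if self.extra_copy_of not in self.g1_pair:
            raise ValueError("extra copy must duplicate one of the pair's haplotypes")
        if not 0.0 <= self.p_disome_gamete <= 1.0:
            raise ValueError("p_disome_gamete must be in [0, 1]")
        for start, end, hap in self.loh_intervals:
            if start > end or start < 1:
                raise ValueError(f"bad LOH interval ({start}, {end})")
            if hap not in self.g1_pair:
                raise ValueError("LOH haplotype must belong to the carrier pair")


@dataclass(frozen=True)
class LethalPair:
    """Two-locus viability rule (synthetic lethality / synthetic viability).

    ``rule`` names the survival predicate over the haplotype pair at the two
    loci. ``match_on_focal`` survives iff (h1 == focal) == (h2 == focal) —
    the pattern where the focal haplotype is only viable at either locus
    when present at both.
    """

    chromosome_1: str
    position_1: int
    chromosome_2: str
    position_2: int
    rule: str = "match_on_focal"
    focal_haplotype: int = 8

    def survives(self, h1: int, h2: int) -> bool:
        if self.rule == "match_on_focal":
            f = self.focal_haplotype
            return (h1 == f) == (h2 == f)
        if self.rule == "always":
            return True
        raise ValueError(f"unknown viability rule {self.rule!r}")


@dataclass(frozen=True)
class Bottleneck:
    """Restrict one intermediate pool to a few effective ancestors.

    ``population`` is 'G1_12', 'G1_34', 'G1_56', 'G1_78', 'G2_14' or 'G2_58';
    ``n_ancestors`` is the number of distinct pool members that all later
    draws are restricted to.
    """

    population: str
    n_ancestors: int

    def __post_init__(self) -> None:
        if self.n_ancestors < 1:
            raise ValueError("n_ancestors must be >= 1")


@dataclass(frozen=True)
class CrossDesign:
    """Topology and size parameters of the 3-level funnel cross.

    Defaults follow the published design: intermediate pools of 576 strains
    per mating type and a crossover rate of 3 per Mb per meiosis.
    """

    pool_size: int = 576
    final_size: int = 2000
    crossover_rate: float = 3.0  # crossovers per Mb per meiosis
    trisomy: TrisomyEvent | None = None
    lethal_pairs: tuple[LethalPair, ...] = ()
    bottlenecks: tuple[Bottleneck, ...] = ()
    founders: tuple[int, ...] = field(default=tuple(range(1, 9)))

    def __post_init__(self) -> None:
        if self.founders != tuple(range(1, 9)):
            raise ValueError("funnel design requires founders labelled 1..8")
        if self.pool_size < 1 or self.final_size < 1:
            raise ValueError("pool sizes must be >= 1")
        if self.crossover_rate < 0:
            raise ValueError("crossover rate must be >= 0")

    def bottleneck_for(self, population: str) -> int | None:
        for b in self.bottlenecks:
            if b.population == population:
                return b.n_ancestors
        return None
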