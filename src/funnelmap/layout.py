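"""Genome coordinate frame: ordered chromosomes with physical lengths.

All positions in this package are 1-based, inclusive, in bp, on the
S288C (R64-1-1) reference frame by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# R64-1-1 nuclear chromosome lengths (bp).
S288C_CHROMOSOMES: dict[str, int] = {
    "chrI": 230_218,
    "chrII": 813_184,
    "chrIII": 316_620,
    "chrIV": 1_531_933,
    "chrV": 576_874,
    "chrVI": 270_161,
    "chrVII": 1_090_940,
    "chrVIII": 562_643,
    "chrIX": 439_888,
    "chrX": 745_751,
    "chrXI": 666_816,
    "chrXII": 1_078_177,
    "chrXIII": 924_431,
    "chrXIV": 784_333,
    "chrXV": 1_091_291,
    "chrXVI": 948_066,
}


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths.

    Parameters
    ----------
    names
        Chromosome names, in genome order. Must be unique.
    lengths
        Chromosome lengths in bp, parallel to ``names``. Must be positive.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @classmethod
    def from_dict(cls, chroms: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(chroms), tuple(chroms.values()))

    @classmethod
    def s288c(cls) -> "GenomeLayout":
        """The default 16-chromosome S288C (R64-1-1) layout."""
        return cls.from_dict(S288C_CHROMOSOMES)

    @property
    def n_chromosomes(self) -> int:
        return len(self.names)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def length_of(self, name: str) -> int:
        return self.lengths[self.index_of(name)]

    def lengths_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=np.int64)
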