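"""Core tabular types and their TSV serialization.

All tables are plain tab-separated text with headers. Haplotype codes are
1..8; 0 is the missing sentinel in files and in memory; a disomic cell is
written ``i/j`` (unordered pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import GenomeLayout

MISSING = 0

FOUNDER_COLS = [f"founder{i}" for i in range(1, 9)]


class TableFormatError(ValueError):
    """Raised when an on-disk table violates its type's invariants."""


@dataclass
class MarkerTable:
    """Biallelic SNV panel with the eight founders' alleles.

    Attributes
    ----------
    chrom : np.ndarray of str, shape (n_markers,)
    pos : np.ndarray of int64, shape (n_markers,)
        1-based positions, strictly increasing within each chromosome.
    ref, alt : np.ndarray of str
        The two allele labels at each marker.
    founder_alleles : np.ndarray of uint8, shape (n_markers, 8)
        0 = reference allele, 1 = alternative; every row contains both
        values (each marker segregates among the founders).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    founder_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.founder_alleles = np.asarray(self.founder_alleles, dtype=np.uint8)
        n = len(self.pos)
        if not (
            len(self.chrom) == len(self.ref) == len(self.alt) == n
            and self.founder_alleles.shape == (n, 8)
        ):
            raise TableFormatError("marker table field shapes are inconsistent")
        self.validate()

    def validate(self) -> None:
        sums = self.founder_alleles.sum(axis=1)
        bad = np.flatnonzero((sums == 0) | (sums == 8))
        if bad.size:
            raise TableFormatError(
                f"marker row {bad[0]} is not biallelic among the founders"
            )
        for name in np.unique(self.chrom):
            p = self.pos[self.chrom == name]
            if np.any(np.diff(p) <= 0):
                row = int(np.flatnonzero(np.diff(p) <= 0)[0]) + 1
                raise TableFormatError(
                    f"positions not strictly increasing on {name} (offset {row})"
                )

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous row range per chromosome (rows are grouped by chrom)."""
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, self.n_markers + 1):
            if i == self.n_markers or self.chrom[i] != self.chrom[start]:
                out[str(self.chrom[start])] = slice(start, i)
                start = i
        return out

    def subset(self, idx: np.ndarray) -> "MarkerTable":
        return MarkerTable(
            self.chrom[idx],
            self.pos[idx],
            self.ref[idx],
            self.alt[idx],
            self.founder_alleles[idx],
        )

    def minor_allele_counts(self) -> np.ndarray:
        """Number of founders carrying the minor allele at each marker."""
        s = self.founder_alleles.sum(axis=1).astype(np.int64)
        return np.minimum(s, 8 - s)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"chromosome": self.chrom, "position": self.pos, "ref": self.ref, "alt": self.alt}
        )
        for k, col in enumerate(FOUNDER_COLS):
            df[col] = self.founder_alleles[:, k]
        return df


def read_marker_table(path) -> MarkerTable:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "ref": str, "alt": str})
    required = ["chromosome", "position", "ref", "alt", *FOUNDER_COLS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    alleles = df[FOUNDER_COLS].to_numpy()
    if not np.isin(alleles, (0, 1)).all():
        row = int(np.argwhere(~np.isin(alleles, (0, 1)))[0, 0])
        raise TableFormatError(f"{path}: non-binary founder call at row {row}")
    try:
        return MarkerTable(
            df["chromosome"].to_numpy(),
            df["position"].to_numpy(),
            df["ref"].to_numpy(),
            df["alt"].to_numpy(),
            alleles.astype(np.uint8),
        )
    except TableFormatError as e:
        raise TableFormatError(f"{path}: {e}") from None


def write_marker_table(table: MarkerTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class AlleleCountMatrix:
    """Read counts per strain x marker for the two alleles of each SNV.

    ``ref_counts[s, m]`` / ``alt_counts[s, m]`` count reads supporting the
    founder-table reference / alternative allele.
    """

    strains: list[str]
    ref_counts: np.ndarray  # (n_strains, n_markers) int32
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int32)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int32)
        if self.ref_counts.shape != self.alt_counts.shape:
            raise TableFormatError("ref and alt count matrices differ in shape")
        if self.ref_counts.shape[0] != len(self.strains):
            raise TableFormatError("strain labels do not match matrix rows")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise TableFormatError("negative read count")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return self.ref_counts.shape[1]

    def total_reads(self) -> np.ndarray:
        """Total read count per strain."""
        return (
            self.ref_counts.sum(axis=1, dtype=np.int64)
            + self.alt_counts.sum(axis=1, dtype=np.int64)
        )


def _write_count_matrix(m: np.ndarray, strains: list[str], path) -> None:
    df = pd.DataFrame(m, index=pd.Index(strains, name="strain"))
    df.columns = [f"m{j}" for j in range(m.shape[1])]
    df.to_csv(path, sep="\t")


def write_allele_counts(counts: AlleleCountMatrix, ref_path, alt_path) -> None:
    """Two TSVs: one matrix per allele (major/minor file pair schema)."""
    _write_count_matrix(counts.ref_counts, counts.strains, ref_path)
    _write_count_matrix(counts.alt_counts, counts.strains, alt_path)


def read_allele_counts(ref_path, alt_path) -> AlleleCountMatrix:
    ref = pd.read_csv(ref_path, sep="\t", index_col=0)
    alt = pd.read_csv(alt_path, sep="\t", index_col=0)
    if list(ref.index) != list(alt.index):
        raise TableFormatError("count matrices have different strain labels")
    return AlleleCountMatrix(
        [str(s) for s in ref.index], ref.to_numpy(), alt.to_numpy()
    )


@dataclass
class HaplotypeMatrix:
    """Founder-of-origin codes per strain x marker.

    ``first`` holds the haplotype code (1..8, or 0 = missing). For cells on
    a disomic chromosome ``second`` holds the other homolog's code; it is 0
    wherever the cell is monosomic or missing. Pairs are unordered and
    normalized so first <= second where both are present.
    """

    strains: list[str]
    first: np.ndarray  # (n_strains, n_markers) int8
    second: np.ndarray

    def __post_init__(self) -> None:
        self.first = np.asarray(self.first, dtype=np.int8)
        self.second = np.asarray(self.second, dtype=np.int8)
        if self.first.shape != self.second.shape:
            raise TableFormatError("haplotype matrices differ in shape")
        if self.first.shape[0] != len(self.strains):
            raise TableFormatError("strain labels do not match matrix rows")
        for arr in (self.first, self.second):
            if arr.size and (arr.min() < 0 or arr.max() > 8):
                raise TableFormatError("haplotype code outside 0..8")
        # normalize unordered pairs
        both = self.second > 0
        lo = np.minimum(self.first, self.second)
        hi = np.maximum(self.first, self.second)
        self.first = np.where(both, lo, self.first)
        self.second = np.where(both, hi, self.second)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return self.first.shape[1]

    def is_disome(self) -> np.ndarray:
        return self.second > 0

    def monosomic_codes(self) -> np.ndarray:
        """Codes with disomic cells masked to missing."""
        return np.where(self.second > 0, MISSING, self.first)


def write_haplotype_matrix(matrix: HaplotypeMatrix, path) -> None:
    cells = matrix.first.astype("U1").astype(object)
    dis = matrix.second > 0
    if dis.any():
        paired = np.char.add(
            np.char.add(matrix.first.astype("U1"), "/"), matrix.second.astype("U1")
        )
        cells[dis] = paired[dis]
    df = pd.DataFrame(cells, index=pd.Index(matrix.strains, name="strain"))
    df.columns = [f"m{j}" for j in range(matrix.n_markers)]
    df.to_csv(path, sep="\t")


def read_haplotype_matrix(path) -> HaplotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw = df.to_numpy()
    first = np.zeros(raw.shape, dtype=np.int8)
    second = np.zeros(raw.shape, dtype=np.int8)
    for (i, j), cell in np.ndenumerate(raw):
        if "/" in cell:
            a, b = cell.split("/", 1)
            first[i, j], second[i, j] = int(a), int(b)
        else:
            first[i, j] = int(cell)
        for v in (first[i, j], second[i, j]):
            if not 0 <= v <= 8:
                raise TableFormatError(
                    f"{path}: haplotype code {v} outside 0..8 at "
                    f"strain {df.index[i]!r}, column {df.columns[j]!r}"
                )
    return HaplotypeMatrix([str(s) for s in df.index], first, second)


@dataclass
class PloidyTable:
    """Per strain x chromosome copy number (1 or 2) with normalized depth."""

    strains: list[str]
    chromosomes: list[str]
    copy_number: np.ndarray  # (n_strains, n_chrom) int8
    normalized_depth: np.ndarray  # float

    def __post_init__(self) -> None:
        self.copy_number = np.asarray(self.copy_number, dtype=np.int8)
        self.normalized_depth = np.asarray(self.normalized_depth, dtype=float)
        if self.copy_number.shape != (len(self.strains), len(self.chromosomes)):
            raise TableFormatError("ploidy table shape mismatch")
        valid = np.isin(self.copy_number, (1, 2)) | ~np.isfinite(self.normalized_depth)
        if not valid.all():
            raise TableFormatError("copy numbers must be 1 or 2")

    def copy_number_of(self, strain_idx: int, chrom: str) -> int:
        return int(self.copy_number[strain_idx, self.chromosomes.index(chrom)])


def write_ploidy_table(table: PloidyTable, path) -> None:
    rows = []
    for i, s in enumerate(table.strains):
        for j, c in enumerate(table.chromosomes):
            rows.append(
                (s, c, int(table.copy_number[i, j]), float(table.normalized_depth[i, j]))
            )
    pd.DataFrame(
        rows, columns=["strain", "chromosome", "copy_number", "normalized_depth"]
    ).to_csv(path, sep="\t", index=False)


def read_ploidy_table(path) -> PloidyTable:
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "chromosome": str})
    strains = list(dict.fromkeys(df["strain"]))
    chroms = list(dict.fromkeys(df["chromosome"]))
    cn = np.ones((len(strains), len(chroms)), dtype=np.int8)
    nd = np.full((len(strains), len(chroms)), np.nan)
    si = {s: i for i, s in enumerate(strains)}
    ci = {c: j for j, c in enumerate(chroms)}
    for r in df.itertuples(index=False):
        cn[si[r.strain], ci[r.chromosome]] = r.copy_number
        nd[si[r.strain], ci[r.chromosome]] = r.normalized_depth
    return PloidyTable(strains, chroms, cn, nd)


def euploid_layout_ploidy(
    strains: list[str], layout: GenomeLayout
) -> PloidyTable:
    """All-monosomic ploidy table (convenience for euploid populations)."""
    shape = (len(strains), layout.n_chromosomes)
    return PloidyTable(
        strains, list(layout.names), np.ones(shape, np.int8), np.ones(shape)
    )
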