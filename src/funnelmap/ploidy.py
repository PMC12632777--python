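"""Chromosome copy-number calls from relative depth, and the ~2 kb
scaffolding marker subset."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .tables import AlleleCountMatrix, MarkerTable, PloidyTable

DEFAULT_SPACING = 2000
DEFAULT_DISOME_THRESHOLD = 1.5


def normalized_depths(
    counts: AlleleCountMatrix, markers: MarkerTable, layout: GenomeLayout
) -> pd.DataFrame:
    """Per strain x chromosome depth, normalized per strain.

    Depth per chromosome is the mean total read count per marker site;
    normalization divides by the strain's median chromosome depth, so a
    monosomic chromosome sits near 1 and a disomic one near 2. Strains
    with zero reads get NaN rows (flagged, not dropped).
    """
    total = counts.ref_counts.astype(np.int64) + counts.alt_counts
    slices = markers.chromosome_slices()
    cols = [c for c in layout.names if c in slices]
    depth = np.empty((counts.n_strains, len(cols)))
    for j, chrom in enumerate(cols):
        sl = slices[chrom]
        depth[:, j] = total[:, sl].mean(axis=1)
    med = np.median(depth, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = depth / med[:, None]
    norm[med == 0] = np.nan
    return pd.DataFrame(norm, index=pd.Index(counts.strains, name="strain"), columns=cols)


def call_ploidy(
    depths: pd.DataFrame, threshold: float = DEFAULT_DISOME_THRESHOLD
) -> PloidyTable:
    """Copy number 2 where normalized depth >= threshold, else 1.

    Strains with undefined depth (no reads) keep NaN depth and are
    flagged by the caller via the depth column.
    """
    if not 1.0 < threshold < 2.0:
        raise ValueError("disome threshold must lie in (1, 2)")
    vals = depths.to_numpy()
    cn = np.where(np.isfinite(vals) & (vals >= threshold), 2, 1).astype(np.int8)
    return PloidyTable(
        [str(s) for s in depths.index], [str(c) for c in depths.columns], cn, vals
    )


@dataclass(frozen=True)
class ScaffoldSet:
    """Greedy-minimal ~evenly spaced marker subset.

    ``indices`` are row indices into the source marker table; the set
    starts at the first marker of each chromosome and repeatedly takes the
    first marker at least ``spacing`` bp downstream.
    """

    indices: np.ndarray
    spacing: int

    @property
    def n_markers(self) -> int:
        return len(self.indices)


def select_scaffold(markers: MarkerTable, spacing: int = DEFAULT_SPACING) -> ScaffoldSet:
    """Greedy per-chromosome selection: first marker, then the first one
    >= spacing bp away, repeated to the chromosome end. Deterministic."""
    chosen: list[int] = []
    for chrom, sl in markers.chromosome_slices().items():
        pos = markers.pos[sl]
        if len(pos) == 0:
            warnings.warn(f"chromosome {chrom} has no markers; skipped")
            continue
        chosen.append(sl.start)
        last = pos[0]
        while True:
            nxt = np.searchsorted(pos, last + spacing, side="left")
            if nxt >= len(pos):
                break
            chosen.append(sl.start + int(nxt))
            last = pos[nxt]
    return ScaffoldSet(np.asarray(chosen, dtype=np.int64), spacing)


def scaffold_coverage(
    scaffold: ScaffoldSet, markers: MarkerTable, radius: int = DEFAULT_SPACING
) -> float:
    """Fraction of the genome within ``radius`` bp of a scaffold marker.

    The denominator is the per-chromosome span from the first to the last
    marker (telomeric regions beyond the outermost markers are excluded);
    single-marker chromosomes have zero span and drop out.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    sel = np.zeros(markers.n_markers, dtype=bool)
    sel[scaffold.indices] = True
    covered = 0.0
    span_total = 0.0
    for chrom, sl in markers.chromosome_slices().items():
        pos = markers.pos[sl]
        span = int(pos[-1]) - int(pos[0])
        if span == 0:
            continue
        span_total += span
        on_chrom = (scaffold.indices >= sl.start) & (scaffold.indices < sl.stop)
        sp = np.sort(markers.pos[scaffold.indices[on_chrom]])
        if len(sp) == 0:
            continue
        lo = np.clip(sp - radius, pos[0], pos[-1]).astype(float)
        hi = np.clip(sp + radius, pos[0], pos[-1]).astype(float)
        # union of [lo, hi] intervals (sp sorted)
        start, end = lo[0], hi[0]
        for a, b in zip(lo[1:], hi[1:]):
            if a <= end:
                end = max(end, b)
            else:
                covered += end - start
                start, end = a, b
        covered += end - start
    return covered / span_total if span_total else 1.0
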