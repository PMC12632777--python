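"""Shared fixtures: small genomes and simulated populations.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import funnelmap as fm


@pytest.fixture(scope="session")
def small_layout() -> fm.GenomeLayout:
    return fm.GenomeLayout.from_dict(
        {"chr1": 1_200_000, "chr2": 900_000, "chr3": 600_000}
    )


@pytest.fixture(scope="session")
def small_markers(small_layout) -> fm.MarkerTable:
    return fm.simulate_founder_markers(
        small_layout, fm.SimOptions(bp_per_marker=400), seed=101
    )


@pytest.fixture(scope="session")
def small_population(small_layout) -> fm.FunnelPopulation:
    """600 strains from modest pools; enough for frequency statistics."""
    design = fm.CrossDesign(pool_size=150, final_size=600)
    return fm.simulate_funnel(design, small_layout, fm.SimOptions(), seed=202)


@pytest.fixture(scope="session")
def small_truth_haplotypes(small_population, small_markers) -> fm.HaplotypeMatrix:
    return small_population.haplotypes_at(small_markers)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_markers() -> fm.MarkerTable:
    """Hand-written 6-marker table on two chromosomes."""
    alleles = np.array(
        [
            [1, 0, 0, 0, 0, 0, 0, 0],
            [0, 1, 1, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 1, 0, 0, 0],
            [1, 1, 1, 1, 0, 0, 0, 0],
            [0, 0, 0, 1, 0, 1, 0, 1],
            [0, 0, 0, 0, 0, 0, 1, 0],
        ],
        dtype=np.uint8,
    )
    return fm.MarkerTable(
        np.array(["chrA"] * 4 + ["chrB"] * 2, dtype=object),
        np.array([100, 5_000, 52_000, 110_000, 40, 70_000]),
        np.array(list("ACGTAC"), dtype=object),
        np.array(list("TGCAGA"), dtype=object),
        alleles,
    )
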