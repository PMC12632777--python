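"""Simulator properties: marker panel statistics, meiosis, funnel
frequencies, viability filtering, and read-count sampling."""

import numpy as np
import pytest

import funnelmap as fm
from funnelmap.simulate import (
    _codes_at,
    default_trisomy_ix,
    founder_genome,
    mate,
    meiosis,
    recombine_copies,
)


class TestFounderMarkers:
    def test_marker_count_tracks_density(self, small_layout):
        mk = fm.simulate_founder_markers(
            small_layout, fm.SimOptions(bp_per_marker=44), seed=1
        )
        expected = small_layout.total_length / 44
        # Poisson noise: 5 sigma band
        assert abs(mk.n_markers - expected) < 5 * np.sqrt(expected)

    def test_private_spectrum_all_one_founder(self, small_layout):
        opts = fm.SimOptions(bp_per_marker=500, sharing_spectrum=(1.0, 0, 0, 0))
        mk = fm.simulate_founder_markers(small_layout, opts, seed=2)
        assert (mk.minor_allele_counts() == 1).all()

    def test_default_spectrum_fractions(self):
        layout = fm.GenomeLayout.from_dict({"chr1": 5_000_000})
        mk = fm.simulate_founder_markers(
            layout, fm.SimOptions(bp_per_marker=50), seed=3
        )
        counts = mk.minor_allele_counts()
        frac1 = (counts == 1).mean()
        # spectrum classes are carrier counts of the minor allele; a 4:4
        # marker can be tallied on either side so compare the 1..3 classes
        assert frac1 == pytest.approx(0.774, abs=0.01)
        assert (counts == 2).mean() == pytest.approx(0.130, abs=0.01)
        assert (counts == 3).mean() == pytest.approx(0.0673, abs=0.01)

    def test_at_least_one_marker_per_chromosome(self):
        layout = fm.GenomeLayout.from_dict({"tiny": 10, "big": 100_000})
        mk = fm.simulate_founder_markers(
            layout, fm.SimOptions(bp_per_marker=1e6), seed=4
        )
        assert set(np.unique(mk.chrom)) == {"tiny", "big"}


class TestMeiosis:
    def test_no_crossover_returns_intact_parent(self, small_layout, rng):
        a = founder_genome(1, small_layout)
        b = founder_genome(2, small_layout)
        g = meiosis(mate(a, b), small_layout, c=0.0, rng=rng)
        for name in small_layout.names:
            (bounds, codes), = g[name]
            assert len(codes) == 1 and codes[0] in (1, 2)

    def test_mean_crossover_count(self, rng):
        length = 1_000_000
        a = (np.array([1]), np.array([1], dtype=np.int8))
        b = (np.array([1]), np.array([2], dtype=np.int8))
        n_break = [
            len(recombine_copies(a, b, length, 3.0, rng)[1]) - 1
            for _ in range(4000)
        ]
        # breakpoints = crossovers (two-haplotype cross, all are visible)
        assert np.mean(n_break) == pytest.approx(3.0, abs=0.1)

    def test_recombinant_fraction_matches_haldane(self, rng):
        """Monte-Carlo recombinant fraction at 1 Mb, c=3, vs closed form."""
        length = 1_200_000
        a = (np.array([1]), np.array([1], dtype=np.int8))
        b = (np.array([1]), np.array([2], dtype=np.int8))
        pos = np.array([100_000, 1_100_000])
        n = 8000
        hits = 0
        for _ in range(n):
            g = recombine_copies(a, b, length, 3.0, rng)
            h = _codes_at(g, pos)
            hits += h[0] != h[1]
        expect = 0.5 * (1 - np.exp(-6.0))  # 1 Mb at 3/Mb = 3 Morgans
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(hits / n - expect) < 3 * se


class TestFunnel:
    def test_haplotype_frequencies_balanced(self, small_truth_haplotypes):
        codes = small_truth_haplotypes.first
        freqs = np.bincount(codes.ravel(), minlength=9)[1:] / codes.size
        assert freqs.sum() == pytest.approx(1.0)
        # each haplotype near 1/8; tolerance reflects pool-size variance
        np.testing.assert_allclose(freqs, 1 / 8, atol=0.03)

    def test_conservation_haplotypes_are_founder_codes(self, small_truth_haplotypes):
        assert set(np.unique(small_truth_haplotypes.first)) <= set(range(1, 9))

    def test_pool_size_one_forces_shared_g1_ancestors(self, small_layout):
        design = fm.CrossDesign(
            pool_size=30,
            final_size=40,
            bottlenecks=tuple(
                fm.Bottleneck(p, 1) for p in ("G1_12", "G1_34", "G1_56", "G1_78")
            ),
        )
        pop = fm.simulate_funnel(design, small_layout, fm.SimOptions(), seed=7)
        assert (pop.lineage[:, :4] == 0).all()

    def test_seeded_determinism(self, small_layout):
        d = fm.CrossDesign(pool_size=20, final_size=30)
        p1 = fm.simulate_funnel(d, small_layout, fm.SimOptions(), seed=9)
        p2 = fm.simulate_funnel(d, small_layout, fm.SimOptions(), seed=9)
        np.testing.assert_array_equal(p1.lineage, p2.lineage)
        for g1, g2 in zip(p1.genomes, p2.genomes):
            for name in small_layout.names:
                np.testing.assert_array_equal(g1[name][0][1], g2[name][0][1])

    def test_lineage_recorded_consistently(self, small_population):
        lin = small_population.lineage
        assert lin.shape[1] == 6
        assert (lin >= 0).all()
        assert (lin[:, :4] < 150).all()  # G1 pool indices


@pytest.fixture(scope="module")
def tri_pop():
    layout = fm.GenomeLayout.from_dict({"chrV": 500_000, "chrIX": 439_888})
    design = fm.CrossDesign(
        pool_size=300, final_size=4000, trisomy=default_trisomy_ix()
    )
    return layout, fm.simulate_funnel(design, layout, fm.SimOptions(), seed=11)


class TestTrisomyIX:
    def test_euploid_chr9_frequencies_near_ninths(self, tri_pop):
        layout, pop = tri_pop
        eup = pop.euploid()
        pos = np.arange(150_000, 439_000, 4000)  # outside LOH intervals
        codes = np.array([_codes_at(g["chrIX"][0], pos) for g in eup.genomes])
        freqs = np.bincount(codes.ravel(), minlength=9)[1:] / codes.size
        np.testing.assert_allclose(freqs[[0, 1, 2, 3, 6, 7]], 1 / 9, atol=0.035)
        assert freqs[5] == pytest.approx(2 / 9, abs=0.05)

    def test_loh_region_loses_a_haplotype(self, tri_pop):
        layout, pop = tri_pop
        eup = pop.euploid()
        pos = np.arange(5000, 40_000, 2000)  # all-haplotype-6 LOH interval
        codes = np.array([_codes_at(g["chrIX"][0], pos) for g in eup.genomes])
        assert not (codes == 5).any()

    def test_disomic_strains_emitted(self, tri_pop):
        layout, pop = tri_pop
        ix = layout.index_of("chrIX")
        rate = (pop.copy_number[:, ix] == 2).mean()
        assert 0.02 < rate < 0.35
        # other chromosome stays euploid (missegregation off)
        assert (pop.copy_number[:, layout.index_of("chrV")] == 1).all()


class TestViabilityFilter:
    def _pop(self, small_layout):
        design = fm.CrossDesign(pool_size=100, final_size=400)
        return fm.simulate_funnel(design, small_layout, fm.SimOptions(), seed=13)

    def test_match_rule_empties_off_diagonal(self, small_layout):
        pop = self._pop(small_layout)
        lethal = fm.LethalPair("chr1", 500_000, "chr2", 400_000, "match_on_focal", 8)
        surv, removed = fm.apply_viability_filter(pop, lethal)
        assert removed > 0 and surv.n_strains + removed == pop.n_strains
        h1 = np.array(
            [_codes_at(g["chr1"][0], np.array([500_000]))[0] for g in surv.genomes]
        )
        h2 = np.array(
            [_codes_at(g["chr2"][0], np.array([400_000]))[0] for g in surv.genomes]
        )
        assert not np.any((h1 == 8) ^ (h2 == 8))

    def test_always_true_rule_keeps_everyone(self, small_layout):
        pop = self._pop(small_layout)
        lethal = fm.LethalPair("chr1", 1, "chr2", 1, "always")
        surv, removed = fm.apply_viability_filter(pop, lethal)
        assert removed == 0 and surv.n_strains == pop.n_strains

    def test_rule_removing_all_raises(self, small_layout, monkeypatch):
        pop = self._pop(small_layout)
        lethal = fm.LethalPair("chr1", 1, "chr2", 1, "match_on_focal", 8)
        monkeypatch.setattr(type(lethal), "survives", lambda self, a, b: False)
        with pytest.raises(ValueError, match="empty|entire"):
            fm.apply_viability_filter(pop, lethal)


class TestReadCounts:
    def test_zero_error_reads_match_truth(self, small_truth_haplotypes, small_markers):
        opts = fm.SimOptions(mean_depth=5.0, error_rate=1e-12)
        counts = fm.simulate_read_counts(
            small_truth_haplotypes, small_markers, opts, seed=17
        )
        fa = small_markers.founder_alleles
        cols = np.arange(small_markers.n_markers)
        true_alt = fa[cols[None, :], small_truth_haplotypes.first - 1] == 1
        assert not counts.alt_counts[~true_alt].any()
        assert not counts.ref_counts[true_alt].any()

    def test_mean_depth(self, small_truth_haplotypes, small_markers):
        counts = fm.simulate_read_counts(
            small_truth_haplotypes, small_markers, fm.SimOptions(), seed=18
        )
        total = counts.ref_counts + counts.alt_counts
        assert total.mean() == pytest.approx(3.8, abs=0.02)

    def test_error_fraction_at_deep_coverage(self, small_markers, small_population):
        haps = small_population.subset(np.arange(50)).haplotypes_at(small_markers)
        opts = fm.SimOptions(mean_depth=30, error_rate=0.01)
        counts = fm.simulate_read_counts(haps, small_markers, opts, seed=19)
        fa = small_markers.founder_alleles
        cols = np.arange(small_markers.n_markers)
        true_alt = fa[cols[None, :], haps.first - 1] == 1
        mism = np.where(true_alt, counts.ref_counts, counts.alt_counts).sum()
        total = (counts.ref_counts + counts.alt_counts).sum()
        assert mism / total == pytest.approx(0.01, rel=0.05)
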