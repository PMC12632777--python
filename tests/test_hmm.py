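"""HMM tests: mapping function, funnel transition law, emissions, and
Viterbi optimality against exhaustive path enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import funnelmap as fm
from funnelmap.hmm import (
    PAIR_STATES,
    LinkageParams,
    disome_emission_loglik,
    disome_transition_matrix,
    emission_loglik,
)


class TestHaldane:
    def test_zero_and_asymptote(self):
        assert fm.haldane_r(0.0) == 0.0
        assert fm.haldane_r(50.0) == pytest.approx(0.5, abs=1e-12)

    def test_one_megabase_at_c3(self):
        assert fm.haldane_r(3.0) == pytest.approx(0.5 * (1 - np.exp(-6)), abs=1e-12)
        assert fm.haldane_r(3.0) == pytest.approx(0.498761, abs=1e-6)

    @given(st.floats(0, 20), st.floats(0, 20))
    @settings(deadline=None)
    def test_monotone(self, m1, m2):
        lo, hi = sorted((m1, m2))
        assert fm.haldane_r(lo) <= fm.haldane_r(hi)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            fm.haldane_r(-0.1)


class TestFunnelTransitions:
    @pytest.mark.parametrize("r", np.linspace(0, 0.5, 11))
    def test_rows_sum_to_one(self, r):
        t = fm.funnel_transition_matrix(float(r))
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("r", [0.05, 0.2, 0.4])
    def test_printed_equations(self, r):
        t = fm.funnel_transition_matrix(r)
        assert t[0, 0] == pytest.approx((1 - r) ** 3)
        assert t[0, 1] == pytest.approx(r * (1 - r) ** 2)
        assert t[0, 2] == pytest.approx(0.5 * r * (1 - r))
        assert t[0, 4] == pytest.approx(0.25 * r)

    def test_limits(self):
        np.testing.assert_allclose(fm.funnel_transition_matrix(0.5), 1 / 8)
        np.testing.assert_allclose(fm.funnel_transition_matrix(0.0), np.eye(8))

    @pytest.mark.parametrize("r", [0.01, 0.1, 0.3, 0.5])
    def test_stationary_distribution_uniform(self, r):
        t = fm.funnel_transition_matrix(r)
        pi = np.full(8, 1 / 8)
        np.testing.assert_allclose(pi @ t, pi, atol=1e-12)

    def test_out_of_range_r_rejected(self):
        with pytest.raises(ValueError):
            fm.funnel_transition_matrix(0.6)

    @pytest.mark.parametrize("r", [0.0, 0.07, 0.33, 0.5])
    def test_disome_rows_sum_to_one(self, r):
        t2 = disome_transition_matrix(r)
        assert t2.shape == (36, 36)
        np.testing.assert_allclose(t2.sum(axis=1), 1.0, atol=1e-12)


class TestEmissions:
    def test_product_of_per_read_terms(self):
        p = LinkageParams()
        fa = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        ll = emission_loglik([0], [3], fa, p)[0]
        assert ll[0] == pytest.approx(3 * np.log(0.99))
        assert ll[1] == pytest.approx(3 * np.log(0.01))
        mixed = emission_loglik([1], [2], fa, p)[0]
        assert mixed[0] == pytest.approx(2 * np.log(0.99) + np.log(0.01))

    def test_zero_coverage_is_uninformative(self):
        ll = emission_loglik([0], [0], np.array([1, 0, 1, 0, 1, 0, 1, 0]), LinkageParams())
        np.testing.assert_array_equal(ll, 0.0)

    def test_disome_mixture(self):
        p = LinkageParams()
        fa = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        ll = disome_emission_loglik([0], [1], fa, p)[0]
        k12 = PAIR_STATES.index((1, 2))
        assert ll[k12] == pytest.approx(np.log(0.5 * 0.99 + 0.5 * 0.01))
        k11 = PAIR_STATES.index((1, 1))
        assert ll[k11] == pytest.approx(np.log(0.99))


def _random_instance(rng, n_states_mono=True, max_len=6):
    """Random markers + counts on one chromosome."""
    length = int(rng.integers(2, max_len + 1))
    pos = np.sort(rng.choice(np.arange(1, 500_000), size=length, replace=False))
    fa = rng.integers(0, 2, size=(length, 8)).astype(np.uint8)
    fa[:, 0] = 1  # guarantee biallelic
    fa[:, 1] = 0
    mk = fm.MarkerTable(
        np.full(length, "chrZ", dtype=object),
        pos,
        np.full(length, "A", dtype=object),
        np.full(length, "C", dtype=object),
        fa,
    )
    n_ref = rng.poisson(2.0, size=(1, length))
    n_alt = rng.poisson(2.0, size=(1, length))
    return mk, n_ref, n_alt


def _path_score(emis, logts, log_init, path):
    s = log_init[path[0]] + emis[0][path[0]]
    for t in range(1, len(path)):
        s += logts[t - 1][path[t - 1], path[t]] + emis[t][path[t]]
    return s


class TestViterbiOracle:
    def test_single_marker_private_allele(self):
        fa = np.zeros((1, 8), dtype=np.uint8)
        fa[0, 2] = 1  # allele private to founder 3
        mk = fm.MarkerTable(
            np.array(["chrZ"], dtype=object), np.array([100]),
            np.array(["A"], dtype=object), np.array(["C"], dtype=object), fa,
        )
        path = fm.viterbi_chromosome(np.array([[0]]), np.array([[5]]), mk, "chrZ")
        assert path[0, 0] == 3

    def test_matches_exhaustive_enumeration_monosome(self):
        """Viterbi attains the exact maximum over all 8^L paths."""
        rng = np.random.default_rng(1234)
        params = LinkageParams()
        for _ in range(150):
            mk, n_ref, n_alt = _random_instance(rng)
            L = mk.n_markers
            emis = [
                emission_loglik(n_ref[:, t], n_alt[:, t], mk.founder_alleles[t], params)[0]
                for t in range(L)
            ]
            rs = params.recombinant_fraction(np.diff(mk.pos))
            logts = [np.log(fm.funnel_transition_matrix(float(r))) for r in rs]
            log_init = np.full(8, -np.log(8))
            best = -np.inf
            best_path = None
            for path in itertools.product(range(8), repeat=L):
                s = _path_score(emis, logts, log_init, path)
                if s > best + 1e-12:
                    best, best_path = s, path
            got = fm.viterbi_chromosome(n_ref, n_alt, mk, "chrZ", params)[0] - 1
            assert _path_score(emis, logts, log_init, got) == pytest.approx(best)

    def test_matches_exhaustive_enumeration_disome(self):
        rng = np.random.default_rng(99)
        params = LinkageParams()
        init = np.log(np.where(np.array([a == b for a, b in PAIR_STATES]), 1.0, 2.0) / 64)
        for _ in range(40):
            mk, n_ref, n_alt = _random_instance(rng, max_len=3)
            L = mk.n_markers
            emis = [
                disome_emission_loglik(
                    n_ref[:, t], n_alt[:, t], mk.founder_alleles[t], params
                )[0]
                for t in range(L)
            ]
            rs = params.recombinant_fraction(np.diff(mk.pos))
            logts = [np.log(disome_transition_matrix(float(r))) for r in rs]
            best = max(
                _path_score(emis, logts, init, path)
                for path in itertools.product(range(36), repeat=L)
            )
            f, s2 = fm.viterbi_disome(n_ref, n_alt, mk, "chrZ", params)
            got = [PAIR_STATES.index((a, b)) for a, b in zip(f[0], s2[0])]
            assert _path_score(emis, logts, init, got) == pytest.approx(best)

    def test_disome_identical_pair_persists_with_tight_linkage(self):
        """A {i,i} state at near-zero R survives along the chromosome."""
        fa = np.zeros((4, 8), dtype=np.uint8)
        fa[:, 4] = 1  # founder 5 carries alt everywhere
        mk = fm.MarkerTable(
            np.full(4, "chrZ", dtype=object), np.array([100, 110, 120, 130]),
            np.full(4, "A", dtype=object), np.full(4, "C", dtype=object), fa,
        )
        n_alt = np.full((1, 4), 10)
        n_ref = np.zeros((1, 4), dtype=int)
        f, s2 = fm.viterbi_disome(n_ref, n_alt, mk, "chrZ")
        assert (f[0] == 5).all() and (s2[0] == 5).all()

    def test_disome_heterozygous_pair_identified(self):
        """Deep coverage at sites distinguishing founders 5 and 6 recovers {5,6}."""
        fa = np.zeros((6, 8), dtype=np.uint8)
        fa[::2, 4] = 1
        fa[1::2, 5] = 1
        mk = fm.MarkerTable(
            np.full(6, "chrZ", dtype=object), np.arange(100, 700, 100),
            np.full(6, "A", dtype=object), np.full(6, "C", dtype=object), fa,
        )
        # half the reads support each homolog's allele
        n_alt = np.full((1, 6), 15)
        n_ref = np.full((1, 6), 15)
        f, s2 = fm.viterbi_disome(n_ref, n_alt, mk, "chrZ")
        assert (f[0] == 5).all() and (s2[0] == 6).all()


class TestInference:
    def test_recovery_accuracy_default_depth(
        self, small_markers, small_population, small_truth_haplotypes
    ):
        sub = small_population.subset(np.arange(120))
        truth = sub.haplotypes_at(small_markers)
        counts = fm.simulate_read_counts(truth, small_markers, fm.SimOptions(), seed=5)
        inferred, excluded = fm.infer_haplotypes(counts, small_markers, read_cutoff=0)
        assert not excluded
        acc = (inferred.first == truth.first).mean()
        assert acc >= 0.99

    def test_accuracy_monotone_in_depth(self, small_markers, small_population):
        sub = small_population.subset(np.arange(60))
        truth = sub.haplotypes_at(small_markers)
        accs = []
        for depth in (3.8, 10.0):
            counts = fm.simulate_read_counts(
                truth, small_markers, fm.SimOptions(mean_depth=depth), seed=6
            )
            inferred, _ = fm.infer_haplotypes(counts, small_markers, read_cutoff=0)
            accs.append((inferred.first == truth.first).mean())
        assert accs[1] >= accs[0]

    def test_low_coverage_strains_excluded(self, tiny_markers):
        counts = fm.AlleleCountMatrix(
            ["deep", "shallow"],
            np.array([[3000, 3000, 3000, 3000, 0, 0], [1, 1, 1, 1, 1, 1]]),
            np.array([[0, 0, 0, 0, 3000, 3000], [0, 0, 0, 0, 0, 0]]),
        )
        haps, excluded = fm.infer_haplotypes(counts, tiny_markers, read_cutoff=12_000)
        assert excluded == ["shallow"]
        assert haps.strains == ["deep"]

    def test_all_zero_counts_warns_and_empties(self, tiny_markers):
        counts = fm.AlleleCountMatrix(
            ["a", "b"], np.zeros((2, 6), int), np.zeros((2, 6), int)
        )
        with pytest.warns(UserWarning):
            haps, excluded = fm.infer_haplotypes(counts, tiny_markers)
        assert haps.n_strains == 0 and set(excluded) == {"a", "b"}

    def test_disome_strain_decoded_with_pair_model(self, small_layout, small_markers):
        layout = small_layout
        design = fm.CrossDesign(pool_size=40, final_size=30)
        pop = fm.simulate_funnel(design, layout, fm.SimOptions(), seed=31)
        truth = pop.haplotypes_at(small_markers)
        # fake a disome on chr3 for strain 0 by pairing with strain 1's copy
        sl = small_markers.chromosome_slices()["chr3"]
        truth.second[0, sl] = truth.first[1, sl]
        truth = fm.HaplotypeMatrix(truth.strains, truth.first, truth.second)
        counts = fm.simulate_read_counts(
            truth, small_markers, fm.SimOptions(mean_depth=8.0), seed=32
        )
        from funnelmap.tables import euploid_layout_ploidy

        ploidy = euploid_layout_ploidy(truth.strains, layout)
        ploidy.copy_number[0, layout.index_of("chr3")] = 2
        inferred, _ = fm.infer_haplotypes(counts, small_markers, ploidy, read_cutoff=0)
        assert inferred.is_disome()[0, sl].all()
        pair_truth = np.sort(
            np.stack([truth.first[0, sl], truth.second[0, sl]]), axis=0
        )
        pair_got = np.stack([inferred.first[0, sl], inferred.second[0, sl]])
        acc = (pair_truth == pair_got).all(axis=0).mean()
        assert acc >= 0.95
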