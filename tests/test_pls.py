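"""Contrast/behavioural PLS, permutation, bootstrap and tail statistics."""

import numpy as np
import pytest
from statsmodels.stats.proportion import proportions_ztest

from conftest import ALPHA_PAIRS, reduced_config
from megsync.connectivity import ConnectivityTensor, pair_index, pair_list
from megsync.grid import make_frequency_grid
from megsync.pls import (
    BootstrapRatios,
    ElementMatrix,
    band_threshold_map,
    behavioural_pls,
    bootstrap_ratios,
    build_element_matrix,
    contrast_pls,
    lv_permutation_test,
    proportion_ztest,
    tail_counts,
)
from megsync.synthetic import simulate_plv_tensor

GRID12 = make_frequency_grid(12, 2, 60)
ALPHA_FI = GRID12.nearest_index(10.0)
ALPHA_COLS = [pair_index(i, j, 12) for i, j in ALPHA_PAIRS]
PLANTED_ELEMENTS = [ALPHA_FI * 66 + c for c in ALPHA_COLS]


def _random_em(n_a=4, n_b=5, n_freq=3, n_pairs=4, seed=0):
    rng = np.random.default_rng(seed)
    return ElementMatrix(
        matrix=rng.uniform(0, 1, size=(n_a + n_b, n_freq * n_pairs)),
        element_labels=np.array(
            [(f, p) for f in range(n_freq) for p in range(n_pairs)]
        ),
        group_sizes=(n_a, n_b),
        n_frequencies=n_freq,
        n_pairs=n_pairs,
    )


class TestBuildElementMatrix:
    def _tensor(self, n_sub=4, n_freq=2, n_regions=3, seed=0):
        rng = np.random.default_rng(seed)
        return ConnectivityTensor(
            plv=rng.uniform(0, 1, size=(n_sub, n_freq, n_regions * (n_regions - 1) // 2)),
            frequencies_hz=np.arange(1.0, n_freq + 1),
            pairs=pair_list(n_regions),
            subject_ids=[f"s{i}" for i in range(n_sub)],
            region_names=[f"r{i}" for i in range(n_regions)],
        )

    def test_small_shape(self):
        tensor = self._tensor()
        em = build_element_matrix(tensor, np.array([1, -1, 1, -1]))
        assert em.matrix.shape == (4, 6)  # 2 freqs x 3 pairs
        assert em.group_sizes == (2, 2)

    def test_full_scale_element_count(self):
        # 30 frequencies x 4005 pairs = 120,150 elements for 90 regions
        assert 30 * (90 * 89 // 2) == 120_150

    def test_rows_blocked_patients_first(self):
        tensor = self._tensor()
        groups = np.array([-1, 1, -1, 1])
        em = build_element_matrix(tensor, groups)
        assert np.allclose(em.matrix[0], tensor.plv[1].ravel())
        assert np.allclose(em.matrix[2], tensor.plv[0].ravel())

    def test_column_labels_round_trip_to_tensor_cells(self):
        tensor = self._tensor(seed=3)
        groups = np.array([1, 1, -1, -1])
        em = build_element_matrix(tensor, groups)
        for col, (fi, p) in enumerate(em.element_labels):
            assert np.allclose(em.matrix[:, col], tensor.plv[:, fi, p])

    def test_invalid_group_label_rejected(self):
        tensor = self._tensor()
        with pytest.raises(ValueError):
            build_element_matrix(tensor, np.array([1, 0, -1, 1]))


class TestContrastPLS:
    def test_single_planted_element_dominates_saliences(self):
        em = _random_em(seed=1)
        em.matrix[: em.group_sizes[0], 5] += 10.0
        model = contrast_pls(em)
        saliences = model.right_vectors[:, 0]
        assert saliences[5] ** 2 / np.sum(saliences**2) >= 0.99

    def test_identical_group_means_give_zero_singular_value(self):
        em = _random_em(n_a=3, n_b=3, seed=2)
        em.matrix[3:] = em.matrix[:3]  # same group means
        model = contrast_pls(em)
        assert model.singular_values[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_give_exactly_one_nonzero_lv(self):
        model = contrast_pls(_random_em(seed=3))
        s = model.singular_values
        assert s[0] > 1e-8
        assert np.all(s[1:] <= 1e-12 * s[0])

    def test_left_vector_antisymmetric_and_patients_negative(self):
        em = _random_em(seed=4)
        em.matrix[: em.group_sizes[0]] += 0.3  # patients elevated
        model = contrast_pls(em)
        u = model.left_vectors[:, 0]
        assert u[0] == pytest.approx(-u[1])
        assert u[0] < 0  # patient block carries the negative weight
        assert np.mean(model.right_vectors[:, 0]) < 0  # elevated elements load negative

    def test_energy_conservation_and_reconstruction(self):
        em = _random_em(n_a=5, n_b=6, n_freq=4, n_pairs=7, seed=5)
        model = contrast_pls(em)
        cross = model.cross_block
        assert np.sum(model.singular_values**2) == pytest.approx(
            np.linalg.norm(cross) ** 2, rel=1e-10
        )
        recon = (
            model.left_vectors
            @ np.diag(model.singular_values)
            @ model.right_vectors.T
        )
        assert np.allclose(recon, cross, atol=1e-10)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            contrast_pls(_random_em(n_a=1, n_b=5))


class TestBehaviouralPLS:
    def test_behaviour_copying_an_element_gives_unit_correlation(self):
        # only element 3 varies; behaviour copies it exactly
        em = _random_em(n_a=10, n_b=0, seed=6)
        em.group_sizes = (10,)
        keep = em.matrix[:, 3].copy()
        em.matrix[:] = 0.5
        em.matrix[:, 3] = keep
        model = behavioural_pls(em, keep.copy())
        saliences = model.right_vectors[:, 0]
        assert np.argmax(np.abs(saliences)) == 3
        assert abs(saliences[3]) == pytest.approx(1.0)
        assert model.overall_correlation == pytest.approx(1.0, abs=1e-9)

    def test_behaviour_tracking_one_element_dominates_saliences(self):
        em = _random_em(n_a=12, n_b=0, seed=16)
        em.group_sizes = (12,)
        model = behavioural_pls(em, em.matrix[:, 3].copy())
        assert np.argmax(np.abs(model.right_vectors[:, 0])) == 3
        assert model.overall_correlation > 0.8

    def test_zero_variance_behaviour_rejected(self):
        em = _random_em()
        with pytest.raises(ValueError, match="variance"):
            behavioural_pls(em, np.ones(em.matrix.shape[0]))

    def test_independent_behaviour_rarely_significant(self):
        em = _random_em(n_a=20, n_b=0, n_freq=4, n_pairs=10, seed=7)
        em.group_sizes = (20,)
        insignificant = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            p, _ = lv_permutation_test(
                em, n_perm=99, seed=rng, behaviour=rng.standard_normal(20)
            )
            insignificant += int(p[0] > 0.05)
        assert insignificant >= 18


class TestPermutationTest:
    def test_planted_contrast_significant(self):
        for seed in range(5):
            tensor, table = simulate_plv_tensor(reduced_config(seed, n_a=20, n_b=21))
            em = build_element_matrix(tensor, table["group"].to_numpy())
            p, _ = lv_permutation_test(em, n_perm=199, seed=seed)
            assert p[0] <= 0.01

    def test_estimator_floor(self):
        # overwhelming contrast with unequal groups: the only permutations
        # matching the observed singular value are exact block reconstitutions,
        # which are vanishingly rare at 6-vs-14
        em = _random_em(n_a=6, n_b=14, seed=8)
        em.matrix[:6] += 100.0
        p, _ = lv_permutation_test(em, n_perm=199, seed=0)
        assert p[0] == pytest.approx(1 / 200)

    def test_no_effect_p_values_spread_over_unit_interval(self):
        ps = []
        for seed in range(20):
            em = _random_em(n_a=8, n_b=8, n_freq=2, n_pairs=5, seed=200 + seed)
            p, _ = lv_permutation_test(em, n_perm=99, seed=seed)
            ps.append(p[0])
        assert np.mean(np.array(ps) <= 0.05) <= 0.15
        assert np.mean(ps) > 0.3  # roughly uniform, not collapsed near 0

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            lv_permutation_test(_random_em(), n_perm=0, seed=0)


class TestBootstrapRatios:
    def test_planted_elements_exceed_three(self):
        hits = 0
        for seed in range(10):
            tensor, table = simulate_plv_tensor(reduced_config(seed, n_a=20, n_b=21))
            em = build_element_matrix(tensor, table["group"].to_numpy())
            ratios = bootstrap_ratios(em, n_boot=199, seed=seed)
            hits += int(np.all(np.abs(ratios.ratios[PLANTED_ELEMENTS]) >= 3))
        assert hits >= 9

    def test_noise_elements_mostly_below_three(self):
        tensor, table = simulate_plv_tensor(reduced_config(3, n_a=20, n_b=21))
        em = build_element_matrix(tensor, table["group"].to_numpy())
        ratios = bootstrap_ratios(em, n_boot=199, seed=3)
        noise = np.ones(ratios.ratios.size, dtype=bool)
        noise[PLANTED_ELEMENTS] = False
        assert np.mean(np.abs(ratios.ratios[noise]) < 3) >= 0.95

    def test_single_bootstrap_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ratios(_random_em(), n_boot=1, seed=0)


class TestTailCounts:
    def test_tail_totals_match_quantile_definition(self):
        rng = np.random.default_rng(9)
        n = 120_150
        n_freq = 30
        ratios = BootstrapRatios(
            ratios=rng.standard_normal(n),
            loadings=np.zeros(n),
            se=np.ones(n),
            n_boot=10,
            element_labels=np.array(
                [(f, p) for f in range(n_freq) for p in range(n // n_freq)]
            ),
        )
        upper, lower, (lo, hi) = tail_counts(ratios, n_freq, tail_q=0.01)
        expected = int(0.01 * n)
        assert abs(upper.sum() - expected) <= 1
        assert abs(lower.sum() - expected) <= 1
        assert lo < 0 < hi

    def test_symmetric_noise_gives_balanced_tails(self):
        rng = np.random.default_rng(10)
        n = 50_000
        ratios = BootstrapRatios(
            ratios=rng.standard_normal(n),
            loadings=np.zeros(n),
            se=np.ones(n),
            n_boot=10,
            element_labels=np.array([(f, p) for f in range(10) for p in range(n // 10)]),
        )
        upper, lower, _ = tail_counts(ratios, 10, tail_q=0.05)
        assert abs(int(upper.sum()) - int(lower.sum())) <= 2

    def test_planted_alpha_effect_concentrates_in_lower_tail(self):
        # patients hyperconnected at alpha -> negative loadings (patient block
        # is oriented negative), so planted elements populate the lower tail
        tensor, table = simulate_plv_tensor(reduced_config(11, n_a=20, n_b=21))
        em = build_element_matrix(tensor, table["group"].to_numpy())
        ratios = bootstrap_ratios(em, n_boot=199, seed=11)
        upper, lower, _ = tail_counts(ratios, em.n_frequencies, 0.01)
        assert np.argmax(lower) == ALPHA_FI

    def test_invalid_tail_fraction_rejected(self):
        ratios = BootstrapRatios(
            ratios=np.zeros(4),
            loadings=np.zeros(4),
            se=np.ones(4),
            n_boot=2,
            element_labels=np.array([(0, 0), (0, 1), (1, 0), (1, 1)]),
        )
        with pytest.raises(ValueError):
            tail_counts(ratios, 2, tail_q=0.6)


class TestProportionZTest:
    @pytest.mark.parametrize(
        "c1,n1,c2,n2",
        [
            (100, 4005, 60, 4005),
            (5, 100, 3, 120),
            (0, 50, 10, 50),
            (400, 4005, 380, 4005),
        ],
    )
    def test_matches_independent_implementation(self, c1, n1, c2, n2):
        z, p = proportion_ztest(c1, n1, c2, n2)
        z_ref, p_ref = proportions_ztest([c1, c2], [n1, n2])
        assert z == pytest.approx(z_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_reference_counts(self):
        z, p = proportion_ztest(100, 4005, 60, 4005)
        assert z == pytest.approx(3.19, abs=0.01)
        assert p == pytest.approx(0.0014, abs=0.0001)

    def test_equal_counts_give_zero(self):
        assert proportion_ztest(7, 100, 7, 100) == (0.0, 1.0)

    def test_zero_pooled_variance_convention(self):
        assert proportion_ztest(0, 10, 0, 20) == (0.0, 1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_ztest(11, 10, 0, 10)


class TestBandThresholdMap:
    def _ratios(self, values, n_freq, n_pairs):
        return BootstrapRatios(
            ratios=np.asarray(values, dtype=float),
            loadings=np.zeros(n_freq * n_pairs),
            se=np.ones(n_freq * n_pairs),
            n_boot=2,
            element_labels=np.array(
                [(f, p) for f in range(n_freq) for p in range(n_pairs)]
            ),
        )

    def test_uniform_high_ratios_fill_the_triangle(self):
        ratios = self._ratios(np.full(2 * 3, 2.0), 2, 3)
        mat = band_threshold_map(ratios, [0, 1], n_regions=3, threshold=1.0)
        iu, ju = np.triu_indices(3, 1)
        assert np.all(mat[iu, ju] == 2.0)
        assert np.allclose(mat, mat.T)

    def test_uniform_low_ratios_give_empty_map(self):
        ratios = self._ratios(np.full(2 * 3, 0.5), 2, 3)
        mat = band_threshold_map(ratios, [0, 1], n_regions=3, threshold=1.0)
        assert np.all(mat == 0.0)

    def test_mixed_ratios_match_brute_force_filter(self):
        rng = np.random.default_rng(12)
        n_freq, n_regions = 4, 6
        n_pairs = n_regions * (n_regions - 1) // 2
        vals = rng.normal(0, 2, size=n_freq * n_pairs)
        ratios = self._ratios(vals, n_freq, n_pairs)
        band = [1, 2]
        mat = band_threshold_map(ratios, band, n_regions, threshold=1.0)
        grid_vals = vals.reshape(n_freq, n_pairs)
        for k, (i, j) in enumerate(pair_list(n_regions)):
            mean = grid_vals[band, k].mean()
            expected = mean if mean > 1.0 else 0.0
            assert mat[i, j] == pytest.approx(expected)

    def test_below_direction(self):
        ratios = self._ratios([-2.0, 0.5, -1.5], 1, 3)
        mat = band_threshold_map(ratios, [0], n_regions=3, threshold=-1.0, direction="below")
        assert mat[0, 1] == -2.0 and mat[1, 2] == -1.5 and mat[0, 2] == 0.0
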