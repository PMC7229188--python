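import numpy as np
import pytest

from dynmod.connectivity import (canonical_hrf, block_connectivity,
                                 condition_connectivity, hrf_weights,
                                 weighted_pearson)
from dynmod.synthgen import (ScenarioSpec, SystemAtlas, constant_partitions,
                             generate_panel)


class TestCanonicalHRF:
    def test_peak_near_six_seconds(self):
        hrf = canonical_hrf(2.0)
        t_peak = np.argmax(hrf.values) * hrf.tr_seconds
        assert abs(t_peak - 6.0) <= 2.0

    def test_finite_support(self):
        hrf = canonical_hrf(2.0)
        assert len(hrf.values) == int(32 / 2) + 1
        assert hrf.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_peak_location_independent_of_sampling(self):
        for tr in (0.5, 1.0, 2.0):
            hrf = canonical_hrf(tr)
            assert abs(np.argmax(hrf.values) * tr - 6.0) <= 2.0

    def test_positive_integral(self):
        assert canonical_hrf(1.0).values.sum() > 0

    def test_rejects_nonpositive_tr(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestHRFWeights:
    def test_zero_regressor_gives_zero_weights(self):
        hrf = canonical_hrf(2.0)
        w = hrf_weights(np.zeros(50), hrf)
        np.testing.assert_array_equal(w, 0.0)

    def test_impulse_recovers_rectified_kernel(self):
        hrf = canonical_hrf(2.0)
        reg = np.zeros(40)
        reg[0] = 1.0
        w = hrf_weights(reg, hrf)
        expected = np.clip(hrf.values, 0, None)
        np.testing.assert_allclose(w[: len(expected)], expected)

    def test_long_block_plateaus_and_never_goes_negative(self):
        hrf = canonical_hrf(2.0)
        reg = np.zeros(60)
        reg[5:35] = 1.0
        w = hrf_weights(reg, hrf)
        assert np.all(w >= 0)
        assert w[20] == pytest.approx(w[21], rel=0.05)  # plateau
        assert np.all(w[: 5] == 0)

    def test_length_mismatch_handled_by_truncation_contract(self):
        hrf = canonical_hrf(2.0)
        w = hrf_weights(np.ones(10), hrf)
        assert w.shape == (10,)


class TestWeightedPearson:
    def test_uniform_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 50))
        expected = np.corrcoef(x, y)[0, 1]
        assert weighted_pearson(x, y, np.ones(50)) == pytest.approx(
            expected, abs=1e-12)

    def test_affine_relation_gives_unit_correlation(self):
        x = np.arange(10.0)
        w = np.linspace(0.5, 2.0, 10)
        assert weighted_pearson(x, 2 * x + 1, w) == pytest.approx(1.0)

    def test_frozen_three_point_example(self):
        # hand evaluation of the weighted-moment formula
        r = weighted_pearson([1, 2, 3], [1, 3, 2], [1, 1, 2])
        assert r == pytest.approx(0.4264014327112209, abs=1e-12)

    def test_agrees_with_numpy_weighted_covariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 30))
        w = rng.random(30) + 0.1
        cov = np.cov(np.vstack([x, y]), aweights=w, ddof=0)
        expected = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert weighted_pearson(x, y, w) == pytest.approx(expected,
                                                          abs=1e-12)

    def test_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 30))
        w = rng.random(30)
        assert weighted_pearson(x, y, w) == pytest.approx(
            weighted_pearson(x, y, 37.5 * w), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            weighted_pearson([1, 2], [1, 2], [0, 0])
        with pytest.raises(ValueError):
            weighted_pearson([1, 1, 1], [1, 2, 3], [1, 1, 1])


def _panel(seed=0, rho_w=0.6, rho_b=0.05, n_blocks=6, spb=25, nodes=24):
    atlas = SystemAtlas.equal_systems(nodes, 4)
    spec = ScenarioSpec(
        n_nodes=nodes, atlas=atlas,
        planted_partitions=constant_partitions(atlas, n_blocks),
        rho_within=rho_w, rho_between=rho_b, n_blocks=n_blocks,
        samples_per_block=spb, seed=seed)
    return generate_panel(spec), atlas


class TestConditionConnectivity:
    def test_planted_structure_raises_within_system_weights(self):
        panel, atlas = _panel()
        A = condition_connectivity(panel, "1-back")
        labels = np.asarray(atlas.labels, dtype=object)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(panel.n_rois, dtype=bool)
        assert A[same & off].mean() > A[~same].mean()

    def test_output_is_symmetric_nonnegative_zero_diagonal(self):
        panel, _ = _panel(seed=3)
        A = condition_connectivity(panel, "2-back")
        np.testing.assert_allclose(A, A.T)
        assert A.min() >= 0
        np.testing.assert_array_equal(np.diag(A), 0.0)

    def test_independent_noise_yields_small_edges(self):
        # null panel: 300 task volumes of pure noise
        panel, _ = _panel(rho_w=0.0, rho_b=0.0, n_blocks=12, spb=25)
        A = condition_connectivity(panel, None)
        off = ~np.eye(panel.n_rois, dtype=bool)
        frac_small = np.mean(A[off] < np.arctanh(0.3))
        assert frac_small >= 0.95

    def test_identical_rows_produce_the_maximal_edge(self):
        panel, _ = _panel(seed=9)
        panel.signal[1] = panel.signal[0]
        A = condition_connectivity(panel, "1-back")
        assert A[0, 1] == pytest.approx(A[0].max())

    def test_unknown_condition_rejected(self):
        panel, _ = _panel()
        with pytest.raises(ValueError):
            condition_connectivity(panel, "3-back")

    def test_fisher_transform_preserves_edge_ranking(self):
        panel, _ = _panel(seed=2)
        Z = condition_connectivity(panel, "1-back", rectify=False)
        iu = np.triu_indices(panel.n_rois, k=1)
        order_z = np.argsort(Z[iu])
        order_r = np.argsort(np.tanh(Z[iu]))
        np.testing.assert_array_equal(order_z, order_r)


class TestBlockConnectivity:
    def test_one_matrix_per_block_with_conditions(self):
        panel, _ = _panel(n_blocks=20, spb=15)
        stack = block_connectivity(panel)
        assert stack.weights.shape[0] == 20
        assert stack.conditions == ["1-back", "2-back"] * 10

    def test_blocks_cluster_by_condition_when_structure_differs(self):
        atlas = SystemAtlas.equal_systems(24, 4)
        labels = np.asarray(atlas.labels, dtype=object)
        merged = labels.copy()
        merged[atlas.members("sys1")] = "sys0"  # 2-back merges two systems
        parts = tuple(labels.copy() if b % 2 == 0 else merged.copy()
                      for b in range(8))
        spec = ScenarioSpec(n_nodes=24, atlas=atlas,
                            planted_partitions=parts, rho_within=0.6,
                            rho_between=0.05, n_blocks=8,
                            samples_per_block=60, seed=21)
        stack = block_connectivity(generate_panel(spec))
        mats = stack.weights.reshape(8, -1)
        mean_1back = mats[::2].mean(axis=0)
        mean_2back = mats[1::2].mean(axis=0)
        for t in range(8):
            d_own = np.linalg.norm(mats[t] - (mean_1back if t % 2 == 0
                                              else mean_2back))
            d_other = np.linalg.norm(mats[t] - (mean_2back if t % 2 == 0
                                                else mean_1back))
            assert d_own < d_other

    def test_between_block_variance_shrinks_with_longer_blocks(self):
        panel_short, _ = _panel(seed=5, n_blocks=6, spb=15)
        panel_long, _ = _panel(seed=5, n_blocks=6, spb=120)
        var_short = block_connectivity(panel_short).weights.var(axis=0).mean()
        var_long = block_connectivity(panel_long).weights.var(axis=0).mean()
        assert var_long < var_short

    def test_too_few_volumes_rejected(self):
        panel, _ = _panel(spb=2)
        with pytest.raises(ValueError, match="fewer than 3"):
            block_connectivity(panel)
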