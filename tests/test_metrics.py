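"""Node metrics, transforms and within-period standardization."""

import numpy as np
import pytest

from matrinet.metrics import (
    betweenness,
    eigenvector_centrality,
    metric_values,
    standardize_within_period,
    strength,
    transform,
    transform_for,
)

from .oracles import betweenness_enumeration, leading_eigenvector


def random_weighted_graph(rng, n, density=0.5, symmetric=True):
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    if symmetric:
        w = np.triu(w, 1)
        w = w + w.T
    np.fill_diagonal(w, 0)
    return w


class TestStrength:
    def test_symmetric_triangle(self):
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0)
        np.testing.assert_allclose(strength(w), 1.0)

    def test_directed_modes(self):
        w = np.zeros((3, 3))
        w[0, 1], w[0, 2] = 3, 1
        assert strength(w, "out")[0] == 4
        assert strength(w, "in")[1] == 3
        assert strength(w, "total")[0] == 4

    def test_isolated_node(self):
        w = np.zeros((2, 2))
        assert strength(w)[0] == 0


class TestEigenvectorCentrality:
    def test_equal_triangle(self):
        w = np.full((3, 3), 0.3)
        np.fill_diagonal(w, 0)
        np.testing.assert_allclose(eigenvector_centrality(w), 1.0, atol=1e-8)

    def test_star_closed_form(self):
        # K_{1,4}: centre 1, leaves 1/2 (leading eigenvalue 2)
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        v = eigenvector_centrality(w)
        assert v[0] == pytest.approx(1.0)
        np.testing.assert_allclose(v[1:], 0.5, atol=1e-8)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        w = random_weighted_graph(rng, 6)
        np.testing.assert_allclose(
            eigenvector_centrality(w), eigenvector_centrality(10 * w), atol=1e-7
        )

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(np.zeros((3, 3)))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dense_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(rng, int(rng.integers(3, 9)))
        if not w.any():
            return
        np.testing.assert_allclose(
            eigenvector_centrality(w), leading_eigenvector(w), atol=1e-6
        )


class TestBetweenness:
    def test_path_midpoint(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        np.testing.assert_allclose(betweenness(w), [0, 1, 0])

    def test_four_cycle_fractional_split(self):
        w = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            w[a, b] = w[b, a] = 1.0
        np.testing.assert_allclose(betweenness(w), 0.5)

    def test_complete_graph_zero(self):
        w = np.ones((5, 5)) - np.eye(5)
        np.testing.assert_allclose(betweenness(w), 0.0)

    def test_inverse_weight_option_changes_paths(self):
        # strong direct edge: with weights-as-costs the direct edge is
        # expensive and the detour via node 1 carries the shortest path
        w = np.zeros((3, 3))
        w[0, 2] = w[2, 0] = 1.0
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 0.3
        assert betweenness(w, "weights_as_costs")[1] == 1.0
        assert betweenness(w, "inverse_weights")[1] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(rng, int(rng.integers(4, 9)), density=0.6)
        np.testing.assert_allclose(
            betweenness(w), betweenness_enumeration(w), atol=1e-8
        )


class TestTransforms:
    def test_elementwise(self):
        np.testing.assert_allclose(transform(np.array([0.0, 4.0]), "log1p"), [0, np.log(5)])
        np.testing.assert_allclose(transform(np.array([4.0]), "sqrt"), [2.0])

    def test_negative_sqrt_rejected(self):
        with pytest.raises(ValueError):
            transform(np.array([-1.0]), "sqrt")

    def test_metric_transform_map(self):
        assert transform_for("strength_groom_given") == "log1p"
        assert transform_for("betweenness_prox") == "log1p"
        assert transform_for("eigencent_groom_total") == "sqrt"
        assert transform_for("betweenness_groom_total") == "sqrt"
        assert transform_for("strength_prox") == "identity"


class TestStandardize:
    def test_sample_sd_zscores(self):
        np.testing.assert_allclose(standardize_within_period(np.array([1.0, 2, 3])), [-1, 0, 1])

    def test_constant_vector_becomes_zero(self):
        np.testing.assert_array_equal(standardize_within_period(np.array([2.0, 2, 2])), 0)

    def test_periods_standardized_independently(self):
        a = standardize_within_period(np.array([1.0, 5, 9]))
        b = standardize_within_period(np.array([100.0, 200, 300]))
        assert abs(a.mean()) < 1e-12 and abs(b.mean()) < 1e-12


def test_permutation_equivariance():
    """Relabeling nodes permutes every metric vector identically."""
    rng = np.random.default_rng(42)
    w = random_weighted_graph(rng, 7, density=0.7)
    pi = rng.permutation(7)
    wp = w[np.ix_(pi, pi)]
    for metric in ("strength_prox", "eigencent_prox", "betweenness_prox"):
        base = metric_values(metric, w)
        np.testing.assert_allclose(metric_values(metric, wp), base[pi], atol=1e-7)
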