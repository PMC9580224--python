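import numpy as np
import pytest

from perceptstrain.kernels import (
    DOGParams,
    GaussianParams,
    GridGeometry,
    Jacobian,
    build_jacobian,
    build_stencil,
)
from perceptstrain.metric import (
    convolutional_distance,
    euclidean_distance,
    first_order_distance,
    perceptual_distance,
    preprocess,
    strain_tensor,
    tiled_distance,
)


class TestPreprocess:
    def test_stretch_to_full_range(self, rng):
        img = rng.uniform(10, 100, (8, 8))
        out = preprocess(img)
        assert out.min() == 0.0
        assert out.max() == 255.0

    def test_full_range_input_unchanged(self, rng):
        img = rng.uniform(0, 255, (6, 6))
        img.flat[0], img.flat[-1] = 0.0, 255.0
        np.testing.assert_allclose(preprocess(img), img)

    def test_gray_color_input_collapses_to_luminance(self, rng):
        plane = rng.uniform(0, 255, (5, 5))
        plane.flat[0], plane.flat[-1] = 0.0, 255.0
        color = np.repeat(plane[..., None], 3, axis=2)
        np.testing.assert_allclose(preprocess(color), plane)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            preprocess(np.full((4, 4), 7.0))


class TestEuclidean:
    def test_identical_images_zero(self, rng):
        a = rng.random((8, 8))
        assert euclidean_distance(a, a) == 0.0

    def test_single_pixel_difference(self):
        a = np.zeros((3, 3))
        b = a.copy()
        b[1, 1] = 0.1
        assert euclidean_distance(a, b) == pytest.approx(0.01)

    def test_matches_elementwise_loop_oracle(self, image_pair):
        a, b = image_pair
        total = 0.0
        for i in range(8):
            for j in range(8):
                total += (b[i, j] - a[i, j]) ** 2
        assert euclidean_distance(a, b) == pytest.approx(total, abs=1e-12)

    def test_mean_variant_divides_by_pixel_count(self, image_pair):
        a, b = image_pair
        assert euclidean_distance(a, b, mean=True) == pytest.approx(
            euclidean_distance(a, b) / 64
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            euclidean_distance(np.zeros((4, 4)), np.zeros((4, 5)))


class TestPerceptualDistance:
    def test_identity_operator_reduces_to_euclidean(self, image_pair):
        a, b = image_pair
        assert perceptual_distance(a, b, np.eye(64)) == pytest.approx(
            euclidean_distance(a, b)
        )

    def test_two_pixel_hand_example(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[0.1, 0.0]])
        P = np.array([[1.0, 0.5], [0.5, 1.0]])
        # P @ (0.1, 0) = (0.1, 0.05) -> squared norm 0.0125
        assert perceptual_distance(a, b, P) == pytest.approx(0.0125)

    def test_matches_triple_product_oracle(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        J = build_jacobian(GridGeometry(4, 4), DOGParams(1.0, 1.7, 0.8))
        delta = (b - a).ravel()
        expected = delta @ (J.entries.T @ J.entries) @ delta
        assert perceptual_distance(a, b, J) == pytest.approx(expected, abs=1e-10)

    def test_nonnegative_with_negative_couplings(self, rng):
        # P^T P is PSD regardless of the sign of off-diagonals
        for _ in range(50):
            M = rng.uniform(-1, 1, (16, 16))
            M = np.triu(M, 1)
            M = M + M.T + np.eye(16)
            a, b = rng.random((4, 4)), rng.random((4, 4))
            assert perceptual_distance(a, b, M) >= 0.0

    def test_geometry_mismatch_rejected(self, image_pair):
        a, b = image_pair
        J = build_jacobian(GridGeometry(4, 4), GaussianParams(1.0))
        with pytest.raises(ValueError, match="match"):
            perceptual_distance(a, b, J)


class TestConvolutionalDistance:
    def test_unit_impulse_equals_euclidean(self, image_pair):
        a, b = image_pair
        impulse = np.zeros((3, 3))
        impulse[1, 1] = 1.0
        assert convolutional_distance(a, b, impulse) == pytest.approx(
            euclidean_distance(a, b)
        )

    def test_identical_images_zero(self, rng):
        a = rng.random((8, 8))
        S = build_stencil(GaussianParams(0.6))
        assert convolutional_distance(a, a, S) == 0.0

    @pytest.mark.parametrize(
        "kernel",
        [GaussianParams(0.6), DOGParams(1.0, 1.8, 0.9)],
        ids=["gaussian", "dog"],
    )
    def test_matches_dense_matrix_oracle(self, rng, kernel):
        radius = 4
        a, b = rng.random((8, 8)), rng.random((8, 8))
        J = build_jacobian(GridGeometry(8, 8), kernel, truncation_radius=radius)
        S = build_stencil(kernel, truncation_radius=radius)
        assert convolutional_distance(a, b, S) == pytest.approx(
            perceptual_distance(a, b, J), abs=1e-8
        )


class TestTiledDistance:
    def test_single_tile_equals_global_quadratic_form(self, image_pair):
        a, b = image_pair
        J = build_jacobian(GridGeometry(8, 8), GaussianParams(1.0))
        assert tiled_distance(a, b, J) == pytest.approx(
            perceptual_distance(a, b, J)
        )

    def test_tile_values_sum(self, rng):
        a, b = rng.random((8, 16)), rng.random((8, 16))
        J = build_jacobian(GridGeometry(8, 8), GaussianParams(0.8))
        v1 = perceptual_distance(a[:, :8], b[:, :8], J)
        v2 = perceptual_distance(a[:, 8:], b[:, 8:], J)
        assert tiled_distance(a, b, J) == pytest.approx(v1 + v2)

    def test_identity_tile_operator_equals_euclidean(self, rng):
        a, b = rng.random((24, 16)), rng.random((24, 16))
        assert tiled_distance(a, b, np.eye(64)) == pytest.approx(
            euclidean_distance(a, b)
        )

    def test_indivisible_image_refused_then_cropped(self, rng):
        a, b = rng.random((10, 10)), rng.random((10, 10))
        with pytest.raises(ValueError, match="divisible"):
            tiled_distance(a, b, np.eye(64))
        cropped = tiled_distance(a, b, np.eye(64), edge="crop")
        assert cropped == pytest.approx(euclidean_distance(a[:8, :8], b[:8, :8]))


class TestStrainTensor:
    def test_identity_gives_zero_strain(self):
        assert np.all(strain_tensor(np.eye(9)) == 0.0)

    def test_unit_diagonal_gives_zero_strain_diagonal(self):
        J = build_jacobian(GridGeometry(3, 3), DOGParams(1.0, 2.0, 0.7))
        assert np.all(np.diag(strain_tensor(J)) == 0.0)

    def test_symmetric_operator_fixed_point(self):
        J = build_jacobian(GridGeometry(3, 3), GaussianParams(1.2))
        np.testing.assert_array_equal(strain_tensor(J), J.entries - np.eye(9))


class TestFirstOrderDistance:
    def test_zero_strain_is_euclidean(self, image_pair):
        a, b = image_pair
        assert first_order_distance(a, b, np.zeros((64, 64))) == pytest.approx(
            euclidean_distance(a, b)
        )

    def test_decomposes_as_euclidean_plus_strain_term(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        J = build_jacobian(GridGeometry(4, 4), GaussianParams(0.9))
        eps = strain_tensor(J)
        delta = (b - a).ravel()
        assert first_order_distance(a, b, eps) == pytest.approx(
            euclidean_distance(a, b) + 2 * delta @ eps @ delta
        )

    def test_error_shrinks_quadratically_with_strain(self, rng):
        # the dropped term (grad u)(grad u)^T is second order in the strain
        a, b = rng.random((3, 3)), rng.random((3, 3))
        base = rng.uniform(-1, 1, (9, 9))
        base = (np.triu(base, 1) + np.triu(base, 1).T)
        gaps = []
        for lam in (0.1, 0.05, 0.025):
            P = np.eye(9) + lam * base
            gap = abs(
                perceptual_distance(a, b, P)
                - first_order_distance(a, b, strain_tensor(P))
            )
            gaps.append(gap)
        assert gaps[0] / gaps[1] == pytest.approx(4.0, rel=0.01)
        assert gaps[1] / gaps[2] == pytest.approx(4.0, rel=0.01)


class TestMetricAxioms:
    def test_axioms_on_random_inputs(self, rng):
        J = build_jacobian(GridGeometry(6, 6), DOGParams(0.9, 1.6, 0.8))
        S = build_stencil(GaussianParams(0.7))
        for _ in range(100):
            a, b = rng.random((6, 6)), rng.random((6, 6))
            lam = rng.uniform(0.5, 2.0)
            for dist in (
                euclidean_distance,
                lambda x, y: perceptual_distance(x, y, J),
                lambda x, y: convolutional_distance(x, y, S),
            ):
                d = dist(a, b)
                assert d >= 0.0
                assert dist(b, a) == pytest.approx(d)
                assert dist(a, a) == 0.0
                # homogeneity: d^2(a, a + lam*delta) = lam^2 d^2(a, b)
                assert dist(a, a + lam * (b - a)) == pytest.approx(
                    lam**2 * d, rel=1e-9
                )
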