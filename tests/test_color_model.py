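"""Unit and property tests for the cubic-polynomial color standardization."""

import json

import numpy as np
import pytest

from colorcard import (
    ChipColorMatrix,
    ColorTransform,
    apply_transform_image,
    apply_transform_pixel,
    deviance,
    deviance_between,
    extend_design,
    fit_homography,
    fit_transform,
    identity_transform,
    pseudoinverse,
)
from colorcard.color_model import ChannelCoefficients, HomographyMatrix
from colorcard.errors import (
    CorrespondenceError,
    FormatError,
    InvalidInputError,
    SingularDesignError,
)
from conftest import random_chips


def lstsq_oracle(design: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Independent brute-force normal-equations solve (9 x c).

    Cubed 8-bit intensities make the normal equations ill-conditioned in
    double precision, so the oracle eliminates in extended precision to stay
    the more accurate side of the comparison.
    """
    design_ld = design.astype(np.longdouble)
    gram = design_ld.T @ design_ld
    rhs = design_ld.T @ targets.astype(np.longdouble)

    def solve(a, b):
        a, b = a.copy(), b.copy()
        n = a.shape[0]
        for i in range(n):
            p = i + np.argmax(np.abs(a[i:, i]))
            a[[i, p]], b[[i, p]] = a[[p, i]], b[[p, i]]
            factor = a[i + 1 :, i] / a[i, i]
            a[i + 1 :] -= factor[:, None] * a[i]
            b[i + 1 :] -= factor[:, None] * b[i]
        x = np.zeros_like(b)
        for i in range(n - 1, -1, -1):
            x[i] = (b[i] - a[i, i + 1 :] @ x[i + 1 :]) / a[i, i]
        return x

    x = solve(gram, rhs)
    for _ in range(3):  # iterative refinement against the squared conditioning
        x = x + solve(gram, rhs - gram @ x)
    return x.astype(float)


def det_oracle(a: np.ndarray) -> float:
    """Determinant by hand-rolled Gaussian elimination with partial pivoting."""
    a = a.astype(float).copy()
    n = a.shape[0]
    det = 1.0
    for i in range(n):
        p = i + np.argmax(np.abs(a[i:, i]))
        if p != i:
            a[[i, p]] = a[[p, i]]
            det = -det
        if a[i, i] == 0.0:
            return 0.0
        det *= a[i, i]
        a[i + 1 :, i:] -= np.outer(a[i + 1 :, i] / a[i, i], a[i, i:])
    return det


class TestExtendDesign:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((2, 3, 4), (2, 3, 4, 4, 9, 16, 8, 27, 64)),
            ((0, 0, 0), (0,) * 9),
            ((1, 1, 1), (1,) * 9),
        ],
    )
    def test_rows_carry_squares_and_cubes(self, row, expected):
        out = extend_design(np.array([row], dtype=float))
        assert out.shape == (1, 9)
        np.testing.assert_allclose(out[0], expected)

    def test_column_structure_on_random_chips(self, rng):
        chips = random_chips(rng)
        design = extend_design(chips)
        np.testing.assert_allclose(design[:, 3:6], design[:, :3] ** 2)
        np.testing.assert_allclose(design[:, 6:9], design[:, :3] ** 3)

    def test_rejects_nonfinite(self):
        with pytest.raises(InvalidInputError):
            extend_design(np.array([[1.0, np.nan, 2.0]]))


class TestPseudoinverse:
    def test_left_inverse_property(self, rng):
        design = extend_design(random_chips(rng))
        m = pseudoinverse(design)
        np.testing.assert_allclose(m @ design, np.eye(9), atol=1e-6)

    def test_square_design_matches_ordinary_inverse(self, rng):
        # 9 random chips give a square, generically invertible design
        design = extend_design(random_chips(rng, k=9))
        np.testing.assert_allclose(
            pseudoinverse(design), np.linalg.inv(design), rtol=1e-6, atol=1e-9
        )

    def test_duplicated_rows_raise_singular_design(self, rng):
        values = rng.uniform(10.0, 245.0, size=(8, 3))
        dup = np.vstack([values, values])  # 16 rows, only 8 distinct colors
        with pytest.raises(SingularDesignError) as err:
            pseudoinverse(extend_design(dup))
        assert err.value.rank <= 8


class TestFitTransform:
    def test_self_fit_is_identity(self, canonical_chips):
        t = fit_transform(canonical_chips, canonical_chips)
        expected = np.zeros((3, 9))
        expected[0, 0] = expected[1, 1] = expected[2, 2] = 1.0
        np.testing.assert_allclose(t.as_matrix(), expected, atol=1e-8)

    def test_recovers_generating_cubic_polynomial(self, rng):
        source = random_chips(rng)
        # gentle in-range cubic: dominant own-channel linear term plus small
        # cross, quadratic, and cubic contributions
        true_coeffs = np.zeros((3, 9))
        for c in range(3):
            true_coeffs[c, c] = rng.uniform(0.6, 0.8)
            true_coeffs[c, (c + 1) % 3] = rng.uniform(0.0, 0.05)
            true_coeffs[c, c + 3] = rng.uniform(-1e-4, 1e-4)
            true_coeffs[c, c + 6] = rng.uniform(-1e-7, 1e-7)
        target_vals = extend_design(source) @ true_coeffs.T
        assert target_vals.min() >= 0 and target_vals.max() <= 255
        target = ChipColorMatrix(target_vals, source.chip_ids, "generated")
        t = fit_transform(source, target)
        np.testing.assert_allclose(t.as_matrix(), true_coeffs, atol=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        source, target = random_chips(rng, image_id="s"), random_chips(rng, image_id="t")
        t = fit_transform(source, target)
        oracle = lstsq_oracle(extend_design(source), target.values).T
        np.testing.assert_allclose(t.as_matrix(), oracle, rtol=1e-8, atol=1e-10)

    def test_residual_matches_oracle_residual(self, rng):
        source, target = random_chips(rng), random_chips(rng)
        design = extend_design(source)
        fitted = design @ fit_transform(source, target).as_matrix().T
        oracle_fit = design @ lstsq_oracle(design, target.values)
        res, res_o = np.linalg.norm(target.values - fitted), np.linalg.norm(
            target.values - oracle_fit
        )
        assert abs(res - res_o) <= 1e-8 * max(res_o, 1e-12)

    def test_chip_id_mismatch_raises(self, rng):
        source = random_chips(rng)
        shuffled = ChipColorMatrix(
            source.values[::-1], list(reversed(source.chip_ids)), "r"
        )
        with pytest.raises(CorrespondenceError):
            fit_transform(source, shuffled)


class TestApplyTransform:
    def test_identity_pixel(self):
        np.testing.assert_allclose(
            apply_transform_pixel(identity_transform(), (100, 200, 40)), (100, 200, 40)
        )

    def test_linear_halving_pixel(self):
        half = np.zeros((3, 9))
        half[0, 0] = half[1, 1] = half[2, 2] = 0.5
        t = ColorTransform(
            ChannelCoefficients(half[0], "R"),
            ChannelCoefficients(half[1], "G"),
            ChannelCoefficients(half[2], "B"),
        )
        np.testing.assert_allclose(apply_transform_pixel(t, (100, 200, 40)), (50, 100, 20))

    def test_clipping_at_255(self):
        double = np.zeros((3, 9))
        double[0, 0] = 2.0
        double[1, 1] = double[2, 2] = 1.0
        t = ColorTransform(
            ChannelCoefficients(double[0], "R"),
            ChannelCoefficients(double[1], "G"),
            ChannelCoefficients(double[2], "B"),
        )
        assert apply_transform_pixel(t, (200, 0, 0))[0] == 255.0

    def test_identity_image_is_byte_identical(self, rng):
        image = rng.integers(0, 256, size=(12, 17, 3), dtype=np.uint8)
        out = apply_transform_image(identity_transform(), image)
        assert out.dtype == np.uint8
        np.testing.assert_array_equal(out, image)

    def test_image_matches_pixelwise_application(self, rng):
        source, target = random_chips(rng), random_chips(rng)
        t = fit_transform(source, target)
        image = rng.integers(0, 256, size=(4, 5, 3), dtype=np.uint8)
        out = apply_transform_image(t, image, output="float")
        for y in range(4):
            for x in range(5):
                expected = t.as_matrix() @ extend_design(
                    image[y, x][None].astype(float)
                )[0]
                np.testing.assert_allclose(out[y, x], expected, rtol=1e-12)

    def test_rejects_non_rgb_raster(self):
        with pytest.raises(FormatError):
            apply_transform_image(identity_transform(), np.zeros((5, 5)))


class TestHomographyAndDeviance:
    def test_self_homography_is_identity(self, canonical_chips):
        h = fit_homography(canonical_chips, canonical_chips)
        np.testing.assert_allclose(h.values, np.eye(9), atol=1e-6)
        assert abs(deviance(h).value) < 1e-6

    def test_consistent_permutation_leaves_h_unchanged(self, rng):
        source, target = random_chips(rng, image_id="s"), random_chips(rng, image_id="t")
        h = fit_homography(source, target)
        perm = rng.permutation(source.k)
        ids = [source.chip_ids[i] for i in perm]
        h_perm = fit_homography(
            ChipColorMatrix(source.values[perm], ids, "s"),
            ChipColorMatrix(target.values[perm], ids, "t"),
        )
        np.testing.assert_allclose(h_perm.values, h.values, rtol=1e-8, atol=1e-10)
        assert np.isclose(
            deviance(h_perm).value, deviance(h).value, rtol=1e-8, atol=1e-10
        )

    def test_h_matches_column_by_column_regressions(self, rng):
        source, target = random_chips(rng), random_chips(rng)
        h = fit_homography(source, target)
        design = extend_design(source)
        ext_target = extend_design(target)
        for j in range(9):
            oracle = lstsq_oracle(design, ext_target[:, j][:, None])[:, 0]
            np.testing.assert_allclose(h.values[j], oracle, rtol=1e-8, atol=1e-10)

    def test_deviance_of_scaled_identity(self):
        assert deviance(HomographyMatrix(2.0 * np.eye(9))).value == 1 - 2**9 == -511

    def test_deviance_matches_elimination_oracle(self, rng):
        from colorcard.synthetic import DistortionSpec, SceneSpec, make_pair
        from colorcard.chip_sampling import sample_chips

        ref, dist, truths = make_pair(
            SceneSpec(seed=3), DistortionSpec(brightness_scale=0.7, gamma=(1.1, 1.0, 0.9))
        )
        layout = truths["layout"]
        h = fit_homography(sample_chips(dist, layout, "d"), sample_chips(ref, layout, "r"))
        expected = 1.0 - det_oracle(h.values)
        assert abs(deviance(h).value - expected) <= 1e-6 * max(abs(expected), 1.0)

    def test_degradation_grows_with_brightness_loss(self, canonical_chips):
        """|D| under a 50% brightness drop exceeds |D| under a 10% drop."""
        scores = {}
        for s in (1.0, 0.9, 0.8, 0.7, 0.6, 0.5):
            dimmed = ChipColorMatrix(
                canonical_chips.values * s, canonical_chips.chip_ids, f"s{s}"
            )
            scores[s] = deviance_between(dimmed, canonical_chips).value
        assert abs(scores[0.5]) > abs(scores[0.9])
        assert abs(scores[1.0]) < 1e-6


class TestSerialization:
    def test_json_round_trip_is_bit_exact(self, rng):
        t = fit_transform(random_chips(rng, image_id="s"), random_chips(rng, image_id="t"))
        back = ColorTransform.from_json(t.to_json())
        assert back.as_matrix().tolist() == t.as_matrix().tolist()
        assert (back.source_image_id, back.target_image_id) == ("s", "t")

    def test_json_document_lists_design_columns(self, canonical_chips):
        doc = json.loads(fit_transform(canonical_chips, canonical_chips).to_json())
        assert doc["design_columns"][:3] == ["r", "g", "b"]
        assert len(doc["coefficients"]["R"]) == 9
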