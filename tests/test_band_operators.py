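"""Operator tests: smooth Heaviside, signed distance, edge map, dilation,
ground-truth narrow band — each against an exhaustive scalar-loop oracle."""

import numpy as np
import pytest

from nbac.autodiff import Tensor
from nbac.band_operators import (
    BandSpec,
    DegenerateBandWarning,
    DegenerateMaskError,
    InvalidParameterError,
    dilate_band,
    edge_extract,
    ground_truth_band,
    heaviside_smooth,
    signed_distance,
    transitional_gate,
)
from nbac.oracles import (
    dilate_bruteforce,
    edge_extract_loop,
    gt_band_bruteforce,
    heaviside_scalar,
    signed_distance_bruteforce,
)
from conftest import random_binary_mask


class TestHeaviside:
    def test_half_at_zero_and_three_quarters_at_epsilon(self):
        for eps in (0.1, 1.0, 7.5):
            assert heaviside_smooth(0.0, eps) == pytest.approx(0.5, abs=1e-15)
            assert heaviside_smooth(eps, eps) == pytest.approx(0.75, abs=1e-15)

    def test_matches_scalar_evaluation_on_grid(self):
        eps = 0.3
        xs = np.array([-10 * eps, -eps, 0.0, eps, 10 * eps])
        expected = np.array([heaviside_scalar(v, eps) for v in xs])
        np.testing.assert_allclose(heaviside_smooth(xs, eps), expected, atol=1e-12)

    def test_complement_symmetry(self, rng):
        x = rng.normal(0, 5, size=(11, 7))
        h = heaviside_smooth(x, 0.7)
        np.testing.assert_allclose(h + heaviside_smooth(-x, 0.7), 1.0, atol=1e-14)
        assert np.all((h > 0) & (h < 1))

    def test_monotone_and_tensor_path(self, rng):
        x = np.sort(rng.normal(size=32))
        h = heaviside_smooth(x, 0.5)
        assert np.all(np.diff(h) > 0)
        t = Tensor(x, requires_grad=True)
        ht = heaviside_smooth(t, 0.5)
        np.testing.assert_allclose(ht.data, h, atol=1e-14)
        ht.sum().backward()
        assert np.all(t.grad > 0)  # strictly increasing

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(InvalidParameterError):
            heaviside_smooth(np.zeros(3), 0.0)
        with pytest.raises(InvalidParameterError):
            heaviside_smooth(np.zeros(3), -1.0)


class TestSignedDistance:
    def test_sign_flip_under_complement(self, rng):
        m = random_binary_mask(rng, (9, 9))
        np.testing.assert_allclose(signed_distance(1 - m), -signed_distance(m))

    def test_centered_square_center_value(self):
        m = np.zeros((5, 5))
        m[1:4, 1:4] = 1
        ref = signed_distance_bruteforce(m)
        got = signed_distance(m)
        np.testing.assert_allclose(got, ref)
        assert got[2, 2] == ref[2, 2] > 0

    def test_single_pixel_four_neighbours(self):
        m = np.zeros((7, 7))
        m[3, 3] = 1
        ref = signed_distance_bruteforce(m)
        got = signed_distance(m)
        for i, j in ((2, 3), (4, 3), (3, 2), (3, 4)):
            assert got[i, j] == ref[i, j] == -1.0

    @pytest.mark.parametrize("shape", [(6, 6), (12, 12), (5, 9)])
    def test_matches_exhaustive_search(self, rng, shape):
        for _ in range(5):
            m = random_binary_mask(rng, shape)
            np.testing.assert_allclose(
                signed_distance(m), signed_distance_bruteforce(m), atol=1e-12
            )

    def test_degenerate_masks_rejected(self):
        with pytest.raises(DegenerateMaskError):
            signed_distance(np.zeros((4, 4)))
        with pytest.raises(DegenerateMaskError):
            signed_distance(np.ones((4, 4)))
        with pytest.raises(InvalidParameterError):
            signed_distance(np.full((4, 4), 0.5))


class TestEdgeExtract:
    def test_constant_field_gives_exact_zero(self):
        spec = BandSpec(B=3)
        assert np.all(edge_extract(np.full((8, 8), 3.7), spec) == 0.0)
        assert np.all(edge_extract(np.full((5, 5, 5), -1.2), spec) == 0.0)

    def test_square_mask_support_is_the_mixing_ring(self):
        """The edge map is positive exactly where a 3x3 neighbourhood mixes
        0s and 1s (enumerated per pixel)."""
        y = np.zeros((12, 12))
        y[3:8, 4:9] = 1
        out = edge_extract(y, BandSpec(B=3))
        yp = np.pad(y, 1, mode="edge")
        for i in range(12):
            for j in range(12):
                neigh = yp[i : i + 3, j : j + 3]
                mixes = neigh.min() != neigh.max()
                assert (out[i, j] > 0) == mixes, (i, j)

    def test_linear_ramp_interior_value(self):
        F = np.tile(np.arange(10.0), (10, 1))  # F(x, y) = y
        out = edge_extract(F, BandSpec(B=3))
        # interior response equals the central difference of a unit ramp
        np.testing.assert_allclose(out[2:-2, 2:-2], 1.0, atol=1e-12)

    @pytest.mark.parametrize("shape", [(9, 9), (16, 16), (5, 5, 5)])
    def test_matches_stencil_loop(self, rng, shape):
        F = rng.random(shape)
        np.testing.assert_allclose(
            edge_extract(F, BandSpec(B=3)), edge_extract_loop(F), atol=1e-12
        )

    def test_invariant_to_constant_offset(self, rng):
        F = rng.random((10, 10))
        spec = BandSpec(B=3)
        np.testing.assert_allclose(
            edge_extract(F, spec), edge_extract(F + 11.3, spec), atol=1e-12
        )

    def test_tensor_path_matches_numpy(self, rng):
        F = rng.random((8, 8))
        t = Tensor(F, requires_grad=True)
        out = edge_extract(t, BandSpec(B=3))
        np.testing.assert_allclose(out.data, edge_extract(F, BandSpec(B=3)), atol=1e-14)
        out.sum().backward()
        assert np.all(np.isfinite(t.grad))


class TestDilateBand:
    def test_identity_for_unit_window(self, rng):
        F = rng.random((7, 7))
        np.testing.assert_array_equal(dilate_band(F, BandSpec(B=1)), F)

    def test_single_pixel_becomes_block(self):
        F = np.zeros((9, 9))
        F[4, 4] = 2.5
        out = dilate_band(F, BandSpec(B=3))
        expected = np.zeros((9, 9))
        expected[3:6, 3:6] = 2.5
        np.testing.assert_array_equal(out, expected)

    @pytest.mark.parametrize("B", [3, 5])
    def test_matches_bruteforce_window_max(self, rng, B):
        for _ in range(5):
            F = rng.random((16, 16))
            np.testing.assert_array_equal(
                dilate_band(F, BandSpec(B=B)), dilate_bruteforce(F, B)
            )

    def test_bruteforce_match_in_3d(self, rng):
        F = rng.random((6, 6, 6))
        np.testing.assert_array_equal(
            dilate_band(F, BandSpec(B=3)), dilate_bruteforce(F, 3)
        )

    def test_monotone_and_extensive(self, rng):
        F = rng.random((12, 12))
        G = F + rng.random((12, 12))
        spec = BandSpec(B=5)
        dF, dG = dilate_band(F, spec), dilate_band(G, spec)
        assert np.all(dF >= F)
        assert np.all(dG >= dF)

    def test_tensor_path_matches_numpy(self, rng):
        F = rng.random((10, 10))
        t = Tensor(F, requires_grad=True)
        out = dilate_band(t, BandSpec(B=5))
        np.testing.assert_array_equal(out.data, dilate_band(F, BandSpec(B=5)))
        out.sum().backward()
        # gradient mass is conserved: each output pixel routes to one argmax
        assert t.grad.sum() == pytest.approx(100.0)

    def test_even_band_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            BandSpec(B=4)
        with pytest.raises(InvalidParameterError):
            BandSpec(B=0)


class TestGroundTruthBand:
    def test_constant_mask_yields_empty_flagged_band(self):
        with pytest.warns(DegenerateBandWarning):
            gtb = ground_truth_band(np.zeros((8, 8)), BandSpec(B=3))
        assert gtb.degenerate
        assert np.all(gtb.band == 0)

    def test_square_band_counts_match_bruteforce(self):
        y = np.zeros((32, 32))
        y[12:20, 12:20] = 1
        gtb = ground_truth_band(y, BandSpec(B=3))
        _, ind, inner, outer = gt_band_bruteforce(y, 3)
        assert inner.sum() == gtb.inner.sum() > 0
        assert outer.sum() == gtb.outer.sum() > 0
        np.testing.assert_array_equal(gtb.indicator, ind)

    def test_subbands_partition_the_band(self, rng):
        y = random_binary_mask(rng, (16, 16))
        gtb = ground_truth_band(y, BandSpec(B=5))
        assert not np.any(gtb.inner & gtb.outer)
        np.testing.assert_array_equal(gtb.inner | gtb.outer, gtb.indicator)
        # every edge pixel is covered
        edge = edge_extract(y, BandSpec(B=5)) > 0
        assert np.all(gtb.indicator[edge])


class TestTransitionalGate:
    def test_constant_input_gives_zero_maps(self):
        F_LC, F_LN = transitional_gate(np.full((10, 10), 4.2), BandSpec(B=5))
        assert np.all(F_LC == 0) and np.all(F_LN == 0)

    def test_band_map_dominates_contour_map(self, rng):
        F = rng.random((14, 14))
        F_LC, F_LN = transitional_gate(F, BandSpec(B=5))
        assert np.all(F_LN >= F_LC)

    @pytest.mark.parametrize("B", [3, 5, 7])
    def test_single_edge_band_support_width(self, B):
        """A step edge yields a band of width B + 1 along the normal: the
        edge response occupies the two columns astride the step and dilation
        widens it by B - 1 (measured by brute-force enumeration)."""
        F = np.zeros((16, 16))
        F[:, 8:] = 1.0
        _, F_LN = transitional_gate(F, BandSpec(B=B))
        ref = dilate_bruteforce(edge_extract_loop(F), B)
        np.testing.assert_allclose(F_LN, ref, atol=1e-12)
        widths = (F_LN[4:12] > 0).sum(axis=1)
        assert np.all(widths == B + 1)
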