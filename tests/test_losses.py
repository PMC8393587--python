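"""Loss tests: closed-form values, analytic reductions, scalar-loop oracle
agreement and finite-difference gradient checks."""

import numpy as np
import pytest

from nbac.autodiff import Tensor
from nbac.band_operators import BandSpec, DegenerateBandWarning, InvalidParameterError
from nbac import losses as L
from nbac import oracles as O
from conftest import random_binary_mask


def centred_square(shape=(16, 16), lo=5, hi=11):
    y = np.zeros(shape)
    y[lo:hi, lo:hi] = 1
    return y


class TestPixelwiseBaselines:
    def test_perfect_prediction_near_zero(self, rng):
        T = random_binary_mask(rng, (6, 6))
        assert L.ce_loss(T, T) <= -np.log(1 - 1e-7) + 1e-12
        assert L.dice_loss(T, T) == pytest.approx(0.0, abs=1e-6)
        assert L.focal_loss(T, T, L.FocalParams(1.0, 0.0)) <= 1e-6

    def test_uniform_half_probability_is_ln_two(self, rng):
        T = random_binary_mask(rng, (5, 5))
        assert L.ce_loss(np.full((5, 5), 0.5), T) == pytest.approx(np.log(2), rel=1e-12)

    def test_disjoint_dice_is_one(self):
        P = np.zeros((4, 4))
        P[:2] = 1
        T = np.zeros((4, 4))
        T[2:] = 1
        assert L.dice_loss(P, T) == pytest.approx(1.0, abs=1e-6)

    def test_focal_reduces_to_ce(self, rng):
        P, T = rng.random((7, 7)), random_binary_mask(rng, (7, 7))
        assert L.focal_loss(P, T, L.FocalParams(alpha=1.0, gamma=0.0)) == pytest.approx(
            L.ce_loss(P, T), abs=1e-12
        )

    def test_uniform_region_loss_is_ln_k(self, rng):
        for K in (2, 3, 5):
            T = np.zeros((K, 4, 4))
            labels = rng.integers(0, K, size=(4, 4))
            for c in range(K):
                T[c] = labels == c
            P = np.full((K, 4, 4), 1.0 / K)
            assert L.region_loss(P, T) == pytest.approx(np.log(K), rel=1e-12)

    def test_negative_focal_params_rejected(self):
        with pytest.raises(InvalidParameterError):
            L.FocalParams(alpha=-0.1)
        with pytest.raises(InvalidParameterError):
            L.FocalParams(gamma=-1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.ce_loss(np.zeros((3, 3)), np.zeros((4, 4)))

    @pytest.mark.parametrize(
        "loss,oracle",
        [
            (L.ce_loss, O.ce_loop),
            (L.dice_loss, O.dice_loop),
        ],
    )
    def test_matches_scalar_loop(self, rng, loss, oracle):
        for _ in range(10):
            P = rng.random((4, 4))
            T = random_binary_mask(rng, (4, 4), require_both=False)
            assert loss(P, T) == pytest.approx(oracle(P, T), abs=1e-9)

    def test_focal_matches_scalar_loop(self, rng):
        fp = L.FocalParams(alpha=0.25, gamma=2.0)
        for _ in range(10):
            P = rng.random((4, 4))
            T = random_binary_mask(rng, (4, 4), require_both=False)
            assert L.focal_loss(P, T, fp) == pytest.approx(O.focal_loop(P, T, fp), abs=1e-9)

    def test_region_matches_scalar_loop(self, rng):
        for _ in range(10):
            raw = rng.random((3, 4, 4))
            P = raw / raw.sum(axis=0)
            labels = rng.integers(0, 3, size=(4, 4))
            T = np.stack([(labels == c).astype(float) for c in range(3)])
            assert L.region_loss(P, T) == pytest.approx(O.region_loop(P, T), abs=1e-9)


class TestBandDescriptors:
    def test_constant_prediction(self, rng):
        y = centred_square()
        band = __import__("nbac.band_operators", fromlist=["ground_truth_band"]).ground_truth_band(
            y, BandSpec(B=3)
        )
        p = np.full((16, 16), 0.37)
        for mode in L.BAND_MODES:
            d = L.band_descriptors(p, band, mode)
            assert d.b_in == pytest.approx(0.37) and d.b_out == pytest.approx(0.37)

    def test_hard_prediction_two_sided(self):
        from nbac.band_operators import ground_truth_band

        y = centred_square()
        band = ground_truth_band(y, BandSpec(B=3))
        d = L.band_descriptors(y, band, "two_sided")
        assert d.b_in == 1.0 and d.b_out == 0.0

    def test_weighted_descriptors_match_loop(self, rng):
        y = centred_square()
        p = rng.random((16, 16))
        for mode in L.BAND_MODES:
            from nbac.band_operators import ground_truth_band

            band = ground_truth_band(y, BandSpec(B=3))
            d = L.band_descriptors(p, band, mode)
            b_in, b_out = O.band_descriptors_loop(p, y, 3, mode)
            assert d.b_in == pytest.approx(b_in, abs=1e-9)
            assert d.b_out == pytest.approx(b_out, abs=1e-9)

    def test_conservation_in_band_vs_complement(self, rng):
        """|band| * b_in + |complement| * b_out recovers sum(p) exactly."""
        from nbac.band_operators import ground_truth_band

        y = centred_square()
        p = rng.random((16, 16))
        band = ground_truth_band(y, BandSpec(B=3))
        d = L.band_descriptors(p, band, "band_vs_complement")
        F = band.band
        lhs = F.sum() * d.b_in + (1 - F).sum() * d.b_out
        assert lhs == pytest.approx(p.sum(), rel=1e-12)

    def test_empty_domain_raises(self):
        from nbac.band_operators import GroundTruthBand

        empty = GroundTruthBand(
            np.zeros((4, 4)), np.zeros((4, 4), bool), np.zeros((4, 4), bool),
            np.zeros((4, 4), bool), True,
        )
        with pytest.raises(L.DegenerateBandError):
            L.band_descriptors(np.zeros((4, 4)), empty, "two_sided")


class TestNBACBandLoss:
    spec = BandSpec(B=3)

    def test_all_zero_inputs_gated_domain_mode(self):
        y = centred_square()
        z = np.zeros((16, 16))
        w = L.NBACWeights(band_mode="gated_domain")
        assert L.nbac_band_loss(z, z, z, y, self.spec, w) == pytest.approx(0.0, abs=1e-12)

    def test_constant_prediction_zero_energy(self):
        y = centred_square()
        p = np.full((16, 16), 0.4)
        z = np.zeros((16, 16))
        for mode in ("two_sided", "band_vs_complement"):
            w = L.NBACWeights(mu=0.0, band_mode=mode)
            assert L.nbac_band_loss(p, z, z, y, self.spec, w) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("mode", L.BAND_MODES)
    def test_matches_bruteforce_oracle(self, rng, mode):
        y = centred_square()
        for _ in range(5):
            p = rng.random((16, 16))
            flc = rng.random((16, 16))
            fln = rng.random((16, 16))
            w = L.NBACWeights(mu=0.7, lambda_in=1.3, lambda_out=0.9, band_mode=mode)
            got = L.nbac_band_loss(p, flc, fln, y, self.spec, w)
            ref = O.nbac_band_loss_loop(p, flc, fln, y, 3, w)
            assert got == pytest.approx(ref, abs=1e-9)

    def test_degenerate_band_skips_energy(self):
        z = np.zeros((8, 8))
        flc = np.ones((8, 8))
        with pytest.warns(DegenerateBandWarning):
            out = L.nbac_band_loss(z, flc, z, z, self.spec, L.NBACWeights(mu=2.0))
        assert out == pytest.approx(2.0)  # only the length term survives

    def test_negative_weights_rejected(self):
        with pytest.raises(InvalidParameterError):
            L.NBACWeights(mu=-1.0)
        with pytest.raises(InvalidParameterError):
            L.NBACWeights(lambda_in=-0.5)

    def test_total_loss_combination(self):
        assert L.nbac_total_loss(2.0, 4.0) == pytest.approx(3.0)
        assert L.nbac_total_loss(0.0, 0.0) == 0.0
        w = L.NBACWeights(branch_region=1.0, branch_band=0.0)
        assert L.nbac_total_loss(5.0, 123.0, w) == 5.0
        # linearity
        w2 = L.NBACWeights(branch_region=0.3, branch_band=0.6)
        assert L.nbac_total_loss(1.0, 2.0, w2) + L.nbac_total_loss(3.0, 4.0, w2) == pytest.approx(
            L.nbac_total_loss(4.0, 6.0, w2)
        )


class TestOscLoss:
    def test_reduces_to_region_loss(self, rng):
        raw = rng.random((3, 8, 8))
        P = raw / raw.sum(axis=0)
        labels = rng.integers(0, 3, size=(8, 8))
        T = np.stack([(labels == c).astype(float) for c in range(3)])
        params = L.OscParams(alpha=1.0, beta=0.0, eta=0.0)
        assert L.osc_loss(P, T, params) == pytest.approx(L.region_loss(P, T), abs=1e-12)

    def test_constant_prediction_has_zero_band_variance(self):
        y = centred_square((12, 12), 4, 8)
        T = np.stack([1 - y, y])
        P = np.stack([np.full((12, 12), 0.6), np.full((12, 12), 0.4)])
        full = L.osc_loss(P, T, L.OscParams(alpha=0.0, beta=1.0, eta=0.0, B=3))
        # with a constant prediction both descriptors equal p, so L2 = 0
        assert full == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        y = centred_square((12, 12), 4, 8)
        T = np.stack([1 - y, y])
        params = L.OscParams(B=3, alpha=0.8, beta=1.1, eta=0.5, epsilon=1.0)
        for _ in range(3):
            raw = rng.random((2, 12, 12))
            P = raw / raw.sum(axis=0)
            got = L.osc_loss(P, T, params)
            ref = O.osc_loss_loop(P, T, params)
            assert got == pytest.approx(ref, abs=1e-9)


class TestChanVese:
    def test_piecewise_constant_fit_is_zero(self):
        phi = np.fromfunction(lambda i, j: 3.5 - i, (8, 8))
        I = np.where(phi > 0, 0.8, 0.2)
        params = L.ChanVeseParams(mu=0.0, nu=0.0)
        assert L.chan_vese_energy(I, phi, params) == pytest.approx(0.0, abs=1e-12)

    def test_area_term_counts_inside_pixels(self):
        phi = np.ones((8, 8))
        phi[0, 0] = -1.0
        I = np.zeros((8, 8))
        params = L.ChanVeseParams(lambda1=0.0, lambda2=0.0, mu=0.0, nu=2.0)
        assert L.chan_vese_energy(I, phi, params) == pytest.approx(2.0 * 63)

    def test_matches_scalar_loop(self, rng):
        params = L.ChanVeseParams(lambda1=1.2, lambda2=0.8, mu=0.5, nu=0.3)
        for _ in range(5):
            I = rng.random((10, 10))
            phi = rng.normal(size=(10, 10))
            assert L.chan_vese_energy(I, phi, params) == pytest.approx(
                O.chan_vese_loop(I, phi, params), abs=1e-9
            )

    def test_one_sided_level_set_rejected(self):
        with pytest.raises(L.DegenerateBandError.__bases__[0]):
            L.chan_vese_energy(np.zeros((4, 4)), np.ones((4, 4)))


def _fd_gradient(f, p0, h=1e-6):
    g = np.zeros_like(p0)
    for idx in np.ndindex(p0.shape):
        p = p0.copy()
        p[idx] = p0[idx] + h
        fp = f(p)
        p[idx] = p0[idx] - h
        fm = f(p)
        g[idx] = (fp - fm) / (2 * h)
    return g


class TestGradients:
    spec = BandSpec(B=3)

    @pytest.mark.parametrize("mode", L.BAND_MODES)
    def test_band_loss_gradient_matches_finite_differences(self, rng, mode):
        from nbac.band_operators import ground_truth_band

        y = centred_square((8, 8), 2, 6)
        p0 = rng.random((8, 8))
        flc = rng.random((8, 8))
        fln = rng.random((8, 8))
        w = L.NBACWeights(mu=0.4, band_mode=mode)
        band = ground_truth_band(y, self.spec)
        desc = L.band_descriptors(p0, band, mode)  # pinned for both paths

        t = Tensor(p0, requires_grad=True)
        loss = L.nbac_band_loss(t, flc, fln, y, self.spec, w, descriptors=desc)
        loss.backward()
        fd = _fd_gradient(
            lambda p: L.nbac_band_loss(p, flc, fln, y, self.spec, w, descriptors=desc),
            p0,
        )
        denom = max(np.abs(fd).max(), 1e-8)
        assert np.abs(t.grad - fd).max() / denom < 1e-4

    def test_osc_gradient_matches_finite_differences(self, rng):
        from nbac.band_operators import ground_truth_band

        y = centred_square((8, 8), 2, 6)
        T = np.stack([1 - y, y])
        raw = rng.uniform(0.1, 0.9, size=(2, 8, 8))
        P0 = raw / raw.sum(axis=0)
        params = L.OscParams(B=3, alpha=0.5, beta=1.0, eta=0.3)
        band = ground_truth_band(y, BandSpec(B=3))
        desc = {1: L.band_descriptors(P0[1], band, "two_sided")}  # pinned

        t = Tensor(P0, requires_grad=True)
        L.osc_loss(t, T, params, descriptors=desc).backward()
        fd = _fd_gradient(lambda P: L.osc_loss(P, T, params, descriptors=desc), P0)
        denom = max(np.abs(fd).max(), 1e-8)
        assert np.abs(t.grad - fd).max() / denom < 1e-4

    def test_gradient_of_contour_length_reaches_edge_map(self, rng):
        y = centred_square((8, 8), 2, 6)
        p = rng.random((8, 8))
        flc = Tensor(rng.random((8, 8)), requires_grad=True)
        fln = rng.random((8, 8))
        loss = L.nbac_band_loss(p, flc, fln, y, self.spec, L.NBACWeights(mu=1.0))
        loss.backward()
        assert np.abs(flc.grad).max() > 0
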