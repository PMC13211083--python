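"""Tests for the spectral downsampler, DFT utilities, HA/MFI blocks and
the SSAFF neck.

The FTD block is checked against a direct-DFT reference implementation
(explicit double sums, no np.fft, independent shift/crop mechanics).
"""

import numpy as np
import pytest

from addetr import nn
from addetr.encoder import (
    AIFI,
    FTD,
    BaselineNeck,
    HABlock,
    IdentityNeck,
    MFIBlock,
    RepConv,
    SSAFFNeck,
    complete_half_spectrum,
    dft2,
    freq_conv_oracle,
    ftd_downsample,
    ha_block,
    idft2,
    rdft2_half,
)
from addetr.nn import Tensor

from test_nn import check_param_grads


def direct_circular_conv(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Brute-force circular convolution by the double sum."""
    H, W = x.shape
    out = np.zeros_like(x, dtype=float)
    for n in range(H):
        for m in range(W):
            acc = 0.0
            for i in range(H):
                for j in range(W):
                    acc += x[i, j] * w[(n - i) % H, (m - j) % W]
            out[n, m] = acc
    return out


def direct_truncated_resample(x: np.ndarray) -> np.ndarray:
    """Independent reference for identity-filter FTD: explicit double-sum
    DFT, keep frequencies in [-H/4, H/4) x [-W/4, W/4), explicit inverse
    on the half-size grid with DC-preserving normalization."""
    H, W = x.shape
    H2, W2 = H // 2, W // 2
    n, m = np.arange(H), np.arange(W)
    X = np.zeros((H, W), dtype=complex)
    for k1 in range(H):
        for k2 in range(W):
            X[k1, k2] = np.sum(x * np.exp(-2j * np.pi * (k1 * n[:, None] / H + k2 * m[None, :] / W)))
    y = np.zeros((H2, W2), dtype=complex)
    for np_ in range(H2):
        for mp in range(W2):
            for f1 in range(-H2 // 2, H2 // 2):
                for f2 in range(-W2 // 2, W2 // 2):
                    y[np_, mp] += X[f1 % H, f2 % W] * np.exp(
                        2j * np.pi * (f1 * np_ / H2 + f2 * mp / W2))
    return (y / (H * W)).real


class TestDFTUtilities:
    def test_constant_input_has_only_dc(self):
        X = dft2(np.full((8, 8), 3.25))
        assert X[0, 0] == pytest.approx(3.25)
        X[0, 0] = 0
        assert np.max(np.abs(X)) < 1e-12

    def test_inversion_identity(self, rng):
        x = rng.normal(size=(8, 8))
        np.testing.assert_allclose(idft2(dft2(x)), x, atol=1e-9)

    def test_single_cosine_two_conjugate_bins(self):
        N = 8
        n = np.arange(N)
        x = np.cos(2 * np.pi * 2 * n / N)[None, :] * np.ones((N, 1))
        X = dft2(x)
        nz = np.argwhere(np.abs(X) > 1e-9)
        assert len(nz) == 2
        (a1, a2), (b1, b2) = nz
        assert (a1, a2) == (0, 2) and (b1, b2) == (0, 6)
        assert X[0, 2] == pytest.approx(np.conj(X[0, 6]))

    def test_half_spectrum_completion_is_real_consistent(self, rng):
        x = rng.normal(size=(6, 8))
        full = complete_half_spectrum(rdft2_half(x), 8)
        np.testing.assert_allclose(full, dft2(x), atol=1e-12)
        np.testing.assert_allclose(idft2(full), x, atol=1e-9)


class TestConvolutionTheorem:
    def test_delta_kernel_is_identity(self, rng):
        x = rng.normal(size=(8, 8))
        w = np.zeros((8, 8))
        w[0, 0] = 1.0
        np.testing.assert_allclose(freq_conv_oracle(x, w), x, atol=1e-9)

    def test_shifted_delta_circularly_shifts(self, rng):
        x = rng.normal(size=(8, 8))
        w = np.zeros((8, 8))
        w[2, 3] = 1.0
        np.testing.assert_allclose(freq_conv_oracle(x, w), np.roll(x, (2, 3), axis=(0, 1)),
                                   atol=1e-9)

    def test_matches_direct_double_sum(self, rng):
        for _ in range(3):
            x = rng.normal(size=(8, 8))
            w = rng.normal(size=(8, 8))
            np.testing.assert_allclose(freq_conv_oracle(x, w), direct_circular_conv(x, w),
                                       atol=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            freq_conv_oracle(np.zeros((8, 8)), np.zeros((4, 4)))


class TestFTD:
    def test_halves_spatial_dims(self):
        ftd = FTD(32)
        out = ftd(Tensor(np.random.default_rng(0).normal(size=(1, 32, 64, 64))))
        assert out.shape == (1, 32, 32, 32)

    def test_constant_preserved_with_identity_filter(self):
        out = ftd_downsample(np.full((1, 3, 16, 16), 2.5))
        np.testing.assert_allclose(out, 2.5, atol=1e-9)

    def test_matches_direct_dft_reference(self, rng):
        x = rng.normal(size=(8, 8))
        out = ftd_downsample(x[None, None])[0, 0]
        np.testing.assert_allclose(out, direct_truncated_resample(x), atol=1e-6)

    def test_band_limited_sinusoid_resampled_exactly(self):
        N = 16
        n = np.arange(N)
        x = np.cos(2 * np.pi * 3 * n / N)[None, :] * np.ones((N, 1))  # f=3 < N/4
        out = ftd_downsample(x[None, None])[0, 0]
        n2 = np.arange(N // 2)
        expected = np.cos(2 * np.pi * 3 * n2 / (N // 2))[None, :] * np.ones((N // 2, 1))
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_above_nyquist_energy_removed(self):
        """A tone above the new Nyquist is erased by spectral truncation
        (zero aliased energy), whereas strided subsampling folds it down."""
        N = 16
        f = 6                                     # N/4 <= f < N/2
        n = np.arange(N)
        x = np.cos(2 * np.pi * f * n / N)[None, :] * np.ones((N, 1))
        out = ftd_downsample(x[None, None])[0, 0]
        spec = np.abs(dft2(out))
        assert np.max(spec) < 1e-9                # no energy anywhere, aliased bin included
        strided = x[::2, ::2]
        alias_bin = np.abs(dft2(strided))[0, (N // 2) - f]
        assert alias_bin > 0.1

    def test_linearity_with_identity_filter(self, rng):
        x = rng.normal(size=(1, 2, 8, 8))
        y = rng.normal(size=(1, 2, 8, 8))
        lhs = ftd_downsample(2.0 * x - 3.0 * y)
        rhs = 2.0 * ftd_downsample(x) - 3.0 * ftd_downsample(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            ftd_downsample(np.zeros((1, 1, 7, 8)))

    def test_gradients_match_finite_differences(self, rng):
        ftd = FTD(2)
        x = Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
        ftd(x)  # materialize the filter for this size
        wr, wi = ftd.filters_real[0], ftd.filters_imag[0]
        wr.data = rng.normal(size=wr.data.shape)
        wi.data = rng.normal(size=wi.data.shape)
        target = rng.normal(size=(1, 2, 2, 2))
        check_param_grads(lambda: (((ftd(x) - target) ** 2)).sum(), [x, wr, wi])


class TestHA:
    def test_identity_configuration_is_identity(self, rng):
        f = Tensor(rng.normal(size=(2, 6, 8, 8)))
        out = ha_block(f, np.zeros(6), 4, np.eye(6), sim_override=1.0)
        np.testing.assert_allclose(out.data, f.data, atol=1e-6)

    def test_orthogonal_patch_fully_suppressed(self):
        # one patch whose descriptor is orthogonal to xi -> sim = 0
        f = np.zeros((1, 2, 4, 4))
        f[0, 0, :2, :2] = 1.0      # patch (0,0): descriptor (1, 0)
        f[0, 1, 2:, 2:] = 1.0      # patch (1,1): descriptor (0, 1)
        xi = np.array([0.0, 1.0])
        out = ha_block(Tensor(f), xi, 2, np.eye(2)).data
        assert np.max(np.abs(out[0, :, :2, :2])) < 1e-12   # suppressed
        np.testing.assert_allclose(out[0, 1, 2:, 2:], 1.0)  # aligned, sim = 1

    def test_sim_scores_clamped_to_unit_interval(self, rng):
        # with P = I the output/input ratio per patch equals the score
        f = rng.uniform(0.5, 1.5, size=(1, 3, 8, 8))
        xi = rng.normal(size=3)
        out = ha_block(Tensor(f), xi, 4, np.eye(3)).data
        ratio = out / f
        assert np.all(ratio >= -1e-12) and np.all(ratio <= 1.0 + 1e-12)

    def test_patch_count_and_divisibility(self, rng):
        ha = HABlock(4, 4, rng)
        out = ha(Tensor(rng.normal(size=(1, 4, 64, 64))))
        assert out.shape == (1, 4, 64, 64)       # N = 64*64/16 = 256 patches, lossless tiling
        with pytest.raises(ValueError):
            ha(Tensor(np.zeros((1, 4, 6, 6))))

    def test_gradients_reach_xi_and_P(self, rng):
        ha = HABlock(3, 2, rng)
        f = Tensor(rng.normal(size=(1, 3, 4, 4)), requires_grad=True)
        loss = (ha(f) ** 2).sum()
        loss.backward()
        assert ha.xi.grad is not None and np.all(np.isfinite(ha.xi.grad))
        assert ha.P.grad is not None and np.all(np.isfinite(ha.P.grad))
        assert f.grad is not None and np.all(np.isfinite(f.grad))


class TestRepConvAndMFI:
    def test_repconv_fuse_equivalence(self, rng):
        rep = RepConv(5, 5, rng)
        # advance running stats with a few training batches
        for _ in range(3):
            rep(Tensor(rng.normal(size=(2, 5, 6, 6))))
        rep.eval()
        x = Tensor(rng.normal(size=(2, 5, 6, 6)))
        train_out = rep(x).data
        rep.fuse()
        np.testing.assert_allclose(rep(x).data, train_out, atol=1e-5)

    def test_mfi_contract_and_gradients(self, rng):
        mfi = MFIBlock(6, 8, 10, rng, p_sizes=(4, 2))
        f1 = Tensor(rng.normal(size=(1, 6, 8, 8)))
        f2 = Tensor(rng.normal(size=(1, 8, 8, 8)))
        out = mfi(f1, f2)
        assert out.shape == (1, 10, 8, 8)
        (out ** 2).sum().backward()
        for p in mfi.parameters():
            assert p.grad is None or np.all(np.isfinite(p.grad))
        grads = [p for p in mfi.parameters() if p.grad is not None]
        assert len(grads) > 10

    def test_mfi_spatial_mismatch_raises(self, rng):
        mfi = MFIBlock(4, 4, 4, rng)
        with pytest.raises(ValueError):
            mfi(Tensor(np.zeros((1, 4, 8, 8))), Tensor(np.zeros((1, 4, 4, 4))))


class TestNecks:
    def _pyramid(self, rng, c=(6, 8, 10), hw=16):
        return {
            8: Tensor(rng.normal(size=(1, c[0], hw, hw))),
            16: Tensor(rng.normal(size=(1, c[1], hw // 2, hw // 2))),
            32: Tensor(rng.normal(size=(1, c[2], hw // 4, hw // 4))),
        }

    def test_ssaff_preserves_strides(self, rng):
        neck = SSAFFNeck((6, 8, 10), 8, rng)
        out = neck(self._pyramid(rng))
        assert out[8].shape == (1, 8, 16, 16)
        assert out[16].shape == (1, 8, 8, 8)
        assert out[32].shape == (1, 8, 4, 4)

    def test_ftd_edge_halves_resolution(self, rng):
        neck = SSAFFNeck((4, 4, 4), 8, rng)
        p3 = Tensor(rng.normal(size=(1, 8, 16, 16)))
        assert neck.ftd3(p3).shape == (1, 8, 8, 8)

    def test_baseline_and_identity_necks_runnable(self, rng):
        pyr = self._pyramid(rng)
        base = BaselineNeck((6, 8, 10), 8, rng)(pyr)
        ident = IdentityNeck((6, 8, 10), 8, rng)(pyr)
        for out in (base, ident):
            assert set(out) == {8, 16, 32}
            for v in out.values():
                assert np.all(np.isfinite(v.data))

    def test_aifi_shape_preserved(self, rng):
        aifi = AIFI(8, 2, rng)
        x = Tensor(rng.normal(size=(2, 8, 4, 4)))
        assert aifi(x).shape == (2, 8, 4, 4)
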