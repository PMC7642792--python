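"""Shell geometry, band-pass filtering, prewhitening, masked correlation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mfscres as m


class TestRadiusGrid:
    def test_anchors(self):
        r = m.frequency_radius_grid(16)
        assert r[0, 0, 0] == 0.0
        assert r[8, 0, 0] == 8.0          # Nyquist along an axis
        assert r[3, 4, 0] == pytest.approx(5.0)   # 3-4-5 triangle

    @pytest.mark.parametrize("n", [16, 32])
    def test_width1_shells_partition_lattice(self, n):
        covered = np.zeros((n, n, n), dtype=int)
        r = m.frequency_radius_grid(n)
        for k in range(1, n // 2 + 1):
            covered += m.rectangular_shell_mask(n, k, 1.0)
        covered[0, 0, 0] += 1  # origin belongs to no shell
        inside = r <= n // 2 - 0.5
        assert (covered[inside] == 1).all()
        assert covered.max() == 1


class TestGaussianBandpass:
    def test_unit_gain_at_band_center(self):
        n, k = 32, 6
        x = np.arange(n)
        wave = np.cos(2 * np.pi * k * x / n)
        vol = m.Volume(np.broadcast_to(wave, (n, n, n)).copy())
        out = m.gaussian_bandpass(vol, m.ShellSpec(k=k, width=1.0))
        assert np.allclose(out.data, vol.data, atol=1e-6 * np.abs(vol.data).max())

    def test_gain_three_sigma_off_center(self):
        n, k, sigma = 64, 10, 1.0
        x = np.arange(n)
        wave = np.cos(2 * np.pi * k * x / n)
        vol = m.Volume(np.broadcast_to(wave, (n, n, n)).copy())
        out = m.gaussian_bandpass(vol, m.ShellSpec(k=k + 3, width=sigma))
        ratio = np.abs(out.data).max() / np.abs(vol.data).max()
        assert ratio == pytest.approx(np.exp(-4.5), rel=1e-4)

    def test_white_noise_output_power_follows_gain_squared(self):
        n, k, sigma = 64, 12, 2.0
        rng = np.random.default_rng(3)
        vol = m.Volume(rng.normal(size=(n, n, n)))
        out = m.gaussian_bandpass(vol, m.ShellSpec(k=k, width=sigma))
        prof = m.power_spectrum_profile(out).values[1:]
        ks = np.arange(1, prof.size + 1)
        expected = np.exp(-((ks - k) ** 2) / sigma**2)  # G squared
        band = np.abs(ks - k) <= 4
        ratio = prof[band] / prof[band].max()
        assert np.allclose(ratio, expected[band] / expected[band].max(),
                           atol=0.12)

    def test_output_is_real_and_range_checked(self):
        vol = m.Volume(np.random.default_rng(0).normal(size=(16,) * 3))
        with pytest.raises(ValueError):
            m.gaussian_bandpass(vol, m.ShellSpec(k=9, width=1.0))


class TestMaskedCorrelation:
    def test_identity_and_sign_flip(self):
        rng = np.random.default_rng(1)
        a = m.Volume(rng.normal(size=(16,) * 3))
        mask = m.make_mask(16, "box", side=9)
        assert m.masked_correlation(a, a, mask) == pytest.approx(1.0)
        b = m.Volume(-a.data)
        assert m.masked_correlation(a, b, mask) == pytest.approx(-1.0)

    def test_independent_noise_bound(self):
        # |r| <= 4/sqrt(N) holds with overwhelming probability
        n = 24
        mask = m.Mask(np.ones((n,) * 3))
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            a = m.Volume(rng.normal(size=(n,) * 3))
            b = m.Volume(rng.normal(size=(n,) * 3))
            if abs(m.masked_correlation(a, b, mask)) <= 4 / np.sqrt(n**3):
                hits += 1
        assert hits >= 29

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance_and_antisymmetry(self, alpha, beta):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(16,) * 3)
        b = rng.normal(size=(16,) * 3)
        sel = np.zeros((16,) * 3, bool)
        sel[4:12, 4:12, 4:12] = True
        r0 = m.masked_correlation(a, b, sel)
        r1 = m.masked_correlation(a, alpha * b + beta, sel)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert m.masked_correlation(a, -b, sel) == pytest.approx(-r0, abs=1e-9)

    def test_degenerate_constant_input_returns_zero_with_warning(self):
        a = m.Volume(np.zeros((16,) * 3))
        b = m.Volume(np.random.default_rng(0).normal(size=(16,) * 3))
        mask = m.make_mask(16, "box", side=5)
        with pytest.warns(UserWarning, match="degenerate"):
            assert m.masked_correlation(a, b, mask) == 0.0

    def test_empty_mask_raises(self):
        a = m.Volume(np.ones((16,) * 3))
        with pytest.raises(m.EmptyMaskError):
            m.masked_correlation(a, a, np.zeros((16,) * 3, bool))


class TestPrewhiten:
    def test_colored_noise_flattened(self):
        n = 48
        rng = np.random.default_rng(5)
        vol = m.Volume(rng.normal(size=(n,) * 3))
        # color with a 1/r amplitude falloff
        r = np.maximum(m.frequency_radius_grid(n), 1.0)
        colored = np.fft.ifftn(np.fft.fftn(vol.data) / r).real
        out = m.prewhiten(m.Volume(colored))
        prof = m.power_spectrum_profile(out).values[1: n // 2 + 1]
        assert np.allclose(prof, 1.0, rtol=1e-6)

    def test_white_input_stays_flat(self):
        vol = m.Volume(np.random.default_rng(6).normal(size=(32,) * 3))
        out = m.prewhiten(vol)
        prof = m.power_spectrum_profile(out).values[1:17]
        assert np.allclose(prof, 1.0, rtol=1e-6)

    def test_zero_power_shell_raises_with_index(self):
        n = 32
        x = np.arange(n)
        wave = np.cos(2 * np.pi * 5 * x / n)  # single shell only
        vol = m.Volume(np.broadcast_to(wave, (n,) * 3).copy())
        with pytest.raises(m.spectral.ZeroPowerShellError, match=r"\d"):
            m.prewhiten(vol)


class TestRotationalAverage:
    def test_constant_volume_flat_profile(self):
        prof = m.rotational_average_real(m.Volume(np.full((32,) * 3, 2.5)))
        assert np.allclose(prof.values[: 16], 2.5)

    def test_gaussian_blob_matches_closed_form(self):
        n, sigma = 48, 6.0
        ax = np.arange(n) - n // 2
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        r2 = z**2 + y**2 + x**2
        vol = m.Volume(np.exp(-r2 / (2 * sigma**2)))
        prof = m.rotational_average_real(vol).values
        rr = np.arange(prof.size)
        expected = np.exp(-(rr**2) / (2 * sigma**2))
        assert np.allclose(prof[:18], expected[:18], atol=0.02)

    def test_solvent_noise_higher_outside_structure(self):
        # difference of half-maps with extra solvent noise: radial profile of
        # the squared noise is higher outside the phantom support
        phantom = m.make_phantom(
            64, "blob-ensemble", seed=2, placement_radius=0.15 * 64
        )
        u, v = m.make_half_pair(
            phantom, np.ones(32), seed=3, solvent_noise_factor=1.5
        )
        e = (u.data - v.data) / 2
        prof = m.rotational_average_real(e**2).values
        inner = prof[1:7].mean()     # center, covered by the blob support
        outer = prof[22:30].mean()   # solvent
        assert outer > inner
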