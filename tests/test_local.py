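"""Local (moving-box), segment-focused and helical resolution."""

import numpy as np
import pytest
from scipy import ndimage

import mfscres as m

N = 64


def _uniform_pair(n=N, k1=12, seed=30):
    """Spatially stationary pair, noise-free to shell k1, nothing beyond."""
    ks = np.arange(1, n // 2 + 1)
    profile = np.where(ks <= k1, np.inf, 0.0)
    phantom = m.make_phantom(n, "shell-limited", seed=seed, k1=n // 2)
    return m.make_half_pair(phantom, profile, seed=seed + 1)


class TestBoxCorrelation:
    def test_matches_masked_correlation_at_interior_centers(self):
        from mfscres.local import _box_corr_volume

        rng = np.random.default_rng(0)
        a = rng.normal(size=(24,) * 3)
        b = a + rng.normal(size=(24,) * 3)
        side = 7
        corr = _box_corr_volume(a, b, side)
        for center in [(12, 12, 12), (8, 14, 10), (5, 5, 18)]:
            box = m.make_mask(24, "box", side=side, center=center)
            ref = m.masked_correlation(a, b, box)
            assert corr[center] == pytest.approx(ref, abs=1e-10)


class TestLocalResolutionMap:
    def test_uniform_ssnr_gives_uniform_map(self):
        k1 = 12
        u, v = _uniform_pair(k1=k1)
        region = m.make_mask(N, "sphere", diameter=0.4 * N)
        lmap = m.local_resolution_map(
            u, v, region, box_side=15, stride=4, sigma_g=3.0
        )
        vals = lmap.data[lmap.region_mask & (lmap.data > 0)]
        assert vals.size > 0
        k_eff = N * u.pixel_size / vals
        # local estimates cluster within two shells of the band limit
        frac_close = np.mean(np.abs(k_eff - k1) <= 2)
        assert frac_close >= 0.9

    def test_two_compartment_phantom_is_bimodal(self):
        # inner region band-limited to k_in, outer to k_out < k_in; the
        # Gaussian window diffuses each estimate by about 2 sigma_g shells
        n = N
        k_in, k_out, sigma_g = 14, 6, 2.0
        ax = np.arange(n)
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        c = n // 2
        r = np.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2)
        inner = r <= 0.17 * n
        outer = (r > 0.24 * n) & (r <= 0.40 * n)
        kb = m.shell_index_grid(n)

        def bandlimit(d, k1):
            f = np.fft.fftn(d)
            f[kb > k1] = 0
            return np.fft.ifftn(f).real

        def compartment(seed, k1, weight):
            # alternating projections: (nearly) band-limited AND compact
            s = bandlimit(np.random.default_rng(seed).normal(size=(n,) * 3), k1)
            for _ in range(10):
                s = bandlimit(s * weight, k1)
            return s / s.std()

        w_in = ndimage.gaussian_filter(inner.astype(float), 2.0)
        w_out = ndimage.gaussian_filter(outer.astype(float), 2.0)
        signal = compartment(1, k_in, w_in) + compartment(2, k_out, w_out)
        noise = 0.8 * signal.std()
        u = m.Volume(signal + np.random.default_rng(50).normal(scale=noise,
                                                               size=(n,) * 3))
        v = m.Volume(signal + np.random.default_rng(51).normal(scale=noise,
                                                               size=(n,) * 3))
        region = m.Mask((inner | outer).astype(float))
        lmap = m.local_resolution_map(u, v, region, box_side=11, stride=4,
                                      sigma_g=sigma_g)
        k_eff = np.zeros_like(lmap.data)
        good = lmap.data > 0
        k_eff[good] = n / lmap.data[good]
        # erode compartments so boxes do not straddle the boundary
        inner_core = ndimage.binary_erosion(inner, iterations=5) & good
        outer_core = ndimage.binary_erosion(outer, iterations=5) & good
        tol = 2 * sigma_g + 1
        med_in = np.median(k_eff[inner_core])
        med_out = np.median(k_eff[outer_core])
        assert abs(med_in - k_in) <= tol
        assert abs(med_out - k_out) <= tol
        assert med_in - med_out >= (k_in - k_out) / 2

    def test_pure_noise_mostly_sentinel(self):
        n = 48
        phantom = m.make_phantom(n, "shell-limited", seed=50, k1=n // 2)
        region = m.make_mask(n, "sphere", diameter=0.4 * n)
        fractions = []
        for seed in range(5):
            u, v = m.make_half_pair(phantom, np.zeros(n // 2), seed=800 + seed)
            lmap = m.local_resolution_map(u, v, region, box_side=11, stride=4)
            evaluated = lmap.region_mask
            fractions.append(
                np.count_nonzero(lmap.data[evaluated] > 0)
                / np.count_nonzero(evaluated)
            )
        assert np.mean(fractions) <= 0.05

    def test_box_must_fit(self):
        u, v = _uniform_pair(n=32, k1=8, seed=60)
        region = m.make_mask(32, "sphere", diameter=10)
        with pytest.raises(ValueError):
            m.local_resolution_map(u, v, region, box_side=33)
        with pytest.raises(ValueError):
            m.local_resolution_map(u, v, region, box_side=8)  # even


class TestSegments:
    def test_identical_ssnr_segments_agree(self):
        u, v = _uniform_pair(k1=10, seed=70)
        labels = np.zeros((N,) * 3, dtype=int)
        labels[14:28, 14:28, 14:28] = 1
        labels[36:50, 36:50, 36:50] = 2
        segs = m.SegmentSet(labels)
        out = m.segment_resolution(u, v, segs, sigma_g=3.0)
        k1_, k2_ = out[1][0].k_star, out[2][0].k_star
        assert abs(k1_ - k2_) <= 1

    def test_union_segment_curve_lies_between(self):
        u, v = _uniform_pair(k1=10, seed=71)
        labels = np.zeros((N,) * 3, dtype=int)
        labels[16:26, 16:26, 16:26] = 1
        labels[38:48, 38:48, 38:48] = 2
        union = np.zeros((N,) * 3, dtype=int)
        union[(labels == 1) | (labels == 2)] = 3
        segs = m.SegmentSet(labels)
        seg_union = m.SegmentSet(union)
        out = m.segment_resolution(u, v, segs, sigma_g=3.0, k_max=12)
        out_u = m.segment_resolution(u, v, seg_union, sigma_g=3.0, k_max=12)
        lo = np.minimum(out[1][1].value, out[2][1].value)
        hi = np.maximum(out[1][1].value, out[2][1].value)
        mid = out_u[3][1].value
        low_k = slice(0, 8)
        assert (mid[low_k] >= lo[low_k] - 0.1).all()
        assert (mid[low_k] <= hi[low_k] + 0.1).all()

    def test_single_voxel_segment_unresolvable(self):
        u, v = _uniform_pair(k1=10, seed=72)
        labels = np.zeros((N,) * 3, dtype=int)
        labels[32, 32, 32] = 1
        with pytest.warns(UserWarning, match="voxel"):
            out = m.segment_resolution(u, v, m.SegmentSet(labels))
        assert not out[1][0].resolved


class TestHelical:
    def test_disk_geometry_from_rise_and_pixel(self):
        params = m.HelicalParams(rise=5.13, pixel_size=1.24, n_disks=8,
                                 radius=37)
        assert params.disk_height_pixels == pytest.approx(4.14, abs=0.005)
        mask, meta = m.helical_disk_mask(params, 256)
        assert meta.mask_height_pixels == 33
        assert meta.n_disks == 8

    def test_minimal_cylinder_count_brute_force(self):
        params = m.HelicalParams(rise=3.0, pixel_size=1.0, n_disks=1, radius=2)
        mask, meta = m.helical_disk_mask(params, 16, pixel_size=1.0)
        assert meta.mask_height_pixels == 3
        ref = m.make_mask(16, "cylinder", radius=2, height=3)
        assert mask.count == ref.count

    def _helical_pair(self, k1=10, seed=80):
        phantom = m.make_phantom(
            N, "helical", seed=seed, rise=8.0, pixel_size=1.0, radius=14,
            k1=N // 2,
        )
        ks = np.arange(1, N // 2 + 1)
        profile = np.where(ks <= k1, 50.0, 0.0)
        u, v = m.make_half_pair(phantom, profile, seed=seed + 1)
        return u, v

    def test_band_limited_filament_resolution(self):
        k1 = 10
        u, v = self._helical_pair(k1=k1)
        params = m.HelicalParams(rise=8.0, pixel_size=1.0, n_disks=3, radius=14)
        res, _ = m.helical_resolution(u, v, params)
        assert abs(res.k_star - k1) <= 1

    def test_invariant_to_disk_count(self):
        u, v = self._helical_pair(k1=10, seed=90)
        k_stars = []
        for nd in (2, 4, 6):
            params = m.HelicalParams(rise=8.0, pixel_size=1.0, n_disks=nd,
                                     radius=14)
            res, _ = m.helical_resolution(u, v, params)
            k_stars.append(res.k_star)
        assert max(k_stars) - min(k_stars) <= 1

    def test_ndf_unchanged_when_disks_double(self):
        # voxel count and divisor double together
        for nd in (2, 4):
            params = m.HelicalParams(rise=8.0, pixel_size=1.0, n_disks=nd,
                                     radius=10)
            mask, _ = m.helical_disk_mask(params, N, pixel_size=1.0)
            model = m.NdfModel(sigma_g=1.0, mask_fraction=mask.fraction,
                               disk_divisor=nd)
            if nd == 2:
                base = m.ndf_masked(10, model)
            else:
                assert m.ndf_masked(10, model) == pytest.approx(base, rel=1e-9)

    def test_noise_filament_unresolvable(self):
        phantom = m.make_phantom(N, "helical", seed=95, rise=8.0,
                                 pixel_size=1.0, radius=14)
        u, v = m.make_half_pair(phantom, np.zeros(N // 2), seed=96)
        params = m.HelicalParams(rise=8.0, pixel_size=1.0, n_disks=4, radius=14)
        res, _ = m.helical_resolution(u, v, params)
        assert not res.resolved
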