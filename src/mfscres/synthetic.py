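"""Synthetic phantoms, masks and half-map pairs with controlled SSNR.

Half-map pairs follow the image-formation model u = f + r₁, v = f + r₂: a
shared band-limited signal plus two independent Gaussian noise fields.  The
noise is shaped per width-1 Fourier shell against the phantom's *measured*
shell power, so the expected unmasked FSC at shell k equals exactly
φ(k) = ssnr(k)/(1 + ssnr(k)) for any phantom.  An optional extra
solvent-only noise term emulates real reconstructions, where noise outside
the particle is stronger than within it.

These generators emulate the spectral statistics of cryo-EM half-maps; they
do not model CTF, projection geometry or alignment error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Mask, Volume
from .spectral import shell_index_grid


def ssnr_from_fsc(phi: np.ndarray) -> np.ndarray:
    """Per-shell SSNR implied by a target FSC profile (∞ where φ = 1)."""
    phi = np.asarray(phi, dtype=float)
    if ((phi < 0) | (phi > 1)).any():
        raise ValueError("FSC profile must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        return np.where(phi < 1, phi / (1.0 - phi), np.inf)


def fsc_from_ssnr(ssnr: np.ndarray) -> np.ndarray:
    """Expected FSC from a per-shell SSNR profile: ssnr/(1 + ssnr)."""
    ssnr = np.asarray(ssnr, dtype=float)
    if (ssnr < 0).any():
        raise ValueError("SSNR must be nonnegative")
    with np.errstate(invalid="ignore"):
        return np.where(np.isinf(ssnr), 1.0, ssnr / (1.0 + ssnr))


@dataclass
class Phantom:
    """A noise-free signal volume plus its ground-truth support mask."""

    volume: Volume
    support: Mask
    kind: str
    seed: int
    band_limit: int | None = None      # shells beyond this carry no power
    helical: dict | None = None        # rise/radius metadata for filaments


def _ball(n: int, center, radius: float) -> np.ndarray:
    ax = np.arange(n)
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    cz, cy, cx = center
    return (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= radius**2


def _band_limit(data: np.ndarray, k1: int) -> np.ndarray:
    ft = np.fft.fftn(data)
    ft[shell_index_grid(data.shape[0]) > k1] = 0.0
    return np.fft.ifftn(ft).real


def make_phantom(n: int, kind: str, seed: int = 0, **options) -> Phantom:
    """Build a deterministic test phantom.

    kinds
    -----
    ``blob-ensemble``
        Sum of randomly placed Gaussian blobs inside a sphere; options
        ``n_blobs`` (12), ``blob_sigma`` (0.055·n), ``placement_radius``
        (0.3·n).  Support is the union of balls of radius 2·blob_sigma.
    ``shell-limited``
        Gaussian random field with power only at shells k ≤ ``k1``
        (required option); support is the full volume.
    ``helical``
        A disk-shaped random motif repeated along z with period
        ``rise`` / ``pixel_size`` voxels inside a cylinder of ``radius``
        voxels; optionally band-limited at ``k1``.
    """
    if n < 32 or n % 2:
        raise ValueError(f"n must be even and >= 32, got {n}")
    rng = np.random.default_rng(seed)
    pixel_size = float(options.get("pixel_size", 1.0))

    if kind == "blob-ensemble":
        n_blobs = int(options.get("n_blobs", 12))
        blob_sigma = float(options.get("blob_sigma", 0.055 * n))
        placement_radius = float(options.get("placement_radius", 0.3 * n))
        c = n / 2
        data = np.zeros((n, n, n))
        support = np.zeros((n, n, n), dtype=bool)
        ax = np.arange(n)
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        for _ in range(n_blobs):
            while True:
                pos = rng.uniform(-placement_radius, placement_radius, 3)
                if np.linalg.norm(pos) <= placement_radius:
                    break
            amp = rng.uniform(0.5, 1.5)
            cz, cy, cx = c + pos
            r2 = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2
            data += amp * np.exp(-r2 / (2 * blob_sigma**2))
            support |= r2 <= (2 * blob_sigma) ** 2
        data[~support] = 0.0
        return Phantom(
            Volume(data, pixel_size), Mask(support.astype(float), pixel_size),
            kind, seed,
        )

    if kind == "shell-limited":
        if "k1" not in options:
            raise ValueError("shell-limited phantom requires option k1")
        k1 = int(options["k1"])
        if not 1 <= k1 <= n // 2:
            raise ValueError(f"k1={k1} outside 1..{n // 2}")
        data = _band_limit(rng.normal(size=(n, n, n)), k1)
        support = np.ones((n, n, n))
        return Phantom(
            Volume(data, pixel_size), Mask(support, pixel_size),
            kind, seed, band_limit=k1,
        )

    if kind == "helical":
        rise = float(options.get("rise", 5.0))
        radius = float(options.get("radius", 0.3 * n))
        k1 = options.get("k1")
        period = rise / pixel_size
        c = n / 2
        ax = np.arange(n)
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        rad2 = (y - c) ** 2 + (x - c) ** 2
        # smooth random motif as a function of (phase along z, x, y)
        motif = rng.normal(size=(n, n))
        motif = ndimage.gaussian_filter(motif, 2.0, mode="wrap")
        phase_gain = 0.5 * (1.0 + np.cos(2 * np.pi * z / period))  # period = rise/p
        cyl = rad2 <= radius**2
        data = phase_gain * motif[np.newaxis, :, :] * cyl
        if k1 is not None:
            data = _band_limit(data, int(k1))
            k1 = int(k1)
        support = np.broadcast_to(cyl, (n, n, n)).astype(float)
        return Phantom(
            Volume(data, pixel_size), Mask(support, pixel_size),
            kind, seed, band_limit=k1,
            helical={"rise": rise, "radius": radius},
        )

    raise ValueError(f"unknown phantom kind {kind!r}")


def make_half_pair(
    phantom: Phantom,
    profile: np.ndarray,
    seed: int = 0,
    solvent_noise_factor: float = 0.0,
    background: float = 0.0,
) -> tuple[Volume, Volume]:
    """Two half-maps sharing the phantom's signal, noise shaped per shell.

    ``profile`` is the target per-shell SSNR for k = 1..n/2 (∞ allowed for
    noise-free shells).  Noise power at shell k is set so the expected FSC
    equals ssnr/(1 + ssnr) against the phantom's measured shell power.  At
    shells with zero target SSNR the shared signal is removed outright (a
    correlation of exactly zero cannot be reached by adding finite noise)
    and the noise level defaults to the phantom's mean in-band power, so
    the curve drops into the null band there.

    ``solvent_noise_factor`` adds extra white noise outside the support,
    scaled relative to the in-structure noise sigma — real half-map
    difference volumes show elevated solvent noise.

    ``background`` adds the same constant offset to both half-maps, in
    units of the noise standard deviation.  Reconstructed density maps sit
    on a shared solvent level rather than on zero; it is this shared
    background that a tight multiplicative mask imprints on both maps and
    that the classical FSC then reads as common signal.  The offset lives
    at DC only, so unmasked FSC/mFSC curves (shells k >= 1) are unaffected.
    """
    n = phantom.volume.n
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (n // 2,):
        raise ValueError(
            f"profile must have length n/2 = {n // 2}, got {profile.shape}"
        )
    if (profile < 0).any():
        raise ValueError("SSNR profile must be nonnegative")

    ft = np.fft.fftn(phantom.volume.data)
    kbin = shell_index_grid(n)
    nbins = int(kbin.max()) + 1
    psum = np.bincount(kbin.ravel(), weights=(np.abs(ft) ** 2).ravel(),
                       minlength=nbins)
    cnt = np.bincount(kbin.ravel(), minlength=nbins)
    pf = np.divide(psum, cnt, out=np.zeros(nbins), where=cnt > 0)

    phi = fsc_from_ssnr(profile)
    # zero-power shells up to float residue of the band-limiting FFT
    in_band = pf[1: n // 2 + 1] > 1e-12 * pf[1: n // 2 + 1].max()
    bad = np.nonzero((profile > 0) & ~in_band)[0] + 1
    if bad.size:
        raise ValueError(
            f"phantom has zero power at shell(s) {bad.tolist()} where a "
            "positive SSNR was requested"
        )
    base = pf[1: n // 2 + 1][in_band].mean() if in_band.any() else 1.0

    # per-shell target noise power (per Fourier coefficient) and the
    # per-shell retention factor of the shared signal
    pn = np.zeros(nbins)
    keep = np.ones(nbins)
    for i in range(n // 2):
        k = i + 1
        if phi[i] >= 1.0:
            pn[k] = 0.0
        elif phi[i] <= 0.0:
            pn[k] = base
            keep[k] = 0.0
        else:
            pn[k] = pf[k] * (1.0 - phi[i]) / phi[i]
    pn[n // 2 + 1:] = base   # corner shells beyond Nyquist
    keep[n // 2 + 1:] = 0.0
    pn[0] = 0.0

    if (keep != 1.0).any():
        ft = ft * keep[kbin]
    signal = np.fft.ifftn(ft).real if (keep != 1.0).any() else phantom.volume.data

    # real white noise has E|FT|² = n³ per coefficient; scale amplitudes
    amp = np.sqrt(pn / n**3)[kbin]
    rng = np.random.default_rng(seed)
    halves = []
    for _ in range(2):
        noise = np.fft.ifftn(np.fft.fftn(rng.normal(size=(n, n, n))) * amp).real
        if solvent_noise_factor > 0:
            outside = ~phantom.support.boolean()
            noise = noise + (solvent_noise_factor * np.std(noise)
                             * rng.normal(size=(n, n, n)) * outside)
        halves.append(Volume(signal + noise, phantom.volume.pixel_size))
    if background != 0.0:
        sigma = float(np.std(halves[0].data - signal))
        for h in halves:
            h.data += background * sigma
    return halves[0], halves[1]


def make_mask(n: int, kind: str, pixel_size: float = 1.0, **options) -> Mask:
    """Build an analysis mask.

    kinds: ``sphere`` (binary ball, option ``diameter``, default 0.7·n),
    ``soft-sphere`` (cosine fall-off over ``edge_width`` voxels, default 5),
    ``blob-support`` (a phantom's support, optionally ``dilate``-d),
    ``cylinder`` (``radius``, ``height``, axis z, centered), and
    ``box`` (cube of ``side`` voxels at ``center``, default volume center).
    """
    if n < 8 or n % 2:
        raise ValueError(f"n must be even and >= 8, got {n}")
    c = n / 2
    ax = np.arange(n)

    if kind == "sphere":
        diameter = float(options.get("diameter", 0.7 * n))
        data = _ball(n, (c, c, c), diameter / 2).astype(float)
    elif kind == "soft-sphere":
        diameter = float(options.get("diameter", 0.7 * n))
        edge = float(options.get("edge_width", 5.0))
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        r = np.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2)
        r0 = diameter / 2 - edge / 2   # full weight inside, cosine edge
        data = np.clip((r - r0) / edge, 0.0, 1.0)
        data = 0.5 * (1.0 + np.cos(np.pi * data))
    elif kind == "blob-support":
        phantom: Phantom = options["phantom"]
        data = phantom.support.data.copy()
        dilate = int(options.get("dilate", 0))
        if dilate > 0:
            data = ndimage.binary_dilation(
                data > 0.5, iterations=dilate
            ).astype(float)
        pixel_size = phantom.volume.pixel_size
    elif kind == "cylinder":
        radius = float(options["radius"])
        height = int(options["height"])
        if height > n or radius > c:
            raise ValueError("cylinder does not fit inside the volume")
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        rad = (y - c) ** 2 + (x - c) ** 2 <= radius**2
        z0 = n // 2 - height // 2
        slab = (z >= z0) & (z < z0 + height)
        data = (rad & slab).astype(float)
    elif kind == "box":
        side = int(options["side"])
        if side > n:
            raise ValueError("box does not fit inside the volume")
        center = options.get("center", (n // 2, n // 2, n // 2))
        data = np.zeros((n, n, n))
        half = side // 2
        sl = tuple(slice(int(ci) - half, int(ci) - half + side) for ci in center)
        if any(s.start < 0 or s.stop > n for s in sl):
            raise ValueError("box exceeds the volume at this center")
        data[sl] = 1.0
    else:
        raise ValueError(f"unknown mask kind {kind!r}")

    if not data.any():
        raise ValueError(f"mask of kind {kind!r} came out empty")
    return Mask(data, pixel_size=pixel_size)
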