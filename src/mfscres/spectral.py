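"""Fourier-domain machinery shared by the FSC/mFSC calculations.

Shell geometry, Gaussian band-pass filtering, rotational averages,
prewhitening and the masked real-space correlation coefficient.  All
reciprocal-space quantities live on the unshifted FFT lattice (origin at
index [0,0,0]); radii are measured in Fourier pixels, related to spatial
frequency by s = k/n.  The DC term (k = 0) is excluded from every shell,
filter and normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import EmptyMaskError, Mask, Volume


@dataclass(frozen=True)
class ShellSpec:
    """A reciprocal-space window: a shell at Fourier-pixel radius ``k``.

    ``kind`` selects between the rectangular (binary, classical FSC) window
    and the Gaussian band-pass used by the mFSC; ``width`` is the rectangular
    shell width, or sigma_g, in Fourier pixels.
    """

    k: int
    kind: str = "gaussian"
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("rectangular", "gaussian"):
            raise ValueError(f"unknown shell kind {self.kind!r}")
        if self.k < 1:
            raise ValueError(f"shell index must be >= 1, got {self.k}")
        if self.width <= 0:
            raise ValueError(f"shell width must be > 0, got {self.width}")


@dataclass
class SpectralProfile:
    """A 1D radial profile of a named spectral quantity, indexed by shell."""

    values: np.ndarray
    meaning: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@lru_cache(maxsize=8)
def _radius_grid_cached(n: int) -> np.ndarray:
    f = np.fft.fftfreq(n) * n  # signed Fourier-pixel coordinates
    fz, fy, fx = np.meshgrid(f, f, f, indexing="ij", sparse=True)
    r = np.sqrt(fz**2 + fy**2 + fx**2)
    r.flags.writeable = False
    return r


def frequency_radius_grid(n: int) -> np.ndarray:
    """Euclidean distance to the Fourier-space origin, in Fourier pixels.

    Laid out to match ``numpy.fft.fftn`` output (origin at [0,0,0]).
    """
    if n % 2:
        raise ValueError(f"n must be even, got {n}")
    return _radius_grid_cached(n)


def shell_index_grid(n: int) -> np.ndarray:
    """Width-1 shell membership: each lattice point's nearest integer radius.

    Point s belongs to shell k iff k - 1/2 <= ||s|| < k + 1/2, so consecutive
    width-1 shells partition the lattice.  Indices run past n/2 in the cube
    corners; callers normally use shells 1..n/2 only.
    """
    return np.floor(frequency_radius_grid(n) + 0.5).astype(np.intp)


def rectangular_shell_mask(n: int, k: int, width: float = 1.0) -> np.ndarray:
    """Boolean selector of lattice points with k - w/2 <= r < k + w/2."""
    if not 1 <= k <= n // 2:
        raise ValueError(f"shell index k={k} outside 1..{n // 2}")
    r = frequency_radius_grid(n)
    return (r >= k - width / 2) & (r < k + width / 2)


def gaussian_shell_gain(n: int, k: float, sigma_g: float) -> np.ndarray:
    """Amplitude gain exp(-(r - k)²/(2 σ_g²)) of the Gaussian shell filter.

    The gain is applied to amplitudes (not squared); the DC term is zeroed.
    """
    if sigma_g <= 0:
        raise ValueError(f"sigma_g must be > 0, got {sigma_g}")
    r = frequency_radius_grid(n)
    g = np.exp(-((r - k) ** 2) / (2.0 * sigma_g**2))
    g = g.copy()
    g[0, 0, 0] = 0.0
    return g


def bandpass_ft(ft: np.ndarray, k: float, sigma_g: float) -> np.ndarray:
    """Band-pass an already-computed FFT around shell ``k``; returns a real
    volume.  Workhorse for curve computations that reuse one FFT per map."""
    n = ft.shape[0]
    out = np.fft.ifftn(ft * gaussian_shell_gain(n, k, sigma_g))
    return np.ascontiguousarray(out.real)


def gaussian_bandpass(v: Volume, shell: ShellSpec) -> Volume:
    """Gaussian band-pass of a volume around a Fourier shell.

    The filter is radially symmetric, so Friedel symmetry — and hence the
    realness of the output — is preserved exactly up to float rounding.
    """
    if shell.kind != "gaussian":
        raise ValueError("gaussian_bandpass requires a gaussian ShellSpec")
    if not 1 <= shell.k <= v.n // 2:
        raise ValueError(f"shell index k={shell.k} outside 1..{v.n // 2}")
    data = bandpass_ft(np.fft.fftn(v.data), shell.k, shell.width)
    return Volume(data, pixel_size=v.pixel_size)


def masked_correlation(
    a: Volume | np.ndarray,
    b: Volume | np.ndarray,
    m: Mask | np.ndarray,
    subtract_mean: bool = True,
) -> float:
    """Pearson-type correlation of two volumes over a binary mask's support.

    This is the real-space inner-product correlation restricted to the
    voxels where the mask is 1.  Restricting the support only removes terms
    from the sums; unlike multiplicative masking before an FFT it cannot
    correlate independent data.

    By construction the correlation assumes zero-mean arguments; a
    band-passed volume restricted to a sub-region generally is not, so the
    within-mask mean of each argument is removed by default
    (``subtract_mean=False`` restores the raw normalized inner product).

    Returns 0 with a warning when either argument is constant on the mask.
    """
    av = a.data if isinstance(a, Volume) else np.asarray(a)
    bv = b.data if isinstance(b, Volume) else np.asarray(b)
    sel = m.boolean() if isinstance(m, Mask) else np.asarray(m, bool)
    if not sel.any():
        raise EmptyMaskError("masked correlation over an empty mask")
    x = av[sel]
    y = bv[sel]
    if x.size < 2:
        raise ValueError("mask support must contain at least 2 voxels")
    if subtract_mean:
        x = x - x.mean()
        y = y - y.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        warnings.warn("degenerate (zero-variance) input to masked_correlation")
        return 0.0
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def prewhiten(v: Volume) -> Volume:
    """Flatten the rotationally averaged power spectrum.

    Divides the FT by the per-shell root-mean-square amplitude, so every
    width-1 shell of the output has unit mean power.  The DC term is left
    unchanged.  Shells 1..n/2 must all carry power; a dead shell raises with
    its index.  (Corner shells beyond Nyquist are normalized too when they
    carry power, and passed through otherwise.)
    """
    n = v.n
    ft = np.fft.fftn(v.data)
    kbin = shell_index_grid(n)
    power = np.abs(ft) ** 2
    nbins = int(kbin.max()) + 1
    sums = np.bincount(kbin.ravel(), weights=power.ravel(), minlength=nbins)
    counts = np.bincount(kbin.ravel(), minlength=nbins)
    mean_power = np.divide(sums, counts, out=np.zeros(nbins), where=counts > 0)
    # "zero power" relative to the strongest shell: float rounding of an FFT
    # leaves ~1e-30 of residue in analytically empty shells
    tiny = 1e-12 * mean_power[1: n // 2 + 1].max()
    dead = [k for k in range(1, n // 2 + 1) if mean_power[k] <= tiny]
    if dead:
        raise ZeroPowerShellError(
            f"cannot prewhiten: zero power in shell(s) {dead}"
        )
    scale = np.ones(nbins)
    ok = mean_power > tiny
    scale[ok] = 1.0 / np.sqrt(mean_power[ok])
    scale[0] = 1.0  # DC untouched
    out = np.fft.ifftn(ft * scale[kbin]).real
    return Volume(out, pixel_size=v.pixel_size)


class ZeroPowerShellError(ValueError):
    """A Fourier shell with identically zero power cannot be normalized."""


def power_spectrum_profile(v: Volume | np.ndarray) -> SpectralProfile:
    """Rotational average of the power spectrum over shells k = 0..n/2."""
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    n = data.shape[0]
    ft = np.fft.fftn(data)
    kbin = shell_index_grid(n)
    power = np.abs(ft) ** 2
    nbins = int(kbin.max()) + 1
    sums = np.bincount(kbin.ravel(), weights=power.ravel(), minlength=nbins)
    counts = np.bincount(kbin.ravel(), minlength=nbins)
    prof = np.divide(sums, counts, out=np.zeros(nbins), where=counts > 0)
    return SpectralProfile(prof[: n // 2 + 1], meaning="rotationally averaged power spectrum")


def rotational_average_real(v: Volume | np.ndarray) -> SpectralProfile:
    """Rotational average of voxel values about the volume center.

    Radial bins are one voxel wide, centered on index n/2 along each axis.
    Useful as a diagnostic of solvent-vs-structure noise levels in a
    half-map difference volume.
    """
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    n = data.shape[0]
    ax = np.arange(n) - n // 2
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    r = np.sqrt(z**2 + y**2 + x**2)
    rbin = np.floor(r + 0.5).astype(np.intp)
    nbins = int(rbin.max()) + 1
    sums = np.bincount(rbin.ravel(), weights=data.ravel(), minlength=nbins)
    counts = np.bincount(rbin.ravel(), minlength=nbins)
    prof = np.divide(sums, counts, out=np.zeros(nbins), where=counts > 0)
    return SpectralProfile(prof, meaning="real-space rotational average")
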