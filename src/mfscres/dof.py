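"""Per-shell degrees of freedom (ndf) for FSC/mFSC significance testing.

The ndf is the effective number of independent samples entering a shell's
correlation estimate.  For a width-1 rectangular shell it is the shell's
lattice-point count, well approximated by the sphere-surface continuum form
4πk².  The Gaussian window of the mFSC spreads over several shells; a
Monte-Carlo PCA experiment (see :func:`mc_ndf_gaussian_window`) shows its
effective thickness is about 3σ_g, giving ndf ≈ 4πk²·3σ_g.  A binary mask
retains only a fraction |m|/n³ of real-space samples, and for a helical map
only one disk in ``disk_divisor`` is statistically unique, so the masked ndf
is scaled by mask_fraction / disk_divisor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import shell_index_grid

#: Fisher z variance is 1/(ndf - 3); anything at or below 3 is uninformative.
NDF_FLOOR = 4.0

#: Effective thickness (in shells) of a unit-σ Gaussian window, from the
#: Monte-Carlo PCA calibration (ndf ≅ 3 σ_g).
GAUSSIAN_NDF_PER_SIGMA = 3.0


@dataclass(frozen=True)
class NdfModel:
    """Parameters of the closed-form ndf model for a masked mFSC."""

    sigma_g: float = 1.0
    n: int | None = None
    mask_fraction: float = 1.0
    disk_divisor: int = 1

    def __post_init__(self) -> None:
        if self.sigma_g <= 0:
            raise ValueError("sigma_g must be > 0")
        if not 0 < self.mask_fraction <= 1:
            raise ValueError("mask_fraction must be in (0, 1]")
        if self.disk_divisor < 1:
            raise ValueError("disk_divisor must be >= 1")

    def ndf(self, k) -> np.ndarray | float:
        """Vectorized masked ndf at shell index/indices ``k``."""
        k = np.asarray(k, dtype=float)
        raw = (4.0 * np.pi * k**2 * GAUSSIAN_NDF_PER_SIGMA * self.sigma_g
               * self.mask_fraction / self.disk_divisor)
        out = np.maximum(raw, NDF_FLOOR)
        return float(out) if out.ndim == 0 else out


def ndf_rectangular(k: int | np.ndarray) -> float | np.ndarray:
    """Continuum lattice count of a width-1 shell: 4πk²."""
    k = np.asarray(k, dtype=float)
    out = 4.0 * np.pi * k**2
    return float(out) if out.ndim == 0 else out


def shell_voxel_count(n: int, k: int, width: float = 1.0) -> int:
    """Exact lattice-point count of a rectangular shell (brute force).

    Available as the discrete alternative to the continuum 4πk² form.
    """
    kbin = shell_index_grid(n)
    if width == 1.0:
        return int(np.count_nonzero(kbin == k))
    from .spectral import rectangular_shell_mask

    return int(np.count_nonzero(rectangular_shell_mask(n, k, width)))


def ndf_gaussian(k: int | np.ndarray, model: NdfModel | float = 1.0) -> float | np.ndarray:
    """Unmasked mFSC ndf with a Gaussian window: 4πk² · 3σ_g.

    ``model`` may be an :class:`NdfModel` or σ_g directly.  With σ_g = 1
    this runs from ≅ 1000 at k = 5 to ≅ 1.5 million at k = 200.
    """
    sigma = model.sigma_g if isinstance(model, NdfModel) else float(model)
    if sigma <= 0:
        raise ValueError("sigma_g must be > 0")
    k = np.asarray(k, dtype=float)
    out = 4.0 * np.pi * k**2 * GAUSSIAN_NDF_PER_SIGMA * sigma
    return float(out) if out.ndim == 0 else out


def ndf_masked(k: int | np.ndarray, model: NdfModel) -> float | np.ndarray:
    """Masked (and optionally helical) ndf, floored at :data:`NDF_FLOOR`.

    Scales the Gaussian-window ndf by the mask fraction |m|/n³ and divides
    by the number of symmetry-redundant helical disks.  The floor keeps the
    Fisher variance finite: a microscopic mask then degrades to an
    uninformative (very wide) confidence interval instead of crashing.
    """
    raw = ndf_gaussian(k, model) * model.mask_fraction / model.disk_divisor
    raw = np.asarray(raw)
    if (raw < NDF_FLOOR).any():
        warnings.warn(
            f"ndf below floor {NDF_FLOOR} for some shells; mask too small "
            "to be informative there"
        )
    out = np.maximum(raw, NDF_FLOOR)
    return float(out) if out.ndim == 0 else out


@dataclass
class McNdfResult:
    """Outcome of the Monte-Carlo PCA ndf estimate for a Gaussian window."""

    ndf_estimate: int
    sigma_g: float
    array_length: int
    iterations: int
    seed: int
    warning: str | None = None


def mc_ndf_gaussian_window(
    array_length: int,
    sigma_g: float,
    iterations: int = 10_000,
    seed: int = 0,
    batch: int = 2_000,
) -> McNdfResult:
    """Monte-Carlo PCA estimate of the ndf induced by a Gaussian window.

    Procedure: repeatedly (i) draw an N(0,1) array, (ii) multiply by a
    Gaussian window of width σ_g centered mid-array, (iii) accumulate the
    outer-product covariance ``c``, (iv) shuffle the entries and accumulate
    the shuffled covariance ``d`` as a randomization control.  After all
    iterations, both matrices are eigendecomposed and the estimate is the
    highest rank at which an eigenvalue of ``c`` still exceeds the
    rank-matched eigenvalue of ``d`` — shuffling destroys the window's
    structure but preserves the marginal noise, so ranks beyond the estimate
    are indistinguishable from noise.

    Accumulation is batched (``c += X.T @ X`` over blocks of iterations),
    which is algebraically identical to per-iteration outer products.
    Bit-reproducible for a fixed seed.
    """
    if array_length < 8 * sigma_g:
        warnings.warn(
            f"array_length={array_length} < 8*sigma_g: the window is "
            "effectively flat and the estimate saturates at the array length"
        )
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    idx = np.arange(array_length)
    window = np.exp(-((idx - array_length / 2) ** 2) / (2.0 * sigma_g**2))
    c = np.zeros((array_length, array_length))
    d = np.zeros((array_length, array_length))
    done = 0
    while done < iterations:
        b = min(batch, iterations - done)
        done += b
        x = rng.normal(size=(b, array_length)) * window
        c += x.T @ x
        xs = rng.permuted(x, axis=1)
        d += xs.T @ xs
    eig_c = np.sort(np.linalg.eigvalsh(c))[::-1]
    eig_d = np.sort(np.linalg.eigvalsh(d))[::-1]
    above = eig_c > eig_d
    exceed = np.nonzero(above)[0]
    estimate = int(exceed.max()) + 1 if exceed.size else 1
    warning = None
    if iterations < 1_000:
        warning = (
            f"{iterations} iterations may be too few for stable "
            "eigenvalue ordering"
        )
        warnings.warn(warning)
    return McNdfResult(
        ndf_estimate=estimate,
        sigma_g=float(sigma_g),
        array_length=int(array_length),
        iterations=int(iterations),
        seed=int(seed),
        warning=warning,
    )
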