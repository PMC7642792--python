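"""FSC, mFSC and SSNR curves.

The classical FSC correlates the Fourier transforms of the (optionally
mask-multiplied) half-maps shell by shell.  The mFSC band-passes each
half-map around a shell first and correlates in real space under a binary
mask, which eliminates mask-convolution artifacts at the cost of two 3D FFTs
per shell.  Correlations map to spectral SNR by SSNR = |c| / (1 - |c|).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Mask, Volume
from .spectral import (
    ShellSpec,
    bandpass_ft,
    masked_correlation,
    rectangular_shell_mask,
    shell_index_grid,
)


@dataclass
class ResolutionCurve:
    """Per-shell correlation values of an FSC-family curve.

    Shell indices ``k`` run 1..k_max (Fourier pixels); spatial frequency is
    k/(n·p) in 1/Å and the corresponding resolution n·p/k in Å.
    """

    k: np.ndarray
    value: np.ndarray
    method: str                      # "fsc" | "mfsc"
    shell: ShellSpec
    n: int
    pixel_size: float
    mask_count: int | None = None    # |m| of the binary mask, if masked

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.intp)
        self.value = np.asarray(self.value, dtype=np.float64)
        if self.k.shape != self.value.shape:
            raise ValueError("k and value must be aligned")
        if self.value.size and (np.abs(self.value) > 1 + 1e-9).any():
            raise ValueError("curve values must lie in [-1, 1]")
        self.value = np.clip(self.value, -1.0, 1.0)

    @property
    def k_max(self) -> int:
        return int(self.k[-1]) if self.k.size else 0

    @property
    def spatial_frequency(self) -> np.ndarray:
        """Spatial frequency per shell, 1/Å."""
        return self.k / (self.n * self.pixel_size)

    @property
    def resolution_per_shell(self) -> np.ndarray:
        """Nominal resolution per shell, Å (n·p/k)."""
        return self.n * self.pixel_size / self.k


@dataclass
class SsnrCurve:
    """Per-shell spectral signal-to-noise ratio."""

    k: np.ndarray
    ssnr: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.intp)
        self.ssnr = np.asarray(self.ssnr, dtype=np.float64)
        if (self.ssnr < 0).any():
            raise ValueError("SSNR must be nonnegative")


def snr_from_correlation(c: float) -> float:
    """SNR implied by a correlation coefficient: |c| / (1 - |c|).

    The absolute value makes the SNR nonnegative for anticorrelated inputs
    (identical volumes with opposite contrast).  |c| >= 1 returns inf with a
    warning.  The mapping is sharply nonlinear: c = 0.143 gives SNR ≈ 0.17,
    c = 0.5 gives 1, and only c = 0.91 reaches SNR = 10.
    """
    a = abs(float(c))
    if a >= 1.0:
        warnings.warn("correlation magnitude >= 1 implies infinite SNR")
        return float("inf")
    return a / (1.0 - a)


def ssnr_curve(curve: ResolutionCurve) -> SsnrCurve:
    """Element-wise correlation-to-SNR conversion of a resolution curve."""
    ssnr = np.array([snr_from_correlation(v) for v in curve.value])
    return SsnrCurve(k=curve.k.copy(), ssnr=ssnr)


def _default_k_max(n: int, k_max: int | None) -> int:
    # Nyquist shell (k = n/2) is only partially sampled; stop one short.
    if k_max is None:
        return n // 2 - 1
    if not 1 <= k_max <= n // 2:
        raise ValueError(f"k_max={k_max} outside 1..{n // 2}")
    return int(k_max)


def fsc(
    u: Volume,
    v: Volume,
    mask: Mask | None = None,
    width: float = 1.0,
    k_max: int | None = None,
) -> ResolutionCurve:
    """Classical Fourier shell correlation, optionally with a soft mask.

    The mask (if any) multiplies both half-maps *before* the transforms —
    the traditional protocol, reproduced here including its artifacts: the
    mask's transform is convolved into every coefficient, so a tight mask
    correlates even independent noise at low frequency.

    Per shell the value is Re⟨U, V⟩ / (‖U‖·‖V‖) over the shell's lattice
    points (the inner product of Friedel-symmetric transforms is real).
    """
    u.require_same_geometry(v)
    if mask is not None:
        u.require_same_geometry(mask)
    km = _default_k_max(u.n, k_max)

    ud = u.data if mask is None else u.data * mask.data
    vd = v.data if mask is None else v.data * mask.data
    fu = np.fft.fftn(ud)
    fv = np.fft.fftn(vd)

    ks = np.arange(1, km + 1)
    values = np.empty(km)
    if width == 1.0:
        kbin = shell_index_grid(u.n)
        cross = np.bincount(kbin.ravel(), weights=(fu * np.conj(fv)).real.ravel())
        pu = np.bincount(kbin.ravel(), weights=(np.abs(fu) ** 2).ravel())
        pv = np.bincount(kbin.ravel(), weights=(np.abs(fv) ** 2).ravel())
        for i, k in enumerate(ks):
            values[i] = _normalized(cross[k], pu[k], pv[k], k)
    else:
        for i, k in enumerate(ks):
            sel = rectangular_shell_mask(u.n, int(k), width)
            su, sv = fu[sel], fv[sel]
            values[i] = _normalized(
                float(np.sum((su * np.conj(sv)).real)),
                float(np.sum(np.abs(su) ** 2)),
                float(np.sum(np.abs(sv) ** 2)),
                k,
            )
    return ResolutionCurve(
        k=ks,
        value=values,
        method="fsc",
        shell=ShellSpec(k=1, kind="rectangular", width=width),
        n=u.n,
        pixel_size=u.pixel_size,
        mask_count=None if mask is None else mask.count,
    )


def _normalized(cross: float, pu: float, pv: float, k: int) -> float:
    if pu <= 0.0 or pv <= 0.0:
        warnings.warn(f"zero power in shell k={k}; FSC set to 0")
        return 0.0
    return float(np.clip(cross / np.sqrt(pu * pv), -1.0, 1.0))


def mfsc(
    u: Volume,
    v: Volume,
    mask: Mask | None,
    sigma_g: float = 1.0,
    k_max: int | None = None,
    subtract_mean: bool = True,
) -> ResolutionCurve:
    """Modified FSC: filter first, then correlate inside the mask.

    For every shell k, both half-maps are Gaussian band-passed around k
    (width ``sigma_g`` Fourier pixels) and the real-space correlation is
    computed over the support of the binary mask.  ``mask=None`` means full
    support.  The mask must be binary — the method's premise is that support
    restriction, unlike multiplication by a soft profile, cannot introduce
    correlation.
    """
    u.require_same_geometry(v)
    if sigma_g <= 0:
        raise ValueError(f"sigma_g must be > 0, got {sigma_g}")
    if mask is not None:
        u.require_same_geometry(mask)
        if not mask.is_binary:
            raise ValueError(
                "mfsc requires a binary mask; binarize_mask(mask, 0.5) first"
            )
        sel = mask.boolean()
        if not sel.any():
            raise ValueError("mfsc mask is empty")
    else:
        sel = np.ones(u.data.shape, dtype=bool)
    km = _default_k_max(u.n, k_max)

    fu = np.fft.fftn(u.data)
    fv = np.fft.fftn(v.data)
    ks = np.arange(1, km + 1)
    values = np.empty(km)
    for i, k in enumerate(ks):
        a = bandpass_ft(fu, int(k), sigma_g)
        b = bandpass_ft(fv, int(k), sigma_g)
        values[i] = masked_correlation(a, b, sel, subtract_mean=subtract_mean)
    return ResolutionCurve(
        k=ks,
        value=values,
        method="mfsc",
        shell=ShellSpec(k=1, kind="gaussian", width=sigma_g),
        n=u.n,
        pixel_size=u.pixel_size,
        mask_count=None if mask is None else mask.count,
    )


def curve_to_tsv(
    curve: ResolutionCurve,
    path: str | Path,
    ndf: np.ndarray | None = None,
    ci_cutoff: np.ndarray | None = None,
) -> None:
    """Write a curve as TSV: k, spatial_frequency (1/Å), resolution (Å),
    value, ssnr, and optionally ndf and ci_cutoff columns."""
    cols = {
        "k": curve.k,
        "spatial_frequency": curve.spatial_frequency,
        "resolution": curve.resolution_per_shell,
        "value": curve.value,
        "ssnr": ssnr_curve(curve).ssnr,
    }
    if ndf is not None:
        cols["ndf"] = np.asarray(ndf, dtype=float)
    if ci_cutoff is not None:
        cols["ci_cutoff"] = np.asarray(ci_cutoff, dtype=float)
    header = "\t".join(cols)
    stacked = np.column_stack(list(cols.values()))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in stacked:
            fh.write("\t".join(f"{x:.6g}" for x in row) + "\n")


def curve_to_json(
    curve: ResolutionCurve,
    path: str | Path | None = None,
    **metadata,
) -> dict:
    """Curve plus metadata as a JSON-serializable dict (written if ``path``)."""
    doc = {
        "method": curve.method,
        "n": int(curve.n),
        "pixel_size": float(curve.pixel_size),
        "shell_kind": curve.shell.kind,
        "shell_width": float(curve.shell.width),
        "mask_count": curve.mask_count,
        "k": curve.k.tolist(),
        "value": curve.value.tolist(),
        **metadata,
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc
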