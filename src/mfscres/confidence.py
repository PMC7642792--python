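"""Fisher-z confidence machinery and the resolution-determination rule.

A correlation r with ndf effective samples has a Fisher z-transform
z = arctanh(r) that is approximately normal with standard deviation
1/sqrt(ndf - 3) (valid for ndf > 25 and r < 0.95).  Rather than reading the
resolution off the curve at a fixed threshold t, we ask at each shell
whether the observed correlation is *significantly* above t at one-sided
level α: the curve must exceed the back-transformed cutoff

    tanh( arctanh(t) + q(1 - α) / sqrt(ndf - 3) )

which approaches t from above as ndf grows.  Small masks mean small ndf,
high cutoffs, and therefore conservative resolution claims — by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .curves import ResolutionCurve

#: Above this correlation the normal approximation to z degrades.
FISHER_VALIDITY_BOUND = 0.95


@dataclass(frozen=True)
class CiParams:
    """Threshold and significance settings of the resolution test.

    ``t`` is the correlation cutoff defining "resolved" (0.143 by default;
    0.5 is the other common convention).  ``alpha`` is the one-sided
    significance level; ``two_sided=True`` replaces α by α/2.
    """

    t: float = 0.143
    alpha: float = 0.01
    two_sided: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.t < FISHER_VALIDITY_BOUND:
            raise ValueError(f"t must be in [0, {FISHER_VALIDITY_BOUND}), got {self.t}")
        if not 0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")

    @property
    def effective_alpha(self) -> float:
        return self.alpha / 2 if self.two_sided else self.alpha


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z-transform, arctanh(r) = ½ ln((1+r)/(1−r))."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1).any():
        raise ValueError("|r| must be < 1 for the Fisher z-transform")
    if (np.abs(r) >= FISHER_VALIDITY_BOUND).any():
        warnings.warn(
            f"correlation >= {FISHER_VALIDITY_BOUND}: normal approximation "
            "of z is degraded"
        )
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def z_sd(ndf: float | np.ndarray) -> float | np.ndarray:
    """Standard deviation of the z-transformed coefficient, (ndf − 3)^(−½)."""
    ndf = np.asarray(ndf, dtype=float)
    if (ndf <= 3).any():
        raise ValueError("ndf must exceed 3 for a finite Fisher variance")
    out = 1.0 / np.sqrt(ndf - 3.0)
    return float(out) if out.ndim == 0 else out


def ci_cutoff(
    t: float, alpha: float, ndf: float | np.ndarray
) -> float | np.ndarray:
    """Correlation the curve must reach to be significantly above ``t``.

    tanh(arctanh(t) + q(1−α)·(ndf−3)^(−½)); strictly above t for finite
    ndf, decreasing in ndf with limit t.  Equivalently: the smallest
    observed value whose one-sided *lower* confidence bound reaches t
    (tanh is monotone, so the two formulations coincide).
    """
    q = stats.norm.ppf(1.0 - alpha)
    out = np.tanh(fisher_z(t) + q * np.asarray(z_sd(ndf)))
    return float(out) if out.ndim == 0 else out


def significant(
    curve_value: float, t: float, alpha: float, ndf: float
) -> bool:
    """Is the observed correlation significantly above threshold ``t``?"""
    return bool(curve_value >= ci_cutoff(t, alpha, ndf))


@dataclass
class ResolutionResult:
    """Resolution determined from a curve plus the cutoff used per shell.

    ``k_star`` is the last shell of the initial run of significant shells;
    0 is the sentinel for "no resolvable signal".  The resolution is
    n/k_star pixels, i.e. p·n/k_star Å.
    """

    k_star: int
    n: int
    pixel_size: float
    cutoff_curve: np.ndarray
    params: CiParams
    ndf_per_k: np.ndarray
    mode: str = "ci"             # "ci" | "threshold"
    k: np.ndarray = field(default=None)  # shell indices aligned with cutoffs

    @property
    def resolved(self) -> bool:
        return self.k_star > 0

    @property
    def resolution_pixels(self) -> float | None:
        """Resolution in pixels per period, n/k*; None if unresolved."""
        return self.n / self.k_star if self.resolved else None

    @property
    def resolution_angstrom(self) -> float | None:
        return (
            self.pixel_size * self.n / self.k_star if self.resolved else None
        )

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "k_star": int(self.k_star),
            "resolved": self.resolved,
            "resolution_pixels": self.resolution_pixels,
            "resolution_angstrom": self.resolution_angstrom,
            "t": self.params.t,
            "alpha": self.params.effective_alpha,
        }


def _initial_run_end(sig: np.ndarray) -> int:
    """Index (0-based) past the end of the first contiguous True run; 0 if none."""
    hits = np.nonzero(sig)[0]
    if hits.size == 0:
        return 0
    start = hits[0]
    rest = np.nonzero(~sig[start:])[0]
    return int(start + (rest[0] if rest.size else sig.size - start))


def determine_resolution(
    curve: ResolutionCurve,
    ndf_per_k: np.ndarray,
    params: CiParams = CiParams(),
    mode: str = "ci",
    run_rule: str = "initial",
) -> ResolutionResult:
    """Determine the resolution of a curve under the significance test.

    Per shell the curve value is compared with the one-sided CI cutoff (or
    with the plain threshold t when ``mode="threshold"``, reproducing the
    traditional fixed-threshold reading).  ``k_star`` is the end of the
    initial contiguous run of passing shells — a stray high-frequency
    excursion above the cutoff cannot inflate the resolution.
    ``run_rule="global"`` instead takes the highest passing shell.
    """
    if curve.k.size == 0:
        raise ValueError("empty curve")
    ndf_per_k = np.asarray(ndf_per_k, dtype=float)
    if ndf_per_k.shape != curve.k.shape:
        raise ValueError("ndf_per_k must align with curve.k")
    if mode not in ("ci", "threshold"):
        raise ValueError(f"unknown mode {mode!r}")
    if run_rule not in ("initial", "global"):
        raise ValueError(f"unknown run_rule {run_rule!r}")

    alpha = params.effective_alpha
    if mode == "ci":
        cutoffs = np.asarray(ci_cutoff(params.t, alpha, ndf_per_k))
    else:
        cutoffs = np.full(curve.k.shape, params.t)
    sig = curve.value >= cutoffs
    if run_rule == "initial":
        end = _initial_run_end(sig)
        k_star = int(curve.k[end - 1]) if end > 0 else 0
    else:
        hits = np.nonzero(sig)[0]
        k_star = int(curve.k[hits[-1]]) if hits.size else 0
    return ResolutionResult(
        k_star=k_star,
        n=curve.n,
        pixel_size=curve.pixel_size,
        cutoff_curve=cutoffs,
        params=params,
        ndf_per_k=ndf_per_k,
        mode=mode,
        k=curve.k.copy(),
    )
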