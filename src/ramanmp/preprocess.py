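"""Spectral preprocessing: common grid, baseline, smoothing, scaling.

Raw spectra arrive with slightly different axes and ride on a broad
fluorescence background.  Before classification every spectrum is

1. refitted by cubic spline onto a common grid (559–1990 cm⁻¹, 3 cm⁻¹
   pitch → 478 points),
2. baseline-corrected with an asymmetric-least-squares estimator using one
   fixed "universal" parameter set,
3. lightly smoothed with a smoothing spline whose strength is kept small
   enough not to degrade the signal, and
4. scaled by its own standard deviation so every spectrum has unit SD.

Constant (zero-variance) spectra — produced e.g. by acquisition
desynchronization — are flagged degenerate and bypass classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.linalg import solveh_banded

from .spectra import Spectrum


class CoverageError(ValueError):
    """Input axis does not cover the target grid (no extrapolation)."""


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing chain.

    ``baseline_lam`` (smoothness) and ``baseline_p`` (asymmetry) are the
    "universal" baseline parameters applied to every spectrum;
    ``smooth_lam`` is the roughness penalty of the smoothing spline, kept
    small so noiseless signals pass through essentially unchanged.
    """

    grid_start: float = 559.0
    grid_end: float = 1990.0
    grid_step: float = 3.0
    baseline_lam: float = 1e5
    baseline_p: float = 0.01
    baseline_niter: int = 10
    smooth_lam: float = 5.0

    def __post_init__(self) -> None:
        if not self.grid_start < self.grid_end:
            raise ValueError("grid_start must be < grid_end")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        n = (self.grid_end - self.grid_start) / self.grid_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(grid_end - grid_start) must be divisible by grid_step")

    @property
    def grid(self) -> np.ndarray:
        """The common wavenumber axis (bit-identical across calls)."""
        n = int(round((self.grid_end - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


def refit_grid(s: Spectrum, p: PreprocessParams | None = None) -> Spectrum:
    """Cubic-spline interpolation of a spectrum onto the common grid.

    The input axis must cover the target range; extrapolation is refused.
    """
    p = p or PreprocessParams()
    if s.wavenumbers[0] > p.grid_start or s.wavenumbers[-1] < p.grid_end:
        raise CoverageError(
            f"input axis [{s.wavenumbers[0]:g}, {s.wavenumbers[-1]:g}] does not "
            f"cover target [{p.grid_start:g}, {p.grid_end:g}]"
        )
    grid = p.grid
    spl = CubicSpline(s.wavenumbers, s.intensities)
    return s.replace(wavenumbers=grid, intensities=spl(grid))


def _asls_penalty_bands(n: int, lam: float) -> np.ndarray:
    """Upper banded form (for solveh_banded) of lam * D2ᵀD2."""
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    m = (lam * (d2.T @ d2)).todia()
    ab = np.zeros((3, n))
    for off, data in zip(m.offsets, m.data):
        if off >= 0:
            ab[2 - off, :] = data
    return ab


def estimate_baseline(
    y: np.ndarray, lam: float = 1e5, p: float = 0.01, niter: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares baseline of one intensity vector.

    Minimizes sum(w_i (y_i - z_i)^2) + lam * sum((Δ²z)^2) with asymmetric
    weights w_i = p where y > z (peaks) and 1 - p elsewhere, iterated to
    convergence; the result hugs the smooth background under the peaks.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        return y.copy()
    pen = _asls_penalty_bands(n, lam)
    w = np.ones(n)
    z = y
    for _ in range(niter):
        ab = pen.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def correct_baseline(s: Spectrum, p: PreprocessParams | None = None) -> Spectrum:
    """Subtract the estimated background; keep it in ``meta['baseline']``."""
    p = p or PreprocessParams()
    base = estimate_baseline(
        s.intensities, lam=p.baseline_lam, p=p.baseline_p, niter=p.baseline_niter
    )
    out = s.replace(intensities=s.intensities - base)
    out.meta["baseline"] = base
    return out


def smooth(s: Spectrum, p: PreprocessParams | None = None) -> Spectrum:
    """Smoothing spline over all points with a small roughness penalty.

    The penalty is deliberately weak: a noiseless smooth signal is
    reproduced essentially unchanged, while high-frequency noise is
    attenuated.
    """
    p = p or PreprocessParams()
    if len(s) < 4 or p.smooth_lam <= 0:
        return s.replace()
    spl = make_smoothing_spline(s.wavenumbers, s.intensities, lam=p.smooth_lam)
    return s.replace(intensities=spl(s.wavenumbers))


#: spectra whose SD falls below this (relative to their magnitude) are
#: treated as constant
_DEGENERATE_SD_RTOL = 1e-12


def scale_sd(s: Spectrum) -> Spectrum:
    """Scale intensities by their own standard deviation (population SD).

    Output SD is exactly 1 for non-constant inputs.  Constant spectra have
    no spectral information: they are returned zeroed with
    ``meta['degenerate'] = True`` and later classified as NMP with
    confidence 0.
    """
    sd = float(np.std(s.intensities))
    scale_ref = max(1.0, float(np.max(np.abs(s.intensities))) if len(s) else 1.0)
    if sd <= _DEGENERATE_SD_RTOL * scale_ref:
        out = s.replace(intensities=np.zeros_like(s.intensities))
        out.meta["degenerate"] = True
        return out
    return s.replace(intensities=s.intensities / sd)


def preprocess_pipeline(s: Spectrum, p: PreprocessParams | None = None) -> Spectrum:
    """Full chain: refit_grid → correct_baseline → smooth → scale_sd."""
    p = p or PreprocessParams()
    out = refit_grid(s, p)
    ptp = float(np.ptp(out.intensities))
    level = max(1.0, float(np.max(np.abs(out.intensities))))
    if ptp <= 1e-9 * level:
        # constant input (e.g. a missed acquisition frame): only numerical
        # ripple survives the refit; flag degenerate instead of letting
        # SD-scaling blow that ripple up to unit variance
        return scale_sd(out.replace(intensities=np.zeros_like(out.intensities)))
    out = correct_baseline(out, p)
    out = smooth(out, p)
    return scale_sd(out)
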