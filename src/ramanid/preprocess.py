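"""Spectral preprocessing: baseline correction, smoothing, normalization.

The chain applied to every single-cell spectrum, in this fixed order:

1. crop to the fingerprint window (default 600–1800 cm⁻¹),
2. baseline correction by iterative modified polynomial fitting (ModPoly):
   fit a low-order polynomial to the spectrum, clamp the spectrum to the fit
   wherever it lies above it, refit, and repeat until the fit stabilises —
   the converged fit estimates the fluorescence background, which is
   subtracted,
3. Savitzky–Golay smoothing (local polynomial least squares),
4. max-normalization: clip negatives (possible after baseline subtraction)
   to zero, then divide by the spectrum maximum, mapping intensities to
   [0, 1] with max exactly 1.

ModPoly is the standard polynomial-fitting baseline for Raman spectra of
biological cells, where a broad fluorescence background sits under narrow
vibrational bands; clamping from above makes the fit hug the background
rather than the peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import savgol_filter

from .io import SpectrumSet

__all__ = [
    "PreprocessConfig",
    "MeanSpectrum",
    "correct_baseline",
    "smooth_spectrum",
    "normalize_max",
    "crop_set",
    "preprocess_set",
    "summarize_mean_sd",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    crop_low, crop_high : cm⁻¹ — fingerprint window bounds.
    baseline_order : polynomial order of the ModPoly background fit.
    baseline_max_iter, baseline_tol : iteration cap and relative-change
        stopping threshold of the ModPoly loop.
    sg_window : Savitzky–Golay window length in points (odd).
    sg_polyorder : Savitzky–Golay polynomial order (< sg_window).
    """

    crop_low: float = 600.0
    crop_high: float = 1800.0
    baseline_order: int = 5
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-3
    sg_window: int = 11
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        if not self.crop_low < self.crop_high:
            raise ValueError("crop_low must be < crop_high")
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")


@dataclass(eq=False)
class MeanSpectrum:
    """Group mean spectrum with a pointwise standard-deviation band."""

    axis: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    species: str
    n_cells: int

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.axis.size == self.mean.size == self.sd.size):
            raise ValueError("axis, mean and sd must have equal length")
        if np.any(self.sd < 0):
            raise ValueError("sd must be nonnegative")


def _chebyshev_design(n: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    # Chebyshev basis on [-1, 1] keeps the normal equations well conditioned
    # at orders ~5-8 where a raw Vandermonde already struggles.
    x = np.linspace(-1.0, 1.0, n)
    V = np.polynomial.chebyshev.chebvander(x, order)
    return V, np.linalg.pinv(V)


def correct_baseline(y: np.ndarray, order: int = 5, max_iter: int = 100,
                     tol: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and subtract the background of one spectrum (ModPoly).

    Returns ``(baseline, corrected)`` with ``corrected = y - baseline``.
    Iteration stops when the maximum relative change of the fitted baseline
    drops below ``tol``, or after ``max_iter`` refits.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("correct_baseline expects a 1-D intensity vector")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input intensities")
    if order >= y.size - 1:
        raise ValueError(f"order {order} too high for {y.size}-point spectrum")
    baseline = _modpoly(y[None, :], order, max_iter, tol)[0]
    return baseline, y - baseline


def _modpoly(Y: np.ndarray, order: int, max_iter: int, tol: float) -> np.ndarray:
    """Vectorised ModPoly baselines for an (n_cells, n_points) matrix."""
    n = Y.shape[1]
    V, P = _chebyshev_design(n, order)
    work = Y.copy()
    fit = work @ P.T @ V.T
    scale = np.maximum(np.max(np.abs(Y), axis=1, keepdims=True), 1e-300)
    for _ in range(max_iter):
        work = np.minimum(work, fit)
        new_fit = work @ P.T @ V.T
        delta = np.max(np.abs(new_fit - fit), axis=1, keepdims=True) / scale
        fit = new_fit
        if np.all(delta < tol):
            break
    return fit


def smooth_spectrum(y: np.ndarray, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky–Golay smoothing; output has the same length as the input."""
    y = np.asarray(y, dtype=float)
    if window % 2 == 0 or window > y.shape[-1] or polyorder >= window:
        raise ValueError(
            f"invalid Savitzky–Golay parameters: window={window}, "
            f"polyorder={polyorder}, n={y.shape[-1]}")
    return savgol_filter(y, window_length=window, polyorder=polyorder, axis=-1)


def normalize_max(y: np.ndarray) -> np.ndarray:
    """Clip negatives to zero and divide by the spectrum maximum.

    Baseline subtraction can leave small negative residuals; clipping first
    guarantees the output lies in [0, 1] with max exactly 1.
    """
    y = np.clip(np.asarray(y, dtype=float), 0.0, None)
    m = y.max(axis=-1, keepdims=True)
    if np.any(m <= 0):
        raise ValueError("cannot max-normalize an all-zero/all-negative spectrum")
    return y / m


def crop_set(s: SpectrumSet, low: float, high: float) -> SpectrumSet:
    """Restrict the axis to [low, high] (inclusive)."""
    keep = (s.axis >= low) & (s.axis <= high)
    if keep.sum() < 2:
        raise ValueError(f"crop window [{low}, {high}] keeps fewer than 2 points")
    return SpectrumSet(s.axis[keep], s.intensities[:, keep], s.labels, dict(s.meta))


def preprocess_set(s: SpectrumSet, cfg: PreprocessConfig | None = None) -> SpectrumSet:
    """Apply crop → baseline correction → smoothing → max-normalization.

    Labels are preserved; the applied configuration is recorded in ``meta``.
    Failures in a component step are re-raised annotated with the cell_id.
    """
    cfg = cfg or PreprocessConfig()
    s = crop_set(s, cfg.crop_low, cfg.crop_high)
    baselines = _modpoly(s.intensities, cfg.baseline_order,
                         cfg.baseline_max_iter, cfg.baseline_tol)
    corrected = s.intensities - baselines
    smoothed = smooth_spectrum(corrected, cfg.sg_window, cfg.sg_polyorder)
    out = np.empty_like(smoothed)
    for i in range(s.n_cells):
        try:
            out[i] = normalize_max(smoothed[i])
        except ValueError as exc:
            cid = s.labels["cell_id"].iloc[i]
            raise ValueError(f"cell {cid!r}: {exc}") from exc
    meta = dict(s.meta)
    meta["preprocess"] = asdict(cfg)
    return SpectrumSet(s.axis, out, s.labels, meta)


def summarize_mean_sd(s: SpectrumSet, by: str = "species") -> list[MeanSpectrum]:
    """Per-group pointwise mean spectrum and population standard deviation.

    The shaded error band around a mean spectrum: the narrower it is relative
    to the peaks, the more repeatable the single-cell spectra of that group.
    """
    if by not in s.labels.columns:
        raise ValueError(f"unknown label field {by!r}")
    out: list[MeanSpectrum] = []
    for name, idx in s.labels.groupby(by, sort=True).groups.items():
        rows = s.intensities[np.asarray(idx)]
        if rows.shape[0] == 0:
            raise ValueError(f"empty group {name!r}")
        out.append(MeanSpectrum(axis=s.axis, mean=rows.mean(axis=0),
                                sd=rows.std(axis=0, ddof=0),
                                species=str(name), n_cells=rows.shape[0]))
    return out
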