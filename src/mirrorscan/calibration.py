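"""Spectral, dark-frame and radiometric calibration of a line-scan imager.

Covers the standard hyperspectral calibration chain:

* wavelength axis: a least-squares characteristic polynomial
  ``lambda = a0 + a1*p + ... + ad*p^d`` mapping sensor pixel ``p`` to
  wavelength, fitted from reference-peak correspondences;
* spectral resolution: the smallest separation of known emission lines that
  still yields two distinct detected peaks, which bounds the usable channel
  width and hence the channel count;
* dark frames: per-pixel linear hot-pixel model ``h_bg = a*T_exp + b``
  fitted over exposure time, subtracted from every measurement;
* reflectance: flat-field normalization against a white (Spectralon)
  reference, ``R = (raw - dark) / (white - dark)``;
* SNR: ``10*log10(mu_hat / sigma_hat^2)`` per (exposure, wavelength) cell
  from replicate reflectance samples, with maximum-likelihood (1/N)
  variance as the default estimator;
* light-source stability: tail-window linear trend of the mean white
  reference over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy import signal

__all__ = [
    "SpectralCalibration",
    "DarkFrameModel",
    "SNRProfile",
    "StabilityResult",
    "fit_wavelength_polynomial",
    "pixel_to_wavelength",
    "detect_peaks",
    "resolution_bound",
    "channel_count",
    "channel_count_range",
    "fit_dark_model",
    "subtract_dark",
    "reflectance_calibrate",
    "snr",
    "snr_profile",
    "stability_trace",
    "SNR_INF",
]

#: sentinel stored for cells whose replicate variance is exactly zero
SNR_INF = np.inf


class CalibrationError(ValueError):
    """Invalid calibration input."""


# ---------------------------------------------------------------------------
# Wavelength axis
# ---------------------------------------------------------------------------

@dataclass
class SpectralCalibration:
    """Characteristic polynomial of a spectrograph plus channel bookkeeping.

    ``coefficients`` are ascending powers (nm, nm/px, nm/px^2, ...).
    """

    coefficients: np.ndarray
    px_per_channel: int = 1
    resolution_bound_nm: float | None = None
    wavelength_range: tuple[float, float] | None = None
    residuals_nm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, float))
        if self.coefficients.size < 2:
            raise CalibrationError("calibration polynomial needs degree >= 1")
        if self.px_per_channel < 1:
            raise CalibrationError("px_per_channel must be >= 1")
        if self.resolution_bound_nm is not None and self.resolution_bound_nm <= 0:
            raise CalibrationError("resolution_bound_nm must be > 0")

    @property
    def degree(self) -> int:
        return self.coefficients.size - 1

    def __call__(self, p):
        return pixel_to_wavelength(p, self)

    def is_monotonic(self, n_pixels: int) -> bool:
        """Whether the polynomial increases over ``[0, n_pixels)``."""
        lam = P.polyval(np.arange(n_pixels, dtype=float), self.coefficients)
        return bool(np.all(np.diff(lam) > 0))


def fit_wavelength_polynomial(peaks, degree: int) -> SpectralCalibration:
    """Least-squares characteristic polynomial from (pixel, nm) peak pairs.

    Exact interpolation when the number of pairs equals ``degree + 1``;
    fit residuals (nm) are stored on the result.
    """
    arr = np.asarray(peaks, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise CalibrationError("peaks must be an (n, 2) table of (pixel, nm)")
    px, lam = arr[:, 0], arr[:, 1]
    if degree < 1:
        raise CalibrationError("degree must be >= 1")
    if np.unique(px).size != px.size:
        raise CalibrationError("duplicate pixel positions in peak table")
    if px.size < degree + 1:
        raise CalibrationError(
            f"need >= {degree + 1} peaks for a degree-{degree} fit, got {px.size}"
        )
    coeffs = P.polyfit(px, lam, degree)
    res = lam - P.polyval(px, coeffs)
    return SpectralCalibration(
        coefficients=coeffs,
        wavelength_range=(float(lam.min()), float(lam.max())),
        residuals_nm=res,
    )


def pixel_to_wavelength(p, cal: SpectralCalibration):
    """Evaluate the characteristic polynomial at pixel/channel positions."""
    lam = P.polyval(np.asarray(p, dtype=float), cal.coefficients)
    return lam if np.ndim(lam) else float(lam)


# ---------------------------------------------------------------------------
# Peaks and spectral resolution
# ---------------------------------------------------------------------------

def detect_peaks(spectrum, min_prominence: float = 0.05) -> np.ndarray:
    """Sub-pixel local maxima of a 1-D spectrum.

    ``min_prominence`` is a fraction of the spectrum's dynamic range.  Peak
    positions are refined by 3-point parabolic interpolation and returned
    ascending.  A flat or empty spectrum yields no peaks.
    """
    s = np.asarray(spectrum, dtype=float)
    if s.size < 5:
        raise CalibrationError("spectrum must have >= 5 samples")
    span = float(s.max() - s.min())
    if span == 0.0:
        return np.empty(0)
    idx, _ = signal.find_peaks(s, prominence=min_prominence * span)
    out = []
    for i in idx:
        if 0 < i < s.size - 1:
            denom = s[i - 1] - 2 * s[i] + s[i + 1]
            shift = 0.5 * (s[i - 1] - s[i + 1]) / denom if denom != 0 else 0.0
            out.append(i + float(np.clip(shift, -0.5, 0.5)))
        else:
            out.append(float(i))
    return np.sort(np.asarray(out))


def match_peaks_to_lines(
    detected_nm: np.ndarray,
    known_nm: np.ndarray,
    *,
    intensities: np.ndarray | None = None,
    max_offset_nm: float = np.inf,
) -> dict[int, int]:
    """Greedy one-to-one nearest-neighbour assignment of peaks to known lines.

    Returns ``{line_index: peak_index}``.  Pairs are taken in order of
    increasing wavelength distance; ties broken by peak intensity (higher
    first) when intensities are supplied.
    """
    detected_nm = np.asarray(detected_nm, float)
    known_nm = np.asarray(known_nm, float)
    pairs = []
    for li, lam in enumerate(known_nm):
        for pi, pk in enumerate(detected_nm):
            d = abs(pk - lam)
            if d <= max_offset_nm:
                inten = -intensities[pi] if intensities is not None else 0.0
                pairs.append((d, inten, li, pi))
    pairs.sort()
    assigned: dict[int, int] = {}
    used_peaks: set[int] = set()
    for _, _, li, pi in pairs:
        if li not in assigned and pi not in used_peaks:
            assigned[li] = pi
            used_peaks.add(pi)
    return assigned


def resolution_bound(
    known_lines,
    spectrum,
    cal: SpectralCalibration,
    *,
    min_prominence: float = 0.02,
):
    """Empirical spectral-resolution bound from known emission lines.

    Detects peaks in ``spectrum`` (indexed by sensor pixel), converts them
    to wavelength through ``cal``, and checks each adjacent pair of known
    lines for two *distinct* matched peaks.  Returns ``(bound_nm,
    (line_lo, line_hi))``: the smallest separation among resolved adjacent
    pairs and the witness pair.  Raises if no pair is resolved.
    """
    lines = np.sort(np.asarray(known_lines, dtype=float))
    if lines.size < 2:
        raise CalibrationError("resolution_bound needs >= 2 known lines")
    s = np.asarray(spectrum, dtype=float)
    pk_px = detect_peaks(s, min_prominence)
    pk_nm = np.asarray([pixel_to_wavelength(p, cal) for p in pk_px])
    inten = np.interp(pk_px, np.arange(s.size), s) if pk_px.size else pk_px

    best: tuple[float, tuple[float, float]] | None = None
    for lo, hi in zip(lines[:-1], lines[1:]):
        sep = hi - lo
        m = match_peaks_to_lines(
            pk_nm, np.array([lo, hi]), intensities=inten, max_offset_nm=sep / 2
        )
        if len(m) == 2 and m[0] != m[1]:
            if best is None or sep < best[0]:
                best = (float(sep), (float(lo), float(hi)))
    if best is None:
        raise CalibrationError(
            "no adjacent pair of known lines was resolved into two peaks; "
            "resolution bound undefined"
        )
    return best


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def channel_count(n_pixels: int, px_per_channel: int) -> int:
    """Number of spectral channels when binning ``px_per_channel`` pixels.

    Nearest-integer (half away from zero) rounding of the ratio, e.g.
    1088 px at 5 px/channel -> 218 channels.
    """
    if n_pixels <= 0 or px_per_channel <= 0:
        raise CalibrationError("n_pixels and px_per_channel must be > 0")
    return _round_half_away(n_pixels / px_per_channel)


def channel_count_range(lambda_min: float, lambda_max: float, res_nm: float) -> int:
    """Channels fitting in a wavelength range at a given resolution."""
    if res_nm <= 0 or lambda_max <= lambda_min:
        raise CalibrationError("need lambda_max > lambda_min and res_nm > 0")
    return _round_half_away((lambda_max - lambda_min) / res_nm)


# ---------------------------------------------------------------------------
# Dark frames
# ---------------------------------------------------------------------------

@dataclass
class DarkFrameModel:
    """Per-pixel linear dark/hot-pixel model ``h_bg = a*T_exp + b``.

    ``slope`` in counts/s, ``intercept`` in counts, both sensor-shaped.
    """

    slope: np.ndarray
    intercept: np.ndarray
    residual_rms: np.ndarray | None = field(default=None, repr=False)
    hot_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.slope.shape != self.intercept.shape:
            raise CalibrationError("slope and intercept grids must share shape")

    def predict(self, t_exp: float) -> np.ndarray:
        """Predicted background at exposure ``t_exp`` (clamped at 0)."""
        return np.clip(self.slope * t_exp + self.intercept, 0.0, None)


def fit_dark_model(
    frames,
    exposures_s,
    *,
    hot_factor: float = 5.0,
) -> DarkFrameModel:
    """Per-pixel OLS of dark counts against exposure time.

    ``frames`` is a sequence of sensor-shaped dark frames, one per entry of
    ``exposures_s`` (at least 2 distinct exposures).  Pixels whose fitted
    slope exceeds ``hot_factor`` times the median slope are flagged hot.
    """
    t = np.asarray(exposures_s, dtype=float)
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len({f.shape for f in frames}) != 1:
        raise CalibrationError("dark frames must share a common shape")
    stack = np.stack(frames)
    if stack.shape[0] != t.size:
        raise CalibrationError("one exposure per frame required")
    if np.unique(t).size < 2:
        raise CalibrationError("fit_dark_model needs >= 2 distinct exposure times")

    # closed-form simple linear regression, vectorized over pixels
    tm = t.mean()
    dt = t - tm
    denom = np.sum(dt**2)
    slope = np.tensordot(dt, stack, axes=(0, 0)) / denom
    intercept = stack.mean(axis=0) - slope * tm
    pred = slope[None] * t[:, None, None] + intercept[None]
    rms = np.sqrt(np.mean((stack - pred) ** 2, axis=0))
    med = float(np.median(slope))
    hot = slope > hot_factor * max(med, np.finfo(float).tiny)
    return DarkFrameModel(slope=slope, intercept=intercept, residual_rms=rms, hot_mask=hot)


def subtract_dark(frame, model: DarkFrameModel, t_exp: float) -> np.ndarray:
    """Subtract the predicted dark background; result clamped at 0.

    Not idempotent: applying it twice subtracts the background twice.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != model.slope.shape:
        raise CalibrationError(
            f"frame shape {frame.shape} does not match model {model.slope.shape}"
        )
    return np.clip(frame - model.predict(t_exp), 0.0, None)


# ---------------------------------------------------------------------------
# Reflectance and SNR
# ---------------------------------------------------------------------------

def reflectance_calibrate(raw, white_ref, dark_pred, *, denom_eps: float = 1e-9):
    """Flat-field reflectance ``(raw - dark) / (white - dark)``.

    Returns ``(reflectance, mask)``; samples where the white reference does
    not exceed the dark prediction by more than ``denom_eps`` are masked
    (NaN).  Raises if the entire white reference is dark.
    """
    raw = np.asarray(raw, dtype=float)
    white = np.asarray(white_ref, dtype=float)
    dark = np.asarray(dark_pred, dtype=float)
    if raw.shape != white.shape or raw.shape != dark.shape:
        raise CalibrationError("raw, white and dark must share a shape")
    denom = white - dark
    mask = denom > denom_eps
    if not mask.any():
        raise CalibrationError("white reference is entirely dark; cannot calibrate")
    refl = np.full(raw.shape, np.nan)
    refl[mask] = (raw[mask] - dark[mask]) / denom[mask]
    return refl, mask


def snr(samples, *, ddof: int = 0):
    """SNR of replicate samples: ``10*log10(mu_hat / sigma_hat^2)`` dB.

    ``mu_hat`` is the sample mean and ``sigma_hat^2`` the variance with
    ``ddof=0`` (maximum-likelihood, 1/N) by default.  Zero variance yields
    the infinite-SNR sentinel; non-positive means are undefined (NaN).
    Returns ``(snr_db, mu_hat, var_hat)``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise CalibrationError("snr needs >= 2 replicate samples")
    mu = float(np.mean(x))
    var = float(np.var(x, ddof=ddof))
    if var == 0.0:
        return SNR_INF, mu, var
    if mu <= 0.0:
        return float("nan"), mu, var
    return 10.0 * math.log10(mu / var), mu, var


@dataclass
class SNRProfile:
    """SNR table over (exposure, wavelength), long format.

    ``table`` columns: ``t_exp_s, lambda_nm, mu, var, snr_db``.  Cells with
    zero variance carry the infinite-SNR sentinel and are excluded from
    aggregates.
    """

    table: pd.DataFrame

    def mean_snr_db(self) -> float:
        s = self.table["snr_db"]
        s = s[np.isfinite(s)]
        return float(s.mean()) if len(s) else float("nan")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def snr_profile(replicates, t_exp_levels, wavelengths_nm, *, ddof: int = 0) -> SNRProfile:
    """Build an SNR profile from replicate reflectance samples.

    ``replicates`` has shape ``(N, n_exposures, n_wavelengths)`` — N
    replicate captures per (exposure, wavelength) cell.
    """
    x = np.asarray(replicates, dtype=float)
    t_levels = np.asarray(t_exp_levels, dtype=float)
    lam = np.asarray(wavelengths_nm, dtype=float)
    if x.ndim != 3 or x.shape[1] != t_levels.size or x.shape[2] != lam.size:
        raise CalibrationError(
            "replicates must be (N, n_exposures, n_wavelengths) matching the axes"
        )
    if x.shape[0] < 2:
        raise CalibrationError("need >= 2 replicates per cell")
    rows = []
    for i, t in enumerate(t_levels):
        for j, w in enumerate(lam):
            s_db, mu, var = snr(x[:, i, j], ddof=ddof)
            rows.append((t, w, mu, var, s_db))
    return SNRProfile(pd.DataFrame(rows, columns=["t_exp_s", "lambda_nm", "mu", "var", "snr_db"]))


# ---------------------------------------------------------------------------
# Light-source stability
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    """Result of :func:`stability_trace`."""

    means: np.ndarray
    timestamps_s: np.ndarray
    tail_slope_per_s: float
    steady_state_mean: float
    stable: bool


def stability_trace(
    timestamps_s,
    means,
    *,
    tail_fraction: float = 0.5,
    rel_slope_tol_per_s: float = 1e-4,
) -> StabilityResult:
    """Linear drift of the mean white-reference level over time.

    Fits a line to the last ``tail_fraction`` of the trace (to skip source
    warm-up) and declares the source stable when the absolute slope is
    below ``rel_slope_tol_per_s`` times the tail mean, per second.  The
    default tolerance (0.01%/s) caps the drift over a ~100 s full scan at
    about 1% of the reference level.
    """
    t = np.asarray(timestamps_s, dtype=float)
    m = np.asarray(means, dtype=float)
    if t.size != m.size or t.size < 3:
        raise CalibrationError("stability_trace needs >= 3 (timestamp, mean) points")
    n_tail = max(3, int(round(tail_fraction * t.size)))
    tt, mm = t[-n_tail:], m[-n_tail:]
    slope, _ = np.polyfit(tt, mm, 1)
    steady = float(np.mean(mm))
    tol = abs(rel_slope_tol_per_s * steady)
    return StabilityResult(
        means=m,
        timestamps_s=t,
        tail_slope_per_s=float(slope),
        steady_state_mean=steady,
        stable=bool(abs(slope) <= tol),
    )
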