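"""Rotating-mirror scan geometry: the tangential object-plane model.

A mirror at angle ``theta`` to the object-plane normal reflects the camera's
line of sight onto the plane at position

    y_d = r * tan(pi/2 - 2*theta) = r * tan(gamma),      gamma = pi/2 - 2*theta,

where ``r`` is the normal mirror-to-plane distance.  Away from the normal
point (``theta = pi/4``, ``gamma = 0``) the optical path lengthens by
``delta_r = r*(1/sin(2*theta) - 1)`` and the in-line magnification changes by
the same factor ``h(theta) = 1/sin(2*theta)``, so objects appear scaled along
the line.  Scan rows map linearly to mirror angle through the stepper's
angular resolution; the mapping row -> angle -> object position is what this
module provides, forward and inverse, together with distortion bounds,
rectification onto a uniform object-plane grid, and estimation of ``r`` and
the normal-row index from grid-target scans.

Conventions
-----------
* Rows are 0-based; ``y_pi4`` (the row where ``theta = pi/4``) may be
  fractional and may lie outside the frame.
* ``x`` in :func:`pixel_to_object` is a *signed column offset from the
  central column*, in pixels; pixel centers carry the coordinates.
* ``gamma = pi/2 - 2*theta``: positive gamma corresponds to positive object
  position ``y_d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math
import tomllib

import numpy as np
from scipy import optimize
from scipy.ndimage import map_coordinates

__all__ = [
    "ScannerGeometry",
    "LinearRange",
    "GeometryFit",
    "step_angle",
    "row_to_angle",
    "angle_to_object_y",
    "path_elongation",
    "width_scale",
    "pixel_to_object",
    "object_to_pixel",
    "linearized_object_y",
    "linear_range",
    "rectify",
    "detect_grid_rows",
    "fit_geometry",
    "residual_noise_sigma",
]


class GeometryError(ValueError):
    """Invalid geometry parameter or out-of-domain mirror angle."""


class FitError(RuntimeError):
    """A least-squares fit could not be performed or did not converge."""


def step_angle(s: float, n_steps: int) -> float:
    """Angular resolution of the mirror drive, ``s * 2*pi / n_steps`` (rad).

    ``s`` is the (micro)stepping factor: the number of drive steps taken
    between consecutive scan lines.  ``n_steps`` is the number of steps per
    full mirror revolution (19 200 for the reference device).
    """
    if not (s > 0) or n_steps < 1 or int(n_steps) != n_steps:
        raise GeometryError(
            f"step_angle requires s > 0 and integer n_steps >= 1, got s={s}, n_steps={n_steps}"
        )
    return s * 2.0 * math.pi / n_steps


@dataclass(frozen=True)
class ScannerGeometry:
    """Geometric parameters of a rotating-mirror line scanner.

    Parameters
    ----------
    r_mm
        Normal mirror-to-object-plane distance (mm).
    n_steps_per_rev
        Stepper steps per full mirror revolution.
    microstep_factor
        Steps advanced between consecutive scan lines (dimensionless).
    y_pi4
        Fractional row index where the view is normal to the plane
        (``theta = pi/4``).  May lie outside ``[0, n_rows)``.
    delta_x_mm
        Spatial sampling pitch along the line at the normal point (mm/px).
    n_rows, n_cols
        Image dimensions in pixels (rows = scan direction).
    """

    r_mm: float
    n_steps_per_rev: int = 19200
    microstep_factor: float = 1.0
    y_pi4: float = 599.5
    delta_x_mm: float = 0.1
    n_rows: int = 1200
    n_cols: int = 1200

    def __post_init__(self) -> None:
        if not (self.r_mm > 0):
            raise GeometryError(f"r_mm must be > 0, got {self.r_mm}")
        if self.n_steps_per_rev < 1 or int(self.n_steps_per_rev) != self.n_steps_per_rev:
            raise GeometryError("n_steps_per_rev must be a positive integer")
        if not (self.microstep_factor > 0):
            raise GeometryError("microstep_factor must be > 0")
        if not (self.delta_x_mm > 0):
            raise GeometryError("delta_x_mm must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("n_rows and n_cols must be >= 1")

    @property
    def delta_theta(self) -> float:
        """Mirror angle advanced per scan row (rad)."""
        return step_angle(self.microstep_factor, self.n_steps_per_rev)

    @property
    def x_center(self) -> float:
        """Column index of the image center (fractional for even widths)."""
        return (self.n_cols - 1) / 2.0

    # -- config I/O ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "r_mm": self.r_mm,
            "steps_per_rev": self.n_steps_per_rev,
            "microstep_factor": self.microstep_factor,
            "y_pi4": self.y_pi4,
            "delta_x_mm": self.delta_x_mm,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
        }

    def to_dict_init(self) -> dict:
        """Field dict usable as constructor kwargs."""
        return {
            "r_mm": self.r_mm,
            "n_steps_per_rev": self.n_steps_per_rev,
            "microstep_factor": self.microstep_factor,
            "y_pi4": self.y_pi4,
            "delta_x_mm": self.delta_x_mm,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScannerGeometry":
        return cls(
            r_mm=d["r_mm"],
            n_steps_per_rev=int(d.get("steps_per_rev", 19200)),
            microstep_factor=d.get("microstep_factor", 1.0),
            y_pi4=d.get("y_pi4", 599.5),
            delta_x_mm=d.get("delta_x_mm", 0.1),
            n_rows=int(d.get("n_rows", 1200)),
            n_cols=int(d.get("n_cols", 1200)),
        )

    @classmethod
    def from_file(cls, path) -> "ScannerGeometry":
        """Load a geometry block from a TOML or JSON config file."""
        text = open(path, "rb").read()
        if str(path).endswith(".json"):
            d = json.loads(text)
        else:
            d = tomllib.loads(text.decode())
        if "geometry" in d:
            d = d["geometry"]
        return cls.from_dict(d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def row_to_angle(y, g: ScannerGeometry):
    """Mirror angle for scan row ``y``: ``theta = dtheta*(y - y_pi4) + pi/4``."""
    y = np.asarray(y, dtype=float)
    theta = g.delta_theta * (y - g.y_pi4) + math.pi / 4
    return theta if theta.ndim else float(theta)


def angle_to_row(theta, g: ScannerGeometry):
    """Inverse of :func:`row_to_angle`."""
    theta = np.asarray(theta, dtype=float)
    y = (theta - math.pi / 4) / g.delta_theta + g.y_pi4
    return y if y.ndim else float(y)


def _check_theta_domain(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if np.any(~np.isfinite(theta)) or np.any(theta <= 0.0) or np.any(theta >= math.pi / 2):
        raise GeometryError(
            "mirror angle must lie strictly inside (0, pi/2): the reflected ray "
            "never meets the object plane outside this interval"
        )
    return theta


def angle_to_object_y(theta, r: float):
    """Object-plane line position ``y_d = r*tan(pi/2 - 2*theta)`` (mm).

    Zero at ``theta = pi/4`` and antisymmetric about it.
    """
    theta = _check_theta_domain(theta)
    y_d = r * np.tan(math.pi / 2 - 2.0 * theta)
    return y_d if y_d.ndim else float(y_d)


def width_scale(theta):
    """In-line scaling factor ``h(theta) = sqrt(1 + 1/tan^2(2 theta)) = 1/sin(2 theta)``.

    Always >= 1; equals 1 at the normal point ``theta = pi/4`` and is
    symmetric about it.
    """
    theta = _check_theta_domain(theta)
    h = 1.0 / np.sin(2.0 * theta)
    return h if h.ndim else float(h)


def path_elongation(theta, r: float):
    """Optical-path elongation ``delta_r = r*(1/sin(2 theta) - 1)`` (mm), >= 0."""
    theta = _check_theta_domain(theta)
    dr = r * (1.0 / np.sin(2.0 * theta) - 1.0)
    return dr if np.ndim(dr) else float(dr)


def linearized_object_y(theta, r: float):
    """Small-angle linearization ``y_d ~ -r*(2*theta - pi/2)`` (mm)."""
    theta = np.asarray(theta, dtype=float)
    y = -r * (2.0 * theta - math.pi / 2)
    return y if y.ndim else float(y)


def pixel_to_object(x, y, g: ScannerGeometry):
    """Map pixel coordinates to object-plane coordinates (mm).

    ``x`` is the signed column offset from the central column (pixels);
    ``y`` is the row index.  Returns ``(x_d, y_d)`` where
    ``y_d = r*tan(pi/2 - 2*theta(y))`` and ``x_d = x*delta_x*h(theta(y))``.
    """
    theta = row_to_angle(y, g)
    y_d = angle_to_object_y(theta, g.r_mm)
    x_d = np.asarray(x, dtype=float) * g.delta_x_mm * width_scale(theta)
    if np.ndim(x_d) == 0:
        x_d = float(x_d)
    return x_d, y_d


def object_to_pixel(x_d, y_d, g: ScannerGeometry):
    """Inverse of :func:`pixel_to_object`: object-plane mm to (x offset, row)."""
    y_d = np.asarray(y_d, dtype=float)
    gamma = np.arctan2(y_d, g.r_mm)
    theta = (math.pi / 2 - gamma) / 2.0
    y = angle_to_row(theta, g)
    x = np.asarray(x_d, dtype=float) / (g.delta_x_mm * width_scale(theta))
    if np.ndim(x) == 0:
        x, y = float(x), float(y)
    return x, y


@dataclass(frozen=True)
class LinearRange:
    """Symmetric mirror-angle interval over which the sweep is near-linear.

    ``gamma_half_width`` is the half-width of the interval of
    ``gamma = pi/2 - 2*theta`` (rad); ``theta_interval`` the corresponding
    mirror-angle interval; ``max_rel_elongation`` the relative path
    elongation ``delta_r / r`` attained at the interval edges.
    """

    gamma_half_width: float
    theta_interval: tuple[float, float]
    max_rel_elongation: float


def linear_range(max_rel_elongation: float) -> LinearRange:
    """Widest symmetric gamma interval keeping ``delta_r/r`` within a bound.

    Inverts the edge condition ``1/cos(gamma) - 1 = max_rel_elongation``:
    the half-width is ``arccos(1/(1 + tol))``.  A tolerance of 0 gives the
    degenerate interval ``{gamma = 0}``; tolerances must stay below
    ``sqrt(2) - 1`` (the elongation at gamma = pi/4, where the interval
    would reach the plane-parallel ray).
    """
    tol = float(max_rel_elongation)
    if not (0.0 <= tol < math.sqrt(2) - 1):
        raise GeometryError(
            f"max_rel_elongation must lie in [0, sqrt(2)-1), got {tol}"
        )
    g_half = math.acos(1.0 / (1.0 + tol))
    return LinearRange(
        gamma_half_width=g_half,
        theta_interval=(math.pi / 4 - g_half / 2, math.pi / 4 + g_half / 2),
        max_rel_elongation=(1.0 / math.cos(g_half) - 1.0) if g_half else 0.0,
    )


# ---------------------------------------------------------------------------
# Rectification
# ---------------------------------------------------------------------------

def rectify(image: np.ndarray, g: ScannerGeometry, target_pitch: float):
    """Resample a scanned image onto a uniform object-plane grid.

    The output grid covers the object-plane footprint of the input frame at
    ``target_pitch`` mm/px in both axes.  Each output sample is obtained by
    inverse-mapping its object coordinates through the tangential model and
    bilinearly interpolating the source; samples whose source coordinates
    fall outside the frame are masked (no extrapolation).

    Parameters
    ----------
    image
        2-D ``(rows, cols)`` or 3-D ``(rows, cols, bands)`` array.
    g
        Scanner geometry (rows must map into mirror angles in (0, pi/2)).
    target_pitch
        Output pixel pitch, mm per pixel.

    Returns
    -------
    rectified : ndarray, float
        ``(ny, nx[, bands])`` resampled image; masked samples are NaN.
    mask : ndarray, bool
        True where the output sample is valid.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise GeometryError("cannot rectify an empty image")
    if not (target_pitch > 0):
        raise GeometryError("target_pitch must be > 0")
    squeeze = image.ndim == 2
    if squeeze:
        image = image[:, :, None]
    n_rows, n_cols, n_bands = image.shape

    # object-plane footprint of the source frame
    rows = np.arange(n_rows, dtype=float)
    theta = row_to_angle(rows, g)
    _check_theta_domain(theta)
    y_obj = angle_to_object_y(theta, g.r_mm)
    half_w = g.x_center * g.delta_x_mm  # narrowest line is at theta = pi/4 (h = 1)
    y_lo, y_hi = float(np.min(y_obj)), float(np.max(y_obj))

    y_grid = np.arange(y_lo, y_hi + target_pitch / 2, target_pitch)
    x_grid = np.arange(-half_w, half_w + target_pitch / 2, target_pitch)
    Xd, Yd = np.meshgrid(x_grid, y_grid)

    x_px, y_px = object_to_pixel(Xd, Yd, g)
    col = x_px + g.x_center
    valid = (y_px >= 0) & (y_px <= n_rows - 1) & (col >= 0) & (col <= n_cols - 1)

    out = np.full((len(y_grid), len(x_grid), n_bands), np.nan)
    coords = np.vstack([y_px.ravel(), col.ravel()])
    for b in range(n_bands):
        band = map_coordinates(
            image[:, :, b].astype(float), coords, order=1, mode="constant", cval=np.nan
        ).reshape(Xd.shape)
        out[:, :, b] = np.where(valid, band, np.nan)
    mask = valid & np.all(np.isfinite(out), axis=2)
    out[~mask] = np.nan
    if squeeze:
        out = out[:, :, 0]
    return out, mask


# ---------------------------------------------------------------------------
# Geometry estimation from grid scans
# ---------------------------------------------------------------------------

def detect_grid_rows(profile: np.ndarray, *, threshold: float | None = None) -> np.ndarray:
    """Row centers of dark grid lines in a scan-direction intensity profile.

    ``profile`` is a 1-D intensity trace along the scan axis (e.g., one
    column of a grid-target scan).  Rows below ``threshold`` (default: the
    min/max midpoint) are dark; each contiguous dark run yields one line
    center: the midpoint of the two half-level edge crossings, located to
    sub-pixel by linear interpolation (exact when edges are linear ramps,
    as produced by area sampling plus bilinear resampling).  Runs touching
    the profile boundary are dropped, since their centers are biased by
    truncation.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 3:
        raise GeometryError("profile must be 1-D with >= 3 samples")
    if threshold is None:
        threshold = 0.5 * (p.min() + p.max())
    dark = p < threshold
    centers = []
    i = 0
    n = p.size
    while i < n:
        if dark[i]:
            j = i
            while j < n and dark[j]:
                j += 1
            if i > 0 and j < n:  # interior run only
                left = i - 1 + (p[i - 1] - threshold) / (p[i - 1] - p[i])
                right = j - 1 + (p[j - 1] - threshold) / (p[j - 1] - p[j])
                centers.append(0.5 * (left + right))
            i = j
        else:
            i += 1
    return np.asarray(centers)


@dataclass
class GeometryFit:
    """Result of :func:`fit_geometry`."""

    r_mm: float
    y_pi4: float
    grid_offset_mm: float
    residuals_mm: np.ndarray = field(repr=False)
    rms_mm: float = 0.0


def fit_geometry(
    edge_rows: np.ndarray,
    cell_mm: float,
    g0: ScannerGeometry,
) -> GeometryFit:
    """Estimate ``r`` and ``y_pi4`` from detected grid-edge rows.

    The rows of detected grid lines in a scan of a uniform grid target
    (pitch ``cell_mm``) are mapped to object positions through the
    tangential model; a nonlinear least-squares fit adjusts ``r``,
    ``y_pi4`` and a global grid offset so that the mapped positions match
    a uniform ladder ``offset + k*cell_mm``.  The residual series (mm) is
    returned for downstream noise analysis.

    Requires at least 3 edges; ``g0`` supplies the fixed stepper
    resolution and the initial guess for ``r`` and ``y_pi4``.
    """
    edge_rows = np.sort(np.asarray(edge_rows, dtype=float))
    if edge_rows.size < 3:
        raise FitError(
            f"fit_geometry needs >= 3 grid edges, got {edge_rows.size}"
        )
    if not (cell_mm > 0):
        raise GeometryError("cell_mm must be > 0")
    dtheta = g0.delta_theta
    k = np.arange(edge_rows.size, dtype=float)

    def predict(params):
        r, y_pi4 = params
        theta = dtheta * (edge_rows - g0.y_pi4 - y_pi4) + math.pi / 4
        return r * np.tan(math.pi / 2 - 2.0 * theta)

    def residual(params):
        pos = predict(params)
        # grid positions descend with increasing row (y_d decreases with theta);
        # project out the ladder offset analytically
        ladder = -k * cell_mm
        off = np.mean(pos - ladder)
        return pos - ladder - off

    try:
        sol = optimize.least_squares(
            residual, x0=[g0.r_mm, 0.0], method="lm", max_nfev=10000
        )
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise FitError(f"geometry fit failed: {exc}") from exc
    if not sol.success or not np.isfinite(sol.x).all() or sol.x[0] <= 0:
        raise FitError(
            f"geometry fit did not converge (status {sol.status}): {sol.message}"
        )
    r_hat, dy = sol.x
    pos = predict(sol.x)
    off = float(np.mean(pos + k * cell_mm))
    res = residual(sol.x)
    return GeometryFit(
        r_mm=float(r_hat),
        y_pi4=float(g0.y_pi4 + dy),
        grid_offset_mm=off,
        residuals_mm=res,
        rms_mm=float(np.sqrt(np.mean(res**2))),
    )


def residual_noise_sigma(
    residuals: np.ndarray,
    *,
    clip_factor: float = 3.0,
    n_bins: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Split fit residuals into a smooth trend and Gaussian noise; estimate sigma.

    Slowly varying deterministic structure (e.g., a cosine-like misalignment
    trace) concentrates its power in few Fourier bins.  Bins whose spectral
    power exceeds ``clip_factor`` times the median bin power are attributed
    to the trend: their amplitude is clipped down to the average noise
    spectral power density (estimated from the unclipped bins), and the
    removed excess is the deterministic component.  A Gaussian PDF is then
    fitted to the histogram of the remainder and its standard deviation
    returned.

    Under a pure-noise null the clipping still removes a known fraction of
    power (the exponential tail of the bin-power distribution above the
    threshold); the returned sigma divides this fraction back out, so the
    estimator is unbiased when no trend is present and the correction is
    absorbed by the clipped trend bins when one is.

    Returns
    -------
    sigma_mm : float
        Histogram-fitted Gaussian standard deviation of the stochastic part.
    trend : ndarray
        The removed deterministic component (same length as input).
    """
    x = np.asarray(residuals, dtype=float)
    if x.size < 32:
        raise FitError(f"residual_noise_sigma needs >= 32 samples, got {x.size}")
    F = np.fft.rfft(x)
    power = np.abs(F) ** 2
    med = np.median(power[1:])
    is_trend = power > clip_factor * med
    is_trend[0] = True  # DC / mean is always deterministic
    noise_bins = power[1:][~is_trend[1:]]
    p_avg = float(np.mean(noise_bins)) if noise_bins.size else 0.0
    scale = np.ones_like(power)
    above = is_trend & (power > 0)
    scale[above] = np.sqrt(p_avg / power[above])  # clip down to the noise floor
    scale[0] = 0.0
    noise = np.fft.irfft(F * scale, n=x.size)
    trend = x - noise
    s = float(np.std(noise))
    if s == 0.0:
        return 0.0, trend

    # power fraction a pure-noise signal retains after clipping its
    # exponential-tail bins (P > k*mean, k = clip_factor*ln2) to the
    # truncated-mean floor; divide the fitted sigma by its square root
    k = clip_factor * math.log(2.0)
    tail = math.exp(-k)
    trunc_mean = (1.0 - (1.0 + k) * tail) / (1.0 - tail)
    retained = 1.0 - ((1.0 + k) * tail - tail * trunc_mean)
    correction = 1.0 / math.sqrt(retained)

    if n_bins is None:
        n_bins = max(16, int(np.sqrt(noise.size)))
    counts, edges = np.histogram(noise, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(z, mu, sigma):
        return np.exp(-0.5 * ((z - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))

    try:
        popt, _ = optimize.curve_fit(gauss, centers, counts, p0=[0.0, s], maxfev=5000)
        sigma = abs(float(popt[1]))
    except RuntimeError:
        sigma = s
    return sigma * correction, trend
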