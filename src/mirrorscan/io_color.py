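"""File I/O, band extraction, CIE color reconstruction and the spec sheet.

ENVI cubes (text ``.hdr`` header + raw binary body) are the de facto
exchange format for hyperspectral data; this module reads all three
interleaves (BIL/BIP/BSQ) and writes BIL.  Color reconstruction integrates
spectra against the CIE 1931 2-degree standard-observer color matching
functions (evaluated from the published piecewise-Gaussian analytic fit)
and normalizes to a white reference so that the reference maps to RGB
white; XYZ is converted to sRGB with the standard D65 matrix and gamma
encoding.  ``build_report`` assembles the benchmark spec sheet from the
fits and models produced by the other modules.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path

import numpy as np
import tifffile

from .simulator import HyperCube

__all__ = [
    "read_envi",
    "write_envi",
    "extract_band",
    "cie_cmf",
    "cie_color",
    "BenchmarkReport",
    "build_report",
    "write_band_tiff",
]


class EnviError(IOError):
    """Malformed or inconsistent ENVI header/body pair."""


_DTYPE_CODES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_CODE_FOR = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}


def _parse_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise EnviError("not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    key, buf, in_brace = None, [], False
    for line in text.splitlines()[1:]:
        if in_brace:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_brace, key, buf = False, None, []
            continue
        if "=" not in line:
            continue
        k, v = line.split("=", 1)
        k, v = k.strip().lower(), v.strip()
        if v.startswith("{") and "}" not in v:
            key, buf, in_brace = k, [v], True
        else:
            fields[k] = v
    return fields


def read_envi(path) -> HyperCube:
    """Read an ENVI cube (``.hdr`` + sibling raw file) into a HyperCube.

    Accepts BIL, BIP and BSQ interleaves; the returned cube is always
    (lines, samples, bands).  The wavelength array, exposure and bit-depth
    metadata keys are restored when present.
    """
    hdr_path = Path(path)
    if hdr_path.suffix != ".hdr":
        hdr_path = hdr_path.with_suffix(".hdr")
    fields = _parse_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype = _DTYPE_CODES[int(fields["data type"])]
    except KeyError as exc:
        raise EnviError(f"ENVI header missing required field: {exc}") from exc
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", 0))

    raw_path = hdr_path.with_suffix(".raw")
    if not raw_path.exists():
        for ext in ("", ".img", ".dat", ".bil"):
            cand = hdr_path.with_suffix(ext) if ext else hdr_path.with_suffix("")
            if cand.exists() and cand != hdr_path:
                raw_path = cand
                break
    data = np.fromfile(raw_path, dtype=dtype, offset=offset)
    if data.size != samples * lines * bands:
        raise EnviError(
            f"body size {data.size} does not match header "
            f"{lines}x{samples}x{bands}"
        )
    if interleave == "bil":
        cube = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = data.reshape(lines, samples, bands)
    elif interleave == "bsq":
        cube = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise EnviError(f"unknown interleave {interleave!r}")

    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip().strip("{}")
        wavelengths = np.array([float(t) for t in wl_text.replace(",", " ").split()])
    else:
        wavelengths = np.arange(bands, dtype=float)
    meta = {}
    for k in ("t_exp_s", "gain_counts", "gain_db"):
        if k in fields:
            meta[k] = float(fields[k])
    meta["bits"] = int(fields.get("bits", 16 if dtype == np.uint16 else 8))
    if "geometry" in fields:
        try:
            meta["geometry"] = json.loads(fields["geometry"].strip().strip("{}"))
        except json.JSONDecodeError:
            pass
    return HyperCube(data=np.ascontiguousarray(cube), wavelengths_nm=wavelengths,
                     metadata=meta)


def write_envi(cube: HyperCube, path) -> None:
    """Write a HyperCube as an ENVI pair (``.hdr`` + ``.raw``), BIL interleave."""
    hdr_path = Path(path)
    if hdr_path.suffix != ".hdr":
        hdr_path = hdr_path.with_suffix(".hdr")
    raw_path = hdr_path.with_suffix(".raw")
    data = np.asarray(cube.data)
    if data.dtype not in _CODE_FOR:
        data = data.astype(np.float64)
    lines, samples, bands = data.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths_nm)
    lines_out = [
        "ENVI",
        "description = {mirrorscan hyperspectral cube}",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODE_FOR[data.dtype]}",
        "interleave = bil",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"wavelength = {{ {wl} }}",
    ]
    for k in ("t_exp_s", "gain_counts", "gain_db", "bits"):
        if k in cube.metadata:
            lines_out.append(f"{k} = {cube.metadata[k]}")
    if "geometry" in cube.metadata:
        lines_out.append(f"geometry = {{ {json.dumps(cube.metadata['geometry'])} }}")
    hdr_path.write_text("\n".join(lines_out) + "\n")
    data.transpose(0, 2, 1).tofile(raw_path)  # BIL: line-major, band, sample


def extract_band(cube: HyperCube, lam_nm: float):
    """Return the 2-D plane of the channel nearest ``lam_nm``.

    Ties between two equidistant channels go to the lower index.  Returns
    ``(image, actual_center_nm)``; wavelengths outside the axis range are
    an error.
    """
    wl = cube.wavelengths_nm
    if not (wl.min() <= lam_nm <= wl.max()):
        raise ValueError(
            f"{lam_nm} nm outside the cube's wavelength range "
            f"[{wl.min():.1f}, {wl.max():.1f}]"
        )
    idx = int(np.argmin(np.abs(wl - lam_nm)))  # argmin takes the first (lower) tie
    return cube.data[:, :, idx], float(wl[idx])


def write_band_tiff(image: np.ndarray, path, *, bits: int = 16) -> None:
    """Write a single band (or mask) as an 8- or 16-bit TIFF."""
    dtype = np.uint8 if bits == 8 else np.uint16
    tifffile.imwrite(path, np.asarray(image).astype(dtype))


# ---------------------------------------------------------------------------
# CIE 1931 color reconstruction
# ---------------------------------------------------------------------------

def _pw_gauss(x, mu, s1, s2):
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def cie_cmf(lam_nm) -> np.ndarray:
    """CIE 1931 2-degree color matching functions on a wavelength axis (nm).

    Evaluated from the piecewise-Gaussian analytic approximation of the
    tabulated observer; returns an ``(n, 3)`` array of (xbar, ybar, zbar).
    """
    lam = np.asarray(lam_nm, dtype=float)
    x = (1.056 * _pw_gauss(lam, 599.8, 37.9, 31.0)
         + 0.362 * _pw_gauss(lam, 442.0, 16.0, 26.7)
         - 0.065 * _pw_gauss(lam, 501.1, 20.4, 26.2))
    y = (0.821 * _pw_gauss(lam, 568.8, 46.9, 40.5)
         + 0.286 * _pw_gauss(lam, 530.9, 16.3, 31.1))
    z = (1.217 * _pw_gauss(lam, 437.0, 11.8, 36.0)
         + 0.681 * _pw_gauss(lam, 459.0, 26.0, 13.8))
    return np.stack([x, y, z], axis=-1)


#: linear sRGB (D65) from XYZ
_XYZ_TO_SRGB = np.array([
    [3.2404542, -1.5371385, -0.4985314],
    [-0.9692660, 1.8760108, 0.0415560],
    [0.0556434, -0.2040259, 1.0572252],
])


def _gamma_srgb(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, 0.0, 1.0)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1 / 2.4) - 0.055)


def cie_color(spectra, wavelengths_nm, *, white_spectrum=None, cmf=None):
    """Reconstruct XYZ and sRGB from spectra via the CIE 1931 observer.

    ``spectra`` is ``(..., n_channels)`` (a cube's data, or one spectrum);
    integration is a rectangle rule on the native wavelength axis over the
    CMF support.  The result is normalized so that ``white_spectrum``
    (default: equal-energy) maps to RGB white — the per-channel flat-field
    convention — then converted with the XYZ->sRGB D65 matrix, gamma
    encoded and clipped to [0, 1].

    Returns ``(xyz, rgb)`` with trailing axis 3.
    """
    if isinstance(spectra, HyperCube):
        S = np.asarray(spectra.data, dtype=float)
        lam = spectra.wavelengths_nm
    else:
        S = np.asarray(spectra, dtype=float)
        lam = np.asarray(wavelengths_nm, dtype=float)
    M = cie_cmf(lam) if cmf is None else np.asarray(cmf, float)
    support = M.sum(axis=1) > 1e-6
    if not support.any():
        raise ValueError("wavelength axis does not overlap the CMF support")
    dlam = np.gradient(lam)
    W = M * dlam[:, None]  # quadrature-weighted CMFs

    xyz = np.tensordot(S, W, axes=([-1], [0]))
    white = np.ones_like(lam) if white_spectrum is None else np.asarray(white_spectrum, float)
    white_xyz = white @ W
    rgb_lin = xyz @ _XYZ_TO_SRGB.T
    white_rgb = white_xyz @ _XYZ_TO_SRGB.T
    if np.any(white_rgb <= 0):
        raise ValueError("white reference maps to a non-positive RGB channel")
    rgb = _gamma_srgb(rgb_lin / white_rgb)
    return xyz, rgb


# ---------------------------------------------------------------------------
# Benchmark spec sheet
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Spec-sheet summary of a characterized scanner.

    Every populated field is traceable to an estimator in this package;
    fields left ``None`` are reported as absent, never fabricated.
    """

    wavelength_range_nm: tuple[float, float] | None = None
    spectral_channels: int | None = None
    resolution_bound_nm: float | None = None
    resolution_px: tuple[int, int] | None = None
    steps_per_rev: int | None = None
    linear_range_rad: float | None = None
    efficiency_at_reference: float | None = None
    reference_exposure_s: float | None = None
    resolved_distance_mm: float | None = None
    fitted_r_mm: float | None = None
    microstep_sigma_mm: float | None = None
    t_extra_s: float | None = None

    _UNITS = {
        "wavelength_range_nm": "nm",
        "spectral_channels": "channels",
        "resolution_bound_nm": "nm",
        "resolution_px": "px",
        "steps_per_rev": "steps/rev",
        "linear_range_rad": "rad",
        "efficiency_at_reference": "fraction",
        "reference_exposure_s": "s",
        "resolved_distance_mm": "mm",
        "fitted_r_mm": "mm",
        "microstep_sigma_mm": "mm",
        "t_extra_s": "s",
    }

    def to_json_dict(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            out[k] = list(v) if isinstance(v, tuple) else v
            out[f"{k}_units"] = self._UNITS[k]
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    def to_markdown(self) -> str:
        rows = ["| Specification | Value | Units |", "|---|---|---|"]
        for k, v in asdict(self).items():
            shown = "absent" if v is None else (f"{v}")
            rows.append(f"| {k.replace('_', ' ')} | {shown} | {self._UNITS[k]} |")
        return "\n".join(rows)


def build_report(
    *,
    geometry_fit=None,
    extra_delay_fit=None,
    calibration=None,
    microstep_sigma_mm: float | None = None,
    linear_range=None,
    efficiency: float | None = None,
    reference_exposure_s: float | None = None,
    resolved_distance_mm: float | None = None,
    resolution_px: tuple[int, int] | None = None,
    steps_per_rev: int | None = None,
    n_spectral_pixels: int | None = None,
) -> BenchmarkReport:
    """Assemble the spec sheet from estimator outputs (all optional).

    Accepts a :class:`~mirrorscan.geometry.GeometryFit`, an
    :class:`~mirrorscan.timing.ExtraDelayFit`, a
    :class:`~mirrorscan.calibration.SpectralCalibration`, plus scalar
    benchmark numbers; absent sections stay absent in the report.
    """
    rep = BenchmarkReport()
    if geometry_fit is not None:
        rep.fitted_r_mm = geometry_fit.r_mm
    if extra_delay_fit is not None:
        rep.t_extra_s = extra_delay_fit.t_extra_s
    if calibration is not None:
        rep.wavelength_range_nm = calibration.wavelength_range
        rep.resolution_bound_nm = calibration.resolution_bound_nm
        if n_spectral_pixels is not None and calibration.px_per_channel:
            from .calibration import channel_count
            rep.spectral_channels = channel_count(
                n_spectral_pixels, calibration.px_per_channel
            )
    rep.microstep_sigma_mm = microstep_sigma_mm
    if linear_range is not None:
        rep.linear_range_rad = linear_range.gamma_half_width
    rep.efficiency_at_reference = efficiency
    rep.reference_exposure_s = reference_exposure_s
    rep.resolved_distance_mm = resolved_distance_mm
    rep.resolution_px = resolution_px
    rep.steps_per_rev = steps_per_rev
    return rep
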