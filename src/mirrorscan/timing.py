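"""Acquisition-timing budget of a line-scanning imager.

Each scan line costs the exposure time plus deterministic overhead
(network transfer, driver/API calls, buffer copies, actuator motion) plus a
random operating-system scheduling delay:

    T_line = T_exp + T_rx + T_api + T_mcpy + T_act + T_rand
           = T_exp + T_extra + T_rand.

The line rate (lines per second, the scan analogue of FPS) is 1/T_line, and
the *efficiency* eps = T_exp / T_line measures the fraction of wall time
actually spent collecting photons; it approaches 1 as exposure dominates.
The constant overhead T_extra is estimated from timing logs by nonlinear
least squares on the measured line rates against 1/(T_exp + T_extra).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DelayModel",
    "TimingLog",
    "ExtraDelayFit",
    "transfer_time",
    "lps",
    "efficiency",
    "fit_extra_delay",
    "ideal_acquisition_time",
    "image_time",
]

#: canonical timing-log CSV columns
LOG_COLUMNS = [
    "t_exp_s", "wall_s", "t_rx_s", "t_api_s", "t_mcpy_s", "t_act_s",
    "bit_depth", "scenario",
]

RAND_LAWS = ("exponential", "half_normal", "none")


class TimingError(ValueError):
    """Invalid timing parameter."""


@dataclass(frozen=True)
class DelayModel:
    """Additive per-line timing budget (all components in seconds).

    ``t_rand_sigma`` is the scale of the random OS-delay law: the mean of an
    exponential law, or the sigma of a half-normal one.
    """

    t_exp: float = 0.1
    t_rx: float = 0.0
    t_api: float = 0.0
    t_mcpy: float = 0.0
    t_act: float = 0.0
    t_rand_sigma: float = 0.0
    t_rand_law: str = "none"

    def __post_init__(self) -> None:
        for name in ("t_exp", "t_rx", "t_api", "t_mcpy", "t_act", "t_rand_sigma"):
            if getattr(self, name) < 0:
                raise TimingError(f"{name} must be >= 0")
        if self.t_rand_law not in RAND_LAWS:
            raise TimingError(f"t_rand_law must be one of {RAND_LAWS}")

    @property
    def t_extra(self) -> float:
        """Deterministic non-exposure overhead per line."""
        return self.t_rx + self.t_api + self.t_mcpy + self.t_act

    @property
    def mean_t_rand(self) -> float:
        """Expected random OS delay per line."""
        if self.t_rand_law == "none" or self.t_rand_sigma == 0:
            return 0.0
        if self.t_rand_law == "exponential":
            return self.t_rand_sigma
        return self.t_rand_sigma * math.sqrt(2.0 / math.pi)  # half-normal mean

    @property
    def t_line(self) -> float:
        """Expected total per-line time."""
        return self.t_exp + self.t_extra + self.mean_t_rand

    def draw_t_rand(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample ``n`` random OS delays from the configured law."""
        if self.t_rand_law == "none" or self.t_rand_sigma == 0:
            return np.zeros(n)
        if self.t_rand_law == "exponential":
            return rng.exponential(self.t_rand_sigma, n)
        return np.abs(rng.normal(0.0, self.t_rand_sigma, n))

    def with_exposure(self, t_exp: float) -> "DelayModel":
        return replace(self, t_exp=t_exp)


class TimingLog:
    """Per-line acquisition timing records, backed by a DataFrame.

    Columns follow the fixed CSV schema ``t_exp_s, wall_s, t_rx_s, t_api_s,
    t_mcpy_s, t_act_s, bit_depth, scenario``; component breakdowns may be
    zero when not measured.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ("t_exp_s", "wall_s") if c not in df.columns]
        if missing:
            raise TimingError(f"timing log missing required columns: {missing}")
        df = df.copy()
        for c in LOG_COLUMNS:
            if c not in df.columns:
                df[c] = "" if c == "scenario" else 0
        if (df["wall_s"] < df["t_exp_s"]).any():
            raise TimingError("per-line wall time cannot be below exposure time")
        self.df = df[LOG_COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, t_exp_s, wall_s, **extra) -> "TimingLog":
        return cls(pd.DataFrame({"t_exp_s": t_exp_s, "wall_s": wall_s, **extra}))

    @classmethod
    def from_csv(cls, path) -> "TimingLog":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def mean_wall_by_level(self) -> pd.Series:
        return self.df.groupby("t_exp_s")["wall_s"].mean()

    def efficiency_by_level(self) -> pd.Series:
        """Empirical per-level efficiency, t_exp / mean(wall time)."""
        m = self.mean_wall_by_level()
        return pd.Series(m.index.to_numpy() / m.to_numpy(), index=m.index, name="efficiency")


def transfer_time(h: int, w: int, b: float, r_b: float, omega: float = 1.019) -> float:
    """Network transfer time of one frame, ``h*w*b*omega / r_b`` seconds.

    ``h``, ``w`` are sensor height/width in pixels, ``b`` the bit depth
    (bits/pixel; 0 is allowed as a degenerate no-payload case), ``r_b`` the
    link bitrate in bits/s and ``omega >= 1`` the protocol overhead factor.
    """
    if h <= 0 or w <= 0 or b < 0 or r_b <= 0 or omega < 1:
        raise TimingError(
            "transfer_time requires h, w, r_b > 0, b >= 0, omega >= 1"
        )
    return h * w * b * omega / r_b


def lps(t_exp: float, t_extra: float) -> float:
    """Lines per second, ``1 / (t_exp + t_extra)``."""
    if t_exp <= 0:
        raise TimingError("t_exp must be > 0")
    if t_extra < 0:
        raise TimingError("t_extra must be >= 0")
    return 1.0 / (t_exp + t_extra)


def efficiency(t_exp: float, t_extra: float, t_rand: float = 0.0) -> float:
    """Scanning efficiency ``eps = t_exp / (t_exp + t_extra + t_rand)``.

    Strictly increasing in ``t_exp`` for fixed overhead, with supremum 1.
    """
    if t_exp <= 0:
        raise TimingError("t_exp must be > 0")
    if t_extra < 0 or t_rand < 0:
        raise TimingError("overheads must be >= 0")
    return t_exp / (t_exp + t_extra + t_rand)


@dataclass
class ExtraDelayFit:
    """Result of :func:`fit_extra_delay`."""

    t_extra_s: float
    residual_lps_rms: float
    residual_wall_std_s: float
    n_levels: int
    n_records: int


def fit_extra_delay(log: TimingLog) -> ExtraDelayFit:
    """Estimate the constant overhead from a timing log.

    Nonlinear least squares of the measured line rates (1/wall time) against
    the model ``lps = 1/(t_exp + t_extra)`` across all records; requires at
    least 3 distinct exposure levels.  The wall-time residual spread
    (attributable to the random OS delay) is reported alongside.
    """
    df = log.df
    levels = np.unique(df["t_exp_s"].to_numpy())
    if levels.size < 3:
        raise TimingError(
            f"fit_extra_delay needs >= 3 distinct exposure levels, got {levels.size}"
        )
    t_exp = df["t_exp_s"].to_numpy(float)
    wall = df["wall_s"].to_numpy(float)
    meas_lps = 1.0 / wall

    def residual(p):
        return meas_lps - 1.0 / (t_exp + p[0])

    sol = optimize.least_squares(residual, x0=[max(np.mean(wall - t_exp), 1e-9)],
                                 bounds=([0.0], [np.inf]))
    if not sol.success:
        raise TimingError(f"overhead fit failed: {sol.message}")
    t_extra = float(sol.x[0])
    res_wall = wall - (t_exp + t_extra)
    return ExtraDelayFit(
        t_extra_s=t_extra,
        residual_lps_rms=float(np.sqrt(np.mean(sol.fun**2))),
        residual_wall_std_s=float(np.std(res_wall)),
        n_levels=int(levels.size),
        n_records=len(df),
    )


MODALITIES = ("snapshot", "staring", "whiskbroom", "pushbroom", "rotating_mirror")


def ideal_acquisition_time(
    modality: str,
    t_exp: float,
    aux_time: float = 0.0,
    *,
    n_lines: int = 1,
    n_filters: int = 1,
    n_x: int = 1,
    n_y: int = 1,
) -> float:
    """Ideal (overhead-free) acquisition time of a full image, by modality.

    ``aux_time`` is the per-step auxiliary delay of the modality: filter
    change (staring), platform move (whiskbroom/pushbroom) or mirror
    actuation (rotating_mirror).

    - snapshot:        T_exp
    - staring:         (T_exp + T_change) * N_filters
    - whiskbroom:      (T_exp + T_move) * N_x * N_y
    - pushbroom:       (T_exp + T_move) * N_line
    - rotating_mirror: (T_exp + T_act) * N_line
    """
    if min(n_lines, n_filters, n_x, n_y) < 1:
        raise TimingError("counts must be >= 1")
    key = modality.lower().replace(" ", "_").replace("-", "_")
    if key == "snapshot":
        return t_exp
    if key == "staring":
        return (t_exp + aux_time) * n_filters
    if key == "whiskbroom":
        return (t_exp + aux_time) * n_x * n_y
    if key in ("pushbroom", "rotating_mirror"):
        return (t_exp + aux_time) * n_lines
    raise TimingError(f"unknown modality {modality!r}; expected one of {MODALITIES}")


def image_time(
    n_lines: int,
    t_line: float,
    eps_avg: float,
    *,
    formula: str = "per_line",
) -> float:
    """Total image acquisition time ``T_img = N_lines * T_line / eps_avg``.

    With ``formula="per_line"`` (default) the second argument is the mean
    per-line wall time and is divided by the average efficiency, which
    double-counts overhead when ``t_line`` already includes it; this is the
    conventional benchmark form.  ``formula="exposure"`` treats the second
    argument as the exposure time instead, giving
    ``N_lines * T_exp / eps_avg`` — algebraically the expected total wall
    time without double counting.
    """
    if not (0.0 < eps_avg <= 1.0):
        raise TimingError("eps_avg must lie in (0, 1]")
    if n_lines < 0:
        raise TimingError("n_lines must be >= 0")
    if formula not in ("per_line", "exposure"):
        raise TimingError("formula must be 'per_line' or 'exposure'")
    return n_lines * t_line / eps_avg
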