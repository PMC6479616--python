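import numpy as np
import pytest

from mirrorscan import (
    DelayModel, NoiseSpec, SceneSpec, ScannerGeometry,
    detect_grid_rows, simulate_scan,
)


def small_geometry(r_mm: float, n_rows: int = 480, n_cols: int = 64) -> ScannerGeometry:
    """Reduced-row geometry whose gamma span stays at [-pi/8, +pi/8].

    The reference device sweeps 1200 rows at one step per row; scaling the
    microstep factor by 1200/n_rows preserves the angular span so the
    distortion regime matches full-size scans.
    """
    return ScannerGeometry(
        r_mm=r_mm,
        microstep_factor=1200.0 / n_rows,
        y_pi4=(n_rows - 1) / 2.0,
        delta_x_mm=0.5,
        n_rows=n_rows,
        n_cols=n_cols,
    )


def scan_amsler(r_mm: float, *, n_rows: int = 480, noise: NoiseSpec | None = None,
                seed: int = 0, line_width_mm: float = 2.0, pitch_mm: float = 6.0):
    """Simulate a single-band Amsler-grid scan and return (cube, geometry).

    Grid lines are wider than the scan-row pitch everywhere in the frame so
    that no line is skipped by sampling.
    """
    g = small_geometry(r_mm, n_rows=n_rows)
    scene = SceneSpec(kind="amsler_grid", grid_pitch_mm=pitch_mm,
                      line_width_mm=line_width_mm)
    cube, _ = simulate_scan(
        scene, g, DelayModel(), noise or NoiseSpec(), t_exp=0.1,
        wavelengths_nm=np.array([550.0]), seed=seed,
    )
    return cube, g


def amsler_edge_rows(cube, g, *, x_mm: float = 3.0) -> np.ndarray:
    """Detected grid-line row centers along a column clear of vertical lines."""
    col = int(round(x_mm / g.delta_x_mm + g.x_center))
    return detect_grid_rows(cube.data[:, col, 0].astype(float))


@pytest.fixture
def geometry_225() -> ScannerGeometry:
    return small_geometry(225.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
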