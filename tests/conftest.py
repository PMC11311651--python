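import numpy as np
import pytest

from chipinvasion import Calibration, CellDetection, build_geometry


@pytest.fixture(scope="session")
def default_geom():
    return build_geometry()


@pytest.fixture
def identity_cal():
    return Calibration(um_per_px=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_detection(rng, center_xy, n_px=12, spread_px=3, cal=None):
    """Random multi-pixel detection around a physical center (identity cal)."""
    cal = cal or Calibration(um_per_px=1.0)
    cx, cy = center_xy
    cols = np.round(cx / cal.um_per_px + rng.integers(-spread_px, spread_px + 1, n_px))
    rows = np.round(cy / cal.um_per_px + rng.integers(-spread_px, spread_px + 1, n_px))
    footprint = np.unique(
        np.column_stack([rows, cols]).astype(int), axis=0
    )
    return CellDetection(
        centroid_um=(float(cx), float(cy)),
        pixel_footprint=footprint,
        area_um2=float(footprint.shape[0]) * cal.um_per_px**2,
        modality="fluorescence",
        calibration=cal,
    )


def brute_force_scores(dets, geom):
    """Exhaustive per-pixel oracle for crossings and max invasion distance.

    Loops over every footprint pixel of every detection and every window —
    deliberately naive and independent of the vectorized implementation.
    """
    crossed = [False] * geom.n_windows
    best = 0.0
    for det in dets:
        for x, y in det.footprint_um():
            if y > geom.crossing_boundary_y_um:
                for k, (lo, hi) in enumerate(geom.ipt_windows):
                    if lo <= x < hi:
                        crossed[k] = True
            if y - geom.post_center_y_um > best:
                best = y - geom.post_center_y_um
    return crossed, max(0.0, best)


def random_detection_field(rng, geom, n_dets=50, cal=None):
    """Detections scattered over the channel system, some past the posts."""
    x0, x1 = geom.active_window_x_um
    xs = rng.uniform(x0 - 100, x1 + 100, n_dets)
    ys = rng.uniform(-geom.channel_width_um, geom.channel_width_um + 200, n_dets)
    return [
        make_detection(rng, (x, y), cal=cal) for x, y in zip(xs, ys)
    ]
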