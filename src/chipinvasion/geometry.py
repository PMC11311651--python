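"""Parametric model of the chip layout and the invasion-scoring geometry.

Physical coordinate frame
-------------------------
The origin sits at the left end of the post row, on the line through the
post centers.  ``+x`` runs along the channel, ``+y`` points toward the
upper Matrigel channel, so the post outer edge (the crossing boundary)
lies at ``y = post_diameter_um / 2`` and invasion distances are positive.

A channel divider with ``n`` posts defines ``n + 1`` inter-post-threshold
(IPT) windows along ``x``.  Interior window boundaries sit at post center
x-coordinates; the two end windows are closed by the edges of the active
window (the x-extent that contains the post row).  Windows follow the
half-open convention ``[lo, hi)`` so every x belongs to exactly one window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChipGeometry",
    "Calibration",
    "GeometryError",
    "build_geometry",
    "ipt_window",
    "to_physical",
    "to_pixel",
]


class GeometryError(ValueError):
    """Raised for invalid chip dimensions or out-of-range window indices."""


@dataclass(frozen=True)
class ChipGeometry:
    """Physical layout of one channel divider and its scoring geometry.

    All lengths in μm.  ``ipt_windows`` is an ordered list of half-open
    ``(lo, hi)`` x-intervals tiling ``active_window_x_um``.
    """

    n_posts: int
    post_diameter_um: float
    post_gap_um: float
    channel_width_um: float
    channel_length_um: float
    post_center_y_um: float = 0.0
    active_window_x_um: tuple[float, float] = (0.0, 0.0)
    ipt_windows: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    crossing_boundary_y_um: float = 0.0

    @property
    def n_windows(self) -> int:
        return len(self.ipt_windows)

    @property
    def post_pitch_um(self) -> float:
        """Center-to-center post spacing."""
        return self.post_diameter_um + self.post_gap_um

    def post_centers(self) -> np.ndarray:
        """(n_posts, 2) array of post center coordinates in μm."""
        x0 = self.active_window_x_um[0] + self.post_gap_um + self.post_diameter_um / 2
        xs = x0 + np.arange(self.n_posts) * self.post_pitch_um
        ys = np.full(self.n_posts, self.post_center_y_um)
        return np.column_stack([xs, ys])

    def to_json(self) -> str:
        """Serialize the geometry for provenance records."""
        return json.dumps(
            {
                "n_posts": self.n_posts,
                "post_diameter_um": self.post_diameter_um,
                "post_gap_um": self.post_gap_um,
                "channel_width_um": self.channel_width_um,
                "channel_length_um": self.channel_length_um,
                "post_center_y_um": self.post_center_y_um,
                "active_window_x_um": list(self.active_window_x_um),
                "ipt_windows": [list(w) for w in self.ipt_windows],
                "crossing_boundary_y_um": self.crossing_boundary_y_um,
            },
            indent=2,
        )


def build_geometry(
    n_posts: int = 16,
    post_diameter_um: float = 150.0,
    post_gap_um: float = 200.0,
    channel_width_um: float = 1000.0,
    channel_length_um: float = 30000.0,
) -> ChipGeometry:
    """Build a :class:`ChipGeometry` from physical chip dimensions.

    Defaults describe the reference chip: 16 posts of 150 μm diameter with
    200 μm edge-to-edge gaps, separating 1 mm wide, 3 cm long channels.
    The post row occupies an active window much shorter than the channel;
    it is treated as centered along the channel, with the first and last
    IPT windows closed by the active-window edges.

    Raises
    ------
    GeometryError
        If any dimension is non-positive, ``n_posts < 1``, or the post row
        does not fit in the channel.
    """
    if n_posts < 1:
        raise GeometryError(f"n_posts must be >= 1, got {n_posts}")
    for name, value in [
        ("post_diameter_um", post_diameter_um),
        ("post_gap_um", post_gap_um),
        ("channel_width_um", channel_width_um),
        ("channel_length_um", channel_length_um),
    ]:
        if not value > 0:
            raise GeometryError(f"{name} must be > 0, got {value}")

    active_len = n_posts * post_diameter_um + (n_posts + 1) * post_gap_um
    if active_len > channel_length_um:
        raise GeometryError(
            f"post row ({active_len} um) does not fit in channel "
            f"({channel_length_um} um)"
        )

    # Origin at the active-window start, so the window spans [0, active_len].
    pitch = post_diameter_um + post_gap_um
    first_center_x = post_gap_um + post_diameter_um / 2
    boundaries = [0.0]
    boundaries += [first_center_x + i * pitch for i in range(n_posts)]
    boundaries.append(active_len)
    windows = tuple(
        (boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)
    )

    return ChipGeometry(
        n_posts=n_posts,
        post_diameter_um=post_diameter_um,
        post_gap_um=post_gap_um,
        channel_width_um=channel_width_um,
        channel_length_um=channel_length_um,
        post_center_y_um=0.0,
        active_window_x_um=(0.0, active_len),
        ipt_windows=windows,
        crossing_boundary_y_um=post_diameter_um / 2,
    )


def ipt_window(geometry: ChipGeometry, index: int) -> tuple[float, float]:
    """Return the half-open x-interval ``[lo, hi)`` of IPT window ``index``."""
    if not 0 <= index < geometry.n_windows:
        raise GeometryError(
            f"window index {index} out of range 0..{geometry.n_windows - 1}"
        )
    return geometry.ipt_windows[index]


@dataclass(frozen=True)
class Calibration:
    """Affine map between pixel and physical (μm) coordinates.

    ``origin_px`` is the pixel coordinate (x_px, y_px) mapped to the
    physical origin.  ``y_axis_toward_upper_channel`` states whether
    increasing pixel row index moves toward the upper channel (+y); for
    typical image conventions (row 0 at top, upper channel at the top of
    the frame) this is ``False``.
    """

    um_per_px: float = 1.0
    origin_px: tuple[float, float] = (0.0, 0.0)
    y_axis_toward_upper_channel: bool = True

    def __post_init__(self) -> None:
        if not self.um_per_px > 0:
            raise GeometryError(f"um_per_px must be > 0, got {self.um_per_px}")

    @property
    def y_sign(self) -> float:
        return 1.0 if self.y_axis_toward_upper_channel else -1.0


def to_physical(cal: Calibration, px: tuple[float, float]) -> tuple[float, float]:
    """Map a pixel coordinate ``(x_px, y_px)`` to physical μm ``(x, y)``."""
    x_px, y_px = px
    x_um = (np.asarray(x_px, dtype=float) - cal.origin_px[0]) * cal.um_per_px
    y_um = cal.y_sign * (np.asarray(y_px, dtype=float) - cal.origin_px[1]) * cal.um_per_px
    if np.ndim(x_px) == 0:
        return (float(x_um), float(y_um))
    return (x_um, y_um)


def to_pixel(cal: Calibration, um: tuple[float, float]) -> tuple[float, float]:
    """Map a physical μm coordinate ``(x, y)`` to pixel ``(x_px, y_px)``."""
    x_um, y_um = um
    x_px = np.asarray(x_um, dtype=float) / cal.um_per_px + cal.origin_px[0]
    y_px = cal.y_sign * np.asarray(y_um, dtype=float) / cal.um_per_px + cal.origin_px[1]
    if np.ndim(x_um) == 0:
        return (float(x_px), float(y_px))
    return (x_px, y_px)
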