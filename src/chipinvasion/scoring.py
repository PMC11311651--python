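"""Invasion metrics on a scored chip.

Two metrics are computed per chip per day:

* the per-window crossing vector — for each inter-post-threshold (IPT)
  window, whether any cell has at least one footprint pixel past the post
  outer edge within that window's x-extent — and its popcount;
* the maximum invasion distance — the furthest any footprint pixel lies
  beyond the post-center line, clamped below at zero.

Crossing is judged against the post OUTER edge while distance is measured
from the post CENTER line; the two reference lines differ by the post
radius (75 μm for the default chip) and are kept distinct in the geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import ChipGeometry
from .imaging import CellDetection

__all__ = [
    "InvasionScore",
    "score_crossings",
    "count_ipts",
    "max_invasion_distance",
    "fold_difference",
    "day_over_day_change",
    "score_detections",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InvasionScore:
    """Per-chip, per-day invasion result."""

    chip_id: str
    day: int
    crossings: tuple[bool, ...]
    n_ipts_crossed: int
    max_distance_um: float

    def __post_init__(self) -> None:
        if self.n_ipts_crossed != sum(self.crossings):
            raise ValueError("n_ipts_crossed inconsistent with crossing vector")
        if self.max_distance_um < 0:
            raise ValueError("max_distance_um must be >= 0")

    @property
    def crossings_str(self) -> str:
        """Crossing vector as a 0/1 string for CSV export."""
        return "".join("1" if c else "0" for c in self.crossings)


def _footprints_um(dets: list[CellDetection]) -> np.ndarray:
    """Stack all footprint pixels of all detections into one (n, 2) μm array."""
    if not dets:
        return np.empty((0, 2))
    return np.vstack([d.footprint_um() for d in dets])


def score_crossings(dets: list[CellDetection], geom: ChipGeometry) -> np.ndarray:
    """Boolean crossing vector, one entry per IPT window.

    Entry ``k`` is True iff some detection has a footprint pixel with
    ``y > crossing_boundary_y_um`` and x inside window ``k`` (half-open
    ``[lo, hi)``).  A cell spanning several windows marks each of them.
    An empty detection list yields an all-False vector.
    """
    out = np.zeros(geom.n_windows, dtype=bool)
    pts = _footprints_um(dets)
    if pts.size == 0:
        return out
    crossed = pts[pts[:, 1] > geom.crossing_boundary_y_um]
    if crossed.size == 0:
        return out
    lows = np.array([w[0] for w in geom.ipt_windows])
    highs = np.array([w[1] for w in geom.ipt_windows])
    x = crossed[:, 0]
    for k in range(geom.n_windows):
        out[k] = bool(np.any((x >= lows[k]) & (x < highs[k])))
    return out


def count_ipts(crossings, expected_length: int = 17) -> int:
    """Number of crossed windows in a crossing vector of the expected length."""
    vec = np.asarray(crossings, dtype=bool)
    if vec.ndim != 1 or vec.size != expected_length:
        raise ValueError(
            f"crossing vector must have length {expected_length}, got shape {vec.shape}"
        )
    return int(vec.sum())


def max_invasion_distance(dets: list[CellDetection], geom: ChipGeometry) -> float:
    """Furthest footprint pixel's distance past the post-center line, in μm.

    Measured perpendicular to the post row and clamped at 0: cells that
    stay below the center line score 0, not negative.  An empty detection
    list scores 0.  Detections below the lower channel (downward invasion)
    are not scored; a diagnostic count is logged.
    """
    pts = _footprints_um(dets)
    if pts.size == 0:
        return 0.0
    y = pts[:, 1]
    n_downward = int(np.sum(y < geom.post_center_y_um - geom.channel_width_um))
    if n_downward:
        log.info("%d footprint pixels below the lower channel (not scored)", n_downward)
    return float(max(0.0, y.max() - geom.post_center_y_um))


def score_detections(
    dets: list[CellDetection], geom: ChipGeometry, chip_id: str, day: int
) -> InvasionScore:
    """Convenience wrapper producing a complete :class:`InvasionScore`."""
    crossings = score_crossings(dets, geom)
    return InvasionScore(
        chip_id=chip_id,
        day=day,
        crossings=tuple(bool(c) for c in crossings),
        n_ipts_crossed=int(crossings.sum()),
        max_distance_um=max_invasion_distance(dets, geom),
    )


def fold_difference(a: float, b: float) -> float:
    """Ratio ``a / b`` between two positive group summaries.

    Summaries report this rounded to one decimal; the raw ratio is
    returned here.
    """
    if b == 0:
        raise ZeroDivisionError("fold difference undefined for zero denominator")
    return a / b


def day_over_day_change(
    score_d2: InvasionScore, score_d1: InvasionScore
) -> tuple[float | None, float | None]:
    """Per-metric day-2 / day-1 fold change for one chip.

    Returns ``(ipt_fold, distance_fold)``; a fold is ``None`` (flagged
    undefined, never infinite) when the day-1 value is zero.

    Raises
    ------
    ValueError
        If the two scores are not a (day 1, day 2) pair from the same chip.
    """
    if score_d1.chip_id != score_d2.chip_id:
        raise ValueError(
            f"chip mismatch: {score_d1.chip_id!r} vs {score_d2.chip_id!r}"
        )
    if (score_d1.day, score_d2.day) != (1, 2):
        raise ValueError(
            f"expected a (day 1, day 2) pair, got days "
            f"({score_d1.day}, {score_d2.day})"
        )
    ipt_fold = (
        score_d2.n_ipts_crossed / score_d1.n_ipts_crossed
        if score_d1.n_ipts_crossed
        else None
    )
    dist_fold = (
        score_d2.max_distance_um / score_d1.max_distance_um
        if score_d1.max_distance_um
        else None
    )
    return ipt_fold, dist_fold
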