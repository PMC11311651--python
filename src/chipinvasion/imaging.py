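"""Microscopy image IO, cell segmentation, and label-positivity rates.

Segmentation is deliberately simple: global threshold (Otsu or fixed),
4-connected components, minimum-area filter.  Touching cells are not
split; the downstream invasion metrics (any-cell window crossing and the
furthest-pixel distance) are insensitive to under-segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .geometry import Calibration, to_physical

__all__ = [
    "ChipImage",
    "CellDetection",
    "ImageFormatError",
    "read_image_stack",
    "segment_cells",
    "positivity_rate",
    "detections_to_table",
]

log = logging.getLogger(__name__)

MODALITIES = ("fluorescence", "brightfield")


class ImageFormatError(ValueError):
    """Unreadable or unsupported image input."""


@dataclass
class ChipImage:
    """One calibrated grayscale frame from one chip on one day."""

    pixels: np.ndarray
    modality: str
    day: int
    chip_id: str
    calibration: Calibration

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ImageFormatError(
                f"expected 2D grayscale frame, got shape {self.pixels.shape}"
            )
        if self.modality not in MODALITIES:
            raise ImageFormatError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ImageFormatError("pixel intensities must be finite and >= 0")


@dataclass
class CellDetection:
    """One segmented cell.

    ``pixel_footprint`` is an (n, 2) integer array of (row, col) pixels;
    physical coordinates are derived through ``calibration``.
    """

    centroid_um: tuple[float, float]
    pixel_footprint: np.ndarray
    area_um2: float
    modality: str
    calibration: Calibration = field(default_factory=Calibration)

    def footprint_um(self) -> np.ndarray:
        """(n, 2) array of footprint pixel centers in physical (x, y) μm."""
        rows = self.pixel_footprint[:, 0].astype(float)
        cols = self.pixel_footprint[:, 1].astype(float)
        x, y = to_physical(self.calibration, (cols, rows))
        return np.column_stack([x, y])

    @property
    def max_y_um(self) -> float:
        """y of the footprint pixel furthest toward the upper channel."""
        return float(self.footprint_um()[:, 1].max())


def read_image_stack(path: str | Path, metadata: dict) -> list[ChipImage]:
    """Read a single- or multi-page grayscale TIFF into :class:`ChipImage` frames.

    ``metadata`` must provide ``chip_id``, ``day``, ``modality`` and a
    ``calibration`` (:class:`Calibration` instance).  Pages keep file order.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such file: {path}")
    cal = metadata.get("calibration")
    if not isinstance(cal, Calibration):
        raise ImageFormatError("metadata must include a Calibration under 'calibration'")
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several concrete types
        raise ImageFormatError(f"cannot read TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ImageFormatError(
            f"{path}: expected grayscale pages, got array of shape {pages.shape}"
        )
    return [
        ChipImage(
            pixels=page,
            modality=metadata.get("modality", "fluorescence"),
            day=int(metadata.get("day", 0)),
            chip_id=str(metadata.get("chip_id", path.stem)),
            calibration=cal,
        )
        for page in pages
    ]


def _threshold_value(pixels: np.ndarray, threshold_method: str) -> float | None:
    """Resolve a threshold rule to a value; None means no foreground.

    The Otsu value is floored at a robust background estimate
    (median + 4 sigma via MAD): on sparse-foreground frames Otsu
    otherwise splits the background noise itself.
    """
    if threshold_method.startswith("fixed:"):
        return float(threshold_method.split(":", 1)[1])
    if threshold_method != "otsu":
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    if np.ptp(pixels) == 0:
        return None  # blank or saturated-uniform frame
    background = float(np.median(pixels))
    sigma = 1.4826 * float(np.median(np.abs(pixels - background)))
    return max(float(threshold_otsu(pixels)), background + 4.0 * sigma)


def segment_cells(
    img: ChipImage,
    min_area_um2: float = 50.0,
    threshold_method: str = "otsu",
) -> list[CellDetection]:
    """Segment labeled cells from one frame.

    Pixels above the threshold are grouped into 4-connected components;
    components smaller than ``min_area_um2`` are dropped.  Brightfield
    frames are inverted (cells darker than background) before Otsu.
    Detections are sorted by descending furthest-pixel y (deepest invader
    first).  A blank frame yields an empty list.
    """
    pixels = np.asarray(img.pixels, dtype=float)
    if img.modality == "brightfield":
        pixels = pixels.max() - pixels  # cells dark on bright background
    thr = _threshold_value(pixels, threshold_method)
    if thr is None:
        log.warning("uniform-intensity frame %s: no detections", img.chip_id)
        return []
    mask = pixels > thr
    if not mask.any():
        return []

    cal = img.calibration
    px_area_um2 = cal.um_per_px**2
    labels = cc_label(mask, connectivity=1)
    dets: list[CellDetection] = []
    for region in regionprops(labels):
        area_um2 = region.area * px_area_um2
        if area_um2 < min_area_um2:
            continue
        footprint = np.asarray(region.coords)  # (n, 2) row, col
        crow, ccol = region.centroid
        cx, cy = to_physical(cal, (ccol, crow))
        dets.append(
            CellDetection(
                centroid_um=(cx, cy),
                pixel_footprint=footprint,
                area_um2=float(area_um2),
                modality=img.modality,
                calibration=cal,
            )
        )
    dets.sort(key=lambda d: d.max_y_um, reverse=True)
    return dets


def positivity_rate(
    brightfield_dets: list[CellDetection],
    fluorescence_dets: list[CellDetection],
    match_radius_um: float = 15.0,
) -> float:
    """Fraction of brightfield-detected cells carrying a fluorescence label.

    Matches are made greedily nearest-first between centroids; each
    fluorescence detection is consumed by at most one brightfield cell.

    Raises
    ------
    ValueError
        If the brightfield list is empty (the rate is undefined) or
        ``match_radius_um <= 0``.
    """
    if not brightfield_dets:
        raise ValueError("positivity rate undefined: no brightfield detections")
    if not match_radius_um > 0:
        raise ValueError(f"match_radius_um must be > 0, got {match_radius_um}")
    if not fluorescence_dets:
        return 0.0

    bf = np.array([d.centroid_um for d in brightfield_dets], dtype=float)
    fl = np.array([d.centroid_um for d in fluorescence_dets], dtype=float)
    dist = np.linalg.norm(bf[:, None, :] - fl[None, :, :], axis=2)

    pairs = np.argwhere(dist <= match_radius_um)
    order = np.argsort(dist[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_bf: set[int] = set()
    used_fl: set[int] = set()
    n_matched = 0
    for i, j in pairs[order]:
        if i in used_bf or j in used_fl:
            continue
        used_bf.add(int(i))
        used_fl.add(int(j))
        n_matched += 1
    return n_matched / len(brightfield_dets)


def detections_to_table(dets: list[CellDetection], chip_id: str, day: int):
    """Flatten detections into a pandas DataFrame for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chip_id": chip_id,
                "day": day,
                "modality": d.modality,
                "centroid_x_um": d.centroid_um[0],
                "centroid_y_um": d.centroid_um[1],
                "area_um2": d.area_um2,
            }
            for d in dets
        ],
        columns=[
            "chip_id",
            "day",
            "modality",
            "centroid_x_um",
            "centroid_y_um",
            "area_um2",
        ],
    )
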