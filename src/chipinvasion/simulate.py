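"""Agent-based synthetic chip experiments with ground truth.

Cells are agents performing a biased random walk in the central channel:
per step, ``Δx ~ N(0, diffusion)`` and ``Δy ~ N(effective_drift,
diffusion)`` with ``effective_drift = drift / (1 + dose / IC50)``.  The
drift points toward the upper Matrigel channel (the chemotactic gradient
direction); posts and channel walls reflect.  The invasive phenotype has
positive drift; the non-invasive phenotype has zero drift and is seeded
in spatial clusters deep in the channel.

None of the dynamics comes from measured migration rates: the walk, the
``1 / (1 + dose/IC50)`` inhibition law, and the default rates are
synthetic calibration chosen so that default arms reproduce the expected
orderings (invasive >> non-invasive, day 2 > day 1, dose-dependent
decrease) — they are not measured biology.

Rendering draws each labeled cell as an isotropic Gaussian blob of width
``psf_sigma_um`` plus additive Gaussian background noise at a stated
peak-SNR.  Ground-truth scores are computed directly from agent
positions by rasterizing each cell's half-maximum disc — the contour at
which thresholding at half the blob amplitude would cut the noiseless
blob — onto the same pixel grid, bypassing rendering, noise, and
segmentation entirely.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import Calibration, ChipGeometry, build_geometry, to_pixel
from .imaging import CellDetection, ChipImage
from .scoring import InvasionScore, score_detections

__all__ = [
    "SimulationParams",
    "SimState",
    "simulate",
    "render",
    "frame_calibration",
    "ground_truth_detections",
    "generate_experiment",
    "default_experiment_config",
    "default_dose_config",
    "estimate_effective_drift",
    "HALF_MAX_FACTOR",
]

#: radius of the half-maximum contour of a Gaussian blob, in units of sigma
HALF_MAX_FACTOR = math.sqrt(2.0 * math.log(2.0))

PHENOTYPES = ("invasive", "non_invasive")


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated arm (one phenotype at one dose)."""

    phenotype: str = "invasive"
    drift_um_per_step: float = 3.0
    diffusion_um: float = 2.0
    steps_per_day: int = 50
    n_cells: int = 150
    clustering_radius_um: float = 60.0
    dose_uM: float = 0.0
    ic50_uM: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.drift_um_per_step < 0 or self.diffusion_um < 0:
            raise ValueError("drift and diffusion must be >= 0")
        if self.steps_per_day < 1 or self.n_cells < 1:
            raise ValueError("steps_per_day and n_cells must be >= 1")
        if self.dose_uM < 0 or self.ic50_uM <= 0:
            raise ValueError("dose must be >= 0 and IC50 > 0")
        if self.phenotype == "non_invasive" and self.drift_um_per_step != 0:
            raise ValueError("non_invasive phenotype must have zero drift")

    @property
    def effective_drift(self) -> float:
        """Per-step drift after dose inhibition: drift / (1 + dose/IC50)."""
        return self.drift_um_per_step / (1.0 + self.dose_uM / self.ic50_uM)


@dataclass(frozen=True)
class SimState:
    """Agent positions (μm) in one chip at one time point."""

    positions: np.ndarray
    day: float
    geometry: ChipGeometry


def _channel_bounds(geom: ChipGeometry) -> tuple[float, float, float, float]:
    """Reflecting box (xmin, xmax, ymin, ymax) around the walk domain.

    The walk is confined between the bottom of the cell channel and the
    top of the upper Matrigel channel; x is confined to the channel ends.
    """
    half_extra = (geom.channel_length_um - (
        geom.active_window_x_um[1] - geom.active_window_x_um[0])) / 2.0
    xmin = geom.active_window_x_um[0] - half_extra
    xmax = geom.active_window_x_um[1] + half_extra
    ymin = geom.post_center_y_um - geom.channel_width_um
    ymax = geom.crossing_boundary_y_um + geom.channel_width_um
    return xmin, xmax, ymin, ymax


def _inside_post(pos: np.ndarray, geom: ChipGeometry) -> np.ndarray:
    """Boolean mask: which positions lie strictly inside a post disc.

    Post pitch exceeds the post diameter, so only the nearest post along x
    can contain a point.
    """
    r = geom.post_diameter_um / 2.0
    centers = geom.post_centers()
    idx = np.clip(
        np.rint((pos[:, 0] - centers[0, 0]) / geom.post_pitch_um).astype(int),
        0,
        geom.n_posts - 1,
    )
    d2 = np.sum((pos - centers[idx]) ** 2, axis=1)
    return d2 < r * r


def _reflect_posts(pos: np.ndarray, old: np.ndarray, geom: ChipGeometry) -> np.ndarray:
    """Reflect positions out of post discs; revert moves that stay invalid."""
    inside = _inside_post(pos, geom)
    if not inside.any():
        return pos
    r = geom.post_diameter_um / 2.0
    centers = geom.post_centers()
    out = pos.copy()
    sub = pos[inside]
    idx = np.clip(
        np.rint((sub[:, 0] - centers[0, 0]) / geom.post_pitch_um).astype(int),
        0,
        geom.n_posts - 1,
    )
    delta = sub - centers[idx]
    dist = np.linalg.norm(delta, axis=1)
    safe = dist > 1e-9
    mirrored = sub.copy()
    mirrored[safe] = centers[idx[safe]] + delta[safe] * (
        (2.0 * r - dist[safe]) / dist[safe]
    )[:, None]
    out[inside] = mirrored
    # Rare pathologies (landed on a center, mirrored into a neighbor): revert.
    bad = _inside_post(out, geom)
    out[bad] = old[bad]
    return out


def _reflect_walls(pos: np.ndarray, geom: ChipGeometry) -> np.ndarray:
    xmin, xmax, ymin, ymax = _channel_bounds(geom)
    out = pos.copy()
    for axis, lo, hi in ((0, xmin, xmax), (1, ymin, ymax)):
        v = out[:, axis]
        v = np.where(v < lo, 2 * lo - v, v)
        v = np.where(v > hi, 2 * hi - v, v)
        out[:, axis] = v
    return out


def _seed_positions(
    params: SimulationParams, geom: ChipGeometry, rng: np.random.Generator
) -> np.ndarray:
    """Day-0 seeding inside the central channel (never inside a post)."""
    x0, x1 = geom.active_window_x_um
    y_top = geom.post_center_y_um
    y_bot = y_top - geom.channel_width_um
    margin = 5.0
    n = params.n_cells

    if params.phenotype == "non_invasive":
        # Clustered seeding in the deeper half of the channel; cohesion is
        # static (no attractive forces), which suffices for the scored
        # behavior of the clustering phenotype.
        n_clusters = max(1, n // 20)
        centers = np.column_stack(
            [
                rng.uniform(x0, x1, n_clusters),
                rng.uniform(y_bot + margin, (y_bot + y_top) / 2.0, n_clusters),
            ]
        )
        which = rng.integers(0, n_clusters, n)
        pos = centers[which] + rng.normal(0.0, params.clustering_radius_um, (n, 2))
        pos = _reflect_walls(pos, geom)
        pos[:, 1] = np.minimum(pos[:, 1], y_top - margin)
    else:
        pos = np.column_stack(
            [
                rng.uniform(x0, x1, n),
                rng.uniform(y_bot + margin, y_top - margin, n),
            ]
        )
    # rejection-resample anything seeded inside a post disc
    for _ in range(100):
        inside = _inside_post(pos, geom)
        if not inside.any():
            break
        k = int(inside.sum())
        pos[inside] = np.column_stack(
            [
                rng.uniform(x0, x1, k),
                rng.uniform(y_bot + margin, y_top - margin, k),
            ]
        )
    return pos


def simulate(
    params: SimulationParams, geom: ChipGeometry, n_days: int
) -> list[SimState]:
    """Run one chip for ``n_days`` days; returns day 0..n_days states.

    Deterministic for a fixed ``params.seed``.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    rng = np.random.default_rng(params.seed)
    pos = _seed_positions(params, geom, rng)
    states = [SimState(positions=pos.copy(), day=0.0, geometry=geom)]
    drift = params.effective_drift
    for day in range(1, n_days + 1):
        for _ in range(params.steps_per_day):
            step = rng.normal(
                loc=(0.0, drift),
                scale=params.diffusion_um,
                size=pos.shape,
            )
            new = _reflect_walls(pos + step, geom)
            new = _reflect_posts(new, pos, geom)
            pos = new
        states.append(SimState(positions=pos.copy(), day=float(day), geometry=geom))
    return states


# ---------------------------------------------------------------------------
# rendering and ground truth


def frame_calibration(
    geom: ChipGeometry, cal: Calibration, margin_um: float = 25.0
) -> tuple[Calibration, tuple[int, int]]:
    """Calibration anchored to the rendered frame, plus (rows, cols).

    The frame covers the channel system around the post row: x over the
    active window plus a margin, y from the bottom of the cell channel to
    the top of the upper Matrigel channel.
    """
    xmin = geom.active_window_x_um[0] - margin_um
    xmax = geom.active_window_x_um[1] + margin_um
    ymin = geom.post_center_y_um - geom.channel_width_um - margin_um
    ymax = geom.crossing_boundary_y_um + geom.channel_width_um + margin_um
    u = cal.um_per_px
    cols = int(np.ceil((xmax - xmin) / u)) + 1
    rows = int(np.ceil((ymax - ymin) / u)) + 1
    if cal.y_axis_toward_upper_channel:
        origin = (-xmin / u, -ymin / u)
    else:
        origin = (-xmin / u, ymax / u)
    frame_cal = replace(cal, origin_px=origin)
    return frame_cal, (rows, cols)


def render(
    state: SimState,
    cal: Calibration,
    psf_sigma_um: float = 6.0,
    snr: float = 50.0,
    labeled_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
    modality: str = "fluorescence",
    chip_id: str = "chip",
) -> tuple[ChipImage, pd.DataFrame]:
    """Render one state as a grayscale frame plus a ground-truth table.

    Each labeled cell becomes a Gaussian blob of peak amplitude
    ``snr * noise_sd`` over the background; unlabeled cells are omitted
    from fluorescence frames but always appear (dark) in brightfield.
    The returned DataFrame lists every cell with columns ``x_um``,
    ``y_um``, ``labeled``.
    """
    if snr <= 0:
        raise ValueError(f"snr must be > 0, got {snr}")
    if not 0 < labeled_fraction <= 1:
        raise ValueError(f"labeled_fraction must be in (0, 1], got {labeled_fraction}")
    if rng is None:
        rng = np.random.default_rng(0)

    frame_cal, (rows, cols) = frame_calibration(state.geometry, cal)
    u = frame_cal.um_per_px
    n = state.positions.shape[0]
    labeled = rng.random(n) < labeled_fraction

    noise_sd = 20.0
    background = 100.0
    amplitude = snr * noise_sd
    signal = np.zeros((rows, cols), dtype=np.float64)
    reach = int(np.ceil(4.0 * psf_sigma_um / u))
    draw = labeled if modality == "fluorescence" else np.ones(n, dtype=bool)
    for (x_um, y_um), on in zip(state.positions, draw):
        if not on:
            continue
        cx, cy = to_pixel(frame_cal, (x_um, y_um))
        c0, r0 = int(round(cx)), int(round(cy))
        rlo, rhi = max(0, r0 - reach), min(rows, r0 + reach + 1)
        clo, chi = max(0, c0 - reach), min(cols, c0 + reach + 1)
        if rlo >= rhi or clo >= chi:
            continue
        rr = np.arange(rlo, rhi)
        cc = np.arange(clo, chi)
        dy = (rr - cy) * u
        dx = (cc - cx) * u
        blob = np.exp(
            -(dy[:, None] ** 2 + dx[None, :] ** 2) / (2.0 * psf_sigma_um**2)
        )
        signal[rlo:rhi, clo:chi] += amplitude * blob

    if modality == "fluorescence":
        pixels = background + signal
    else:
        pixels = (background + 10 * amplitude) - signal  # cells dark on bright
    pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, None).astype(np.float32)

    img = ChipImage(
        pixels=pixels,
        modality=modality,
        day=int(round(state.day)),
        chip_id=chip_id,
        calibration=frame_cal,
    )
    truth = pd.DataFrame(
        {
            "x_um": state.positions[:, 0],
            "y_um": state.positions[:, 1],
            "labeled": labeled,
        }
    )
    return img, truth


def ground_truth_detections(
    positions: np.ndarray,
    geom: ChipGeometry,
    cal: Calibration,
    psf_sigma_um: float = 6.0,
) -> list[CellDetection]:
    """Rasterize each agent's half-maximum disc into a detection.

    This is the scoring ground truth: the pixel footprint each cell would
    produce if its rendered blob were cut exactly at half amplitude, with
    no noise, overlap, or segmentation involved.
    """
    frame_cal, (rows, cols) = frame_calibration(geom, cal)
    u = frame_cal.um_per_px
    r_um = HALF_MAX_FACTOR * psf_sigma_um
    reach = int(np.ceil(r_um / u)) + 1
    dets: list[CellDetection] = []
    for x_um, y_um in np.asarray(positions, dtype=float):
        cx, cy = to_pixel(frame_cal, (x_um, y_um))
        c0, r0 = int(round(cx)), int(round(cy))
        rr = np.arange(max(0, r0 - reach), min(rows, r0 + reach + 1))
        cc = np.arange(max(0, c0 - reach), min(cols, c0 + reach + 1))
        dy = (rr - cy) * u
        dx = (cc - cx) * u
        mask = (dy[:, None] ** 2 + dx[None, :] ** 2) < r_um**2
        pix_r, pix_c = np.nonzero(mask)
        if pix_r.size == 0:
            continue
        footprint = np.column_stack([rr[pix_r], cc[pix_c]])
        dets.append(
            CellDetection(
                centroid_um=(float(x_um), float(y_um)),
                pixel_footprint=footprint,
                area_um2=float(footprint.shape[0]) * u * u,
                modality="fluorescence",
                calibration=frame_cal,
            )
        )
    return dets


# ---------------------------------------------------------------------------
# full experiments


def default_experiment_config() -> dict:
    """Three-phenotype design: two invasive lines and one clustering line,
    days 1-2, three chips each.  Rates are synthetic calibration only."""
    return {
        "seed": 0,
        "n_days": 2,
        "n_chips": 3,
        "geometry": {},
        "calibration": {"um_per_px": 2.0},
        "render": {"psf_sigma_um": 6.0, "snr": 50.0, "labeled_fraction": 1.0},
        "arms": [
            {
                "cell_line": "INV1",
                "phenotype": "invasive",
                "drift_um_per_step": 3.0,
                "diffusion_um": 2.0,
                "steps_per_day": 50,
                "n_cells": 150,
                "dose_uM": 0.0,
            },
            {
                "cell_line": "INV2",
                "phenotype": "invasive",
                "drift_um_per_step": 3.5,
                "diffusion_um": 2.0,
                "steps_per_day": 50,
                "n_cells": 150,
                "dose_uM": 0.0,
            },
            {
                "cell_line": "NONINV",
                "phenotype": "non_invasive",
                "drift_um_per_step": 0.0,
                "diffusion_um": 1.5,
                "steps_per_day": 50,
                "n_cells": 150,
                "dose_uM": 0.0,
            },
        ],
    }


def default_dose_config() -> dict:
    """Inhibitor titration of the invasive phenotype at 0/1/10/100 μM."""
    cfg = default_experiment_config()
    cfg["arms"] = [
        {
            "cell_line": "INV1",
            "phenotype": "invasive",
            "drift_um_per_step": 3.0,
            "diffusion_um": 2.0,
            "steps_per_day": 50,
            "n_cells": 150,
            "dose_uM": dose,
            "ic50_uM": 1.0,
        }
        for dose in (0.0, 1.0, 10.0, 100.0)
    ]
    return cfg


def _params_from_arm(arm: dict, seed: int) -> SimulationParams:
    known = {
        "phenotype",
        "drift_um_per_step",
        "diffusion_um",
        "steps_per_day",
        "n_cells",
        "clustering_radius_um",
        "dose_uM",
        "ic50_uM",
    }
    kwargs = {k: v for k, v in arm.items() if k in known}
    return SimulationParams(seed=seed, **kwargs)


def generate_experiment(
    config: dict, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every arm of an experiment design.

    Returns ``(experiment_table, truth_table)``:

    * ``experiment_table`` — long-format records (cell_line, day, dose_uM,
      chip_id, metric_name, value), both metrics per chip-day, scored
      directly from agent positions (ground truth);
    * ``truth_table`` — per-chip-day agent positions.

    When ``out_dir`` is given, fluorescence TIFFs, metadata sidecars, and
    both tables are written there.
    """
    required = {"seed", "n_days", "n_chips", "arms"}
    missing = required - set(config)
    if missing:
        raise ValueError(f"config missing keys: {sorted(missing)}")
    if not config["arms"]:
        raise ValueError("config defines no arms")

    geom = build_geometry(**config.get("geometry", {}))
    cal = Calibration(**config.get("calibration", {"um_per_px": 2.0}))
    render_cfg = config.get("render", {})
    psf_sigma = float(render_cfg.get("psf_sigma_um", 6.0))
    snr = float(render_cfg.get("snr", 50.0))
    labeled_fraction = float(render_cfg.get("labeled_fraction", 1.0))

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    seed_seq = np.random.SeedSequence(int(config["seed"]))
    n_chips = int(config["n_chips"])
    n_days = int(config["n_days"])
    chip_seeds = seed_seq.spawn(len(config["arms"]) * n_chips)

    records: list[dict] = []
    truth_rows: list[pd.DataFrame] = []
    for a, arm in enumerate(config["arms"]):
        cell_line = arm.get("cell_line", f"arm{a}")
        dose = float(arm.get("dose_uM", 0.0))
        for c in range(n_chips):
            chip_seed = chip_seeds[a * n_chips + c]
            params = _params_from_arm(arm, seed=int(chip_seed.generate_state(1)[0]))
            chip_id = f"{cell_line}_d{dose:g}_chip{c}"
            states = simulate(params, geom, n_days)
            render_rng = np.random.default_rng(chip_seed.spawn(1)[0])
            for state in states:
                day = int(round(state.day))
                truth = pd.DataFrame(
                    {
                        "chip_id": chip_id,
                        "cell_line": cell_line,
                        "dose_uM": dose,
                        "day": day,
                        "x_um": state.positions[:, 0],
                        "y_um": state.positions[:, 1],
                    }
                )
                truth_rows.append(truth)
                if day >= 1:
                    dets = ground_truth_detections(
                        state.positions, geom, cal, psf_sigma
                    )
                    score = score_detections(dets, geom, chip_id, day)
                    for metric, value in (
                        ("n_ipts_crossed", float(score.n_ipts_crossed)),
                        ("max_distance_um", score.max_distance_um),
                    ):
                        records.append(
                            {
                                "cell_line": cell_line,
                                "day": day,
                                "dose_uM": dose,
                                "chip_id": chip_id,
                                "metric_name": metric,
                                "value": value,
                            }
                        )
                if out_path is not None:
                    img, _ = render(
                        state,
                        cal,
                        psf_sigma_um=psf_sigma,
                        snr=snr,
                        labeled_fraction=labeled_fraction,
                        rng=render_rng,
                        chip_id=chip_id,
                    )
                    stem = f"{chip_id}_day{day}_fluorescence"
                    tifffile.imwrite(out_path / f"{stem}.tif", img.pixels)
                    meta = {
                        "chip_id": chip_id,
                        "cell_line": cell_line,
                        "dose_uM": dose,
                        "day": day,
                        "modality": "fluorescence",
                        "um_per_px": img.calibration.um_per_px,
                        "origin_px": list(img.calibration.origin_px),
                        "y_axis_toward_upper_channel": (
                            img.calibration.y_axis_toward_upper_channel
                        ),
                        "psf_sigma_um": psf_sigma,
                        "snr": snr,
                    }
                    (out_path / f"{stem}.json").write_text(json.dumps(meta, indent=2))

    table = pd.DataFrame(records)
    truth_table = (
        pd.concat(truth_rows, ignore_index=True) if truth_rows else pd.DataFrame()
    )
    if out_path is not None:
        table.to_csv(out_path / "experiment_table.csv", index=False)
        truth_table.to_csv(out_path / "ground_truth_positions.csv", index=False)
        (out_path / "geometry.json").write_text(geom.to_json())
    return table, truth_table


def estimate_effective_drift(
    dets_by_day: dict[int, list[CellDetection]], steps_per_day: int
) -> float:
    """Recover the per-step drift from segmented frames of successive days.

    Uses the change in mean detection-centroid y between the earliest and
    latest available day, divided by the elapsed number of steps.
    """
    days = sorted(dets_by_day)
    if len(days) < 2:
        raise ValueError("need detections from at least two days")
    d0, d1 = days[0], days[-1]
    if not dets_by_day[d0] or not dets_by_day[d1]:
        raise ValueError("empty detection list for a required day")
    mean_y0 = float(np.mean([d.centroid_um[1] for d in dets_by_day[d0]]))
    mean_y1 = float(np.mean([d.centroid_um[1] for d in dets_by_day[d1]]))
    return (mean_y1 - mean_y0) / ((d1 - d0) * steps_per_day)
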