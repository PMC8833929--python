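"""Synthetic data generators with planted ground truth.

Every generator in this module emulates one of the raw inputs the pipeline
consumes: time-lapse two-channel wells of fluorescent nuclei (or the per-cell
measurement tables derived from them), cycloheximide-chase decay series,
two-channel colocalization image pairs, and expression/survival cohorts.
Each generator is driven by a frozen config dataclass carrying an explicit
seed, and returns the generated data together with a ground-truth record so
that every planted quantity can be recovered by a direct, pipeline-independent
oracle computation.

Conventions
-----------
* Per-cell reporter intensities follow a log-normal law (right-skewed,
  strictly positive, as fluorescence distributions are); the law is
  parameterized by its median and log-scale sigma.
* Cells are not tracked between frames: each time point is an independent
  population sample, matching an analysis of per-time-point distributions.
* Planted stabilizers multiply the population median at the final time point
  by their fold effect, rising linearly over the last 24 h of the course.
* Images are 16-bit single-plane frames; nuclei are disks of configurable
  radius on a uniform background so that area/intensity oracles are exact.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk as _disk_coords

from .errors import ConfigurationError, PlacementError

logger = logging.getLogger(__name__)

CONTROL_ID = "EV"  # empty-vector control construct


# ---------------------------------------------------------------------------
# intensity laws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityLaw:
    """Distribution of per-cell intensities.

    ``lognormal`` is parameterized by its *median* and log-scale ``sigma``
    (so ``X = median * exp(sigma * Z)`` with ``Z`` standard normal);
    ``normal`` by mean (``median`` field) and standard deviation (``sigma``).
    """

    family: str = "lognormal"
    median: float = 100.0
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal"):
            raise ConfigurationError(f"unknown intensity law family {self.family!r}")
        if self.family == "lognormal" and self.median <= 0:
            raise ConfigurationError("lognormal law requires median > 0")
        if self.sigma < 0:
            raise ConfigurationError("intensity law sigma must be >= 0")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.family == "lognormal":
            return self.median * np.exp(self.sigma * rng.standard_normal(size))
        return rng.normal(self.median, self.sigma, size)


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimConfig:
    """Conditions of a simulated overexpression screen.

    Defaults mirror the screen layout: 41 constructs plus an empty-vector
    control, at least 2400 analyzed cells per construct at the final time
    point, frames every 2 h over 72 h. ``planted_effects`` are per-construct
    fold multipliers on the 72-h median (1.0 = null); ``trajectory_slopes``
    are intensity change per hour over the last 24 h (``None`` derives the
    slope that ramps the median linearly from baseline to its 72-h value).
    """

    n_constructs: int = 41
    n_control_wells: int = 1
    cells_per_construct: int = 2400
    transfection_fraction: float = 1.0
    control_intensity_law: IntensityLaw = field(default_factory=IntensityLaw)
    marker_intensity_law: IntensityLaw = field(
        default_factory=lambda: IntensityLaw("lognormal", 80.0, 0.4)
    )
    planted_effects: Sequence[float] | float | None = None
    trajectory_slopes: Sequence[float] | float | None = None
    noise_sd: float = 2.0
    bleedthrough_alpha: float = 0.0
    poisson_noise: bool = False
    frame_interval_h: float = 2.0
    duration_h: float = 72.0
    ramp_start_h: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_constructs < 1:
            raise ConfigurationError("n_constructs must be >= 1")
        if self.n_control_wells < 1:
            raise ConfigurationError("n_control_wells must be >= 1")
        if self.cells_per_construct < 2:
            raise ConfigurationError("cells_per_construct must be >= 2")
        if not 0.0 <= self.transfection_fraction <= 1.0:
            raise ConfigurationError("transfection_fraction must be in [0, 1]")
        if self.frame_interval_h <= 0:
            raise ConfigurationError("frame_interval_h must be > 0")
        if self.duration_h <= 0:
            raise ConfigurationError("duration_h must be > 0")
        if not 0 <= self.ramp_start_h < self.duration_h:
            raise ConfigurationError("ramp_start_h must lie in [0, duration_h)")
        if self.noise_sd < 0 or self.bleedthrough_alpha < 0:
            raise ConfigurationError("noise_sd and bleedthrough_alpha must be >= 0")
        if np.any(np.asarray(self.folds()) <= 0):
            raise ConfigurationError("fold multipliers must be > 0")

    def construct_ids(self) -> list[str]:
        return [f"DUB{i + 1:02d}" for i in range(self.n_constructs)]

    def folds(self) -> np.ndarray:
        return _broadcast(self.planted_effects, self.n_constructs, 1.0, "planted_effects")

    def slopes(self) -> np.ndarray | None:
        if self.trajectory_slopes is None:
            return None
        return _broadcast(self.trajectory_slopes, self.n_constructs, 0.0, "trajectory_slopes")

    def times(self) -> np.ndarray:
        n = int(round(self.duration_h / self.frame_interval_h))
        return np.round(np.linspace(0.0, n * self.frame_interval_h, n + 1), 9)


def _broadcast(value, n: int, default: float, name: str) -> np.ndarray:
    if value is None:
        return np.full(n, default)
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(n, arr[0])
    if arr.size != n:
        raise ConfigurationError(f"{name} must be a scalar or have length {n}")
    return arr.copy()


def _median_profile(cfg: ScreenSimConfig, fold: float, slope: float | None) -> np.ndarray:
    """Population-median trajectory for one construct over the time grid."""
    times = cfg.times()
    base = cfg.control_intensity_law.median
    m = np.full(times.size, base)
    ramp = times > cfg.ramp_start_h
    span = cfg.duration_h - cfg.ramp_start_h
    if slope is None:
        m[ramp] = base + base * (fold - 1.0) * (times[ramp] - cfg.ramp_start_h) / span
    else:
        m[ramp] = np.maximum(base, base * fold - slope * (cfg.duration_h - times[ramp]))
    return m


def simulate_screen_measurements(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a per-cell measurement table with planted effects.

    Returns ``(measurements, truth)``. ``measurements`` has one row per cell
    per time point with columns ``construct_id, time_h, field, label, area,
    mean_reporter, mean_marker, transfected``; the empty-vector control is
    included under construct id ``"EV"``. ``truth`` flags each construct as
    null or stabilizer with its planted fold and effective last-24-h slope.
    """
    rng = np.random.default_rng(config.seed)
    times = config.times()
    law = config.control_intensity_law
    folds = config.folds()
    slopes = config.slopes()

    ids = [CONTROL_ID] + config.construct_ids()
    all_folds = np.concatenate([[1.0], folds])
    all_slopes = [None] * len(ids) if slopes is None else [0.0, *slopes]
    n_cells = [config.cells_per_construct * config.n_control_wells] + [
        config.cells_per_construct
    ] * config.n_constructs

    chunks = []
    truth_rows = []
    for cid, fold, slope, n in zip(ids, all_folds, all_slopes, n_cells):
        m = _median_profile(config, fold, slope)
        z = rng.standard_normal((times.size, n))
        if law.family == "lognormal":
            reporter = m[:, None] * np.exp(law.sigma * z)
        else:
            reporter = m[:, None] + law.sigma * z
        transfected = rng.random((times.size, n)) < config.transfection_fraction
        marker = config.marker_intensity_law.sample(rng, (times.size, n)) * transfected
        reporter = reporter + config.bleedthrough_alpha * marker
        if config.noise_sd > 0:
            reporter = reporter + rng.normal(0.0, config.noise_sd, reporter.shape)
            marker = marker + rng.normal(0.0, config.noise_sd, marker.shape)
        np.clip(reporter, 0.0, None, out=reporter)
        np.clip(marker, 0.0, None, out=marker)

        labels = np.arange(n)
        chunks.append(
            pd.DataFrame(
                {
                    "construct_id": np.repeat(cid, times.size * n),
                    "time_h": np.repeat(times, n),
                    "field": np.tile(labels % 4, times.size),
                    "label": np.tile(labels, times.size),
                    "area": 314.0,
                    "mean_reporter": reporter.ravel(),
                    "mean_marker": marker.ravel(),
                    "transfected": transfected.ravel(),
                }
            )
        )
        eff_slope = (m[-1] - np.interp(config.ramp_start_h, times, m)) / (
            config.duration_h - config.ramp_start_h
        )
        truth_rows.append(
            {
                "construct_id": cid,
                "planted_fold": fold,
                "trajectory_slope": eff_slope,
                "is_stabilizer": bool(fold > 1.0),
            }
        )

    measurements = pd.concat(chunks, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return measurements, truth


# ---------------------------------------------------------------------------
# screen images
# ---------------------------------------------------------------------------

def _place_disks(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    radius: int,
    attempt_limit: int,
) -> np.ndarray:
    """Rejection-sample ``n`` non-overlapping disk centers; (n, 2) array."""
    margin = radius + 1
    if n > 0 and (shape[0] <= 2 * margin or shape[1] <= 2 * margin):
        raise PlacementError(f"grid {shape} too small for disks of radius {radius}")
    centers: list[tuple[int, int]] = []
    attempts = 0
    min_d2 = (2 * radius + 2) ** 2
    while len(centers) < n:
        if attempts >= attempt_limit:
            raise PlacementError(
                f"could not place {n} non-overlapping nuclei within "
                f"{attempt_limit} attempts"
            )
        attempts += 1
        r = int(rng.integers(margin, shape[0] - margin))
        c = int(rng.integers(margin, shape[1] - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_d2 for r0, c0 in centers):
            centers.append((r, c))
    return np.asarray(centers, dtype=int).reshape(n, 2)


@dataclass
class WellImages:
    """Simulated two-channel time course for one construct (one field)."""

    construct_id: str
    times: np.ndarray
    pages: np.ndarray  # (n_times, 2, H, W) uint16; channel 0 reporter, 1 marker
    truth: pd.DataFrame  # one row per planted disk

    def frame(self, time_index: int, channel: int) -> np.ndarray:
        return self.pages[time_index, channel]


@dataclass
class ScreenImageSet:
    wells: dict[str, WellImages]
    manifest: pd.DataFrame
    truth: pd.DataFrame
    clipped_pixels: int

    def write(self, out_dir: str | Path) -> None:
        """Write one multi-page TIFF per construct (time-major, channel order
        reporter/marker) plus ``manifest.csv`` and ``truth.csv``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cid, well in self.wells.items():
            stack = well.pages.reshape(-1, *well.pages.shape[2:])
            tifffile.imwrite(out / f"{cid}.tif", stack)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def simulate_screen_images(
    config: ScreenSimConfig,
    image_shape: tuple[int, int] = (256, 256),
    cell_radius: int = 10,
    cells_per_frame: int | None = None,
    background: float = 5.0,
    bit_depth: int = 16,
    attempt_limit: int = 50_000,
) -> ScreenImageSet:
    """Render the screen as disk-nuclei image series with ground truth.

    Nuclei are static disks placed without overlap; each carries a per-cell
    base intensity drawn from the construct's law at baseline and scaled by
    the construct's median trajectory over time. The marker channel is
    nonzero only inside transfected cells. Intensities are clipped to the
    declared integer bit depth; clipping events are counted and logged.
    """
    rng = np.random.default_rng(config.seed)
    times = config.times()
    law = config.control_intensity_law
    base = law.median
    folds = np.concatenate([[1.0], config.folds()])
    slopes = config.slopes()
    all_slopes = [None] * (config.n_constructs + 1) if slopes is None else [0.0, *slopes]
    ids = [CONTROL_ID] + config.construct_ids()
    n_frame = cells_per_frame if cells_per_frame is not None else config.cells_per_construct
    vmax = float(2**bit_depth - 1)
    dtype = np.uint16 if bit_depth <= 16 else np.uint32

    wells: dict[str, WellImages] = {}
    manifest_rows = []
    truth_frames = []
    clipped = 0
    for cid, fold, slope in zip(ids, folds, all_slopes):
        centers = _place_disks(rng, n_frame, image_shape, cell_radius, attempt_limit)
        base_int = law.sample(rng, n_frame)
        transfected = rng.random(n_frame) < config.transfection_fraction
        marker_int = config.marker_intensity_law.sample(rng, n_frame) * transfected
        profile = _median_profile(config, fold, slope) / base

        pages = np.empty((times.size, 2, *image_shape), dtype=dtype)
        for ti in range(times.size):
            rep = np.full(image_shape, background, dtype=float)
            mark = np.full(image_shape, background, dtype=float)
            for i in range(n_frame):
                rr, cc = _disk_coords(tuple(centers[i]), cell_radius, shape=image_shape)
                rep[rr, cc] = background + base_int[i] * profile[ti]
                if transfected[i]:
                    mark[rr, cc] = background + marker_int[i]
            if config.bleedthrough_alpha > 0:
                rep = rep + config.bleedthrough_alpha * (mark - background)
            if config.poisson_noise:
                rep = rng.poisson(np.clip(rep, 0, None)).astype(float)
                mark = rng.poisson(np.clip(mark, 0, None)).astype(float)
            if config.noise_sd > 0:
                rep = rep + rng.normal(0.0, config.noise_sd, image_shape)
                mark = mark + rng.normal(0.0, config.noise_sd, image_shape)
            clipped += int(np.sum(rep < 0) + np.sum(rep > vmax))
            clipped += int(np.sum(mark < 0) + np.sum(mark > vmax))
            pages[ti, 0] = np.clip(np.rint(rep), 0, vmax).astype(dtype)
            pages[ti, 1] = np.clip(np.rint(mark), 0, vmax).astype(dtype)
            for ch_idx, ch_name in enumerate(("reporter", "marker")):
                manifest_rows.append(
                    {
                        "construct_id": cid,
                        "well": cid,
                        "field": 0,
                        "time_h": times[ti],
                        "channel": ch_name,
                        "page_index": 2 * ti + ch_idx,
                        "file": f"{cid}.tif",
                    }
                )
        truth = pd.DataFrame(
            {
                "construct_id": cid,
                "cell": np.arange(n_frame),
                "row": centers[:, 0],
                "col": centers[:, 1],
                "radius": cell_radius,
                "base_intensity": base_int,
                "transfected": transfected,
                "planted_fold": fold,
            }
        )
        wells[cid] = WellImages(cid, times, pages, truth)
        truth_frames.append(truth)

    if clipped:
        logger.warning("bit-depth clipping applied to %d pixels", clipped)
    truth_all = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame()
    )
    return ScreenImageSet(wells, pd.DataFrame(manifest_rows), truth_all, clipped)


# ---------------------------------------------------------------------------
# chase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChaseSimConfig:
    """One-phase exponential decay series: Y(t) = (Y0-plateau)e^{-kt} + plateau."""

    y0: float = 100.0
    plateau: float = 0.0
    k: float = 0.3402  # per hour
    sample_interval_min: float = 30.0
    duration_h: float = 12.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigurationError("decay rate k must be >= 0")
        if not self.y0 >= self.plateau >= 0:
            raise ConfigurationError("require y0 >= plateau >= 0")
        if self.duration_h <= 0 or self.sample_interval_min <= 0:
            raise ConfigurationError("duration and sampling interval must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def simulate_chase_series(config: ChaseSimConfig) -> pd.DataFrame:
    """Sample the decay on its time grid; columns ``time_h, intensity``."""
    rng = np.random.default_rng(config.seed)
    step = config.sample_interval_min / 60.0
    n = int(math.floor(config.duration_h / step + 1e-9))
    t = np.round(np.arange(n + 1) * step, 9)
    y = (config.y0 - config.plateau) * np.exp(-config.k * t) + config.plateau
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, y.shape)
    return pd.DataFrame({"time_h": t, "intensity": y})


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColocSimConfig:
    """Two registered channels with a planted signal-overlap fraction.

    ``planted_coloc_fraction`` is the fraction of channel-A intensity mass
    placed inside channel-B-positive pixels. Background defaults to zero so
    the direct mass-ratio oracle is exact.
    """

    grid_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 8
    nucleus_radius: int = 15
    planted_coloc_fraction: float = 0.5
    a_intensity: float = 120.0
    b_intensity: float = 100.0
    background: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_coloc_fraction <= 1.0:
            raise ConfigurationError("planted_coloc_fraction must be in [0, 1]")
        if self.n_nuclei < 0:
            raise ConfigurationError("n_nuclei must be >= 0")
        if self.a_intensity <= 0 or self.b_intensity <= 0:
            raise ConfigurationError("channel intensities must be > 0")
        if self.noise_sd < 0 or self.background < 0:
            raise ConfigurationError("noise_sd and background must be >= 0")


@dataclass
class ColocPair:
    channel_a: np.ndarray
    channel_b: np.ndarray
    nuclear_mask: np.ndarray
    planted_fraction: float


def simulate_coloc_pair(config: ColocSimConfig) -> ColocPair:
    """Generate a registered channel pair inside disk nuclei.

    Channel B occupies a random subset of nuclear pixels; channel A support
    is split between B-positive and B-negative nuclear pixels so that the
    fraction of A mass inside B-positive pixels equals the planted fraction
    up to integer rounding.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    mask = np.zeros(shape, dtype=bool)
    if config.n_nuclei > 0:
        centers = _place_disks(rng, config.n_nuclei, shape, config.nucleus_radius, 50_000)
        for r, c in centers:
            rr, cc = _disk_coords((r, c), config.nucleus_radius, shape=shape)
            mask[rr, cc] = True

    a = np.full(shape, config.background, dtype=float)
    b = np.full(shape, config.background, dtype=float)
    if mask.any():
        idx = np.flatnonzero(mask.ravel())
        in_b = idx[rng.random(idx.size) < 0.5]
        out_b = np.setdiff1d(idx, in_b, assume_unique=True)
        b.ravel()[in_b] += config.b_intensity

        n_a = int(0.6 * min(in_b.size, out_b.size))
        n_in = int(round(config.planted_coloc_fraction * n_a))
        a_in = rng.choice(in_b, size=n_in, replace=False)
        a_out = rng.choice(out_b, size=n_a - n_in, replace=False)
        a.ravel()[np.concatenate([a_in, a_out])] += config.a_intensity

    if config.noise_sd > 0:
        a = np.clip(a + rng.normal(0.0, config.noise_sd, shape), 0, None)
        b = np.clip(b + rng.normal(0.0, config.noise_sd, shape), 0, None)
    return ColocPair(a, b, mask, config.planted_coloc_fraction)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Expression + survival cohort with a planted hazard difference.

    The focal gene (named ``"focal"`` in the output) sits at
    ``target_gene_rank`` by realized median FPKM. Samples in the focal
    gene's top expression quartile have their event hazard multiplied by
    ``hazard_ratio_top_vs_bottom``; independent exponential censoring is
    calibrated so that roughly ``censoring_rate`` of baseline samples are
    censored.
    """

    n_genes: int = 171
    n_samples: int = 811
    target_gene_rank: int = 9
    baseline_hazard: float = 0.05  # events per month
    hazard_ratio_top_vs_bottom: float = 2.0
    censoring_rate: float = 0.3
    expression_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 4:
            raise ConfigurationError("need n_genes >= 1 and n_samples >= 4")
        if not 1 <= self.target_gene_rank <= self.n_genes:
            raise ConfigurationError(
                f"target_gene_rank must be in [1, {self.n_genes}]"
            )
        if self.hazard_ratio_top_vs_bottom <= 0:
            raise ConfigurationError("hazard ratio must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError("censoring_rate must be in [0, 1)")


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate ``(fpkm, clinical, truth)``.

    ``fpkm`` is a genes x samples matrix (the focal gene's row index is named
    ``"focal"``); ``clinical`` has columns ``sample, time, event``. The focal
    label is assigned to the row whose realized median lands exactly at the
    target rank, so the planted rank is exact rather than probabilistic.
    """
    rng = np.random.default_rng(config.seed)
    base_medians = np.exp(rng.normal(3.0, 1.5, config.n_genes))
    z = rng.standard_normal((config.n_genes, config.n_samples))
    matrix = base_medians[:, None] * np.exp(config.expression_sigma * z)

    realized = np.median(matrix, axis=1)
    order = np.argsort(-realized, kind="stable")  # descending: rank 1 first
    focal_row = order[config.target_gene_rank - 1]
    names = [f"gene_{i + 1:03d}" for i in range(config.n_genes)]
    names[focal_row] = "focal"
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    fpkm = pd.DataFrame(matrix, index=pd.Index(names, name="gene"), columns=samples)

    focal_expr = matrix[focal_row]
    top = focal_expr > np.quantile(focal_expr, 0.75)
    hazard = np.where(top, config.baseline_hazard * config.hazard_ratio_top_vs_bottom,
                      config.baseline_hazard)
    event_t = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        c_rate = config.baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
        censor_t = rng.exponential(1.0 / c_rate, config.n_samples)
    else:
        censor_t = np.full(config.n_samples, np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    clinical = pd.DataFrame({"sample": samples, "time": time, "event": event})

    truth = {
        "focal_gene": "focal",
        "target_gene_rank": config.target_gene_rank,
        "hazard_ratio_top_vs_bottom": config.hazard_ratio_top_vs_bottom,
        "n_top_quartile": int(top.sum()),
    }
    return fpkm, clinical, truth
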