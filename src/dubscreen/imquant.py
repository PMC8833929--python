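"""Per-cell quantification of two-channel fluorescence frames.

The processing chain mirrors a standard high-content workflow: Gaussian
smoothing followed by rolling-ball background subtraction (grayscale opening
with a disk structuring element, default radius 100 px), Otsu segmentation of
the reporter channel into 8-connected objects, and per-object statistics
(area, per-channel mean and population standard deviation). Objects are not
tracked between frames; downstream analysis works on per-time-point
population distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation
from skimage.feature import peak_local_max

from .errors import DimensionError, IntegrityError, ParameterError

__all__ = [
    "ImageFrame",
    "WellTimeSeries",
    "subtract_background",
    "segment_cells",
    "measure_cells",
    "estimate_bleedthrough",
    "correct_bleedthrough",
    "build_timeseries",
    "quantify_images",
]


@dataclass
class ImageFrame:
    """A single-channel 2-D intensity grid with acquisition metadata."""

    pixels: np.ndarray
    channel: str = "reporter"
    time_h: float = 0.0
    well: str = ""
    field: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise DimensionError("frame must be a 2-D grid of size >= 1x1")


def _pixels(frame) -> np.ndarray:
    return frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame, dtype=float)


def _like(frame, pixels: np.ndarray):
    if isinstance(frame, ImageFrame):
        out = ImageFrame(pixels, frame.channel, frame.time_h, frame.well, frame.field)
        return out
    return pixels


def subtract_background(frame, radius: int = 100, smooth_sigma: float = 2.0,
                        decomposition: str | None = "sequence"):
    """Smooth, then remove the rolling-ball background and clip at zero.

    The background is the grayscale opening of the smoothed image with a disk
    structuring element of the given radius; the flat background of a frame
    is therefore removed entirely, and the output never contains negative
    pixels. ``decomposition="sequence"`` uses a fast decomposed footprint
    (a close approximation of the full disk); pass ``None`` for the exact
    disk on small images.
    """
    img = _pixels(frame)
    if radius < 1:
        raise ParameterError("radius must be >= 1")
    if smooth_sigma < 0:
        raise ParameterError("smooth_sigma must be >= 0")
    if radius > img.shape[0] and radius > img.shape[1]:
        raise ParameterError(
            f"radius {radius} exceeds both image dimensions {img.shape}"
        )
    if smooth_sigma > 0:
        img = filters.gaussian(img, sigma=smooth_sigma, preserve_range=True)
    footprint = morphology.disk(radius, decomposition=decomposition)
    background = morphology.opening(img, footprint)
    return _like(frame, np.clip(img - background, 0.0, None))


def segment_cells(frame, min_area: int = 50, split_touching: bool = False,
                  threshold: float | None = None,
                  split_min_distance: int = 5) -> np.ndarray:
    """Label reporter-positive cells on a background-subtracted frame.

    Objects are 8-connected components above an automatic Otsu threshold
    (overridable), holes filled, objects smaller than ``min_area`` removed.
    With ``split_touching`` a distance-transform watershed separates merged
    objects. A blank (constant) frame yields an empty labeling.
    """
    img = _pixels(frame)
    if threshold is None:
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=np.int32)
        threshold = filters.threshold_otsu(img)
    mask = img > threshold
    mask = ndi.binary_fill_holes(mask)
    # objects strictly smaller than min_area are removed
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1, connectivity=2)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)

    if split_touching:
        distance = ndi.distance_transform_edt(mask)
        peaks = peak_local_max(
            distance, min_distance=split_min_distance, labels=mask,
            exclude_border=False,
        )
        peak_mask = np.zeros(mask.shape, dtype=bool)
        peak_mask[tuple(peaks.T)] = True
        markers, _ = ndi.label(peak_mask, structure=np.ones((3, 3)))
        labels = segmentation.watershed(-distance, markers, mask=mask)
        labels = morphology.remove_small_objects(labels, max_size=min_area - 1)
        # compact label ids after removals
        labels, _, _ = segmentation.relabel_sequential(labels)
    else:
        labels, _ = ndi.label(mask, structure=np.ones((3, 3)))
    return labels.astype(np.int32)


def measure_cells(labels: np.ndarray, frames: Mapping[str, "ImageFrame | np.ndarray"],
                  construct_id: str | None = None, time_h: float | None = None,
                  field_id: int = 0) -> pd.DataFrame:
    """One record per labeled object: area, centroid, per-channel mean and
    population standard deviation (divisor n).

    ``frames`` maps channel names (``"reporter"``, optionally ``"marker"``)
    to grids sharing the label grid's dimensions.
    """
    labels = np.asarray(labels)
    n = int(labels.max())
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:]
    present = counts > 0

    rows, cols = np.indices(labels.shape)
    with np.errstate(invalid="ignore"):
        cen_r = np.bincount(flat, rows.ravel(), minlength=n + 1)[1:] / counts
        cen_c = np.bincount(flat, cols.ravel(), minlength=n + 1)[1:] / counts

    out = pd.DataFrame(
        {
            "label": np.arange(1, n + 1)[present],
            "area": counts[present].astype(float),
            "centroid_row": cen_r[present],
            "centroid_col": cen_c[present],
        }
    )
    for name, frame in frames.items():
        img = _pixels(frame)
        if img.shape != labels.shape:
            raise DimensionError(
                f"channel {name!r} shape {img.shape} != labels shape {labels.shape}"
            )
        w = img.ravel()
        with np.errstate(invalid="ignore"):
            mean = np.bincount(flat, w, minlength=n + 1)[1:] / counts
            mean_sq = np.bincount(flat, w * w, minlength=n + 1)[1:] / counts
        var = np.clip(mean_sq - mean**2, 0.0, None)
        out[f"mean_{name}"] = mean[present]
        out[f"sd_{name}"] = np.sqrt(var[present])
    if construct_id is not None:
        out.insert(0, "construct_id", construct_id)
    if time_h is not None:
        out.insert(1 if construct_id is not None else 0, "time_h", time_h)
    out["field"] = field_id
    return out


def estimate_bleedthrough(control_records: pd.DataFrame) -> float:
    """Bleed-through coefficient from marker-only control wells.

    Slope of the regression of reporter on marker mean intensity through the
    origin: alpha = sum(r * m) / sum(m^2).
    """
    m = control_records["mean_marker"].to_numpy(float)
    r = control_records["mean_reporter"].to_numpy(float)
    denom = float(np.sum(m * m))
    if denom == 0:
        raise ParameterError("control records carry no marker signal")
    return float(np.sum(r * m) / denom)


def correct_bleedthrough(records: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Subtract ``alpha * mean_marker`` from ``mean_reporter``, floored at 0."""
    if alpha < 0:
        raise ParameterError("alpha must be >= 0")
    out = records.copy()
    if alpha > 0:
        out["mean_reporter"] = np.clip(
            out["mean_reporter"] - alpha * out["mean_marker"], 0.0, None
        )
    return out


@dataclass
class WellTimeSeries:
    """Per-construct population time course pooled across fields."""

    construct_id: str
    times: np.ndarray
    values: dict[float, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def n_cells(self) -> np.ndarray:
        return np.array([self.values[t].size for t in self.times])

    @property
    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "n_cells": self.n_cells,
                "mean": [float(np.mean(self.values[t])) if self.values[t].size else np.nan
                         for t in self.times],
                "median": [float(np.median(self.values[t])) if self.values[t].size else np.nan
                           for t in self.times],
            }
        )


def build_timeseries(records: pd.DataFrame,
                     value_column: str = "mean_reporter") -> dict[str, WellTimeSeries]:
    """Pool cell records into per-construct time series.

    Records must carry ``construct_id`` and ``time_h``; cells from all fields
    of a well are pooled per time point. Duplicated (construct, time, field,
    label) keys indicate a double-counted object and raise.
    """
    if records.empty:
        return {}
    for col in ("construct_id", "time_h", value_column):
        if col not in records.columns:
            raise IntegrityError(f"records lack required column {col!r}")
    key_cols = [c for c in ("construct_id", "time_h", "field", "label")
                if c in records.columns]
    if len(key_cols) == 4 and records.duplicated(key_cols).any():
        raise IntegrityError("duplicated (construct, time, field, label) keys")

    out: dict[str, WellTimeSeries] = {}
    for cid, grp in records.groupby("construct_id", sort=False, observed=True):
        times = np.sort(grp["time_h"].unique())
        values = {
            float(t): sub[value_column].to_numpy(float)
            for t, sub in grp.groupby("time_h", sort=True)
        }
        out[str(cid)] = WellTimeSeries(str(cid), times.astype(float), values)
    return out


def quantify_images(manifest: pd.DataFrame | str | Path,
                    images_dir: str | Path | None = None,
                    radius: int = 100, smooth_sigma: float = 2.0,
                    min_area: int = 50, split_touching: bool = False,
                    alpha: float = 0.0,
                    decomposition: str | None = "sequence") -> pd.DataFrame:
    """Run subtract -> segment -> measure over a TIFF + manifest layout.

    The manifest (CSV or DataFrame) has columns ``construct_id, well, field,
    time_h, channel, page_index, file``; pages live in multi-page TIFFs under
    ``images_dir``. Returns pooled cell records ready for
    :func:`build_timeseries`.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        if images_dir is None:
            images_dir = manifest_path.parent
        manifest = pd.read_csv(manifest_path)
    if images_dir is None:
        raise ParameterError("images_dir is required with an in-memory manifest")
    images_dir = Path(images_dir)

    records = []
    cache: dict[str, np.ndarray] = {}
    group_cols = ["construct_id", "well", "field", "time_h"]
    for (cid, _well, field_id, time_h), grp in manifest.groupby(group_cols, sort=True):
        by_channel = {}
        for _, row in grp.iterrows():
            fname = str(row["file"])
            if fname not in cache:
                cache[fname] = tifffile.imread(images_dir / fname)
            by_channel[row["channel"]] = cache[fname][int(row["page_index"])].astype(float)
        reporter = subtract_background(by_channel["reporter"], radius=radius,
                                       smooth_sigma=smooth_sigma,
                                       decomposition=decomposition)
        labels = segment_cells(reporter, min_area=min_area, split_touching=split_touching)
        frames = {"reporter": reporter}
        if "marker" in by_channel:
            frames["marker"] = by_channel["marker"]
        rec = measure_cells(labels, frames, construct_id=str(cid),
                            time_h=float(time_h), field_id=int(field_id))
        records.append(rec)
    if not records:
        return pd.DataFrame()
    out = pd.concat(records, ignore_index=True)
    if alpha > 0 and "mean_marker" in out.columns:
        out = correct_bleedthrough(out, alpha)
    return out
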