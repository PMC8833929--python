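"""Nuclear colocalization via intensity-weighted Manders coefficients.

M1 is the fraction of channel-A intensity (e.g. c-MYC) residing in pixels
where channel B (e.g. OTUB1) is above threshold, restricted to a nuclear
mask; M2 is the symmetric fraction of B in A-positive pixels. Thresholds may
be fixed, or chosen automatically by a Costes-style criterion: the largest
joint threshold scale at which the below-threshold pixels of the two
channels show no positive correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .errors import (
    DegenerateChannelError,
    DimensionError,
    EmptyMaskError,
    UndefinedCoefficientError,
)

__all__ = ["ColocResult", "nuclear_mask", "auto_thresholds", "manders", "colocalize"]


@dataclass
class ColocResult:
    m1: float  # fraction of A intensity in B-positive pixels
    m2: float  # fraction of B intensity in A-positive pixels
    threshold_a: float
    threshold_b: float
    threshold_method: str
    n_mask_pixels: int


def nuclear_mask(nuclear_channel: np.ndarray, min_area: int = 50) -> np.ndarray:
    """Otsu-thresholded, hole-filled, small-object-removed nuclear mask.

    A blank (constant) channel yields an empty mask with a warning; the
    colocalization operations then refuse to run on it.
    """
    img = np.asarray(nuclear_channel, dtype=float)
    if np.ptp(img) == 0:
        warnings.warn("nuclear channel is constant; mask is empty", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    mask = img > filters.threshold_otsu(img)
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1, connectivity=2)
    if not mask.any():
        warnings.warn("nuclear mask is empty after filtering", stacklevel=2)
    return mask


def auto_thresholds(channel_a: np.ndarray, channel_b: np.ndarray,
                    mask: np.ndarray, n_steps: int = 200,
                    fixed: tuple[float, float] | None = None) -> tuple[float, float]:
    """Joint per-channel thresholds for the Manders computation.

    With ``fixed`` set, the pair is returned verbatim. Otherwise the
    thresholds are ``s * max(channel)`` for the largest scale ``s`` at which
    the pixels below both thresholds are uncorrelated or anticorrelated
    (Pearson r <= 0) and both channels retain above-threshold pixels inside
    the mask. Returned thresholds never exceed the channel maxima.
    """
    if fixed is not None:
        return float(fixed[0]), float(fixed[1])
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape or a.shape != np.asarray(mask).shape:
        raise DimensionError("channels and mask must share dimensions")
    if not np.any(mask):
        raise EmptyMaskError("cannot choose thresholds on an empty mask")
    av, bv = a[mask], b[mask]
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise DegenerateChannelError("constant channel; thresholds undefined")

    amax, bmax = float(av.max()), float(bv.max())
    for s in np.linspace(1.0, 0.0, n_steps + 1)[1:-1]:
        ta, tb = s * amax, s * bmax
        if not (np.any(av > ta) and np.any(bv > tb)):
            continue
        below = (av < ta) & (bv < tb)
        if below.sum() < 2:
            continue
        ab, bb = av[below], bv[below]
        if np.ptp(ab) == 0 or np.ptp(bb) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(ab, bb)[0, 1])
        if r <= 0:
            return ta, tb
    # fall back to the most permissive thresholds that keep signal
    return 0.0, 0.0


def manders(channel_a: np.ndarray, channel_b: np.ndarray, mask: np.ndarray,
            thresholds: tuple[float, float],
            threshold_method: str = "fixed") -> ColocResult:
    """Intensity-weighted Manders split coefficients within a nuclear mask.

    M1 = sum of A over (A > t_a) & (B > t_b) / sum of A over (A > t_a);
    M2 symmetric. Raises when the mask is empty or no A (resp. B) pixels
    exceed the threshold.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise DimensionError("channels and mask must share dimensions")
    if not mask.any():
        raise EmptyMaskError("empty nuclear mask")
    ta, tb = float(thresholds[0]), float(thresholds[1])
    if ta < 0 or tb < 0:
        raise UndefinedCoefficientError("thresholds must be >= 0")

    av, bv = a[mask], b[mask]
    a_pos = av > ta
    b_pos = bv > tb
    sum_a = float(av[a_pos].sum())
    sum_b = float(bv[b_pos].sum())
    if sum_a <= 0:
        raise UndefinedCoefficientError("no above-threshold channel-A pixels")
    if sum_b <= 0:
        raise UndefinedCoefficientError("no above-threshold channel-B pixels")
    m1 = float(av[a_pos & b_pos].sum()) / sum_a
    m2 = float(bv[a_pos & b_pos].sum()) / sum_b
    return ColocResult(m1, m2, ta, tb, threshold_method, int(mask.sum()))


def colocalize(channel_a: np.ndarray, channel_b: np.ndarray,
               mask: np.ndarray | None = None,
               nuclear_channel: np.ndarray | None = None,
               thresholds: "str | tuple[float, float]" = "auto") -> ColocResult:
    """High-level entry point: derive the mask and thresholds, then score.

    ``mask`` may be given directly, or computed from ``nuclear_channel``;
    with neither, the whole frame is used. ``thresholds`` is ``"auto"``
    (Costes-style scan) or an explicit ``(t_a, t_b)`` pair.
    """
    a = np.asarray(channel_a, dtype=float)
    if mask is None:
        mask = (
            nuclear_mask(nuclear_channel)
            if nuclear_channel is not None
            else np.ones(a.shape, dtype=bool)
        )
    if isinstance(thresholds, str):
        if thresholds != "auto":
            raise UndefinedCoefficientError(f"unknown threshold mode {thresholds!r}")
        ta, tb = auto_thresholds(a, channel_b, mask)
        method = "costes"
    else:
        ta, tb = thresholds
        method = "fixed"
    return manders(a, channel_b, mask, (ta, tb), threshold_method=method)
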