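"""Image-series binarization and the white-pixel degradation statistic.

A degradation experiment is followed as a time series of photographs of a
single well containing bright polymer grains on dark agar.  Every frame of
one series is binarized with the *same* closed grey-level interval, so that
white-pixel counts are comparable over time, and the remaining polymer area
at time ``t`` is expressed as a percentage of the area at ``t0``::

    remaining(t) = 100 * WP_t / WP_t0

where ``WP_t`` is the number of white (in-threshold) pixels of frame ``t``.
The curve starts at exactly 100 and falls as the polymer is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .kinetics import KineticCurve

__all__ = [
    "ImageSeries",
    "ThresholdRange",
    "BinarySeries",
    "to_grey",
    "binarize_series",
    "suggest_threshold",
    "degradation_curve",
    "circular_mask",
]

#: ITU-R BT.601 luma weights used for RGB -> grey conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def circular_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disc of ``radius`` pixels around ``center`` (row, col)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@dataclass
class ImageSeries:
    """Ordered, time-stamped grey-level frames of one well.

    Parameters
    ----------
    frames : list of ndarray
        2-D grey-level arrays in [0, 1], one per time point, all the same
        shape.  RGB or integer input should go through :func:`to_grey` first.
    times : ndarray
        Acquisition times in hours, strictly increasing; ``times[0]`` is the
        reference t0.
    sample_id, blend_label : str
        Identification carried through to the kinetics output.
    well_mask : ndarray of bool, optional
        Region of interest; pixels outside it are never counted.
    """

    frames: list[np.ndarray]
    times: np.ndarray
    sample_id: str = ""
    blend_label: str = ""
    well_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) == 0:
            raise ValueError("series must contain at least one frame")
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times differ in length")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames must share one shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.well_mask is not None and self.well_mask.shape != shape:
            raise ValueError("well mask shape does not match frames")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class ThresholdRange:
    """Closed grey-level interval [low, high] shared by a whole series.

    A pixel is white iff ``low <= grey <= high``; both ends are inclusive
    so that boundary grey levels behave predictably.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ValueError(
                f"threshold range must satisfy 0 <= low <= high <= 1, got [{self.low}, {self.high}]"
            )


@dataclass
class BinarySeries:
    """Binarized frames with their white-pixel counts."""

    masks: list[np.ndarray]
    white_counts: np.ndarray
    times: np.ndarray
    sample_id: str = ""
    blend_label: str = ""
    threshold: ThresholdRange | None = None

    def __len__(self) -> int:
        return len(self.masks)


def to_grey(frame: np.ndarray) -> np.ndarray:
    """Convert a frame to a 2-D grey-level array in [0, 1].

    Integer input is normalized by its dtype's full range (255 for uint8,
    65535 for uint16); RGB is collapsed with the 0.299/0.587/0.114 luma
    weights.  Float input is assumed to already live in [0, 1].
    """
    frame = np.asarray(frame)
    if frame.ndim == 3:
        if frame.shape[2] != 3:
            raise ValueError(f"expected 1 or 3 channels, got {frame.shape[2]}")
    elif frame.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-channel image, got shape {frame.shape}")

    if np.issubdtype(frame.dtype, np.integer):
        info = np.iinfo(frame.dtype)
        grey = frame.astype(float) / info.max
    else:
        grey = frame.astype(float)

    if grey.ndim == 3:
        grey = grey @ _LUMA
    return np.clip(grey, 0.0, 1.0)


def binarize_series(series: ImageSeries, thr: ThresholdRange) -> BinarySeries:
    """Apply one threshold range to every frame of a series.

    The same interval is applied to all frames so counts are directly
    comparable; when the series carries a well mask, out-of-well pixels are
    forced to black before counting.
    """
    masks: list[np.ndarray] = []
    counts = np.empty(len(series), dtype=np.int64)
    for i, frame in enumerate(series.frames):
        mask = (frame >= thr.low) & (frame <= thr.high)
        if series.well_mask is not None:
            mask &= series.well_mask
        masks.append(mask)
        counts[i] = int(mask.sum())
    return BinarySeries(
        masks=masks,
        white_counts=counts,
        times=series.times.copy(),
        sample_id=series.sample_id,
        blend_label=series.blend_label,
        threshold=thr,
    )


def suggest_threshold(series: ImageSeries, pull: float = 0.25) -> ThresholdRange:
    """Propose a grain-anchored threshold range from the reference frame.

    The t0 frame (before any mycelium has grown) is split by Otsu's
    criterion, restricted to the well; the suggested ``low`` is then placed
    a fraction ``pull`` of the class separation *below the bright-class
    mean*::

        low = mu_fg - pull * (mu_fg - mu_bg)

    Anchoring near the grain intensity rather than at the Otsu cut leaves
    headroom for bright filamentous growth that appears only in later
    frames: the raw Otsu threshold on an agar-dominated histogram falls
    close to the agar mode and would admit mycelium wholesale.  The result
    is a *suggestion* — the experimenter may override it after inspecting
    the binarized series.

    Raises
    ------
    ValueError
        If the reference frame is constant ("degenerate histogram").
    """
    t0 = series.frames[0]
    pixels = t0[series.well_mask] if series.well_mask is not None else t0.ravel()
    if np.ptp(pixels) == 0:
        raise ValueError("degenerate histogram: reference frame is constant")
    t_otsu = float(threshold_otsu(pixels))
    mu_fg = float(pixels[pixels > t_otsu].mean())
    mu_bg = float(pixels[pixels <= t_otsu].mean())
    return ThresholdRange(low=mu_fg - pull * (mu_fg - mu_bg), high=1.0)


def degradation_curve(binary: BinarySeries) -> KineticCurve:
    """Remaining-polymer percentage ``100 * WP_t / WP_t0`` over time.

    The value at t0 is exactly 100.  Values above 100 (apparent grain
    growth, e.g. specular highlights) are kept rather than clipped, since
    they flag acquisition problems.

    Raises
    ------
    ValueError
        If the reference frame has no white pixels.
    """
    wp0 = binary.white_counts[0]
    if wp0 == 0:
        raise ValueError("empty reference frame: WP(t0) = 0")
    values = 100.0 * binary.white_counts / wp0
    values[0] = 100.0
    return KineticCurve(
        times=binary.times.copy(),
        values=values,
        sample_id=binary.sample_id,
        blend_label=binary.blend_label,
    )
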