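"""Quantitative evaluation of reconstructed slice videos.

Temporal SNR maps, RMSE against a reference, zero-mean ROI signal traces
with their RMS (the intensity-variation measure used to compare sampling
schemes), and x-t profiles for visualizing motion along a fixed line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TSNRMap:
    """Per-pixel temporal SNR; ``valid`` is False where the temporal SD is 0."""

    values: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)


def tsnr(video: np.ndarray) -> TSNRMap:
    """Temporal mean of the magnitude over its sample SD (ddof=1), per pixel.

    ``video``: (T, N, N); pixels whose magnitude never varies are flagged
    invalid rather than producing infinities.
    """
    video = np.asarray(video)
    if video.ndim != 3 or video.shape[0] < 2:
        raise ValueError("need a (frames, N, N) video with at least 2 frames")
    mag = np.abs(video)
    mean = mag.mean(axis=0)
    sd = mag.std(axis=0, ddof=1)
    valid = sd > 0
    values = np.zeros_like(mean)
    values[valid] = mean[valid] / sd[valid]
    return TSNRMap(values=values, valid=valid)


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared magnitude difference between two arrays."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.abs(a - b) ** 2)))


def roi_trace(video: np.ndarray, roi_mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Zero-mean per-frame ROI signal and its RMS.

    The per-frame mean magnitude over the ROI is centred by subtracting its
    temporal mean; the RMS of the centred trace quantifies residual
    frame-to-frame intensity variation in a static region.
    """
    video = np.asarray(video)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != video.shape[-2:]:
        raise ValueError("ROI mask shape does not match the image grid")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    trace = np.abs(video)[:, roi_mask].mean(axis=1)
    trace = trace - trace.mean()
    return trace, float(np.sqrt(np.mean(trace**2)))


def xt_profile(video: np.ndarray, *, axis: str = "row", index: int | None = None,
               start: int = 0, stop: int | None = None) -> np.ndarray:
    """Space-time image of the magnitude along a fixed pixel line.

    ``axis='row'`` takes image row ``index`` (columns ``start:stop``);
    ``axis='col'`` takes image column ``index``.  Returns (line length, T).
    """
    video = np.asarray(video)
    t_frames, nr, ncol = video.shape
    if axis not in ("row", "col"):
        raise ValueError("axis must be 'row' or 'col'")
    size = nr if axis == "col" else ncol
    other = ncol if axis == "col" else nr
    if index is None:
        index = other // 2
    stop = size if stop is None else stop
    if not (0 <= index < other and 0 <= start < stop <= size):
        raise ValueError("line out of bounds")
    if axis == "row":
        prof = np.abs(video[:, index, start:stop])
    else:
        prof = np.abs(video[:, start:stop, index])
    return prof.T
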