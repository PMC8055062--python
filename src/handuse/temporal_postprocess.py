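"""Temporal post-processing of per-frame score tracks.

Every per-frame track — classifier scores *and* ground-truth label tracks
alike — goes through the same three steps before any metric is computed:

1. moving-average smoothing with a centred 120-frame window (4 s at
   30 fps), truncated at task boundaries (the divisor is the number of
   in-range taps, so no data is invented at the edges);
2. per-task min-max normalization: subtract the minimum, divide by the
   range; a constant track maps to all zeros and is flagged;
3. thresholding at 0.5, strictly above → positive (interaction /
   manipulator), otherwise negative (no interaction / stabilizer).

Running the ground truth through the identical pipeline keeps predictions
and annotations comparable after smoothing.  Note the degenerate case: a
track that is constant after smoothing (e.g. a task that is interaction
throughout, or a hand-waving task with no interactions at all) normalizes
to all zeros; the constant flag is surfaced so that evaluation can treat
such tasks with accuracy-style metrics only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PostprocessConfig",
    "moving_average",
    "minmax_normalize",
    "binarize",
    "postprocess_track",
]


@dataclass(frozen=True)
class PostprocessConfig:
    window: int = 120
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge truncation.

    Output ``i`` is the mean of the in-range values at indices
    ``[i - window//2, i - window//2 + window)``; near the edges the divisor
    shrinks to the number of in-range taps.  Length is preserved.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series is empty")
    n = series.size
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(series)])
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) - half + window, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def minmax_normalize(series: np.ndarray) -> tuple[np.ndarray, bool]:
    """Per-task min-max normalization to [0, 1].

    Returns ``(normalized, constant_flag)``; a constant input maps to all
    zeros with the flag set.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series is empty")
    lo, hi = float(series.min()), float(series.max())
    if hi - lo <= 0:
        return np.zeros_like(series), True
    return (series - lo) / (hi - lo), False


def binarize(series: np.ndarray, config: PostprocessConfig = PostprocessConfig()) -> np.ndarray:
    """Threshold a normalized track: strictly above → positive."""
    return np.asarray(series, dtype=float) > config.threshold


def postprocess_track(
    values: np.ndarray, config: PostprocessConfig = PostprocessConfig()
) -> tuple[np.ndarray, bool]:
    """Smooth, normalize and threshold one per-frame track.

    The single code path used for both prediction tracks and ground-truth
    annotation tracks.  Returns ``(binary_labels, constant_flag)``.
    """
    smoothed = moving_average(values, config.window)
    normalized, constant = minmax_normalize(smoothed)
    return binarize(normalized, config), constant
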