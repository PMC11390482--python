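"""Behavior-conditioned controls: running splits, running-activity
correlation, and pupil trace handling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

__all__ = [
    "RunningModulation",
    "detect_pupil",
    "event_window_speed",
    "filter_pupil_trace",
    "running_activity_correlation",
    "split_fast_slow",
]


def event_window_speed(
    onsets,
    timestamps: np.ndarray,
    running_speed: np.ndarray,
    window: tuple[float, float] = (0.4, 2.0),
) -> np.ndarray:
    """Mean running speed in the response window of each event."""
    onsets = np.asarray(onsets, dtype=float)
    out = np.empty(onsets.size)
    eps = 1e-6  # onsets can coincide exactly with frame times
    for i, onset in enumerate(onsets):
        mask = (timestamps >= onset + window[0] - eps) & (
            timestamps < onset + window[1] - eps
        )
        out[i] = running_speed[mask].mean() if mask.any() else np.nan
    return out


def split_fast_slow(
    onsets,
    timestamps: np.ndarray,
    running_speed: np.ndarray,
    window: tuple[float, float] = (0.4, 2.0),
):
    """Median split of events by window-mean running speed.

    Uses the same 0.4-2.0 s window as the calcium responses. Events are
    stably sorted by speed; the lower half (floor(n/2) events) is "slow",
    the rest "fast", so ties are broken by event order and the two sets
    always partition the events. Returns (slow_idx, fast_idx).
    """
    speeds = event_window_speed(onsets, timestamps, running_speed, window)
    if speeds.size < 2:
        raise ValueError("need at least 2 events to split")
    order = np.argsort(speeds, kind="stable")
    half = speeds.size // 2
    return np.sort(order[:half]), np.sort(order[half:])


@dataclass
class RunningModulation:
    pearson_r: float
    r_squared: float
    valid: bool = True


def running_activity_correlation(responses, speeds) -> RunningModulation:
    """Pearson correlation of trial responses with trial running speed.

    R^2 (coefficient of determination) is the square of r. Zero-variance
    speed makes the correlation undefined; the record is flagged invalid.
    """
    r_arr = np.asarray(responses, dtype=float)
    s_arr = np.asarray(speeds, dtype=float)
    if r_arr.size != s_arr.size:
        raise ValueError("responses and speeds must have equal length")
    if r_arr.size < 3:
        raise ValueError("need at least 3 trials")
    if s_arr.std() == 0 or r_arr.std() == 0:
        return RunningModulation(np.nan, np.nan, valid=False)
    r = float(stats.pearsonr(r_arr, s_arr).statistic)
    return RunningModulation(pearson_r=r, r_squared=r * r)


def detect_pupil(frame: np.ndarray, threshold: float, dark_pupil: bool = True):
    """Threshold-based pupil detection on a single eye-camera frame.

    Binarizes the frame (below threshold = pupil for a dark pupil on a
    bright field), keeps the largest connected region, and returns
    (center_y, center_x, area) with the center of mass of that region.
    Returns None when nothing is detected (a missing-value record).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D grayscale")
    mask = frame < threshold if dark_pupil else frame > threshold
    if not mask.any():
        return None
    labels = measure.label(mask)
    props = measure.regionprops(labels)
    largest = max(props, key=lambda p: p.area)
    cy, cx = largest.centroid
    return float(cy), float(cx), int(largest.area)


def filter_pupil_trace(
    area_trace,
    window: int = 11,
    n_mad: float = 3.0,
) -> np.ndarray:
    """Replace moving-median outliers by linear interpolation.

    A sample is an outlier when it deviates from its window's median by
    more than ``n_mad`` scaled median absolute deviations of the window
    values (the Hampel identifier). Outliers are replaced by linear
    interpolation between the surrounding inliers (edge outliers take the
    nearest inlier value).
    """
    x = np.asarray(area_trace, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    half = window // 2
    padded = np.pad(x, half, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, window)
    med = np.median(win, axis=1)
    scaled = 1.4826 * np.median(np.abs(win - med[:, None]), axis=1)
    outlier = np.abs(x - med) > n_mad * scaled
    if not outlier.any():
        return x.copy()
    good = np.flatnonzero(~outlier)
    if good.size == 0:
        return med  # everything flagged: fall back to the moving median
    filtered = x.copy()
    bad = np.flatnonzero(outlier)
    filtered[bad] = np.interp(bad, good, x[good])
    return filtered


def join_behavior(response_table: pd.DataFrame, trial_speeds: pd.DataFrame) -> pd.DataFrame:
    """Left-join per-trial behavior summaries into a response table by trial_id."""
    return response_table.merge(trial_speeds, on="trial_id", how="left")
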