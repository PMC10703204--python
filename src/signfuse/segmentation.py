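"""Activity detection from windowed signal amplitude.

A sliding window of length ``K`` samples advancing by ``T`` samples is
passed over each channel; the mean absolute value (MAV) of every window
forms an amplitude envelope.  A window is *active* when any channel's
MAV strictly exceeds the modality threshold.  Word segments are maximal
active runs of the OR of the sEMG and ACC masks; gesture stages inside a
segment are maximal sEMG-active runs, so a brief muscle relaxation while
the arm keeps moving splits stages without splitting the word.

Window indices are 0-based; window ``w`` covers samples
``[w*T, w*T + K)``.  Segments and stages are half-open window-index
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Threshold floor used when a calibration recording is identically zero.
EPSILON_THRESHOLD = 1e-12


@dataclass
class SegmenterConfig:
    window_len: int = 50       # K, samples
    step: int = 25             # T, samples
    t_semg: float | None = None
    t_acc: float | None = None
    min_segment: int = 8       # windows; shorter runs are discarded
    max_gap: int = 3           # windows; internal 0-runs <= this are closed
    min_stage_gap: int = 2     # windows of sEMG quiet needed to split stages
    min_stage: int = 4         # windows; shorter stages are spurious, dropped

    def __post_init__(self) -> None:
        if self.window_len < 3:
            raise ValueError("window_len must be >= 3")
        _check_step(self.window_len, self.step)
        for name in ("t_semg", "t_acc"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")


def _check_step(K: int, T: int) -> None:
    if T < 1:
        raise ValueError("step must be >= 1")
    if not (K / 3 <= T <= K / 2):
        warnings.warn(
            f"step T={T} outside the recommended range [K/3, K/2] for K={K}",
            stacklevel=3,
        )


@dataclass
class WindowedEnvelope:
    values: np.ndarray         # (n_channels, n_windows), >= 0
    window_starts: np.ndarray  # (n_windows,) 0-based sample indices
    window_len: int
    step: int

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


@dataclass
class ActivitySegment:
    start: int  # window index, inclusive
    end: int    # window index, exclusive
    stage_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment [{self.start}, {self.end})")


def mav(x: np.ndarray) -> float:
    """Mean absolute value of a sample series."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mav of an empty series is undefined")
    return float(np.mean(np.abs(x)))


def n_windows_for(n_samples: int, K: int, T: int) -> int:
    return (n_samples - K) // T + 1


def sliding_mav(channels: np.ndarray, K: int, T: int) -> WindowedEnvelope:
    """Per-window MAV envelope of a (n_channels, n_samples) array.

    The trailing partial window is discarded.
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    n_samples = channels.shape[1]
    if n_samples < K:
        raise ValueError(f"need at least K={K} samples, got {n_samples}")
    _check_step(K, T)
    n_win = n_windows_for(n_samples, K, T)
    starts = np.arange(n_win) * T
    # stride trick: (n_channels, n_win, K) view, no copy
    windows = np.lib.stride_tricks.sliding_window_view(channels, K, axis=1)[:, ::T, :]
    values = np.abs(windows[:, :n_win, :]).mean(axis=2)
    return WindowedEnvelope(values=values, window_starts=starts, window_len=K, step=T)


def calibrate_thresholds(
    rest_semg: np.ndarray,
    rest_acc: np.ndarray,
    k_sigma: float = 3.0,
    K: int = 50,
    T: int = 25,
) -> tuple[float, float]:
    """Per-modality activity thresholds from a rest-only recording.

    Threshold = mean + k_sigma * sd of the window MAVs pooled across the
    modality's channels, floored at :data:`EPSILON_THRESHOLD`.
    """
    if k_sigma < 0:
        raise ValueError("k_sigma must be >= 0")
    if k_sigma == 0:
        warnings.warn("k_sigma=0 sets thresholds at the rest mean", stacklevel=2)
    out = []
    for rest in (rest_semg, rest_acc):
        env = sliding_mav(rest, K, T)
        pooled = env.values.ravel()
        thr = float(pooled.mean() + k_sigma * pooled.std(ddof=1 if pooled.size > 1 else 0))
        out.append(max(thr, EPSILON_THRESHOLD))
    return out[0], out[1]


def amplitude_mask(env: WindowedEnvelope, threshold: float) -> np.ndarray:
    """1 where any channel's window MAV strictly exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return (env.values > threshold).any(axis=0).astype(np.int8)


def _runs(mask: np.ndarray, value: int) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of ``value`` in a 1-D mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([value ^ 1], mask, [value ^ 1])) == value))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def _close_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Set internal 0-runs of length <= max_gap to 1."""
    out = mask.copy()
    ones = _runs(mask, 1)
    for (s0, e0), (s1, _e1) in zip(ones, ones[1:]):
        if s1 - e0 <= max_gap:
            out[e0:s1] = 1
    return out


def detect_segments(
    semg_mask: np.ndarray,
    acc_mask: np.ndarray,
    cfg: SegmenterConfig,
) -> list[ActivitySegment]:
    """Word segments from the OR of the two modality masks."""
    semg_mask = np.asarray(semg_mask)
    acc_mask = np.asarray(acc_mask)
    if semg_mask.shape != acc_mask.shape:
        raise ValueError(
            f"mask length mismatch: {semg_mask.shape} vs {acc_mask.shape}"
        )
    combined = (semg_mask.astype(bool) | acc_mask.astype(bool)).astype(np.int8)
    closed = _close_gaps(combined, cfg.max_gap)
    return [
        ActivitySegment(s, e)
        for s, e in _runs(closed, 1)
        if e - s >= cfg.min_segment
    ]


def split_stages(
    seg: ActivitySegment,
    semg_mask: np.ndarray,
    acc_mask: np.ndarray,
    cfg: SegmenterConfig,
) -> ActivitySegment:
    """Attach gesture-stage bounds to a segment.

    Stages are maximal sEMG-active runs inside the segment after closing
    sEMG 0-runs shorter than ``min_stage_gap``; a quiet run of at least
    ``min_stage_gap`` windows during which the ACC stream stays active
    marks a stage switch (the quiet gap belongs to neither stage).
    Quiet runs with no ACC activity are closed as well — without arm
    movement they cannot be a gesture switch.  Stages shorter than
    ``min_stage`` windows are discarded as threshold-noise artifacts.
    A segment whose sEMG is never active (or whose stages were all
    discarded) is returned as a single whole-segment stage.
    """
    semg_mask = np.asarray(semg_mask)
    if seg.end > len(semg_mask):
        raise ValueError("segment exceeds mask range")
    local = semg_mask[seg.start:seg.end].astype(np.int8)
    acc_local = np.asarray(acc_mask)[seg.start:seg.end].astype(np.int8)
    if not local.any():
        seg.stage_bounds = [(seg.start, seg.end)]
        return seg
    closed = local.copy()
    ones = _runs(local, 1)
    for (s0, e0), (s1, _e1) in zip(ones, ones[1:]):
        gap_len = s1 - e0
        acc_active = acc_local[e0:s1].any()
        if gap_len < cfg.min_stage_gap or not acc_active:
            closed[e0:s1] = 1
    bounds = [
        (seg.start + s, seg.start + e)
        for s, e in _runs(closed, 1)
        if e - s >= cfg.min_stage
    ]
    seg.stage_bounds = bounds if bounds else [(seg.start, seg.end)]
    return seg


def segment_recording(
    semg: np.ndarray,
    acc: np.ndarray,
    cfg: SegmenterConfig,
) -> list[ActivitySegment]:
    """Convenience: envelopes -> masks -> segments -> stages.

    ``cfg.t_semg`` and ``cfg.t_acc`` must be set (calibrated or given).
    """
    if cfg.t_semg is None or cfg.t_acc is None:
        raise ValueError("thresholds not set; run calibrate_thresholds first")
    env_semg = sliding_mav(semg, cfg.window_len, cfg.step)
    env_acc = sliding_mav(acc, cfg.window_len, cfg.step)
    m_semg = amplitude_mask(env_semg, cfg.t_semg)
    m_acc = amplitude_mask(env_acc, cfg.t_acc)
    segs = detect_segments(m_semg, m_acc, cfg)
    return [split_stages(s, m_semg, m_acc, cfg) for s in segs]
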