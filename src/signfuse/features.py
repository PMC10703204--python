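"""Observation streams for the two-chain fusion classifier.

A segment (or stage) of a recording becomes two aligned streams sharing
one windowing grid: the gesture stream (per-window MAV of the 4 sEMG
channels) and the trajectory stream (per-window mean of the 6 motion
axes, optionally with first differences appended).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import n_windows_for, sliding_mav
from .synthgen import Recording


@dataclass
class FeatureConfig:
    window_len: int = 50
    step: int = 25
    include_derivative: bool = True  # trajectory stream only


@dataclass
class ObservationPair:
    """Two aligned feature streams for one segment or stage."""

    gesture: np.ndarray     # (T_obs, 4)
    trajectory: np.ndarray  # (T_obs, 6) or (T_obs, 12)

    def __post_init__(self) -> None:
        if len(self.gesture) != len(self.trajectory):
            raise ValueError("streams must have equal length")
        if len(self.gesture) < 1:
            raise ValueError("streams must be non-empty")
        if not (np.isfinite(self.gesture).all() and np.isfinite(self.trajectory).all()):
            raise ValueError("non-finite feature values")

    def __len__(self) -> int:
        return len(self.gesture)


def _check_span(rec: Recording, span: tuple[int, int], K: int) -> tuple[int, int]:
    s, e = int(span[0]), int(span[1])
    if not 0 <= s < e <= rec.n_samples:
        raise ValueError(f"span [{s}, {e}) outside recording of {rec.n_samples}")
    if e - s < K:
        raise ValueError(f"span of {e - s} samples shorter than window {K}")
    return s, e


def gesture_stream(
    rec: Recording, span: tuple[int, int], cfg: FeatureConfig
) -> np.ndarray:
    """(T_obs, 4) per-window MAV of the sEMG channels over ``span``."""
    s, e = _check_span(rec, span, cfg.window_len)
    env = sliding_mav(rec.semg[:, s:e], cfg.window_len, cfg.step)
    return env.values.T.copy()


def trajectory_stream(
    rec: Recording, span: tuple[int, int], cfg: FeatureConfig
) -> np.ndarray:
    """Per-window means of ACC+AV axes; first differences appended if
    ``include_derivative`` (zeros for the first window)."""
    s, e = _check_span(rec, span, cfg.window_len)
    motion = rec.motion[:, s:e]
    K, T = cfg.window_len, cfg.step
    n_win = n_windows_for(e - s, K, T)
    windows = np.lib.stride_tricks.sliding_window_view(motion, K, axis=1)[:, ::T, :]
    means = windows[:, :n_win, :].mean(axis=2).T  # (T_obs, 6)
    if not cfg.include_derivative:
        return means
    diffs = np.diff(means, axis=0, prepend=means[:1])
    diffs[0] = 0.0
    return np.hstack([means, diffs])


def build_observation_pair(
    rec: Recording, span: tuple[int, int], cfg: FeatureConfig
) -> ObservationPair:
    """Both streams on the same windowing grid."""
    return ObservationPair(
        gesture=gesture_stream(rec, span, cfg),
        trajectory=trajectory_stream(rec, span, cfg),
    )


def stage_span_samples(
    stage_bound: tuple[int, int], window_len: int, step: int
) -> tuple[int, int]:
    """Sample-domain span covered by a half-open window-index interval."""
    w0, w1 = stage_bound
    return w0 * step, (w1 - 1) * step + window_len
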