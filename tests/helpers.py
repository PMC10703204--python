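"""Shared test utilities."""

import math


def window_bracket_start(s: int, K: int, T: int) -> tuple[int, int]:
    """Valid detected-start window range for an activity onset at sample s.

    A detector may fire on the first window merely overlapping the onset
    (strong signal) or the first window fully inside it (weak signal);
    plus/minus one analysis step of slack on either side.
    """
    w_any = math.ceil((s - K + 1) / T)
    w_full = math.ceil(s / T)
    return w_any - 1, w_full + 1


def window_bracket_end(e: int, K: int, T: int) -> tuple[int, int]:
    """Valid detected-end (exclusive) window range for an offset at sample e."""
    w_any = (e - 1) // T
    w_full = (e - K) // T
    return w_full - 1 + 1, w_any + 1 + 1


def boundaries_ok(start_w: int, end_w: int, s: int, e: int, K: int, T: int) -> bool:
    lo_s, hi_s = window_bracket_start(s, K, T)
    lo_e, hi_e = window_bracket_end(e, K, T)
    return lo_s <= start_w <= hi_s and lo_e <= end_w <= hi_e
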