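"""Seeded generator of multimodal word recordings with ground truth.

Emulates a single-arm acquisition setup: 4 surface-EMG channels plus a
wrist inertial unit (3-axis acceleration, 3-axis angular velocity), all
sampled at 1 kHz.  A word is a ~2 s activity burst padded by rest; each
gesture stage amplitude-modulates the sEMG noise with a per-gesture
channel profile, while the trajectory stream follows a per-class smooth
template.  Multi-stage (dynamic) words insert a brief sEMG relaxation at
each gesture switch while the trajectory stays active — the signature
that segmentation must not mistake for a word boundary.

All randomness flows through explicit seeds; identical arguments give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from .lexicon import Lexicon, LexiconEntry

SEMG_CHANNELS = ["ECR", "ED", "FDS", "EPB"]
CHANNEL_NAMES = (
    [f"semg_{c}" for c in SEMG_CHANNELS]
    + ["acc_x", "acc_y", "acc_z"]
    + ["av_x", "av_y", "av_z"]
)


class GenerationError(RuntimeError):
    pass


@dataclass
class Recording:
    semg: np.ndarray  # (4, n_samples)
    acc: np.ndarray   # (3, n_samples)
    av: np.ndarray    # (3, n_samples)
    fs: float
    channel_names: list[str] = field(default_factory=lambda: list(CHANNEL_NAMES))

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        n = {self.semg.shape[1], self.acc.shape[1], self.av.shape[1]}
        if len(n) != 1:
            raise ValueError("semg/acc/av sample counts differ")
        if self.semg.shape[0] != 4 or self.acc.shape[0] != 3 or self.av.shape[0] != 3:
            raise ValueError("expected 4 sEMG + 3 ACC + 3 AV channels")

    @property
    def n_samples(self) -> int:
        return self.semg.shape[1]

    @property
    def motion(self) -> np.ndarray:
        """(6, n) stacked ACC + AV."""
        return np.vstack([self.acc, self.av])


@dataclass
class GroundTruth:
    word_id: int
    category: str
    segment: tuple[int, int]                 # half-open sample interval
    stage_intervals: list[tuple[int, int]]   # half-open, ordered, in segment
    stage_states: list[tuple[int, int]]      # (gesture, movement) per stage


@dataclass
class GestureProfileSet:
    levels: np.ndarray  # (G, 4) per-gesture per-channel sEMG noise SD
    baseline_sd: float = 1.0


@dataclass
class TrajectoryTemplateSet:
    templates: np.ndarray  # (M, 6, n_t); row 0 is the rest (zero) template
    noise_sd: float = 0.3


@dataclass
class SynthConfig:
    fs: float = 1000.0
    word_duration: float = 2.0     # seconds
    rest_pad: float = 0.5          # seconds each side (jittered per word)
    relaxation_gap: float = 0.15   # seconds of sEMG quiet at a stage switch
    ramp: float = 0.03             # seconds of envelope ramp at state changes
    duration_jitter: float = 0.05  # relative
    pad_jitter: float = 0.2        # relative, leading pad only
    #: sEMG amplitude attenuation range for stages after the first: a
    #: gesture executed right after a rapid switch is less crisp.
    stage_attenuation: tuple[float, float] = (0.6, 1.0)

    def __post_init__(self) -> None:
        for name in ("fs", "word_duration", "rest_pad", "relaxation_gap", "ramp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.relaxation_gap >= self.word_duration / 4:
            raise ValueError("relaxation_gap must be < word_duration / 4")


def make_gesture_profiles(
    n_gestures: int,
    seed: int,
    separation: float = 3.0,
    baseline_sd: float = 1.0,
    max_tries: int = 1000,
) -> GestureProfileSet:
    """Per-gesture 4-channel amplitude profiles with a minimum pairwise gap."""
    if n_gestures < 1:
        raise ValueError("n_gestures must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        levels = rng.uniform(2.0, 8.0, size=(n_gestures, 4))
        if n_gestures == 1:
            return GestureProfileSet(levels=levels, baseline_sd=baseline_sd)
        d = np.linalg.norm(levels[:, None, :] - levels[None, :, :], axis=2)
        if d[np.triu_indices(n_gestures, k=1)].min() >= separation:
            return GestureProfileSet(levels=levels, baseline_sd=baseline_sd)
    raise GenerationError(
        f"could not place {n_gestures} profiles with separation {separation}"
    )


def make_trajectory_templates(
    n_movement_states: int,
    n_t: int = 2000,
    seed: int = 0,
    separation: float = 3.0,
    noise_sd: float = 0.3,
    max_tries: int = 1000,
) -> TrajectoryTemplateSet:
    """Smooth 6-axis waveform per movement class; class 0 is rest (zero).

    Each class is a per-axis amplitude vector shaped by a flat-topped
    (Tukey) envelope with a per-class sinusoidal ripple, so classes are
    separated mainly by their mean window amplitude.
    """
    if n_movement_states < 1:
        raise ValueError("n_movement_states must be >= 1")
    if n_t < 10:
        raise ValueError("n_t must be >= 10")
    rng = np.random.default_rng(seed)
    tau = np.linspace(0.0, 1.0, n_t)
    env = tukey(n_t, alpha=0.2)
    n_active = n_movement_states - 1
    for _ in range(max_tries):
        amps = rng.uniform(2.0, 6.0, size=(n_active, 6)) * rng.choice(
            [-1.0, 1.0], size=(n_active, 6)
        )
        if n_active <= 1:
            break
        d = np.linalg.norm(amps[:, None, :] - amps[None, :, :], axis=2)
        if d[np.triu_indices(n_active, k=1)].min() >= separation:
            break
    else:
        raise GenerationError("could not separate trajectory templates")
    freqs = rng.uniform(1.0, 3.0, size=max(n_active, 1))
    phases = rng.uniform(0.0, 2 * np.pi, size=max(n_active, 1))
    templates = np.zeros((n_movement_states, 6, n_t))
    for m in range(1, n_movement_states):
        ripple = 1.0 + 0.2 * np.sin(2 * np.pi * freqs[m - 1] * tau + phases[m - 1])
        templates[m] = amps[m - 1][:, None] * (env * ripple)[None, :]
    return TrajectoryTemplateSet(templates=templates, noise_sd=noise_sd)


def _ramped_envelope(n: int, start: int, end: int, ramp: int) -> np.ndarray:
    """0->1 trapezoid over [start, end) with linear ramps of ``ramp`` samples."""
    env = np.zeros(n)
    width = end - start
    r = max(1, min(ramp, width // 2))
    env[start:start + r] = np.linspace(0.0, 1.0, r, endpoint=False)
    env[start + r:end - r] = 1.0
    env[end - r:end] = np.linspace(1.0, 0.0, r)
    return env


def _resample_template(template: np.ndarray, n_out: int) -> np.ndarray:
    """Linear time-rescale of a (6, n_t) template to n_out samples."""
    n_t = template.shape[1]
    x_out = np.linspace(0.0, 1.0, n_out)
    x_in = np.linspace(0.0, 1.0, n_t)
    return np.vstack([np.interp(x_out, x_in, row) for row in template])


def _trajectory_spans(
    stage_intervals: list[tuple[int, int]],
    movements: list[int],
) -> list[tuple[int, int, int]]:
    """(start, end, movement) spans covering stages and relaxation gaps.

    Consecutive stages sharing a nonzero movement merge into one
    continuous sweep; otherwise each inter-stage gap is bridged by the
    neighbouring nonzero movement (previous preferred) so the trajectory
    stream stays active while the muscles relax.
    """
    spans: list[tuple[int, int, int]] = []
    i = 0
    n = len(stage_intervals)
    while i < n:
        s, e = stage_intervals[i]
        m = movements[i]
        j = i
        while j + 1 < n and movements[j + 1] == m and m != 0:
            j += 1
            e = stage_intervals[j][1]
        spans.append((s, e, m))
        i = j + 1
    # bridge gaps between spans
    bridged: list[tuple[int, int, int]] = []
    for k, (s, e, m) in enumerate(spans):
        s2, e2 = s, e
        if k > 0:
            prev_end = spans[k - 1][1]
            if spans[k - 1][2] == 0 and m != 0:
                s2 = prev_end  # cover the gap with this span's template
        if k + 1 < len(spans):
            next_start = spans[k + 1][0]
            if m != 0:
                e2 = next_start  # extend through the gap
        bridged.append((s2, e2, m))
    return bridged


def synthesize_word(
    entry: LexiconEntry,
    profiles: GestureProfileSet,
    templates: TrajectoryTemplateSet,
    cfg: SynthConfig,
    seed: int,
) -> tuple[Recording, GroundTruth]:
    """One seeded recording of one word, with sample-exact ground truth."""
    rng = np.random.default_rng(seed)
    fs = cfg.fs
    n_stages = len(entry.stages)

    dur = cfg.word_duration * (1 + rng.uniform(-1, 1) * cfg.duration_jitter)
    pad0 = cfg.rest_pad * (1 + rng.uniform(-1, 1) * cfg.pad_jitter)
    gap = int(round(cfg.relaxation_gap * fs))
    ramp = int(round(cfg.ramp * fs))
    stage_len = int(round((dur * fs - (n_stages - 1) * gap) / n_stages))
    if stage_len < int(0.2 * fs):
        raise GenerationError(
            f"word {entry.word_id}: {n_stages} stages do not fit in "
            f"{cfg.word_duration}s"
        )
    start = int(round(pad0 * fs))
    stage_intervals = []
    pos = start
    for _ in range(n_stages):
        stage_intervals.append((pos, pos + stage_len))
        pos += stage_len + gap
    seg_end = stage_intervals[-1][1]
    n = seg_end + int(round(cfg.rest_pad * fs))

    # sEMG: noise with per-sample SD = baseline + stage profile excess
    sd = np.full((4, n), profiles.baseline_sd)
    for k, ((s, e), st) in enumerate(zip(stage_intervals, entry.stages)):
        lev = profiles.levels[st.gesture - 1]  # gesture indices are 1-based
        atten = 1.0 if k == 0 else rng.uniform(*cfg.stage_attenuation)
        env = _ramped_envelope(n, s, e, ramp)
        sd += atten * (lev[:, None] - profiles.baseline_sd) * env[None, :]
    semg = rng.standard_normal((4, n)) * sd

    # trajectory: per-span template + noise
    motion = rng.standard_normal((6, n)) * templates.noise_sd
    movements = [st.movement for st in entry.stages]
    for s, e, m in _trajectory_spans(stage_intervals, movements):
        if m == 0:
            continue
        motion[:, s:e] += _resample_template(templates.templates[m], e - s)

    rec = Recording(semg=semg, acc=motion[:3], av=motion[3:], fs=fs)
    gt = GroundTruth(
        word_id=entry.word_id,
        category=entry.category,
        segment=(start, seg_end),
        stage_intervals=stage_intervals,
        stage_states=[(st.gesture, st.movement) for st in entry.stages],
    )
    return rec, gt


def synthesize_rest(
    duration: float,
    cfg: SynthConfig,
    seed: int,
    baseline_sd: float = 1.0,
    motion_noise_sd: float = 0.3,
) -> Recording:
    """A pure-rest recording, used for threshold calibration."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * cfg.fs))
    semg = rng.standard_normal((4, n)) * baseline_sd
    motion = rng.standard_normal((6, n)) * motion_noise_sd
    return Recording(semg=semg, acc=motion[:3], av=motion[3:], fs=cfg.fs)


def recording_seed(base_seed: int, subject: int, word_id: int) -> int:
    """Stable per-(subject, word) sub-seed."""
    ss = np.random.SeedSequence([base_seed, subject, word_id])
    return int(ss.generate_state(1)[0])


def subject_gains(base_seed: int, subject: int, sd: float = 0.1) -> np.ndarray:
    """Per-subject multiplicative channel gains (lognormal, seeded)."""
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, subject, 10**9]))
    return np.exp(rng.normal(0.0, sd, size=10))


@dataclass
class SynthDataset:
    manifest: pd.DataFrame  # subject, word_id, category, split
    recordings: list[Recording]
    ground_truths: list[GroundTruth]
    profiles: GestureProfileSet
    templates: TrajectoryTemplateSet


def synthesize_dataset(
    lex: Lexicon,
    n_subjects: int,
    cfg: SynthConfig,
    seed: int,
    separation: float = 3.0,
) -> SynthDataset:
    """One recording per (subject, word); even subjects train, odd test.

    Subject indices are 0-based, so a lone subject lands in the train
    split; with an even number of subjects the split is exactly half
    train / half test, stratified by word.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    profiles = make_gesture_profiles(
        lex.n_gestures, seed=recording_seed(seed, 0, 0), separation=separation
    )
    templates = make_trajectory_templates(
        lex.n_movement_states, n_t=2000, seed=recording_seed(seed, 1, 0)
    )
    rows = []
    recs: list[Recording] = []
    gts: list[GroundTruth] = []
    for subject in range(n_subjects):
        gains = subject_gains(seed, subject)
        for entry in lex.entries:
            rec, gt = synthesize_word(
                entry, profiles, templates, cfg,
                seed=recording_seed(seed, subject, entry.word_id),
            )
            rec.semg *= gains[:4, None]
            rec.acc *= gains[4:7, None]
            rec.av *= gains[7:, None]
            recs.append(rec)
            gts.append(gt)
            rows.append(
                {
                    "subject": subject,
                    "word_id": entry.word_id,
                    "category": entry.category,
                    "split": "train" if subject % 2 == 0 else "test",
                }
            )
    manifest = pd.DataFrame(rows)
    return SynthDataset(
        manifest=manifest,
        recordings=recs,
        ground_truths=gts,
        profiles=profiles,
        templates=templates,
    )
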