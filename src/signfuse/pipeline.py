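"""End-to-end orchestration: simulate -> segment -> featurize -> train ->
classify -> per-category accuracy report."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import chmm, segmentation
from .chmm import CoupledHMM, EmissionModel, TrainReport
from .features import FeatureConfig, ObservationPair, build_observation_pair, stage_span_samples
from .lexicon import CATEGORIES, CompositeState, Lexicon
from .segmentation import SegmenterConfig, calibrate_thresholds, segment_recording
from .synthgen import Recording, SynthConfig, SynthDataset, synthesize_dataset

log = logging.getLogger("signfuse")

RECORDING_COLUMNS = [
    "t",
    "semg1", "semg2", "semg3", "semg4",
    "accx", "accy", "accz",
    "avx", "avy", "avz",
]

#: Leading samples of every recording assumed to be rest (for threshold
#: calibration); safely below the minimum jittered leading pad.
CALIBRATION_LEAD = 350


class FormatError(ValueError):
    pass


class RunError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Recording file I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """CSV with a ``# fs=...`` header line; 17-significant-digit floats."""
    n = rec.n_samples
    t = np.arange(n) / rec.fs
    data = np.column_stack([t, rec.semg.T, rec.acc.T, rec.av.T])
    with open(path, "w", encoding="utf-8") as fh:
        fs = rec.fs
        fh.write(f"# fs={fs:.17g}\n")
        fh.write(",".join(RECORDING_COLUMNS) + "\n")
        np.savetxt(fh, data, fmt="%.17g", delimiter=",")


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise FormatError(f"{path}: missing '# fs=' header line")
        try:
            fs = float(header.split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable fs in header") from exc
        df = pd.read_csv(fh, float_precision="round_trip")
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in RECORDING_COLUMNS]
    if extra:
        raise FormatError(f"{path}: unexpected columns {extra}")
    t = df["t"].to_numpy()
    if len(t) > 1 and not (np.diff(t) > 0).all():
        raise FormatError(f"{path}: non-monotone time column")
    return Recording(
        semg=df[["semg1", "semg2", "semg3", "semg4"]].to_numpy().T,
        acc=df[["accx", "accy", "accz"]].to_numpy().T,
        av=df[["avx", "avy", "avz"]].to_numpy().T,
        fs=fs,
    )


def read_recording_xlsx(path: str | Path, sheet: int | str = 0, fs: float = 1000.0) -> Recording:
    """Adapter for spreadsheet-stored recordings with the same column names."""
    df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    missing = [c for c in RECORDING_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return Recording(
        semg=df[["semg1", "semg2", "semg3", "semg4"]].to_numpy(float).T,
        acc=df[["accx", "accy", "accz"]].to_numpy(float).T,
        av=df[["avx", "avy", "avz"]].to_numpy(float).T,
        fs=fs,
    )


def write_ground_truth(gt, path: str | Path) -> None:
    doc = {
        "word_id": gt.word_id,
        "category": gt.category,
        "segment": list(gt.segment),
        "stage_intervals": [list(iv) for iv in gt.stage_intervals],
        "stage_states": [list(s) for s in gt.stage_states],
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


# ---------------------------------------------------------------------------
# Threshold calibration from pooled leading rest
# ---------------------------------------------------------------------------

def calibrate_from_recordings(
    recordings: list[Recording],
    cfg: SegmenterConfig,
    k_sigma: float = 4.5,
    n_lead: int = CALIBRATION_LEAD,
    max_recordings: int = 40,
) -> tuple[float, float]:
    """Thresholds from the pooled leading-rest portions of recordings.

    The sample is spread evenly across the list so per-subject gain
    differences are represented in the pooled rest statistics.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    stride = max(1, len(recordings) // max_recordings)
    sample = recordings[::stride][:max_recordings]
    semg = np.hstack([r.semg[:, :n_lead] for r in sample])
    acc = np.hstack([r.acc[:, :n_lead] for r in sample])
    return calibrate_thresholds(semg, acc, k_sigma, cfg.window_len, cfg.step)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def build_warm_start_model(
    lex: Lexicon,
    labelled_sequences: list[tuple[list[ObservationPair], list[CompositeState]]],
    smoothing: float = 1e-3,
) -> CoupledHMM:
    """Supervised parameter estimate from lexicon-labelled stage data.

    Each item pairs one recording's per-stage observations with its
    lexicon stage states.  Emissions pool all frames labelled with each
    chain state; initial vectors count first-stage states; transition
    tensors count within-stage dwells and stage switches, with additive
    smoothing so unseen rows stay proper distributions.
    """
    N1, N2 = lex.n_gestures, lex.n_movement_states
    if not labelled_sequences:
        raise ValueError("no labelled sequences")
    d1 = labelled_sequences[0][0][0].gesture.shape[1]
    d2 = labelled_sequences[0][0][0].trajectory.shape[1]
    sums1 = np.zeros((N1, d1)); sq1 = np.zeros((N1, d1)); n1 = np.zeros(N1)
    sums2 = np.zeros((N2, d2)); sq2 = np.zeros((N2, d2)); n2 = np.zeros(N2)
    pi_counts = [np.full(N1, smoothing), np.full(N2, smoothing)]
    A_counts = [
        np.full((N1, N2, N1), smoothing),
        np.full((N1, N2, N2), smoothing),
    ]
    for stage_obs, states in labelled_sequences:
        if len(stage_obs) != len(states):
            raise ValueError("stage/label count mismatch")
        pi_counts[0][states[0].gesture - 1] += 1
        pi_counts[1][states[0].movement] += 1
        for k, (obs, st) in enumerate(zip(stage_obs, states)):
            g, mv = st.gesture - 1, st.movement
            o1 = np.asarray(obs.gesture, float)
            o2 = np.asarray(obs.trajectory, float)
            sums1[g] += o1.sum(axis=0); sq1[g] += (o1**2).sum(axis=0)
            n1[g] += len(o1)
            sums2[mv] += o2.sum(axis=0); sq2[mv] += (o2**2).sum(axis=0)
            n2[mv] += len(o2)
            T_obs = len(obs)
            A_counts[0][g, mv, g] += T_obs - 1
            A_counts[1][g, mv, mv] += T_obs - 1
            if k + 1 < len(states):
                nxt = states[k + 1]
                A_counts[0][g, mv, nxt.gesture - 1] += 1
                A_counts[1][g, mv, nxt.movement] += 1
    mu1 = np.zeros((N1, d1)); var1 = np.ones((N1, d1))
    mu2 = np.zeros((N2, d2)); var2 = np.ones((N2, d2))
    seen1 = n1 > 0
    mu1[seen1] = sums1[seen1] / n1[seen1, None]
    var1[seen1] = np.maximum(sq1[seen1] / n1[seen1, None] - mu1[seen1] ** 2, chmm.VAR_FLOOR)
    seen2 = n2 > 0
    mu2[seen2] = sums2[seen2] / n2[seen2, None]
    var2[seen2] = np.maximum(sq2[seen2] / n2[seen2, None] - mu2[seen2] ** 2, chmm.VAR_FLOOR)
    return CoupledHMM(
        n1=N1,
        n2=N2,
        initial=[p / p.sum() for p in pi_counts],
        transitions=[A / A.sum(axis=2, keepdims=True) for A in A_counts],
        emissions=EmissionModel(means=[mu1, mu2], vars=[var1, var2]),
    )


def _extract_stage_obs(
    rec: Recording,
    seg_cfg: SegmenterConfig,
    feat_cfg: FeatureConfig,
) -> list[ObservationPair] | None:
    """Segment a recording and featurize each detected stage.

    Returns None if no segment is found; if several segments survive,
    the longest is used.
    """
    segs = segment_recording(rec.semg, rec.acc, seg_cfg)
    if not segs:
        return None
    seg = max(segs, key=lambda s: s.end - s.start)
    out = []
    for bound in seg.stage_bounds:
        span = stage_span_samples(bound, feat_cfg.window_len, feat_cfg.step)
        span = (max(span[0], 0), min(span[1], rec.n_samples))
        out.append(build_observation_pair(rec, span, feat_cfg))
    return out


@dataclass
class TrainedModel:
    model: CoupledHMM
    report: TrainReport
    n_used: int
    n_skipped: int
    thresholds: tuple[float, float]


def train_on_dataset(
    lex: Lexicon,
    dataset: SynthDataset,
    seg_cfg: SegmenterConfig | None = None,
    feat_cfg: FeatureConfig | None = None,
    max_iter: int = 3,
    tol: float = 1e-4,
    max_skip_fraction: float = 0.10,
) -> TrainedModel:
    """Segment + featurize the train split, warm-start, then EM-train."""
    seg_cfg = seg_cfg or SegmenterConfig()
    feat_cfg = feat_cfg or FeatureConfig()
    train_idx = dataset.manifest.index[dataset.manifest["split"] == "train"]
    if len(train_idx) == 0:
        raise RunError("manifest has no train split")
    t_semg, t_acc = calibrate_from_recordings(
        [dataset.recordings[i] for i in train_idx], seg_cfg
    )
    seg_cfg.t_semg, seg_cfg.t_acc = t_semg, t_acc
    labelled = []
    all_obs: list[ObservationPair] = []
    n_skipped = 0
    for i in train_idx:
        rec = dataset.recordings[i]
        entry = lex.entry(int(dataset.manifest.loc[i, "word_id"]))
        stage_obs = _extract_stage_obs(rec, seg_cfg, feat_cfg)
        if stage_obs is None or len(stage_obs) != len(entry.stages):
            got = 0 if stage_obs is None else len(stage_obs)
            log.info(
                "skip train recording subject=%s word=%s: %d stages, expected %d",
                dataset.manifest.loc[i, "subject"], entry.word_id, got, len(entry.stages),
            )
            n_skipped += 1
            continue
        labelled.append((stage_obs, entry.stages))
        all_obs.extend(stage_obs)
    if n_skipped > max_skip_fraction * len(train_idx):
        raise RunError(
            f"{n_skipped}/{len(train_idx)} training recordings skipped "
            f"(> {max_skip_fraction:.0%})"
        )
    init = build_warm_start_model(lex, labelled)
    model, report = chmm.em_fit(init, all_obs, max_iter=max_iter, tol=tol)
    return TrainedModel(
        model=model,
        report=report,
        n_used=len(labelled),
        n_skipped=n_skipped,
        thresholds=(t_semg, t_acc),
    )


# ---------------------------------------------------------------------------
# Evaluation and reporting
# ---------------------------------------------------------------------------

def _pct_floor(num: int, den: int) -> float:
    """Percentage truncated (not rounded) to two decimals, as printed in
    the reference results table (80/92 -> 86.95, 434/480 -> 90.41)."""
    if den == 0:
        return 0.0
    return math.floor(Fraction(num, den) * 10000) / 100.0


@dataclass
class EvaluationReport:
    rows: list[dict]          # per category: category, n_words, n_test, n_correct, accuracy_pct
    total: dict               # same keys, category="Total(average)"
    confusion: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def micro_average_pct(self) -> float:
        return self.total["accuracy_pct"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows + [self.total])

    def to_json_dict(self) -> dict:
        return {
            "rows": self.rows,
            "total": self.total,
            "confusion": [
                {"true": t, "pred": p, "count": c}
                for (t, p), c in sorted(self.confusion.items())
            ],
        }


def accuracy_report(
    correct: dict[str, int],
    totals: dict[str, int],
    n_words: dict[str, int] | None = None,
    confusion: dict[tuple[int, int], int] | None = None,
) -> EvaluationReport:
    """Per-category accuracies plus the micro-averaged total row.

    The overall accuracy is total-correct over total-samples (micro),
    not the mean of the category accuracies.
    """
    rows = []
    for cat in CATEGORIES:
        c = int(correct.get(cat, 0))
        t = int(totals.get(cat, 0))
        if c > t:
            raise ValueError(f"{cat}: correct {c} > total {t}")
        rows.append(
            {
                "category": cat,
                "n_words": int(n_words.get(cat, 0)) if n_words else 0,
                "n_test": t,
                "n_correct": c,
                "accuracy_pct": _pct_floor(c, t),
            }
        )
    tc = sum(r["n_correct"] for r in rows)
    tt = sum(r["n_test"] for r in rows)
    total = {
        "category": "Total(average)",
        "n_words": sum(r["n_words"] for r in rows),
        "n_test": tt,
        "n_correct": tc,
        "accuracy_pct": _pct_floor(tc, tt),
    }
    return EvaluationReport(rows=rows, total=total, confusion=confusion or {})


def evaluate_on_dataset(
    lex: Lexicon,
    dataset: SynthDataset,
    trained: TrainedModel,
    seg_cfg: SegmenterConfig | None = None,
    feat_cfg: FeatureConfig | None = None,
    use_category: bool = True,
) -> EvaluationReport:
    """Classify every test recording and tally per-category accuracy.

    ``use_category`` restricts candidates to the recording's vocabulary
    category (one decomposition status table per category); recordings
    yielding no segment count as errors.
    """
    seg_cfg = seg_cfg or SegmenterConfig()
    feat_cfg = feat_cfg or FeatureConfig()
    seg_cfg.t_semg, seg_cfg.t_acc = trained.thresholds
    test_idx = dataset.manifest.index[dataset.manifest["split"] == "test"]
    if len(test_idx) == 0:
        raise RunError("manifest has no test split")
    correct = {c: 0 for c in CATEGORIES}
    totals = {c: 0 for c in CATEGORIES}
    confusion: dict[tuple[int, int], int] = {}
    for i in test_idx:
        rec = dataset.recordings[i]
        true_id = int(dataset.manifest.loc[i, "word_id"])
        cat = str(dataset.manifest.loc[i, "category"])
        totals[cat] += 1
        stage_obs = _extract_stage_obs(rec, seg_cfg, feat_cfg)
        if stage_obs is None:
            log.info("no segment for test recording word=%s", true_id)
            confusion[(true_id, -1)] = confusion.get((true_id, -1), 0) + 1
            continue
        try:
            pred, _ = chmm.classify_word(
                trained.model, stage_obs, lex,
                category=cat if use_category else None,
            )
        except LookupError:
            confusion[(true_id, -1)] = confusion.get((true_id, -1), 0) + 1
            continue
        confusion[(true_id, pred)] = confusion.get((true_id, pred), 0) + 1
        if pred == true_id:
            correct[cat] += 1
    from .lexicon import category_counts

    n_words = category_counts(lex)
    return accuracy_report(correct, totals, n_words, confusion)


def run_experiment(
    lex: Lexicon,
    n_subjects: int = 8,
    seed: int = 0,
    synth_cfg: SynthConfig | None = None,
    seg_cfg: SegmenterConfig | None = None,
    feat_cfg: FeatureConfig | None = None,
    max_iter: int = 3,
    tol: float = 1e-4,
) -> tuple[EvaluationReport, TrainedModel, SynthDataset]:
    """Simulate, train and evaluate in memory; fully seeded."""
    synth_cfg = synth_cfg or SynthConfig()
    dataset = synthesize_dataset(lex, n_subjects, synth_cfg, seed)
    trained = train_on_dataset(lex, dataset, seg_cfg, feat_cfg, max_iter=max_iter, tol=tol)
    report = evaluate_on_dataset(lex, dataset, trained, seg_cfg, feat_cfg)
    return report, trained, dataset
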