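"""Vocabulary decomposition data model.

A sign-language word is an ordered list of *stages*; each stage is a
composite ``(gesture, movement)`` state.  Gesture states are indexed
``1..G``; movement states are indexed ``0..M-1`` where ``0`` is the rest
(no-trajectory) state.  Words fall into three categories:

``SHGV``
    single-hand gesture vocabulary — exactly one stage.
``DHGV``
    double-hand gesture vocabulary — exactly one stage.
``DGV``
    dynamic gesture vocabulary — two or more stages (the gesture changes
    mid-word, with a brief muscle relaxation at each switch).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

CATEGORIES = ("SHGV", "DHGV", "DGV")


class LexiconError(ValueError):
    """Raised for malformed or invariant-violating lexicon data."""


@dataclass(frozen=True, order=True)
class CompositeState:
    """A (gesture, movement) pair; one stage of a word."""

    gesture: int
    movement: int

    def validate(self, n_gestures: int, n_movement_states: int) -> list[str]:
        problems = []
        if not 1 <= self.gesture <= n_gestures:
            problems.append(
                f"gesture index {self.gesture} outside 1..{n_gestures}"
            )
        if not 0 <= self.movement < n_movement_states:
            problems.append(
                f"movement index {self.movement} outside 0..{n_movement_states - 1}"
            )
        return problems


@dataclass
class LexiconEntry:
    word_id: int
    label: str
    category: str
    stages: list[CompositeState]
    provenance: str | None = None

    def validate(self, n_gestures: int, n_movement_states: int) -> list[str]:
        problems = []
        if self.word_id < 1:
            problems.append(f"word_id {self.word_id} must be >= 1")
        if self.category not in CATEGORIES:
            problems.append(
                f"word {self.word_id}: unknown category {self.category!r}"
            )
        if not self.stages:
            problems.append(f"word {self.word_id}: no stages")
        if self.category in ("SHGV", "DHGV") and len(self.stages) != 1:
            problems.append(
                f"word {self.word_id}: {self.category} requires exactly 1 stage, "
                f"got {len(self.stages)}"
            )
        if self.category == "DGV" and len(self.stages) < 2:
            problems.append(
                f"word {self.word_id}: DGV requires >= 2 stages, got {len(self.stages)}"
            )
        for k, s in enumerate(self.stages):
            for p in s.validate(n_gestures, n_movement_states):
                problems.append(f"word {self.word_id} stage {k}: {p}")
        return problems


@dataclass
class Lexicon:
    entries: list[LexiconEntry]
    n_gestures: int
    n_movement_states: int  # including rest state 0

    def validate(self) -> list[str]:
        problems = []
        if not self.entries:
            problems.append("lexicon has no entries")
        seen: set[int] = set()
        for e in self.entries:
            if e.word_id in seen:
                problems.append(f"duplicate word_id {e.word_id}")
            seen.add(e.word_id)
            problems.extend(e.validate(self.n_gestures, self.n_movement_states))
        return problems

    def entry(self, word_id: int) -> LexiconEntry:
        for e in self.entries:
            if e.word_id == word_id:
                return e
        raise KeyError(word_id)

    def __len__(self) -> int:
        return len(self.entries)


def composite_state_count(n_gestures: int, n_movement_states: int) -> int:
    """Number of composite states formed by two chains of the given sizes."""
    if n_gestures < 1 or n_movement_states < 1:
        raise ValueError(
            "state counts must be >= 1, got "
            f"({n_gestures}, {n_movement_states})"
        )
    return n_gestures * n_movement_states


def words_for_state(
    lex: Lexicon, s: CompositeState, stage_index: int
) -> list[tuple[int, str]]:
    """All (word_id, label) whose stage ``stage_index`` equals ``s``.

    Returns entries ordered by word_id; an empty list is a valid result.
    """
    if stage_index < 0:
        raise ValueError("stage_index must be >= 0")
    out = [
        (e.word_id, e.label)
        for e in lex.entries
        if stage_index < len(e.stages) and e.stages[stage_index] == s
    ]
    out.sort(key=lambda t: t[0])
    return out


def category_counts(lex: Lexicon) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for e in lex.entries:
        counts[e.category] = counts.get(e.category, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

def _entry_to_dict(e: LexiconEntry) -> dict:
    d = {
        "word_id": e.word_id,
        "label": e.label,
        "category": e.category,
        "stages": [[s.gesture, s.movement] for s in e.stages],
    }
    if e.provenance is not None:
        d["provenance"] = e.provenance
    return d


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    doc = {
        "n_gestures": lex.n_gestures,
        "n_movement_states": lex.n_movement_states,
        "entries": [_entry_to_dict(e) for e in lex.entries],
    }
    Path(path).write_text(
        json.dumps(doc, ensure_ascii=False, indent=1) + "\n", encoding="utf-8"
    )


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon JSON file.

    Raises :class:`LexiconError` on parse failure or with the full list of
    invariant violations if any entry is invalid.
    """
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise LexiconError(f"cannot parse lexicon file {path}: {exc}") from exc
    try:
        entries = [
            LexiconEntry(
                word_id=int(d["word_id"]),
                label=str(d["label"]),
                category=str(d["category"]),
                stages=[CompositeState(int(g), int(m)) for g, m in d["stages"]],
                provenance=d.get("provenance"),
            )
            for d in doc["entries"]
        ]
        lex = Lexicon(
            entries=entries,
            n_gestures=int(doc["n_gestures"]),
            n_movement_states=int(doc["n_movement_states"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise LexiconError(f"malformed lexicon file {path}: {exc}") from exc
    problems = lex.validate()
    if problems:
        raise LexiconError(
            "invalid lexicon: " + "; ".join(problems)
        )
    return lex


def default_lexicon_path() -> Path:
    return Path(__file__).parent / "data" / "lexicon_120.json"


def load_default_lexicon() -> Lexicon:
    """The packaged 120-word fixture (45 SHGV + 52 DHGV + 23 DGV)."""
    return load_lexicon(default_lexicon_path())
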