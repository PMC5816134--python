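"""Core containers shared across the analysis pipeline.

Each container enforces the invariants the downstream analyses rely on:
distance matrices are symmetric, nonnegative, zero-diagonal; naming trials
carry ordinal certainty codes in {1, 2, 3}; triad trials consist of three
distinct stimuli with a chosen pair drawn from them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LAYOUTS = ("sound_left", "sound_right")

#: The nine contextual-emotional categories of the stimulus corpus.
CONTEXT_CATEGORIES = (
    "amusement", "anger", "disgust", "effort", "fear",
    "joy", "pain", "pleasure", "sadness",
)


class ValidationError(ValueError):
    """Raised when input data violates a documented contract."""


@dataclass(frozen=True)
class NamingTrial:
    """One participant x stimulus naming event.

    ``sound_names`` / ``emotion_names`` are ordered tuples; by convention the
    first element is the primary (first-chosen) label.  Certainty codes:
    1 = "Don't know", 2 = "Unsure", 3 = "Sure".  Latencies are seconds from
    sound onset to the first click of each kind; ``None`` marks an
    unanswered block.
    """

    participant: str
    language: str
    stimulus: str
    sound_names: tuple[str, ...]
    emotion_names: tuple[str, ...]
    certainty_sound: int | None
    certainty_emotion: int | None
    t_first_sound: float | None
    t_first_emotion: float | None
    t_next: float
    layout: str

    def __post_init__(self):
        for c in (self.certainty_sound, self.certainty_emotion):
            if c is not None and c not in (1, 2, 3):
                raise ValidationError(f"certainty must be 1, 2 or 3; got {c!r}")
        for t in (self.t_first_sound, self.t_first_emotion, self.t_next):
            if t is not None and not (t > 0):
                raise ValidationError(f"latencies must be positive; got {t!r}")
        if self.layout not in LAYOUTS:
            raise ValidationError(f"layout must be one of {LAYOUTS}; got {self.layout!r}")


@dataclass(frozen=True)
class TriadTrial:
    """A triad similarity judgment: three stimuli, one chosen pair."""

    participant: str
    items: tuple[str, str, str]
    chosen_pair: frozenset

    def __post_init__(self):
        if len(set(self.items)) != 3:
            raise ValidationError(f"triad items must be distinct; got {self.items}")
        pair = frozenset(self.chosen_pair)
        if len(pair) != 2 or not pair <= set(self.items):
            raise ValidationError(
                f"chosen_pair must be two of the triad items; got {self.chosen_pair}"
            )
        object.__setattr__(self, "chosen_pair", pair)


class DistanceMatrix:
    """Symmetric nonnegative stimulus x stimulus dissimilarities, zero diagonal."""

    def __init__(self, stimuli: Sequence[str], values: np.ndarray, *, tol: float = 1e-8):
        stimuli = tuple(str(s) for s in stimuli)
        values = np.asarray(values, dtype=float)
        n = len(stimuli)
        if len(set(stimuli)) != n:
            raise ValidationError("stimulus ids must be unique")
        if values.shape != (n, n):
            raise ValidationError(f"values must be {n}x{n}; got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("distances must be finite")
        if np.abs(values - values.T).max(initial=0.0) > tol:
            raise ValidationError("distance matrix must be symmetric")
        if np.abs(np.diag(values)).max(initial=0.0) > tol:
            raise ValidationError("distance matrix diagonal must be zero")
        if values.min(initial=0.0) < -tol:
            raise ValidationError("distances must be nonnegative")
        values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(values, 0.0)
        self.stimuli = stimuli
        self.values = values

    @property
    def n(self) -> int:
        return len(self.stimuli)

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle entries in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.stimuli), columns=list(self.stimuli))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="stimulus")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValidationError("distance CSV must have matching row/column ids")
        return cls(df.index.astype(str), df.to_numpy(dtype=float))

    def reorder(self, stimuli: Sequence[str]) -> "DistanceMatrix":
        idx = [self.stimuli.index(str(s)) for s in stimuli]
        return DistanceMatrix([self.stimuli[i] for i in idx], self.values[np.ix_(idx, idx)])

    def __repr__(self):
        return f"DistanceMatrix(n={self.n})"


@dataclass
class AcousticFeatureTable:
    """Stimulus x feature matrix of precomputed acoustic measurements."""

    stimuli: tuple[str, ...]
    features: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.stimuli = tuple(str(s) for s in self.stimuli)
        self.features = tuple(str(f) for f in self.features)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.features)) != len(self.features):
            raise ValidationError("feature names must be unique")
        if self.values.shape != (len(self.stimuli), len(self.features)):
            raise ValidationError("values shape must be (n_stimuli, n_features)")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("acoustic features must be finite (no missing values)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.stimuli), columns=list(self.features))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="stimulus")

    @classmethod
    def from_csv(cls, path) -> "AcousticFeatureTable":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.index.astype(str)), tuple(df.columns), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# CSV round-trips for trial tables
# ---------------------------------------------------------------------------

_SEP = ";"


def naming_trials_to_frame(trials: Iterable[NamingTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append({
            "participant": t.participant,
            "language": t.language,
            "stimulus": t.stimulus,
            "sound_names": _SEP.join(t.sound_names),
            "emotion_names": _SEP.join(t.emotion_names),
            "certainty_sound": t.certainty_sound,
            "certainty_emotion": t.certainty_emotion,
            "t_first_sound": t.t_first_sound,
            "t_first_emotion": t.t_first_emotion,
            "t_next": t.t_next,
            "layout": t.layout,
        })
    return pd.DataFrame(rows)


def naming_trials_from_frame(df: pd.DataFrame) -> list[NamingTrial]:
    def _labels(x):
        if pd.isna(x) or x == "":
            return ()
        return tuple(str(x).split(_SEP))

    def _num(x):
        return None if pd.isna(x) else float(x)

    def _cert(x):
        return None if pd.isna(x) else int(x)

    trials = []
    for row in df.itertuples(index=False):
        trials.append(NamingTrial(
            participant=str(row.participant),
            language=str(row.language),
            stimulus=str(row.stimulus),
            sound_names=_labels(row.sound_names),
            emotion_names=_labels(row.emotion_names),
            certainty_sound=_cert(row.certainty_sound),
            certainty_emotion=_cert(row.certainty_emotion),
            t_first_sound=_num(row.t_first_sound),
            t_first_emotion=_num(row.t_first_emotion),
            t_next=float(row.t_next),
            layout=str(row.layout),
        ))
    return trials


def triad_trials_to_frame(trials: Iterable[TriadTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        chosen = sorted(t.chosen_pair)
        rows.append({
            "participant": t.participant,
            "item1": t.items[0], "item2": t.items[1], "item3": t.items[2],
            "chosen1": chosen[0], "chosen2": chosen[1],
        })
    return pd.DataFrame(rows)


def triad_trials_from_frame(df: pd.DataFrame) -> list[TriadTrial]:
    return [
        TriadTrial(
            participant=str(r.participant),
            items=(str(r.item1), str(r.item2), str(r.item3)),
            chosen_pair=frozenset((str(r.chosen1), str(r.chosen2))),
        )
        for r in df.itertuples(index=False)
    ]
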