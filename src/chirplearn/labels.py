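"""Class vocabulary, weak recording-level annotations, and target vectors.

Annotations carry one primary species, zero or more secondary (background)
species, and no timing. The vocabulary always contains a dedicated noise
class for "no birds present" clips; it is treated as a regular output class,
mutually exclusive with species labels within a single target.

Annotation CSV dialect: columns ``recording_id, primary_species,
secondary_species, split`` with secondary species semicolon-joined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NOISE_CLASS",
    "ClassVocabulary",
    "RecordingAnnotation",
    "build_target",
    "curate_species",
    "data_regime",
    "read_annotations",
    "write_annotations",
]

NOISE_CLASS = "noise"


@dataclass(frozen=True)
class ClassVocabulary:
    """Ordered species codes plus the dedicated noise class.

    The ordering is part of the model contract: logit index i corresponds to
    ``classes[i]`` in every checkpoint and prediction table.
    """

    classes: tuple[str, ...]

    def __post_init__(self):
        classes = tuple(self.classes)
        if len(set(classes)) != len(classes):
            raise ValueError("duplicate class codes in vocabulary")
        if classes.count(NOISE_CLASS) != 1:
            raise ValueError(f"vocabulary must contain exactly one {NOISE_CLASS!r} class")
        object.__setattr__(self, "classes", classes)

    @classmethod
    def from_species(cls, species_ids: list[str]) -> "ClassVocabulary":
        return cls(tuple(species_ids) + (NOISE_CLASS,))

    @property
    def noise_class_index(self) -> int:
        return self.classes.index(NOISE_CLASS)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(c for c in self.classes if c != NOISE_CLASS)

    def index(self, code: str) -> int:
        try:
            return self.classes.index(code)
        except ValueError:
            raise KeyError(f"unknown species code {code!r}") from None

    def __len__(self) -> int:
        return len(self.classes)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"classes": list(self.classes)}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassVocabulary":
        return cls(tuple(json.loads(Path(path).read_text())["classes"]))


@dataclass(frozen=True)
class RecordingAnnotation:
    """Weak label set for one recording: primary + optional secondaries."""

    recording_id: str
    primary_species: str
    secondary_species: tuple[str, ...] = ()
    source: str = ""

    def __post_init__(self):
        secondary = tuple(self.secondary_species)
        if self.primary_species in secondary:
            raise ValueError(
                f"primary species {self.primary_species!r} repeated in secondary")
        if len(set(secondary)) != len(secondary):
            raise ValueError("duplicate secondary species")
        object.__setattr__(self, "secondary_species", secondary)

    @property
    def all_species(self) -> tuple[str, ...]:
        return (self.primary_species,) + self.secondary_species


def build_target(annotation: RecordingAnnotation, vocab: ClassVocabulary,
                 use_secondary: bool, mode: str = "multi") -> np.ndarray:
    """Membership target vector for one annotation.

    single mode: one-hot on the primary species. multi mode: 1 at the
    primary and, iff ``use_secondary``, at each secondary species.
    Noise-only recordings are one-hot on the noise class in both modes.
    """
    if mode not in ("single", "multi"):
        raise ValueError(f"mode must be 'single' or 'multi', got {mode!r}")
    target = np.zeros(len(vocab))
    target[vocab.index(annotation.primary_species)] = 1.0
    if mode == "multi" and use_secondary:
        for code in annotation.secondary_species:
            target[vocab.index(code)] = 1.0
    return target


def curate_species(counts: dict[str, int] | pd.Series,
                   min_recordings: int = 10) -> list[str]:
    """Retain species with at least ``min_recordings`` recordings.

    Deterministic and order-preserving over the input table.
    """
    if isinstance(counts, pd.Series):
        items = list(counts.items())
    else:
        items = list(counts.items())
    for code, n in items:
        if n < 0:
            raise ValueError(f"negative recording count for {code!r}")
    return [code for code, n in items if n >= min_recordings]


def data_regime(count: int) -> str:
    """Stratify a per-species recording count: <50 low, 50-200 medium, >200 high."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if count < 50:
        return "low"
    if count <= 200:
        return "medium"
    return "high"


def write_annotations(path: str | Path, annotations: list[RecordingAnnotation],
                      splits: dict[str, str] | None = None) -> None:
    splits = splits or {}
    rows = [{
        "recording_id": a.recording_id,
        "primary_species": a.primary_species,
        "secondary_species": ";".join(a.secondary_species),
        "split": splits.get(a.recording_id, ""),
    } for a in annotations]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotations(path: str | Path) -> tuple[list[RecordingAnnotation], dict[str, str]]:
    df = pd.read_csv(path, keep_default_na=False)
    annotations, splits = [], {}
    for row in df.itertuples(index=False):
        secondary = tuple(s for s in str(row.secondary_species).split(";") if s)
        annotations.append(RecordingAnnotation(
            recording_id=str(row.recording_id),
            primary_species=str(row.primary_species),
            secondary_species=secondary,
        ))
        if getattr(row, "split", ""):
            splits[str(row.recording_id)] = str(row.split)
    return annotations, splits
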