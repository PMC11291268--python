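"""Onset-based clinical scoring for GNAO1 encephalopathy.

Disease onset (postnatal days) serves as the clinical score.  Onsets are
binned into four classes — very early (<10 d), early (10 d to <3 months),
late (3 months to <2 years) and very late (≥2 years) — with the month/year
boundaries taken as 90 and 730 days (round clinical conventions; both are
configurable because day equivalents are a choice, not a measurement).

A packaged dictionary maps each studied GNAO1 missense mutation to its
disorder (DEE17, the severe epileptic encephalopathy, or NEDIM, the milder
movement disorder), its onset class, and its biochemical activity status
(whether recombinant protein shows measurable nucleotide binding).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Disorder",
    "OnsetClass",
    "PatientRecord",
    "UnknownMutationError",
    "DEFAULT_BOUNDARIES",
    "classify_onset",
    "load_mutation_table",
    "disorder_of",
    "activity_of",
    "onset_class_of",
    "group_onset_summary",
]


class Disorder(str, enum.Enum):
    DEE17 = "DEE17"
    NEDIM = "NEDIM"


class OnsetClass(str, enum.Enum):
    VERY_EARLY = "very_early"
    EARLY = "early"
    LATE = "late"
    VERY_LATE = "very_late"


class UnknownMutationError(KeyError):
    """Mutation label absent from the packaged dictionary."""


#: (very_early|early, early|late, late|very_late) boundaries in days
DEFAULT_BOUNDARIES: tuple[int, int, int] = (10, 90, 730)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    mutation: str
    onset_days: int
    disorder: Disorder

    def __post_init__(self) -> None:
        if self.onset_days < 0:
            raise ValueError("onset_days must be >= 0")
        object.__setattr__(self, "disorder", Disorder(self.disorder))


def classify_onset(
    onset_days: int, boundaries: Sequence[int] = DEFAULT_BOUNDARIES
) -> OnsetClass:
    """Bin an onset into the four half-open classes.

    [0, b0) → very_early; [b0, b1) → early; [b1, b2) → late; [b2, ∞) →
    very_late, with default boundaries (10, 90, 730) days.
    """
    if onset_days < 0:
        raise ValueError(f"onset_days must be >= 0, got {onset_days}")
    b0, b1, b2 = boundaries
    if not 0 < b0 < b1 < b2:
        raise ValueError("boundaries must be strictly increasing and positive")
    if onset_days < b0:
        return OnsetClass.VERY_EARLY
    if onset_days < b1:
        return OnsetClass.EARLY
    if onset_days < b2:
        return OnsetClass.LATE
    return OnsetClass.VERY_LATE


def load_mutation_table() -> pd.DataFrame:
    """The packaged mutation dictionary, indexed by mutation label."""
    with resources.files("gnao1kit.data").joinpath("mutations.csv").open() as fh:
        table = pd.read_csv(fh)
    return table.set_index("mutation")


_TABLE: Optional[pd.DataFrame] = None


def _table() -> pd.DataFrame:
    global _TABLE
    if _TABLE is None:
        _TABLE = load_mutation_table()
    return _TABLE


def _lookup(mutation: str, column: str) -> str:
    table = _table()
    if mutation not in table.index:
        raise UnknownMutationError(
            f"unknown GNAO1 mutation {mutation!r}; known: {', '.join(table.index)}"
        )
    return str(table.loc[mutation, column])


def disorder_of(mutation: str) -> Disorder:
    """DEE17 or NEDIM for a known mutation; unknown labels raise."""
    return Disorder(_lookup(mutation, "disorder"))


def activity_of(mutation: str) -> str:
    """'active' or 'inactive' (measurable nucleotide binding or not)."""
    return _lookup(mutation, "activity")


def onset_class_of(mutation: str) -> OnsetClass:
    """The onset class assigned to a mutation in the dictionary."""
    return OnsetClass(_lookup(mutation, "onset_class"))


class Grouping(str, enum.Enum):
    BY_DISORDER = "by_disorder"
    BY_ACTIVITY = "by_activity"
    BY_MUTATION = "by_mutation"


def group_onset_summary(
    records: Iterable[PatientRecord],
    grouping: Grouping | str = Grouping.BY_DISORDER,
) -> pd.DataFrame:
    """Per-group patient count and median onset.

    Medians are taken over patients, not over per-mutation medians (cohort
    sizes differ per mutation); even-count medians are the mean of the
    central pair.  Grouping by activity uses the packaged dictionary;
    records with mutations absent from it are dropped with a warning.
    Returns a DataFrame with columns ``group``, ``n``,
    ``median_onset_days``.
    """
    records = list(records)
    if not records:
        raise ValueError("no patient records supplied")
    grouping = Grouping(grouping)
    rows = []
    for rec in records:
        if grouping is Grouping.BY_DISORDER:
            key = rec.disorder.value
        elif grouping is Grouping.BY_MUTATION:
            key = rec.mutation
        else:
            try:
                key = activity_of(rec.mutation)
            except UnknownMutationError:
                warnings.warn(
                    f"dropping patient {rec.patient_id}: mutation "
                    f"{rec.mutation!r} not in the dictionary",
                    stacklevel=2,
                )
                continue
        rows.append((key, rec.onset_days))
    if not rows:
        raise ValueError("no records left after dropping unknown mutations")
    frame = pd.DataFrame(rows, columns=["group", "onset_days"])
    out = (
        frame.groupby("group", sort=True)["onset_days"]
        .agg(n="size", median_onset_days="median")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
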