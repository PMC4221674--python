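"""The 2x2 factorial sample design (age x mating status).

Every pipeline stage is keyed on the same four physiological conditions:
young virgin, young mated, aged virgin and aged mated females.  A
:class:`SampleDesign` records one sample per (condition, replicate) cell
and fixes the column order that feature tables must follow.

Pairwise contrasts follow a fixed sign convention: within an age class the
difference is mated - virgin, and within a mating status it is aged - young.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

#: The four conditions, in canonical order.
CONDITIONS: tuple[str, ...] = (
    "young_virgin",
    "young_mated",
    "aged_virgin",
    "aged_mated",
)

#: Short condition codes used in sample ids and column names.
CONDITION_CODES: dict[str, str] = {
    "young_virgin": "YV",
    "young_mated": "YM",
    "aged_virgin": "AV",
    "aged_mated": "AM",
}

#: The four pairwise contrasts as (name, plus_condition, minus_condition).
#: Signs are mated - virgin within age, aged - young within mating status.
CONTRASTS: tuple[tuple[str, str, str], ...] = (
    ("young_mating", "young_mated", "young_virgin"),
    ("aged_mating", "aged_mated", "aged_virgin"),
    ("virgin_aging", "aged_virgin", "young_virgin"),
    ("mated_aging", "aged_mated", "young_mated"),
)

CONTRAST_NAMES: tuple[str, ...] = tuple(c[0] for c in CONTRASTS)


@dataclass(frozen=True)
class Sample:
    """One sequenced sample: a pool of females from one condition cell."""

    sample_id: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class SampleDesign:
    """Immutable layout of samples over the four conditions."""

    samples: tuple[Sample, ...]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def condition_labels(self) -> list[str]:
        return [s.condition for s in self.samples]

    @property
    def n_replicates(self) -> int:
        return len(self.samples) // len(CONDITIONS)

    def samples_in(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return [s.sample_id for s in self.samples if s.condition == condition]

    def condition_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.condition
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "condition": self.condition_labels,
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleDesign":
        samples = tuple(
            Sample(str(r.sample_id), str(r.condition), int(r.replicate))
            for r in frame.itertuples()
        )
        return cls(samples)

    @classmethod
    def read_tsv(cls, path) -> "SampleDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def make_design(n_replicates: int = 2) -> SampleDesign:
    """Build the 4 x n_replicates design.

    Two replicates per condition is the minimum for the permutation ANOVA
    (within-condition variance is undefined below that), hence
    ``n_replicates < 2`` raises.
    """
    if n_replicates < 2:
        raise ValueError(
            "at least 2 replicates per condition are required "
            "(permutation ANOVA needs within-condition variance)"
        )
    samples = tuple(
        Sample(f"{CONDITION_CODES[cond]}_{rep}", cond, rep)
        for cond in CONDITIONS
        for rep in range(1, n_replicates + 1)
    )
    return SampleDesign(samples)


def validate_columns(columns: Iterable[str], design: SampleDesign) -> None:
    """Raise if a feature table's columns do not match the design's samples."""
    cols = list(columns)
    if sorted(cols) != sorted(design.sample_ids):
        raise ValueError(
            f"table columns {cols} do not match design samples {design.sample_ids}"
        )
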