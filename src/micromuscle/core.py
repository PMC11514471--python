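"""Shared domain types for the micromuscle pipeline.

Coordinates are 0-based half-open internally; GFF3 I/O converts from the
1-based inclusive convention.  All sequences are held in the DNA alphabet
(U is converted to T on input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


class AnnotationError(ValueError):
    """Raised for inconsistent hairpin/mature annotations."""


class Locus(NamedTuple):
    """Genomic placement of a hairpin (start is 0-based)."""

    chrom: str
    strand: str
    start: int


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA arm on its hairpin (0-based, half-open)."""

    mature_id: str
    arm: str  # '5p', '3p' or 'unlabelled'
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"mature {self.mature_id}: degenerate interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class HairpinRecord:
    """Pre-miRNA hairpin: sequence, annotated mature arms, optional genomic locus."""

    hairpin_id: str
    sequence: str
    matures: list[MatureAnnotation] = field(default_factory=list)
    locus: Locus | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        for m in self.matures:
            if m.end > len(self.sequence):
                raise AnnotationError(
                    f"mature {m.mature_id} extends past hairpin {self.hairpin_id} "
                    f"(end {m.end} > length {len(self.sequence)})"
                )

    def mature(self, mature_id: str) -> MatureAnnotation:
        for m in self.matures:
            if m.mature_id == mature_id:
                return m
        raise KeyError(mature_id)


class AlignmentHit(NamedTuple):
    """Placement of a read on a hairpin; quant-mode hits have 0 mismatches.

    ``length`` is the read length; in isomiR mode ``offset + length`` may
    overhang the hairpin 3' end (overhanging bases count as mismatches).
    """

    hairpin_id: str
    offset: int
    length: int
    mismatches: int


@dataclass
class CountMatrix:
    """Raw counts (mature ids x sample ids) plus per-sample metadata.

    ``samples`` is indexed by sample id and carries at least a ``condition``
    column; time-course matrices also carry ``timepoint``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("duplicate feature ids in count matrix")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative entries in count matrix")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def condition(self, sample: str) -> str:
        return str(self.samples.loc[sample, "condition"])

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[sample_ids].copy(), self.samples.loc[sample_ids].copy())

    def to_tsv(self, counts_path, samples_path=None) -> None:
        self.counts.rename_axis("mature_id").to_csv(counts_path, sep="\t")
        if samples_path is not None:
            self.samples.rename_axis("sample").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype=str)
        return cls(counts, samples)


def timepoint_order(samples: pd.DataFrame) -> list[str]:
    """Ordered unique time points.

    Labels with a numeric suffix (P1, P5, P14, P90, day3, ...) sort by that
    number; otherwise the order of first appearance in the sample sheet is kept.
    """
    seen: list[str] = []
    for t in samples["timepoint"]:
        if t not in seen:
            seen.append(t)

    def _num(label):
        digits = "".join(c for c in str(label) if c.isdigit())
        return float(digits) if digits else None

    nums = [_num(t) for t in seen]
    if all(n is not None for n in nums) and len(set(nums)) == len(nums):
        return [t for _, t in sorted(zip(nums, seen))]
    return seen


def rng_for(seed: int, stage: int) -> np.random.Generator:
    """Independent generator per pipeline stage from one master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))
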