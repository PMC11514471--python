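"""Raw FASTQ -> collapsed, filtered read sets.

Two branches mirror the analysis design: ``quant`` (adapter clip, collapse,
10-35 nt window) feeds exact-match quantification; ``isomir`` (adapter clip,
whole-read quality filter, collapse, >= 12 nt) feeds mismatch-tolerant
end-modification calling.  Adapter matching is exact-prefix with a minimum
overlap; reads without an adapter are discarded, as are reads containing N
(exact-match mapping downstream cannot place them).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .core import ConfigurationError
from . import io as mio


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class PreprocessParams:
    """Filter settings; ``mode`` picks the branch defaults.

    quant: length window [10, 35] inclusive, no quality filter.
    isomir: length >= 12, quality filter (>= 95% of bases at Q >= 20).
    ``flank_trim_n`` removes fixed random flanks (4N chemistry) from both
    ends of the clipped insert; off by default.
    """

    adapter: str
    mode: str = "quant"
    min_adapter_overlap: int = 8
    min_len: int | None = None
    max_len: int | None = None
    quality_q: int = 20
    quality_frac: float = 0.95
    apply_quality_filter: bool | None = None
    flank_trim_n: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("quant", "isomir"):
            raise ConfigurationError(f"mode must be quant|isomir, got {self.mode}")
        if not self.adapter:
            raise ConfigurationError("adapter must be non-empty")
        if not 0 < self.min_adapter_overlap <= len(self.adapter):
            raise ConfigurationError(
                "min_adapter_overlap must be in (0, len(adapter)]"
            )
        if not 0.0 <= self.quality_frac <= 1.0:
            raise ConfigurationError("quality_frac must be in [0, 1]")
        if self.min_len is None:
            self.min_len = 10 if self.mode == "quant" else 12
        if self.max_len is None and self.mode == "quant":
            self.max_len = 35
        if self.apply_quality_filter is None:
            self.apply_quality_filter = self.mode == "isomir"


@dataclass
class PreprocessStats:
    """Per-stage read tallies (kept/dropped at each filter)."""

    n_input: int = 0
    n_no_adapter: int = 0
    n_quality_fail: int = 0
    n_with_n: int = 0
    n_length_fail: int = 0  # read-count weighted, applied post-collapse
    n_kept: int = 0
    extra: dict = field(default_factory=dict)


def clip_adapter(read: RawRead, params: PreprocessParams) -> RawRead | None:
    """Sequence left of the leftmost adapter match, or None when absent.

    The match anchor is the first ``min_adapter_overlap`` bases of the
    adapter; a partial adapter at the 3' end is found by the same anchor as
    long as at least that much of it is present.  Qualities are trimmed in
    lockstep; after clipping, ``flank_trim_n`` bases are removed from each
    end of the insert (4N chemistry).
    """
    anchor = params.adapter[: params.min_adapter_overlap]
    idx = read.sequence.find(anchor)
    if idx == -1:
        return None
    seq = read.sequence[:idx]
    quals = read.qualities[:idx]
    if params.flank_trim_n:
        n = params.flank_trim_n
        if len(seq) <= 2 * n:
            seq, quals = "", ()
        else:
            seq, quals = seq[n:-n], quals[n:-n]
    return RawRead(read.id, seq, tuple(quals))


def quality_pass(read: RawRead, params: PreprocessParams) -> bool:
    """True iff the fraction of bases at Q >= quality_q reaches quality_frac (inclusive)."""
    if len(read.sequence) == 0:
        return False
    good = sum(1 for q in read.qualities if q >= params.quality_q)
    return good / len(read.qualities) >= params.quality_frac


def collapse(sequences: Iterable[str]) -> tuple[dict[str, int], int]:
    """Unique sequences with multiplicities; returns (collapsed, n dropped for N)."""
    counts: Counter[str] = Counter()
    dropped = 0
    for seq in sequences:
        if "N" in seq:
            dropped += 1
        else:
            counts[seq] += 1
    return dict(counts), dropped


def length_filter(collapsed: dict[str, int], params: PreprocessParams) -> dict[str, int]:
    """Inclusive length window; isomir mode has no upper bound by default."""
    lo = params.min_len
    hi = params.max_len if params.max_len is not None else float("inf")
    return {seq: c for seq, c in collapsed.items() if lo <= len(seq) <= hi}


def preprocess_reads(
    reads: Iterable[RawRead], params: PreprocessParams
) -> tuple[dict[str, int], PreprocessStats]:
    """Full branch: clip -> (quality) -> collapse -> length filter."""
    stats = PreprocessStats()
    clipped: list[str] = []
    for read in reads:
        stats.n_input += 1
        cut = clip_adapter(read, params)
        if cut is None:
            stats.n_no_adapter += 1
            continue
        if params.apply_quality_filter and not quality_pass(cut, params):
            stats.n_quality_fail += 1
            continue
        clipped.append(cut.sequence)
    collapsed, stats.n_with_n = collapse(clipped)
    kept = length_filter(collapsed, params)
    stats.n_length_fail = sum(collapsed.values()) - sum(kept.values())
    stats.n_kept = sum(kept.values())
    return kept, stats


def preprocess_fastq(source, params: PreprocessParams) -> tuple[dict[str, int], PreprocessStats]:
    reads = (RawRead(rid, seq, tuple(quals)) for rid, seq, quals in mio.read_fastq(source))
    return preprocess_reads(reads, params)
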