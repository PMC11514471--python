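"""Exact full-length sense mapping of collapsed reads to hairpins and the
mature +/- 2 nt windowed count matrix.

A read counts toward a mature arm iff some zero-mismatch placement of the
full read lies entirely inside the arm's interval widened by 2 nt on each
side (clipped to the hairpin).  Containment, not mere overlap, is required:
it excludes loop-spanning fragments.  A multi-mapping read contributes its
full collapse count to every qualifying mature by default (``multimap='all'``);
``'fractional'`` splits the count evenly instead.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .core import AnnotationError, AlignmentHit, CountMatrix, HairpinRecord

MATURE_WINDOW_NT = 2


def match_read(sequence: str, hairpins: list[HairpinRecord]) -> list[AlignmentHit]:
    """All exact sense occurrences of the read in any hairpin."""
    hits: list[AlignmentHit] = []
    n = len(sequence)
    if n == 0:
        return hits
    for h in hairpins:
        start = h.sequence.find(sequence)
        while start != -1:
            hits.append(AlignmentHit(h.hairpin_id, start, n, 0))
            start = h.sequence.find(sequence, start + 1)
    return hits


def _window(m, hairpin_len: int, pad: int = MATURE_WINDOW_NT) -> tuple[int, int]:
    if m.start >= m.end:
        raise AnnotationError(f"mature {m.mature_id}: degenerate window")
    return max(0, m.start - pad), min(hairpin_len, m.end + pad)


def count_mature(
    reads: dict[str, int],
    hairpins: list[HairpinRecord],
    multimap: str = "all",
) -> pd.Series:
    """Per-mature summed counts for one sample of collapsed reads.

    Each read contributes once per (read, mature) pair even when several
    placements qualify; under ``multimap='fractional'`` its count is divided
    by the number of qualifying matures.
    """
    if multimap not in ("all", "fractional"):
        raise ValueError(f"multimap must be all|fractional, got {multimap}")
    by_id = {h.hairpin_id: h for h in hairpins}
    mature_ids = [m.mature_id for h in hairpins for m in h.matures]
    totals = pd.Series(0.0, index=pd.Index(mature_ids, name="mature_id"))
    for seq, count in reads.items():
        hits = match_read(seq, hairpins)
        qualifying: set[str] = set()
        for hit in hits:
            h = by_id[hit.hairpin_id]
            for m in h.matures:
                lo, hi = _window(m, len(h.sequence))
                if hit.offset >= lo and hit.offset + hit.length <= hi:
                    qualifying.add(m.mature_id)
        if not qualifying:
            continue
        w = count / len(qualifying) if multimap == "fractional" else count
        for mid in qualifying:
            totals[mid] += w
    if multimap == "all":
        totals = totals.astype(int)
    return totals


def quantify_sample_set(
    samples: dict[str, dict[str, int]],
    hairpins: list[HairpinRecord],
    metadata: pd.DataFrame | None = None,
    multimap: str = "all",
) -> CountMatrix:
    """Count matrix over a set of samples on a shared annotation.

    ``samples`` maps sample id -> collapsed reads; every annotated mature is
    a row (zero-filled).  ``metadata`` (indexed by sample id) defaults to a
    one-condition sheet.
    """
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    cols = {s: count_mature(reads, hairpins, multimap=multimap) for s, reads in samples.items()}
    counts = pd.DataFrame(cols)
    if metadata is None:
        metadata = pd.DataFrame({"condition": ["all"] * len(samples)}, index=list(samples))
    return CountMatrix(counts, metadata.copy())


def base_mean_filter(
    matrix: CountMatrix, threshold: float = 10.0
) -> tuple[CountMatrix, pd.Series]:
    """Drop rows at or below the baseMean expression cutoff (strictly > kept).

    baseMean is the mean of size-factor-normalized counts over all samples
    (median-of-ratios normalization).
    """
    from .diffexp import size_factors  # local import to avoid a cycle

    if matrix.counts.shape[1] < 2:
        raise ValueError("base_mean_filter needs >= 2 samples")
    if not matrix.counts.to_numpy().any():
        warnings.warn("all-zero count matrix; baseMean filter returns empty result")
        empty = CountMatrix(matrix.counts.iloc[:0], matrix.samples)
        return empty, pd.Series(dtype=float, name="baseMean")
    sf = size_factors(matrix.counts)
    base_mean = (matrix.counts / sf).mean(axis=1).rename("baseMean")
    keep = base_mean > threshold
    return CountMatrix(matrix.counts.loc[keep].copy(), matrix.samples), base_mean
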