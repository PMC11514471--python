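"""IsomiR detection: mismatch-tolerant alignment to hairpins and
classification of end modifications relative to the annotated mature arms.

A read is placed at every sense offset on every hairpin with at most
``max_mismatches`` substitutions; placements may overhang the hairpin 3' end
by up to ``max_overhang`` nt, each overhanging base counting as a mismatch
(long non-templated tails remain classifiable within the budget).  Terminal
contiguous mismatches are peeled off as candidate non-templated additions
(3' before 5'); the remaining core must match the hairpin exactly — internal
variants are out of scope.  Core ends are then compared with the mature ends
to score trimming and templated extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlignmentHit, HairpinRecord
from .diffexp import bh_adjust

DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MAX_OVERHANG = 4
DEFAULT_MIN_COUNT = 2

#: an alignment is assigned to an arm only if it overlaps it by
#: max(MIN_ARM_OVERLAP_NT, MIN_ARM_OVERLAP_FRAC * arm length)
MIN_ARM_OVERLAP_NT = 10
MIN_ARM_OVERLAP_FRAC = 0.5

PROFILE_CLASSES = (
    "f_trim5", "f_trim3", "f_add5", "f_add3",
    "f_nta3_A", "f_nta3_U", "f_oligoU", "f_oligoA", "f_canonical",
)


@dataclass(frozen=True)
class IsomirCall:
    """End-modification classification of one collapsed read."""

    sequence: str
    count: int
    mature_id: str
    core_start: int
    core_end: int
    trim5: int
    trim3: int
    ext5_templated: int
    ext3_templated: int
    nta5: str
    nta3: str

    @property
    def canonical(self) -> bool:
        return not (
            self.trim5 or self.trim3 or self.ext5_templated or self.ext3_templated
            or self.nta5 or self.nta3
        )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def align_mismatch(
    sequence: str,
    hairpins: list[HairpinRecord],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> list[AlignmentHit]:
    """All sense placements with <= max_mismatches substitutions.

    Overhanging bases past the hairpin 3' end (at most ``max_overhang``)
    count as mismatches.
    """
    read = _encode(sequence)
    n = len(read)
    hits: list[AlignmentHit] = []
    for h in hairpins:
        # pad with a sentinel so overhang positions always mismatch
        padded = np.concatenate(
            [_encode(h.sequence), np.zeros(max_overhang, dtype=np.uint8)]
        )
        if len(padded) < n:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(padded, n)
        mm = (windows != read).sum(axis=1)
        for offset in np.nonzero(mm <= max_mismatches)[0]:
            hits.append(AlignmentHit(h.hairpin_id, int(offset), n, int(mm[offset])))
    return hits


def classify_isomir(
    hit: AlignmentHit,
    hairpin: HairpinRecord,
    sequence: str,
    count: int = 1,
) -> IsomirCall | None:
    """Classify one placement, or None when it is not a clean end-variant."""
    hseq = hairpin.sequence
    n = len(sequence)
    start, end = hit.offset, hit.offset + n

    # 1. arm assignment by maximal overlap
    best, best_ov = None, -1
    for m in hairpin.matures:
        ov = min(end, m.end) - max(start, m.start)
        if ov > best_ov:
            best, best_ov = m, ov
    if best is None:
        return None
    if best_ov < max(MIN_ARM_OVERLAP_NT, int(np.ceil(MIN_ARM_OVERLAP_FRAC * len(best)))):
        return None

    # 2. peel terminal mismatches: 3' first, then 5'
    mismatch = [
        pos >= len(hseq) or sequence[i] != hseq[pos]
        for i, pos in enumerate(range(start, end))
    ]
    k3 = 0
    while k3 < n and mismatch[n - 1 - k3]:
        k3 += 1
    k5 = 0
    while k5 < n - k3 and mismatch[k5]:
        k5 += 1
    if any(mismatch[k5 : n - k3]):
        return None  # internal variant: out of scope
    nta5 = sequence[:k5]
    nta3 = sequence[n - k3 :] if k3 else ""
    core_start, core_end = start + k5, end - k3
    if core_end <= core_start:
        return None

    # 3. compare core ends with the mature ends
    trim5 = max(0, core_start - best.start)
    ext5 = max(0, best.start - core_start)
    trim3 = max(0, best.end - core_end)
    ext3 = max(0, core_end - best.end)
    return IsomirCall(
        sequence=sequence,
        count=count,
        mature_id=best.mature_id,
        core_start=core_start,
        core_end=core_end,
        trim5=trim5,
        trim3=trim3,
        ext5_templated=ext5,
        ext3_templated=ext3,
        nta5=nta5,
        nta3=nta3,
    )


def _mod_weight(call: IsomirCall) -> int:
    return (call.trim5 + call.trim3 + call.ext5_templated + call.ext3_templated
            + len(call.nta5) + len(call.nta3))


def classify_read(
    sequence: str,
    count: int,
    hairpins: list[HairpinRecord],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> IsomirCall | None:
    """Best classification over all placements of one collapsed read.

    Ties resolve to the fewest mismatches, then the least-modified call,
    then (hairpin id, offset) for determinism.
    """
    by_id = {h.hairpin_id: h for h in hairpins}
    candidates = []
    for hit in align_mismatch(sequence, hairpins, max_mismatches, max_overhang):
        call = classify_isomir(hit, by_id[hit.hairpin_id], sequence, count)
        if call is not None:
            candidates.append((hit.mismatches, _mod_weight(call), hit.hairpin_id, hit.offset, call))
    if not candidates:
        return None
    return min(candidates, key=lambda t: t[:4])[4]


def classify_sample(
    reads: dict[str, int],
    hairpins: list[HairpinRecord],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> list[IsomirCall]:
    calls = []
    for seq in sorted(reads):
        call = classify_read(seq, reads[seq], hairpins, max_mismatches, max_overhang)
        if call is not None:
            calls.append(call)
    return calls


def _is_homopolymer(s: str, base: str) -> bool:
    return len(s) > 0 and set(s) == {base}


def aggregate_profile(
    calls: list[IsomirCall],
    min_count: int = DEFAULT_MIN_COUNT,
    weight_by_count: bool = True,
) -> pd.Series:
    """Pooled modification frequencies for one sample.

    Calls below ``min_count`` collapsed-read support are excluded.
    Frequencies are fractions of all assigned reads (count-weighted by
    default); oligoU/oligoA require a homopolymer 3' tail of length >= 2.
    """
    kept = [c for c in calls if c.count >= min_count]
    freqs = pd.Series(0.0, index=list(PROFILE_CLASSES))
    denom = sum((c.count if weight_by_count else 1) for c in kept)
    freqs["n_assigned"] = float(denom)
    if denom == 0:
        return freqs
    for c in kept:
        w = (c.count if weight_by_count else 1) / denom
        if c.trim5:
            freqs["f_trim5"] += w
        if c.trim3:
            freqs["f_trim3"] += w
        if c.ext5_templated or c.nta5:
            freqs["f_add5"] += w
        if c.ext3_templated or c.nta3:
            freqs["f_add3"] += w
        if _is_homopolymer(c.nta3, "A"):
            freqs["f_nta3_A"] += w
            if len(c.nta3) >= 2:
                freqs["f_oligoA"] += w
        if _is_homopolymer(c.nta3, "T"):
            freqs["f_nta3_U"] += w
            if len(c.nta3) >= 2:
                freqs["f_oligoU"] += w
        if c.canonical:
            freqs["f_canonical"] += w
    return freqs


def profile_table(profiles: dict[str, pd.Series]) -> pd.DataFrame:
    """Samples x modification classes."""
    return pd.DataFrame(profiles).T.rename_axis("sample")


def compare_profiles(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-class group means, fold ratio (A/B) and t test with BH across classes.

    Inputs are per-sample profile tables (rows = samples); with a single
    sample in a group only the ratio is reported.
    """
    classes = [c for c in PROFILE_CLASSES if c in group_a.columns]
    rows = []
    eps = 1e-9
    for cls in classes:
        a = group_a[cls].to_numpy(dtype=float)
        b = group_b[cls].to_numpy(dtype=float)
        row = {
            "class": cls,
            "mean_a": a.mean(),
            "mean_b": b.mean(),
            "ratio_a_over_b": (a.mean() + eps) / (b.mean() + eps),
        }
        if len(a) >= 2 and len(b) >= 2:
            if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and np.isclose(a.mean(), b.mean()):
                row["stat"], row["pvalue"] = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b)
                row["stat"], row["pvalue"] = float(t), float(p)
        else:
            row["stat"], row["pvalue"] = np.nan, np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("class")
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out
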