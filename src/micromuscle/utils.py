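"""Small self-contained statistics: percent spliced-in, 2^-ddCt fold
changes, IUPAC motif scanning and target-set distribution shifts."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def psi(inclusion: float, exclusion: float) -> float:
    """Percent spliced-in: 100 * inclusion / (inclusion + exclusion)."""
    if inclusion < 0 or exclusion < 0:
        raise ValueError("band signals must be non-negative")
    total = inclusion + exclusion
    if total == 0:
        raise ValueError("PSI undefined: both inclusion and exclusion signals are zero")
    return 100.0 * inclusion / total


def delta_psi(test: tuple[float, float], control: tuple[float, float]) -> float:
    """PSI(test) - PSI(control), in percentage points."""
    return psi(*test) - psi(*control)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired cycle thresholds for a target and its reference gene."""

    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.target_ct) and np.isfinite(self.reference_ct)):
            raise ValueError("Ct values must be finite")


def ddct_fold(test: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct = (test.target_ct - test.reference_ct) - (control.target_ct - control.reference_ct)
    return float(2.0 ** (-ddct))


def motif_scan(sequence: str, motif: str = "YGCY") -> list[int]:
    """0-based start positions of all (overlapping) IUPAC motif matches."""
    seq = sequence.upper().replace("U", "T")
    try:
        pattern = "".join(
            f"[{IUPAC[sym]}]" if len(IUPAC[sym]) > 1 else IUPAC[sym]
            for sym in motif.upper()
        )
    except KeyError as exc:
        raise ValueError(f"non-IUPAC motif symbol: {exc.args[0]!r}") from None
    return [m.start() for m in re.finditer(f"(?={pattern})", seq)]


def target_shift(
    all_log2fc: Mapping[str, float],
    target_set: Iterable[str],
    against: str = "nontargets",
) -> tuple[float, float, float]:
    """Cumulative-distribution shift of a target set's fold changes.

    Two-sample Kolmogorov-Smirnov test of the targets' log2 fold changes
    against the non-targets (default) or against all genes; returns
    (D, two-sided p, signed median difference targets - background).
    """
    if against not in ("nontargets", "all"):
        raise ValueError("against must be nontargets|all")
    targets = set(target_set) & set(all_log2fc)
    if not targets:
        raise ValueError("target set does not intersect the fold-change universe")
    if len(targets) < 5:
        raise ValueError("need >= 5 targets in the fold-change universe")
    tvals = np.array([all_log2fc[g] for g in sorted(targets)])
    if against == "nontargets":
        background = [g for g in all_log2fc if g not in targets]
        if not background:
            raise ValueError("non-target background is empty")
        bvals = np.array([all_log2fc[g] for g in sorted(background)])
    else:
        bvals = np.array([all_log2fc[g] for g in sorted(all_log2fc)])
    d, p = stats.ks_2samp(tvals, bvals)
    return float(d), float(p), float(np.median(tvals) - np.median(bvals))
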