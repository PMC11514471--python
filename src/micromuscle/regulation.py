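"""Transcript-level vs posttranscriptional regulation inference.

Hairpins co-located within a polycistron-scale window on one chromosome and
strand are grouped into genomic clusters (single-linkage chaining with a
50 kb consecutive-gap threshold); the two arms of a hairpin form arm pairs.
A differentially expressed miRNA whose cluster- or arm-mate changes
significantly in the same direction is called deregulated at the transcript
level (the shared pri-miRNA is the parsimonious target of regulation); a
significant miRNA with expressed but non-concordant mates is a
posttranscriptional candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotationError, HairpinRecord

DEFAULT_CLUSTER_GAP_BP = 50_000


@dataclass
class ClusterAssignment:
    cluster_id: str
    members: list[str]
    chrom: str
    strand: str
    span_bp: int


def build_clusters(
    hairpins: list[HairpinRecord], gap_bp: int = DEFAULT_CLUSTER_GAP_BP
) -> list[ClusterAssignment]:
    """Single-linkage chaining of located hairpins per chromosome and strand.

    Consecutive hairpins (sorted by start) closer than ``gap_bp`` join one
    chain, so a chain may span more than ``gap_bp`` end to end.  Hairpins
    without a locus are excluded with a warning.
    """
    located = [h for h in hairpins if h.locus is not None]
    skipped = [h.hairpin_id for h in hairpins if h.locus is None]
    if skipped:
        warnings.warn(f"hairpins without genomic locus excluded from clustering: {skipped}")
    by_key: dict[tuple[str, str], list[HairpinRecord]] = {}
    for h in located:
        by_key.setdefault((h.locus.chrom, h.locus.strand), []).append(h)
    clusters: list[ClusterAssignment] = []
    for (chrom, strand) in sorted(by_key):
        members = sorted(by_key[(chrom, strand)], key=lambda h: (h.locus.start, h.hairpin_id))
        chain: list[HairpinRecord] = []
        for h in members:
            if chain and h.locus.start - chain[-1].locus.start > gap_bp:
                clusters.append(_finish_chain(chain, chrom, strand, len(clusters)))
                chain = []
            chain.append(h)
        if chain:
            clusters.append(_finish_chain(chain, chrom, strand, len(clusters)))
    return clusters


def _finish_chain(chain, chrom, strand, idx) -> ClusterAssignment:
    start = chain[0].locus.start
    end = chain[-1].locus.start + len(chain[-1].sequence)
    return ClusterAssignment(
        cluster_id=f"cluster_{idx + 1}",
        members=[h.hairpin_id for h in chain],
        chrom=chrom,
        strand=strand,
        span_bp=end - start,
    )


def pair_arms(hairpins: list[HairpinRecord]) -> dict[str, str]:
    """Mutual arm-mate map (mature id -> mature id) for two-arm hairpins."""
    pairs: dict[str, str] = {}
    for h in hairpins:
        if len(h.matures) > 2:
            raise AnnotationError(f"hairpin {h.hairpin_id} has more than two mature records")
        if len(h.matures) == 2:
            a, b = h.matures
            pairs[a.mature_id] = b.mature_id
            pairs[b.mature_id] = a.mature_id
    return pairs


def classify_regulation(
    de: pd.DataFrame,
    hairpins: list[HairpinRecord],
    clusters: list[ClusterAssignment] | None = None,
    alpha: float = 0.05,
    rule: str = "any",
) -> pd.DataFrame:
    """Label each significant miRNA by cluster/arm concordance.

    ``de`` is a Wald/LRT result table restricted to the expressed
    (baseMean-filtered) universe, indexed by mature id with log2FoldChange
    and padj.  A significant miRNA is ``transcript_level`` when at least one
    (``rule='any'``; ``'all'`` requires every significant mate) cluster- or
    arm-mate is significant with the same fold-change sign,
    ``posttranscriptional_candidate`` when it has expressed mates but no
    concordant significant one, and ``unassigned`` without expressed mates.
    Evidence for every expressed mate is serialized in the ``evidence``
    column as ``mate:relation:log2fc:padj:concordant`` items.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be any|all")
    if clusters is None:
        clusters = build_clusters(hairpins)
    cluster_of = {hid: c.cluster_id for c in clusters for hid in c.members}
    members_of = {c.cluster_id: c.members for c in clusters}
    arm_pairs = pair_arms(hairpins)
    matures_by_hairpin = {h.hairpin_id: [m.mature_id for m in h.matures] for h in hairpins}
    hairpin_of = {m.mature_id: h.hairpin_id for h in hairpins for m in h.matures}

    sig = de["padj"] < alpha
    rows = []
    for mid in de.index[sig.to_numpy()]:
        hid = hairpin_of.get(mid)
        if hid is None:
            raise AnnotationError(f"DE mature {mid} absent from annotation")
        mates: list[tuple[str, str]] = []
        if mid in arm_pairs:
            mates.append((arm_pairs[mid], "arm"))
        cid = cluster_of.get(hid)
        if cid is not None:
            for other_hid in members_of[cid]:
                if other_hid != hid:
                    mates.extend((m, "cluster") for m in matures_by_hairpin[other_hid])
        expressed = [(m, rel) for m, rel in mates if m in de.index]
        evidence, concordant_flags = [], []
        sign = np.sign(de.loc[mid, "log2FoldChange"])
        for m, rel in expressed:
            m_lfc = de.loc[m, "log2FoldChange"]
            m_padj = de.loc[m, "padj"]
            m_sig = bool(m_padj < alpha)
            conc = bool(m_sig and np.sign(m_lfc) == sign and sign != 0)
            if m_sig:
                concordant_flags.append(conc)
            evidence.append(f"{m}:{rel}:{m_lfc:+.3f}:{m_padj:.3g}:{int(conc)}")
        if not expressed:
            label = "unassigned"
        elif concordant_flags and (any(concordant_flags) if rule == "any" else all(concordant_flags)):
            label = "transcript_level"
        else:
            label = "posttranscriptional_candidate"
        rows.append(
            {
                "mature_id": mid,
                "label": label,
                "log2FoldChange": de.loc[mid, "log2FoldChange"],
                "padj": de.loc[mid, "padj"],
                "n_expressed_mates": len(expressed),
                "evidence": ";".join(evidence),
            }
        )
    return pd.DataFrame(
        rows, columns=["mature_id", "label", "log2FoldChange", "padj",
                       "n_expressed_mates", "evidence"]
    ).set_index("mature_id")


@dataclass
class ModelComparison:
    """Cross-model overlap of significant miRNA changes."""

    n_a_only: int
    n_shared: int
    n_b_only: int
    pearson_r: float
    pearson_p: float
    sign_concordant_fraction: float
    shared: pd.DataFrame = field(repr=False, default=None)

    @property
    def overlap_fraction_of_a(self) -> float:
        tot = self.n_a_only + self.n_shared
        return self.n_shared / tot if tot else float("nan")


def compare_models(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_log2fc: float = 0.0,
) -> ModelComparison:
    """Overlap, Pearson correlation and sign concordance of two DE tables.

    Significant sets are intersected with both expressed universes (rows
    present, padj non-NaN, in both tables); ``min_abs_log2fc`` optionally
    restricts to larger fold changes.  Pearson r is computed on the shared
    significant set and left NaN below 3 shared miRNAs.
    """
    universe = de_a.index[de_a["padj"].notna()].intersection(
        de_b.index[de_b["padj"].notna()]
    )
    def _sig(de):
        s = (de.loc[universe, "padj"] < alpha)
        if min_abs_log2fc > 0:
            s &= de.loc[universe, "log2FoldChange"].abs() > min_abs_log2fc
        return set(universe[s.to_numpy()])

    sig_a, sig_b = _sig(de_a), _sig(de_b)
    shared_ids = sorted(sig_a & sig_b)
    shared = pd.DataFrame(
        {
            "log2fc_a": de_a.loc[shared_ids, "log2FoldChange"],
            "log2fc_b": de_b.loc[shared_ids, "log2FoldChange"],
        }
    )
    if len(shared_ids) >= 3:
        r, p = stats.pearsonr(shared["log2fc_a"], shared["log2fc_b"])
    else:
        r, p = float("nan"), float("nan")
    if shared_ids:
        concord = float(
            np.mean(np.sign(shared["log2fc_a"]) == np.sign(shared["log2fc_b"]))
        )
    else:
        concord = float("nan")
    return ModelComparison(
        n_a_only=len(sig_a) - len(shared_ids),
        n_shared=len(shared_ids),
        n_b_only=len(sig_b) - len(shared_ids),
        pearson_r=float(r),
        pearson_p=float(p),
        sign_concordant_fraction=concord,
        shared=shared,
    )
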