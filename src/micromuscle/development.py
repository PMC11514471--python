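"""Developmental trajectory analysis: expression-pattern clustering over a
time course and the knockout-vs-development "adult-to-newborn shift".

Per-miRNA profiles (mean normalized count per time point, z-scored across
time points) are clustered by average-linkage hierarchical clustering under
a 1 - Pearson-correlation distance, cut into k groups (default six).  The
shift analysis correlates knockout fold changes with developmental fold
changes over the miRNAs significant in both, reporting the global Pearson r
and the fraction of opposite-sign pairs (the per-miRNA reading of
"negatively correlated").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import CountMatrix, timepoint_order
from . import diffexp


@dataclass
class TrajectoryCluster:
    label: str
    members: list[str]
    centroid: pd.Series  # z-scored mean profile over time points


def _profiles(
    matrix: CountMatrix, sf: pd.Series | None = None, time_col: str = "timepoint"
) -> pd.DataFrame:
    norm = diffexp.normalize(matrix.counts, sf)
    tps = timepoint_order(matrix.samples.rename(columns={time_col: "timepoint"}))
    labels = matrix.samples[time_col]
    prof = pd.DataFrame(
        {t: norm.loc[:, (labels == t).to_numpy()].mean(axis=1) for t in tps}
    )
    return prof


def _zscore(prof: pd.DataFrame) -> pd.DataFrame:
    mu = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=0)
    return prof.sub(mu, axis=0).div(sd, axis=0)


def _shape_label(centroid: np.ndarray, idx: int) -> str:
    d = np.diff(centroid)
    if np.all(d > 0):
        return "monotone_up"
    if np.all(d < 0):
        return "monotone_down"
    return f"cluster_{idx}"


def cluster_trajectories(
    matrix: CountMatrix,
    lrt_results: pd.DataFrame,
    k: int = 6,
    alpha: float = 0.05,
    sf: pd.Series | None = None,
    time_col: str = "timepoint",
) -> list[TrajectoryCluster]:
    """Average-linkage clustering of LRT-significant miRNA z-profiles.

    Distance is 1 - Pearson correlation of the z-scored profiles, so
    clusters capture trajectory shape, not level.  Zero-variance profiles
    are excluded (their z-score is undefined).  Monotone centroids are
    labelled by shape, others by index.
    """
    sig = lrt_results.index[(lrt_results["padj"] < alpha).to_numpy()]
    prof = _profiles(matrix, sf, time_col).loc[prof_index(sig, matrix)]
    prof = prof[prof.std(axis=1, ddof=0) > 0]
    if k > len(prof):
        raise ValueError(f"k={k} exceeds the {len(prof)} clusterable significant miRNAs")
    z = _zscore(prof)
    dist = pdist(z.to_numpy(), metric="correlation")
    linkage = hierarchy.linkage(dist, method="average")
    assignment = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    clusters = []
    seen: dict[str, int] = {}
    for ci in sorted(set(assignment)):
        members = list(z.index[assignment == ci])
        centroid = z.loc[members].mean(axis=0)
        label = _shape_label(centroid.to_numpy(), ci)
        seen[label] = seen.get(label, 0) + 1
        if seen[label] > 1:  # shape labels must stay unique across clusters
            label = f"{label}_{seen[label]}"
        clusters.append(TrajectoryCluster(label=label, members=members, centroid=centroid))
    return clusters


def prof_index(sig, matrix: CountMatrix):
    return [m for m in sig if m in matrix.counts.index]


def cluster_membership(clusters: list[TrajectoryCluster]) -> pd.Series:
    out = {}
    for i, c in enumerate(clusters):
        for m in c.members:
            out[m] = c.label if c.label else str(i)
    return pd.Series(out, name="trajectory_cluster")


@dataclass
class ShiftReport:
    """Knockout-vs-development fold-change comparison on the shared significant set."""

    n_shared: int
    pearson_r: float
    pearson_p: float
    fraction_negative: float
    table: pd.DataFrame = field(repr=False, default=None)


def shift_analysis(
    dev_de: pd.DataFrame,
    ko_de: pd.DataFrame,
    alpha: float = 0.05,
    trajectory: pd.Series | None = None,
) -> ShiftReport:
    """Correlate developmental (adult vs newborn) and knockout fold changes.

    Shared set: significant in both tables at ``alpha``.  fraction_negative
    is the fraction of shared miRNAs with opposite fold-change signs (pairs
    with a zero fold change are excluded from the denominator).
    """
    shared_ids = sorted(
        set(dev_de.index[(dev_de["padj"] < alpha).to_numpy()])
        & set(ko_de.index[(ko_de["padj"] < alpha).to_numpy()])
    )
    table = pd.DataFrame(
        {
            "dev_log2fc": dev_de.loc[shared_ids, "log2FoldChange"],
            "ko_log2fc": ko_de.loc[shared_ids, "log2FoldChange"],
        }
    )
    if trajectory is not None:
        table["trajectory_cluster"] = trajectory.reindex(shared_ids)
    if len(shared_ids) >= 3:
        r, p = stats.pearsonr(table["dev_log2fc"], table["ko_log2fc"])
    else:
        r, p = float("nan"), float("nan")
    signs = np.sign(table["dev_log2fc"]) * np.sign(table["ko_log2fc"])
    nonzero = signs[signs != 0]
    frac_neg = float((nonzero < 0).mean()) if len(nonzero) else float("nan")
    return ShiftReport(
        n_shared=len(shared_ids),
        pearson_r=float(r),
        pearson_p=float(p),
        fraction_negative=frac_neg,
        table=table,
    )


def pairwise_timepoint_contrasts(
    matrix: CountMatrix,
    time_col: str = "timepoint",
    min_base_mean: float = diffexp.DEFAULT_MIN_BASE_MEAN,
    alpha: float = 0.05,
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Wald contrasts for consecutive time-point pairs plus each-vs-first.

    Returns the contrast tables keyed by (earlier, later) and a summary of
    significant counts and pairwise overlaps of the significant sets.
    """
    tps = timepoint_order(matrix.samples.rename(columns={time_col: "timepoint"}))
    if len(tps) < 2:
        raise ValueError("need >= 2 time points")
    wanted: list[tuple[str, str]] = []
    for a, b in zip(tps, tps[1:]):
        wanted.append((a, b))
    for b in tps[1:]:
        if (tps[0], b) not in wanted:
            wanted.append((tps[0], b))
    results = {}
    labels = matrix.samples[time_col]
    for a, b in wanted:
        cols = labels.isin([a, b])
        sub = matrix.subset_samples(list(matrix.samples.index[cols.to_numpy()]))
        sub = CountMatrix(sub.counts, sub.samples.assign(condition=sub.samples[time_col]))
        results[(a, b)] = diffexp.wald_test(sub, (a, b), min_base_mean=min_base_mean)
    sig_sets = {
        pair: set(res.index[(res["padj"] < alpha).to_numpy()]) for pair, res in results.items()
    }
    rows = []
    pairs = list(results)
    for i, p1 in enumerate(pairs):
        for p2 in pairs[i:]:
            rows.append(
                {
                    "contrast_a": f"{p1[0]}-{p1[1]}",
                    "contrast_b": f"{p2[0]}-{p2[1]}",
                    "n_sig_a": len(sig_sets[p1]),
                    "n_sig_b": len(sig_sets[p2]),
                    "n_overlap": len(sig_sets[p1] & sig_sets[p2]),
                }
            )
    return results, pd.DataFrame(rows)
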