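"""Negative-binomial differential expression.

A deliberately transparent analogue of the standard count-based DE
framework: median-of-ratios size factors, per-feature method-of-moments
dispersion moderated by a fitted mean-dispersion trend, a Wald test on the
log2 ratio of group means for two-group contrasts, and a likelihood-ratio
test (full: one mean per time point; reduced: a single mean) for time
courses.  P values are Benjamini-Hochberg adjusted within the
expression-filtered universe (baseMean > 10 by default).

The NB parameterization is mean mu and dispersion phi, variance
mu + phi * mu^2 (phi = 0 is Poisson).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 0.01
DEFAULT_MIN_BASE_MEAN = 10.0

RESULT_COLUMNS = ["baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    sf_j = median over features (with all-positive counts) of
    count_ij / geometric-mean_i.  When no feature is positive in every
    sample, falls back to geometric means over positive entries only.
    """
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        ref = x[all_pos]
        log_geo = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_geo[:, None]
    else:
        warnings.warn("no feature with all-positive counts; using positive-entry geometric means")
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(x, where=x > 0), np.nan)
        log_geo = np.nanmean(logx, axis=1)
        ratios = logx - log_geo[:, None]
    sf = np.exp(np.nanmedian(ratios, axis=0))
    if not np.all(np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("size factors undefined for at least one sample")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(counts)
    return counts / sf


def base_mean(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.Series:
    return normalize(counts, sf).mean(axis=1).rename("baseMean")


def estimate_dispersion(
    counts: pd.DataFrame,
    conditions: pd.Series,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Moderated per-feature dispersion.

    Method-of-moments within conditions on normalized counts,
    phi = max((s^2 - mu) / mu^2, 1e-8); a 1/mu trend fitted across features
    by least squares; the final value is the larger of the feature-wise and
    trend estimates, floored at 0.01.  Groups with a single replicate
    contribute no variance (trend only, with a warning).
    """
    norm = normalize(counts, sf)
    conditions = conditions.loc[norm.columns]
    groups = conditions.unique()
    n_informative = sum((conditions == g).sum() >= 2 for g in groups)
    if n_informative == 0:
        warnings.warn("no condition has >= 2 replicates; dispersion from trend floor only")
    var_parts, mean_all = [], norm.mean(axis=1).to_numpy()
    for g in groups:
        sub = norm.loc[:, (conditions == g).to_numpy()]
        if sub.shape[1] >= 2:
            var_parts.append(sub.var(axis=1, ddof=1).to_numpy())
    if var_parts:
        s2 = np.mean(var_parts, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_mom = (s2 - mean_all) / np.square(mean_all)
        phi_mom = np.where(np.isfinite(phi_mom), phi_mom, 0.0)
        phi_mom = np.maximum(phi_mom, 1e-8)
    else:
        phi_mom = np.full(len(norm), 1e-8)

    # trend phi_hat(mu) = a0 + a1/mu over features with positive mean
    ok = mean_all > 0
    if ok.sum() >= 2:
        design = np.column_stack([np.ones(ok.sum()), 1.0 / mean_all[ok]])
        coef, *_ = np.linalg.lstsq(design, phi_mom[ok], rcond=None)
        with np.errstate(divide="ignore"):
            trend = coef[0] + coef[1] / mean_all
        trend = np.where(ok, np.maximum(trend, 0.0), 0.0)
    else:
        trend = np.zeros(len(norm))
    final = np.maximum.reduce([phi_mom, trend, np.full(len(norm), DISPERSION_FLOOR)])
    return pd.DataFrame(
        {"phi_mom": phi_mom, "phi_trend": trend, "phi": final}, index=norm.index
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaN p values propagate and are excluded from m."""
    p = np.asarray(p, dtype=float)
    padj = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        padj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return padj


def _finish(df: pd.DataFrame, min_base_mean: float) -> pd.DataFrame:
    """Attach padj within the baseMean-filtered universe; keep sub-threshold rows with NaN."""
    p = df["pvalue"].to_numpy(dtype=float).copy()
    p[df["baseMean"].to_numpy() <= min_base_mean] = np.nan
    df["padj"] = bh_adjust(p)
    return df


def wald_test(
    matrix: CountMatrix,
    contrast: tuple[str, str],
    sf: pd.Series | None = None,
    dispersion: pd.Series | None = None,
    min_base_mean: float = DEFAULT_MIN_BASE_MEAN,
) -> pd.DataFrame:
    """Two-group Wald test; log2FoldChange is group B relative to group A.

    log2fc = log2((mean normalized B + 0.5) / (mean normalized A + 0.5));
    its standard error comes from the delta method on the NB group means,
    Var(log mu_hat_k) = (1 + phi * mu_k) / (n_k * mu_k).
    """
    group_a, group_b = contrast
    cond = matrix.samples["condition"]
    for g in (group_a, group_b):
        if (cond == g).sum() == 0:
            raise ValueError(f"condition {g!r} absent from sample metadata")
        if (cond == g).sum() < 2:
            raise ValueError(f"condition {g!r} needs >= 2 replicates for the Wald test")
    counts = matrix.counts
    if sf is None:
        sf = size_factors(counts)
    norm = normalize(counts, sf)
    if dispersion is None:
        both = cond.isin([group_a, group_b])
        disp = estimate_dispersion(
            counts.loc[:, both.to_numpy()], cond[both], sf[both.to_numpy()]
        )
        dispersion = disp["phi"]
    phi = dispersion.loc[counts.index].to_numpy()

    cols_a = (cond == group_a).to_numpy()
    cols_b = (cond == group_b).to_numpy()
    mean_a = norm.loc[:, cols_a].mean(axis=1).to_numpy()
    mean_b = norm.loc[:, cols_b].mean(axis=1).to_numpy()
    n_a, n_b = cols_a.sum(), cols_b.sum()
    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))
    mu_a = mean_a + PSEUDOCOUNT
    mu_b = mean_b + PSEUDOCOUNT
    var_log = (1.0 + phi * mu_a) / (n_a * mu_a) + (1.0 + phi * mu_b) / (n_b * mu_b)
    se = np.sqrt(var_log) / np.log(2.0)
    with np.errstate(invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    df = pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1).to_numpy(),
            "log2FoldChange": log2fc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pvalue,
        },
        index=counts.index.rename("mature_id"),
    )
    return _finish(df, min_base_mean)


def _nb_loglik(k: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-pmf; mu broadcast over samples, phi per row."""
    mu = np.maximum(mu, 1e-8)
    r = 1.0 / np.maximum(phi, 1e-8)[:, None]
    p = r / (r + mu)
    return stats.nbinom.logpmf(k, r, p).sum(axis=1)


def lrt_timecourse(
    matrix: CountMatrix,
    time_col: str = "timepoint",
    sf: pd.Series | None = None,
    dispersion: pd.Series | None = None,
    min_base_mean: float = DEFAULT_MIN_BASE_MEAN,
) -> pd.DataFrame:
    """Likelihood-ratio test across time points at fixed dispersion.

    Full model: one NB mean per time point; reduced: one overall mean; the
    statistic 2(l_full - l_reduced) is referred to chi-square with T - 1 df.
    Reported log2FoldChange contrasts the last time point against the first.
    """
    from .core import timepoint_order

    if time_col not in matrix.samples.columns:
        raise ValueError(f"sample sheet has no {time_col!r} column")
    tps = timepoint_order(matrix.samples.rename(columns={time_col: "timepoint"}))
    if len(tps) < 2:
        raise ValueError("likelihood-ratio test needs >= 2 time points")
    labels = matrix.samples[time_col]
    for t in tps:
        if (labels == t).sum() < 2:
            raise ValueError(f"time point {t!r} needs >= 2 replicates")
    counts = matrix.counts
    if sf is None:
        sf = size_factors(counts)
    norm = normalize(counts, sf)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, labels.rename("condition"), sf)["phi"]
    phi = dispersion.loc[counts.index].to_numpy()

    k = counts.to_numpy(dtype=float)
    sfv = sf.to_numpy()
    # per-time-point mean of normalized counts; expected raw count = sf_j * q_t
    q_by_tp = {t: norm.loc[:, (labels == t).to_numpy()].mean(axis=1).to_numpy() for t in tps}
    mu_full = np.empty_like(k)
    for j, s in enumerate(counts.columns):
        mu_full[:, j] = q_by_tp[labels.loc[s]] * sfv[j]
    q_all = norm.mean(axis=1).to_numpy()
    mu_red = q_all[:, None] * sfv[None, :]
    ll_full = _nb_loglik(k, mu_full, phi)
    ll_red = _nb_loglik(k, mu_red, phi)
    stat = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    pvalue = stats.chi2.sf(stat, df=len(tps) - 1)
    log2fc = np.log2((q_by_tp[tps[-1]] + PSEUDOCOUNT) / (q_by_tp[tps[0]] + PSEUDOCOUNT))
    df = pd.DataFrame(
        {
            "baseMean": q_all,
            "log2FoldChange": log2fc,
            "lfcSE": np.nan,
            "stat": stat,
            "pvalue": pvalue,
        },
        index=counts.index.rename("mature_id"),
    )
    return _finish(df, min_base_mean)
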