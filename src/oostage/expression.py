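"""Transcriptome-complexity statistics and differential expression.

Implements the expression-side analyses of the NSN/SN oocyte comparison:
per-cell detected-transcript counts, the depth-matched Wilcoxon comparison,
the "SN-missing" transcript filter, NSN expression quartiles with the
quartile-bias chi-square, a per-group over-dispersion screen, and a
negative-binomial Wald differential-expression pipeline (median-of-ratios
size factors, trended dispersion, per-transcript NB GLM with the stage as
the single covariate, Benjamini-Hochberg adjustment and optional
normal-prior fold-change shrinkage).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, InsufficientDataError

logger = logging.getLogger("oostage.expression")

STAGES = ("NSN", "SN", "intermediate", "unknown")

# Hauck-Donner guard: clamp |log2 fold change| during NB GLM fitting so that
# groups with all-zero counts keep an informative Wald statistic.
_MAX_ABS_LFC = 10.0


@dataclass
class CountMatrix:
    """Raw transcript x sample counts plus per-sample metadata.

    ``counts``: DataFrame indexed by transcript id, columns = sample ids,
    non-negative integers.  ``meta``: DataFrame indexed by sample id with at
    least a ``stage`` column (NSN / SN / intermediate / unknown); a
    ``total_reads`` column is filled from column sums when absent.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ConfigError("CountMatrix: duplicate transcript ids")
        if self.counts.columns.has_duplicates:
            raise ConfigError("CountMatrix: duplicate sample ids")
        if (np.asarray(self.counts) < 0).any():
            raise ConfigError("CountMatrix: negative counts")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ConfigError(f"CountMatrix: samples without metadata: {sorted(missing)}")
        if "stage" not in self.meta.columns:
            raise ConfigError("CountMatrix: meta lacks 'stage' column")
        bad = set(self.meta["stage"]) - set(STAGES)
        if bad:
            raise ConfigError(f"CountMatrix: unknown stage labels {sorted(bad)}")
        self.meta = self.meta.loc[list(self.counts.columns)].copy()
        if "total_reads" not in self.meta.columns:
            self.meta["total_reads"] = self.counts.sum(axis=0)

    def samples(self, stage: str) -> list[str]:
        return list(self.meta.index[self.meta["stage"] == stage])

    def require_groups(self, stages=("NSN", "SN"), min_n: int = 1) -> None:
        for st in stages:
            if len(self.samples(st)) < min_n:
                raise InsufficientDataError(
                    f"need >= {min_n} samples with stage '{st}', have {len(self.samples(st))}")


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    observed: np.ndarray = field(default=None, repr=False)
    expected: np.ndarray = field(default=None, repr=False)


@dataclass
class RankSumResult:
    statistic: float
    pvalue: float
    n_nsn: int
    n_sn: int
    method: str


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization).

    Transcripts with a zero in any sample are excluded from the reference
    geometric mean; if none remain, total-count ratios are used instead.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() == 0:
        logger.warning("size_factors: no all-positive transcripts; falling back to library-size ratios")
        totals = arr.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(sf, index=counts.columns, name="size_factor")
    sub = arr[positive]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def detected_transcripts(m: CountMatrix, min_count: int = 1) -> pd.Series:
    """Per-sample number of transcripts with count >= ``min_count``."""
    if m.counts.shape[0] == 0:
        raise InsufficientDataError("empty count matrix")
    return (m.counts >= min_count).sum(axis=0).rename("n_detected")


def depth_matched_comparison(detected: pd.Series, meta: pd.DataFrame,
                             band: tuple[float, float],
                             stages: tuple[str, str] = ("NSN", "SN")) -> RankSumResult:
    """Wilcoxon rank-sum on detected-transcript counts, restricted to samples
    whose total reads fall inside ``band`` (inclusive).

    Exact null distribution for group sizes <= 25, otherwise the normal
    approximation with continuity correction.
    """
    lo, hi = band
    in_band = (meta["total_reads"] >= lo) & (meta["total_reads"] <= hi)
    groups = []
    for st in stages:
        ids = meta.index[(meta["stage"] == st) & in_band]
        vals = detected.reindex(ids).dropna().to_numpy()
        if len(vals) == 0:
            raise InsufficientDataError(
                f"no '{st}' samples with total reads in [{lo}, {hi}]")
        groups.append(vals)
    method = "exact" if max(len(g) for g in groups) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue),
                         len(groups[0]), len(groups[1]), method)


def sn_missing_filter(m: CountMatrix, nsn_min_frac: float = 7 / 9,
                      sn_zero_frac: float = 10 / 16) -> list[str]:
    """Transcripts detected in most NSN cells but absent from most SN cells.

    A transcript passes when it has >=1 count in at least
    ceil(nsn_min_frac * n_NSN) NSN samples and exactly 0 counts in at least
    ceil(sn_zero_frac * n_SN) SN samples (the 7/9 and 10/16 rule generalized
    to fractions).  Output preserves the matrix row order.
    """
    m.require_groups()
    nsn = m.counts[m.samples("NSN")]
    sn = m.counts[m.samples("SN")]
    k_nsn = math.ceil(nsn_min_frac * nsn.shape[1])
    k_sn = math.ceil(sn_zero_frac * sn.shape[1])
    pass_nsn = (nsn >= 1).sum(axis=1) >= k_nsn
    pass_sn = (sn == 0).sum(axis=1) >= k_sn
    return list(m.counts.index[pass_nsn & pass_sn])


def expression_quartiles(m: CountMatrix, stage: str = "NSN") -> pd.Series:
    """Q1..Q4 labels (Q1 lowest) over transcripts expressed in ``stage``.

    Expression = group mean of size-factor-normalized counts; "expressed"
    means >=1 raw count in at least one sample of the group.  Ties are broken
    by transcript row order, and quartile sizes differ by at most one.
    """
    ids = m.samples(stage)
    if not ids:
        raise InsufficientDataError(f"no samples with stage '{stage}'")
    sf = size_factors(m.counts)
    norm = m.counts[ids] / sf[ids]
    expressed = (m.counts[ids] >= 1).any(axis=1)
    means = norm.mean(axis=1)[expressed]
    order = np.argsort(means.to_numpy(), kind="stable")
    n = len(means)
    labels = np.empty(n, dtype=object)
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    for i, r in enumerate(ranks):
        labels[i] = f"Q{r * 4 // n + 1}"
    return pd.Series(labels, index=means.index, name="quartile")


def quartile_bias_test(selected_ids, quartiles: pd.Series) -> ChiSquareResult:
    """Pearson chi-square of the quartile composition of a transcript set
    against the quartile proportions of all expressed transcripts."""
    qs = ["Q1", "Q2", "Q3", "Q4"]
    labelled = quartiles.reindex([t for t in selected_ids]).dropna()
    if len(labelled) == 0:
        raise InsufficientDataError("no selected transcript carries a quartile label")
    observed = np.array([(labelled == q).sum() for q in qs], dtype=float)
    base = np.array([(quartiles == q).sum() for q in qs], dtype=float)
    expected = len(labelled) * base / base.sum()
    if (expected == 0).any():
        raise InsufficientDataError(
            "expected count of 0 in a quartile cell; pool quartiles before testing")
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = len(qs) - 1
    return ChiSquareResult(statistic, df, float(stats.chi2.sf(statistic, df)),
                           observed, expected)


def overdispersion_compare(m: CountMatrix, q_threshold: float = 0.05,
                           stages: tuple[str, str] = ("NSN", "SN")) -> dict[str, list[str]]:
    """Per-stage over-dispersed transcript screen.

    Within each group, a log-log linear mean-CV^2 trend is fitted across
    transcripts on normalized counts; each transcript's variance is compared
    to its trend expectation with the scaled chi-square statistic
    (n-1) * s^2 / sigma_trend^2 ~ chi^2_{n-1}, upper tail, BH-adjusted.
    Transcripts with degenerate (zero) variance or zero mean are skipped.
    """
    out: dict[str, list[str]] = {}
    sf = size_factors(m.counts)
    for st in stages:
        ids = m.samples(st)
        if len(ids) < 3:
            raise InsufficientDataError(f"over-dispersion screen needs >=3 '{st}' samples")
        norm = (m.counts[ids] / sf[ids]).to_numpy(dtype=float)
        n = norm.shape[1]
        mean = norm.mean(axis=1)
        var = norm.var(axis=1, ddof=1)
        usable = (mean > 0) & (var > 0)
        cv2 = var[usable] / mean[usable] ** 2
        x = np.log(mean[usable])
        coef = np.polyfit(x, np.log(cv2), 1)
        sigma2 = np.exp(np.polyval(coef, x)) * mean[usable] ** 2
        statistic = (n - 1) * var[usable] / sigma2
        pvals = stats.chi2.sf(statistic, n - 1)
        reject, _, _, _ = multipletests(pvals, alpha=q_threshold, method="fdr_bh")
        out[st] = list(m.counts.index[usable][reject])
    return out


# ---------------------------------------------------------------------------
# negative-binomial differential expression
# ---------------------------------------------------------------------------

def _trended_dispersion(norm: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Per-transcript NB dispersion from a 1/mean method-of-moments trend.

    Within-group moments avoid inflating dispersion with the condition
    effect; the trend alpha(mu) = a0 + a1/mu is fitted by least squares over
    transcripts with informative moments and clipped to be non-negative.
    """
    means = np.stack([norm[:, idx].mean(axis=1) for idx in group_idx])
    vars_ = np.stack([norm[:, idx].var(axis=1, ddof=1) for idx in group_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = (vars_ - means) / means ** 2
    weights = np.stack([np.full(norm.shape[0], len(idx) - 1.0) for idx in group_idx])
    ok = np.isfinite(alpha_hat)
    alpha_mom = np.where(ok, alpha_hat, 0.0)
    w = np.where(ok, weights, 0.0)
    with np.errstate(invalid="ignore"):
        alpha_t = (alpha_mom * w).sum(axis=0) / np.maximum(w.sum(axis=0), 1e-12)
    base_mean = norm.mean(axis=1)
    fit_mask = (base_mean > 1.0) & np.isfinite(alpha_t)
    a0, a1 = 0.01, 1.0
    if fit_mask.sum() >= 10:
        u = 1.0 / base_mean[fit_mask]
        y = alpha_t[fit_mask]
        A = np.column_stack([np.ones(u.size), u])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
    return np.maximum(a0 + a1 / np.maximum(base_mean, 1e-8), 1e-8)


def _nb_glm_wald(y: np.ndarray, x: np.ndarray, sf: np.ndarray,
                 alpha: np.ndarray, tol: float = 1e-10,
                 max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Fisher scoring for the NB GLM log mu = log sf + b0 + b1*x.

    Returns (b1, se_b1) in natural-log units; the scoring weight is
    W = mu / (1 + alpha*mu).  Coefficients are clamped at |b1| <= 10*ln2.
    """
    g, s = y.shape
    log_sf = np.log(sf)
    cap = _MAX_ABS_LFC * math.log(2.0)
    norm = y / sf
    m0 = np.maximum(norm[:, x == 0].mean(axis=1), 1e-8)
    m1 = np.maximum(norm[:, x == 1].mean(axis=1), 1e-8)
    b0 = np.log(m0)
    b1 = np.clip(np.log(m1) - np.log(m0), -cap, cap)
    for _ in range(max_iter):
        eta = log_sf[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -60, 60))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (b0[:, None] + b1[:, None] * x[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x * z).sum(axis=1)
        det = sw * swxx - swx ** 2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        new_b0 = (swxx * swz - swx * swxz) / det
        new_b1 = (sw * swxz - swx * swz) / det
        new_b1 = np.clip(new_b1, -cap, cap)
        new_b0 = np.clip(new_b0, -60, 60)
        delta = max(np.max(np.abs(new_b0 - b0)), np.max(np.abs(new_b1 - b1)))
        b0, b1 = new_b0, new_b1
        if delta < tol:
            break
    eta = log_sf[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -60, 60))
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    det = np.maximum(sw * swxx - swx ** 2, 1e-300)
    se_b1 = np.sqrt(sw / det)
    return b1, se_b1


def differential_expression(m: CountMatrix, stages: tuple[str, str] = ("NSN", "SN"),
                            shrink: bool = True) -> pd.DataFrame:
    """Negative-binomial Wald differential expression, ``stages[1]`` vs
    ``stages[0]`` (positive LFC = higher in the second stage).

    Steps: median-of-ratios size factors; trended method-of-moments
    dispersion; per-transcript NB GLM with the stage indicator as the single
    covariate; two-sided Wald p; BH adjustment; optional normal-prior
    shrinkage of the fold change.  All-zero transcripts are dropped with a
    log notice.  Rows are sorted by padj, then |LFC| descending, then id.
    """
    m.require_groups(stages, min_n=2)
    ids = m.samples(stages[0]) + m.samples(stages[1])
    x = np.array([0] * len(m.samples(stages[0])) + [1] * len(m.samples(stages[1])), dtype=float)
    counts = m.counts[ids]
    nonzero = counts.sum(axis=1) > 0
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("differential_expression: dropped %d all-zero transcripts", dropped)
    counts = counts[nonzero]
    y = counts.to_numpy(dtype=float)
    sf = size_factors(counts).to_numpy()
    norm = y / sf
    group_idx = [np.flatnonzero(x == 0), np.flatnonzero(x == 1)]
    alpha = _trended_dispersion(norm, group_idx)
    b1, se = _nb_glm_wald(y, x, sf, alpha)
    lfc = b1 / math.log(2.0)
    zstat = b1 / se
    pvalue = 2.0 * stats.norm.sf(np.abs(zstat))
    _, padj, _, _ = multipletests(pvalue, method="fdr_bh")
    table = pd.DataFrame({
        "transcript": counts.index,
        "baseMean": norm.mean(axis=1),
        "lfc": lfc,
        "se": se / math.log(2.0),
        "pvalue": pvalue,
        "padj": padj,
    })
    if shrink:
        # normal-prior width matched to the upper quantile of well-estimated
        # fold changes (robust to the huge SEs of low-expression transcripts)
        solid = table["baseMean"] > np.median(table["baseMean"])
        if solid.sum() < 10:
            solid = pd.Series(True, index=table.index)
        tau = float(np.quantile(np.abs(table.loc[solid, "lfc"]), 0.90)) / 1.645
        tau2 = max(tau * tau, 1e-6)
        table["lfc_shrunk"] = table["lfc"] * tau2 / (tau2 + table["se"] ** 2)
    else:
        table["lfc_shrunk"] = table["lfc"]
    table["direction"] = np.sign(table["lfc"]).astype(int)
    table = table.sort_values(
        by=["padj", "lfc", "transcript"],
        key=lambda col: -col.abs() if col.name == "lfc" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    return table
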