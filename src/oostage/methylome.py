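"""Single-cell bisulfite QC, methylation domains and consensus DMR calling.

The DMR procedure works on pre-defined methylation domains (unmethylated
0-25%, methylated 70-100%, intermediate in between).  Because single-cell
bisulfite coverage is sparse (each cell observes only 10-22% of CpGs),
cells are pooled into pseudobulk groups: per iteration, three random
disjoint groups of four oocytes per stage are drawn, each domain covered in
all six groups is tested with a binomial (logit-link) regression of the
grouped methylated/unmethylated counts on stage, and a domain is called in
that iteration when the two-sided p-value is below alpha AND the pooled
NSN-SN difference strictly exceeds the difference threshold (10 percentage
points by default).  One hundred iterations with fresh groupings are run
and domains called with a consistent sign in at least half of the testable
iterations form the consensus DMR set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InsufficientDataError
from .intervals import overlaps_any, validate_intervals

logger = logging.getLogger("oostage.methylome")

DOMAIN_CLASSES = ("unmethylated", "intermediate", "methylated")


@dataclass
class MethCallSet:
    """One cell's sparse cytosine calls plus library QC statistics.

    ``calls``: DataFrame with columns chrom, pos (0-based), context
    ("CpG"/"non-CpG"), meth, unmeth.  Counts may be fractional in the
    generator's expectation mode.  ``stats`` carries at least
    ``mapping_efficiency`` (percent) and ``n_cpgs`` (distinct CpGs covered).
    """

    cell_id: str
    stage: str
    calls: pd.DataFrame
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.calls
        needed = {"chrom", "pos", "context", "meth", "unmeth"}
        if not needed.issubset(c.columns):
            raise ConfigError(f"MethCallSet {self.cell_id}: missing columns {needed - set(c.columns)}")
        if (c["meth"] < 0).any() or (c["unmeth"] < 0).any():
            raise ConfigError(f"MethCallSet {self.cell_id}: negative counts")
        if ((c["meth"] + c["unmeth"]) <= 0).any():
            raise ConfigError(f"MethCallSet {self.cell_id}: call with zero total count")

    def context_calls(self, context: str) -> pd.DataFrame:
        return self.calls[self.calls["context"] == context]


@dataclass
class QCReport:
    table: pd.DataFrame
    n_input: int
    n_pass: int


def global_methylation(cell: MethCallSet, context: str = "CpG") -> float:
    """Percent methylation over all calls in a context; NaN when no call."""
    sub = cell.context_calls(context)
    total = float(sub["meth"].sum() + sub["unmeth"].sum())
    if total == 0:
        logger.warning("global_methylation: %s has no %s calls", cell.cell_id, context)
        return float("nan")
    return 100.0 * float(sub["meth"].sum()) / total


def qc_filter(cells: list[MethCallSet], min_mapping: float = 10.0,
              min_cpgs: int = 500_000,
              noncpg_bounds: tuple[float, float | None] = (1.0, None)
              ) -> tuple[list[MethCallSet], QCReport]:
    """Library-level QC: strict thresholds on mapping efficiency (>10%) and
    distinct CpGs covered (>500,000), plus a somatic-contamination flag for
    cells whose global non-CpG methylation is below the lower bound (very
    low non-CpG methylation with correspondingly high CpG methylation is the
    signature of somatic-cell contamination)."""
    rows = []
    passing = []
    lower, upper = noncpg_bounds
    for cell in cells:
        mapping = float(cell.stats.get("mapping_efficiency", float("nan")))
        n_cpgs = float(cell.stats.get("n_cpgs", float("nan")))
        noncpg = global_methylation(cell, "non-CpG")
        ok_map = mapping > min_mapping
        ok_cov = n_cpgs > min_cpgs
        contaminated = (not math.isnan(noncpg)) and (noncpg < lower)
        if upper is not None and not math.isnan(noncpg):
            contaminated = contaminated or noncpg > upper
        verdict = ok_map and ok_cov and not contaminated
        rows.append({
            "cell_id": cell.cell_id, "stage": cell.stage,
            "mapping_efficiency": mapping, "n_cpgs": n_cpgs,
            "noncpg_pct": noncpg, "pass_mapping": ok_map,
            "pass_coverage": ok_cov, "contamination_flag": contaminated,
            "pass": verdict,
        })
        if verdict:
            passing.append(cell)
    report = QCReport(pd.DataFrame(rows), len(cells), len(passing))
    if not passing:
        logger.warning("qc_filter: no cell passed QC")
    return passing, report


def segment_domains(windows: pd.DataFrame, low: float = 25.0,
                    high: float = 70.0) -> pd.DataFrame:
    """Segment a pooled methylation tiling into methylation domains.

    ``windows``: chrom, start, end, meth (percent; NaN = uncovered).
    Windows below ``low`` form unmethylated domains, above ``high``
    methylated domains, the rest intermediate; contiguous same-class runs
    merge (uncovered windows break runs and are not covered by any domain).
    Merging is idempotent, so the classes partition the covered territory.
    """
    if low >= high:
        raise ConfigError(f"segment_domains: low ({low}) must be < high ({high})")
    windows = validate_intervals(windows, "windows")
    rows = []
    for chrom, sub in windows.groupby("chrom", sort=True):
        prev_class, prev_end, cur_start = None, None, None
        for start, end, meth in zip(sub["start"], sub["end"], sub["meth"]):
            if pd.isna(meth):
                cls = None
            elif meth < low:
                cls = "unmethylated"
            elif meth > high:
                cls = "methylated"
            else:
                cls = "intermediate"
            contiguous = prev_end is not None and start == prev_end
            if cls == prev_class and cls is not None and contiguous:
                prev_end = end
                continue
            if prev_class is not None:
                rows.append((chrom, cur_start, prev_end, prev_class))
            prev_class, cur_start, prev_end = cls, start, end
        if prev_class is not None:
            rows.append((chrom, cur_start, prev_end, prev_class))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])


def pseudobulk_groups(cells: list[MethCallSet], group_size: int = 4,
                      n_groups: int = 3, seed: int = 0,
                      stages: tuple[str, str] = ("NSN", "SN")) -> dict[str, list[list[str]]]:
    """Random disjoint pseudobulk groups per stage (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    need = group_size * n_groups
    out: dict[str, list[list[str]]] = {}
    for st in stages:
        ids = [c.cell_id for c in cells if c.stage == st]
        if len(ids) < need:
            raise InsufficientDataError(
                f"pseudobulk_groups: stage '{st}' has {len(ids)} cells, needs >= {need}")
        chosen = rng.permutation(ids)[:need]
        out[st] = [list(chosen[i * group_size:(i + 1) * group_size]) for i in range(n_groups)]
    return out


def cell_domain_counts(cells: list[MethCallSet], domains: pd.DataFrame,
                       context: str = "CpG") -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-cell per-domain pooled (meth, total) count matrices.

    Returns (meth, total) arrays of shape (n_cells, n_domains) and the
    genome-sorted domain frame the columns refer to.  This is the shared
    precomputation behind the iterative DMR procedure.
    """
    domains = validate_intervals(domains, "domains")
    by_chrom = {}
    for chrom, sub in domains.groupby("chrom", sort=False):
        by_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                           sub.index.to_numpy())
    n_dom = len(domains)
    meth = np.zeros((len(cells), n_dom))
    total = np.zeros((len(cells), n_dom))
    for ci, cell in enumerate(cells):
        calls = cell.context_calls(context)
        for chrom, sub in calls.groupby("chrom", sort=False):
            if chrom not in by_chrom:
                continue
            ds, de, didx = by_chrom[chrom]
            pos = sub["pos"].to_numpy()
            j = np.searchsorted(ds, pos, side="right") - 1
            inside = (j >= 0) & (pos < de[np.clip(j, 0, len(de) - 1)])
            tgt = didx[j[inside]]
            np.add.at(meth[ci], tgt, sub["meth"].to_numpy()[inside])
            np.add.at(total[ci], tgt,
                      (sub["meth"] + sub["unmeth"]).to_numpy()[inside])
    return meth, total, domains


def domain_methylation(group: list[MethCallSet], domains: pd.DataFrame,
                       min_calls: int = 10) -> pd.DataFrame:
    """Pooled percent methylation per domain for one pseudobulk group.

    Domains with fewer than ``min_calls`` pooled observations are marked
    uncovered (NaN percent).
    """
    meth, total, domains = cell_domain_counts(group, domains)
    m = meth.sum(axis=0)
    t = total.sum(axis=0)
    covered = t >= min_calls
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(covered, 100.0 * m / np.where(t > 0, t, 1), np.nan)
    out = domains.copy()
    out["meth_calls"] = m
    out["total_calls"] = t
    out["covered"] = covered
    out["pct"] = pct
    return out


def binomial_glm_test(nsn_meth, nsn_unmeth, sn_meth, sn_unmeth):
    """Two-sided Wald test from the binomial GLM (logit link) with stage as
    the single predictor, vectorized over domains.

    With stage as the only covariate the GLM MLE is saturated in stage, so
    the Wald statistic reduces exactly to the pooled log-odds-ratio z test:
    beta = logit(p_SN) - logit(p_NSN), se = sqrt(1/m1 + 1/u1 + 1/m2 + 1/u2).
    Perfect-separation cells (a zero margin) fall back to the Fisher exact
    test on the pooled 2x2 table, with a log notice.
    """
    m1 = np.atleast_1d(np.asarray(nsn_meth, dtype=float))
    u1 = np.atleast_1d(np.asarray(nsn_unmeth, dtype=float))
    m2 = np.atleast_1d(np.asarray(sn_meth, dtype=float))
    u2 = np.atleast_1d(np.asarray(sn_unmeth, dtype=float))
    sep = (m1 == 0) | (u1 == 0) | (m2 == 0) | (u2 == 0)
    pvalue = np.ones(m1.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.log(m2 / u2) - np.log(m1 / u1)
        se = np.sqrt(1 / m1 + 1 / u1 + 1 / m2 + 1 / u2)
        z = np.where(sep, 0.0, beta / se)
    pvalue[~sep] = 2.0 * stats.norm.sf(np.abs(z[~sep]))
    if sep.any():
        logger.debug("binomial_glm_test: Fisher fallback for %d separated domains", int(sep.sum()))
        for i in np.flatnonzero(sep):
            table = np.round([[m1[i], u1[i]], [m2[i], u2[i]]]).astype(int)
            pvalue[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    return pvalue


def _iteration_from_counts(group_meth: np.ndarray, group_total: np.ndarray,
                           n_groups: int, diff_threshold: float, alpha: float,
                           min_calls: float) -> pd.DataFrame:
    """One DMR iteration from stacked (2*n_groups, n_domains) count arrays;
    NSN groups first."""
    testable = (group_total >= min_calls).all(axis=0)
    nsn_m = group_meth[:n_groups].sum(axis=0)
    nsn_t = group_total[:n_groups].sum(axis=0)
    sn_m = group_meth[n_groups:].sum(axis=0)
    sn_t = group_total[n_groups:].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_nsn = 100.0 * nsn_m / np.where(nsn_t > 0, nsn_t, 1)
        p_sn = 100.0 * sn_m / np.where(sn_t > 0, sn_t, 1)
    diff = p_sn - p_nsn
    pvalue = np.ones(diff.shape)
    idx = np.flatnonzero(testable)
    if idx.size:
        pvalue[idx] = binomial_glm_test(nsn_m[idx], nsn_t[idx] - nsn_m[idx],
                                        sn_m[idx], sn_t[idx] - sn_m[idx])
    called = testable & (pvalue < alpha) & (np.abs(diff) > diff_threshold)
    return pd.DataFrame({
        "testable": testable, "pvalue": pvalue, "diff": diff,
        "called": called, "sign": np.sign(diff).astype(int),
    })


def dmr_iteration(nsn_groups: list[list[MethCallSet]],
                  sn_groups: list[list[MethCallSet]],
                  domains: pd.DataFrame, diff_threshold: float = 10.0,
                  alpha: float = 0.05, min_calls: int = 10) -> pd.DataFrame:
    """Single-iteration differential-methylation calls over domains.

    The pooled NSN-SN difference must strictly exceed ``diff_threshold``
    percentage points ("more than 10%") in addition to GLM significance.
    """
    cells = [c for g in nsn_groups for c in g] + [c for g in sn_groups for c in g]
    meth, total, domains = cell_domain_counts(cells, domains)
    sizes = [len(g) for g in nsn_groups + sn_groups]
    bounds = np.cumsum([0] + sizes)
    gm = np.stack([meth[bounds[i]:bounds[i + 1]].sum(axis=0) for i in range(len(sizes))])
    gt = np.stack([total[bounds[i]:bounds[i + 1]].sum(axis=0) for i in range(len(sizes))])
    res = _iteration_from_counts(gm, gt, len(nsn_groups), diff_threshold, alpha, min_calls)
    return pd.concat([domains.reset_index(drop=True), res], axis=1)


def consensus_dmrs(iteration_calls: list[pd.DataFrame], domains: pd.DataFrame,
                   consensus: float = 0.5, diff_threshold: float = 10.0,
                   pooled_pct: pd.DataFrame | None = None) -> pd.DataFrame:
    """Consensus DMR table over completed iterations.

    A domain enters the table when it was called with a consistent (dominant)
    sign in at least ``consensus`` of the iterations in which it was
    testable.  ``mean_diff`` averages the NSN-SN difference over the calling
    iterations, so |mean_diff| strictly exceeds the difference threshold.
    """
    if not iteration_calls:
        raise InsufficientDataError("consensus_dmrs: no completed iterations")
    domains = validate_intervals(domains, "domains")
    n_dom = len(domains)
    n_testable = np.zeros(n_dom, dtype=int)
    n_hyper = np.zeros(n_dom, dtype=int)
    n_hypo = np.zeros(n_dom, dtype=int)
    sum_hyper = np.zeros(n_dom)
    sum_hypo = np.zeros(n_dom)
    for it in iteration_calls:
        n_testable += it["testable"].to_numpy().astype(int)
        hyper = (it["called"] & (it["sign"] > 0)).to_numpy()
        hypo = (it["called"] & (it["sign"] < 0)).to_numpy()
        n_hyper += hyper
        n_hypo += hypo
        d = it["diff"].to_numpy()
        sum_hyper += np.where(hyper, d, 0.0)
        sum_hypo += np.where(hypo, d, 0.0)
    dominant_hyper = n_hyper >= n_hypo
    n_dom_calls = np.where(dominant_hyper, n_hyper, n_hypo)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_testable > 0, n_dom_calls / np.maximum(n_testable, 1), 0.0)
        mean_diff = np.where(dominant_hyper,
                             sum_hyper / np.maximum(n_hyper, 1),
                             sum_hypo / np.maximum(n_hypo, 1))
    keep = (n_testable > 0) & (n_dom_calls > 0) & (frac >= consensus)
    out = domains.loc[keep].copy()
    out["consensus_fraction"] = frac[keep]
    out["mean_diff"] = mean_diff[keep]
    out["n_testable"] = n_testable[keep]
    out["dmr_class"] = np.where(dominant_hyper[keep], "hyper_in_SN", "hypo_in_SN")
    if pooled_pct is not None:
        out["nsn_pct"] = pooled_pct["nsn_pct"].to_numpy()[keep]
        out["sn_pct"] = pooled_pct["sn_pct"].to_numpy()[keep]
    return out.reset_index(drop=True)


def call_consensus_dmrs(cells: list[MethCallSet], domains: pd.DataFrame,
                        n_iter: int = 100, group_size: int = 4, n_groups: int = 3,
                        diff_threshold: float = 10.0, alpha: float = 0.05,
                        min_calls: int = 10, consensus: float = 0.5,
                        seed: int = 0) -> pd.DataFrame:
    """End-to-end iterative pseudobulk consensus DMR calling.

    Iteration i draws fresh pseudobulk groups with sub-seed (seed, i), so
    any iteration is independently reproducible.  Cell-by-domain counts are
    precomputed once; each iteration only re-pools rows.
    """
    nsn = [c for c in cells if c.stage == "NSN"]
    sn = [c for c in cells if c.stage == "SN"]
    need = group_size * n_groups
    for st, group in (("NSN", nsn), ("SN", sn)):
        if len(group) < need:
            raise InsufficientDataError(
                f"call_consensus_dmrs: stage '{st}' has {len(group)} cells, needs >= {need}")
    ordered = nsn + sn
    meth, total, domains = cell_domain_counts(ordered, domains)
    n_nsn = len(nsn)
    calls = []
    for i in range(n_iter):
        rng = np.random.default_rng([seed, i])
        pick_nsn = rng.permutation(n_nsn)[:need]
        pick_sn = n_nsn + rng.permutation(len(sn))[:need]
        rows = []
        for g in range(n_groups):
            rows.append(pick_nsn[g * group_size:(g + 1) * group_size])
        for g in range(n_groups):
            rows.append(pick_sn[g * group_size:(g + 1) * group_size])
        gm = np.stack([meth[r].sum(axis=0) for r in rows])
        gt = np.stack([total[r].sum(axis=0) for r in rows])
        calls.append(_iteration_from_counts(gm, gt, n_groups, diff_threshold,
                                            alpha, min_calls))
    all_m_nsn = meth[:n_nsn].sum(axis=0)
    all_t_nsn = total[:n_nsn].sum(axis=0)
    all_m_sn = meth[n_nsn:].sum(axis=0)
    all_t_sn = total[n_nsn:].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = pd.DataFrame({
            "nsn_pct": 100.0 * all_m_nsn / np.where(all_t_nsn > 0, all_t_nsn, np.nan),
            "sn_pct": 100.0 * all_m_sn / np.where(all_t_sn > 0, all_t_sn, np.nan),
        })
    return consensus_dmrs(calls, domains, consensus=consensus,
                          diff_threshold=diff_threshold, pooled_pct=pooled)


@dataclass
class EnrichmentResult:
    odds_ratio: float
    log2_fold_enrichment: float
    pvalue: float
    query_overlap: int
    query_total: int
    random_overlap_mean: float
    notes: list = field(default_factory=list)


def feature_enrichment(dmrs: pd.DataFrame, feature: pd.DataFrame,
                       universe: pd.DataFrame, n_random: int = 1000,
                       seed: int = 0) -> EnrichmentResult:
    """Overlap enrichment of a DMR set with a genomic feature set, against
    count-matched random domain draws from the universe.

    Fisher's exact test is computed on the 2x2 table of
    (query vs pooled random draws) x (overlaps feature vs not); the log2
    fold enrichment compares the query overlap fraction with the mean
    random overlap fraction over ``n_random`` seeded draws.  Zero margins
    get the Haldane-Anscombe 0.5 correction (logged).
    """
    dmrs = validate_intervals(dmrs, "dmrs")
    feature = validate_intervals(feature, "feature")
    universe = validate_intervals(universe, "universe")
    if len(dmrs) == 0 or len(universe) < len(dmrs):
        raise InsufficientDataError("feature_enrichment: universe must contain the query")
    rng = np.random.default_rng(seed)
    q_hit = int(overlaps_any(dmrs, feature).sum())
    n_q = len(dmrs)
    uni_hits = overlaps_any(universe, feature)
    r_hit_total = 0
    for _ in range(n_random):
        draw = rng.choice(len(universe), size=n_q, replace=False)
        r_hit_total += int(uni_hits[draw].sum())
    r_mean_frac = r_hit_total / (n_random * n_q)

    # random column on the per-draw scale (count-matched to the query, as a
    # LOLA-style random background set of the same size)
    r_hit = r_mean_frac * n_q
    table = np.array([[q_hit, n_q - q_hit],
                      [r_hit, n_q - r_hit]], dtype=float)
    notes = []
    if (table == 0).any():
        table = table + 0.5
        notes.append("Haldane-Anscombe 0.5 correction applied")
        logger.info("feature_enrichment: %s", notes[-1])
    odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    _, pvalue = stats.fisher_exact(np.round(table).astype(int), alternative="two-sided")
    q_frac = q_hit / n_q if q_hit > 0 else 0.5 / n_q
    r_frac = r_mean_frac if r_mean_frac > 0 else 0.5 / n_q
    log2fe = math.log2(q_frac / r_frac)
    return EnrichmentResult(float(odds), float(log2fe), float(pvalue),
                            q_hit, n_q, r_mean_frac, notes)
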