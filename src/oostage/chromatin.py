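"""Histone-mark window quantification and joint chromatin categories.

A genome is tiled into fixed-width (default 2 kb) windows carrying RPKM for
H3K4me3, H3K27me3 and H3K36me3 plus a 10%-input control.  Windows whose
input RPKM falls outside [0.04, 2] are dropped as unmappable/artefactual;
remaining windows are "enriched" for a mark when its RPKM exceeds 1
(strictly) and assigned the exact combination of enriched marks, one of
seven named joint categories or "none".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InsufficientDataError
from .intervals import merge_intervals, sample_intervals, validate_intervals

logger = logging.getLogger("oostage.chromatin")

MARKS = ("H3K4me3", "H3K27me3", "H3K36me3")

# Canonical category names: the exact combination of enriched marks.
CATEGORIES = (
    "H3K4me3+H3K27me3",
    "H3K4me3",
    "H3K27me3",
    "H3K36me3+H3K4me3+H3K27me3",
    "H3K36me3+H3K4me3",
    "H3K36me3+H3K27me3",
    "H3K36me3",
    "none",
)

CATEGORY_MARKS: dict[str, frozenset] = {
    "H3K4me3+H3K27me3": frozenset({"H3K4me3", "H3K27me3"}),
    "H3K4me3": frozenset({"H3K4me3"}),
    "H3K27me3": frozenset({"H3K27me3"}),
    "H3K36me3+H3K4me3+H3K27me3": frozenset(MARKS),
    "H3K36me3+H3K4me3": frozenset({"H3K36me3", "H3K4me3"}),
    "H3K36me3+H3K27me3": frozenset({"H3K36me3", "H3K27me3"}),
    "H3K36me3": frozenset({"H3K36me3"}),
    "none": frozenset(),
}

_COMBO_TO_NAME = {marks: name for name, marks in CATEGORY_MARKS.items()}


@dataclass
class CategoryEnrichment:
    """Per-category composition of a query interval set vs a random set."""

    table: pd.DataFrame  # index category: query_count, query_frac, random_frac, log2fe
    statistic: float
    df: int
    pvalue: float
    n_query_windows: int = 0
    n_random_draws: int = 0
    notes: list = field(default_factory=list)


def window_rpkm(counts: np.ndarray, library_total: float, width: int = 2000) -> np.ndarray:
    """Reads per kilobase of window per million mapped reads."""
    if library_total <= 0:
        raise ConfigError("window_rpkm: library_total must be > 0")
    counts = np.asarray(counts, dtype=float)
    return counts / (width / 1000.0) / (library_total / 1e6)


def filter_windows(track: pd.DataFrame, input_low: float = 0.04,
                   input_high: float = 2.0) -> pd.Series:
    """Validity mask from the input control: exclusion is strict, so windows
    at exactly ``input_low`` or ``input_high`` RPKM are retained."""
    inp = track["input_rpkm"]
    return ((inp >= input_low) & (inp <= input_high)).rename("valid")


def assign_categories(track: pd.DataFrame, enrich_threshold: float = 1.0,
                      input_low: float = 0.04, input_high: float = 2.0) -> pd.DataFrame:
    """Mark-enrichment flags and joint category per valid window.

    A mark is enriched when RPKM strictly exceeds ``enrich_threshold``
    (exactly 1.0 is *not* enriched).  Invalid windows get a null category.
    Idempotent: re-running on its own output gives identical labels.
    """
    out = track.copy()
    out["valid"] = filter_windows(out, input_low, input_high)
    enriched = {mark: out[mark].to_numpy() > enrich_threshold for mark in MARKS}
    code = (enriched["H3K4me3"].astype(int)
            + 2 * enriched["H3K27me3"].astype(int)
            + 4 * enriched["H3K36me3"].astype(int))
    name_by_code = np.empty(8, dtype=object)
    for c in range(8):
        combo = frozenset(m for bit, m in zip((1, 2, 4), MARKS) if c & bit)
        name_by_code[c] = _COMBO_TO_NAME[combo]
    out["category"] = pd.Series(name_by_code[code], index=out.index).where(out["valid"], other=pd.NA)
    return out


def windows_overlapping(track: pd.DataFrame, query: pd.DataFrame) -> np.ndarray:
    """Boolean mask over track rows: window overlaps >=1 query interval."""
    merged = merge_intervals(query)
    mask = np.zeros(len(track), dtype=bool)
    chroms = track["chrom"].to_numpy()
    ws = track["start"].to_numpy()
    we = track["end"].to_numpy()
    for chrom, sub in merged.groupby("chrom", sort=False):
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        s_arr = sub["start"].to_numpy()
        e_arr = sub["end"].to_numpy()
        idx = np.searchsorted(e_arr, ws[sel], side="right")
        ok = idx < len(s_arr)
        cand = np.clip(idx, 0, len(s_arr) - 1)
        mask[sel] = ok & (s_arr[cand] < we[sel])
    return mask


def category_by_domain(track: pd.DataFrame, domains: pd.DataFrame):
    """Composition of each joint category across methylation-domain classes.

    A window belongs to the domain containing its midpoint.  Returns the
    (category x class) percentage table and the Pearson chi-square (no
    continuity correction) on the count contingency table; categories with
    zero windows are dropped from the test with a log notice.
    """
    domains = validate_intervals(domains, "domains")
    if "class" not in domains.columns:
        raise ConfigError("category_by_domain: domains need a 'class' column")
    valid = track.dropna(subset=["category"])
    mid = ((valid["start"] + valid["end"]) // 2).to_numpy()
    chroms = valid["chrom"].to_numpy()
    labels = np.full(len(valid), None, dtype=object)
    for chrom, sub in domains.groupby("chrom", sort=False):
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        ds = sub["start"].to_numpy()
        de = sub["end"].to_numpy()
        cls = sub["class"].to_numpy()
        pos = np.searchsorted(ds, mid[sel], side="right") - 1
        inside = (pos >= 0) & (mid[sel] < de[np.clip(pos, 0, len(de) - 1)])
        labels[sel[inside]] = cls[pos[inside]]
    assigned = pd.DataFrame({
        "category": valid["category"].to_numpy(),
        "class": labels,
    }).dropna()
    table = pd.crosstab(assigned["category"], assigned["class"])
    empty = [c for c in CATEGORIES if c not in table.index or table.loc[c].sum() == 0]
    if empty:
        logger.info("category_by_domain: categories without windows dropped: %s", empty)
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise InsufficientDataError("contingency table too small for a chi-square test")
    statistic, pvalue, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    pct = table.div(table.sum(axis=1), axis=0) * 100.0
    return pct, ChiLike(statistic=float(statistic), df=int(df), pvalue=float(pvalue), counts=table)


@dataclass
class ChiLike:
    statistic: float
    df: int
    pvalue: float
    counts: pd.DataFrame = None


def dmr_category_enrichment(track: pd.DataFrame, query: pd.DataFrame,
                            n_random: int = 100, seed: int = 0) -> CategoryEnrichment:
    """Joint-category enrichment of windows inside a query interval set
    against count- and length-matched random intervals.

    Random intervals inherit the query's length distribution (permuted) and
    are placed uniformly over the merged valid-window territory; only valid
    windows are tallied, so overhang into excluded territory is harmless.
    log2 fold enrichment = log2(query fraction / mean random fraction), with
    a Haldane-style 0.5 pseudo-count on empty cells (logged).
    """
    query = validate_intervals(query, "query")
    valid = track.dropna(subset=["category"])
    if len(valid) == 0:
        raise InsufficientDataError("no valid categorized windows in track")
    qmask = windows_overlapping(valid, query)
    if qmask.sum() == 0:
        raise InsufficientDataError("query intervals overlap no valid window")
    qcounts = valid.loc[qmask, "category"].value_counts().reindex(CATEGORIES, fill_value=0)

    rng = np.random.default_rng(seed)
    territory = valid[["chrom", "start", "end"]]
    lengths = (query["end"] - query["start"]).to_numpy()
    rcounts = pd.Series(0, index=pd.Index(CATEGORIES), dtype=float)
    for _ in range(n_random):
        rand = sample_intervals(territory, rng.permutation(lengths), rng)
        rmask = windows_overlapping(valid, rand)
        rcounts = rcounts.add(valid.loc[rmask, "category"].value_counts(), fill_value=0)
    rcounts = rcounts.reindex(CATEGORIES, fill_value=0)

    notes = []
    qc = qcounts.to_numpy(dtype=float)
    rc = rcounts.to_numpy(dtype=float)
    zero = (qc == 0) | (rc == 0)
    if zero.any():
        notes.append(f"0.5 pseudo-count applied to categories {list(np.array(CATEGORIES)[zero])}")
        logger.info("dmr_category_enrichment: %s", notes[-1])
    qfrac = (qc + 0.5 * zero) / (qc.sum() + 0.5 * zero.sum())
    rfrac = (rc + 0.5 * zero) / (rc.sum() + 0.5 * zero.sum())
    log2fe = np.log2(qfrac / rfrac)

    cont = np.vstack([qc, rc])
    keep = cont.sum(axis=0) > 0
    statistic, pvalue, df, _ = stats.chi2_contingency(cont[:, keep], correction=False)
    table = pd.DataFrame({
        "query_count": qcounts,
        "query_frac": qc / qc.sum(),
        "random_frac": rc / max(rc.sum(), 1.0),
        "log2fe": log2fe,
    })
    return CategoryEnrichment(table, float(statistic), int(df), float(pvalue),
                              n_query_windows=int(qmask.sum()),
                              n_random_draws=n_random, notes=notes)


def replicate_correlation(tracks: dict[str, pd.DataFrame], mark: str) -> pd.DataFrame:
    """Pairwise Pearson correlation of window RPKM between replicate tracks."""
    names = list(tracks)
    mat = np.column_stack([tracks[n][mark].to_numpy(dtype=float) for n in names])
    return pd.DataFrame(np.corrcoef(mat.T), index=names, columns=names)
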