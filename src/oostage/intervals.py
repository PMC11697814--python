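"""Sorted-interval primitives shared by the genomic modules.

All intervals are 0-based half-open and live in pandas DataFrames with at
least the columns ``chrom``, ``start``, ``end``; extra columns pass through
untouched.  Overlap queries use binary search over per-chromosome sorted,
merged interval arrays, which is exact for arbitrary interval sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError

REQUIRED_COLUMNS = ("chrom", "start", "end")


def validate_intervals(df: pd.DataFrame, name: str = "intervals") -> pd.DataFrame:
    """Check and genome-sort an interval frame; returns a sorted copy."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{name}: missing required column '{col}'")
    if len(df) and (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise FormatError(f"{name}: start >= end at row {bad}")
    if len(df) and (df["chrom"].astype(str).str.len() == 0).any():
        raise FormatError(f"{name}: empty chromosome name")
    out = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return out


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of an interval set: overlapping or book-ended intervals merged."""
    df = validate_intervals(df)
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each query interval overlap >=1 subject interval?

    Order of the result follows the row order of ``query`` as given.
    """
    hit = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return hit
    merged = merge_intervals(subject)
    by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy())
                for c, g in merged.groupby("chrom", sort=False)}
    chroms = query["chrom"].to_numpy()
    qs = query["start"].to_numpy()
    qe = query["end"].to_numpy()
    for chrom in np.unique(chroms):
        if chrom not in by_chrom:
            continue
        s_arr, e_arr = by_chrom[chrom]
        sel = np.flatnonzero(chroms == chrom)
        # first merged interval whose end is > query start
        idx = np.searchsorted(e_arr, qs[sel], side="right")
        ok = idx < len(s_arr)
        cand = np.clip(idx, 0, len(s_arr) - 1)
        hit[sel] = ok & (s_arr[cand] < qe[sel])
    return hit


def sample_intervals(territory: pd.DataFrame, lengths: np.ndarray,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Draw random intervals with the given lengths from a territory.

    Each interval start is placed uniformly within the merged territory
    (segments chosen with probability proportional to their length); the
    interval keeps its requested length and may overhang its segment end.
    """
    terr = merge_intervals(territory)
    seg_len = (terr["end"] - terr["start"]).to_numpy().astype(float)
    probs = seg_len / seg_len.sum()
    seg = rng.choice(len(terr), size=len(lengths), p=probs)
    offset = np.floor(rng.random(len(lengths)) * seg_len[seg]).astype(int)
    starts = terr["start"].to_numpy()[seg] + offset
    return pd.DataFrame({
        "chrom": terr["chrom"].to_numpy()[seg],
        "start": starts,
        "end": starts + np.asarray(lengths, dtype=int),
    })
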