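"""Readers and writers for the plain-text formats used across the package.

Conventions: BED and all internal intervals are 0-based half-open; Bismark
coverage files are 1-based inclusive and converted on read/write.  Count
matrices travel as TSV (transcripts x samples) with a sidecar metadata TSV,
or as MatrixMarket plus row/column name files.  All writers round-trip
through their readers losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .expression import CountMatrix
from .intervals import validate_intervals
from .methylome import MethCallSet

logger = logging.getLogger("oostage.io")

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


def read_bed(path) -> pd.DataFrame:
    """BED3-BED6 reader; returns sorted, validated 0-based intervals."""
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3 or len(parts) > 6:
                raise FormatError(f"{path}:{lineno}: expected 3-6 BED columns, got {len(parts)}")
            if ncols is None:
                ncols = len(parts)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if not parts[0]:
                raise FormatError(f"{path}:{lineno}: empty chromosome name")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rows.append([parts[0], start, end] + parts[3:])
    df = pd.DataFrame(rows, columns=list(BED_COLUMNS[:ncols or 3]))
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return validate_intervals(df, str(path))


def write_bed(df: pd.DataFrame, path, extra_cols: tuple = ()) -> None:
    cols = ["chrom", "start", "end"] + [c for c in ("name", "score", "strand") + tuple(extra_cols)
                                        if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bismark_cov(path, context: str | None = "CpG") -> pd.DataFrame:
    """Bismark-coverage-style TSV (plain or gzip): chrom, start(1-based),
    end, %meth, count_meth, count_unmeth, with an optional 7th context
    column.  Positions come back 0-based; the percent column is
    cross-checked against the counts (tolerance 0.1 points, counts win)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", compression="infer")
    if df.shape[1] not in (6, 7):
        raise FormatError(f"{path}: expected 6 or 7 columns, got {df.shape[1]}")
    names = ["chrom", "start", "end", "pct", "meth", "unmeth"]
    if df.shape[1] == 7:
        names.append("context")
    df.columns = names
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        bad = int(df.index[(df["meth"] < 0) | (df["unmeth"] < 0)][0]) + 1
        raise FormatError(f"{path}: negative count at data line {bad}")
    total = df["meth"] + df["unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        recomputed = 100.0 * df["meth"] / total.where(total > 0)
    mismatch = (recomputed - df["pct"]).abs() > 0.1
    if mismatch.any():
        logger.warning("%s: %%meth column disagrees with counts on %d lines; counts win",
                       path, int(mismatch.sum()))
    out = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "pos": df["start"].astype(int) - 1,
        "context": df["context"] if "context" in df.columns else (context or "CpG"),
        "meth": df["meth"],
        "unmeth": df["unmeth"],
    })
    return out


def write_bismark_cov(calls: pd.DataFrame, path, with_context: bool = True) -> None:
    total = calls["meth"] + calls["unmeth"]
    out = pd.DataFrame({
        "chrom": calls["chrom"],
        "start": calls["pos"].astype(int) + 1,
        "end": calls["pos"].astype(int) + 1,
        "pct": (100.0 * calls["meth"] / total.where(total > 0)).round(6),
        "meth": calls["meth"],
        "unmeth": calls["unmeth"],
    })
    if with_context and "context" in calls.columns:
        out["context"] = calls["context"]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_meth_cells(directory, meta: pd.DataFrame | None = None) -> list[MethCallSet]:
    """Load every ``*.cov``/``*.cov.gz`` in a directory as one cell each;
    stage and library stats come from an optional metadata frame (indexed by
    cell id, columns stage / mapping_efficiency / n_cpgs)."""
    cells = []
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.name.endswith((".cov", ".cov.gz")))
    for p in paths:
        cell_id = p.name.split(".")[0]
        calls = read_bismark_cov(p)
        stats = {}
        stage = "unknown"
        if meta is not None and cell_id in meta.index:
            row = meta.loc[cell_id]
            stage = row.get("stage", "unknown")
            stats = {k: row[k] for k in ("mapping_efficiency", "n_cpgs") if k in row}
        if "n_cpgs" not in stats:
            stats["n_cpgs"] = int((calls["context"] == "CpG").sum())
        cells.append(MethCallSet(cell_id, stage, calls, stats))
    return cells


def read_counts_tsv(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


def write_counts_tsv(m: CountMatrix, counts_path, meta_path) -> None:
    m.counts.to_csv(counts_path, sep="\t")
    m.meta.to_csv(meta_path, sep="\t")


def write_counts_mtx(m: CountMatrix, prefix) -> None:
    """MatrixMarket export: <prefix>.mtx plus row/column name sidecars."""
    from scipy import io as spio
    from scipy import sparse

    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(m.counts.to_numpy()))
    prefix.with_suffix(".transcripts.txt").write_text("\n".join(m.counts.index) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(m.counts.columns) + "\n")
    m.meta.to_csv(prefix.with_suffix(".meta.tsv"), sep="\t")


def read_counts_mtx(prefix) -> CountMatrix:
    from scipy import io as spio

    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray().astype(int)
    transcripts = prefix.with_suffix(".transcripts.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    meta = pd.read_csv(prefix.with_suffix(".meta.tsv"), sep="\t", index_col=0)
    return CountMatrix(pd.DataFrame(mat, index=transcripts, columns=samples), meta)


def read_bedgraph(path, value_name: str = "value") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", value_name])
    return validate_intervals(df, str(path))


def write_bedgraph(df: pd.DataFrame, path, value_col: str) -> None:
    df[["chrom", "start", "end", value_col]].to_csv(path, sep="\t", header=False, index=False)


def write_window_track(track: pd.DataFrame, out_dir, marks=("H3K4me3", "H3K27me3", "H3K36me3")) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for mark in marks:
        write_bedgraph(track, out_dir / f"{mark}.bedgraph", mark)
    write_bedgraph(track, out_dir / "input.bedgraph", "input_rpkm")


def read_window_track(mark_paths: dict, input_path) -> pd.DataFrame:
    """Assemble a window track from per-mark bedGraphs plus the input track;
    all files must tile identical windows."""
    track = None
    for mark, path in mark_paths.items():
        df = read_bedgraph(path, mark)
        if track is None:
            track = df
        else:
            if not (track[["chrom", "start", "end"]].to_numpy()
                    == df[["chrom", "start", "end"]].to_numpy()).all():
                raise FormatError(f"{path}: window tiling differs between mark tracks")
            track[mark] = df[mark].to_numpy()
    inp = read_bedgraph(input_path, "input_rpkm")
    if not (track[["chrom", "start", "end"]].to_numpy()
            == inp[["chrom", "start", "end"]].to_numpy()).all():
        raise FormatError(f"{input_path}: window tiling differs from mark tracks")
    track["input_rpkm"] = inp["input_rpkm"].to_numpy()
    return track


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    needed = {"transcript", "lfc", "padj"}
    if not needed.issubset(table.columns):
        raise FormatError(f"{path}: DE table needs columns {sorted(needed)}")
    return table
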