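"""The 100-transcript NSN/SN chromatin-stage classifier.

The marker panel is the intersection of significant differential transcripts
(padj < 0.05) with an external reference DEG list, split by direction and
ranked by adjusted p-value: the top 65 transcripts down-regulated in SN and
the top 35 up-regulated form the default panel.  The reference cohort's
normalized marker expression ("classifier matrix") is Z-scored per marker,
projected by PCA, and per-stage centroids stored.  Query samples are
normalized against the reference, scaled with the stored statistics, and
called by nearest centroid; a sample is left unclassified unless the ratio
of nearest to farthest centroid distance is below a "clear clustering"
threshold.  UMAP embeddings are available for visualization only and never
enter the calling path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigError, InsufficientDataError
from .expression import CountMatrix, size_factors

logger = logging.getLogger("oostage.classifier")

DIRECTIONS = ("down_in_SN", "up_in_SN")


@dataclass
class ClassifierModel:
    """Marker panel plus frozen reference statistics and projection."""

    markers: pd.DataFrame                 # transcript, direction, padj (ranked)
    n_down: int
    n_up: int
    ref_matrix: pd.DataFrame | None = None    # normalized counts, markers x ref samples
    ref_labels: pd.Series | None = None
    marker_mean: pd.Series | None = None      # normalized-scale mean per marker
    marker_sd: pd.Series | None = None
    components: np.ndarray | None = None      # (k, n_markers) PCA loadings
    centroids: dict | None = None             # stage -> (k,) vector
    n_components: int = 2
    ref_log_geomean: pd.Series | None = None  # for query size factors
    umap_seed: int = 42

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["transcript"])

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.markers.to_csv(path / "markers.tsv", sep="\t", index=False)
        manifest = {"n_down": self.n_down, "n_up": self.n_up,
                    "n_components": self.n_components, "umap_seed": self.umap_seed,
                    "fitted": self.components is not None}
        (path / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        if self.components is None:
            return
        self.ref_matrix.to_csv(path / "ref_matrix.tsv", sep="\t")
        self.ref_labels.rename("stage").to_csv(path / "ref_labels.tsv", sep="\t")
        pd.DataFrame({"mean": self.marker_mean, "sd": self.marker_sd}) \
            .to_csv(path / "scaler.tsv", sep="\t")
        pd.DataFrame(self.components,
                     index=[f"PC{i + 1}" for i in range(self.components.shape[0])],
                     columns=self.marker_ids).to_csv(path / "components.tsv", sep="\t")
        pd.DataFrame(self.centroids,
                     index=[f"PC{i + 1}" for i in range(self.n_components)]) \
            .to_csv(path / "centroids.tsv", sep="\t")
        self.ref_log_geomean.rename("log_geomean").to_csv(path / "geomean.tsv", sep="\t")

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        path = Path(path)
        manifest = yaml.safe_load((path / "manifest.yaml").read_text())
        markers = pd.read_csv(path / "markers.tsv", sep="\t")
        model = cls(markers, manifest["n_down"], manifest["n_up"],
                    n_components=manifest["n_components"],
                    umap_seed=manifest["umap_seed"])
        if not manifest["fitted"]:
            return model
        model.ref_matrix = pd.read_csv(path / "ref_matrix.tsv", sep="\t", index_col=0)
        model.ref_labels = pd.read_csv(path / "ref_labels.tsv", sep="\t", index_col=0)["stage"]
        scaler = pd.read_csv(path / "scaler.tsv", sep="\t", index_col=0)
        model.marker_mean = scaler["mean"]
        model.marker_sd = scaler["sd"]
        model.components = pd.read_csv(path / "components.tsv", sep="\t", index_col=0).to_numpy()
        cent = pd.read_csv(path / "centroids.tsv", sep="\t", index_col=0)
        model.centroids = {c: cent[c].to_numpy() for c in cent.columns}
        model.ref_log_geomean = pd.read_csv(path / "geomean.tsv", sep="\t", index_col=0)["log_geomean"]
        return model


def build_classifier(de: pd.DataFrame, reference_deg_ids, n_down: int = 65,
                     n_up: int = 35, padj_threshold: float = 0.05,
                     require_direction=None) -> ClassifierModel:
    """Select the marker panel from a ranked DE table.

    Significant transcripts (padj < ``padj_threshold``) are intersected with
    the external reference DEG list by identity (set ``require_direction``
    to a mapping id -> sign to additionally demand direction agreement),
    split by sign of the fold change, and the top ``n_down`` / ``n_up`` by
    ascending padj (ties: |LFC| descending, then id) are taken.  Ranking is
    recomputed, so the panel is invariant to the row order of ``de``.
    """
    ref = set(reference_deg_ids)
    sig = de[(de["padj"] < padj_threshold) & de["transcript"].isin(ref)].copy()
    if require_direction is not None:
        agree = [np.sign(require_direction.get(t, 0)) == np.sign(l)
                 for t, l in zip(sig["transcript"], sig["lfc"])]
        sig = sig[np.array(agree, dtype=bool)]
    sig = sig.sort_values(
        by=["padj", "lfc", "transcript"],
        key=lambda col: -col.abs() if col.name == "lfc" else col,
        kind="mergesort",
    )
    down = sig[sig["lfc"] < 0]
    up = sig[sig["lfc"] > 0]
    if len(down) < n_down or len(up) < n_up:
        raise InsufficientDataError(
            f"build_classifier: need {n_down} down / {n_up} up candidates, "
            f"have {len(down)} down / {len(up)} up")
    panel = pd.concat([
        down.head(n_down).assign(direction="down_in_SN"),
        up.head(n_up).assign(direction="up_in_SN"),
    ])[["transcript", "direction", "padj"]].reset_index(drop=True)
    return ClassifierModel(panel, n_down, n_up)


def _pca(z: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic PCA of a (samples x features) matrix.

    Sign convention: each component's largest-|loading| entry is positive.
    Returns (components (k, features), scores (samples, k)).
    """
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    comps = vt[:k]
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return comps, z @ comps.T


def fit_reference(model: ClassifierModel, reference: CountMatrix,
                  n_components: int = 2) -> ClassifierModel:
    """Freeze reference statistics, PCA loadings and stage centroids."""
    reference.require_groups(("NSN", "SN"), min_n=3)
    missing = [t for t in model.marker_ids if t not in reference.counts.index]
    if missing:
        raise InsufficientDataError(
            f"fit_reference: markers absent from reference: {missing[:10]}"
            + ("..." if len(missing) > 10 else ""))
    sf = size_factors(reference.counts)
    norm = reference.counts / sf
    sub = norm.loc[model.marker_ids]
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        dropped = list(sub.index[~keep])
        logger.warning("fit_reference: dropping %d zero-variance markers: %s; "
                       "panel size now %d", len(dropped), dropped[:5], int(keep.sum()))
        model.markers = model.markers[model.markers["transcript"].isin(sub.index[keep])] \
            .reset_index(drop=True)
        sub = sub.loc[keep]
        sd = sd[keep]
    mean = sub.mean(axis=1)
    z = ((sub.sub(mean, axis=0)).div(sd, axis=0)).to_numpy().T  # samples x markers
    k = min(n_components, min(z.shape))
    comps, scores = _pca(z, k)
    labels = reference.meta["stage"]
    centroids = {}
    for st in ("NSN", "SN"):
        idx = np.flatnonzero((labels == st).to_numpy())
        centroids[st] = scores[idx].mean(axis=0)
    with np.errstate(divide="ignore"):
        logc = np.log(reference.counts.to_numpy(dtype=float))
    all_pos = np.isfinite(logc).all(axis=1)
    model.ref_matrix = sub
    model.ref_labels = labels
    model.marker_mean = mean
    model.marker_sd = sd
    model.components = comps
    model.centroids = centroids
    model.n_components = k
    model.ref_log_geomean = pd.Series(np.mean(logc[all_pos], axis=1),
                                      index=reference.counts.index[all_pos])
    return model


def _query_size_factors(counts: pd.DataFrame, ref_log_geomean: pd.Series) -> pd.Series:
    shared = counts.index.intersection(ref_log_geomean.index)
    sub = counts.loc[shared].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        ratios = np.log(sub) - ref_log_geomean.loc[shared].to_numpy()[:, None]
    sf = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        col = ratios[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise InsufficientDataError("query sample shares no positive transcript with reference")
        sf[j] = np.exp(np.median(col))
    return pd.Series(sf, index=counts.columns)


def project(model: ClassifierModel, query: CountMatrix,
            min_marker_frac: float = 0.8) -> pd.DataFrame:
    """Project query samples into the model's PC space (samples x PCs).

    Markers absent from the query (at most 1 - ``min_marker_frac`` of the
    panel) are imputed at the reference mean, i.e. Z = 0, with a log notice.
    """
    if model.components is None:
        raise ConfigError("model is not fitted; call fit_reference first")
    present = [t for t in model.marker_ids if t in query.counts.index]
    frac = len(present) / len(model.marker_ids)
    if frac < min_marker_frac:
        raise InsufficientDataError(
            f"only {frac:.0%} of markers present in query (need >= {min_marker_frac:.0%})")
    if len(present) < len(model.marker_ids):
        logger.info("project: imputing %d absent markers at the reference mean",
                    len(model.marker_ids) - len(present))
    sf = _query_size_factors(query.counts, model.ref_log_geomean)
    norm = query.counts / sf
    z = pd.DataFrame(0.0, index=model.marker_ids, columns=query.counts.columns)
    z.loc[present] = (norm.loc[present].sub(model.marker_mean[present], axis=0)
                      .div(model.marker_sd[present], axis=0))
    scores = z.to_numpy().T @ model.components.T
    return pd.DataFrame(scores, index=query.counts.columns,
                        columns=[f"PC{i + 1}" for i in range(scores.shape[1])])


def classify(model: ClassifierModel, query: CountMatrix,
             ratio_threshold: float = 0.8) -> pd.DataFrame:
    """Nearest-centroid stage calls with the clear-clustering ratio rule.

    A sample is called NSN or SN when the ratio of its distance to the
    nearer centroid over the farther one is <= ``ratio_threshold``;
    otherwise it stays unclassified (equidistant samples always do).
    Deterministic given model + query; UMAP never enters this path.
    """
    scores = project(model, query)
    d_nsn = np.linalg.norm(scores.to_numpy() - model.centroids["NSN"], axis=1)
    d_sn = np.linalg.norm(scores.to_numpy() - model.centroids["SN"], axis=1)
    near = np.where(d_nsn <= d_sn, "NSN", "SN")
    d_near = np.minimum(d_nsn, d_sn)
    d_far = np.maximum(d_nsn, d_sn)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(d_far > 0, d_near / d_far, 1.0)
    call = np.where(ratio <= ratio_threshold, near, "unclassified")
    return pd.DataFrame({
        "sample": scores.index,
        "call": call,
        "d_nsn": d_nsn,
        "d_sn": d_sn,
        "confidence_ratio": ratio,
    }).set_index("sample")


def umap_embedding(model: ClassifierModel, query: CountMatrix | None = None,
                   seed: int | None = None, **umap_kwargs) -> pd.DataFrame:
    """Seeded UMAP of reference (+ optional query) marker Z-scores.

    Visualization only — stage calls never depend on this embedding.
    """
    import umap  # deferred: heavy import, viz-only dependency

    z_ref = ((self_ref := model.ref_matrix).sub(model.marker_mean, axis=0)
             .div(model.marker_sd, axis=0)).T
    frames = [z_ref]
    if query is not None:
        sf = _query_size_factors(query.counts, model.ref_log_geomean)
        norm = query.counts / sf
        zq = pd.DataFrame(0.0, index=model.marker_ids, columns=query.counts.columns)
        present = [t for t in model.marker_ids if t in norm.index]
        zq.loc[present] = (norm.loc[present].sub(model.marker_mean[present], axis=0)
                           .div(model.marker_sd[present], axis=0))
        frames.append(zq.T)
    mat = pd.concat(frames)
    reducer = umap.UMAP(random_state=model.umap_seed if seed is None else seed,
                        **umap_kwargs)
    emb = reducer.fit_transform(mat.to_numpy())
    return pd.DataFrame(emb, index=mat.index, columns=["UMAP1", "UMAP2"])


@dataclass
class SkewReport:
    proportions: pd.DataFrame
    odds_ratio: float
    pvalue: float
    table: pd.DataFrame = field(default=None, repr=False)


def cohort_skew_report(calls_by_condition: dict[str, pd.DataFrame]) -> SkewReport:
    """NSN/SN/unclassified proportions per condition plus a two-sided Fisher
    exact test on the 2x2 classified-call table (first two conditions)."""
    if len(calls_by_condition) < 2:
        raise InsufficientDataError("cohort_skew_report needs >= 2 conditions")
    rows = {}
    for cond, calls in calls_by_condition.items():
        counts = calls["call"].value_counts()
        rows[cond] = {k: int(counts.get(k, 0)) for k in ("NSN", "SN", "unclassified")}
    table = pd.DataFrame(rows).T
    classified = table[["NSN", "SN"]]
    if (classified.sum(axis=1) == 0).any():
        raise InsufficientDataError("a condition has no classified sample")
    props = table.div(table.sum(axis=1), axis=0)
    sub = classified.iloc[:2].to_numpy()
    odds, pvalue = stats.fisher_exact(sub, alternative="two-sided")
    return SkewReport(props, float(odds), float(pvalue), table)
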