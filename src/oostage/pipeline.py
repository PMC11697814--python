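"""End-to-end pipeline over the three modalities with a reproducibility
manifest.

``run_pipeline`` executes expression -> classifier -> methylome -> chromatin
stages on the configured inputs (by default the synthetic generators, which
share the pipeline seed), writes each stage's tables under the output
directory and records a manifest of package version, seeds, thresholds and
SHA-256 hashes of every written file so a run can be replayed and verified
byte for byte.  A stage failure aborts with the stage name; outputs written
so far are renamed with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from . import chromatin, classifier, expression, methylome, simulate
from .config import PipelineConfig
from .errors import OostageError
from .io import (write_bed, write_bismark_cov, write_counts_tsv, write_de_table,
                 write_window_track)

logger = logging.getLogger("oostage.pipeline")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run every stage on synthetic data defined by ``cfg``; returns the
    manifest dict (also written as ``manifest.json``)."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"version": __version__, "config": cfg.to_dict(), "stages": {}}
    stage = "setup"

    def emit(path: Path):
        written.append(path)

    try:
        sim_cfg = cfg.sim_config()

        stage = "expression"
        matrix, truth_counts = simulate.simulate_counts(sim_cfg)
        write_counts_tsv(matrix, out / "counts.tsv", out / "samples.tsv")
        emit(out / "counts.tsv"); emit(out / "samples.tsv")
        detected = expression.detected_transcripts(matrix)
        detected.to_csv(out / "detected.tsv", sep="\t")
        emit(out / "detected.tsv")
        missing = expression.sn_missing_filter(matrix)
        (out / "sn_missing.txt").write_text("\n".join(missing) + ("\n" if missing else ""))
        emit(out / "sn_missing.txt")
        de = expression.differential_expression(matrix)
        write_de_table(de, out / "de_table.tsv")
        emit(out / "de_table.tsv")
        manifest["stages"]["expression"] = {
            "n_samples": int(matrix.counts.shape[1]),
            "n_transcripts": int(matrix.counts.shape[0]),
            "n_sn_missing": len(missing),
            "n_de_padj05": int((de["padj"] < cfg.padj_threshold).sum()),
        }

        stage = "classifier"
        reference_degs = truth_counts.degraded_ids + truth_counts.missing_ids + \
            truth_counts.upregulated_ids
        model = classifier.build_classifier(de, reference_degs,
                                            n_down=cfg.n_down, n_up=cfg.n_up,
                                            padj_threshold=cfg.padj_threshold)
        classifier.fit_reference(model, matrix)
        model.save(out / "classifier_model")
        for p in sorted((out / "classifier_model").iterdir()):
            emit(p)
        query_cfg = simulate.SimConfig(**{**sim_cfg.to_dict(), "seed": sim_cfg.seed + 1})
        query, truth_query = simulate.simulate_counts(
            query_cfg, degraded_ids=truth_counts.degraded_ids,
            missing_ids=truth_counts.missing_ids,
            upregulated_ids=truth_counts.upregulated_ids)
        calls = classifier.classify(model, query, ratio_threshold=cfg.ratio_threshold)
        calls.to_csv(out / "stage_calls.tsv", sep="\t")
        emit(out / "stage_calls.tsv")
        manifest["stages"]["classifier"] = {
            "panel_size": len(model.marker_ids),
            "n_query": int(len(calls)),
            "n_classified": int((calls["call"] != "unclassified").sum()),
        }

        stage = "methylome"
        cells, domains, truth_meth = simulate.simulate_methylomes(sim_cfg)
        meth_dir = out / "meth_cells"
        meth_dir.mkdir(exist_ok=True)
        for cell in cells[:2]:   # per-cell call exports (sample; all cells stay in memory)
            write_bismark_cov(cell.calls, meth_dir / f"{cell.cell_id}.cov")
            emit(meth_dir / f"{cell.cell_id}.cov")
        passing, qc = methylome.qc_filter(cells, min_mapping=cfg.min_mapping,
                                          min_cpgs=0,  # synthetic scale
                                          noncpg_bounds=(cfg.noncpg_lower, None))
        qc.table.to_csv(out / "meth_qc.tsv", sep="\t", index=False)
        emit(out / "meth_qc.tsv")
        dmrs = methylome.call_consensus_dmrs(
            passing, domains, n_iter=cfg.n_iterations, group_size=cfg.group_size,
            n_groups=cfg.n_groups, diff_threshold=cfg.diff_threshold,
            alpha=cfg.alpha, min_calls=cfg.min_calls, consensus=cfg.consensus,
            seed=cfg.seed)
        dmrs.to_csv(out / "dmrs.tsv", sep="\t", index=False)
        emit(out / "dmrs.tsv")
        write_bed(domains.assign(name=domains["class"]), out / "domains.bed")
        emit(out / "domains.bed")
        manifest["stages"]["methylome"] = {
            "n_cells_pass_qc": qc.n_pass,
            "n_domains": int(len(domains)),
            "n_dmrs": int(len(dmrs)),
            "n_hyper": int((dmrs["dmr_class"] == "hyper_in_SN").sum()) if len(dmrs) else 0,
        }

        stage = "chromatin"
        track, truth_chip = simulate.simulate_chip_windows(sim_cfg)
        categorized = chromatin.assign_categories(track,
                                                  enrich_threshold=cfg.enrich_threshold,
                                                  input_low=cfg.input_low,
                                                  input_high=cfg.input_high)
        write_window_track(track, out / "chip_tracks")
        for p in sorted((out / "chip_tracks").iterdir()):
            emit(p)
        categorized.to_csv(out / "windows_categorized.tsv", sep="\t", index=False)
        emit(out / "windows_categorized.tsv")
        pct, chi = chromatin.category_by_domain(categorized, domains)
        pct.to_csv(out / "category_by_domain.tsv", sep="\t")
        emit(out / "category_by_domain.tsv")
        if len(dmrs):
            enr = chromatin.dmr_category_enrichment(categorized, dmrs,
                                                    n_random=cfg.n_random, seed=cfg.seed)
            enr.table.to_csv(out / "dmr_category_enrichment.tsv", sep="\t")
            emit(out / "dmr_category_enrichment.tsv")
        manifest["stages"]["chromatin"] = {
            "n_windows": int(len(categorized)),
            "n_valid": int(categorized["valid"].sum()),
            "domain_chi2_p": float(chi.pvalue),
        }
    except OostageError as exc:
        for p in written:
            if p.exists():
                p.rename(p.with_name(p.name + ".partial"))
        raise OostageError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest["files"] = {str(p.relative_to(out)): _sha256(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d files, manifest written", len(written))
    return manifest
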