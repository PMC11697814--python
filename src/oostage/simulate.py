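"""Synthetic NSN/SN oocyte data with recorded ground truth.

Three generators, one per modality, all driven by a single :class:`SimConfig`
seed with per-modality sub-streams:

* :func:`simulate_counts` — two-group negative-binomial scRNA-seq count
  matrices with an SN silencing signature (degraded transcripts, an
  "SN-missing" subset drawn from lowly expressed transcripts and an
  up-regulated subset) and library-depth variation;
* :func:`simulate_methylomes` — a domain-structured genome (unmethylated /
  intermediate / methylated), sparse bimodal per-cell CpG calls at realistic
  coverage (~10-22% of CpGs per cell), a low level of non-CpG methylation
  and planted hyper-DMRs inside intermediate domains;
* :func:`simulate_chip_windows` — 2-kb window tracks for H3K4me3, H3K27me3
  and H3K36me3 with seven joint-mark categories plus an input-control track
  exercising the validity filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chromatin import CATEGORY_MARKS, MARKS
from .errors import ConfigError
from .expression import CountMatrix
from .methylome import MethCallSet

# Default joint-category proportions of valid 2-kb windows in the GV oocyte;
# the remainder of probability mass is the "none" category.
DEFAULT_MARK_GRAMMAR = {
    "H3K4me3+H3K27me3": 0.089,
    "H3K4me3": 0.143,
    "H3K27me3": 0.185,
    "H3K36me3+H3K4me3+H3K27me3": 0.005,
    "H3K36me3+H3K4me3": 0.046,
    "H3K36me3+H3K27me3": 0.021,
    "H3K36me3": 0.246,
}

# class -> (proportion when drawing the next domain, mean length in bp);
# proportions follow the GV-oocyte domain-class counts, lengths the
# tens-of-kb scale of oocyte methylation domains
DEFAULT_DOMAIN_GRAMMAR = {
    "unmethylated": (0.30, 80_000),
    "intermediate": (0.49, 60_000),
    "methylated": (0.21, 80_000),
}

DOMAIN_METH_RANGES = {
    "unmethylated": (0.0, 25.0),
    "intermediate": (25.0, 70.0),
    "methylated": (70.0, 100.0),
}


@dataclass
class SimConfig:
    """All knobs for the three synthetic generators (defaults = the study
    conditions: 9 NSN / 16 SN transcriptomes, 12 NSN / 28 SN methylomes at
    ~15% CpG coverage, 20 planted 30-point hyper-DMRs, 2-kb windows)."""

    seed: int = 0

    # --- transcriptome ---
    n_nsn: int = 9
    n_sn: int = 16
    n_transcripts: int = 5000
    abundance_seed: int = 1234   # the shared "biology": base transcript abundances
    depth_range: tuple = (1_900_000, 5_300_000)
    frac_silenced: float = 0.20
    frac_missing: float = 0.05
    frac_upregulated: float = 0.07
    degradation_factor: float = 0.25
    upregulation_factor: float = 4.0
    missing_cell_frac: float = 10 / 16
    dispersion_a0: float = 0.05
    dispersion_a1: float = 2.0
    log_abundance_sd: float = 2.0

    # --- methylome ---
    n_nsn_meth: int = 12
    n_sn_meth: int = 28
    genome_spec: tuple = (("chr1", 42_000_000), ("chr2", 42_000_000))
    domain_grammar: dict = field(default_factory=lambda: dict(DEFAULT_DOMAIN_GRAMMAR))
    min_domain_length: int = 35_000
    n_planted_dmrs: int = 20
    dmr_effect: float = 30.0
    cpg_density: float = 8.0       # CpGs per kb
    coverage_frac: float = 0.15    # per-cell fraction of CpGs observed
    noncpg_density: float = 4.0
    noncpg_level: float = 0.04
    mapping_eff_range: tuple = (30.0, 60.0)
    n_contaminated: int = 0
    contaminated_noncpg: float = 0.002
    meth_mode: str = "read"        # "read" (0/1 calls) or "expectation"

    # --- ChIP windows ---
    window_size: int = 2000
    mark_grammar: dict = field(default_factory=lambda: dict(DEFAULT_MARK_GRAMMAR))
    mark_high_range: tuple = (1.5, 6.0)
    mark_low_range: tuple = (0.02, 0.8)
    input_band: tuple = (0.04, 2.0)
    fraction_invalid: float = 0.10

    def validate(self) -> None:
        for name in ("frac_silenced", "frac_missing", "frac_upregulated",
                     "missing_cell_frac", "coverage_frac", "noncpg_level",
                     "fraction_invalid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"SimConfig.{name} must be in [0, 1], got {v}")
        if self.depth_range[0] > self.depth_range[1]:
            raise ConfigError("SimConfig.depth_range: min > max")
        if self.dmr_effect < 0:
            raise ConfigError("SimConfig.dmr_effect must be >= 0 (0 = null case)")
        if self.coverage_frac == 0:
            raise ConfigError("SimConfig.coverage_frac must be > 0")
        if not self.genome_spec:
            raise ConfigError("SimConfig.genome_spec must be nonempty")
        total = sum(self.mark_grammar.values())
        if total > 1.0 + 1e-9:
            raise ConfigError(f"SimConfig.mark_grammar proportions sum to {total} > 1")
        unknown = set(self.mark_grammar) - set(CATEGORY_MARKS)
        if unknown:
            raise ConfigError(f"SimConfig.mark_grammar has unknown categories {sorted(unknown)}")
        if set(self.domain_grammar) != set(DOMAIN_METH_RANGES):
            raise ConfigError("SimConfig.domain_grammar must define unmethylated/intermediate/methylated")
        if self.meth_mode not in ("read", "expectation"):
            raise ConfigError(f"SimConfig.meth_mode must be 'read' or 'expectation', got {self.meth_mode}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Planted ground truth resolving against the generated objects."""

    stages: dict = field(default_factory=dict)          # sample/cell id -> stage
    degraded_ids: list = field(default_factory=list)
    missing_ids: list = field(default_factory=list)
    upregulated_ids: list = field(default_factory=list)
    contaminated_ids: list = field(default_factory=list)
    domains: pd.DataFrame | None = None   # chrom,start,end,class,nsn_meth,sn_meth
    dmrs: pd.DataFrame | None = None      # planted intervals with per-stage truth
    window_categories: pd.Series | None = None


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_counts(cfg: SimConfig, degraded_ids=None, missing_ids=None,
                    upregulated_ids=None) -> tuple[CountMatrix, SimTruth]:
    """Two-group NB count matrix with an SN silencing signature.

    With ``frac_silenced == 0`` the SN signature is switched off entirely
    (no degraded, missing or up-regulated transcripts) so both groups draw
    from identical distributions.  Passing explicit id lists reuses a
    previously planted signature, e.g. to generate query cohorts that share
    the reference signature.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    g = cfg.n_transcripts
    ids = np.array([f"tx{i:05d}" for i in range(g)])
    # base abundances come from their own seed so that cohorts generated with
    # different seeds still share one underlying transcriptome
    rel = np.random.default_rng([cfg.abundance_seed, 0]).lognormal(
        mean=0.0, sigma=cfg.log_abundance_sd, size=g)
    rel /= rel.sum()

    if cfg.frac_silenced == 0 and degraded_ids is None:
        degraded = np.array([], dtype=int)
        missing = np.array([], dtype=int)
        upreg = np.array([], dtype=int)
    elif degraded_ids is None:
        degraded = np.sort(rng.choice(g, size=round(cfg.frac_silenced * g), replace=False))
        order = np.argsort(rel, kind="stable")
        low_half = order[: g // 2]                       # bottom two quartiles
        pool = np.setdiff1d(low_half, degraded)
        n_missing = min(round(cfg.frac_missing * g), len(pool))
        missing = np.sort(rng.choice(pool, size=n_missing, replace=False))
        rest = np.setdiff1d(np.arange(g), np.union1d(degraded, missing))
        n_up = min(round(cfg.frac_upregulated * g), len(rest))
        upreg = np.sort(rng.choice(rest, size=n_up, replace=False))
    else:
        id_pos = {t: i for i, t in enumerate(ids)}
        degraded = np.array(sorted(id_pos[t] for t in degraded_ids))
        missing = np.array(sorted(id_pos[t] for t in (missing_ids or [])), dtype=int)
        upreg = np.array(sorted(id_pos[t] for t in (upregulated_ids or [])), dtype=int)

    factor = np.ones(g)
    factor[degraded] = cfg.degradation_factor
    factor[missing] = cfg.degradation_factor
    factor[upreg] = cfg.upregulation_factor
    rel_sn = rel * factor
    rel_sn /= rel_sn.sum()

    n = cfg.n_nsn + cfg.n_sn
    depths = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1, size=n)
    stages = ["NSN"] * cfg.n_nsn + ["SN"] * cfg.n_sn
    sample_ids = [f"NSN_{i + 1:02d}" for i in range(cfg.n_nsn)] + \
                 [f"SN_{i + 1:02d}" for i in range(cfg.n_sn)]
    mean_depth = np.mean(cfg.depth_range)
    mu_base = rel * mean_depth
    alpha = cfg.dispersion_a0 + cfg.dispersion_a1 / np.maximum(mu_base, 1e-8)
    r = 1.0 / alpha

    counts = np.zeros((g, n), dtype=np.int64)
    for s in range(n):
        mu = (rel_sn if stages[s] == "SN" else rel) * depths[s]
        p = r / (r + np.maximum(mu, 1e-12))
        counts[:, s] = rng.negative_binomial(r, p)

    sn_cols = np.arange(cfg.n_nsn, n)
    k_min = math.ceil(cfg.missing_cell_frac * cfg.n_sn)
    for t in missing:
        n_zero = int(rng.integers(k_min, cfg.n_sn + 1))
        cols = rng.choice(sn_cols, size=n_zero, replace=False)
        counts[t, cols] = 0

    meta = pd.DataFrame({
        "stage": stages,
        "source": "simulated",
        "total_reads": depths,
    }, index=sample_ids)
    matrix = CountMatrix(pd.DataFrame(counts, index=ids, columns=sample_ids), meta)
    truth = SimTruth(
        stages=dict(zip(sample_ids, stages)),
        degraded_ids=list(ids[degraded]),
        missing_ids=list(ids[missing]),
        upregulated_ids=list(ids[upreg]),
    )
    return matrix, truth


def _tile_domains(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = list(cfg.domain_grammar)
    probs = np.array([cfg.domain_grammar[c][0] for c in classes], dtype=float)
    probs /= probs.sum()
    rows = []
    for chrom, length in cfg.genome_spec:
        pos = 0
        while pos < length:
            cls = classes[rng.choice(len(classes), p=probs)]
            mean_len = cfg.domain_grammar[cls][1]
            extra = rng.exponential(max(mean_len - cfg.min_domain_length, 1.0))
            end = min(pos + cfg.min_domain_length + int(extra), length)
            rows.append((chrom, pos, end, cls))
            pos = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])


def simulate_methylomes(cfg: SimConfig) -> tuple[list[MethCallSet], pd.DataFrame, SimTruth]:
    """Sparse single-cell methylomes over a domain-structured genome.

    Per-domain true methylation is drawn from the class range (unmethylated
    U(0,25), intermediate U(25,70), methylated U(70,100)); planted
    hyper-DMRs raise the SN truth of ``n_planted_dmrs`` intermediate domains
    by ``dmr_effect`` points (their NSN base is drawn low enough that the
    effect never clips).  Each cell observes an independent Bernoulli
    subsample of CpGs at ``coverage_frac``; calls are single-read 0/1 draws
    from the domain truth ("read" mode) or fractional expected counts
    ("expectation" mode).
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    domains = _tile_domains(cfg, rng)
    n_dom = len(domains)
    lo = np.array([DOMAIN_METH_RANGES[c][0] for c in domains["class"]])
    hi = np.array([DOMAIN_METH_RANGES[c][1] for c in domains["class"]])
    nsn_meth = rng.uniform(lo, hi)

    inter_idx = domains.index[domains["class"] == "intermediate"].to_numpy()
    if cfg.n_planted_dmrs > len(inter_idx):
        raise ConfigError(
            f"SimConfig.n_planted_dmrs={cfg.n_planted_dmrs} exceeds the "
            f"{len(inter_idx)} intermediate domains generated")
    planted = np.sort(rng.choice(inter_idx, size=cfg.n_planted_dmrs, replace=False))
    base_hi = min(70.0, 100.0 - cfg.dmr_effect)
    nsn_meth[planted] = rng.uniform(25.0, base_hi, size=len(planted))
    sn_meth = nsn_meth.copy()
    sn_meth[planted] = nsn_meth[planted] + cfg.dmr_effect

    # genome-wide site lists shared across cells
    cpg_chrom, cpg_pos, cpg_dom = [], [], []
    nc_chrom, nc_pos = [], []
    for chrom, length in cfg.genome_spec:
        sub = domains[domains["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        didx = sub.index.to_numpy()
        n_sites = int(length / 1000 * cfg.cpg_density)
        pos = np.unique(rng.integers(0, length, size=n_sites))
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        cpg_chrom.append(np.full(inside.sum(), chrom, dtype=object))
        cpg_pos.append(pos[inside])
        cpg_dom.append(didx[j[inside]])
        n_nc = int(length / 1000 * cfg.noncpg_density)
        nc_p = np.unique(rng.integers(0, length, size=n_nc))
        nc_chrom.append(np.full(len(nc_p), chrom, dtype=object))
        nc_pos.append(nc_p)
    cpg_chrom = np.concatenate(cpg_chrom)
    cpg_pos = np.concatenate(cpg_pos)
    cpg_dom = np.concatenate(cpg_dom)
    nc_chrom = np.concatenate(nc_chrom)
    nc_pos = np.concatenate(nc_pos)
    p_site = {"NSN": nsn_meth[cpg_dom] / 100.0, "SN": sn_meth[cpg_dom] / 100.0}

    n_cells = cfg.n_nsn_meth + cfg.n_sn_meth
    cell_stages = ["NSN"] * cfg.n_nsn_meth + ["SN"] * cfg.n_sn_meth
    cell_ids = [f"NSN_m{i + 1:02d}" for i in range(cfg.n_nsn_meth)] + \
               [f"SN_m{i + 1:02d}" for i in range(cfg.n_sn_meth)]
    contaminated = set()
    if cfg.n_contaminated:
        contaminated = set(rng.choice(cell_ids, size=cfg.n_contaminated, replace=False))

    cells = []
    for cid, stage in zip(cell_ids, cell_stages):
        obs = rng.random(len(cpg_pos)) < cfg.coverage_frac
        p = p_site[stage][obs]
        if cid in contaminated:
            p = 0.5 + 0.5 * p   # somatic-like boost of CpG methylation
        if cfg.meth_mode == "read":
            m = (rng.random(p.size) < p).astype(float)
            u = 1.0 - m
        else:
            m, u = p, 1.0 - p
        nc_obs = rng.random(len(nc_pos)) < cfg.coverage_frac
        nc_level = cfg.contaminated_noncpg if cid in contaminated else cfg.noncpg_level
        if cfg.meth_mode == "read":
            nc_m = (rng.random(int(nc_obs.sum())) < nc_level).astype(float)
            nc_u = 1.0 - nc_m
        else:
            k = int(nc_obs.sum())
            nc_m = np.full(k, nc_level)
            nc_u = 1.0 - nc_m
        calls = pd.DataFrame({
            "chrom": np.concatenate([cpg_chrom[obs], nc_chrom[nc_obs]]),
            "pos": np.concatenate([cpg_pos[obs], nc_pos[nc_obs]]),
            "context": np.concatenate([np.full(int(obs.sum()), "CpG", dtype=object),
                                       np.full(int(nc_obs.sum()), "non-CpG", dtype=object)]),
            "meth": np.concatenate([m, nc_m]),
            "unmeth": np.concatenate([u, nc_u]),
        }).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        stats = {
            "mapping_efficiency": float(rng.uniform(*cfg.mapping_eff_range)),
            "n_cpgs": int(obs.sum()),
        }
        cells.append(MethCallSet(cid, stage, calls, stats))

    truth_domains = domains.copy()
    truth_domains["nsn_meth"] = nsn_meth
    truth_domains["sn_meth"] = sn_meth
    dmr_truth = truth_domains.loc[planted].copy().reset_index(names="domain_index")
    truth = SimTruth(
        stages=dict(zip(cell_ids, cell_stages)),
        contaminated_ids=sorted(contaminated),
        domains=truth_domains,
        dmrs=dmr_truth,
    )
    return cells, domains[["chrom", "start", "end", "class"]].copy(), truth


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    if lo == hi:
        return np.full(size, float(lo))
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_chip_windows(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """2-kb window track with planted joint-mark categories.

    Marks present in a window's true category draw RPKM from
    ``mark_high_range`` (log-uniform, strictly above the enrichment
    threshold by default); absent marks draw from ``mark_low_range``.  A
    ``fraction_invalid`` share of windows gets an input RPKM forced outside
    the validity band (half below, half above).
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    rows = []
    for chrom, length in cfg.genome_spec:
        n = length // cfg.window_size
        starts = np.arange(n) * cfg.window_size
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + cfg.window_size,
        }))
    track = pd.concat(rows, ignore_index=True)
    n = len(track)

    cats = list(cfg.mark_grammar) + ["none"]
    probs = np.array([cfg.mark_grammar[c] for c in cfg.mark_grammar] +
                     [1.0 - sum(cfg.mark_grammar.values())])
    probs = np.clip(probs, 0, None)
    probs /= probs.sum()
    cat_idx = rng.choice(len(cats), size=n, p=probs)
    categories = np.array(cats, dtype=object)[cat_idx]

    for mark in MARKS:
        present = np.array([mark in CATEGORY_MARKS[c] for c in cats])[cat_idx]
        high = _loguniform(rng, *cfg.mark_high_range, size=n)
        low = _loguniform(rng, max(cfg.mark_low_range[0], 1e-6), cfg.mark_low_range[1], size=n) \
            if cfg.mark_low_range[0] != cfg.mark_low_range[1] \
            else np.full(n, float(cfg.mark_low_range[0]))
        track[mark] = np.where(present, high, low)

    band_lo, band_hi = cfg.input_band
    invalid = rng.random(n) < cfg.fraction_invalid
    low_side = rng.random(n) < 0.5
    inp = rng.uniform(band_lo + 0.01, band_hi - 0.1, size=n)
    inp = np.where(invalid & low_side, rng.uniform(0.0, band_lo * 0.9, size=n), inp)
    inp = np.where(invalid & ~low_side, rng.uniform(band_hi * 1.05, band_hi * 2.5, size=n), inp)
    track["input_rpkm"] = inp

    truth = SimTruth(window_categories=pd.Series(categories, index=track.index,
                                                 name="true_category"))
    return track, truth
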