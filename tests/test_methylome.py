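"""QC, domain segmentation and the consensus DMR procedure."""

import numpy as np
import pandas as pd
import pytest

from oostage import methylome as M
from oostage.errors import ConfigError, InsufficientDataError
from oostage.simulate import simulate_methylomes

from conftest import small_meth_config


def make_cell(cell_id, stage, spec, mapping=50.0, n_cpgs=600_000):
    """Cell from a list of (chrom, pos, context, meth, unmeth)."""
    calls = pd.DataFrame(spec, columns=["chrom", "pos", "context", "meth", "unmeth"])
    return M.MethCallSet(cell_id, stage, calls,
                         {"mapping_efficiency": mapping, "n_cpgs": n_cpgs})


def uniform_cell(cell_id, stage, n, pct, chrom="chr1", start=0, step=10,
                 noncpg_pct=4.0, **kw):
    """n CpG calls at the given percent methylation plus 200 non-CpG calls."""
    n_meth = round(n * pct / 100)
    spec = [(chrom, start + i * step, "CpG", 1, 0) for i in range(n_meth)]
    spec += [(chrom, start + i * step, "CpG", 0, 1) for i in range(n_meth, n)]
    nc_meth = round(200 * noncpg_pct / 100)
    spec += [(chrom, 10 ** 6 + i, "non-CpG", int(i < nc_meth), int(i >= nc_meth))
             for i in range(200)]
    return make_cell(cell_id, stage, spec, **kw)


class TestGlobalMethylation:
    def test_simple_ratio(self):
        cell = make_cell("c", "NSN", [("chr1", i, "CpG", m, u) for i, (m, u) in
                                      enumerate([(1, 0), (1, 0), (0, 1), (0, 1)])])
        assert M.global_methylation(cell) == pytest.approx(50.0)

    def test_all_methylated(self):
        cell = make_cell("c", "NSN", [("chr1", i, "CpG", 1, 0) for i in range(5)])
        assert M.global_methylation(cell) == pytest.approx(100.0)

    def test_no_calls_is_nan(self):
        cell = make_cell("c", "NSN", [("chr1", 1, "CpG", 1, 0)])
        assert np.isnan(M.global_methylation(cell, "non-CpG"))

    def test_matches_line_by_line_oracle(self, meth_small):
        _, cells, _, _ = meth_small
        cell = cells[0]
        num = den = 0.0
        for _, row in cell.calls.head(5000).iterrows():
            if row["context"] == "CpG":
                num += row["meth"]
                den += row["meth"] + row["unmeth"]
        sub = M.MethCallSet(cell.cell_id, cell.stage, cell.calls.head(5000), cell.stats)
        assert M.global_methylation(sub) == pytest.approx(100 * num / den, abs=1e-9)

    def test_estimate_close_to_truth_at_depth(self):
        rng = np.random.default_rng(1)
        n = 200_000
        meth = rng.random(n) < 0.32
        cell = make_cell("c", "SN", None)
        cell.calls = pd.DataFrame({"chrom": "chr1", "pos": np.arange(n), "context": "CpG",
                                   "meth": meth.astype(int), "unmeth": (~meth).astype(int)})
        assert abs(M.global_methylation(cell) - 32.0) < 1.5


class TestQC:
    def test_mapping_boundary_strict(self):
        cells = [uniform_cell("low", "NSN", 100, 50.0, mapping=9.9),
                 uniform_cell("at", "NSN", 100, 50.0, mapping=10.0),
                 uniform_cell("ok", "NSN", 100, 50.0, mapping=10.1)]
        passing, report = M.qc_filter(cells, min_cpgs=0)
        assert [c.cell_id for c in passing] == ["ok"]

    def test_cpg_coverage_boundary(self):
        cells = [uniform_cell("a", "NSN", 100, 50.0, n_cpgs=500_000),
                 uniform_cell("b", "NSN", 100, 50.0, n_cpgs=500_001)]
        passing, _ = M.qc_filter(cells)
        assert [c.cell_id for c in passing] == ["b"]

    def test_contaminated_cells_flagged_exactly(self):
        cfg = small_meth_config(seed=31, n_contaminated=2)
        cells, _, truth = simulate_methylomes(cfg)
        passing, report = M.qc_filter(cells, min_cpgs=0)
        flagged = set(report.table.loc[report.table["contamination_flag"], "cell_id"])
        assert flagged == set(truth.contaminated_ids)
        assert {c.cell_id for c in passing} == set(truth.stages) - flagged


class TestSegmentation:
    def windows(self, meths, chrom="chr1", width=1000):
        return pd.DataFrame({
            "chrom": chrom,
            "start": np.arange(len(meths)) * width,
            "end": (np.arange(len(meths)) + 1) * width,
            "meth": meths,
        })

    def test_uniform_low_track_single_domain(self):
        dom = M.segment_domains(self.windows([10.0] * 8))
        assert len(dom) == 1
        assert dom.iloc[0]["class"] == "unmethylated"
        assert (dom.iloc[0]["start"], dom.iloc[0]["end"]) == (0, 8000)

    def test_three_blocks_three_classes(self):
        dom = M.segment_domains(self.windows([10, 10, 80, 80, 40, 40]))
        assert list(dom["class"]) == ["unmethylated", "methylated", "intermediate"]

    def test_uncovered_windows_break_runs(self):
        dom = M.segment_domains(self.windows([10, np.nan, 10]))
        assert len(dom) == 2
        assert set(dom["class"]) == {"unmethylated"}

    def test_bad_bounds_error(self):
        with pytest.raises(ConfigError):
            M.segment_domains(self.windows([10]), low=70, high=25)

    def test_recovers_truth_classes_from_expectation_mode(self):
        cfg = small_meth_config(seed=32, coverage_frac=1.0, meth_mode="expectation",
                                n_nsn_meth=2, n_sn_meth=2)
        cells, domains, truth = simulate_methylomes(cfg)
        nsn = [c for c in cells if c.stage == "NSN"]
        width = 2000
        tiles = []
        for chrom, length in cfg.genome_spec:
            starts = np.arange(length // width) * width
            tiles.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                       "end": starts + width}))
        tiles = pd.concat(tiles, ignore_index=True)
        meth, total, tiles = M.cell_domain_counts(nsn, tiles)
        with np.errstate(invalid="ignore"):
            tiles["meth"] = 100 * meth.sum(axis=0) / total.sum(axis=0)
        recovered = M.segment_domains(tiles)
        # base-level agreement with the generated domain classes
        agree = genome = 0
        for chrom, length in cfg.genome_spec:
            t = np.empty(length, dtype=object)
            for _, d in truth.domains[truth.domains["chrom"] == chrom].iterrows():
                t[d["start"]:d["end"]] = d["class"]
            r = np.empty(length, dtype=object)
            for _, d in recovered[recovered["chrom"] == chrom].iterrows():
                r[d["start"]:d["end"]] = d["class"]
            agree += (t == r).sum()
            genome += length
        assert agree / genome >= 0.98


class TestPseudobulk:
    def make_cells(self, n_nsn=12, n_sn=28):
        return [uniform_cell(f"N{i}", "NSN", 20, 50.0) for i in range(n_nsn)] + \
               [uniform_cell(f"S{i}", "SN", 20, 50.0) for i in range(n_sn)]

    def test_disjoint_groups_cover_required_cells(self):
        groups = M.pseudobulk_groups(self.make_cells(), seed=1)
        for st in ("NSN", "SN"):
            ids = [c for g in groups[st] for c in g]
            assert len(ids) == 12 and len(set(ids)) == 12

    def test_deterministic_given_seed(self):
        cells = self.make_cells()
        assert M.pseudobulk_groups(cells, seed=7) == M.pseudobulk_groups(cells, seed=7)

    def test_insufficient_cells_error_states_minimum(self):
        with pytest.raises(InsufficientDataError, match="12"):
            M.pseudobulk_groups(self.make_cells(n_nsn=11), seed=0)

    def test_many_distinct_partitions_over_iterations(self):
        cells = self.make_cells()
        seen = set()
        for i in range(100):
            groups = M.pseudobulk_groups(cells, seed=i)
            seen.add(tuple(sorted(tuple(sorted(g)) for g in groups["SN"])))
        assert len(seen) >= 95


class TestDomainMethylation:
    domains = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})

    def test_pooling_arithmetic(self):
        c1 = make_cell("a", "NSN", [("chr1", 1, "CpG", 3, 1)])
        c2 = make_cell("b", "NSN", [("chr1", 2, "CpG", 1, 3)])
        out = M.domain_methylation([c1, c2], self.domains, min_calls=1)
        assert out["pct"].iloc[0] == pytest.approx(50.0)
        assert out["total_calls"].iloc[0] == 8

    def test_uncovered_domain(self):
        c1 = make_cell("a", "NSN", [("chr2", 1, "CpG", 1, 0)])
        out = M.domain_methylation([c1], self.domains)
        assert not out["covered"].iloc[0]
        assert np.isnan(out["pct"].iloc[0])


class TestIterationTest:
    def test_glm_example_counts(self):
        p = M.binomial_glm_test(200, 800, 500, 500)
        assert p[0] < 1e-6

    def test_matches_statsmodels_grouped_glm(self):
        import statsmodels.api as sm
        cases = [(200, 800, 500, 500), (30, 70, 45, 55), (12, 8, 7, 13)]
        for m1, u1, m2, u2 in cases:
            ours = M.binomial_glm_test(m1, u1, m2, u2)[0]
            fit = sm.GLM(np.array([[m1, u1], [m2, u2]]),
                         sm.add_constant(np.array([0.0, 1.0])),
                         family=sm.families.Binomial()).fit()
            assert ours == pytest.approx(fit.pvalues[1], rel=1e-4)

    def test_perfect_separation_fisher_fallback(self):
        p = M.binomial_glm_test(0, 50, 30, 20)
        oracle = 1.0  # placeholder; compare directly to scipy
        from scipy.stats import fisher_exact
        oracle = fisher_exact([[0, 50], [30, 20]])[1]
        assert p[0] == pytest.approx(oracle, rel=1e-12)

    def iteration(self, nsn_counts, sn_counts):
        """Build groups of single cells carrying the prescribed counts."""
        domains = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        nsn_groups = [[make_cell(f"N{i}", "NSN", [("chr1", 1, "CpG", m, u)])]
                      for i, (m, u) in enumerate(nsn_counts)]
        sn_groups = [[make_cell(f"S{i}", "SN", [("chr1", 1, "CpG", m, u)])]
                     for i, (m, u) in enumerate(sn_counts)]
        return M.dmr_iteration(nsn_groups, sn_groups, domains)

    def test_identical_proportions_not_called(self):
        res = self.iteration([(40, 60)] * 3, [(40, 60)] * 3)
        assert res["diff"].iloc[0] == 0.0
        assert not res["called"].iloc[0]

    def test_thirty_point_difference_called_hyper(self):
        res = self.iteration([(66, 267), (67, 266), (67, 267)],
                             [(166, 167), (167, 166), (167, 167)])
        assert res["diff"].iloc[0] == pytest.approx(30.0, abs=0.1)
        assert res["called"].iloc[0] and res["sign"].iloc[0] > 0
        assert res["pvalue"].iloc[0] < 1e-6

    def test_exactly_ten_points_never_called(self):
        """Strict 'more than 10%' rule: a 10.0-point difference is not a call."""
        res = self.iteration([(40, 60)] * 3, [(50, 50)] * 3)
        assert res["diff"].iloc[0] == pytest.approx(10.0, abs=1e-12)
        assert not res["called"].iloc[0]


def fake_iteration_frames(n_iter, testable, called_iters, diff=20.0, sign=1):
    frames = []
    for i in range(n_iter):
        frames.append(pd.DataFrame({
            "testable": [i < testable],
            "pvalue": [1e-9 if i in called_iters else 0.5],
            "diff": [sign * diff if i in called_iters else 0.0],
            "called": [i in called_iters],
            "sign": [sign if i in called_iters else 0],
        }))
    return frames


class TestConsensus:
    domains = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})

    def test_half_of_testable_retained(self):
        frames = fake_iteration_frames(100, 100, set(range(50)))
        out = M.consensus_dmrs(frames, self.domains)
        assert len(out) == 1
        assert out["consensus_fraction"].iloc[0] == pytest.approx(0.5)
        assert out["dmr_class"].iloc[0] == "hyper_in_SN"

    def test_just_below_half_excluded(self):
        frames = fake_iteration_frames(100, 100, set(range(49)))
        assert len(M.consensus_dmrs(frames, self.domains)) == 0

    def test_denominator_is_testable_iterations(self):
        frames = fake_iteration_frames(100, 80, set(range(40)))
        out = M.consensus_dmrs(frames, self.domains)
        assert out["consensus_fraction"].iloc[0] == pytest.approx(0.5)
        assert out["n_testable"].iloc[0] == 80

    def test_monotone_in_consensus_threshold(self):
        frames = fake_iteration_frames(100, 100, set(range(60)))
        lo = M.consensus_dmrs(frames, self.domains, consensus=0.5)
        hi = M.consensus_dmrs(frames, self.domains, consensus=0.7)
        assert len(hi) <= len(lo)

    def test_mean_diff_exceeds_threshold(self):
        frames = fake_iteration_frames(100, 100, set(range(55)), diff=12.0)
        out = M.consensus_dmrs(frames, self.domains)
        assert abs(out["mean_diff"].iloc[0]) > 10.0


class TestEndToEnd:
    def test_planted_dmrs_recovered_small_scale(self, meth_small):
        _, cells, domains, truth = meth_small
        dmrs = M.call_consensus_dmrs(cells, domains, n_iter=30, seed=3)
        planted = set(zip(truth.dmrs["chrom"], truth.dmrs["start"], truth.dmrs["end"]))
        found = set(zip(dmrs["chrom"], dmrs["start"], dmrs["end"]))
        assert len(planted & found) / len(planted) >= 0.8
        hit = dmrs[[k in planted for k in zip(dmrs["chrom"], dmrs["start"], dmrs["end"])]]
        assert (hit["dmr_class"] == "hyper_in_SN").all()

    def test_reproducible_given_seed(self, meth_small):
        _, cells, domains, _ = meth_small
        d1 = M.call_consensus_dmrs(cells, domains, n_iter=10, seed=5)
        d2 = M.call_consensus_dmrs(cells, domains, n_iter=10, seed=5)
        pd.testing.assert_frame_equal(d1, d2)

    def test_monotone_in_diff_threshold(self, meth_small):
        _, cells, domains, _ = meth_small
        lo = M.call_consensus_dmrs(cells, domains, n_iter=20, seed=4, diff_threshold=10)
        hi = M.call_consensus_dmrs(cells, domains, n_iter=20, seed=4, diff_threshold=25)
        assert len(hi) <= len(lo)
        assert set(zip(hi["chrom"], hi["start"])) <= set(zip(lo["chrom"], lo["start"]))


class TestFeatureEnrichment:
    def make_universe(self, rng, n=2000):
        starts = np.sort(rng.choice(10_000_000, size=n, replace=False))
        return pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 500})

    def test_feature_equals_universe_is_null(self, rng):
        uni = self.make_universe(rng)
        query = uni.iloc[:100]
        res = M.feature_enrichment(query, uni, uni, n_random=50, seed=1)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.05)
        assert res.log2_fold_enrichment == pytest.approx(0.0, abs=0.05)

    def test_log2fe_arithmetic(self, rng):
        # query 80/100 overlapping vs random mean 40/100 -> log2FE = 1
        assert np.log2((80 / 100) / (40 / 100)) == pytest.approx(1.0)

    def test_planted_enrichment_recovered(self, rng):
        # query composed so feature overlap is 5x the 10% background rate
        for seed in range(5):
            r = np.random.default_rng(seed)
            uni = self.make_universe(r)
            feat_mask = r.random(len(uni)) < 0.1
            feature = uni[feat_mask]
            in_idx = np.flatnonzero(feat_mask)
            out_idx = np.flatnonzero(~feat_mask)
            n_hit = 36   # 5x-enriched composition: odds 36/64 vs 0.1/0.9
            pick = np.concatenate([r.choice(in_idx, n_hit, replace=False),
                                   r.choice(out_idx, 100 - n_hit, replace=False)])
            query = uni.iloc[pick]
            res = M.feature_enrichment(query, feature, uni, n_random=200, seed=seed)
            assert 3.0 <= res.odds_ratio <= 8.0
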