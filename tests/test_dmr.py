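import numpy as np
import pandas as pd
import pytest

from dmrkit.binning import BinGrid, bin_methylation, call_dmcs
from dmrkit.dmr import (
    DmrParams,
    call_dmrs,
    call_ectopic_chg,
    dmrs_to_frame,
    merge_candidates,
    screen_bins,
)
from dmrkit.simulate import (
    SimConfig,
    apply_epimutagenesis,
    generate_genome_annotation,
    generate_true_methylome,
    registry_overlap_metrics,
    simulate_wgbs_counts,
)

from conftest import make_table
from oracles import brute_force_call_dmrs, brute_merge


def bin_rows(sites):
    """sites: list of (pos, count_m, count_u[, context]) on Chr1 +."""
    return [("Chr1", p[0], "+", p[1], p[2], p[3] if len(p) > 3 else "CG") for p in sites]


def strong_bin(bin_start, level_a, level_b, n_sites=6, cov=10, context="CG"):
    """n_sites cytosines in one bin with the given exact levels in a and b."""
    rows_a, rows_b = [], []
    for i in range(n_sites):
        pos = bin_start + 5 + i * 10
        rows_a.append(("Chr1", pos, "+", int(round(level_a * cov)), cov - int(round(level_a * cov)), context))
        rows_b.append(("Chr1", pos, "+", int(round(level_b * cov)), cov - int(round(level_b * cov)), context))
    return rows_a, rows_b


class TestScreenBins:
    def _screen(self, rows_a, rows_b, params):
        a = make_table(rows_a, sample_id="a")
        b = make_table(rows_b, sample_id="b")
        grid = BinGrid(params.bin_size)
        bins_a = bin_methylation(a, params.context, grid, params.min_cov)
        bins_b = bin_methylation(b, params.context, grid, params.min_cov)
        dmcs = call_dmcs(a, b, params.context, params.min_diff, params.min_cov)
        return screen_bins(bins_a, bins_b, dmcs, params)

    def test_qualifying_cg_bin_is_candidate(self):
        rows_a, rows_b = strong_bin(1000, 0.8, 0.3, n_sites=5)
        cand = self._screen(rows_a, rows_b, DmrParams.cg())
        assert len(cand) == 1
        assert cand.iloc[0]["n_dmc"] == 5
        assert cand.iloc[0]["delta"] == pytest.approx(-0.5)

    def test_too_few_dmcs_disqualifies(self):
        rows_a, rows_b = strong_bin(1000, 0.8, 0.3, n_sites=3)
        cand = self._screen(rows_a, rows_b, DmrParams.cg())
        assert len(cand) == 0

    def test_dmc_direction_must_match_bin_direction(self):
        # bin-level hypo delta driven by 4 strongly losing sites, but 2 sites
        # gain: only the 4 matching DMCs count
        rows_a = bin_rows([(1005, 10, 0), (1015, 10, 0), (1025, 10, 0), (1035, 10, 0), (1045, 0, 10), (1055, 0, 10)])
        rows_b = bin_rows([(1005, 0, 10), (1015, 0, 10), (1025, 0, 10), (1035, 0, 10), (1045, 10, 0), (1055, 10, 0)])
        cand = self._screen(rows_a, rows_b, DmrParams.cg())
        assert len(cand) == 0 or cand.iloc[0]["n_dmc"] == 4

    def test_undefined_bin_level_disqualifies(self):
        rows_a, rows_b = strong_bin(1000, 0.9, 0.1, n_sites=5, cov=2)  # below min_cov
        cand = self._screen(rows_a, rows_b, DmrParams.cg())
        assert len(cand) == 0


class TestMergeCandidates:
    def _cand(self, intervals):
        return pd.DataFrame(
            [
                {"chrom": "Chr1", "start": s, "end": e, "level_a": 0.8, "level_b": 0.3,
                 "delta": -0.5, "n_dmc": 4}
                for s, e in intervals
            ]
        )

    def test_gap_exactly_200_merges(self):
        dmrs = merge_candidates(self._cand([(1000, 1100), (1300, 1400)]), DmrParams.cg())
        assert len(dmrs) == 1
        assert (dmrs[0].start, dmrs[0].end, dmrs[0].n_bins) == (1000, 1400, 2)

    def test_gap_300_discards_singletons(self):
        dmrs = merge_candidates(self._cand([(1000, 1100), (1400, 1500)]), DmrParams.cg())
        assert dmrs == []

    def test_lone_candidate_never_a_dmr(self):
        assert merge_candidates(self._cand([(1000, 1100)]), DmrParams.cg()) == []

    def test_matches_union_find_oracle_on_random_sets(self):
        rng = np.random.default_rng(23)
        params = DmrParams.cg()
        for _ in range(200):
            n = rng.integers(0, 12)
            starts = np.sort(rng.choice(np.arange(0, 5000, 100), size=n, replace=False))
            intervals = [(int(s), int(s) + 100) for s in starts]
            got = merge_candidates(self._cand(intervals), params)
            expected = brute_merge(
                [("Chr1", s, e, -0.5) for s, e in intervals], params.merge_gap
            )
            assert [(d.chrom, d.start, d.end) for d in got] == [
                (c, s, e) for c, s, e, _m in expected
            ]
            assert [tuple(b[0] for b in d.member_bins) for d in got] == [
                tuple(intervals[i][0] for i in m) for _c, _s, _e, m in expected
            ]


def simulate_pair(chrom_length=200_000, seed=0, **kw):
    cfg = SimConfig(chrom_length=chrom_length, seed=seed, **kw)
    genome, features = generate_genome_annotation(cfg)
    truth = generate_true_methylome(genome, features, cfg)
    em2, registry = apply_epimutagenesis(truth, cfg)
    control = simulate_wgbs_counts(truth, cfg, "control", seed=seed + 1)
    treated = simulate_wgbs_counts(em2, cfg, "treated", seed=seed + 2)
    return control, treated, registry, cfg


class TestCallDmrs:
    def test_self_comparison_yields_nothing(self, small_truth, small_config):
        counts = simulate_wgbs_counts(small_truth, small_config, "s", seed=5)
        for params in (DmrParams.cg(), DmrParams.cg("hyper"), DmrParams.chg(), DmrParams.chg("hyper")):
            assert call_dmrs(counts, counts, params) == []

    def test_hypo_hyper_symmetry(self):
        control, treated, _reg, _cfg = simulate_pair(chrom_length=100_000, seed=3)
        hypo = call_dmrs(control, treated, DmrParams.cg("hypo"))
        hyper = call_dmrs(treated, control, DmrParams.cg("hyper"))
        assert [(d.chrom, d.start, d.end) for d in hypo] == [
            (d.chrom, d.start, d.end) for d in hyper
        ]
        assert len(hypo) > 0

    def test_monotone_in_thresholds(self):
        control, treated, _reg, _cfg = simulate_pair(chrom_length=100_000, seed=4)
        grid = BinGrid(100)

        def candidates(min_dmc, min_diff):
            params = DmrParams(context="CG", direction="hypo", min_dmc=min_dmc, min_diff=min_diff)
            bins_a = bin_methylation(control, "CG", grid, params.min_cov)
            bins_b = bin_methylation(treated, "CG", grid, params.min_cov)
            dmcs = call_dmcs(control, treated, "CG", params.min_diff, params.min_cov)
            cand = screen_bins(bins_a, bins_b, dmcs, params)
            return set(zip(cand["chrom"], cand["start"]))

        base = candidates(4, 0.40)
        assert candidates(5, 0.40) <= base
        assert candidates(4, 0.50) <= base

    def test_composition_equals_manual_stages(self):
        control, treated, _reg, _cfg = simulate_pair(chrom_length=100_000, seed=6)
        params = DmrParams.cg()
        grid = BinGrid(params.bin_size)
        bins_a = bin_methylation(control, "CG", grid, params.min_cov)
        bins_b = bin_methylation(treated, "CG", grid, params.min_cov)
        dmcs = call_dmcs(control, treated, "CG", params.min_diff, params.min_cov)
        manual = merge_candidates(screen_bins(bins_a, bins_b, dmcs, params), params)
        auto = call_dmrs(control, treated, params)
        assert dmrs_to_frame(auto).equals(dmrs_to_frame(manual))

    def test_output_sorted_and_disjoint(self):
        control, treated, _reg, _cfg = simulate_pair(chrom_length=150_000, seed=8)
        dmrs = call_dmrs(control, treated, DmrParams.cg())
        assert len(dmrs) >= 2
        for prev, nxt in zip(dmrs, dmrs[1:]):
            assert (prev.chrom, prev.start) <= (nxt.chrom, nxt.start)
            if prev.chrom == nxt.chrom:
                assert prev.end <= nxt.start

    def test_matches_brute_force_reference(self):
        control, treated, _reg, _cfg = simulate_pair(chrom_length=100_000, seed=9)
        params = DmrParams.cg()
        got = call_dmrs(control, treated, params)
        expected = brute_force_call_dmrs(
            control, treated,
            context="CG", direction="hypo", min_dmc=4, min_diff=0.40,
            merge_gap=200, bin_size=100, min_cov=4,
        )
        assert [(d.chrom, d.start, d.end) for d in got] == [
            (c, s, e) for c, s, e, _m in expected
        ]
        assert len(got) > 0

    def test_precision_against_planted_registry(self):
        control, treated, registry, _cfg = simulate_pair(chrom_length=200_000, seed=10)
        dmrs = call_dmrs(control, treated, DmrParams.cg())
        metrics = registry_overlap_metrics(dmrs, registry)
        assert metrics["n_called"] > 0
        assert metrics["precision"] >= 0.9


class TestEctopicChg:
    def test_unmethylated_control_with_gain_is_candidate(self):
        rows_a, rows_b = strong_bin(2000, 0.0, 0.25, n_sites=4, cov=20, context="CHG")
        rows_a2, rows_b2 = strong_bin(2300, 0.0, 0.25, n_sites=4, cov=20, context="CHG")
        a = make_table(rows_a + rows_a2, sample_id="a")
        b = make_table(rows_b + rows_b2, sample_id="b")
        dmrs = call_ectopic_chg(a, b)
        assert len(dmrs) == 1
        assert (dmrs[0].start, dmrs[0].end, dmrs[0].direction) == (2000, 2400, "ectopic")

    def test_methylated_control_site_blocks_bin(self):
        rows_a, rows_b = strong_bin(2000, 0.0, 0.25, n_sites=4, cov=20, context="CHG")
        rows_a2, rows_b2 = strong_bin(2300, 0.0, 0.25, n_sites=4, cov=20, context="CHG")
        # one control site in the first bin carries 3 methylated reads
        rows_a[0] = ("Chr1", rows_a[0][1], "+", 3, 17, "CHG")
        a = make_table(rows_a + rows_a2, sample_id="a")
        b = make_table(rows_b + rows_b2, sample_id="b")
        # first bin ineligible -> the second is a discarded singleton
        assert call_ectopic_chg(a, b) == []

    def test_recall_on_planted_chg_gains(self):
        cfg = SimConfig(
            chrom_length=200_000,
            seed=12,
            base_levels={"CG": (0.8, 0.9, 0.7), "CHG": (0.0, 0.0, 0.0), "CHH": (0.02, 0.1, 0.02)},
            treatment_delta=0.3,
            treatment_prob=0.1,
        )
        genome, features = generate_genome_annotation(cfg)
        truth = generate_true_methylome(genome, features, cfg)
        em2, registry = apply_epimutagenesis(truth, cfg, contexts=("CHG",))
        control = simulate_wgbs_counts(truth, cfg, "control", seed=13)
        treated = simulate_wgbs_counts(em2, cfg, "treated", seed=14)
        dmrs = call_ectopic_chg(control, treated)
        metrics = registry_overlap_metrics(dmrs, registry)
        assert metrics["recall"] >= 0.9
        assert metrics["precision"] >= 0.9
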