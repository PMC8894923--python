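import numpy as np
import pandas as pd
import pytest

from dmrkit.io import ValidationError
from dmrkit.simulate import (
    SimConfig,
    apply_epimutagenesis,
    apply_restoration,
    cytosine_sites,
    generate_genome_annotation,
    generate_true_methylome,
    simulate_study,
    simulate_wgbs_counts,
)


def naive_context(seq, pos, strand):
    """Independent per-position context scan used as the oracle."""
    if strand == "+":
        assert seq[pos] == "C"
        nxt1 = seq[pos + 1] if pos + 1 < len(seq) else "N"
        nxt2 = seq[pos + 2] if pos + 2 < len(seq) else "N"
        if nxt1 == "G":
            return "CG"
        return "CHG" if nxt2 == "G" else "CHH"
    assert seq[pos] == "G"
    prv1 = seq[pos - 1] if pos - 1 >= 0 else "N"
    prv2 = seq[pos - 2] if pos - 2 >= 0 else "N"
    if prv1 == "C":
        return "CG"
    return "CHG" if prv2 == "C" else "CHH"


class TestGenomeAnnotation:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(chrom_length=100_000, seed=7)
        g1, f1 = generate_genome_annotation(cfg)
        g2, f2 = generate_genome_annotation(cfg)
        assert g1 == g2
        pd.testing.assert_frame_equal(f1.df, f2.df)

    def test_zero_te_density(self):
        cfg = SimConfig(chrom_length=50_000, te_density=0, seed=1)
        _g, features = generate_genome_annotation(cfg)
        assert len(features.transposable_elements) == 0
        assert len(features.genes) > 0

    def test_features_within_bounds_and_disjoint(self, small_genome, small_config):
        _genome, features = small_genome
        df = features.df.sort_values(["chrom", "start"])
        assert (df["start"] >= 0).all()
        assert (df["end"] <= small_config.chrom_length).all()
        for _, sub in df.groupby("chrom"):
            ends = sub["end"].to_numpy()
            starts = sub["start"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()

    def test_context_labels_match_sequence_scan(self, small_genome):
        genome, _features = small_genome
        sites = cytosine_sites(genome)
        rng = np.random.default_rng(3)
        rows = sites.iloc[rng.choice(len(sites), size=50, replace=False)]
        for chrom, pos, strand, context in rows[["chrom", "pos", "strand", "context"]].itertuples(index=False):
            assert context == naive_context(genome[chrom], pos, strand)

    def test_infeasible_density_raises(self):
        with pytest.raises(ValidationError, match="density"):
            generate_genome_annotation(SimConfig(chrom_length=5_000, gene_density=500, seed=2))


class TestTrueMethylome:
    def test_te_cg_mean_close_to_configured(self, small_genome):
        genome, features = small_genome
        cfg = SimConfig(chrom_length=200_000, seed=42)
        truth = generate_true_methylome(genome, features, cfg)
        sites = truth.df
        te = features.transposable_elements
        in_te = np.zeros(len(sites), dtype=bool)
        for chrom, s, e in te[["chrom", "start", "end"]].itertuples(index=False):
            in_te |= (sites["chrom"] == chrom) & (sites["pos"] >= s) & (sites["pos"] < e)
        sel = sites[in_te & (sites["context"] == "CG")]
        assert len(sel) >= 1000
        assert abs(sel["p"].mean() - cfg.base_levels["CG"][1]) <= 0.02

    def test_zero_base_level_stays_exactly_zero(self, small_genome):
        genome, features = small_genome
        cfg = SimConfig(
            chrom_length=200_000,
            seed=5,
            base_levels={"CG": (0.8, 0.9, 0.7), "CHG": (0.05, 0.4, 0.05), "CHH": (0.02, 0.1, 0.0)},
        )
        truth = generate_true_methylome(genome, features, cfg)
        # intergenic CHH sites must be exactly 0
        df = truth.df
        feat = features.df
        in_feat = np.zeros(len(df), dtype=bool)
        for chrom, s, e in feat[["chrom", "start", "end"]].itertuples(index=False):
            in_feat |= (df["chrom"] == chrom) & (df["pos"] >= s) & (df["pos"] < e)
        sel = df[~in_feat & (df["context"] == "CHH")]
        assert len(sel) > 0
        assert (sel["p"] == 0.0).all()

    def test_identical_seed_identical_truth(self, small_genome):
        genome, features = small_genome
        cfg = SimConfig(chrom_length=200_000, seed=8)
        t1 = generate_true_methylome(genome, features, cfg)
        t2 = generate_true_methylome(genome, features, cfg)
        pd.testing.assert_frame_equal(t1.df, t2.df)


class TestEpimutagenesis:
    def test_zero_probability_is_identity(self, small_genome, small_truth):
        cfg = SimConfig(chrom_length=200_000, seed=42, treatment_prob=0.0)
        em2, registry = apply_epimutagenesis(small_truth, cfg)
        pd.testing.assert_frame_equal(em2.df, small_truth.df)
        assert len(registry) == 0

    def test_full_delta_clips_to_zero(self, small_truth):
        cfg = SimConfig(chrom_length=200_000, seed=42, treatment_prob=0.3, treatment_delta=-1.0)
        em2, registry = apply_epimutagenesis(small_truth, cfg)
        df = em2.df
        assert len(registry) > 0
        for chrom, s, e in registry[["chrom", "start", "end"]].head(10).itertuples(index=False):
            sel = df[(df["chrom"] == chrom) & (df["pos"] >= s) & (df["pos"] < e) & (df["context"] == "CG")]
            assert (sel["p"] == 0.0).all()

    def test_non_cg_untouched_by_default(self, small_truth):
        cfg = SimConfig(chrom_length=200_000, seed=42, treatment_prob=0.5)
        em2, _reg = apply_epimutagenesis(small_truth, cfg)
        for ctx in ("CHG", "CHH"):
            a = small_truth.df[small_truth.df["context"] == ctx]["p"]
            b = em2.df[em2.df["context"] == ctx]["p"]
            assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_planted_fraction_matches_binomial(self):
        cfg = SimConfig(chrom_length=1_000_000, seed=6, treatment_prob=0.2, gene_density=2, te_density=1)
        genome, features = generate_genome_annotation(cfg)
        truth = generate_true_methylome(genome, features, cfg)
        _em2, registry = apply_epimutagenesis(truth, cfg)
        n_tiles = cfg.chrom_length // cfg.region_size
        frac = len(registry) / n_tiles
        se = np.sqrt(0.2 * 0.8 / n_tiles)
        assert abs(frac - 0.2) <= 3 * se


@pytest.fixture(scope="module")
def em2_setup(small_truth):
    cfg = SimConfig(chrom_length=200_000, seed=42, treatment_prob=0.3)
    em2, registry = apply_epimutagenesis(small_truth, cfg)
    return cfg, em2, registry


class TestRestoration:
    def test_probability_one_restores_planted_regions(self, small_truth, em2_setup):
        cfg, em2, registry = em2_setup
        cfg1 = SimConfig(chrom_length=200_000, seed=42, treatment_prob=0.3, restoration_prob=1.0)
        em3, reg3 = apply_restoration(em2, small_truth, registry, cfg1)
        assert reg3["restored"].all()
        pd.testing.assert_series_equal(em3.df["p"], small_truth.df["p"])

    def test_probability_zero_keeps_em2(self, small_truth, em2_setup):
        cfg, em2, registry = em2_setup
        cfg0 = SimConfig(chrom_length=200_000, seed=42, treatment_prob=0.3, restoration_prob=0.0)
        em3, reg3 = apply_restoration(em2, small_truth, registry, cfg0)
        assert not reg3["restored"].any()
        pd.testing.assert_frame_equal(em3.df, em2.df)

    def test_unplanted_positions_never_change(self, small_truth, em2_setup):
        cfg, em2, registry = em2_setup
        em3, _reg3 = apply_restoration(em2, small_truth, registry, cfg, seed=99)
        planted = np.zeros(len(em2.df), dtype=bool)
        pos = em2.df["pos"].to_numpy()
        for chrom, s, e in registry[["chrom", "start", "end"]].itertuples(index=False):
            planted |= (em2.df["chrom"] == chrom).to_numpy() & (pos >= s) & (pos < e)
        assert np.array_equal(em3.df["p"].to_numpy()[~planted], em2.df["p"].to_numpy()[~planted])

    def test_restored_count_binomial(self):
        cfg = SimConfig(chrom_length=1_000_000, seed=20, treatment_prob=1.0, restoration_prob=0.35,
                        gene_density=2, te_density=1)
        genome, features = generate_genome_annotation(cfg)
        truth = generate_true_methylome(genome, features, cfg)
        em2, registry = apply_epimutagenesis(truth, cfg)
        assert len(registry) == 1000
        _em3, reg3 = apply_restoration(em2, truth, registry, cfg)
        se = np.sqrt(0.35 * 0.65 * 1000)
        assert abs(reg3["restored"].sum() - 350) <= 3 * se

    def test_sibling_draws_differ_by_seed(self, small_truth, em2_setup):
        cfg, em2, registry = em2_setup
        cfg5 = SimConfig(chrom_length=200_000, seed=42, treatment_prob=0.3, restoration_prob=0.5)
        _a, reg_a = apply_restoration(em2, small_truth, registry, cfg5, seed=1)
        _b, reg_b = apply_restoration(em2, small_truth, registry, cfg5, seed=2)
        assert not reg_a["restored"].equals(reg_b["restored"])


class TestWgbsCounts:
    def test_fully_methylated_sites(self, small_truth, small_config):
        truth = small_truth.copy()
        truth.df["p"] = 1.0
        cfg = SimConfig(chrom_length=200_000, seed=42, conversion_error=0.0)
        counts = simulate_wgbs_counts(truth, cfg, "s", seed=3)
        assert (counts.df["count_u"] == 0).all()

    def test_unmethylated_sites(self, small_truth):
        truth = small_truth.copy()
        truth.df["p"] = 0.0
        cfg = SimConfig(chrom_length=200_000, seed=42)
        counts = simulate_wgbs_counts(truth, cfg, "s", seed=4)
        assert (counts.df["count_m"] == 0).all()

    def test_counts_are_consistent(self, small_truth):
        cfg = SimConfig(chrom_length=200_000, seed=42, mean_coverage=2.0)
        counts = simulate_wgbs_counts(small_truth, cfg, "s", seed=5)
        assert (counts.df["count_m"] >= 0).all()
        assert (counts.df["count_u"] >= 0).all()
        # zero-coverage sites retained in the table
        assert ((counts.df["count_m"] + counts.df["count_u"]) == 0).any()

    def test_genome_wide_level_law_of_large_numbers(self, small_truth):
        truth = small_truth.copy()
        truth.df["p"] = 0.5
        cfg = SimConfig(chrom_length=200_000, seed=42, mean_coverage=30, conversion_error=0.0)
        counts = simulate_wgbs_counts(truth, cfg, "s", seed=6)
        level = counts.df["count_m"].sum() / (counts.df["count_m"] + counts.df["count_u"]).sum()
        assert abs(level - 0.5) <= 0.01

    def test_deterministic_given_seed(self, small_truth, small_config):
        c1 = simulate_wgbs_counts(small_truth, small_config, "s", seed=7)
        c2 = simulate_wgbs_counts(small_truth, small_config, "s", seed=7)
        pd.testing.assert_frame_equal(c1.df, c2.df)


class TestStudyAssembly:
    def test_structure_matches_design(self):
        cfg = SimConfig(chrom_length=60_000, seed=30, gene_density=5, te_density=2)
        study = simulate_study(cfg)
        ids = set(study["samples"])
        assert {"untreated_1", "untreated_2", "solvent_1", "solvent_2"} <= ids
        assert {"suppressor_1", "suppressor_2", "nonsuppressor_1", "nonsuppressor_2"} <= ids
        assert {"sibling_1", "sibling_2"} <= ids
        assert set(study["registries"]) >= {"suppressor_1", "sibling_1"}
        # nonsuppressor registries are much sparser than suppressor ones
        assert len(study["registries"]["nonsuppressor_1"]) < len(study["registries"]["suppressor_1"])
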