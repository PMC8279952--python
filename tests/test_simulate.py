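"""Synthetic-data generators: determinism, construction guarantees, and the
observation-error algebra of the simulated bisulfite counts."""

import numpy as np
import pandas as pd
import pytest

from dyadkin.core import RegionSet
from dyadkin.kinetics import KineticParams, evolve, observation_matrix
from dyadkin.simulate import (
    ConfigError,
    MethylationProfile,
    SimulationConfig,
    build_toy_genome,
    simulate_lfq,
    simulate_long_reads,
    simulate_passage_series,
    simulate_wgbs,
)

from conftest import quick_config


def flat_kinetics(genome, **iap_overrides):
    classes = set(genome.feature_classes()) | {"intergenic"}
    out = {c: KineticParams() for c in classes}
    if iap_overrides:
        out["IAPEz_int"] = KineticParams(**iap_overrides)
    return out


class TestToyGenome:
    def test_identical_seed_identical_genome(self):
        g1 = build_toy_genome(quick_config(seed=1))
        g2 = build_toy_genome(quick_config(seed=1))
        np.testing.assert_array_equal(g1.cpg_sites["chrS"], g2.cpg_sites["chrS"])
        pd.testing.assert_frame_equal(g1.features.df, g2.features.df)

    def test_seed_changes_cpg_positions(self):
        g1 = build_toy_genome(quick_config(seed=1))
        g2 = build_toy_genome(quick_config(seed=2))
        assert set(g1.cpg_sites["chrS"]) != set(g2.cpg_sites["chrS"])

    def test_iapez_element_lengths_and_cpg_load(self, small_genome):
        iap = small_genome.features.select_label("IAPEz_int")
        assert len(iap) >= 20
        assert ((iap.lengths >= 5000) & (iap.lengths <= 7000)).all()
        cpg = small_genome.cpg_sites["chrS"]
        for _, r in iap.df.iterrows():
            n = ((cpg >= r["start"]) & (cpg < r["end"])).sum()
            assert n >= 20

    def test_cgi_density_exceeds_intergenic(self, small_genome):
        cpg = small_genome.cpg_sites["chrS"]

        def density(label):
            sub = small_genome.features.select_label(label)
            n = sum(
                ((cpg >= r["start"]) & (cpg < r["end"])).sum()
                for _, r in sub.df.iterrows()
            )
            return n / sub.lengths.sum()

        assert density("CGI") >= 5 * density("intergenic")

    def test_no_cpgs_in_gaps(self, small_genome):
        cpg = small_genome.cpg_sites["chrS"]
        for _, g in small_genome.gap_mask.df.iterrows():
            assert not ((cpg >= g["start"]) & (cpg < g["end"])).any()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="coverage_mean"):
            SimulationConfig(coverage_mean=-1).validate()


class TestWgbs:
    def test_unmethylated_error_free_all_zero(self, small_genome):
        cfg = quick_config(seed=3, conversion_failure=0.0, inappropriate_conversion=0.0)
        m = simulate_wgbs(small_genome, MethylationProfile.baseline(level=0.0), cfg)
        assert (m.df["count_M"] == 0).all()

    def test_fully_methylated_error_free_all_one(self, small_genome):
        cfg = quick_config(seed=3, conversion_failure=0.0, inappropriate_conversion=0.0)
        profile = MethylationProfile({c: 1.0 for c in small_genome.feature_classes()},
                                     background=1.0)
        m = simulate_wgbs(small_genome, profile, cfg)
        assert (m.df["count_U"] == 0).all()

    def test_half_methylated_pooled_beta(self, small_genome):
        cfg = quick_config(seed=4, coverage_mean=50.0,
                           conversion_failure=0.0, inappropriate_conversion=0.0)
        profile = MethylationProfile({c: 0.5 for c in small_genome.feature_classes()},
                                     background=0.5)
        m = simulate_wgbs(small_genome, profile, cfg)
        pooled = m.df["count_M"].sum() / (m.df["count_M"].sum() + m.df["count_U"].sum())
        assert pooled == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("p_true,err_kw,expected_of", [
        (0.0, {"conversion_failure": 0.02, "inappropriate_conversion": 0.0}, "e"),
        (1.0, {"conversion_failure": 0.0, "inappropriate_conversion": 0.03}, "one_minus_c"),
    ])
    def test_observation_error_algebra(self, small_genome, p_true, err_kw, expected_of):
        """p_true=0 gives pooled beta ~ e; p_true=1 gives ~ 1-c (3 SE bound)."""
        cfg = quick_config(seed=5, coverage_mean=30.0, **err_kw)
        profile = MethylationProfile(
            {c: p_true for c in small_genome.feature_classes()}, background=p_true
        )
        m = simulate_wgbs(small_genome, profile, cfg)
        n = int(m.coverage.sum())
        assert n >= 100_000
        pooled = m.df["count_M"].sum() / n
        target = cfg.conversion_failure if expected_of == "e" else 1 - cfg.inappropriate_conversion
        se = np.sqrt(target * (1 - target) / n)
        assert abs(pooled - target) <= 3 * se


class TestPassageSeries:
    def test_all_zero_kinetics_stays_uu(self, small_genome):
        cfg = quick_config(seed=6, conversion_failure=0.0, inappropriate_conversion=0.0)
        ms, ds = simulate_passage_series(
            small_genome, flat_kinetics(small_genome), 6, cfg, passages=(0, 5),
            baseline_profile=MethylationProfile.baseline(level=0.0),
        )
        for d in ds:
            states = d[["n_MU", "n_UM", "n_MM"]].to_numpy()
            assert (states == 0).all()

    def test_full_maintenance_from_mm_is_absorbing(self, small_genome):
        cfg = quick_config(seed=7, conversion_failure=0.0, inappropriate_conversion=0.0)
        classes = set(small_genome.feature_classes()) | {"intergenic"}
        kin = {c: KineticParams(mu=1.0) for c in classes}
        profile = MethylationProfile({c: 1.0 for c in classes}, background=1.0)
        with pytest.raises(ConfigError):
            MethylationProfile.baseline(level=1.0)  # guard: baseline must stay low
        ms, ds = simulate_passage_series(
            small_genome, kin, 6, cfg, passages=(0, 5), baseline_profile=profile
        )
        for d in ds:
            assert (d[["n_UU", "n_MU", "n_UM"]].to_numpy() == 0).all()

    def test_targeted_gain_exceeds_background_at_p5(self, small_genome):
        cfg = quick_config(seed=8)
        kin = flat_kinetics(small_genome, mu=0.95, delta_n=0.2)
        ms, _ = simulate_passage_series(small_genome, kin, 2, cfg, passages=(0, 5))
        m5 = ms[-1]
        iap_mask = np.zeros(len(m5), dtype=bool)
        pos = m5.df["pos"].to_numpy()
        for _, r in small_genome.features.select_label("IAPEz_int").df.iterrows():
            iap_mask |= (pos >= r["start"]) & (pos < r["end"])
        beta = m5.beta
        assert np.nanmean(beta[iap_mask]) > np.nanmean(beta[~iap_mask]) + 0.1

    def test_dyad_marginals_match_model_within_multinomial_error(self, small_genome):
        """Per-strand methylation from generated dyad counts equals the
        generating model's marginal within a 99% binomial CI (n >= 1e4)."""
        cfg = quick_config(seed=9)
        params = KineticParams(mu=0.9, delta_n=0.1, e=cfg.conversion_failure,
                               c=cfg.inappropriate_conversion)
        classes = set(small_genome.feature_classes()) | {"intergenic"}
        kin = {c: params for c in classes}
        n = 20_000
        ms, ds = simulate_passage_series(
            small_genome, kin, 6, cfg, passages=(0, 1, 5), n_dyads_per_class=n,
            baseline_profile=MethylationProfile.baseline(sorted(classes), level=0.0),
        )
        O = observation_matrix(params.e, params.c)
        for d, passages_done in zip(ds, (0, 1, 5)):
            p_true_now = evolve(np.array([1.0, 0, 0, 0]), params, 6 * passages_done)
            q = p_true_now @ O
            expected_plus = q[1] + q[3]
            row = d[d["class"] == "IAPEz_int"].iloc[0]
            observed_plus = (row["n_MU"] + row["n_MM"]) / n
            se = np.sqrt(expected_plus * (1 - expected_plus) / n)
            assert abs(observed_plus - expected_plus) <= 2.58 * se + 1e-9

    def test_inconsistent_class_sets_rejected(self, small_genome):
        with pytest.raises(ConfigError, match="kinetics missing"):
            simulate_passage_series(
                small_genome, {"IAPEz_int": KineticParams()}, 6, quick_config()
            )


class TestLongReads:
    def test_no_deletions_single_block_per_read(self, small_genome):
        cfg = quick_config(seed=10, n_reads=100)
        m = simulate_wgbs(small_genome, MethylationProfile.baseline(), cfg)
        empty = RegionSet(pd.DataFrame(columns=["contig", "start", "end", "label"]))
        reads = simulate_long_reads(small_genome, m, empty, cfg)
        assert (reads.blocks.groupby("read_id").size() == 1).all()

    def test_deletion_splits_spanning_read_into_two_blocks(self, small_genome):
        cfg = quick_config(seed=11, n_reads=300)
        m = simulate_wgbs(small_genome, MethylationProfile.baseline(), cfg)
        deletion = RegionSet(
            pd.DataFrame([("chrS", 300_000, 310_000, "del")],
                         columns=["contig", "start", "end", "label"])
        )
        reads = simulate_long_reads(small_genome, m, deletion, cfg)
        spanning = reads.blocks.groupby("read_id").filter(
            lambda g: g["start"].min() < 300_000 and g["end"].max() > 310_000
        )
        assert len(spanning) > 0
        for _, g in spanning.groupby("read_id"):
            assert len(g) == 2
            assert set(g["end"]).issuperset({300_000}) or 300_000 in g["end"].values
            assert 310_000 in g["start"].values
        # no call inside the deletion
        assert not (
            (reads.calls["pos"] >= 300_000) & (reads.calls["pos"] < 310_000)
        ).any()

    def test_error_free_fully_methylated_calls_all_m(self, small_genome):
        cfg = quick_config(seed=12, n_reads=50, call_error=0.0,
                           conversion_failure=0.0, inappropriate_conversion=0.0)
        profile = MethylationProfile(
            {c: 1.0 for c in small_genome.feature_classes()}, background=1.0
        )
        m = simulate_wgbs(small_genome, profile, cfg)
        empty = RegionSet(pd.DataFrame(columns=["contig", "start", "end", "label"]))
        reads = simulate_long_reads(small_genome, m, empty, cfg)
        assert (reads.calls["call"] == "M").all()

    def test_determinism(self, small_genome):
        cfg = quick_config(seed=13, n_reads=50)
        m = simulate_wgbs(small_genome, MethylationProfile.baseline(), cfg)
        empty = RegionSet(pd.DataFrame(columns=["contig", "start", "end", "label"]))
        r1 = simulate_long_reads(small_genome, m, empty, cfg)
        r2 = simulate_long_reads(small_genome, m, empty, cfg)
        pd.testing.assert_frame_equal(r1.blocks, r2.blocks)
        pd.testing.assert_frame_equal(r1.calls, r2.calls)


class TestLfq:
    def test_no_dropout_no_missing(self):
        cfg = quick_config(seed=14)
        cfg.lfq.dropout_max = 0.0
        sim = simulate_lfq(cfg)
        assert not sim.matrix.isna().any().any()

    def test_spiked_rows_have_largest_prenoise_differences(self):
        cfg = quick_config(seed=15)
        cfg.lfq.n_proteins, cfg.lfq.n_spiked, cfg.lfq.effect_log2 = 1000, 20, 4.0
        sim = simulate_lfq(cfg)
        bait_cols = sim.groups[sim.groups == "bait"].index
        ctrl_cols = sim.groups[sim.groups == "control"].index
        diff = sim.truth[bait_cols].mean(axis=1) - sim.truth[ctrl_cols].mean(axis=1)
        top20 = set(diff.nlargest(20).index)
        assert top20 == set(sim.spiked)

    def test_dropout_concentrates_at_low_intensity(self):
        cfg = quick_config(seed=16)
        sim = simulate_lfq(cfg)
        missing_mask = sim.matrix.isna()
        assert missing_mask.any().any()
        observed_means = sim.truth[missing_mask].stack().mean()
        kept_means = sim.truth[~missing_mask].stack().mean()
        assert observed_means < kept_means

    def test_determinism(self):
        cfg = quick_config(seed=17)
        s1, s2 = simulate_lfq(cfg), simulate_lfq(cfg)
        pd.testing.assert_frame_equal(s1.matrix, s2.matrix)
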