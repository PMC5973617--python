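"""Synthetic experiment generator: determinism, conservation, null
construction and ground-truth structure."""

import dataclasses
import math

import numpy as np
import pytest

from beflitter import (
    Composition,
    ConfigurationError,
    SyntheticConfig,
    compute_metrics,
    generate_experiment,
    ground_truth,
    write_experiment,
)


class TestConfig:
    def test_design_has_fifteen_compositions_for_four_species(self, paper_config):
        comps = paper_config.compositions()
        assert len(comps) == 15
        assert sorted(c.richness for c in comps) == [1] * 4 + [2] * 6 + [3] * 4 + [4]

    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("gamma", -0.1, "gamma"),
            ("f_d", 1.5, "f_d"),
            ("assimilation_efficiency", -0.2, "assimilation_efficiency"),
            ("k_micro", {"A": 0.01}, "k_micro"),
            ("preference_trait", "no_such_trait", "preference"),
            ("replicates", 0, "replicates"),
        ],
    )
    def test_invalid_fields_name_the_field(self, field, value, match):
        with pytest.raises(ConfigurationError, match=match):
            SyntheticConfig(**{field: value})

    def test_scenario_constructors(self):
        assert SyntheticConfig.null().gamma == 1.0
        assert SyntheticConfig.null().preference_exponent == 0.0
        assert SyntheticConfig.complementarity_only().gamma > 1.0
        assert SyntheticConfig.selection_only().preference_exponent > 0.0


class TestDeterminism:
    def test_identical_seed_gives_identical_csv_bytes(self, tmp_path):
        cfg = SyntheticConfig(seed=123, replicates=2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_experiment(generate_experiment(cfg), p1)
        write_experiment(generate_experiment(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_changes_output(self):
        r1 = generate_experiment(SyntheticConfig(seed=1, replicates=2))
        r2 = generate_experiment(SyntheticConfig(seed=2, replicates=2))
        assert r1[0].final_afdm != r2[0].final_afdm

    def test_adding_replicates_never_changes_existing_ones(self):
        small = generate_experiment(SyntheticConfig(seed=9, replicates=4))
        large = generate_experiment(SyntheticConfig(seed=9, replicates=8))
        small_ids = {r.microcosm_id: r for r in small}
        large_ids = {r.microcosm_id: r for r in large}
        assert set(small_ids) <= set(large_ids)
        for mid, rec in small_ids.items():
            assert large_ids[mid].final_afdm == rec.final_afdm
            assert large_ids[mid].fpom_filter_mass == rec.fpom_filter_mass


class TestDesignShape:
    def test_paper_design_counts(self, paper_records):
        assert len(paper_records) == 150
        assert sum(r.detritivores_present for r in paper_records) == 75
        by_mixture = {}
        for r in paper_records:
            by_mixture.setdefault(r.composition.label, []).append(r)
        assert len(by_mixture) == 15
        assert all(len(v) == 10 for v in by_mixture.values())

    def test_disc_allocation_splits_48_equally(self, paper_records):
        for rec in paper_records:
            assert rec.n_discs_per_species * rec.composition.richness == 48

    def test_three_larvae_with_case_lengths_when_detritivores(self, paper_records):
        for rec in paper_records:
            if rec.detritivores_present:
                assert len(rec.detritivore_case_lengths) == 3
            else:
                assert rec.detritivore_case_lengths is None


class TestMechanisms:
    def test_conservation_noise_free(self):
        """Post-leach AFDM = final AFDM + microbial loss + consumption,
        verified against an independent closed form with consumption off."""
        cfg = SyntheticConfig.null(seed=3, replicates=2, consumption_rate=0.0).with_noise_off()
        t = cfg.duration
        for rec in generate_experiment(cfg):
            for sp in rec.composition.species:
                post_leach = rec.initial_airdry_dm[sp] * cfg.leaching[sp]
                microbial = post_leach * (1.0 - math.exp(-cfg.k_micro[sp] * t))
                assert rec.final_afdm[sp] == pytest.approx(
                    post_leach - microbial, abs=1e-9
                )

    def test_no_consumption_makes_arms_identical(self):
        cfg = SyntheticConfig.null(seed=3, replicates=2, consumption_rate=0.0).with_noise_off()
        records = generate_experiment(cfg)
        by_key = {}
        for r in records:
            by_key.setdefault(r.composition.label, {})[r.detritivores_present] = r
        for label, arms in by_key.items():
            assert arms[True].final_afdm == pytest.approx(arms[False].final_afdm)
            assert sum(arms[True].fpom_filter_mass) == pytest.approx(
                sum(arms[False].fpom_filter_mass), abs=1e-9
            )

    def test_fpom_is_f_m_of_microbial_when_consumption_off(self):
        cfg = SyntheticConfig.null(seed=3, replicates=2, consumption_rate=0.0).with_noise_off()
        t = cfg.duration
        for rec in generate_experiment(cfg):
            microbial = sum(
                rec.initial_airdry_dm[sp]
                * cfg.leaching[sp]
                * (1.0 - math.exp(-cfg.k_micro[sp] * t))
                for sp in rec.composition.species
            )
            assert sum(rec.fpom_filter_mass) == pytest.approx(cfg.f_m * microbial, abs=1e-9)

    def test_null_mixture_loss_is_proportional_monoculture_loss(self):
        """gamma = 1 and equal preferences force each mixture species to
        lose exactly p_i times its monoculture loss (no diversity effect
        by construction)."""
        cfg = SyntheticConfig.null(seed=3, replicates=2).with_noise_off()
        records = generate_experiment(cfg)
        mono_loss = {}
        for r in records:
            if r.composition.richness == 1 and r.detritivores_present:
                sp = r.composition.species[0]
                mono_loss[sp] = (
                    r.initial_airdry_dm[sp] * cfg.leaching[sp] - r.final_afdm[sp]
                )
        for r in records:
            if r.composition.richness > 1 and r.detritivores_present:
                p = 1.0 / r.composition.richness
                for sp in r.composition.species:
                    loss = r.initial_airdry_dm[sp] * cfg.leaching[sp] - r.final_afdm[sp]
                    assert loss == pytest.approx(p * mono_loss[sp], rel=1e-9)

    def test_case_lengths_recover_larval_mass(self, paper_config, paper_records):
        allo = paper_config.allometry
        for rec in paper_records[:20]:
            if rec.detritivores_present:
                total = sum(allo.dm(cl) for cl in rec.detritivore_case_lengths)
                assert 5.0 < total < 40.0  # plausible biomass near 17.8 mg


class TestGroundTruth:
    def test_null_config_has_zero_expected_effects(self):
        truth = ground_truth(SyntheticConfig.null())
        for mx in truth["mixtures"].values():
            assert mx["net"] == pytest.approx(0.0, abs=1e-9)
            assert mx["complementarity"] == pytest.approx(0.0, abs=1e-9)
            assert mx["selection"] == pytest.approx(0.0, abs=1e-9)
            assert mx["fpom_net"] == pytest.approx(0.0, abs=1e-9)

    def test_complementarity_only_gives_positive_ce_negligible_se(self):
        truth = ground_truth(SyntheticConfig.complementarity_only())
        for mx in truth["mixtures"].values():
            assert mx["complementarity"] > 0
            assert abs(mx["selection"]) < 0.1 * mx["complementarity"]

    def test_preference_for_top_species_gives_positive_se(self):
        truth = ground_truth(SyntheticConfig.selection_only())
        mono = truth["monoculture_normalized_loss"]
        # the preferred (highest-N) species also has the top monoculture loss
        assert max(mono, key=mono.get) == "A"
        for label, mx in truth["mixtures"].items():
            if "A" in label:
                assert mx["selection"] > 0

    def test_identity_holds_in_ground_truth(self, paper_config):
        truth = ground_truth(paper_config)
        for mx in truth["mixtures"].values():
            assert mx["net"] == pytest.approx(
                mx["complementarity"] + mx["selection"], abs=1e-9
            )

    def test_mean_growth_near_forty_two_percent(self, paper_config, paper_metrics):
        """Design-wide mean detritivore growth emulates the observed ~42%."""
        det = paper_metrics[paper_metrics["detritivores"]]
        assert det["growth_pct"].mean() == pytest.approx(42.0, abs=5.0)


class TestNoiseModel:
    def test_mass_noise_is_mean_preserving(self):
        cfg = SyntheticConfig.null(seed=0, replicates=60, mass_cv=0.10)
        records = generate_experiment(cfg)
        vals = [
            r.final_afdm["A"]
            for r in records
            if r.composition.label == "A" and not r.detritivores_present
        ]
        truth = generate_experiment(cfg.with_noise_off())[0]
        post_leach = truth.initial_airdry_dm["A"] * cfg.leaching["A"]
        expected = post_leach - post_leach * (1 - math.exp(-cfg.k_micro["A"] * cfg.duration))
        mean = np.mean(vals)
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - expected) < 4 * sem

    def test_fpom_events_nonnegative_and_sum_close_to_total(self, paper_records):
        for rec in paper_records:
            assert all(f >= 0 for f in rec.fpom_filter_mass)
            assert len(rec.fpom_filter_mass) == 3
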