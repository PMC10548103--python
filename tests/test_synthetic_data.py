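"""The forward simulator: determinism, Mendelian consistency, and the
closed-form expectations its draws must satisfy."""

import numpy as np
import pandas as pd
import pytest

from progenyarray import (
    Generation,
    MultilocusGenotype,
    SimulationConfig,
    apply_genotyping_noise,
    draw_allele_frequencies,
    expected_selfed_fraction,
    simulate_experiment,
    simulate_founder_genotypes,
    simulate_offspring_genotype,
    simulate_progeny_arrays,
)
from progenyarray.synthetic_data import SimulationError


class TestConfigValidation:
    def test_class_probs_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="class_probs"):
            SimulationConfig(class_probs=(0.5, 0.5, 0.5, 0.5), seed=1)

    def test_mixer_rate_bounded(self):
        with pytest.raises(SimulationError, match="s_mixer"):
            SimulationConfig(s_mixer=0.5, seed=1)

    def test_too_few_alleles_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(alleles_per_locus=1, seed=1)


class TestAlleleFrequencyDraws:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=9)
        a = draw_allele_frequencies(cfg)
        b = draw_allele_frequencies(cfg)
        assert all(np.array_equal(a[l], b[l]) for l in a)

    def test_frequencies_sum_to_one(self):
        freqs = draw_allele_frequencies(SimulationConfig(seed=2))
        assert len(freqs) == 10  # 9 active + 1 excluded locus
        for p in freqs.values():
            assert p.sum() == pytest.approx(1.0)

    def test_high_concentration_near_uniform(self):
        cfg = SimulationConfig(seed=3, freq_concentration=1e6, alleles_per_locus=10)
        freqs = draw_allele_frequencies(cfg)
        for p in freqs.values():
            np.testing.assert_allclose(p, 0.1, atol=0.01)

    def test_dirichlet_mean_frequency(self):
        """With concentration 1 over 10 alleles the mean per-allele
        frequency over many draws is 1/10."""
        rng = np.random.default_rng(5)
        draws = rng.dirichlet(np.ones(10), size=10_000)
        np.testing.assert_allclose(draws.mean(axis=0), 0.1, atol=0.01)


class TestFounderGenotypes:
    def test_fixed_allele_gives_monomorphic_homozygotes(self):
        freqs = {"L1": np.array([1.0, 0.0])}
        table = simulate_founder_genotypes(freqs, 20, np.random.default_rng(1))
        assert all(ind.call("L1") == (1, 1) for ind in table.individuals)

    def test_heterozygosity_matches_hwe(self):
        freqs = {"L1": np.array([0.3, 0.7])}
        table = simulate_founder_genotypes(freqs, 5000, np.random.default_rng(6))
        h_obs = np.mean([len(set(i.call("L1"))) == 2 for i in table.individuals])
        assert abs(h_obs - 2 * 0.3 * 0.7) < 0.02


class TestOffspringGenotypes:
    def test_homozygous_cross_is_fixed(self):
        mom = MultilocusGenotype("M", Generation.F1, None, {"L1": (1, 1)})
        dad = MultilocusGenotype("D", Generation.F1, None, {"L1": (2, 2)})
        rng = np.random.default_rng(0)
        for k in range(20):
            child = simulate_offspring_genotype(mom, dad, rng, f"c{k}")
            assert child.call("L1") == (1, 2)

    def test_selfed_heterozygote_segregates_1_2_1(self):
        mom = MultilocusGenotype("M", Generation.F1, None, {"L1": (1, 2)})
        rng = np.random.default_rng(7)
        counts = {(1, 1): 0, (1, 2): 0, (2, 2): 0}
        for k in range(4000):
            counts[simulate_offspring_genotype(mom, mom, rng, f"c{k}").call("L1")] += 1
        assert abs(counts[(1, 1)] / 4000 - 0.25) < 0.025
        assert abs(counts[(1, 2)] / 4000 - 0.50) < 0.025

    def test_offspring_shares_allele_with_mother_at_every_locus(self):
        table, truth, _ = simulate_progeny_arrays(
            n_families=5, n_juveniles=6, selfing_rate=0.5, n_candidates=3, seed=14
        )
        for _, row in truth.iterrows():
            juv = table.get(row.juvenile_id)
            mom = table.get(row.mother_id)
            for locus, pair in juv.calls.items():
                assert set(pair) & set(mom.call(locus))


class TestGenotypingNoise:
    def test_zero_rates_identity(self):
        cfg = SimulationConfig(seed=4, dropout_rate=0.0, null_allele_freq=0.0)
        freqs = draw_allele_frequencies(cfg)
        table = simulate_founder_genotypes(freqs, 30, np.random.default_rng(3))
        assert apply_genotyping_noise(table, cfg) == table

    def test_full_dropout_erases_everything(self):
        cfg = SimulationConfig(seed=4, dropout_rate=1.0, null_allele_freq=0.0)
        freqs = draw_allele_frequencies(cfg)
        table = simulate_founder_genotypes(freqs, 10, np.random.default_rng(3))
        noisy = apply_genotyping_noise(table, cfg)
        assert all(not ind.calls for ind in noisy.individuals)

    def test_dropout_rate_recovered(self):
        cfg = SimulationConfig(seed=4, dropout_rate=0.05, null_allele_freq=0.0)
        freqs = draw_allele_frequencies(cfg)
        table = simulate_founder_genotypes(freqs, 1000, np.random.default_rng(3))
        noisy = apply_genotyping_noise(table, cfg, np.random.default_rng(8))
        n_total = sum(len(i.calls) for i in table.individuals)
        n_left = sum(len(i.calls) for i in noisy.individuals)
        assert abs((n_total - n_left) / n_total - 0.05) < 0.01

    def test_null_alleles_confined_to_flagged_locus(self):
        cfg = SimulationConfig(seed=4, dropout_rate=0.0, null_allele_freq=0.5)
        sim_panel_cfg = cfg
        freqs = draw_allele_frequencies(cfg)
        from progenyarray import GenotypeTable

        base = simulate_founder_genotypes(freqs, 200, np.random.default_rng(3))
        table = GenotypeTable(sim_panel_cfg.panel(), base.individuals)
        noisy = apply_genotyping_noise(table, cfg)
        null_locus = "L10"
        changed = sum(
            noisy.get(i.individual_id).call(null_locus) != i.call(null_locus)
            for i in table.individuals
        )
        assert changed > 0
        for i in table.individuals:
            for locus in table.active_loci:
                assert noisy.get(i.individual_id).call(locus) == i.call(locus)


class TestSimulateExperiment:
    def test_all_outcrossers_never_self(self):
        cfg = SimulationConfig(seed=6, class_probs=(1.0, 0.0, 0.0, 0.0))
        sim = simulate_experiment(cfg)
        assert not sim.truth.juveniles.selfed.any()
        assert (sim.truth.individuals.propensity_class == "outcrosser").all()

    def test_all_selfers_at_rate_one_sire_is_mother(self):
        cfg = SimulationConfig(seed=6, class_probs=(0.0, 0.0, 0.0, 1.0), s_selfer=1.0)
        sim = simulate_experiment(cfg)
        juv = sim.truth.juveniles
        assert juv.selfed.all()
        assert (juv.sire_id == juv.mother_id).all()

    def test_pooled_selfed_fraction_matches_closed_form(self):
        """Realized selfed fraction among genotyped juveniles averages to
        the class-weighted closed-form expectation (replicated runs tame
        the ~0.05 class-sampling noise of a single 56-family cohort)."""
        cfg0 = SimulationConfig(seed=0)
        expect = expected_selfed_fraction(cfg0)
        fracs = []
        for seed in range(8):
            sim = simulate_experiment(SimulationConfig(seed=seed))
            gen = sim.truth.juveniles[sim.truth.juveniles.genotyped]
            fracs.append(gen.selfed.mean())
        assert abs(np.mean(fracs) - expect) < 0.05

    def test_shapes_and_truth_completeness(self):
        cfg = SimulationConfig(seed=1)
        sim = simulate_experiment(cfg)
        assert len(sim.truth.individuals) == 274
        assert sim.truth.individuals.mother_id.nunique() == 38
        assert len(sim.records) == 274
        treatments = sim.truth.individuals.treatment.value_counts()
        assert treatments["once_paired"] == 137
        # every emitted genotype has a truth row
        truth_ids = set(sim.truth.individuals.individual_id) | set(
            sim.truth.juveniles.juvenile_id
        )
        for ind in sim.genotypes.individuals:
            if ind.generation in (Generation.F1, Generation.F2):
                assert ind.individual_id in truth_ids
        # genotyped juveniles per family within the configured bounds
        gen = sim.truth.juveniles[sim.truth.juveniles.genotyped]
        per_fam = gen.groupby("mother_id").size()
        assert per_fam.max() <= cfg.juveniles_per_family_cap
        assert per_fam.min() >= cfg.juveniles_per_family_floor

    def test_no_maternal_mismatch_before_noise(self):
        cfg = SimulationConfig(seed=2, dropout_rate=0.0, null_allele_freq=0.0)
        sim = simulate_experiment(cfg)
        f2 = sim.genotypes.by_generation(Generation.F2)
        for juv in f2[:200]:
            mom = sim.genotypes.get(juv.mother_id)
            for locus, pair in juv.calls.items():
                if mom.call(locus) is not None:
                    assert set(pair) & set(mom.call(locus))

    def test_byte_identical_reproducibility(self):
        cfg = SimulationConfig(seed=123)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        assert a.genotypes == b.genotypes
        assert a.records == b.records
        pd.testing.assert_frame_equal(a.truth.individuals, b.truth.individuals)
        pd.testing.assert_frame_equal(a.truth.juveniles, b.truth.juveniles)

    def test_candidate_window_bounds_true_sires(self):
        """Repeatedly paired broods are sired only within the 3-5 partner
        window recorded in the truth table."""
        cfg = SimulationConfig(seed=44)
        sim = simulate_experiment(cfg)
        ind = sim.truth.individuals.set_index("individual_id")
        juv = sim.truth.juveniles
        outcrossed = juv[~juv.selfed]
        for _, row in outcrossed.sample(200, random_state=0).iterrows():
            info = ind.loc[row.mother_id]
            window = info.partner_ids.split(";")[: info.candidate_window]
            assert row.sire_id in window
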