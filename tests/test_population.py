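"""Population simulator: fitness, MEP cohorts, batch, competition, growth."""

import dataclasses
import math

import numpy as np
import pytest

from stimcnv import (
    Cell,
    EnvironmentCondition,
    FitnessParams,
    GrowthCurve,
    LocusConfig,
    ModelParams,
    RateParams,
    inhibition,
    run_batch_culture,
    run_competition,
    run_mep_cohort,
    simulate_growth_curve,
    step_division,
)
from stimcnv.errors import ConfigurationError, DomainError, ParameterError, StateError
from stimcnv.inference import max_growth_rate

FP = FitnessParams()

#: parameters with CNV switched off entirely
NO_CNV = dataclasses.replace(ModelParams(), rate=RateParams(b=0.0, r_max=0.0))


class TestInhibition:
    def test_no_copper_no_inhibition(self):
        for copies in (0, 3, 13, 100):
            assert inhibition(copies, 0.0, FP) == 0.0

    def test_vanishes_at_high_copy_number(self):
        assert inhibition(10_000, 1.0, FP) < 1e-3

    def test_decreasing_in_copies(self):
        grid = np.arange(0, 40)
        vals = inhibition(grid, 0.75, FP)
        assert np.all(np.diff(vals) < 0)

    def test_three_copies_lethally_inhibited_at_0p75(self):
        """0.75 mM copper fully inhibits 3-copy cells: their inhibition
        exceeds the death half-point, unlike the high-copy strain's."""
        assert inhibition(3, 0.75, FP) > FP.death_threshold
        assert inhibition(3, 0.75, FP) > inhibition(13, 0.75, FP)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            inhibition(-1, 0.5, FP)
        with pytest.raises(DomainError):
            inhibition(3, -0.5, FP)


class TestStepDivision:
    def test_dead_cell_rejected(self, cup1_locus, plain_env, model, rng):
        cell = Cell(alleles=[13, 13], alive=False)
        with pytest.raises(StateError):
            step_division(cell, plain_env, cup1_locus, model=model, rng=rng)

    def test_no_mutation_identity(self, cup1_locus, plain_env, rng):
        cell = Cell(alleles=[13, 14])
        dt, daughter = step_division(cell, plain_env, cup1_locus, model=NO_CNV, rng=rng)
        assert cell.alleles == [13, 14]
        assert daughter is not None and daughter.alleles == [13, 14]
        assert dt == pytest.approx(1.0 / FP.mu_max)
        assert cell.divisions == 1

    def test_estradiol_blocks_daughters(self, cup1_locus, rng):
        env = EnvironmentCondition(estradiol=True)
        cell = Cell(alleles=[13, 13])
        for _ in range(20):
            if not cell.alive:
                break
            _, daughter = step_division(cell, env, cup1_locus, model=NO_CNV, rng=rng)
            assert daughter is None


class TestMepCohort:
    def test_division_count_matches_untreated_calibration(self, cup1_locus, rng):
        """Unstressed founders complete about 12 divisions in 24 hours."""
        env = EnvironmentCondition(estradiol=True)
        res = run_mep_cohort(100, env, 24.0, cup1_locus, model=NO_CNV, rng=rng)
        assert 10.0 <= res.mean_divisions <= 14.0

    def test_copper_lowers_viability(self, cup1_locus, model):
        rng = np.random.default_rng(5)
        untreated = run_mep_cohort(
            150, EnvironmentCondition(estradiol=True), 24.0, cup1_locus,
            model=model, rng=rng,
        )
        treated = run_mep_cohort(
            150, EnvironmentCondition(copper_mM=1.0, estradiol=True), 24.0,
            cup1_locus, model=model, rng=rng,
        )
        assert treated.viability < untreated.viability
        assert untreated.viability > 0.75

    def test_lineages_never_exceed_cohort(self, cup1_locus, model):
        """MEP conservation: with zero escape probability the recovered
        founders can never outnumber the starting cohort."""
        rng = np.random.default_rng(11)
        res = run_mep_cohort(
            50, EnvironmentCondition(estradiol=True), 24.0, cup1_locus,
            model=model, rng=rng,
        )
        assert res.n_recovered <= res.n_start
        assert res.allele_table["cell_id"].nunique() == res.n_recovered

    def test_basal_cnv_fraction_matches_binomial_expectation(self, cup1_locus):
        """Without stimulation the deviating-allele fraction of recovered
        founders follows the closed form 1−(1−b·q·½)^divisions per allele,
        where q is the probability a drawn event has a non-zero net delta and
        ½ is the chance the mutated allele stays with the mother."""
        from stimcnv import enumerate_switch_outcomes, SwitchScheme

        b = 0.004
        basal_only = dataclasses.replace(ModelParams(), rate=RateParams(b=b, r_max=0.0))
        rng = np.random.default_rng(3)
        res = run_mep_cohort(
            400, EnvironmentCondition(estradiol=True), 24.0, cup1_locus,
            model=basal_only, rng=rng,
        )
        counts = res.to_counts([cup1_locus.copies] * 2)
        q_change = sum(
            o.probability
            for o in enumerate_switch_outcomes(SwitchScheme()).outcomes
            if o.delta != 0
        )
        p_div = b * q_change * 0.5
        p_expect = 1.0 - (1.0 - p_div) ** res.mean_divisions
        n = counts.alleles_assayed
        se = math.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(counts.events / n - p_expect) < 3 * se

    def test_empty_cohort_flagged(self, cup1_locus, plain_env, model, rng):
        res = run_mep_cohort(0, plain_env, 24.0, cup1_locus, model=model, rng=rng)
        assert res.n_recovered == 0
        assert len(res.allele_table) == 0
        assert math.isnan(res.viability)


class TestBatchCulture:
    def test_rate_zero_keeps_parental_allele(self, cup1_locus, plain_env):
        rng = np.random.default_rng(1)
        res = run_batch_culture([13] * 300, plain_env, 8, cup1_locus, model=NO_CNV, rng=rng)
        assert res.distribution.index.tolist() == [13]
        assert res.distribution.iloc[0] == 1.0
        assert not res.extinct

    def test_galactose_stimulates_cnv_over_glucose(self, gal_locus, model):
        """Paired runs of the galactose-inducible construct: induction in
        galactose produces far more non-parental alleles than glucose."""
        def nonparental(galactose, seed):
            rng = np.random.default_rng(seed)
            res = run_batch_culture(
                [17] * 400, EnvironmentCondition(galactose_frac=galactose), 10,
                gal_locus, model=model, rng=rng,
            )
            return 1.0 - res.distribution.get(17, 0.0)

        for seed in (0, 1, 2):
            assert nonparental(1.0, seed) > 5 * max(nonparental(0.0, seed), 0.002)

    def test_copper_selection_raises_mean_copy_number(self, model):
        """Selection sanity: under copper, the abundance-weighted mean copy
        number ends at or above the neutral (no-copper) run's."""
        locus = LocusConfig("CUP1", copies=3, promoter_kind="copper_inducible")

        def weighted_mean(copper, seed):
            rng = np.random.default_rng(seed)
            res = run_batch_culture(
                [3] * 400, EnvironmentCondition(copper_mM=copper), 8, locus,
                model=model, rng=rng,
            )
            return float((res.distribution.index * res.distribution).sum())

        for seed in (0, 1, 2):
            assert weighted_mean(0.3, seed) >= weighted_mean(0.0, seed) - 0.05

    def test_degenerate_inputs_rejected(self, cup1_locus, plain_env, model, rng):
        with pytest.raises(DomainError):
            run_batch_culture([], plain_env, 5, cup1_locus, model=model, rng=rng)
        with pytest.raises(DomainError):
            run_batch_culture([13], plain_env, 0, cup1_locus, model=model, rng=rng)


class TestCompetition:
    def test_identical_populations_stay_even(self, model):
        """Neutral competition is exchangeable: the mean share change across
        seeds is within 2 SE of zero."""
        locus = LocusConfig("CUP1", copies=3)
        changes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = run_competition(
                ("A", [3] * 200), ("B", [3] * 200), EnvironmentCondition(), 6,
                locus, model=model, rng=rng,
            )
            changes.append(res.change)
        changes = np.asarray(changes)
        se = changes.std(ddof=1) / math.sqrt(len(changes))
        assert abs(changes.mean()) < 2 * se + 1e-9

    def test_amplified_population_wins_in_copper(self, model):
        locus = LocusConfig("CUP1", copies=13)
        rng = np.random.default_rng(42)
        res = run_competition(
            ("amplified", [13] * 300), ("naive", [3] * 300),
            EnvironmentCondition(copper_mM=0.3), 10, locus, model=model, rng=rng,
        )
        assert res.change > 10.0
        assert res.after["amplified"] + res.after["naive"] == pytest.approx(100.0)

    def test_marker_collision_rejected(self, model, rng):
        locus = LocusConfig("CUP1", copies=3)
        with pytest.raises(ConfigurationError):
            run_competition(
                ("A", [3] * 10), ("A", [3] * 10), EnvironmentCondition(), 5,
                locus, model=model, rng=rng,
            )


class TestGrowthCurve:
    def test_zero_founders_flat_at_blank(self, cup1_locus, plain_env, model, rng):
        curve = simulate_growth_curve([], plain_env, 24, 0.25, cup1_locus, model=model, rng=rng)
        assert np.allclose(curve.od, model.sim.od_blank)

    def test_max_derivative_matches_logistic_form(self, cup1_locus, plain_env, model, rng):
        """Noiseless simulated curve: max dOD/dt ≈ mu·C/4 (within 5%)."""
        curve = simulate_growth_curve(
            [13] * 100, plain_env, 72, 0.25, cup1_locus, model=model, rng=rng
        )
        expected = model.fitness.mu_max * model.sim.od_capacity / 4.0
        assert max_growth_rate(curve).rate == pytest.approx(expected, rel=0.05)

    def test_lethal_copper_prevents_growth(self, model, rng):
        """3-copy cells in 0.75 mM copper never reach 10% of capacity."""
        locus = LocusConfig("CUP1", copies=3)
        curve = simulate_growth_curve(
            [3] * 100, EnvironmentCondition(copper_mM=0.75), 72, 0.25, locus,
            model=NO_CNV, rng=rng,
        )
        assert np.all(curve.od - model.sim.od_blank < 0.1 * model.sim.od_capacity)

    def test_validation(self):
        with pytest.raises(ParameterError):
            GrowthCurve(times=np.array([0.0, 1.0, 0.5]), od=np.zeros(3))
        with pytest.raises(ParameterError):
            GrowthCurve(times=np.array([0.0, 1.0]), od=np.array([0.1, -0.1]))
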