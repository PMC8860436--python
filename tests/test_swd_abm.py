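"""Agent-based field model: sperm precedence, cohorts, stepping, eradication."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ssims.genetics import ssims_male, wt_female, wt_male
from ssims.swd_abm import (
    Agent,
    LifecycleParams,
    ReleaseStrategy,
    SeasonConfig,
    SimState,
    days_to_eradication,
    released_cohort,
    run_season,
    step_day,
    update_sperm_store,
)
from ssims.tet_dosimetry import TetParams, rearing_steady_state


class TestSpermStore:
    def test_first_mating_takes_full_weight(self):
        store = update_sperm_store((), ssims_male(), 0.8)
        assert store == ((ssims_male(), 1.0),)

    def test_last_male_precedence_rescales_prior_weights(self):
        a, b = wt_male(), ssims_male()
        store = update_sperm_store(((a, 1.0),), b, 0.8)
        weights = dict((g.to_string(), w) for g, w in store)
        assert weights[a.to_string()] == pytest.approx(0.2)
        assert weights[b.to_string()] == pytest.approx(0.8)

    def test_third_mating_compounds_geometrically(self):
        a, b = wt_male(), ssims_male()
        store = update_sperm_store(((a, 0.2), (b, 0.8)), a, 0.8)
        total = sum(w for _, w in store)
        assert total == pytest.approx(1.0)
        assert [round(w, 4) for _, w in store] == [0.04, 0.16, 0.8]

    def test_invalid_p2_rejected(self):
        with pytest.raises(ValueError):
            update_sperm_store((), wt_male(), 1.5)


class TestReleasedCohort:
    def test_male_only_emits_only_ssims_males(self):
        rng = np.random.default_rng(0)
        agents = released_cohort(ReleaseStrategy(kind="SSIMS_male_only"), 10, rng)
        assert len(agents) == 10
        assert all(a.sex == "male" and a.genotype == ssims_male() for a in agents)

    def test_bisex_strategies_use_exact_floor_split(self):
        rng = np.random.default_rng(0)
        agents = released_cohort(ReleaseStrategy(kind="RIDL"), 10, rng)
        assert sum(a.sex == "female" for a in agents) == 5
        agents = released_cohort(ReleaseStrategy(kind="SSIMS_double_amp"), 11, rng)
        assert sum(a.sex == "female" for a in agents) == 5

    def test_released_exposure_is_rearing_steady_state(self):
        rng = np.random.default_rng(0)
        p = TetParams()
        double = released_cohort(ReleaseStrategy(kind="SSIMS_double_amp"), 4, rng)
        assert double[0].tet_exposure == pytest.approx(rearing_steady_state(100.0, p))
        single = released_cohort(ReleaseStrategy(kind="SSIMS_single_amp"), 4, rng)
        assert single[0].tet_exposure == pytest.approx(rearing_steady_state(10.0, p))

    def test_empty_and_invalid(self):
        rng = np.random.default_rng(0)
        assert released_cohort(ReleaseStrategy(kind="SSIMS_double_amp"), 0, rng) == []
        with pytest.raises(ValueError):
            ReleaseStrategy(kind="XXX")


class TestStepDay:
    def test_empty_state_stays_empty(self):
        state = SimState()
        step_day(state, 20.0, np.random.default_rng(0))
        assert state.n == 0

    def test_unmated_female_without_males_lays_nothing(self):
        state = SimState()
        state.add_agents([Agent(genotype=wt_female())])
        for _ in range(10):
            step_day(state, 18.0, np.random.default_rng(1))
        assert state.day_eggs_laid == 0

    def test_wt_female_with_ssims_store_never_produces_larvae(self):
        state = SimState()
        state.add_agents(
            [Agent(genotype=wt_female(), sperm_store=((ssims_male(), 1.0),))]
        )
        rng = np.random.default_rng(2)
        laid = 0
        for _ in range(20):
            step_day(state, 18.0, rng)
            laid += state.day_eggs_laid
            assert state.day_eggs_inviable == state.day_eggs_laid
        assert laid > 0
        assert state.fieldborn_gm_created == 0
        # only the mother herself can remain alive; no offspring ever enters
        assert state.n <= 1

    def test_mated_wt_female_with_male_produces_offspring(self):
        state = SimState()
        state.add_agents(
            [
                Agent(genotype=wt_female(), sperm_store=((wt_male(), 1.0),)),
                Agent(genotype=wt_male()),
            ]
        )
        rng = np.random.default_rng(3)
        for _ in range(5):
            step_day(state, 18.0, rng)
        assert state.n > 2


class TestDaysToEradication:
    def test_persistent_zero_from_day_three(self):
        assert days_to_eradication(np.array([5, 2, 0, 0, 0])) == 3

    def test_transient_zero_does_not_count(self):
        assert days_to_eradication(np.array([1, 0, 3, 0, 0])) == 4

    def test_not_reached(self):
        assert days_to_eradication(np.array([5, 2, 1, 1, 2])) is None

    def test_never_present(self):
        assert days_to_eradication(np.array([0, 0, 0])) == 1


class TestRunSeason:
    def test_zero_population_no_releases_all_zero(self, mean_curve_temps):
        cfg = SeasonConfig(initial_adults=0)
        s = run_season(cfg, mean_curve_temps, seed=1)
        assert s.total_alive.sum() == 0
        assert s.cumulative_wt_hatched == 0
        assert days_to_eradication(s) == 1

    def test_series_shorter_than_window_errors(self, mean_curve_temps):
        cfg = SeasonConfig(start=dt.date(2021, 2, 1), end=dt.date(2021, 9, 1))
        with pytest.raises(ValueError):
            run_season(cfg, mean_curve_temps, seed=1)

    def test_identical_seed_gives_bit_identical_summary(self, mean_curve_temps):
        cfg = SeasonConfig(
            strategy=ReleaseStrategy(kind="SSIMS_double_amp", size=40, interval=7)
        )
        a = run_season(cfg, mean_curve_temps, seed=9)
        b = run_season(cfg, mean_curve_temps, seed=9)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.eggs_laid, b.eggs_laid)
        assert a.cumulative_wt_hatched == b.cumulative_wt_hatched
        assert a.gm_female_pupae_by_gen == b.gm_female_pupae_by_gen
        pd.testing.assert_frame_equal(a.to_tidy(), b.to_tidy())

    def test_tidy_census_reconstructs_totals(self, mean_curve_temps):
        cfg = SeasonConfig(
            start=dt.date(2021, 5, 1), end=dt.date(2021, 6, 30), initial_adults=40
        )
        s = run_season(cfg, mean_curve_temps, seed=4)
        tidy = s.to_tidy()
        assert (tidy["count"] > 0).all()
        assert tidy["count"].sum() == s.counts.sum()
        assert set(tidy["class"]) <= {"WT", "SSIMS", "EGI", "FL", "RIDL", "OTHER"}

    def test_summary_row_columns(self, mean_curve_temps):
        cfg = SeasonConfig(
            start=dt.date(2021, 5, 1), end=dt.date(2021, 5, 31), initial_adults=10
        )
        row = run_season(cfg, mean_curve_temps, seed=5).summary_row()
        assert list(row.columns) == [
            "cumulative_wt_hatched",
            "days_to_eradication",
            "seed",
        ]


class TestLifecycleParams:
    def test_rate_curves_piecewise_shapes(self):
        lc = LifecycleParams()
        assert lc.adult_mortality(-10.0) == lc.mort_cold
        assert lc.adult_mortality(15.0) == lc.mort_opt
        assert lc.adult_mortality(50.0) == lc.mort_hot
        assert lc.fecundity(lc.fec_t0) == 0.0
        assert lc.fecundity((lc.fec_t1 + lc.fec_t2) / 2) == lc.fec_peak
        assert lc.fecundity(lc.fec_t3 + 1.0) == 0.0
        mid = (lc.mort_opt_hi + lc.mort_hot_t) / 2
        assert lc.mort_opt < lc.adult_mortality(mid) < lc.mort_hot
        assert lc.juvenile_mortality_at(10.0) == lc.juvenile_mortality
        assert lc.juvenile_mortality_at(40.0) == pytest.approx(
            lc.juvenile_mortality + lc.juvenile_mort_hot
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            LifecycleParams(juvenile_mortality=1.5)
        with pytest.raises(ValueError):
            LifecycleParams(carrying_capacity=0.0)
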