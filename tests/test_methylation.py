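"""Maintenance-efficiency dynamics: equilibrium algebra, the binomial
population update against a per-cell oracle, and the Gillespie variant."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stochclock as sc
from stochclock.bulk import GroundState
from stochclock.methylation import (DEFAULT_LIMITS, GillespieConfig,
                                    MaintenanceRates, MethylationPopulation,
                                    RateLimits, _gillespie_site, equilibrium,
                                    estimate_rates, init_population,
                                    step_population)


def universal(e_m, e_d, n=1):
    return MaintenanceRates.universal(n, e_m, e_d)


class TestEquilibrium:
    @pytest.mark.parametrize("e_m,e_d,expected", [
        (0.999, 0.001, 0.5),   # symmetric rates force the midpoint
        (0.98, 0.0, 0.0),      # no de novo methylation
        (1.0, 0.05, 1.0),      # methylation never lost
    ])
    def test_closed_form(self, e_m, e_d, expected):
        assert equilibrium(universal(e_m, e_d))[0] == pytest.approx(expected)

    def test_perfect_maintenance_flagged_not_numeric(self):
        meq = equilibrium(universal(1.0, 0.0))
        assert np.isnan(meq[0])

    def test_rates_outside_probability_range_rejected(self):
        with pytest.raises(ValueError):
            MaintenanceRates(np.array([1.1]), np.array([0.0]))


class TestEstimateRates:
    def test_algebraic_inversion_with_pinned_e_m(self):
        # pin E_m to 0.999 via degenerate limits; M_eq=0.5 forces E_d=0.001
        limits = RateLimits(0.9989, 0.999, 0.0, 0.23)
        rates = estimate_rates(np.array([0.5]), limits, "fix_em", seed=0)
        assert rates.e_m[0] == pytest.approx(0.999, abs=1e-4)
        assert rates.e_d[0] == pytest.approx(
            0.5 * (1 - rates.e_m[0]) / 0.5, abs=1e-12)

    def test_degenerate_equilibria_short_circuit(self):
        rates = estimate_rates(np.array([0.0, 1.0]), DEFAULT_LIMITS,
                               "fix_em", seed=1)
        assert rates.e_d[0] == 0.0
        assert rates.e_m[1] == 1.0

    @pytest.mark.parametrize("fix_side", ["fix_em", "fix_ed"])
    def test_round_trip_matches_equilibrium_equation(self, fix_side, rng):
        meq = rng.uniform(0.01, 0.99, 1000)
        limits = DEFAULT_LIMITS if fix_side == "fix_em" else \
            RateLimits(0.0, 1.0, 0.0, 0.23)
        rates = estimate_rates(meq, limits, fix_side, seed=2)
        np.testing.assert_allclose(equilibrium(rates), meq, atol=1e-12)
        if fix_side == "fix_em":
            assert rates.within_limits().all()

    def test_retry_exhaustion_names_the_feature(self):
        # E_m in (0.95, 0.96] forces E_d = 1 - E_m ~ 0.04 >> the 1e-6 cap
        limits = RateLimits(0.95, 0.96, 0.0, 1e-6)
        with pytest.raises(RuntimeError, match="feature 0"):
            estimate_rates(np.array([0.5]), limits, "fix_em", seed=3)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            estimate_rates(np.array([1.5]))


class TestPopulation:
    def test_init_rounds_betas_to_counts(self):
        g = GroundState(np.array([0.13, 0.0, 1.0]))
        pop = init_population(g, n_cells=1000)
        np.testing.assert_array_equal(pop.methylated_counts, [130, 0, 1000])
        # exact .5 ties round half-up (0.25 and 10 are float-exact)
        tie = init_population(GroundState(np.array([0.25, 0.75])), n_cells=10)
        np.testing.assert_array_equal(tie.methylated_counts, [3, 8])

    def test_counts_conserved_under_stepping(self, rng):
        pop = init_population(GroundState(np.linspace(0, 1, 50)), 100)
        rates = MaintenanceRates.random(50, seed=4)
        for _ in range(20):
            pop = step_population(pop, rates, rng)
            assert pop.methylated_counts.min() >= 0
            assert pop.methylated_counts.max() <= 100

    def test_perfect_maintenance_is_frozen(self, rng):
        pop = init_population(GroundState(np.array([0.3, 0.8])), 1000)
        rates = universal(1.0, 0.0, n=2)
        out = step_population(pop, rates, rng)
        np.testing.assert_array_equal(out.methylated_counts,
                                      pop.methylated_counts)

    def test_binomial_update_matches_per_cell_bernoulli_oracle(self, rng):
        """The aggregated Binomial(m,E_m)+Binomial(n-m,E_d) update must be
        distributionally identical to flipping each cell's coin."""
        n_cells, m0, e_m, e_d, reps = 50, 20, 0.9, 0.2, 10_000
        pop = MethylationPopulation(np.full(reps, m0), n_cells)
        rates = MaintenanceRates(np.full(reps, e_m), np.full(reps, e_d))
        binom = step_population(pop, rates, rng).methylated_counts

        cells = np.zeros((reps, n_cells), dtype=bool)
        cells[:, :m0] = True
        u = rng.uniform(size=(reps, n_cells))
        stayed = cells & (u < e_m)
        gained = ~cells & (u < e_d)
        oracle = (stayed | gained).sum(axis=1)

        exp_mean = m0 * e_m + (n_cells - m0) * e_d
        exp_var = m0 * e_m * (1 - e_m) + (n_cells - m0) * e_d * (1 - e_d)
        se = np.sqrt(exp_var / reps)
        for counts in (binom, oracle):
            assert counts.mean() == pytest.approx(exp_mean, abs=5 * se)
            assert counts.var() == pytest.approx(exp_var, rel=0.1)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(0.9, 0.9999), st.floats(0.0001, 0.1),
           st.floats(0.0, 1.0))
    def test_expected_beta_follows_geometric_decay(self, e_m, e_d, b0):
        """E[b_t] - M_eq = (b_0 - M_eq) (E_m - E_d)^t, checked by exact
        expectation propagation through the update recurrence."""
        meq = e_d / (1 + e_d - e_m)
        b = b0
        for t in range(1, 11):
            b = b * e_m + (1 - b) * e_d
            closed = meq + (b0 - meq) * (e_m - e_d) ** t
            assert b == pytest.approx(closed, abs=1e-12)


class TestMethylationDataset:
    def test_age_zero_equals_rounded_ground(self):
        g = sc.make_ground_state(30, seed=5)
        rates = universal(0.999, 0.001, 30)
        ds = sc.simulate_methylation_dataset(g, rates, max_age=3, n_sets=2,
                                             n_cells=1000, seed=6)
        young = ds.matrix[ds.ages == 0]
        expected = np.floor(g.values * 1000 + 0.5) / 1000
        np.testing.assert_array_equal(young[0], expected)
        np.testing.assert_array_equal(young[1], expected)

    def test_high_maintenance_deviates_minimally_from_ground(self):
        """At E_m = E_u = 99.9% a simulated age of 100 stays close to the
        ground state (geometric decay toward 0.5 is slow)."""
        g = sc.make_ground_state(200, seed=7)
        rates = universal(0.999, 0.001, 200)
        ds = sc.simulate_methylation_dataset(g, rates, max_age=100, n_sets=1,
                                             n_cells=1000, seed=8)
        old = ds.matrix[ds.ages == 99][0]
        expected_shrink = 1 - 0.998 ** 99  # relative drift toward 0.5
        drift = np.abs(old - g.values).mean()
        assert drift < 0.1
        analytic = np.abs(g.values - 0.5).mean() * expected_shrink
        assert drift == pytest.approx(analytic, abs=0.02)


class TestGillespie:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GillespieConfig(switch_rate_on=0.0)
        with pytest.raises(ValueError):
            GillespieConfig(tmax=-1.0)

    def test_first_switch_time_is_exponential(self, rng):
        """From an all-unmethylated single-cell start with a negligible
        reverse rate, the fraction switched by tmax is 1 - exp(-0.1 * 5)."""
        cfg = GillespieConfig(switch_rate_on=0.1, switch_rate_off=1e-12,
                              tmax=5.0)
        obs = np.array([5.0])
        switched = sum(
            _gillespie_site(0, 1, cfg, obs, rng)[0][0] for _ in range(4000))
        frac = switched / 4000
        assert frac == pytest.approx(1 - np.exp(-0.5), abs=0.03)

    def test_zero_time_observation_equals_initial_state(self):
        g = sc.make_ground_state(10, seed=9)
        cfg = GillespieConfig(seed=10)
        ds = sc.gillespie_dataset(g, cfg, n_samples_per_time=1,
                                  n_timepoints=6, n_cells=100)
        start = ds.matrix[ds.ages == 0][0]
        np.testing.assert_array_equal(
            start, np.floor(g.values * 100 + 0.5) / 100)

    def test_nrmax_truncation_warns(self):
        g = GroundState(np.array([0.5]))
        cfg = GillespieConfig(switch_rate_on=5.0, switch_rate_off=5.0,
                              tmax=5.0, nrmax=3, seed=11)
        with pytest.warns(UserWarning, match="nrmax"):
            sc.gillespie_dataset(g, cfg, 1, 5, n_cells=100)

    def test_clock_trained_on_gillespie_data_predicts_time(self):
        """Event-based simulation carries the same regression-to-equilibrium
        age signal as the discrete-step chain: held-out r >= 0.9."""
        g = sc.make_ground_state(60, seed=12)
        cfg = GillespieConfig(seed=13)
        ds = sc.gillespie_dataset(g, cfg, n_samples_per_time=4,
                                  n_timepoints=21, n_cells=100)
        train, validation = ds.train_validation_split(2)
        model = sc.train_clock(train, seed=0)
        report = sc.score_predictions(validation.ages,
                                      model.predict(validation))
        assert report.pearson_r >= 0.9
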