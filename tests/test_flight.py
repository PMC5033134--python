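"""Hazard shape, trial simulation, interval-censored likelihood, and recovery."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from coliastherm import (Morphology, NonIdentifiableError, ThermalSensitivity,
                         TrialConfig, fit_sensitivity, hazard,
                         initiation_loglik, simulate_trial,
                         simulate_trial_full, trajectories_from_matrix)
from conftest import constant_series


def warming_series(n=240, t0=360.0, start=15.0, rate=0.05, model=True):
    """A tent-like series whose model temperature warms linearly."""
    s = constant_series(n=n, t0=t0, air=start, soil=start, solar=100.0,
                        wind=0.2, direct_sun=False)
    ramp = start + rate * np.arange(n)
    s.air_temp = ramp.copy()
    s.soil_temp = ramp.copy()
    s.model_temp = ramp.copy()
    return s


def model_cfg(s, interval=1):
    return TrialConfig(check_interval=interval, t_start=int(s.time[0]),
                       t_end=int(s.time[-1]) + 1,
                       temperature_source="model-temp")


class TestHazard:
    def test_half_motivation_at_threshold(self):
        sens = ThermalSensitivity(25.0, 1.0, 0.8)
        assert hazard(25.0, sens) == pytest.approx(0.4)

    def test_cdf_limits(self):
        sens = ThermalSensitivity(25.0, 1.0, 0.7)
        assert hazard(-1e3, sens) == pytest.approx(0.0, abs=1e-12)
        assert hazard(1e3, sens) == pytest.approx(0.7)

    def test_normal_cdf_value(self):
        sens = ThermalSensitivity(25.0, 1.0, 1.0)
        assert hazard(26.0, sens) == pytest.approx(norm.cdf(1.0), abs=1e-9)
        assert hazard(26.0, sens) == pytest.approx(0.8413, abs=5e-4)

    def test_sharp_threshold_at_zero_sd(self):
        sens = ThermalSensitivity(25.0, 0.0, 0.6)
        assert hazard(24.999, sens) == 0.0
        assert hazard(25.0, sens) == pytest.approx(0.6)

    @given(t1=st.floats(-10, 60), t2=st.floats(-10, 60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, t1, t2):
        sens = ThermalSensitivity(25.0, 1.5, 0.8)
        lo, hi = sorted((t1, t2))
        assert hazard(lo, sens) <= hazard(hi, sens) <= sens.p_mot


class TestSimulateTrial:
    def test_unreachable_threshold_grounds_everyone(self):
        s = warming_series()
        recs = simulate_trial([Morphology(0.6, 1.0)] * 20, s,
                              ThermalSensitivity(90.0, 1.0, 1.0), model_cfg(s),
                              seed=0, species="x", site="y")
        assert all(not r.flew for r in recs)
        assert all(r.t_init is None for r in recs)

    def test_deterministic_threshold_fires_at_first_crossing(self):
        s = warming_series(rate=0.05)
        sens = ThermalSensitivity(20.0, 0.0, 1.0)
        recs, times, temps = simulate_trial_full(
            [Morphology(0.6, 1.0)] * 5, s, sens, model_cfg(s, interval=2), seed=0)
        crossing = times[np.argmax(temps[0] >= 20.0)]
        assert all(r.flew and r.t_init == crossing for r in recs)
        assert all(r.temp_at_init >= 20.0 for r in recs)

    def test_geometric_checks_to_initiation_at_threshold(self):
        """Constant temp at mu with p_mot=1: q=1/2 per check, mean checks = 2."""
        s = constant_series(n=121, model_temp=25.0)
        sens = ThermalSensitivity(25.0, 1.0, 1.0)
        recs, times, _ = simulate_trial_full(
            [Morphology(0.6, 1.0)] * 2000, s, sens, model_cfg(s), seed=5)
        checks = np.array([(r.t_init - s.time[0]) for r in recs if r.flew])
        assert len(checks) == 2000
        assert np.mean(checks) == pytest.approx(2.0, abs=0.1)
        assert np.mean(checks == 1.0) == pytest.approx(0.5, abs=0.03)

    def test_seeded_determinism(self):
        s = warming_series()
        sens = ThermalSensitivity(22.0, 1.0, 0.5)
        inds = [Morphology(0.6, 1.0)] * 30
        a = simulate_trial(inds, s, sens, model_cfg(s), seed=9)
        b = simulate_trial(inds, s, sens, model_cfg(s), seed=9)
        assert a == b

    def test_missing_model_channel_raises(self):
        s = constant_series(n=30)
        with pytest.raises(ValueError, match="model_temp"):
            simulate_trial([Morphology(0.6, 1.0)], s,
                           ThermalSensitivity(25, 1, 0.5), model_cfg(s), seed=0)

    def test_warmer_forcing_initiates_no_later(self):
        """A uniformly +5 degC trajectory stochastically advances initiation."""
        cool = warming_series(rate=0.05, start=14.0)
        warm = warming_series(rate=0.05, start=19.0)
        sens = ThermalSensitivity(22.0, 1.0, 0.5)
        inds = [Morphology(0.6, 1.0)] * 400
        rc = simulate_trial(inds, cool, sens, model_cfg(cool), seed=3)
        rw = simulate_trial(inds, warm, sens, model_cfg(warm), seed=3)
        t_cool = np.mean([r.t_init for r in rc if r.flew])
        t_warm = np.mean([r.t_init for r in rw if r.flew])
        assert t_warm < t_cool
        assert np.mean([r.flew for r in rw]) >= np.mean([r.flew for r in rc])

    def test_fixed_threshold_variant(self):
        """Per-individual thresholds: with p_mot=1, init temp tracks the draw."""
        s = warming_series(rate=0.05)
        sens = ThermalSensitivity(20.0, 1.0, 1.0)
        recs = simulate_trial([Morphology(0.6, 1.0)] * 800, s, sens,
                              model_cfg(s), seed=7, fixed_threshold=True)
        temps = np.array([r.temp_at_init for r in recs if r.flew])
        assert np.mean(temps) == pytest.approx(20.0, abs=0.15)


class TestLoglik:
    def test_nonflier_with_zero_hazard_contributes_zero(self):
        s = constant_series(n=30, model_temp=10.0)
        sens = ThermalSensitivity(90.0, 0.0, 1.0)
        recs, times, temps = simulate_trial_full(
            [Morphology(0.6, 1.0)], s, sens, model_cfg(s), seed=0)
        trajs = trajectories_from_matrix(recs, times, temps)
        assert initiation_loglik(recs, trajs, sens) == 0.0

    def test_flier_at_first_check_with_half_hazard(self):
        s = constant_series(n=30, model_temp=25.0)
        sens = ThermalSensitivity(25.0, 1.0, 1.0)  # q = 0.5 at 25
        recs, times, temps = simulate_trial_full(
            [Morphology(0.6, 1.0)] * 50, s, sens, model_cfg(s), seed=1)
        first = [r for r in recs if r.flew and r.t_init == times[0]][0]
        trajs = trajectories_from_matrix([first], times, temps[:1])
        assert initiation_loglik([first], trajs, sens) == pytest.approx(np.log(0.5))

    def test_length_mismatch_raises(self):
        s = constant_series(n=30, model_temp=25.0)
        sens = ThermalSensitivity(25.0, 1.0, 0.5)
        recs, times, temps = simulate_trial_full(
            [Morphology(0.6, 1.0)] * 3, s, sens, model_cfg(s), seed=1)
        trajs = trajectories_from_matrix(recs, times, temps)
        with pytest.raises(ValueError, match="trajectories"):
            initiation_loglik(recs, trajs[:-1], sens)

    def test_concentrates_at_generating_parameters(self):
        """loglik(truth) beats a +2 degC threshold shift in >=95% of replicates."""
        sens = ThermalSensitivity(25.0, 1.5, 0.8)
        shifted = ThermalSensitivity(27.0, 1.5, 0.8)
        s = warming_series(n=300, start=18.0, rate=0.05)
        inds = [Morphology(0.6, 1.0)] * 500
        wins = 0
        for rep in range(100):
            recs, times, temps = simulate_trial_full(
                inds, s, sens, model_cfg(s), seed=1000 + rep)
            trajs = trajectories_from_matrix(recs, times, temps)
            if initiation_loglik(recs, trajs, sens) >= initiation_loglik(
                    recs, trajs, shifted):
                wins += 1
        assert wins >= 95


class TestFit:
    def test_sharp_threshold_recovered_within_one_step(self):
        s = warming_series(n=300, start=18.0, rate=0.05)
        sens = ThermalSensitivity(24.0, 0.0, 1.0)
        recs, times, temps = simulate_trial_full(
            [Morphology(0.6, 1.0)] * 200, s, sens, model_cfg(s), seed=2)
        trajs = trajectories_from_matrix(recs, times, temps)
        fit = fit_sensitivity(recs, trajs, n_boot=0, seed=0)
        assert abs(fit.mu - 24.0) <= 0.05  # one 1-min check = 0.05 degC step

    def test_all_nonfliers_not_identifiable(self):
        s = constant_series(n=30, model_temp=10.0)
        sens = ThermalSensitivity(90.0, 1.0, 0.5)
        recs, times, temps = simulate_trial_full(
            [Morphology(0.6, 1.0)] * 10, s, sens, model_cfg(s), seed=0)
        trajs = trajectories_from_matrix(recs, times, temps)
        with pytest.raises(NonIdentifiableError):
            fit_sensitivity(recs, trajs)

    def test_bootstrap_ci_covers_generating_mu(self):
        """~95% nominal coverage; loose binomial bound over 15 replicates."""
        sens = ThermalSensitivity(25.0, 1.5, 0.8)
        s = warming_series(n=220, start=18.0, rate=0.05)
        inds = [Morphology(0.6, 1.0)] * 150
        covered = 0
        for rep in range(15):
            recs, times, temps = simulate_trial_full(
                inds, s, sens, model_cfg(s), seed=500 + rep)
            trajs = trajectories_from_matrix(recs, times, temps)
            fit = fit_sensitivity(recs, trajs, n_boot=80, seed=rep)
            lo, hi = fit.ci["mu"]
            covered += lo <= 25.0 <= hi
        assert covered >= 11
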