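"""Recover thermal-sensitivity parameters from simulated trial records.

Simulates dose-response-style trials (cohorts held at constant driving
temperatures spanning the threshold) and fits (mu, sd, p_mot) by maximising
the interval-censored hazard likelihood, with case-resampling bootstrap CIs.
"""
import numpy as np

from coliastherm import (EnvSeries, Morphology, ThermalSensitivity,
                         TrialConfig, fit_sensitivity, simulate_trial_full,
                         trajectories_from_matrix)

truth = ThermalSensitivity(mu=25.0, sd=1.5, p_mot=0.8)
records, trajectories = [], []
for gi, temp in enumerate(np.linspace(21, 29, 10)):
    n = 61
    series = EnvSeries(time=np.arange(n, dtype=float),
                       air_temp=np.full(n, temp), soil_temp=np.full(n, temp),
                       solar=np.zeros(n), wind=np.full(n, 0.5),
                       model_temp=np.full(n, temp))
    cfg = TrialConfig(check_interval=1, t_start=0, t_end=n - 1,
                      temperature_source="model-temp")
    recs, times, temps = simulate_trial_full(
        [Morphology(0.6, 1.0)] * 50, series, truth, cfg, seed=100 + gi)
    records += recs
    trajectories += trajectories_from_matrix(recs, times, temps)

fit = fit_sensitivity(records, trajectories, n_boot=200, seed=0)
print(f"true    mu={truth.mu:.2f}  sd={truth.sd:.2f}  p_mot={truth.p_mot:.2f}")
print(f"fitted  mu={fit.mu:.2f}  sd={fit.sd:.2f}  p_mot={fit.p_mot:.2f}")
for k, (lo, hi) in fit.ci.items():
    print(f"  95% CI {k}: ({lo:.2f}, {hi:.2f})")
# The threshold mean is recovered to ~0.1-0.2 C at this sample size (n=500).
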