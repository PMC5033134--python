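"""Stochastic flight-initiation model: thermal hazard, trial simulation, likelihood fit.

Spontaneous flight initiation in a cage reflects both capability (body
temperature above some threshold) and willingness.  Both are captured by a
per-check hazard

    q(T) = p_mot * Phi((T - mu) / sd)

where ``mu`` is the mean initiation threshold (°C), ``sd`` its spread, and
``p_mot`` a per-check motivation probability.  At each check of a trial every
not-yet-flown individual initiates with probability ``q`` evaluated at its
current driving temperature — either the biophysically predicted body
temperature (reciprocal transplants, full sun) or the shared physical-mimic
temperature (common-garden tents).  Because the same hazard generates the
data and enters the interval-censored likelihood, simulation and inference
are internally consistent and parameters are recoverable by maximum
likelihood.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

from .biophys import Morphology, PhysicalParams, _steady_state_arrays
from .microclimate import EnvSeries

__all__ = [
    "ThermalSensitivity",
    "TrialConfig",
    "TrialRecord",
    "FitResult",
    "NonIdentifiableError",
    "hazard",
    "check_times",
    "check_temperatures",
    "simulate_trial",
    "simulate_trial_full",
    "trajectories_from_matrix",
    "initiation_loglik",
    "fit_sensitivity",
    "records_to_frame",
]

RECORD_COLUMNS = (
    "id", "species", "site", "flew", "t_init_min",
    "air_at_init_c", "temp_at_init_c", "absorptivity", "setal_mm",
)


class NonIdentifiableError(ValueError):
    """The likelihood cannot identify threshold parameters (no fliers)."""


@dataclass(frozen=True)
class ThermalSensitivity:
    """Threshold parameters of the flight-initiation hazard."""

    mu: float
    sd: float
    p_mot: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (0.0 < self.p_mot <= 1.0):
            raise ValueError("p_mot must be in (0, 1]")


@dataclass(frozen=True)
class TrialConfig:
    """Observation schedule and driving-temperature source of a trial."""

    check_interval: int
    t_start: int
    t_end: int
    temperature_source: str = "predicted-body"  # or "model-temp"

    def __post_init__(self) -> None:
        if self.check_interval < 1:
            raise ValueError("check_interval must be >= 1 min")
        if self.t_start >= self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.temperature_source not in ("predicted-body", "model-temp"):
            raise ValueError(
                f"unknown temperature_source {self.temperature_source!r}"
            )


@dataclass
class TrialRecord:
    """Outcome of one individual in one trial."""

    id: str
    species: str
    site: str
    flew: bool
    t_init: Optional[float] = None
    air_at_init: Optional[float] = None
    temp_at_init: Optional[float] = None
    morphology: Optional[Morphology] = None

    def __post_init__(self) -> None:
        if self.flew and self.t_init is None:
            raise ValueError("a flier must have t_init")
        if not self.flew and self.t_init is not None:
            raise ValueError("a non-flier must not have t_init")


def hazard(temp, sens: ThermalSensitivity):
    """Per-check initiation probability at driving temperature ``temp`` (°C).

    Vectorised; ``sd = 0`` degenerates to a sharp threshold at ``mu``.
    """
    t = np.asarray(temp, dtype=float)
    if sens.sd == 0:
        q = sens.p_mot * (t >= sens.mu).astype(float)
    else:
        q = sens.p_mot * ndtr((t - sens.mu) / sens.sd)
    return q if q.shape else float(q)


def check_times(cfg: TrialConfig) -> np.ndarray:
    """Check times: ``t_start + k*interval`` for k >= 1, up to ``t_end``."""
    return np.arange(
        cfg.t_start + cfg.check_interval, cfg.t_end + 1, cfg.check_interval,
        dtype=float,
    )


def check_temperatures(individuals: Sequence[Morphology], series: EnvSeries,
                       cfg: TrialConfig, params: Optional[PhysicalParams] = None,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Driving temperature of every individual at every check.

    Returns ``(times, temps, air6)`` where ``temps`` has shape
    ``(n_individuals, n_checks)`` and ``air6`` is the (up to) 6-min mean air
    temperature before each check.  For the predicted-body source each check
    uses the mean environment over the 6 min preceding it (a shorter window is
    used if the series starts later); for the model-temp source all
    individuals share the series' physical-mimic channel.
    """
    params = params or PhysicalParams()
    times = check_times(cfg)
    n = len(individuals)
    k = len(times)

    # Windowed means via cumulative sums on the 1-min grid.
    t0 = series.time[0]
    if cfg.t_start < t0 or cfg.t_end > series.time[-1] + 1:
        raise ValueError("trial window not covered by the series")

    def win_means(values: np.ndarray) -> np.ndarray:
        csum = np.concatenate([[0.0], np.cumsum(values)])
        hi = (times - t0).astype(int)  # exclusive index of sample at time t
        lo = np.maximum(hi - 6, 0)
        return (csum[hi] - csum[lo]) / (hi - lo)

    air6 = win_means(series.air_temp)

    if cfg.temperature_source == "model-temp":
        if series.model_temp is None:
            raise ValueError(
                "temperature_source is 'model-temp' but the series has no "
                "model_temp channel"
            )
        idx = (times - t0).astype(int) - 1  # sample covering [t-1, t)
        row = series.model_temp[idx]
        temps = np.broadcast_to(row, (n, k)).copy()
    else:
        soil6 = win_means(series.soil_temp)
        solar6 = win_means(series.solar)
        wind6 = win_means(series.wind)
        absorp = np.array([m.absorptivity for m in individuals])[:, None]
        setal = np.array([m.setal_length for m in individuals])[:, None]
        d = np.array([m.diameter for m in individuals])[:, None]
        length = np.array([m.length for m in individuals])[:, None]
        temps = _steady_state_arrays(
            absorp, setal, air6[None, :], soil6[None, :], solar6[None, :],
            wind6[None, :], params, direct_sun=series.direct_sun,
            d_mm=d, l_mm=length,
        )
    return times, temps, air6


def simulate_trial_full(individuals: Sequence[Morphology], series: EnvSeries,
                        sens: ThermalSensitivity, cfg: TrialConfig,
                        params: Optional[PhysicalParams] = None, seed=0,
                        species: str = "", site: str = "",
                        id_prefix: Optional[str] = None,
                        fixed_threshold: bool = False,
                        ) -> tuple[list[TrialRecord], np.ndarray, np.ndarray]:
    """Simulate one trial; also return the check times and temperature matrix.

    At each check, initiation coin flips are drawn for all individuals in
    id order (a single uniform vector per check), which makes the outcome
    reproducible for a fixed seed.  ``fixed_threshold=True`` switches to the
    alternative data-generating model in which each individual draws a single
    threshold ``theta ~ N(mu, sd)`` at the start and initiates (with
    per-check probability ``p_mot``) once its temperature reaches ``theta``.
    """
    params = params or PhysicalParams()
    rng = np.random.default_rng(seed)
    times, temps, air6 = check_temperatures(individuals, series, cfg, params)
    n, k = temps.shape

    if fixed_threshold:
        theta = rng.normal(sens.mu, sens.sd, size=n)

    alive = np.ones(n, dtype=bool)
    init_check = np.full(n, -1, dtype=int)
    for j in range(k):
        u = rng.random(n)
        if fixed_threshold:
            q = sens.p_mot * (temps[:, j] >= theta)
        else:
            q = hazard(temps[:, j], sens)
        newly = alive & (u < q)
        init_check[newly] = j
        alive &= ~newly

    prefix = id_prefix if id_prefix is not None else f"{species}-{site}"
    records: list[TrialRecord] = []
    for i in range(n):
        rid = f"{prefix}-{i:04d}"
        if init_check[i] >= 0:
            j = init_check[i]
            records.append(TrialRecord(
                id=rid, species=species, site=site, flew=True,
                t_init=float(times[j]), air_at_init=float(air6[j]),
                temp_at_init=float(temps[i, j]), morphology=individuals[i],
            ))
        else:
            records.append(TrialRecord(
                id=rid, species=species, site=site, flew=False,
                morphology=individuals[i],
            ))
    return records, times, temps


def simulate_trial(individuals: Sequence[Morphology], series: EnvSeries,
                   sens: ThermalSensitivity, cfg: TrialConfig,
                   params: Optional[PhysicalParams] = None, seed=0,
                   species: str = "", site: str = "",
                   id_prefix: Optional[str] = None,
                   fixed_threshold: bool = False) -> list[TrialRecord]:
    """Simulate one trial and return only the records (see simulate_trial_full)."""
    records, _, _ = simulate_trial_full(
        individuals, series, sens, cfg, params, seed, species, site,
        id_prefix, fixed_threshold,
    )
    return records


def trajectories_from_matrix(records: Sequence[TrialRecord], times: np.ndarray,
                             temps: np.ndarray) -> list[np.ndarray]:
    """Per-individual temperature sequences as experienced up to censoring.

    A flier's trajectory ends at (and includes) its initiation check; a
    non-flier's covers every check.
    """
    out = []
    for i, rec in enumerate(records):
        if rec.flew:
            j = int(np.searchsorted(times, rec.t_init))
            out.append(temps[i, : j + 1].copy())
        else:
            out.append(temps[i, :].copy())
    return out


def initiation_loglik(records: Sequence[TrialRecord],
                      temp_trajectories: Sequence[np.ndarray],
                      sens: ThermalSensitivity) -> float:
    """Interval-censored log-likelihood of trial outcomes under the hazard.

    For a flier whose trajectory ends at its initiation check:
    ``sum_{j<last} log(1 - q_j) + log(q_last)``; for a non-flier:
    ``sum_j log(1 - q_j)``.  Finite whenever ``p_mot < 1`` or ``sd > 0``
    (and no impossible outcome is present).
    """
    if len(records) != len(temp_trajectories):
        raise ValueError(
            f"{len(records)} records but {len(temp_trajectories)} trajectories"
        )
    for rec, traj in zip(records, temp_trajectories):
        if rec.flew and len(traj) == 0:
            raise ValueError(f"flier {rec.id} has an empty trajectory")
    if sens.sd == 0:
        # degenerate hazard: fall back to the direct per-record sum
        ll = 0.0
        with np.errstate(divide="ignore"):
            for rec, traj in zip(records, temp_trajectories):
                q = np.asarray(hazard(np.asarray(traj, float), sens), float)
                if rec.flew:
                    ll += float(np.sum(np.log1p(-q[:-1]))) + float(np.log(q[-1]))
                else:
                    ll += float(np.sum(np.log1p(-q)))
        return ll
    temps, surv_mask, flew, last = _pack(records, temp_trajectories)
    return -_packed_negloglik((sens.mu, sens.sd, sens.p_mot),
                              temps, surv_mask, flew, last)


@dataclass
class FitResult:
    """Maximum-likelihood thermal-sensitivity estimate with bootstrap CIs."""

    mu: float
    sd: float
    p_mot: float
    loglik: float
    ci: dict = field(default_factory=dict)
    n_boot: int = 0

    @property
    def sensitivity(self) -> ThermalSensitivity:
        return ThermalSensitivity(self.mu, self.sd, self.p_mot)


def _pack(records, trajectories):
    """Pad trajectories into a dense matrix with masks for fast likelihood."""
    n = len(records)
    lens = np.array([len(t) for t in trajectories], dtype=int)
    kmax = int(lens.max())
    temps = np.zeros((n, kmax))
    surv_mask = np.zeros((n, kmax), dtype=bool)  # checks contributing log(1-q)
    flew = np.array([r.flew for r in records], dtype=bool)
    last = lens - 1
    for i, traj in enumerate(trajectories):
        temps[i, : lens[i]] = traj
        surv_mask[i, : lens[i]] = True
        if flew[i]:
            surv_mask[i, last[i]] = False
    return temps, surv_mask, flew, last


def _packed_negloglik(x, temps, surv_mask, flew, last):
    mu, sd, p = x
    sd = max(sd, 1e-6)
    q = p * ndtr((temps - mu) / sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.sum(np.log1p(-q, where=surv_mask, out=np.zeros_like(q)))
        q_last = q[flew, last[flew]]
        ll += np.sum(np.log(q_last))
    if not np.isfinite(ll):
        return 1e18
    return -ll


def fit_sensitivity(records: Sequence[TrialRecord],
                    temp_trajectories: Sequence[np.ndarray],
                    bounds: Optional[Sequence[tuple]] = None,
                    n_boot: int = 200, seed=0,
                    ci_level: float = 0.95) -> FitResult:
    """Box-constrained ML fit of (mu, sd, p_mot) with case-resampling CIs.

    Starts L-BFGS-B from the best point of a coarse grid over plausible
    thresholds/spreads/motivations; percentile CIs come from ``n_boot``
    bootstrap replicates that resample individuals (each refit starting from
    the point estimate).  Raises :class:`NonIdentifiableError` if no
    individual initiated flight.
    """
    if len(records) != len(temp_trajectories):
        raise ValueError("records and trajectories differ in length")
    flew_any = any(r.flew for r in records)
    if not flew_any:
        raise NonIdentifiableError(
            "no individual initiated flight; threshold parameters are not "
            "identifiable"
        )
    if bounds is None:
        bounds = [(0.0, 50.0), (1e-3, 10.0), (1e-3, 1.0)]

    temps, surv_mask, flew, last = _pack(records, temp_trajectories)
    args = (temps, surv_mask, flew, last)

    init_temps = temps[flew, last[flew]]
    mu_grid = np.linspace(init_temps.min() - 2.0, init_temps.max() + 2.0, 9)
    mu_grid = np.clip(mu_grid, bounds[0][0], bounds[0][1])
    sd_grid = np.clip([0.5, 1.0, 1.5, 2.5], bounds[1][0], bounds[1][1])
    p_grid = np.clip([0.3, 0.6, 0.9], bounds[2][0], bounds[2][1])
    best, best_val = None, np.inf
    for mu0 in mu_grid:
        for sd0 in sd_grid:
            for p0 in p_grid:
                v = _packed_negloglik((mu0, sd0, p0), *args)
                if v < best_val:
                    best, best_val = (mu0, sd0, p0), v

    res = optimize.minimize(_packed_negloglik, best, args=args,
                            method="L-BFGS-B", bounds=bounds)
    mu_hat, sd_hat, p_hat = res.x

    ci: dict = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(records)
        boot = np.empty((n_boot, 3))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            while not flew[idx].any():  # resample until identifiable
                idx = rng.integers(0, n, size=n)
            bargs = (temps[idx], surv_mask[idx], flew[idx], last[idx])
            bres = optimize.minimize(_packed_negloglik, res.x, args=bargs,
                                     method="L-BFGS-B", bounds=bounds)
            boot[b] = bres.x
        alpha = 0.5 * (1.0 - ci_level)
        for j, name in enumerate(("mu", "sd", "p_mot")):
            lo, hi = np.quantile(boot[:, j], [alpha, 1.0 - alpha])
            ci[name] = (float(lo), float(hi))

    return FitResult(mu=float(mu_hat), sd=float(sd_hat), p_mot=float(p_hat),
                     loglik=float(-res.fun), ci=ci, n_boot=n_boot)


def records_to_frame(records: Sequence[TrialRecord],
                     day: Optional[int] = None) -> pd.DataFrame:
    """Tabulate records with the external CSV columns (plus optional day)."""
    rows = []
    for r in records:
        m = r.morphology
        rows.append({
            "id": r.id,
            "species": r.species,
            "site": r.site,
            "flew": int(r.flew),
            "t_init_min": r.t_init if r.flew else np.nan,
            "air_at_init_c": r.air_at_init if r.flew else np.nan,
            "temp_at_init_c": r.temp_at_init if r.flew else np.nan,
            "absorptivity": np.nan if m is None else m.absorptivity,
            "setal_mm": np.nan if m is None else m.setal_length,
        })
    df = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    if day is not None:
        df["day"] = day
    return df
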