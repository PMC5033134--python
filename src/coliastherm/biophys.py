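"""Lumped steady-state heat budget for a basking butterfly, with a transient variant.

The thorax is modelled as a single horizontal cylinder of diameter ``D`` and
length ``L`` wrapped in an insulating setal (fur) layer.  At steady state the
absorbed shortwave flux balances convective and thermal-radiative exchange:

    Q_solar - Q_conv - Q_rad = 0

with

    Q_solar = absorptivity * S * proj_frac * A
    Q_conv  = h_tot * A * (Tb - T_air),   1/h_tot = 1/h_c + d_setae / k_fur
    h_c     = nu_coeff * Re**nu_exp * k_air / D,   Re = u * D / nu_air
    Q_rad   = emissivity * sigma * A * (Tb_K**4 - T_rad_K**4)

where ``A = pi D L`` is the cylinder surface, ``T_rad`` a view-factor-weighted
mix of sky and ground radiant temperatures, and wind ``u`` is floored at a
small value (free convection is not modelled).  Darker wings (higher
absorptivity) and longer setae both raise the equilibrium excess of body over
air temperature, which is the morphological axis of local adaptation this
package quantifies.

The balance is monotone decreasing in Tb, so the root is found by a
vectorised bisection on the bracket ``[T_air - 20, T_air + 40]`` °C; residuals
at convergence are far below the 1e-6 W tolerance.  The transient variant
integrates ``C dTb/dt = Q_net`` and exists to verify that the thermal time
constant is short (tens of seconds), which is what justifies steady-state use
in the trial simulations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .microclimate import EnvSample, EnvSeries, window_mean

__all__ = [
    "Morphology",
    "PhysicalParams",
    "TraitDistribution",
    "ModelDomainError",
    "IntegrationError",
    "steady_state_Tb",
    "transient_Tb",
    "time_constant",
    "predicted_initiation_Tb",
    "sample_traits",
]

SIGMA = 5.670374419e-8  # Stefan-Boltzmann, W m^-2 K^-4
_ZERO_C = 273.15


class ModelDomainError(ValueError):
    """The energy balance has no root inside the solver bracket."""


class IntegrationError(RuntimeError):
    """The transient integration produced a non-finite state."""


@dataclass(frozen=True)
class Morphology:
    """Thermally important phenotype of one individual.

    ``absorptivity`` is the fraction of incident solar flux absorbed by the
    ventral wing surface (melanisation); ``setal_length`` the ventral thoracic
    fur depth in mm; ``diameter``/``length`` the thorax cylinder in mm.
    """

    absorptivity: float
    setal_length: float
    diameter: float = 3.6
    length: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.absorptivity <= 1.0):
            raise ValueError("absorptivity must be in [0, 1]")
        if self.setal_length < 0:
            raise ValueError("setal_length must be >= 0")
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("diameter and length must be > 0")


@dataclass(frozen=True)
class PhysicalParams:
    """Physical coefficients of the heat budget (SI units).

    ``k_fur``: setal-layer conductivity (W/m/K); ``k_air``: air conductivity;
    ``nu_air``: kinematic viscosity of air (m²/s); ``nu_coeff``/``nu_exp``:
    Nusselt–Reynolds correlation Nu = c Re^n for a cylinder in cross-flow;
    ``proj_frac``: projected/total area ratio for the direct beam (lateral
    basking posture); ``diffuse_frac``: the same ratio for isotropic diffuse
    light (tents); ``sky_weight``: view-factor weight of sky vs ground in the
    radiant temperature; ``heat_capacity``: lumped thermal mass (J/K), set so
    the thermal time constant is ~30 s in light wind; ``sky_offset``: clear-sky
    radiant depression of the sky below air temperature at full flux
    ``sky_offset_solar_ref`` (the depression scales linearly with solar flux so
    the balance stays smooth and vanishes at night); ``wind_floor``: minimum
    wind speed used in the Reynolds number.
    """

    k_fur: float = 0.025
    k_air: float = 0.026
    nu_air: float = 1.5e-5
    emissivity: float = 0.95
    nu_coeff: float = 0.6
    nu_exp: float = 0.5
    proj_frac: float = 0.25
    diffuse_frac: float = 0.125
    sky_weight: float = 0.5
    heat_capacity: float = 0.07
    sky_offset: float = 15.0
    sky_offset_solar_ref: float = 1000.0
    wind_floor: float = 0.1

    def __post_init__(self) -> None:
        positive = (
            self.k_fur, self.k_air, self.nu_air, self.nu_coeff, self.nu_exp,
            self.heat_capacity, self.sky_offset_solar_ref, self.wind_floor,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("physical coefficients must be positive")
        for name in ("proj_frac", "diffuse_frac", "sky_weight", "emissivity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.sky_offset < 0:
            raise ValueError("sky_offset must be >= 0")


@dataclass(frozen=True)
class TraitDistribution:
    """Species-level distribution of absorptivity and setal length."""

    species: str
    mean_absorptivity: float
    sd_absorptivity: float
    mean_setal: float
    sd_setal: float

    def __post_init__(self) -> None:
        if self.sd_absorptivity < 0 or self.sd_setal < 0:
            raise ValueError("trait SDs must be >= 0")


def _conductances(setal_mm, diameter_mm, wind, params: PhysicalParams):
    """(h_tot, A_surf) for possibly array-valued morphology/wind inputs."""
    d = np.asarray(diameter_mm, dtype=float) * 1e-3
    u = np.maximum(np.asarray(wind, dtype=float), params.wind_floor)
    re = u * d / params.nu_air
    h_c = params.nu_coeff * re**params.nu_exp * params.k_air / d
    h_tot = 1.0 / (1.0 / h_c + np.asarray(setal_mm, dtype=float) * 1e-3 / params.k_fur)
    return h_tot


def _radiant_temp(air, soil, solar, params: PhysicalParams):
    """View-factor-weighted radiant temperature (°C)."""
    t_sky = np.asarray(air, dtype=float) - params.sky_offset * (
        np.asarray(solar, dtype=float) / params.sky_offset_solar_ref
    )
    return params.sky_weight * t_sky + (1.0 - params.sky_weight) * np.asarray(
        soil, dtype=float
    )


def _net_flux(tb, absorp, setal_mm, d_mm, l_mm, air, soil, solar, wind,
              params: PhysicalParams, direct_sun: bool):
    """Q_net(Tb) in W; monotone decreasing in tb."""
    area = math.pi * np.asarray(d_mm, dtype=float) * 1e-3 * np.asarray(l_mm, dtype=float) * 1e-3
    h_tot = _conductances(setal_mm, d_mm, wind, params)
    proj = params.proj_frac if direct_sun else params.diffuse_frac
    q_solar = np.asarray(absorp, dtype=float) * np.asarray(solar, dtype=float) * proj * area
    q_conv = h_tot * area * (tb - np.asarray(air, dtype=float))
    t_rad_k = _radiant_temp(air, soil, solar, params) + _ZERO_C
    q_rad = params.emissivity * SIGMA * area * ((tb + _ZERO_C) ** 4 - t_rad_k**4)
    return q_solar - q_conv - q_rad


def _steady_state_arrays(absorp, setal_mm, air, soil, solar, wind,
                         params: PhysicalParams, direct_sun: bool = True,
                         d_mm=3.6, l_mm=10.0, n_iter: int = 64) -> np.ndarray:
    """Vectorised bisection for the equilibrium body temperature (°C).

    All arguments broadcast; used directly by the trial simulator, which needs
    thousands of simultaneous solves per cage check.
    """
    shape = np.broadcast_shapes(
        np.shape(absorp), np.shape(setal_mm), np.shape(air), np.shape(soil),
        np.shape(solar), np.shape(wind), np.shape(d_mm), np.shape(l_mm),
    )
    air_b = np.broadcast_to(np.asarray(air, dtype=float), shape)
    lo = air_b - 20.0
    hi = air_b + 40.0

    def f(tb):
        return _net_flux(tb, absorp, setal_mm, d_mm, l_mm, air, soil, solar,
                         wind, params, direct_sun)

    f_lo = f(lo)
    f_hi = f(hi)
    if np.any(f_lo < 0) or np.any(f_hi > 0):
        raise ModelDomainError(
            "no sign change of the energy balance in [air-20, air+40] °C: "
            f"residual at bracket low = {float(np.min(f_lo)):.3g} W, "
            f"at bracket high = {float(np.max(f_hi)):.3g} W"
        )
    lo = lo.copy()
    hi = hi.copy()
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        pos = f(mid) > 0.0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)


def steady_state_Tb(morph: Morphology, env: EnvSample,
                    params: Optional[PhysicalParams] = None,
                    direct_sun: bool = True) -> float:
    """Equilibrium body temperature (°C) for one morphology in one environment.

    Raises :class:`ModelDomainError` if the balance has no root within
    [air - 20, air + 40] °C.
    """
    params = params or PhysicalParams()
    tb = _steady_state_arrays(
        morph.absorptivity, morph.setal_length, env.air_temp, env.soil_temp,
        env.solar, env.wind, params, direct_sun,
        d_mm=morph.diameter, l_mm=morph.length,
    )
    return float(tb)


def transient_Tb(morph: Morphology, series: EnvSeries,
                 params: Optional[PhysicalParams] = None,
                 Tb0: float = 20.0, dt: float = 1.0) -> np.ndarray:
    """Integrate ``C dTb/dt = Q_net`` over a series; output at 1-min cadence.

    The environment is held piecewise-constant within each minute and the
    integration uses explicit sub-minute steps of ``dt`` seconds (``dt <= 1``).
    Returns Tb at each sample time, starting from ``Tb0`` at the first.
    """
    params = params or PhysicalParams()
    if dt > 1.0 or dt <= 0:
        raise ValueError("dt must be in (0, 1] seconds")
    n_sub = int(round(60.0 / dt))
    out = np.empty(len(series))
    tb = float(Tb0)
    out[0] = tb
    for i in range(len(series) - 1):
        s = series.sample(i)
        for _ in range(n_sub):
            q = _net_flux(tb, morph.absorptivity, morph.setal_length,
                          morph.diameter, morph.length, s.air_temp, s.soil_temp,
                          s.solar, s.wind, params, series.direct_sun)
            tb = tb + dt * float(q) / params.heat_capacity
        if not math.isfinite(tb):
            raise IntegrationError(f"non-finite body temperature at minute {i + 1}")
        out[i + 1] = tb
    return out


def time_constant(morph: Morphology, env: EnvSample,
                  params: Optional[PhysicalParams] = None,
                  direct_sun: bool = True) -> float:
    """Closed-form e-folding thermal time constant (s) at the steady state.

    ``tau = C / (A (h_tot + 4 emissivity sigma Tb_K^3))`` linearises the
    radiative term at the equilibrium temperature.  With default parameters
    this is ~30 s in light wind, well under a minute — the justification for
    using the steady-state model during trials.
    """
    params = params or PhysicalParams()
    tb_k = steady_state_Tb(morph, env, params, direct_sun) + _ZERO_C
    area = math.pi * morph.diameter * 1e-3 * morph.length * 1e-3
    h_tot = float(_conductances(morph.setal_length, morph.diameter, env.wind, params))
    h_rad = 4.0 * params.emissivity * SIGMA * tb_k**3
    return params.heat_capacity / (area * (h_tot + h_rad))


def predicted_initiation_Tb(morph: Morphology, series: EnvSeries, t_init: float,
                            params: Optional[PhysicalParams] = None) -> float:
    """Steady-state Tb driven by the 6-min mean environment before ``t_init``.

    Mirrors the field protocol of averaging micrometeorology over the 6 min
    preceding observed flight initiation before evaluating the model.
    """
    env = window_mean(series, t_init, 6.0)
    return steady_state_Tb(morph, env, params, direct_sun=series.direct_sun)


def sample_traits(dist: TraitDistribution, n: int, seed) -> list[Morphology]:
    """Draw ``n`` morphologies from truncated-normal trait distributions.

    Absorptivity is truncated to [0, 1], setal length to [0, inf); zero SD
    collapses to the mean.  Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    def _trunc(mean, sd, lo, hi, size):
        if sd == 0:
            return np.full(size, mean)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    absorp = _trunc(dist.mean_absorptivity, dist.sd_absorptivity, 0.0, 1.0, n)
    setal = _trunc(dist.mean_setal, dist.sd_setal, 0.0, np.inf, n)
    return [Morphology(float(a), float(s)) for a, s in zip(absorp, setal)]
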