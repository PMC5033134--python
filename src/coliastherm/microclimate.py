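"""Synthetic 1-min micrometeorology: generation, enclosure effects, windowed means, logger I/O.

The field loggers the pipeline emulates sample every 10 s and emit 1-min
averages of shade air temperature (10 cm), soil temperature (0.5 cm depth),
total horizontal solar radiation and wind speed; an optional channel records
the temperature of a physical butterfly mimic.  Everything downstream works on
that 1-min cadence, so the cadence is enforced as an invariant of
:class:`EnvSeries`.

Times are minutes since local midnight throughout; windowed means use the
half-open convention ``[t_end - duration, t_end)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "EnvSample",
    "EnvSeries",
    "SiteConfig",
    "EnclosureConfig",
    "generate_diurnal_series",
    "apply_enclosure",
    "window_mean",
    "read_logger_csv",
    "write_logger_csv",
    "LoggerParseError",
    "MissingColumnError",
    "CadenceError",
    "WindowError",
]

LOGGER_COLUMNS = (
    "time_min",
    "air_temp_c",
    "soil_temp_c",
    "solar_wm2",
    "wind_ms",
    "model_temp_c",
)


class LoggerParseError(ValueError):
    """A logger CSV file violates the expected format."""


class MissingColumnError(LoggerParseError):
    """A required column is absent from a logger CSV file."""


class CadenceError(LoggerParseError):
    """Logger time stamps are non-monotone or not on a 1-min cadence."""


class WindowError(ValueError):
    """An averaging window is not fully covered by the series."""


@dataclass(frozen=True)
class EnvSample:
    """One minute of micrometeorology.

    ``time`` is minutes since local midnight; ``air_temp`` is shade air
    temperature at 10 cm (°C); ``soil_temp`` at 0.5 cm depth (°C); ``solar``
    is total horizontal flux (W/m²); ``wind`` in m/s; ``model_temp`` is the
    optional physical-mimic temperature (°C).
    """

    time: float
    air_temp: float
    soil_temp: float
    solar: float
    wind: float
    model_temp: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.solar >= 0):
            raise ValueError(f"solar must be >= 0, got {self.solar}")
        if not (self.wind >= 0):
            raise ValueError(f"wind must be >= 0, got {self.wind}")
        if not (-40.0 < self.air_temp < 60.0):
            raise ValueError(f"air_temp out of plausible range: {self.air_temp}")


@dataclass(frozen=True)
class SiteConfig:
    """Parameters of the synthetic diurnal generator for one site.

    ``t_min``/``t_max`` are the daily air-temperature extremes (°C); ``s_max``
    the clear-sky peak of total horizontal solar flux (W/m²); ``sunrise`` and
    ``sunset`` in minutes since midnight.  Wind is drawn log-normally around
    ``wind_median`` with log-scale spread ``wind_spread``; cloudiness is a
    multiplicative AR(1) factor with per-minute autocorrelation
    ``cloud_autocorr`` and maximum depletion ``cloud_depth``.

    ``soil_sun_gain`` (K at 1000 W/m²) and ``soil_lag_min`` (EMA time scale)
    parameterise the sun-driven excess of shallow-soil over air temperature.
    ``day_temp_sd`` (°C) is the between-day SD of a whole-day temperature
    offset applied by the experiment drivers.
    """

    name: str
    elevation: float
    t_min: float
    t_max: float
    s_max: float
    sunrise: int
    sunset: int
    wind_median: float
    wind_spread: float
    cloud_autocorr: float
    cloud_depth: float
    soil_sun_gain: float = 12.0
    soil_lag_min: float = 45.0
    day_temp_sd: float = 1.5

    def __post_init__(self) -> None:
        vals = [
            self.elevation, self.t_min, self.t_max, self.s_max,
            self.sunrise, self.sunset, self.wind_median, self.wind_spread,
            self.cloud_autocorr, self.cloud_depth, self.soil_sun_gain,
            self.soil_lag_min, self.day_temp_sd,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("SiteConfig values must be finite")
        if self.t_min > self.t_max:
            raise ValueError("t_min must be <= t_max")
        if not (0 <= self.sunrise < self.sunset <= 1440):
            raise ValueError("need 0 <= sunrise < sunset <= 1440")
        if self.s_max <= 0:
            raise ValueError("s_max must be > 0")
        if not (0 <= self.cloud_autocorr < 1):
            raise ValueError("cloud_autocorr must be in [0, 1)")
        if not (0 <= self.cloud_depth <= 1):
            raise ValueError("cloud_depth must be in [0, 1]")


@dataclass(frozen=True)
class EnclosureConfig:
    """Radiative/convective effect of a field enclosure.

    The transplant screen cages cut solar flux by <15% and wind moderately;
    the common-garden nylon tents cut solar by 65% on average, essentially
    eliminate wind, and block the direct beam entirely (``blocks_direct_sun``)
    so only attenuated diffuse light reaches the animal.
    """

    solar_attenuation: float
    wind_factor: float
    blocks_direct_sun: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.solar_attenuation <= 1.0):
            raise ValueError("solar_attenuation must be in [0, 1]")
        if not (0.0 <= self.wind_factor <= 1.0):
            raise ValueError("wind_factor must be in [0, 1]")


@dataclass
class EnvSeries:
    """A fixed-cadence (1-min) micrometeorological record.

    ``direct_sun`` indicates whether the solar channel still contains a direct
    beam component; tents set it False, after which downstream body-temperature
    calculations use the diffuse interception geometry.
    """

    time: np.ndarray
    air_temp: np.ndarray
    soil_temp: np.ndarray
    solar: np.ndarray
    wind: np.ndarray
    model_temp: Optional[np.ndarray] = None
    site: str = ""
    date: str = ""
    elevation: float = float("nan")
    direct_sun: bool = True

    def __post_init__(self) -> None:
        for name in ("time", "air_temp", "soil_temp", "solar", "wind"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.model_temp is not None:
            self.model_temp = np.asarray(self.model_temp, dtype=float)
        n = len(self.time)
        for name in ("air_temp", "soil_temp", "solar", "wind"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length does not match time")
        if self.model_temp is not None and len(self.model_temp) != n:
            raise ValueError("model_temp length does not match time")
        if n >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise CadenceError("time stamps must be strictly increasing")
            if not np.allclose(steps, 1.0):
                raise CadenceError("series must be on a 1-min cadence")

    def __len__(self) -> int:
        return len(self.time)

    def sample(self, i: int) -> EnvSample:
        """The i-th minute as an :class:`EnvSample`."""
        mt = None if self.model_temp is None else float(self.model_temp[i])
        return EnvSample(
            time=float(self.time[i]),
            air_temp=float(self.air_temp[i]),
            soil_temp=float(self.soil_temp[i]),
            solar=float(self.solar[i]),
            wind=float(self.wind[i]),
            model_temp=mt,
        )

    def to_frame(self) -> pd.DataFrame:
        mt = self.model_temp
        return pd.DataFrame(
            {
                "time_min": self.time,
                "air_temp_c": self.air_temp,
                "soil_temp_c": self.soil_temp,
                "solar_wm2": self.solar,
                "wind_ms": self.wind,
                "model_temp_c": np.full(len(self), np.nan) if mt is None else mt,
            }
        )


def _air_curve(t: np.ndarray, site: SiteConfig) -> np.ndarray:
    """Piecewise-cosine diurnal air temperature.

    Minimum ``t_min`` at sunrise, maximum ``t_max`` mid-afternoon (two hours
    after the midpoint of the photoperiod), cosine decay back to the next
    morning's minimum.  Continuous everywhere; the pre-dawn branch is the tail
    of the previous evening's decay assuming identical daily extremes.
    """
    t = np.asarray(t, dtype=float)
    amp = site.t_max - site.t_min
    t_peak = 0.5 * (site.sunrise + site.sunset) + 120.0
    rise_len = t_peak - site.sunrise
    fall_len = site.sunrise + 1440.0 - t_peak

    out = np.empty_like(t)
    rising = (t >= site.sunrise) & (t <= t_peak)
    after = t > t_peak
    before = t < site.sunrise

    out[rising] = site.t_min + amp * 0.5 * (
        1.0 - np.cos(np.pi * (t[rising] - site.sunrise) / rise_len)
    )
    out[after] = site.t_min + amp * 0.5 * (
        1.0 + np.cos(np.pi * (t[after] - t_peak) / fall_len)
    )
    out[before] = site.t_min + amp * 0.5 * (
        1.0 + np.cos(np.pi * (t[before] + 1440.0 - t_peak) / fall_len)
    )
    return out


def generate_diurnal_series(site: SiteConfig, seed) -> EnvSeries:
    """Generate one synthetic day (1440 samples, 1-min cadence) at a site.

    Air temperature follows the piecewise cosine of :func:`_air_curve`; solar
    flux follows the clear-sky half-sine envelope
    ``s_max * max(0, sin(pi (t - sunrise)/(sunset - sunrise)))`` multiplied by
    an AR(1) cloud factor in ``[1 - cloud_depth, 1]``; wind is log-normal
    around the site median; soil temperature is air plus a radiation-driven
    excess smoothed with an exponential lag.  Identical ``(site, seed)``
    always produce a bit-identical series.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(1440, dtype=float)

    air = _air_curve(t, site)

    phase = np.pi * (t - site.sunrise) / (site.sunset - site.sunrise)
    envelope = site.s_max * np.clip(np.sin(phase), 0.0, None)
    envelope[(t < site.sunrise) | (t > site.sunset)] = 0.0

    # AR(1) cloudiness state in [0, 1]; stationary around 0.5.
    eps = rng.random(1440)
    rho = site.cloud_autocorr
    u = np.empty(1440)
    u[0] = eps[0]
    for i in range(1, 1440):
        u[i] = rho * u[i - 1] + (1.0 - rho) * eps[i]
    cloud = 1.0 - site.cloud_depth * u
    solar = envelope * cloud

    wind = site.wind_median * np.exp(site.wind_spread * rng.standard_normal(1440))

    # Shallow soil: tracks air plus a sun-driven excess with thermal lag.
    target = site.soil_sun_gain * solar / 1000.0
    excess = np.empty(1440)
    alpha = 1.0 / site.soil_lag_min
    excess[0] = target[0]
    for i in range(1, 1440):
        excess[i] = excess[i - 1] + alpha * (target[i] - excess[i - 1])
    soil = air + excess

    return EnvSeries(
        time=t,
        air_temp=air,
        soil_temp=soil,
        solar=solar,
        wind=wind,
        site=site.name,
        date="synthetic",
        elevation=site.elevation,
    )


def apply_enclosure(series: EnvSeries, enc: EnclosureConfig) -> EnvSeries:
    """Attenuate a series for a cage or tent; temperatures are unchanged.

    Solar is scaled by ``1 - solar_attenuation`` and wind by ``wind_factor``.
    A beam-blocking enclosure clears the series' ``direct_sun`` flag so that
    downstream radiation interception switches to diffuse geometry.
    """
    return EnvSeries(
        time=series.time.copy(),
        air_temp=series.air_temp.copy(),
        soil_temp=series.soil_temp.copy(),
        solar=series.solar * (1.0 - enc.solar_attenuation),
        wind=series.wind * enc.wind_factor,
        model_temp=None if series.model_temp is None else series.model_temp.copy(),
        site=series.site,
        date=series.date,
        elevation=series.elevation,
        direct_sun=series.direct_sun and not enc.blocks_direct_sun,
    )


def window_mean(series: EnvSeries, t_end: float, duration: float) -> EnvSample:
    """Field-wise mean over the half-open window ``[t_end - duration, t_end)``.

    Raises :class:`WindowError` unless the window is fully covered by the
    series.  The returned sample carries ``time = t_end``.
    """
    t0 = t_end - duration
    if t0 < series.time[0] or t_end > series.time[-1] + 1.0:
        raise WindowError(
            f"window [{t0}, {t_end}) outside series "
            f"[{series.time[0]}, {series.time[-1] + 1.0})"
        )
    mask = (series.time >= t0) & (series.time < t_end)
    if not np.any(mask):
        raise WindowError(f"window [{t0}, {t_end}) contains no samples")
    mt = None
    if series.model_temp is not None:
        mt = float(np.mean(series.model_temp[mask]))
    return EnvSample(
        time=float(t_end),
        air_temp=float(np.mean(series.air_temp[mask])),
        soil_temp=float(np.mean(series.soil_temp[mask])),
        solar=float(np.mean(series.solar[mask])),
        wind=float(np.mean(series.wind[mask])),
        model_temp=mt,
    )


def write_logger_csv(series: EnvSeries, path) -> None:
    """Write a series in the logger CSV format (UTF-8, dot decimal).

    The first line is a ``#`` comment carrying site/date/elevation metadata;
    the header is exactly ``time_min,air_temp_c,soil_temp_c,solar_wm2,wind_ms,
    model_temp_c``.  An absent model-temperature channel is written as empty
    fields.  Floats are written with ``repr`` so that a read-back round-trips
    bit-exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# site={series.site} date={series.date} "
            f"elevation_m={series.elevation!r} direct_sun={int(series.direct_sun)}\n"
        )
        fh.write(",".join(LOGGER_COLUMNS) + "\n")
        mt = series.model_temp
        for i in range(len(series)):
            cells = [
                repr(float(series.time[i])),
                repr(float(series.air_temp[i])),
                repr(float(series.soil_temp[i])),
                repr(float(series.solar[i])),
                repr(float(series.wind[i])),
                "" if mt is None else repr(float(mt[i])),
            ]
            fh.write(",".join(cells) + "\n")


def read_logger_csv(path) -> EnvSeries:
    """Read a logger CSV written by :func:`write_logger_csv` (or compatible).

    Raises :class:`MissingColumnError` naming any absent column and
    :class:`CadenceError` for non-monotone or non-1-min time stamps.
    """
    meta = {"site": "", "date": "", "elevation_m": "nan", "direct_sun": "1"}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            body = fh.read()
        else:
            body = first + fh.read()

    from io import StringIO

    df = pd.read_csv(StringIO(body), float_precision="round_trip")
    for col in LOGGER_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(f"logger file missing column {col!r}")

    time = df["time_min"].to_numpy(dtype=float)
    if len(time) >= 2:
        steps = np.diff(time)
        if np.any(steps <= 0):
            raise CadenceError("time_min must be strictly increasing")
        if not np.allclose(steps, 1.0):
            raise CadenceError(
                f"expected 1-min cadence, found step(s) of {steps[steps != 1.0][:1]}"
            )

    mt_col = df["model_temp_c"].to_numpy(dtype=float)
    model_temp = None if np.all(np.isnan(mt_col)) else mt_col

    return EnvSeries(
        time=time,
        air_temp=df["air_temp_c"].to_numpy(dtype=float),
        soil_temp=df["soil_temp_c"].to_numpy(dtype=float),
        solar=df["solar_wm2"].to_numpy(dtype=float),
        wind=df["wind_ms"].to_numpy(dtype=float),
        model_temp=model_temp,
        site=meta["site"],
        date=meta["date"],
        elevation=float(meta["elevation_m"]),
        direct_sun=bool(int(meta["direct_sun"])),
    )
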