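"""In-silico reciprocal-transplant and common-garden experiments, summaries, decomposition.

The two experiment drivers reproduce the logic of the field designs:

* **Reciprocal transplant** (full sun): both species are caged at a low- and a
  high-elevation site; the driving temperature of each individual is its
  biophysically predicted body temperature, so species differences reflect
  *both* morphology (via the heat budget) and thermal sensitivity (via the
  hazard).
* **Common garden** (tents, no direct sun): both species experience the same
  shared physical-mimic temperature trajectory inside a tent, so morphology
  cannot influence the driving temperature and any difference in initiation
  isolates thermal sensitivity.

Comparing the between-species initiation-time advantage in the two designs
decomposes the field difference into physiological (thermal-sensitivity) and
morphological contributions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import defaults as dflt
from .biophys import Morphology, PhysicalParams, _steady_state_arrays, sample_traits
from .flight import TrialConfig, records_to_frame, simulate_trial
from .microclimate import (EnclosureConfig, EnvSeries, SiteConfig,
                           apply_enclosure, generate_diurnal_series)

__all__ = [
    "ExperimentConfig",
    "Decomposition",
    "InitiationDeltas",
    "default_transplant_config",
    "default_garden_config",
    "run_reciprocal_transplant",
    "run_common_garden",
    "summarize_groups",
    "decompose_contributions",
    "estimate_initiation_deltas",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = (
    "species", "site", "n", "n_flew", "prop_init", "prop_lo", "prop_hi",
    "mean_t_init", "t_lo", "t_hi", "mean_temp_init", "temp_lo", "temp_hi",
    "mean_air_init", "air_lo", "air_hi",
)


@dataclass
class ExperimentConfig:
    """Full specification of one in-silico experiment.

    ``species`` maps label -> (TraitDistribution, ThermalSensitivity); its
    insertion order fixes the positional seed derivation, so relabelling
    species with identical parameters exchanges outcomes exactly.
    """

    design: str  # "reciprocal-transplant" | "common-garden"
    sites: list
    traits: dict
    sensitivities: dict
    enclosure: EnclosureConfig
    n_per_cell: int = 12
    n_days: int = 2
    check_interval: int = 2
    t_end: int = 780
    params: PhysicalParams = field(default_factory=PhysicalParams)
    reference_morphology: Morphology = dflt.EPOXY_MODEL_MORPHOLOGY

    def __post_init__(self) -> None:
        if self.design not in ("reciprocal-transplant", "common-garden"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if set(self.traits) != set(self.sensitivities):
            raise ValueError("traits and sensitivities must list the same species")


def default_transplant_config(n_per_cell: int = 12, n_days: int = 2,
                              **overrides) -> ExperimentConfig:
    """Both species caged in full sun at the low and high sites (2-min checks)."""
    return ExperimentConfig(
        design="reciprocal-transplant",
        sites=[dflt.OLATHE, dflt.MESA_SECO],
        traits={"meadii": dflt.MEADII_TRAITS, "eriphyle": dflt.ERIPHYLE_TRAITS},
        sensitivities={"meadii": dflt.MEADII_SENSITIVITY,
                       "eriphyle": dflt.ERIPHYLE_SENSITIVITY},
        enclosure=dflt.CAGE,
        n_per_cell=n_per_cell,
        n_days=n_days,
        check_interval=2,
        **overrides,
    )


def default_garden_config(n_per_cell: int = 12, n_days: int = 5,
                          **overrides) -> ExperimentConfig:
    """Both species in beam-blocking tents at the low garden site (1-min checks)."""
    return ExperimentConfig(
        design="common-garden",
        sites=[dflt.MONTROSE],
        traits={"meadii": dflt.MEADII_TRAITS, "eriphyle": dflt.ERIPHYLE_TRAITS},
        sensitivities={"meadii": dflt.MEADII_SENSITIVITY,
                       "eriphyle": dflt.ERIPHYLE_SENSITIVITY},
        enclosure=dflt.TENT,
        n_per_cell=n_per_cell,
        n_days=n_days,
        check_interval=1,
        **overrides,
    )


def _child(master_seed, *key) -> np.random.SeedSequence:
    """Deterministic per-stage child seed: SeedSequence(master, spawn_key=key).

    Stage indices: (0, day) day-level weather offset; (1, day, site) series
    generation; (2, day, site, species_pos) trait sampling; (3, day, site,
    species_pos) trial coin flips.  Positional species keys make label swaps
    with identical parameters exactly exchangeable.
    """
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(key))


def _day_site(site: SiteConfig, master_seed, day: int) -> SiteConfig:
    """Apply the day's whole-day temperature offset (shared across sites)."""
    off_rng = np.random.default_rng(_child(master_seed, 0, day))
    off = off_rng.normal(0.0, site.day_temp_sd)
    return replace(site, t_min=site.t_min + off, t_max=site.t_max + off)


def run_reciprocal_transplant(cfg: ExperimentConfig, seed: int = 0) -> pd.DataFrame:
    """Run the full-sun transplant: day x site x species factorial of cage trials.

    Each cell samples ``n_per_cell`` morphologies, generates that day's site
    microclimate, applies the cage enclosure, and simulates a trial with
    2-min checks driven by predicted body temperature.  Deterministic for a
    fixed seed; returns the concatenated record table (with a ``day`` column).
    """
    if cfg.design != "reciprocal-transplant":
        raise ValueError("config design is not 'reciprocal-transplant'")
    frames = []
    for day in range(cfg.n_days):
        for si, site in enumerate(cfg.sites):
            day_site = _day_site(site, seed, day)
            series = generate_diurnal_series(day_site, _child(seed, 1, day, si))
            enclosed = apply_enclosure(series, cfg.enclosure)
            trial_cfg = TrialConfig(
                check_interval=cfg.check_interval, t_start=site.sunrise,
                t_end=cfg.t_end, temperature_source="predicted-body",
            )
            for pi, sp in enumerate(cfg.traits):
                morphs = sample_traits(cfg.traits[sp], cfg.n_per_cell,
                                       _child(seed, 2, day, si, pi))
                recs = simulate_trial(
                    morphs, enclosed, cfg.sensitivities[sp], trial_cfg,
                    cfg.params, _child(seed, 3, day, si, pi),
                    species=sp, site=site.name,
                    id_prefix=f"d{day:02d}-{site.name}-{sp}",
                )
                frames.append(records_to_frame(recs, day=day))
    return pd.concat(frames, ignore_index=True)


def synthesize_model_temp(series: EnvSeries, reference: Morphology,
                          params: PhysicalParams) -> EnvSeries:
    """Attach a physical-mimic temperature channel to an (enclosed) series.

    The channel is the minute-by-minute equilibrium temperature of the
    reference mimic under the series' (attenuated, diffuse) radiation — the
    in-silico counterpart of the epoxy model logged inside the tents.
    """
    model = _steady_state_arrays(
        reference.absorptivity, reference.setal_length,
        series.air_temp, series.soil_temp, series.solar, series.wind,
        params, direct_sun=series.direct_sun,
        d_mm=reference.diameter, l_mm=reference.length,
    )
    out = apply_enclosure(series, EnclosureConfig(0.0, 1.0, False))
    out.direct_sun = series.direct_sun
    out.model_temp = np.asarray(model, dtype=float)
    return out


def run_common_garden(cfg: ExperimentConfig, seed: int = 0) -> pd.DataFrame:
    """Run the no-direct-sun garden: both species on one shared tent trajectory.

    Per day: generate the garden-site microclimate, apply the tent enclosure
    (which blocks the direct beam), synthesise the mimic channel, and simulate
    both species on the SAME trajectory with 1-min checks — morphology is
    sampled and recorded but cannot influence the driving temperature, so the
    design isolates thermal sensitivity.
    """
    if cfg.design != "common-garden":
        raise ValueError("config design is not 'common-garden'")
    site = cfg.sites[0]
    frames = []
    for day in range(cfg.n_days):
        day_site = _day_site(site, seed, day)
        series = generate_diurnal_series(day_site, _child(seed, 1, day, 0))
        tent = apply_enclosure(series, cfg.enclosure)
        tent = synthesize_model_temp(tent, cfg.reference_morphology, cfg.params)
        trial_cfg = TrialConfig(
            check_interval=cfg.check_interval, t_start=site.sunrise,
            t_end=cfg.t_end, temperature_source="model-temp",
        )
        for pi, sp in enumerate(cfg.traits):
            morphs = sample_traits(cfg.traits[sp], cfg.n_per_cell,
                                   _child(seed, 2, day, 0, pi))
            recs = simulate_trial(
                morphs, tent, cfg.sensitivities[sp], trial_cfg,
                cfg.params, _child(seed, 3, day, 0, pi),
                species=sp, site=site.name,
                id_prefix=f"d{day:02d}-{site.name}-{sp}",
            )
            frames.append(records_to_frame(recs, day=day))
    return pd.concat(frames, ignore_index=True)


def _percentile_ci(values: np.ndarray, stat, rng: np.random.Generator,
                   n_boot: int, level: float = 0.95) -> tuple[float, float]:
    n = len(values)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        reps[b] = stat(values[rng.integers(0, n, size=n)])
    alpha = 0.5 * (1.0 - level)
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def summarize_groups(records: pd.DataFrame, n_boot: int = 2000,
                     seed: int = 0) -> pd.DataFrame:
    """Per species x site: initiation proportion and flier means, with CIs.

    Proportions are over all individuals; time/temperature means are over
    fliers only.  CIs are 95% percentile bootstrap over ``n_boot`` case
    resamples; groups with no fliers report NaN means and CI bounds.
    """
    if len(records) == 0:
        raise ValueError("empty record table")
    rng = np.random.default_rng(seed)
    rows = []
    for (sp, site), g in records.groupby(["species", "site"], sort=True):
        flew = g["flew"].to_numpy(dtype=float)
        n = len(g)
        n_flew = int(flew.sum())
        prop = n_flew / n
        prop_lo, prop_hi = _percentile_ci(flew, np.mean, rng, n_boot)
        row = {
            "species": sp, "site": site, "n": n, "n_flew": n_flew,
            "prop_init": prop, "prop_lo": prop_lo, "prop_hi": prop_hi,
        }
        for col, prefix in (("t_init_min", "t"), ("temp_at_init_c", "temp"),
                            ("air_at_init_c", "air")):
            vals = g.loc[g["flew"] == 1, col].to_numpy(dtype=float)
            key = {"t": "mean_t_init", "temp": "mean_temp_init",
                   "air": "mean_air_init"}[prefix]
            if n_flew == 0:
                row[key] = np.nan
                row[f"{prefix}_lo"] = np.nan
                row[f"{prefix}_hi"] = np.nan
            else:
                row[key] = float(np.mean(vals))
                lo, hi = _percentile_ci(vals, np.mean, rng, n_boot)
                row[f"{prefix}_lo"] = lo
                row[f"{prefix}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


@dataclass(frozen=True)
class Decomposition:
    """Physiology/morphology split of the species initiation-time advantage."""

    physiology_pct: float
    morphology_pct: float
    physiology_pct_rounded: int
    morphology_pct_rounded: int


def decompose_contributions(dt_no_sun: float, dt_sun: float) -> Decomposition:
    """Split the initiation-time advantage into physiology vs morphology.

    ``dt_no_sun`` is the advantage (min) without direct sun — attributable to
    thermal sensitivity alone; ``dt_sun`` the advantage in full sun —
    sensitivity plus morphology.  Physiology contributes
    ``dt_no_sun/dt_sun * 100`` percent; morphology the remainder.  Reported
    at full precision and rounded to the nearest 5 percentage points (the
    rounded pair is made to sum to exactly 100 by rounding physiology and
    taking the complement).
    """
    if dt_sun <= 0:
        raise ValueError("dt_sun must be > 0")
    if not (0 <= dt_no_sun <= dt_sun):
        raise ValueError("need 0 <= dt_no_sun <= dt_sun")
    phys = 100.0 * dt_no_sun / dt_sun
    morph = 100.0 - phys
    phys_r = int(5 * round(phys / 5))
    return Decomposition(
        physiology_pct=phys, morphology_pct=morph,
        physiology_pct_rounded=phys_r, morphology_pct_rounded=100 - phys_r,
    )


@dataclass(frozen=True)
class InitiationDeltas:
    """Species differences (low-elev minus high-elev species) with CIs.

    ``dt_no_sun``/``dt_sun`` are the initiation-time differences (min) in the
    garden/transplant at the shared low-elevation environment; ``dTb`` is the
    difference in mean driving temperature at initiation in the garden (°C).
    """

    dt_no_sun: float
    dt_sun: float
    dTb: float
    ci: dict


def _mean_diff(a: np.ndarray, b: np.ndarray, rng, n_boot) -> tuple[float, tuple]:
    diff = float(np.mean(a) - np.mean(b))
    reps = np.empty(n_boot)
    for r in range(n_boot):
        reps[r] = (np.mean(a[rng.integers(0, len(a), len(a))])
                   - np.mean(b[rng.integers(0, len(b), len(b))]))
    lo, hi = np.quantile(reps, [0.025, 0.975])
    return diff, (float(lo), float(hi))


def estimate_initiation_deltas(garden_records: pd.DataFrame,
                               transplant_records: pd.DataFrame,
                               low_site: Optional[str] = None,
                               species_low: str = "eriphyle",
                               species_high: str = "meadii",
                               n_boot: int = 2000, seed: int = 0,
                               ) -> InitiationDeltas:
    """Measure the decomposition inputs from the two record tables.

    ``dt_no_sun`` and ``dTb`` come from the garden table; ``dt_sun`` from the
    transplant table restricted to the low-elevation site (default: the
    default low transplant site).  All deltas are ``species_low`` minus
    ``species_high`` means over fliers, with 95% percentile bootstrap CIs.
    """
    low_site = low_site if low_site is not None else dflt.OLATHE.name
    rng = np.random.default_rng(seed)

    def fliers(df: pd.DataFrame, sp: str, col: str, label: str) -> np.ndarray:
        sub = df[(df["species"] == sp) & (df["flew"] == 1)]
        if (df["species"] == sp).sum() == 0:
            raise ValueError(f"species {sp!r} absent from the {label} table")
        if len(sub) == 0:
            raise ValueError(f"species {sp!r} has no fliers in the {label} table")
        return sub[col].to_numpy(dtype=float)

    tp_low = transplant_records[transplant_records["site"] == low_site]
    if len(tp_low) == 0:
        raise ValueError(f"no transplant records at low site {low_site!r}")

    dt_ns, ci_ns = _mean_diff(
        fliers(garden_records, species_low, "t_init_min", "garden"),
        fliers(garden_records, species_high, "t_init_min", "garden"),
        rng, n_boot)
    dt_s, ci_s = _mean_diff(
        fliers(tp_low, species_low, "t_init_min", "transplant"),
        fliers(tp_low, species_high, "t_init_min", "transplant"),
        rng, n_boot)
    dtb, ci_tb = _mean_diff(
        fliers(garden_records, species_low, "temp_at_init_c", "garden"),
        fliers(garden_records, species_high, "temp_at_init_c", "garden"),
        rng, n_boot)
    return InitiationDeltas(
        dt_no_sun=dt_ns, dt_sun=dt_s, dTb=dtb,
        ci={"dt_no_sun": ci_ns, "dt_sun": ci_s, "dTb": ci_tb},
    )
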