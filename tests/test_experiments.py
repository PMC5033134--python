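"""Experiment drivers, group summaries, deltas, and the decomposition."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from coliastherm import (decompose_contributions, default_garden_config,
                         default_transplant_config, estimate_initiation_deltas,
                         run_common_garden, run_reciprocal_transplant,
                         summarize_groups)
from coliastherm import defaults as dflt
from coliastherm.flight import ThermalSensitivity


def small_transplant(n=12, days=2, **kw):
    return default_transplant_config(n_per_cell=n, n_days=days, **kw)


class TestReciprocalTransplant:
    def test_factorial_record_count(self):
        df = run_reciprocal_transplant(small_transplant(), seed=0)
        assert len(df) == 12 * 2 * 2 * 2  # n x sites x species x days
        assert df["id"].is_unique
        counts = df.groupby(["species", "site"]).size()
        assert set(counts) == {24}  # n_per_cell x n_days

    def test_seed_reproducibility(self):
        a = run_reciprocal_transplant(small_transplant(), seed=4)
        b = run_reciprocal_transplant(small_transplant(), seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_high_elevation_species_dominates_cold_site(self):
        """Darker/furrier + lower threshold: meadii initiate at least as often
        as eriphyle at the cold site."""
        df = run_reciprocal_transplant(small_transplant(n=100, days=1), seed=2)
        cold = df[df["site"] == dflt.MESA_SECO.name]
        pm = cold[cold["species"] == "meadii"]["flew"].mean()
        pe = cold[cold["species"] == "eriphyle"]["flew"].mean()
        assert pm >= pe
        assert pm > 0.5 and pe < 0.2

    def test_design_mismatch_rejected(self):
        cfg = default_garden_config()
        with pytest.raises(ValueError, match="reciprocal-transplant"):
            run_reciprocal_transplant(cfg, seed=0)


class TestCommonGarden:
    def test_identical_sensitivities_indistinguishable(self):
        cfg = default_garden_config(n_per_cell=150, n_days=2)
        cfg.sensitivities = {sp: dflt.MEADII_SENSITIVITY
                             for sp in cfg.sensitivities}
        df = run_common_garden(cfg, seed=3)
        fl = df[df["flew"] == 1]
        a = fl[fl["species"] == "meadii"]["t_init_min"]
        b = fl[fl["species"] == "eriphyle"]["t_init_min"]
        assert ks_2samp(a, b).pvalue > 0.01

    def test_default_sensitivities_order_initiation_temperature(self):
        df = run_common_garden(default_garden_config(n_per_cell=150, n_days=3),
                               seed=3)
        fl = df[df["flew"] == 1]
        tm = fl[fl["species"] == "meadii"]["temp_at_init_c"].mean()
        te = fl[fl["species"] == "eriphyle"]["temp_at_init_c"].mean()
        assert tm < te

    def test_cooler_mornings_delay_initiation(self):
        from dataclasses import replace
        warm_cfg = default_garden_config(n_per_cell=120, n_days=2)
        cool_cfg = default_garden_config(n_per_cell=120, n_days=2)
        cool_cfg.sites = [replace(dflt.MONTROSE,
                                  t_min=dflt.MONTROSE.t_min - 5.0,
                                  t_max=dflt.MONTROSE.t_max - 5.0)]
        warm = run_common_garden(warm_cfg, seed=5)
        cool = run_common_garden(cool_cfg, seed=5)
        for sp in ("meadii", "eriphyle"):
            tw = warm[(warm["species"] == sp) & (warm["flew"] == 1)]["t_init_min"].mean()
            tc = cool[(cool["species"] == sp) & (cool["flew"] == 1)]["t_init_min"].mean()
            assert tc > tw

    def test_label_swap_with_identical_params_exchanges_groups(self):
        """Positional seeding: relabelling species with swapped (identical
        shape) configs exchanges group outcomes exactly."""
        cfg1 = default_garden_config(n_per_cell=40, n_days=1)
        cfg2 = default_garden_config(n_per_cell=40, n_days=1)
        for cfg in (cfg1, cfg2):
            cfg.traits = {sp: dflt.MEADII_TRAITS for sp in cfg.traits}
            cfg.sensitivities = {sp: dflt.MEADII_SENSITIVITY
                                 for sp in cfg.sensitivities}
        cfg2.traits = dict(reversed(list(cfg2.traits.items())))
        cfg2.sensitivities = dict(reversed(list(cfg2.sensitivities.items())))
        df1 = run_common_garden(cfg1, seed=8)
        df2 = run_common_garden(cfg2, seed=8)
        first1 = list(cfg1.traits)[0]
        first2 = list(cfg2.traits)[0]
        g1 = df1[df1["species"] == first1].reset_index(drop=True)
        g2 = df2[df2["species"] == first2].reset_index(drop=True)
        # same positional seeds + same parameters per position => same outcomes
        pd.testing.assert_frame_equal(
            g1.drop(columns=["id", "species"]),
            g2.drop(columns=["id", "species"]))


class TestSummarizeGroups:
    def test_ten_of_eleven_fliers(self):
        rows = [{"species": "meadii", "site": "high", "flew": int(i < 10),
                 "t_init_min": 480.0 if i < 10 else np.nan,
                 "air_at_init_c": 15.0 if i < 10 else np.nan,
                 "temp_at_init_c": 25.0 if i < 10 else np.nan}
                for i in range(11)]
        s = summarize_groups(pd.DataFrame(rows), n_boot=200)
        assert s.loc[0, "prop_init"] == pytest.approx(10 / 11)
        assert s.loc[0, "prop_init"] == pytest.approx(0.909, abs=1e-3)

    def test_degenerate_group_zero_width_ci(self):
        rows = [{"species": "x", "site": "s", "flew": 1, "t_init_min": 480.0,
                 "air_at_init_c": 15.0, "temp_at_init_c": 25.0}] * 5
        s = summarize_groups(pd.DataFrame(rows), n_boot=100)
        assert s.loc[0, "mean_t_init"] == 480.0
        assert s.loc[0, "t_lo"] == s.loc[0, "t_hi"] == 480.0

    def test_single_record_no_crash(self):
        rows = [{"species": "x", "site": "s", "flew": 0, "t_init_min": np.nan,
                 "air_at_init_c": np.nan, "temp_at_init_c": np.nan}]
        s = summarize_groups(pd.DataFrame(rows), n_boot=50)
        assert s.loc[0, "n"] == 1 and s.loc[0, "n_flew"] == 0
        assert np.isnan(s.loc[0, "mean_t_init"])

    def test_ci_contains_point_estimate(self):
        df = run_reciprocal_transplant(small_transplant(n=20, days=1), seed=1)
        s = summarize_groups(df, n_boot=400, seed=0)
        ok = (s["prop_lo"] <= s["prop_init"]) & (s["prop_init"] <= s["prop_hi"])
        assert ok.all()


class TestDecomposition:
    def test_published_worked_example(self):
        d = decompose_contributions(5.0, 35.0)
        assert d.physiology_pct == pytest.approx(14.2857, abs=1e-3)
        assert d.morphology_pct == pytest.approx(85.7143, abs=1e-3)
        assert (d.physiology_pct_rounded, d.morphology_pct_rounded) == (15, 85)

    @pytest.mark.parametrize("dns,ds,expect", [
        (0.0, 35.0, (0.0, 100.0)),
        (35.0, 35.0, (100.0, 0.0)),
    ])
    def test_boundary_cases(self, dns, ds, expect):
        d = decompose_contributions(dns, ds)
        assert (d.physiology_pct, d.morphology_pct) == expect

    @pytest.mark.parametrize("dns,ds", [(5.0, 0.0), (5.0, -1.0), (36.0, 35.0),
                                        (-1.0, 35.0)])
    def test_domain_errors(self, dns, ds):
        with pytest.raises(ValueError):
            decompose_contributions(dns, ds)

    @given(ds=st.floats(0.1, 200), frac=st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_pair_sums_to_hundred_at_both_precisions(self, ds, frac):
        d = decompose_contributions(frac * ds, ds)
        assert d.physiology_pct + d.morphology_pct == 100.0
        assert d.physiology_pct_rounded + d.morphology_pct_rounded == 100


class TestInitiationDeltas:
    def test_identical_species_parameters_yield_null_deltas(self):
        tcfg = small_transplant(n=150, days=1)
        gcfg = default_garden_config(n_per_cell=150, n_days=1)
        for cfg in (tcfg, gcfg):
            cfg.traits = {sp: dflt.MEADII_TRAITS for sp in cfg.traits}
            cfg.sensitivities = {sp: dflt.MEADII_SENSITIVITY
                                 for sp in cfg.sensitivities}
        tp = run_reciprocal_transplant(tcfg, seed=6)
        g = run_common_garden(gcfg, seed=6)
        d = estimate_initiation_deltas(g, tp, n_boot=300, seed=0)
        lo, hi = d.ci["dTb"]
        assert lo <= 0.0 <= hi
        assert abs(d.dt_no_sun) < 6.0
        assert abs(d.dTb) < 0.2

    def test_missing_species_raises(self):
        tp = run_reciprocal_transplant(small_transplant(n=5, days=1), seed=0)
        g = run_common_garden(default_garden_config(n_per_cell=5, n_days=1), seed=0)
        with pytest.raises(ValueError, match="absent"):
            estimate_initiation_deltas(g[g["species"] == "meadii"], tp, n_boot=10)

    def test_shade_advantage_smaller_than_sun_advantage(self):
        tp = run_reciprocal_transplant(small_transplant(n=100, days=1), seed=9)
        g = run_common_garden(default_garden_config(n_per_cell=100, n_days=2), seed=9)
        d = estimate_initiation_deltas(g, tp, n_boot=100, seed=0)
        assert 0 < d.dt_no_sun < d.dt_sun
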