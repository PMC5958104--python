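import math

import numpy as np
import pandas as pd
import pytest

from thalnet.membrane import ConfigurationError
from thalnet.metrics import metrics_from_result
from thalnet.network import NetworkConfig, simulate
from thalnet.sweeps import (PRESETS, SweepGrid, add_radius_strata, gain,
                            input_difference_radius, percent_nonindependent,
                            radius_stratum, run_sweep, stratified_gain_summary)


def toy_sweep_frame():
    """Hand-built long-format sweep table with known gains."""
    rows = []
    for ge in (0.0, 0.01):
        for gg in (0.0, 0.02):
            rows.append(dict(g_elec=ge, g_gaba=gg, g_in2=0.06, t_in2=80.0,
                             n_spikes_tc1=5, n_spikes_tc2=3,
                             psi=0.5 + (10 * ge) + gg,
                             phi=-10.0 + 1000 * ge,
                             latency_tc2=math.nan if ge else 8.0))
    return pd.DataFrame(rows)


class TestGrid:
    def test_defaults_match_study_grid(self):
        g = SweepGrid()
        assert len(g.g_elec_values) == 26
        assert len(g.g_gaba_values) == 11
        assert len(g.g_in2_values) == 9
        assert len(g.t_in2_values) == 11
        assert g.n_points == 26 * 11 * 9 * 11

    def test_baseline_always_included(self):
        g = SweepGrid(g_elec_values=(0.005, 0.01))
        assert g.g_elec_values[0] == 0.0

    def test_validation(self):
        with pytest.raises(ConfigurationError):
            SweepGrid(g_gaba_values=())
        with pytest.raises(ConfigurationError):
            SweepGrid(g_gaba_values=(0.02, 0.01))


class TestGain:
    def test_hand_checked_subtraction(self):
        df = gain(toy_sweep_frame())
        base = df[df.g_elec == 0.0]
        assert np.allclose(base.gain_psi, 0.0)
        assert np.allclose(base.gain_phi, 0.0)
        coupled = df[df.g_elec == 0.01]
        assert np.allclose(coupled.gain_psi, 0.1)
        assert np.allclose(coupled.gain_phi, 10.0)

    def test_metric_constant_in_g_elec_gives_zero_gain(self):
        df = toy_sweep_frame()
        df["psi"] = 0.7
        assert np.allclose(gain(df).gain_psi, 0.0)

    def test_nan_propagates_never_zero(self):
        df = toy_sweep_frame()
        df.loc[(df.g_elec == 0.0) & (df.g_gaba == 0.0), "phi"] = math.nan
        out = gain(df)
        assert out[(out.g_elec == 0.01) & (out.g_gaba == 0.0)] \
            .gain_phi.isna().all()

    def test_missing_baseline_rejected(self):
        df = toy_sweep_frame()
        with pytest.raises(ValueError):
            gain(df[df.g_elec > 0.0])


class TestRadiusStrata:
    def test_identical_inputs_center(self):
        assert input_difference_radius(0.0, 0.0, 0.04, 50.0) == 0.0
        assert radius_stratum(0.0, math.sqrt(2)) == 1

    def test_corner(self):
        r = input_difference_radius(0.04, 50.0, 0.04, 50.0)
        assert r == pytest.approx(math.sqrt(2))
        assert radius_stratum(r, r) == 5

    def test_direct_substitution(self):
        assert input_difference_radius(0.02, 25.0, 0.04, 50.0) == \
            pytest.approx(0.7071, abs=1e-4)

    def test_equal_width_bins(self):
        edges = [radius_stratum(r, 1.0) for r in (0.0, 0.19, 0.21, 0.59,
                                                  0.61, 0.99, 1.0)]
        assert edges == [1, 1, 2, 3, 4, 5, 5]

    def test_annotation_covers_five_strata(self):
        grid = SweepGrid()
        df = pd.DataFrame([
            dict(g_elec=0.0, g_gaba=0.0, g_in2=g, t_in2=t)
            for g in grid.g_in2_values for t in grid.t_in2_values])
        out = add_radius_strata(df, grid)
        assert set(out.stratum) == {1, 2, 3, 4, 5}
        assert out.r_input_diff.max() == pytest.approx(math.sqrt(2))


class TestPercentNonindependent:
    def test_all_independent(self):
        assert percent_nonindependent(np.ones(50)) == 0.0

    def test_all_overlapping(self):
        assert percent_nonindependent(np.zeros(50)) == 100.0

    def test_threshold_and_nan_handling(self):
        psi = np.array([0.79, 0.81, 1.0, math.nan])
        assert percent_nonindependent(psi, threshold=0.8) == \
            pytest.approx(100.0 / 3.0)


class TestStratifiedSummary:
    def test_known_sign_pattern(self):
        df = gain(toy_sweep_frame())
        df["stratum"] = 1
        out = stratified_gain_summary(df)
        row = out[(out.g_elec == 0.01) & (out.g_gaba == 0.0)].iloc[0]
        assert row.nonneg_gain_psi == pytest.approx(0.1)
        assert row.nonneg_gain_phi == pytest.approx(10.0)
        assert row.n_nonpos_psi == 0
        base = out[out.g_elec == 0.0]
        assert np.allclose(base.nonneg_gain_psi, 0.0)
        assert np.allclose(base.nonpos_gain_phi, 0.0)

    def test_missing_values_counted_not_imputed(self):
        df = gain(toy_sweep_frame())
        df["stratum"] = 1
        df.loc[df.index[-1], "gain_phi"] = math.nan
        out = stratified_gain_summary(df)
        assert out.n_missing_phi.sum() == 1


class TestRunSweep:
    def test_single_point_sweep_matches_direct_simulation(self):
        grid = SweepGrid(g_elec_values=(0.0,), g_gaba_values=(0.02,),
                         g_in2_values=(0.09,), t_in2_values=(40.0,))
        df = run_sweep(grid)
        assert len(df) == 1
        res = simulate(NetworkConfig(g_elec=0.0, g_gaba=0.02)
                       .with_input2(0.09, 40.0))
        m = metrics_from_result(res)
        row = df.iloc[0]
        assert row.psi == pytest.approx(m.psi)
        assert row.phi == pytest.approx(m.phi)
        assert row.n_spikes_tc2 == m.n_spikes_tc2

    def test_rows_sorted_and_complete(self):
        grid = SweepGrid(g_elec_values=(0.0, 0.01), g_gaba_values=(0.02,),
                         g_in2_values=(0.06,), t_in2_values=(80.0, 100.0))
        df = run_sweep(grid)
        assert len(df) == 4
        assert df.g_elec.is_monotonic_increasing
        assert (df.error == "").all()

    def test_presets_build_valid_grids(self):
        for name, factory in PRESETS.items():
            grid = factory()
            assert grid.g_elec_values[0] == 0.0
            assert grid.n_points >= 1
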