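"""Generator-level checks: forcing shape, mass balance, determinism, artifacts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluxpam import NoiseLevels, Scenario, simulate_campaign, simulate_forcing, simulate_leaf, write_campaign
from fluxpam.micromet import R_GAS, T_KELVIN
from fluxpam.synthetic import simulate_closures, simulate_pam


@pytest.fixture(scope="module")
def forcing():
    return simulate_forcing(Scenario())


class TestForcing:
    def test_par_peaks_at_configured_maximum(self, forcing):
        # the cycle grid contains solar noon, so the peak is attained exactly
        assert forcing["par"].max() == pytest.approx(1700.0)

    def test_par_nonnegative_and_dark_at_night(self, forcing):
        assert (forcing["par"] >= 0).all()
        night = forcing.index.hour.isin([0, 1, 23])
        assert (forcing.loc[night, "par"] == 0).all()

    def test_temperature_spans_configured_range(self):
        f = simulate_forcing(Scenario(t_min=10.0, t_max=25.0))
        assert f["temp"].min() == pytest.approx(10.0)
        assert f["temp"].max() == pytest.approx(25.0)

    def test_daily_temperature_cycle_shape(self, forcing):
        one_day = forcing.loc["2021-07-01"]
        assert one_day["temp"].idxmin().hour == 3
        assert one_day["temp"].idxmax().hour == 15


class TestLeaf:
    def test_zero_sink_ratio_is_four_everywhere_lit(self):
        sc = Scenario(resp_fraction=0, photoresp_fraction=0, alt_sink_fraction=0)
        truth = simulate_leaf(simulate_forcing(sc), sc)
        lit = truth[truth["par"] > 0]
        np.testing.assert_allclose(lit["etr"] / lit["a_net"], 4.0, rtol=1e-12)

    def test_etr_zero_in_darkness(self):
        sc = Scenario()
        truth = simulate_leaf(simulate_forcing(sc), sc)
        assert (truth.loc[truth["par"] == 0, "etr"] == 0).all()

    def test_respiration_raises_ratio_above_four(self):
        sc = Scenario(resp_fraction=0.2, photoresp_fraction=0, alt_sink_fraction=0)
        truth = simulate_leaf(simulate_forcing(sc), sc)
        lit = truth[truth["par"] > 0]
        # symbolic oracle: ratio = 4 / (1 - resp_fraction) = 5
        np.testing.assert_allclose(lit["etr"] / lit["a_net"], 5.0, rtol=1e-12)

    @given(
        resp=st.floats(0, 0.5),
        pr=st.floats(0, 0.45),
        alt=st.floats(0, 0.45),
    )
    def test_ratio_floor_law(self, resp, pr, alt):
        """ETR/A_NET >= 4 with equality iff all fractions are zero."""
        expected = 4.0 / ((1.0 - pr - alt) * (1.0 - resp))
        sc = Scenario(resp_fraction=resp, photoresp_fraction=pr, alt_sink_fraction=alt)
        truth = simulate_leaf(simulate_forcing(sc), sc)
        lit = truth[truth["par"] > 0]
        ratio = (lit["etr"] / lit["a_net"]).iloc[0]
        assert ratio == pytest.approx(expected, rel=1e-9)
        assert ratio >= 4.0 - 1e-9
        if resp == pr == alt == 0:
            assert ratio == pytest.approx(4.0, rel=1e-12)

    def test_yii_within_bounds_and_dark_value(self):
        sc = Scenario()
        truth = simulate_leaf(simulate_forcing(sc), sc)
        assert truth["yii"].between(0, 1).all()
        assert (truth.loc[truth["par"] == 0, "yii"] == sc.yii_dark).all()

    def test_transpiration_inverts_conductance_relation(self):
        sc = Scenario()
        truth = simulate_leaf(simulate_forcing(sc), sc)
        np.testing.assert_allclose(
            truth["e"], truth["gs"] * truth["vpd"] / sc.pressure_kpa, rtol=1e-12
        )


class TestClosures:
    def test_noise_free_slope_matches_mass_balance_oracle(self):
        """Hand oracle: slope = -A_NET * area / (P V / R T_K), in ppm/s."""
        sc = Scenario(noise=NoiseLevels.zero(), pressure_kpa=101.3)
        truth = simulate_leaf(simulate_forcing(sc), sc)
        stream = simulate_closures(truth, sc)
        cycle = truth.index[40]  # a lit cycle
        grp = stream[stream["timestamp"].dt.floor("20min") == cycle]
        t = (grp["timestamp"] - grp["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
        slope = np.polyfit(t, grp["co2"].to_numpy(), 1)[0]
        n_air = 101.3e3 * sc.chamber_volume_m3 / (R_GAS * (truth.loc[cycle, "temp"] + T_KELVIN))
        expected = -truth.loc[cycle, "a_net"] * sc.leaf_area_m2 / n_air
        assert slope == pytest.approx(expected, rel=1e-9)
        assert truth.loc[cycle, "a_net"] > 1  # the oracle cycle is really lit

    def test_zero_flux_leaf_gives_flat_traces(self):
        sc = Scenario(
            resp_fraction=0, photoresp_fraction=0, alt_sink_fraction=0,
            gs_max=0.0, gs_dark_fraction=0.0, par_max=0.0, noise=NoiseLevels.zero(),
        )
        truth = simulate_leaf(simulate_forcing(sc), sc)
        stream = simulate_closures(truth, sc)
        assert stream["co2"].std() == pytest.approx(0.0, abs=1e-12)
        assert stream["h2o"].std() == pytest.approx(0.0, abs=1e-12)

    def test_doubling_leaf_area_doubles_slope(self):
        sc = Scenario(noise=NoiseLevels.zero())
        truth = simulate_leaf(simulate_forcing(sc), sc)
        s1 = simulate_closures(truth, sc)
        s2 = simulate_closures(truth, sc.with_(leaf_area_m2=2 * sc.leaf_area_m2))
        dev1 = s1["co2"].to_numpy() - sc.co2_ambient_ppm
        dev2 = s2["co2"].to_numpy() - sc.co2_ambient_ppm
        np.testing.assert_allclose(dev2, 2 * dev1, rtol=1e-9, atol=1e-12)

    def test_inflow_relaxation_bends_trace_toward_ambient(self):
        sc = Scenario(noise=NoiseLevels.zero(), inflow_time_constant_s=30.0)
        truth = simulate_leaf(simulate_forcing(sc), sc)
        stream = simulate_closures(truth, sc)
        cycle = truth.index[40]
        grp = stream[stream["timestamp"].dt.floor("20min") == cycle]
        dev = np.abs(grp["co2"].to_numpy() - sc.co2_ambient_ppm)
        increments = np.diff(dev)
        assert (increments[1:] < increments[:-1] - 1e-12).all()  # decelerating


class TestPam:
    def test_gain_cancels_in_yield_ratio(self):
        sc = Scenario(noise=NoiseLevels.zero(), pam_gain=3.7)
        truth = simulate_leaf(simulate_forcing(sc), sc)
        pam = simulate_pam(truth, sc)
        recovered = 1.0 - pam["F_prime"] / pam["F_M_prime"]
        np.testing.assert_allclose(recovered, truth["yii"].to_numpy(), rtol=1e-12)

    def test_gain_step_halves_signals_but_not_yield(self):
        step_time = "2021-07-02 12:00"
        sc = Scenario(noise=NoiseLevels.zero(), gain_step=(step_time, 0.5))
        truth = simulate_leaf(simulate_forcing(sc), sc)
        pam = simulate_pam(truth, sc)
        base = simulate_pam(truth, sc.with_(gain_step=None))
        after = truth.index >= pd.Timestamp(step_time)
        np.testing.assert_array_equal(
            pam.loc[after, "F_M_prime"].to_numpy(),
            0.5 * base.loc[after, "F_M_prime"].to_numpy(),
        )
        y_step = 1.0 - pam["F_prime"] / pam["F_M_prime"]
        y_base = 1.0 - base["F_prime"] / base["F_M_prime"]
        np.testing.assert_array_equal(y_step.to_numpy(), y_base.to_numpy())

    def test_clock_drift_ramps_to_configured_maximum(self):
        sc = Scenario(clock_drift_s=480.0, noise=NoiseLevels.zero())
        truth = simulate_leaf(simulate_forcing(sc), sc)
        pam = simulate_pam(truth, sc)
        offsets = (pam["timestamp"].to_numpy() - truth.index.to_numpy()) / np.timedelta64(1, "s")
        assert offsets[0] == pytest.approx(0.0, abs=1e-6)
        assert offsets[-1] <= 480.0
        assert offsets[-1] == pytest.approx(480.0, rel=0.01)
        assert (np.diff(offsets) >= -1e-9).all()


class TestDeterminism:
    def test_identical_scenario_and_seed_are_byte_identical(self, tmp_path):
        sc = Scenario(seed=42)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_campaign(simulate_campaign(sc), d1)
        write_campaign(simulate_campaign(sc), d2)
        for name in ("chamber.csv", "pam.csv", "ground_truth.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seeds_differ(self):
        c1 = simulate_campaign(Scenario(seed=1))
        c2 = simulate_campaign(Scenario(seed=2))
        assert not np.array_equal(c1.chamber["co2"].to_numpy(), c2.chamber["co2"].to_numpy())
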