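import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ventmux as vm

OPEN_VALVE = vm.ValveModel(r_min=1e-6, r_closed=200.0)  # negligible open resistance


def identical_lungs_config(mode="pressure_control", **kw):
    lung = vm.LungModel(compliance=30.0, resistance=8.0)
    return vm.CircuitConfig(
        standard_lung=lung,
        variable_lung=lung,
        valve=OPEN_VALVE,
        valve_turns=OPEN_VALVE.turns_full_open,
        settings=vm.VentilatorSettings(mode=mode),
        duration=15.0,
        noise_sd=0.0,
        **kw,
    )


class TestValveResistance:
    def test_full_open_gives_r_min(self):
        v = vm.ValveModel()
        assert vm.valve_resistance(v, v.turns_full_open) == pytest.approx(v.r_min)

    def test_full_closure_finite_r_closed(self):
        # even fully closed the valve passes air: resistance finite
        v = vm.ValveModel()
        r = vm.valve_resistance(v, 0.0)
        assert r == pytest.approx(v.r_closed)
        assert math.isfinite(r)

    @given(
        st.tuples(
            st.floats(min_value=0.0, max_value=6.0),
            st.floats(min_value=0.0, max_value=6.0),
        ).filter(lambda p: abs(p[0] - p[1]) > 1e-9)
    )
    def test_strictly_decreasing_in_turns(self, pair):
        v = vm.ValveModel()
        t1, t2 = sorted(pair)
        assert vm.valve_resistance(v, t1) > vm.valve_resistance(v, t2)

    def test_out_of_range_rejected(self):
        v = vm.ValveModel()
        for turns in (-0.1, 6.1):
            with pytest.raises(ValueError):
                vm.valve_resistance(v, turns)


class TestPressureControl:
    def test_identical_lungs_equal_tidal_volumes(self):
        ws = vm.simulate_pressure_control(identical_lungs_config())
        tv_s = ws.truth_for("standard")["tv_mL"].to_numpy()
        tv_v = ws.truth_for("variable")["tv_mL"].to_numpy()
        np.testing.assert_allclose(tv_s, tv_v, rtol=1e-3)

    def test_step_response_matches_closed_form(self):
        # square drive (rise_time=0): TV = C * dP * (1 - exp(-Ti/RC))
        lung = vm.LungModel(compliance=40.0, resistance=6.0)
        s = vm.VentilatorSettings(rise_time=0.0)
        cfg = vm.CircuitConfig(
            standard_lung=lung, variable_lung=lung, valve=OPEN_VALVE,
            valve_turns=6.0, settings=s, duration=10.0, noise_sd=0.0,
        )
        ws = vm.simulate_pressure_control(cfg)
        ti = s.inspiratory_time
        tau = lung.time_constant
        expected = lung.compliance * (s.set_pip - s.peep) * (1 - math.exp(-ti / tau))
        tv = ws.truth_for("standard")["tv_mL"].iloc[-1]
        assert tv == pytest.approx(expected, rel=2e-3)

    def test_long_inspiration_reaches_compliance_limit(self):
        lung = vm.LungModel(compliance=40.0, resistance=2.0)  # tau = 0.08 s
        s = vm.VentilatorSettings(rise_time=0.0, set_rr=6.0, inspiratory_fraction=0.5)
        cfg = vm.CircuitConfig(
            standard_lung=lung, variable_lung=lung, valve=OPEN_VALVE,
            valve_turns=6.0, settings=s, duration=20.0, noise_sd=0.0,
        )
        ws = vm.simulate_pressure_control(cfg)
        tv = ws.truth_for("standard")["tv_mL"].iloc[-1]
        assert tv == pytest.approx(lung.compliance * (s.set_pip - s.peep), rel=1e-3)

    def test_flow_matches_exponential_decay(self):
        # the sampled flow of the square-drive response is Q0 * exp(-t/tau)
        lung = vm.LungModel(compliance=30.0, resistance=10.0)
        s = vm.VentilatorSettings(rise_time=0.0)
        cfg = vm.CircuitConfig(
            standard_lung=lung, variable_lung=lung, valve=OPEN_VALVE,
            valve_turns=6.0, settings=s, duration=5.0, noise_sd=0.0,
        )
        ws = vm.simulate_pressure_control(cfg)
        tau = lung.time_constant
        q0 = (s.set_pip - s.peep) / lung.resistance
        i = np.arange(0, int(s.inspiratory_time * cfg.sample_rate), 50)
        t = ws.time[i]
        np.testing.assert_allclose(
            ws.flows["standard"][i], q0 * np.exp(-t / tau), rtol=5e-3
        )

    def test_valve_sweep_leaves_standard_patient_untouched(self):
        tvs_std, tvs_var = [], []
        for turns in [6.0, 4.0, 2.0, 0.0]:
            cfg = vm.CircuitConfig(valve_turns=turns, duration=15.0, noise_sd=0.0)
            ws = vm.simulate_pressure_control(cfg)
            tvs_std.append(ws.truth_for("standard")["tv_mL"].iloc[-1])
            tvs_var.append(ws.truth_for("variable")["tv_mL"].iloc[-1])
        tvs_std = np.array(tvs_std)
        assert np.max(np.abs(tvs_std - tvs_std[0]) / tvs_std[0]) < 0.005
        assert np.all(np.diff(tvs_var) < 0)


class TestVolumeControl:
    def test_branch_volumes_sum_to_set_volume(self):
        cfg = vm.CircuitConfig(
            settings=vm.VentilatorSettings(mode="volume_control"),
            duration=20.0, noise_sd=0.0,
        )
        ws = vm.simulate_volume_control(cfg)
        per_breath = ws.ground_truth.groupby("onset_s")["tv_mL"].sum()
        np.testing.assert_allclose(per_breath, 1200.0, rtol=0.01)

    def test_identical_lungs_split_evenly(self):
        ws = vm.simulate_volume_control(identical_lungs_config("volume_control"))
        tv_s = ws.truth_for("standard")["tv_mL"].iloc[-1]
        tv_v = ws.truth_for("variable")["tv_mL"].iloc[-1]
        assert tv_s == pytest.approx(tv_v, rel=1e-3)
        assert tv_s == pytest.approx(600.0, rel=0.01)

    def test_closing_valve_shifts_volume_to_standard(self):
        tv_s, tv_v = [], []
        for turns in [6.0, 4.0, 2.0, 1.0, 0.0]:
            cfg = vm.CircuitConfig(
                settings=vm.VentilatorSettings(mode="volume_control"),
                valve_turns=turns, duration=15.0, noise_sd=0.0,
            )
            ws = vm.simulate_volume_control(cfg)
            tv_s.append(ws.truth_for("standard")["tv_mL"].iloc[-1])
            tv_v.append(ws.truth_for("variable")["tv_mL"].iloc[-1])
        assert np.all(np.diff(tv_s) > 0)
        assert np.all(np.diff(tv_v) < 0)

    def test_air_prefers_the_compliant_lung(self):
        # unrestricted split: the high-compliance (variable) patient receives
        # the larger share
        cfg = vm.CircuitConfig(
            settings=vm.VentilatorSettings(mode="volume_control"),
            duration=10.0, noise_sd=0.0,
        )
        ws = vm.simulate_volume_control(cfg)
        assert (
            ws.truth_for("variable")["tv_mL"].iloc[-1]
            > ws.truth_for("standard")["tv_mL"].iloc[-1]
        )


class TestArtifacts:
    def test_zero_noise_zero_rate_is_identity(self):
        ws = vm.simulate_pressure_control(vm.CircuitConfig(duration=10.0))
        out = vm.add_instrument_artifacts(ws, 0.0, 0.0, seed=5)
        for pid in ws.patient_ids:
            np.testing.assert_array_equal(out.flows[pid], ws.flows[pid])

    def test_fixed_seed_reproducible(self):
        ws = vm.simulate_pressure_control(vm.CircuitConfig(duration=20.0))
        a = vm.add_instrument_artifacts(ws, 0.02, 2.0, seed=9)
        b = vm.add_instrument_artifacts(ws, 0.02, 2.0, seed=9)
        for pid in ws.patient_ids:
            np.testing.assert_array_equal(a.flows[pid], b.flows[pid])
        assert a.ground_truth.equals(b.ground_truth)

    def test_noise_mostly_below_instrument_floor(self):
        ws = vm.simulate_pressure_control(vm.CircuitConfig(duration=20.0))
        out = vm.add_instrument_artifacts(ws, 0.03, 0.0, seed=1)
        resid = out.flows["standard"] - ws.flows["standard"]
        assert np.mean(np.abs(resid) < 0.08) > 0.99

    def test_inserted_breaths_violate_rate_tolerance(self):
        cfg = vm.CircuitConfig(duration=60.0, noise_sd=0.0)
        ws = vm.add_instrument_artifacts(
            vm.simulate_pressure_control(cfg), 0.0, 3.0, seed=2
        )
        gt = ws.ground_truth
        spont = gt[gt["spontaneous"]]
        assert len(spont) > 0
        set_rr = cfg.settings.set_rr
        assert (np.abs(spont["rate_bpm"] - set_rr) / set_rr > 0.30).all()
        # mechanical breaths with a defined rate stay within tolerance
        mech = gt[~gt["spontaneous"]].dropna(subset=["rate_bpm"])
        assert (np.abs(mech["rate_bpm"] - set_rr) / set_rr <= 0.30).all()

    def test_negative_noise_rejected(self):
        ws = vm.simulate_pressure_control(vm.CircuitConfig(duration=5.0))
        with pytest.raises(ValueError):
            vm.add_instrument_artifacts(ws, -0.01, 0.0, seed=0)


class TestWaveformSetAndConfig:
    def test_series_share_time_base(self, vc_waves):
        n = len(vc_waves.time)
        for pid in vc_waves.patient_ids:
            assert len(vc_waves.flows[pid]) == n
            assert len(vc_waves.pressures[pid]) == n

    def test_ground_truth_volumes_positive(self, vc_waves):
        assert (vc_waves.ground_truth["tv_mL"] > 0).all()

    def test_simulate_deterministic_for_seed(self, vc_config):
        a = vm.simulate(vc_config)
        b = vm.simulate(vc_config)
        for pid in a.patient_ids:
            np.testing.assert_array_equal(a.flows[pid], b.flows[pid])

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sample_rate=0.0),
            dict(duration=-1.0),
            dict(valve_turns=7.5),
            dict(noise_sd=-0.1),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(vm.ConfigError):
            vm.CircuitConfig(**kwargs)

    def test_invalid_lung_and_settings_rejected(self):
        with pytest.raises(vm.ConfigError):
            vm.LungModel(compliance=0.0, resistance=5.0)
        with pytest.raises(vm.ConfigError):
            vm.VentilatorSettings(set_pip=5.0, peep=10.0)
        with pytest.raises(vm.ConfigError):
            vm.ValveModel(r_min=5.0, r_closed=2.0)
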