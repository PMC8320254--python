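import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coldsense import (
    AnalysisConfig,
    RoiTrace,
    Stimulus,
    call_response,
    call_session,
    derivative,
    smooth_trace,
    threshold_temperature,
)
from coldsense.detection import modality_group
from coldsense.synthetic import CellTruth, peltier_ramp_stimulus, synthesize_trace


def make_trace(green, config, cell_id="c1", area=200.0):
    t = np.arange(len(green)) / config.frame_rate_hz
    return RoiTrace(cell_id=cell_id, area_um2=area, green=np.asarray(green, float),
                    time_s=t)


class TestSmoothing:
    def test_constant_series_unchanged(self, config):
        x = np.full(20, 7.0)
        assert np.allclose(smooth_trace(x, 4), x)

    def test_trailing_average_hand_example(self):
        out = smooth_trace(np.array([0.0, 0.0, 0.0, 4.0]), 4)
        assert out[-1] == pytest.approx(1.0)  # (0+0+0+4)/4
        # prefix averages over what exists
        assert out[0] == pytest.approx(0.0)
        assert np.allclose(out[:3], 0.0)

    def test_width_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert np.allclose(smooth_trace(x, 1), x)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(np.ones(3), 4)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=40))
    def test_causality_prefix_only(self, values):
        """Each smoothed sample depends only on samples at or before it."""
        x = np.asarray(values)
        sm = smooth_trace(x, 4)
        perturbed = x.copy()
        perturbed[-1] += 1000
        sm2 = smooth_trace(perturbed, 4)
        assert np.allclose(sm[:-1], sm2[:-1])


class TestDerivative:
    def test_constant_is_zero(self, config):
        t = np.arange(10) / config.frame_rate_hz
        assert np.allclose(derivative(np.full(10, 5.0), t), 0.0)

    def test_linear_ramp_gives_constant_slope(self, config):
        t = np.arange(10) / config.frame_rate_hz
        assert np.allclose(derivative(3.0 * t, t), 3.0)

    def test_single_frame_step_scaled_by_frame_rate(self, config):
        t = np.arange(4) / config.frame_rate_hz
        y = np.array([0.0, 0.0, 2.0, 2.0])
        d = derivative(y, t)
        assert d[1] == pytest.approx(2.0 * 1.55)

    def test_nonincreasing_time_rejected(self):
        with pytest.raises(ValueError):
            derivative(np.arange(3.0), np.array([0.0, 1.0, 1.0]))


def default_stim(onset=15.0, modality="cold_ice_water"):
    return Stimulus(stimulus_id="s1", modality=modality, onset_s=onset)


class TestCallResponse:
    def test_flat_trace_is_degenerate_nonresponder(self, config, flat_trace_factory):
        call = call_response(flat_trace_factory(), default_stim(), config)
        assert not call.is_responder
        assert call.dff == pytest.approx(0.0)
        assert "degenerate_baseline" in call.flags

    def test_synthetic_responder_recovers_amplitude(self, config):
        cell = CellTruth("c1", "basal_cold", 200.0, {"cold_ice_water"}, False,
                         {"cold_ice_water": 1.0})
        stim = default_stim()
        tr = synthesize_trace(cell, [stim], config, seed=5, noise_sd_frac=0.02)
        call = call_response(tr, stim, config)
        assert call.is_responder
        assert call.dff == pytest.approx(1.0, abs=0.1)
        assert call.onset_s is not None and call.onset_s >= stim.onset_s - 1.0

    def test_small_sharp_transient_fails_only_dff_gate(self, config):
        """A 0.20 ΔF/F0 transient with a sharp rise trips the z gate but is
        discarded by the 0.25 amplitude gate."""
        cell = CellTruth("c1", "basal_cold", 200.0, {"cold_ice_water"}, False,
                         {"cold_ice_water": 0.20})
        stim = default_stim()
        tr = synthesize_trace(cell, [stim], config, seed=5, noise_sd_frac=0.01)
        call = call_response(tr, stim, config)
        assert call.z_max >= config.z_threshold
        assert not call.is_responder
        assert call.discard_reason == "below_dff"

    def test_insufficient_baseline_rejected(self, config, flat_trace_factory):
        with pytest.raises(ValueError, match="pre-stimulus"):
            call_response(flat_trace_factory(), default_stim(onset=3.0), config)

    def test_gate_monotonicity_in_thresholds(self, config):
        """Raising z_threshold or dff_min never adds responders."""
        cell = CellTruth("c1", "basal_cold", 200.0, {"cold_ice_water"}, False,
                         {"cold_ice_water": 0.4})
        stim = default_stim()
        tr = synthesize_trace(cell, [stim], config, seed=9, noise_sd_frac=0.05)
        base = call_response(tr, stim, config).is_responder
        for z in (6.0, 10.0, 30.0):
            stricter = call_response(tr, stim, config.replace(z_threshold=z))
            assert base or not stricter.is_responder
            if not base:
                break
        harsher = call_response(tr, stim, config.replace(dff_min=1.5))
        assert not (harsher.is_responder and not base)

    def test_scale_invariance_of_z_and_dff(self, config):
        cell = CellTruth("c1", "basal_cold", 200.0, {"cold_ice_water"}, False,
                         {"cold_ice_water": 0.8})
        stim = default_stim()
        tr = synthesize_trace(cell, [stim], config, seed=3, noise_sd_frac=0.02)
        call1 = call_response(tr, stim, config)
        tr_scaled = RoiTrace(cell_id="c1", area_um2=200.0, green=tr.green * 7.0,
                             time_s=tr.time_s)
        call2 = call_response(tr_scaled, stim, config)
        assert call2.z_max == pytest.approx(call1.z_max, rel=1e-9)
        assert call2.dff == pytest.approx(call1.dff, rel=1e-9)

    def test_constant_offset_preserves_z_and_shrinks_dff(self, config):
        cell = CellTruth("c1", "basal_cold", 200.0, {"cold_ice_water"}, False,
                         {"cold_ice_water": 0.8})
        stim = default_stim()
        tr = synthesize_trace(cell, [stim], config, seed=3, noise_sd_frac=0.02)
        call1 = call_response(tr, stim, config)
        tr_off = RoiTrace(cell_id="c1", area_um2=200.0, green=tr.green + 500.0,
                          time_s=tr.time_s)
        call2 = call_response(tr_off, stim, config)
        assert call2.z_max == pytest.approx(call1.z_max, rel=1e-9)
        assert call2.dff < call1.dff


class TestThresholdTemperature:
    def test_linear_interpolation_midpoint(self, config):
        stim = peltier_ramp_stimulus(onset_s=0.0, start_C=32.0, end_C=2.0,
                                     ramp_s=30.0)
        from coldsense.detection import threshold_temperature_at
        temp, drop = threshold_temperature_at(15.0, stim)
        assert temp == pytest.approx(17.0)
        assert drop == pytest.approx(15.0)

    def test_onset_at_ramp_start_has_zero_drop(self):
        stim = peltier_ramp_stimulus(onset_s=0.0)
        from coldsense.detection import threshold_temperature_at
        temp, drop = threshold_temperature_at(0.0, stim)
        assert drop == pytest.approx(0.0)

    def test_onset_outside_profile_rejected(self):
        stim = peltier_ramp_stimulus(onset_s=10.0, ramp_s=30.0)
        from coldsense.detection import threshold_temperature_at
        with pytest.raises(ValueError, match="outside"):
            threshold_temperature_at(100.0, stim)

    def test_recovers_true_activation_temperature(self, config):
        """Threshold read back from a cooling ramp lands within one
        frame-equivalent °C of the cell's generated threshold."""
        cfg = config.replace(response_window_s=60.0)
        stim = peltier_ramp_stimulus(onset_s=15.0, ramp_s=60.0)  # 0.5 °C/s
        frame_equiv_C = 0.5 / cfg.frame_rate_hz
        for true_th in (10.0, 17.0, 25.0):
            cell = CellTruth("c", "basal_cold", 200.0, {"cold_peltier"}, False,
                             {"cold_peltier": 1.0}, cold_threshold_C=true_th)
            tr = synthesize_trace(cell, [stim], cfg, seed=4, noise_sd_frac=0.02)
            call = call_response(tr, stim, cfg)
            temp, _ = threshold_temperature(call, stim)
            assert abs(temp - true_th) <= frame_equiv_C


class TestCallSession:
    def test_flat_session_has_empty_responding_population(self, config,
                                                          flat_trace_factory):
        traces = [flat_trace_factory(n_frames=400, cell_id=f"c{i}")
                  for i in range(3)]
        stims = [Stimulus(f"s{i}", "cold_ice_water", 15.0 + 45.0 * i)
                 for i in range(2)]
        calls, mods = call_session(traces, stims, config)
        assert all(not c.is_responder for c in calls)
        assert all(len(m) == 0 for m in mods.values())

    def test_cold_submodalities_pool_into_cold(self, config):
        cell = CellTruth("c1", "basal_cold", 200.0,
                         {"cold_ice_water", "pinch"}, False,
                         {"cold_ice_water": 1.0, "pinch": 1.0})
        stims = [Stimulus("s1", "cold_ice_water", 15.0),
                 Stimulus("s2", "pinch", 60.0)]
        tr = synthesize_trace(cell, stims, config, seed=2, noise_sd_frac=0.02)
        _, mods = call_session([tr], stims, config)
        assert mods["c1"] == {"cold", "pinch"}
        assert modality_group("cold_acetone") == "cold"
        assert modality_group("heat_55C") == "heat_55C"

    def test_window_truncation_stable_under_added_stimulus(self, config):
        """Appending a third stimulus 30+ s after the second leaves the first
        stimulus's call untouched."""
        cell = CellTruth("c1", "basal_cold", 200.0, {"cold_ice_water"}, False,
                         {"cold_ice_water": 0.9})
        two = [Stimulus("s1", "cold_ice_water", 15.0),
               Stimulus("s2", "pinch", 60.0)]
        three = two + [Stimulus("s3", "brush", 95.0)]
        tr = synthesize_trace(cell, three, config, seed=6, noise_sd_frac=0.02)
        calls2, _ = call_session([tr], two, config)
        calls3, _ = call_session([tr], three, config)
        first2 = next(c for c in calls2 if c.stimulus_id == "s1")
        first3 = next(c for c in calls3 if c.stimulus_id == "s1")
        assert first2.z_max == pytest.approx(first3.z_max)
        assert first2.dff == pytest.approx(first3.dff)
        assert first2.is_responder == first3.is_responder
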