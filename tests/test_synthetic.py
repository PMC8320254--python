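import numpy as np
import pytest

from coldsense import (
    AnalysisConfig,
    PopulationSpec,
    Stimulus,
    generate_population,
    simulate_dataset,
    synthesize_stack,
    synthesize_trace,
)
from coldsense.detection import COLD_MODALITIES
from coldsense.synthetic import (
    CellTruth,
    default_stimulus_battery,
    read_stimuli_csv,
    read_traces_csv,
    write_dataset,
)


class TestGeneratePopulation:
    def test_control_has_no_silent_cold_cells(self):
        spec = PopulationSpec(n_cells=400, unmask_prob=0.0, condition="control")
        cells = generate_population(spec, seed=1)
        silent_cold = [c for c in cells
                       if c.cell_class == "silent" and c.is_cold_true]
        assert silent_cold == []

    def test_silent_cold_fraction_within_binomial_noise(self):
        """At n=10000, the silent-cold fraction among all cells sits within
        3 binomial SDs of frac_silent × unmask_prob."""
        spec = PopulationSpec(n_cells=10000, frac_basal_cold=0.2,
                              frac_silent=0.2, unmask_prob=0.95,
                              condition="neuropathic")
        cells = generate_population(spec, seed=3)
        frac = np.mean([c.cell_class == "silent" and c.is_cold_true
                        for c in cells])
        p = 0.2 * 0.95
        sd = np.sqrt(p * (1 - p) / 10000)
        assert abs(frac - p) <= 3 * sd

    def test_deterministic_under_seed(self):
        spec = PopulationSpec(n_cells=50, unmask_prob=0.5)
        a = generate_population(spec, seed=11)
        b = generate_population(spec, seed=11)
        assert [(c.cell_id, c.cell_class, c.area_um2, sorted(c.responds))
                for c in a] == \
               [(c.cell_id, c.cell_class, c.area_um2, sorted(c.responds))
                for c in b]

    def test_areas_positive_and_class_separated(self):
        spec = PopulationSpec(n_cells=2000, unmask_prob=0.5)
        cells = generate_population(spec, seed=5)
        assert all(c.area_um2 > 0 for c in cells)
        silent = [c.area_um2 for c in cells if c.cell_class == "silent"]
        basal = [c.area_um2 for c in cells if c.cell_class == "basal_cold"]
        assert np.mean(silent) > 2 * np.mean(basal)

    @pytest.mark.parametrize("kwargs", [
        {"frac_basal_cold": 0.7, "frac_silent": 0.5},
        {"unmask_prob": 1.5},
        {"area_basal_sd_um2": -1.0},
        {"dff_amp_range": (2.0, 1.0)},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PopulationSpec(**kwargs)


class TestSynthesizeTrace:
    def test_zero_noise_nonresponder_is_constant(self, config):
        cell = CellTruth("c", "other", 300.0, set(), False, {})
        tr = synthesize_trace(cell, default_stimulus_battery(), config,
                              seed=0, noise_sd_frac=0.0)
        assert np.allclose(tr.green, tr.green[0])

    def test_zero_noise_peak_equals_requested_amplitude(self, config):
        cell = CellTruth("c", "basal_cold", 200.0, {"cold_ice_water"}, False,
                         {"cold_ice_water": 1.0})
        stim = Stimulus("s1", "cold_ice_water", 15.0)
        tr = synthesize_trace(cell, [stim], config, seed=0, noise_sd_frac=0.0,
                              f0=100.0)
        assert tr.green.max() / 100.0 - 1 == pytest.approx(1.0, abs=1e-9)

    def test_stimulus_spacing_precondition(self, config):
        cell = CellTruth("c", "other", 300.0, set(), False, {})
        stims = [Stimulus("s1", "pinch", 15.0), Stimulus("s2", "brush", 30.0)]
        with pytest.raises(ValueError, match="separated"):
            synthesize_trace(cell, stims, config, seed=0)

    def test_trace_covers_last_response_window(self, config):
        cell = CellTruth("c", "other", 300.0, set(), False, {})
        stims = default_stimulus_battery()
        tr = synthesize_trace(cell, stims, config, seed=0)
        assert tr.time_s[-1] >= stims[-1].onset_s + config.response_window_s


class TestSimulateDataset:
    def test_full_determinism(self, config):
        spec = PopulationSpec(n_cells=30, unmask_prob=0.5)
        a = simulate_dataset(spec, config, seed=21)
        b = simulate_dataset(spec, config, seed=21)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.green, tb.green)
            assert ta.red_mean == tb.red_mean

    def test_traces_share_timing_and_truth_ids_match(self, neuropathic_dataset):
        ds = neuropathic_dataset
        t0 = ds.traces[0].time_s
        assert all(np.array_equal(tr.time_s, t0) for tr in ds.traces)
        assert {c.cell_id for c in ds.truth} == {tr.cell_id for tr in ds.traces}


@pytest.fixture(scope="module")
def tiny(config):
    spec = PopulationSpec(n_cells=6, unmask_prob=0.5, condition="neuropathic")
    return simulate_dataset(spec, config, seed=7, noise_sd_frac=0.0)


class TestSynthesizeStack:
    def test_roundtrip_identity_with_zero_drift(self, tiny, config):
        from coldsense import extract_roi_traces
        nf = tiny.traces[0].time_s.size
        green, red, mask, _ = synthesize_stack(
            tiny, np.zeros((nf, 2), int), seed=1)
        out = extract_roi_traces(green, mask, 1.0, config.frame_rate_hz, red)
        assert len(out) == len(tiny.traces)
        for got, want in zip(out, tiny.traces):
            assert got.cell_id == want.cell_id
            assert np.allclose(got.green, want.green)

    def test_marker_true_cells_bright_in_red(self, tiny, config):
        from coldsense import extract_roi_traces, measure_background_red
        nf = tiny.traces[0].time_s.size
        green, red, mask, bg_mask = synthesize_stack(
            tiny, np.zeros((nf, 2), int), seed=1)
        bg = measure_background_red(red, bg_mask)
        out = extract_roi_traces(green, mask, 1.0, config.frame_rate_hz, red)
        truth = tiny.truth_by_id()
        for tr in out:
            expect = truth[tr.cell_id].tdtomato
            assert (tr.red_mean > bg.mean + 5 * bg.sd) == expect

    def test_drift_length_checked(self, tiny):
        with pytest.raises(ValueError, match="drift"):
            synthesize_stack(tiny, np.zeros((3, 2), int), seed=1)


class TestDatasetIO:
    def test_csv_roundtrip(self, tmp_path, config):
        spec = PopulationSpec(n_cells=5, unmask_prob=0.5)
        ds = simulate_dataset(spec, config, seed=9)
        paths = write_dataset(ds, tmp_path)
        traces = read_traces_csv(paths["traces"], paths["cells"])
        assert [t.cell_id for t in traces] == [t.cell_id for t in ds.traces]
        for got, want in zip(traces, ds.traces):
            assert np.allclose(got.green, want.green)
            assert got.area_um2 == pytest.approx(want.area_um2)
        stims = read_stimuli_csv(paths["stimuli"])
        assert [s.stimulus_id for s in stims] == \
               [s.stimulus_id for s in ds.stimuli]

    def test_temperature_profile_roundtrip(self, tmp_path, config):
        from coldsense import peltier_ramp_stimulus
        spec = PopulationSpec(n_cells=3)
        stims = [peltier_ramp_stimulus(onset_s=15.0)]
        ds = simulate_dataset(spec, config, seed=2, stimuli=stims)
        paths = write_dataset(ds, tmp_path)
        back = read_stimuli_csv(paths["stimuli"])
        assert np.allclose(back[0].temperature_profile,
                           stims[0].temperature_profile)
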