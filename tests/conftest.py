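import numpy as np
import pytest

from coldsense import AnalysisConfig, PopulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def neuropathic_dataset(config):
    """A mid-sized labelled neuropathic session shared across tests."""
    spec = PopulationSpec(n_cells=120, unmask_prob=0.8, condition="neuropathic")
    return simulate_dataset(spec, config, seed=2024)


@pytest.fixture()
def flat_trace_factory(config):
    """Build constant-baseline RoiTraces covering a given stimulus layout."""
    from coldsense import RoiTrace

    def make(n_frames=120, f0=100.0, cell_id="cellflat", area=200.0):
        t = np.arange(n_frames) / config.frame_rate_hz
        return RoiTrace(cell_id=cell_id, area_um2=area,
                        green=np.full(n_frames, f0), time_s=t)

    return make
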