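import numpy as np
import pytest

from thalnet.membrane import CellParams, steady_state_init
from thalnet.metrics import metrics_from_result
from thalnet.network import NetworkConfig, SimulationSettings, simulate


@pytest.fixture(scope="session")
def default_cell():
    return CellParams()


@pytest.fixture(scope="session")
def rest(default_cell):
    return steady_state_init(default_cell)


def _preset_metrics(configs):
    out = []
    for key, cfg in configs:
        res = simulate(cfg)
        out.append((key, res, metrics_from_result(res)))
    return out


@pytest.fixture(scope="session")
def inhibition_sweep():
    """Feedback-inhibition preset: G_elec=0, in2 = 0.09 mS/cm^2 @ 40 ms,
    G_GABA swept 0..0.05 in 0.005 steps."""
    gabas = np.round(np.arange(0.0, 0.0501, 0.005), 4)
    return _preset_metrics(
        [(g, NetworkConfig(g_elec=0.0, g_gaba=float(g)).with_input2(0.09, 40.0))
         for g in gabas])


@pytest.fixture(scope="session")
def latency_sweep():
    """Delayed-input preset: in2 = 0.06 @ 100 ms, G_GABA=0.020, G_elec swept."""
    gels = np.round(np.arange(0.0, 0.0251, 0.001), 4)
    return _preset_metrics(
        [(g, NetworkConfig(g_elec=float(g), g_gaba=0.020).with_input2(0.06, 100.0))
         for g in gels])


@pytest.fixture(scope="session")
def truncation_sweep():
    """Train-truncation preset: in2 = 0.05 @ 80 ms, G_GABA=0.045, G_elec swept."""
    gels = np.round(np.arange(0.0, 0.0251, 0.001), 4)
    return _preset_metrics(
        [(g, NetworkConfig(g_elec=float(g), g_gaba=0.045).with_input2(0.05, 80.0))
         for g in gels])


@pytest.fixture(scope="session")
def coupled_run():
    """One coupled simulation with spikes in all four cells."""
    cfg = NetworkConfig(g_elec=0.01, g_gaba=0.015).with_input2(0.09, 40.0)
    return simulate(cfg, SimulationSettings())
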