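"""The four-cell thalamic motif and its simulation protocols.

Cell indices are fixed throughout the package::

    0 = TC1   1 = TC2   2 = TRN1   3 = TRN2

Connectivity (the only motif this package builds): each TC excites its own
TRN via AMPA, each TRN inhibits its own TC via GABA_A, and the two TRN cells
are joined by one linear gap junction.  External AMPAergic inputs arrive only
at the TC cells, as scheduled (strength, time) events.

The membrane equation integrated for each cell i is

    C_m dV_i/dt = sum_chn g_chn(t) (E_chn - V_i)
                + sum_syn g_syn(t) (E_syn - V_i)
                + g_elec (V_j - V_i)  [TRN cells only]
                + i_DC

with all conductances as densities on equal-area compartments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import _core
from ._core import NGATE
from .membrane import (CellParams, CellState, ConfigurationError,
                       membrane_derivative, steady_state_init)
from .synapses import ChemicalSynapseParams, GapJunctionParams

TC1, TC2, TRN1, TRN2 = 0, 1, 2, 3
CELL_NAMES = ("TC1", "TC2", "TRN1", "TRN2")

#: conductance ranges used in the study (mS/cm^2 and ms); configs outside
#: these ranges are accepted but are outside the characterized regime.
G_ELEC_RANGE = (0.0, 0.025)
G_GABA_RANGE = (0.0, 0.05)
G_IN2_RANGE = (0.02, 0.1)
T_IN2_RANGE = (10.0, 110.0)
G_AMPA_DEFAULT = 0.05
G_IN1_DEFAULT = 0.06
T_IN1_DEFAULT = 60.0


class SimulationError(RuntimeError):
    """Solver or protocol failure; carries any partial trace in ``partial``."""

    def __init__(self, msg, partial=None):
        super().__init__(msg)
        self.partial = partial


@dataclass(frozen=True)
class InputEvent:
    """One external AMPAergic input: maximal conductance and arrival time."""

    g_in: float  # mS/cm^2
    t_in: float  # ms

    def __post_init__(self):
        if self.g_in < 0:
            raise ConfigurationError("input g_in must be >= 0")
        if self.t_in < 0:
            raise ConfigurationError("input t_in must be >= 0")


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of one four-cell simulation.

    All four cells share ``cell`` (identical intrinsic properties).  The
    default input set is the study's standard: TC1 receives 0.06 mS/cm^2 at
    60 ms; TC2's input is the experimental variable.
    """

    cell: CellParams = field(default_factory=CellParams)
    g_gaba: float = 0.0     # TRN_i -> TC_i, [0, 0.05]
    g_ampa: float = G_AMPA_DEFAULT  # TC_i -> TRN_i, fixed 0.05 in the study
    g_elec: float = 0.0     # TRN1 -- TRN2, [0, 0.025]
    inputs_tc1: Tuple[InputEvent, ...] = (InputEvent(G_IN1_DEFAULT, T_IN1_DEFAULT),)
    inputs_tc2: Tuple[InputEvent, ...] = ()

    def __post_init__(self):
        for name in ("g_gaba", "g_ampa", "g_elec"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        object.__setattr__(self, "inputs_tc1", tuple(self.inputs_tc1))
        object.__setattr__(self, "inputs_tc2", tuple(self.inputs_tc2))

    def with_input2(self, g_in: float, t_in: float) -> "NetworkConfig":
        return replace(self, inputs_tc2=(InputEvent(g_in, t_in),))

    def snapshot(self) -> dict:
        """JSON-serializable snapshot sufficient to re-run this config."""
        d = asdict(self)
        return d


@dataclass(frozen=True)
class SimulationSettings:
    """Solver and protocol settings.

    The solver is an adaptive explicit Runge-Kutta 2(3) pair
    (Bogacki-Shampine) with a hard cap ``max_step`` on the step size
    (default 0.01 ms).  Spikes are upward crossings of ``spike_threshold``
    debounced by ``min_isi``; detected spikes drive the chemical synapses
    with zero delay.  ``idc`` is a steady applied current per cell
    (uA/cm^2), used by the measurement protocols.
    """

    duration: float = 250.0     # ms
    max_step: float = 0.01      # ms
    rtol: float = 1e-3
    atol: float = 1e-6
    spike_threshold: float = 0.0  # mV
    min_isi: float = 1.0        # ms
    idc: Tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    record_every: int = 1

    def __post_init__(self):
        if self.duration <= 0 or self.max_step <= 0:
            raise ConfigurationError("duration and max_step must be > 0")
        if self.record_every < 1:
            raise ConfigurationError("record_every must be >= 1")


@dataclass
class SimulationResult:
    """Time grid, voltage traces, spike times and the config that produced them."""

    t: np.ndarray                      # (n,)
    v: np.ndarray                      # (n, 4): TC1, TC2, TRN1, TRN2
    spikes: Dict[str, np.ndarray]      # cell name -> sorted spike times (ms)
    config: dict                       # config + settings snapshot
    gating_bounds: Tuple[float, float] = (0.0, 1.0)  # min/max over the run
    n_steps: int = 0                   # accepted solver steps

    def trace(self, cell: str) -> np.ndarray:
        return self.v[:, CELL_NAMES.index(cell)]

    def to_csv(self, path):
        import pandas as pd
        cols = {"time_ms": self.t}
        for i, name in enumerate(CELL_NAMES):
            cols[f"V_{name}"] = self.v[:, i]
        pd.DataFrame(cols).to_csv(path, index=False)

    def spikes_to_csv(self, path):
        import pandas as pd
        rows = [(name, t) for name in CELL_NAMES for t in self.spikes[name]]
        pd.DataFrame(rows, columns=["cell", "spike_time_ms"]).to_csv(path, index=False)

    def config_to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.config, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# low-level integration wrapper


def _empty_syn_arrays():
    z = np.zeros(0)
    return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
            z, z, z + 1.0, z + 1.0, z)


def _integrate_raw(y, t0, t1, gbar, erev, cm, idc, kin,
                   syn=None, gap=None, events=None,
                   max_step=0.01, rtol=1e-3, atol=1e-6,
                   thresh=0.0, min_isi=1.0, record_every=1,
                   max_spikes=2000):
    """Thin wrapper around the compiled integrator. Mutates ``y`` in place.

    Returns (t, v, spike_times_per_cell, gate_min, gate_max, n_accepted).
    """
    nc = gbar.shape[0]
    if syn is None:
        syn = _empty_syn_arrays()
    syn_pre, syn_post, syn_gbar, syn_e, syn_taur, syn_tauf, syn_fs = syn
    if gap is None:
        gap = (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64), np.zeros(0))
    gap_i, gap_j, gap_g = gap
    if events is None:
        events = (np.zeros(0, dtype=np.int64), np.zeros(0))
    ext_syn, ext_t = events

    maxrec = int((t1 - t0) / (max_step * record_every) * 8) + 200_000
    for _ in range(3):
        rec_t = np.empty(maxrec)
        rec_v = np.empty((maxrec, nc))
        spike_t = np.empty((nc, max_spikes))
        spike_n = np.zeros(nc, dtype=np.int64)
        gate_min = np.empty(NGATE * nc)
        gate_max = np.empty(NGATE * nc)
        y_work = y.copy()
        nrec, status = _core.integrate(
            y_work, t0, t1, max_step, rtol, atol,
            gbar, erev, cm, idc, kin,
            syn_pre, syn_post, syn_gbar, syn_e, syn_taur, syn_tauf, syn_fs,
            gap_i, gap_j, gap_g, ext_syn, ext_t,
            thresh, min_isi, record_every,
            rec_t, rec_v, spike_t, spike_n, gate_min, gate_max)
        if status == _core.RECORD_OVERFLOW:
            maxrec *= 4
            continue
        if status == _core.SPIKE_OVERFLOW:
            max_spikes *= 4
            continue
        break
    if status == _core.STEP_FAILURE:
        raise SimulationError(
            "adaptive step size underflow (solver failure)",
            partial=(rec_t[:nrec].copy(), rec_v[:nrec].copy()))
    if status != _core.OK:
        raise SimulationError(f"integration failed with status {status}")
    y[:] = y_work
    spikes = [spike_t[i, :spike_n[i]].copy() for i in range(nc)]
    # recorded count excludes duplicates of t1 when the last step lands twice
    return rec_t[:nrec].copy(), rec_v[:nrec].copy(), spikes, gate_min, gate_max, nrec


# ---------------------------------------------------------------------------
# network assembly


@dataclass
class NetworkSystem:
    """Assembled integrable system: parameter arrays + initial state."""

    config: NetworkConfig
    y0: np.ndarray
    gbar: np.ndarray
    erev: np.ndarray
    syn: tuple
    gap: tuple
    events: tuple
    v_rest: float


def build_network(config: NetworkConfig,
                  init_state: CellState | None = None) -> NetworkSystem:
    """Assemble the four-cell system from a config.

    All cells start at the input-free steady state (computed and cached by
    :func:`thalnet.membrane.steady_state_init` unless ``init_state`` is
    given); synaptic states start at A = B = 0.
    """
    if init_state is None:
        init_state = steady_state_init(config.cell)
    gbar1, erev = config.cell.conductance_arrays()
    gbar = np.tile(gbar1, (4, 1))

    # synapses: 4 internal + one per external input event
    gaba = ChemicalSynapseParams.gaba(config.g_gaba)
    ampa = ChemicalSynapseParams.ampa(config.g_ampa)
    syn_params: List[ChemicalSynapseParams] = [ampa, ampa, gaba, gaba]
    syn_pre = [TC1, TC2, TRN1, TRN2]   # presynaptic cell (spike source)
    syn_post = [TRN1, TRN2, TC1, TC2]  # postsynaptic target
    ext_syn: List[int] = []
    ext_t: List[float] = []
    for cell_idx, evs in ((TC1, config.inputs_tc1), (TC2, config.inputs_tc2)):
        for ev in evs:
            syn_params.append(ChemicalSynapseParams.ampa(ev.g_in))
            syn_pre.append(-1)          # externally driven, no presynaptic cell
            syn_post.append(cell_idx)
            ext_syn.append(len(syn_params) - 1)
            ext_t.append(ev.t_in)

    order = np.argsort(np.asarray(ext_t), kind="stable")
    events = (np.asarray(ext_syn, dtype=np.int64)[order],
              np.asarray(ext_t, dtype=float)[order])
    syn = (np.asarray(syn_pre, dtype=np.int64),
           np.asarray(syn_post, dtype=np.int64),
           np.asarray([p.g_bar for p in syn_params]),
           np.asarray([p.e_syn for p in syn_params]),
           np.asarray([p.tau_rise for p in syn_params]),
           np.asarray([p.tau_fall for p in syn_params]),
           np.asarray([p.f_s for p in syn_params]))
    gap = (np.asarray([TRN1], dtype=np.int64), np.asarray([TRN2], dtype=np.int64),
           np.asarray([config.g_elec]))

    ns = len(syn_params)
    y0 = np.empty(4 + 4 * NGATE + 2 * ns)
    y0[:4] = init_state.v
    for i in range(4):
        y0[4 + NGATE * i: 4 + NGATE * (i + 1)] = init_state.gating
    y0[4 + 4 * NGATE:] = 0.0
    return NetworkSystem(config, y0, gbar, erev, syn, gap, events, init_state.v)


def simulate(config: NetworkConfig,
             settings: SimulationSettings | None = None,
             system: NetworkSystem | None = None) -> SimulationResult:
    """Run one 4-cell simulation and return traces + detected spikes.

    Deterministic: identical (config, settings) give identical results.
    """
    if settings is None:
        settings = SimulationSettings()
    for evs in (config.inputs_tc1, config.inputs_tc2):
        for ev in evs:
            if ev.t_in >= settings.duration:
                raise ConfigurationError(
                    f"input at t={ev.t_in} ms outside duration {settings.duration} ms")
    if system is None:
        system = build_network(config)
    y = system.y0.copy()
    t, v, spikes, gmin, gmax, nrec = _integrate_raw(
        y, 0.0, settings.duration, system.gbar, system.erev,
        config.cell.c_m, np.asarray(settings.idc, dtype=float),
        config.cell.kin_array(),
        syn=system.syn, gap=system.gap, events=system.events,
        max_step=settings.max_step, rtol=settings.rtol, atol=settings.atol,
        thresh=settings.spike_threshold, min_isi=settings.min_isi,
        record_every=settings.record_every)
    if not np.all(np.isfinite(v)):
        raise SimulationError("non-finite voltages in trace", partial=(t, v))
    return SimulationResult(
        t=t, v=v,
        spikes={name: spikes[i] for i, name in enumerate(CELL_NAMES)},
        config={"network": config.snapshot(), "settings": asdict(settings)},
        gating_bounds=(float(gmin.min()), float(gmax.max())),
        n_steps=nrec)


def detect_spikes(t: np.ndarray, v: np.ndarray, threshold: float = 0.0,
                  min_isi: float = 1.0) -> np.ndarray:
    """Upward threshold crossings, one event per action potential.

    A minimum inter-event interval (default 1 ms) collapses multiple
    crossings within a single action potential.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    idx = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0] + 1
    out: List[float] = []
    last = -np.inf
    for i in idx:
        if t[i] - last >= min_isi:
            out.append(t[i])
            last = t[i]
    return np.asarray(out)


# ---------------------------------------------------------------------------
# measurement protocols


class ProtocolError(RuntimeError):
    """A measurement protocol left its validity domain (e.g. a spike)."""


DEFAULT_IDC_VALUES = (-0.025, -0.05, -0.075, -0.1)  # uA/cm^2, subthreshold


def _steady_deflections(config: NetworkConfig, idc: Sequence[float],
                        settle: float = 6000.0) -> np.ndarray:
    """Steady-state voltage deflections of all 4 cells under applied current."""
    system = build_network(config)
    settings = SimulationSettings(duration=settle, max_step=0.05, idc=tuple(idc),
                                  record_every=50)
    res = simulate(config, settings, system=system)
    if any(len(s) for s in res.spikes.values()):
        raise ProtocolError(
            f"spike during subthreshold measurement (idc={tuple(idc)})")
    return res.v[-1, :] - system.v_rest


def measure_membrane_conductance(cell: CellParams | None = None,
                                 idc_values: Sequence[float] = DEFAULT_IDC_VALUES,
                                 settle: float = 6000.0) -> float:
    """Effective membrane conductance G_m (mS/cm^2) of a single uncoupled cell.

    Injects each steady current in ``idc_values`` (uA/cm^2, subthreshold),
    measures the steady-state voltage deflection, and returns the slope of
    current against deflection through the origin.
    """
    if cell is None:
        cell = CellParams()
    config = NetworkConfig(cell=cell, g_gaba=0.0, g_ampa=0.0, g_elec=0.0,
                           inputs_tc1=(), inputs_tc2=())
    dvs, cur = [], []
    for i in idc_values:
        if i > 0:
            raise ProtocolError("idc_values must be hyperpolarizing (<= 0)")
        dv = _steady_deflections(config, (i, 0.0, 0.0, 0.0), settle)[TC1]
        dvs.append(dv)
        cur.append(i)
    dvs = np.asarray(dvs)
    cur = np.asarray(cur)
    return float(cur @ dvs / (dvs @ dvs))


def measure_coupling_coefficient(g_elec: float,
                                 cell: CellParams | None = None,
                                 idc_values: Sequence[float] = DEFAULT_IDC_VALUES,
                                 settle: float = 6000.0) -> float:
    """Coupling coefficient of the TRN pair at gap conductance ``g_elec``.

    Steady current is injected into TRN1 with chemical synapses held at zero
    and the gap junction attached; cc = dV_TRN2 / dV_TRN1 at steady state,
    averaged over ``idc_values``.  Raises ProtocolError if any cell spikes.
    """
    if cell is None:
        cell = CellParams()
    config = NetworkConfig(cell=cell, g_gaba=0.0, g_ampa=0.0, g_elec=g_elec,
                           inputs_tc1=(), inputs_tc2=())
    ccs = []
    for i in idc_values:
        if i > 0:
            raise ProtocolError("idc_values must be hyperpolarizing (<= 0)")
        dv = _steady_deflections(config, (0.0, 0.0, i, 0.0), settle)
        if abs(dv[TRN1]) < 1e-12:
            raise ProtocolError("no deflection in injected cell")
        ccs.append(dv[TRN2] / dv[TRN1])
    return float(np.mean(ccs))


def coupling_coefficient_two_point(g_elec: float, g_m: float) -> float:
    """Two-cell steady-state prediction cc = g_elec / (g_m + g_elec)."""
    return g_elec / (g_m + g_elec)
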