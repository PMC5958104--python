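"""Chemical (double-exponential) and electrical (gap-junction) synapses.

Chemical synapses follow the NEURON Exp2Syn two-state scheme: rise state A
and fall state B decay exponentially with tau_rise and tau_fall and are both
incremented by f_s * weight at each presynaptic event, so the conductance

    g(t) = g_bar * (B - A)

is a peak-normalized difference of exponentials: a single unit-weight event
yields max_t g(t) = g_bar exactly, at t_peak after the event.

Gap junctions are linear and symmetric: the current into cell i is
g_elec * (V_j - V_i), and the current into j is its exact negative.
"""

from __future__ import annotations

import math
from bisect import insort
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .membrane import ConfigurationError

GABA_REVERSAL = -75.0   # mV
AMPA_REVERSAL = 0.0     # mV
GABA_TAU_FALL = 5.0     # ms
AMPA_TAU_FALL = 2.0     # ms
RISE_FRACTION = 0.1     # tau_rise = 0.1 * tau_fall for both synapse types


def peak_time(tau_rise: float, tau_fall: float) -> float:
    """Time to peak of the difference of exponentials (ms).

    t_peak = tau_fall*tau_rise/(tau_fall - tau_rise) * ln(tau_fall/tau_rise).
    """
    if not 0 < tau_rise < tau_fall:
        raise ConfigurationError("require 0 < tau_rise < tau_fall")
    return tau_fall * tau_rise / (tau_fall - tau_rise) * math.log(tau_fall / tau_rise)


def normalization_factor(tau_rise: float, tau_fall: float) -> float:
    """Event increment f_s that makes the single-event conductance peak at g_bar.

    With A and B both incremented by f_s, the conductance transient is
    g_bar*f_s*(exp(-t/tau_fall) - exp(-t/tau_rise)), whose maximum (at
    t_peak) equals g_bar exactly when
    f_s = 1 / (exp(-t_peak/tau_fall) - exp(-t_peak/tau_rise)).
    """
    tp = peak_time(tau_rise, tau_fall)
    return 1.0 / (math.exp(-tp / tau_fall) - math.exp(-tp / tau_rise))


@dataclass(frozen=True)
class ChemicalSynapseParams:
    """Double-exponential conductance synapse.

    tau_rise defaults to 0.1*tau_fall.  f_s and t_peak are derived from the
    time constants (use the factory classmethods for the two shipped types).
    """

    g_bar: float           # mS/cm^2
    e_syn: float           # mV
    tau_fall: float        # ms
    tau_rise: float = None  # type: ignore[assignment]  # default 0.1*tau_fall

    def __post_init__(self):
        if self.tau_rise is None:
            object.__setattr__(self, "tau_rise", RISE_FRACTION * self.tau_fall)
        if self.g_bar < 0:
            raise ConfigurationError("g_bar must be >= 0")
        if not 0 < self.tau_rise < self.tau_fall:
            raise ConfigurationError("require 0 < tau_rise < tau_fall")

    @property
    def t_peak(self) -> float:
        return peak_time(self.tau_rise, self.tau_fall)

    @property
    def f_s(self) -> float:
        return normalization_factor(self.tau_rise, self.tau_fall)

    @classmethod
    def gaba(cls, g_bar: float) -> "ChemicalSynapseParams":
        """Fast GABA_A synapse: E = -75 mV, tau_fall = 5 ms."""
        return cls(g_bar, GABA_REVERSAL, GABA_TAU_FALL)

    @classmethod
    def ampa(cls, g_bar: float) -> "ChemicalSynapseParams":
        """AMPA synapse: E = 0 mV, tau_fall = 2 ms."""
        return cls(g_bar, AMPA_REVERSAL, AMPA_TAU_FALL)


@dataclass
class ChemicalSynapseState:
    """Kinetic states of one synapse; quiescent start is A = B = 0."""

    a: float = 0.0
    b: float = 0.0

    def conductance(self, params: ChemicalSynapseParams) -> float:
        return params.g_bar * (self.b - self.a)


@dataclass
class EventQueue:
    """Sorted, non-negative presynaptic event times (ms) with unit weights."""

    times: List[float] = field(default_factory=list)

    def __post_init__(self):
        if any(t < 0 for t in self.times):
            raise ConfigurationError("event times must be non-negative")
        self.times = sorted(self.times)

    def add(self, t: float):
        if t < 0:
            raise ConfigurationError("event times must be non-negative")
        insort(self.times, t)


def synapse_step(state: ChemicalSynapseState, params: ChemicalSynapseParams,
                 events: EventQueue, t_from: float, t_to: float,
                 weight: float = 1.0) -> Tuple[ChemicalSynapseState, float]:
    """Advance the two-state kinetics exactly from t_from to t_to.

    A and B decay exponentially with their time constants between events and
    are incremented by f_s*weight at each event time in (t_from, t_to].
    Returns the new state and the conductance g(t_to) = g_bar*(B - A).
    Exact (closed-form) propagation; used directly by the metric-layer tests
    and as the reference for the network integrator's synapse handling.
    """
    if t_to < t_from:
        raise ValueError("t_to must be >= t_from")
    a, b = state.a, state.b
    fs = params.f_s
    t = t_from
    for tk in events.times:
        if tk <= t:
            continue
        if tk > t_to:
            break
        a *= math.exp(-(tk - t) / params.tau_rise)
        b *= math.exp(-(tk - t) / params.tau_fall)
        a += fs * weight
        b += fs * weight
        t = tk
    a *= math.exp(-(t_to - t) / params.tau_rise)
    b *= math.exp(-(t_to - t) / params.tau_fall)
    new = ChemicalSynapseState(a, b)
    return new, new.conductance(params)


def conductance_timeseries(params: ChemicalSynapseParams, events: EventQueue,
                           t_grid: np.ndarray, weight: float = 1.0) -> np.ndarray:
    """g(t) sampled on t_grid for a quiescent-start synapse."""
    state = ChemicalSynapseState()
    out = np.empty(len(t_grid))
    t_prev = -1e-9  # include events at exactly t = 0
    for i, t in enumerate(t_grid):
        state, g = synapse_step(state, params, events, t_prev, float(t), weight)
        out[i] = g
        t_prev = float(t)
    return out


@dataclass(frozen=True)
class GapJunctionParams:
    """Linear symmetric electrical synapse between two cells."""

    g_elec: float                      # mS/cm^2
    endpoints: Tuple[int, int] = (2, 3)  # cell indices (TRN1, TRN2 by default)

    def __post_init__(self):
        if self.g_elec < 0:
            raise ConfigurationError("g_elec must be >= 0")
        if self.endpoints[0] == self.endpoints[1]:
            raise ConfigurationError("gap junction endpoints must differ")


def gap_current(v_i: float, v_j: float, params: GapJunctionParams) -> float:
    """Gap-junction current density into cell i (uA/cm^2): g_elec*(V_j - V_i)."""
    return params.g_elec * (v_j - v_i)
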