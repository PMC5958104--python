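"""Single-compartment Hodgkin-Huxley cell with seven currents.

The cell is a thalamic-style single compartment carrying a fast transient
Na+ current (NaF), a delayed-rectifier K+ current (KDR), a transient A-type
K+ current (KA), a slowly inactivating K+ current (K2), a slow anomalous
rectifier (H), a low-threshold transient Ca2+ current (CaT, fixed ohmic
reversal at +125 mV) and an ohmic leak.  All conductances are densities
(mS/cm^2); all four cells of the network use identical intrinsic parameters.

Rate functions follow the classic single-compartment thalamic reticular
(nRT) Hodgkin-Huxley formulation; the constants that differ between
published variants of that model (the NaF activation shift and the CaT
time-constant coefficients) are exposed on :class:`CellParams` (see the
kinetics provenance table in docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

from . import _core
from ._core import NGATE

CHANNEL_NAMES = ("NaF", "KDR", "KA", "K2", "H", "CaT", "leak")

GATING_NAMES = (
    "m_NaF", "h_NaF", "m_KDR", "m_KA", "h_KA",
    "m_K2", "h_K2", "m_H", "m_CaT", "h_CaT",
)

#: default maximal conductance density (mS/cm^2) and reversal (mV) per channel
DEFAULT_CHANNELS: Dict[str, Tuple[float, float]] = {
    "NaF": (60.5, 50.0),
    "KDR": (60.0, -100.0),
    "KA": (5.0, -100.0),
    "K2": (0.5, -100.0),
    "H": (0.025, -40.0),
    "CaT": (0.67, 125.0),
    "leak": (0.06, -75.0),
}

#: NaF activation shift (mV) of the kinetics variant this package ships with;
#: set so the input-free cell rests at the reference value -70.6837 mV
#: (see docs/methods.md, kinetics provenance).
DEFAULT_NAF_SHIFT = 0.856

#: CaT time-constant coefficients (ms): tau_m = base + scale/(exp(..)+exp(..)),
#: likewise for tau_h.  Published variants of the underlying T-current model
#: differ in these (temperature scaling); see docs/methods.md.
DEFAULT_CAT_TAUM = (0.44, 0.15)
DEFAULT_CAT_TAUH = (28.3, 0.33)


def _default_kin() -> tuple:
    return (DEFAULT_NAF_SHIFT, *DEFAULT_CAT_TAUM, *DEFAULT_CAT_TAUH)


class ConfigurationError(ValueError):
    """Raised for invalid cell, synapse or network configuration."""


class ConvergenceError(RuntimeError):
    """Raised when steady-state initialization fails to converge.

    Carries the voltage trace of the attempted relaxation in ``trace``
    (a ``(t, V)`` tuple of arrays) for inspection.
    """

    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace


@dataclass(frozen=True)
class ChannelParams:
    """One voltage-gated (or leak) current: name, density, reversal."""

    name: str
    g_bar: float  # mS/cm^2
    e_rev: float  # mV

    def __post_init__(self):
        if self.name not in CHANNEL_NAMES:
            raise ConfigurationError(
                f"unknown channel {self.name!r}; expected one of {CHANNEL_NAMES}")
        if self.g_bar < 0:
            raise ConfigurationError(f"channel {self.name}: g_bar must be >= 0")


def default_channels() -> Tuple[ChannelParams, ...]:
    return tuple(ChannelParams(n, *DEFAULT_CHANNELS[n]) for n in CHANNEL_NAMES)


@dataclass(frozen=True)
class CellParams:
    """Intrinsic parameters of one cell.

    c_m is the specific membrane capacitance (uF/cm^2).  ``naf_shift``
    (mV displacement of the NaF activation curve) and the CaT time-constant
    coefficients select the rate-function variant; the defaults are the
    shipped calibration (docs/methods.md).
    """

    c_m: float = 1.0
    channels: Tuple[ChannelParams, ...] = field(default_factory=default_channels)
    naf_shift: float = DEFAULT_NAF_SHIFT
    cat_taum: Tuple[float, float] = DEFAULT_CAT_TAUM
    cat_tauh: Tuple[float, float] = DEFAULT_CAT_TAUH

    def __post_init__(self):
        if self.c_m <= 0:
            raise ConfigurationError("c_m must be > 0")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate channel names in cell")
        for c in self.channels:
            if c.name not in CHANNEL_NAMES:
                raise ConfigurationError(f"unknown channel {c.name!r}")

    def channel(self, name: str) -> ChannelParams:
        for c in self.channels:
            if c.name == name:
                return c
        raise ConfigurationError(f"cell has no channel named {name!r}")

    def with_channel(self, name: str, g_bar=None, e_rev=None) -> "CellParams":
        """Copy of this cell with one channel's parameters overridden."""
        ch = self.channel(name)
        new = ChannelParams(name,
                            ch.g_bar if g_bar is None else g_bar,
                            ch.e_rev if e_rev is None else e_rev)
        chans = tuple(new if c.name == name else c for c in self.channels)
        return replace(self, channels=chans)

    def conductance_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        """(g_bar, e_rev) arrays in canonical channel order; absent channels
        get zero conductance."""
        g = np.zeros(7)
        e = np.array([DEFAULT_CHANNELS[n][1] for n in CHANNEL_NAMES])
        for c in self.channels:
            k = CHANNEL_NAMES.index(c.name)
            g[k] = c.g_bar
            e[k] = c.e_rev
        return g, e

    def kin_array(self) -> np.ndarray:
        """Variant-dependent kinetics constants in the order the core expects."""
        return np.array([self.naf_shift, *self.cat_taum, *self.cat_tauh])

    def _key(self):
        g, e = self.conductance_arrays()
        return (self.c_m, tuple(self.kin_array()), tuple(g), tuple(e))


@dataclass
class CellState:
    """Membrane potential (mV) plus the 10 gating variables."""

    v: float
    gating: np.ndarray  # shape (10,), order GATING_NAMES

    def copy(self) -> "CellState":
        return CellState(self.v, self.gating.copy())


def _kin_of(cell: "CellParams | None") -> np.ndarray:
    return np.array(_default_kin()) if cell is None else cell.kin_array()


def gating_steady_state(v: float, cell: "CellParams | None" = None) -> np.ndarray:
    """Voltage-dependent steady-state values x_inf(V) of all gating variables."""
    inf = np.empty(NGATE)
    tau = np.empty(NGATE)
    _core.gating_rates(float(v), _kin_of(cell), inf, tau)
    return inf


def gating_time_constants(v: float, cell: "CellParams | None" = None) -> np.ndarray:
    """Voltage-dependent time constants tau_x(V) (ms) of all gating variables."""
    inf = np.empty(NGATE)
    tau = np.empty(NGATE)
    _core.gating_rates(float(v), _kin_of(cell), inf, tau)
    return tau


def gating_derivatives(v: float, gating: np.ndarray,
                       cell: "CellParams | None" = None) -> np.ndarray:
    """First-order relaxation dx/dt = (x_inf(V) - x) / tau_x(V), in 1/ms."""
    gating = np.asarray(gating, dtype=float)
    if gating.shape != (NGATE,):
        raise ValueError(f"gating must have shape ({NGATE},)")
    inf = np.empty(NGATE)
    tau = np.empty(NGATE)
    _core.gating_rates(float(v), _kin_of(cell), inf, tau)
    return (inf - gating) / tau


def channel_open_fraction(gating: np.ndarray, name: str) -> float:
    """Open fraction (product of gating powers) for one channel."""
    out = np.empty(7)
    _core.channel_open_fractions(np.asarray(gating, dtype=float), out)
    return float(out[CHANNEL_NAMES.index(name)])


def ionic_current(v: float, gating: np.ndarray, channel: ChannelParams) -> float:
    """Current density through one channel, uA/cm^2, positive = depolarizing.

    I = g_bar * open_fraction(gating) * (E_rev - V).
    """
    return channel.g_bar * channel_open_fraction(gating, channel.name) * \
        (channel.e_rev - v)


def total_ionic_current(v: float, gating: np.ndarray, cell: CellParams) -> float:
    """Sum of all channel currents of the cell at (V, gating), uA/cm^2."""
    return sum(ionic_current(v, gating, c) for c in cell.channels)


def membrane_derivative(state: CellState, cell: CellParams, i_ext: float = 0.0) -> float:
    """dV/dt (mV/ms) of an isolated cell with external current i_ext."""
    return (total_ionic_current(state.v, state.gating, cell) + i_ext) / cell.c_m


_STEADY_CACHE: Dict[tuple, CellState] = {}


def steady_state_init(cell: CellParams | None = None,
                      duration: float = 5000.0,
                      tol: float = 1e-6,
                      max_step: float = 0.05,
                      v_start: float = -75.0,
                      cache: bool = True) -> CellState:
    """Resting state of an isolated, input-free cell.

    The cell is relaxed from ``v_start`` (gating at its steady state for that
    voltage) for ``duration`` ms (default 5000, long enough for the slowest
    gating variable -- H-current activation, tau ~ 750 ms near rest).  The
    landing point is then polished to the exact fixed point, removing solver
    tolerance noise: at a fixed point every gating variable sits at
    x_inf(V), so the rest voltage is the root of the scalar current balance
    I_total(V, x_inf(V)) = 0 nearest the relaxed voltage.  The returned
    state satisfies |dV/dt| < ``tol`` (mV/ms).

    Raises :class:`ConvergenceError` (with the voltage trace attached) if
    the relaxation is still moving at the end -- an oscillatory rest -- or
    no fixed point exists near the landing voltage.
    """
    if cell is None:
        cell = CellParams()
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    key = (cell._key(), duration, tol, max_step, v_start)
    if cache and key in _STEADY_CACHE:
        return _STEADY_CACHE[key].copy()

    from .network import _integrate_raw  # deferred to avoid a cycle

    y = np.empty(1 + NGATE)
    y[0] = v_start
    y[1:] = gating_steady_state(v_start, cell)
    gbar, erev = cell.conductance_arrays()
    gbar = gbar.reshape(1, 7)
    rt, rv, *_ = _integrate_raw(
        y, 0.0, duration, gbar, erev, cell.c_m,
        idc=np.zeros(1), kin=cell.kin_array(),
        max_step=max_step, record_every=20)
    trace = (rt, rv[:, 0])

    # still-moving check over the final 10% of the relaxation
    tail = rv[rt >= 0.9 * duration, 0]
    if tail.max() - tail.min() > 0.1:
        raise ConvergenceError(
            f"rest did not settle: V moved {tail.max() - tail.min():.3g} mV "
            f"over the last {0.1 * duration:.0f} ms (oscillating rest?)",
            trace=trace)

    def balance(v):
        return total_ionic_current(v, gating_steady_state(v, cell), cell)

    v_end = y[0]
    v0 = _bisect_root(balance, v_end - 1.0, v_end + 1.0)
    if v0 is None or abs(v0 - v_end) > 1.0:
        raise ConvergenceError(
            f"no current-balance fixed point near relaxed V = {v_end:.3f} mV",
            trace=trace)
    state = CellState(v0, gating_steady_state(v0, cell))
    dvdt = abs(membrane_derivative(state, cell))
    if dvdt >= tol:
        raise ConvergenceError(
            f"|dV/dt| = {dvdt:.3g} mV/ms at candidate rest (tol {tol:g})",
            trace=trace)
    if cache:
        _STEADY_CACHE[key] = state.copy()
    return state


def _bisect_root(f, lo, hi, iters=200):
    """Root of f on [lo, hi] by expanding-bracket bisection; None if absent."""
    flo, fhi = f(lo), f(hi)
    for _ in range(8):
        if flo * fhi <= 0:
            break
        lo -= 0.5
        hi += 0.5
        flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        return None
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)
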