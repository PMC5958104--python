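"""Parameter sweeps over (G_elec, G_GABA, G_in2, t_in2), gains and strata.

A sweep runs one four-cell simulation per grid point and collects the TC
pair metrics into a long-format pandas DataFrame (one row per point).  Gains
are differences of a measure from its value in the uncoupled network
(G_elec = 0) at otherwise matched parameters; undefined (NaN) measures stay
undefined.  Input differences relative to the fixed TC1 input are summarized
by a normalized radius binned into five strata.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .membrane import ConfigurationError
from .metrics import metrics_from_result
from .network import (NetworkConfig, SimulationSettings, build_network,
                      simulate, G_IN1_DEFAULT, T_IN1_DEFAULT)

N_STRATA = 5

METRIC_COLUMNS = ("n_spikes_tc1", "n_spikes_tc2", "psi", "phi", "latency_tc2")
GAINABLE = ("psi", "phi")


def _grid(lo: float, hi: float, step: float) -> tuple:
    n = int(round((hi - lo) / step))
    return tuple(np.round(lo + step * np.arange(n + 1), 10))


@dataclass(frozen=True)
class SweepGrid:
    """Grid of swept parameters; fixed quantities follow the study protocol.

    Defaults reproduce the full study grid: G_elec 0..0.025 by 0.001, G_GABA
    0..0.05 by 0.005, G_in2 0.02..0.1 by 0.01, t_in2 10..110 by 10 ms, with
    TC1's input fixed at 0.06 mS/cm^2, 60 ms and G_AMPA at 0.05 mS/cm^2.
    The uncoupled baseline G_elec = 0 is always included.
    """

    g_elec_values: tuple = field(default_factory=lambda: _grid(0.0, 0.025, 0.001))
    g_gaba_values: tuple = field(default_factory=lambda: _grid(0.0, 0.05, 0.005))
    g_in2_values: tuple = field(default_factory=lambda: _grid(0.02, 0.1, 0.01))
    t_in2_values: tuple = field(default_factory=lambda: _grid(10.0, 110.0, 10.0))
    g_in1: float = G_IN1_DEFAULT
    t_in1: float = T_IN1_DEFAULT
    g_ampa: float = 0.05

    def __post_init__(self):
        for name in ("g_elec_values", "g_gaba_values", "g_in2_values",
                     "t_in2_values"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) == 0:
                raise ConfigurationError(f"{name} must be non-empty")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ConfigurationError(f"{name} must be sorted")
            if any(v < 0 for v in vals):
                raise ConfigurationError(f"{name} must be non-negative")
            object.__setattr__(self, name, vals)
        if 0.0 not in self.g_elec_values:
            object.__setattr__(self, "g_elec_values",
                               (0.0,) + self.g_elec_values)

    @property
    def n_points(self) -> int:
        return (len(self.g_elec_values) * len(self.g_gaba_values)
                * len(self.g_in2_values) * len(self.t_in2_values))

    def points(self):
        return itertools.product(self.g_elec_values, self.g_gaba_values,
                                 self.g_in2_values, self.t_in2_values)


def _run_point(point, grid: SweepGrid, settings: SimulationSettings,
               base_config: NetworkConfig):
    g_elec, g_gaba, g_in2, t_in2 = point
    from dataclasses import replace
    from .network import InputEvent
    config = replace(base_config, g_elec=g_elec, g_gaba=g_gaba,
                     g_ampa=grid.g_ampa,
                     inputs_tc1=(InputEvent(grid.g_in1, grid.t_in1),),
                     inputs_tc2=(InputEvent(g_in2, t_in2),))
    row = {"g_elec": g_elec, "g_gaba": g_gaba, "g_in2": g_in2, "t_in2": t_in2}
    try:
        res = simulate(config, settings)
        m = metrics_from_result(res, t_in2)
        row.update(n_spikes_tc1=m.n_spikes_tc1, n_spikes_tc2=m.n_spikes_tc2,
                   psi=m.psi, phi=m.phi, latency_tc2=m.latency_tc2,
                   error="")
    except Exception as exc:  # record failure, continue the sweep
        row.update(n_spikes_tc1=-1, n_spikes_tc2=-1, psi=math.nan,
                   phi=math.nan, latency_tc2=math.nan, error=str(exc))
    return row


def run_sweep(grid: SweepGrid,
              settings: Optional[SimulationSettings] = None,
              base_config: Optional[NetworkConfig] = None,
              n_jobs: int = 1) -> pd.DataFrame:
    """One simulation per grid point; returns a long-format metrics table.

    Deterministic and order-independent: rows are always sorted by
    (g_elec, g_gaba, g_in2, t_in2).  Individual simulation failures are
    recorded in the ``error`` column and do not abort the sweep.
    """
    if settings is None:
        settings = SimulationSettings()
    if base_config is None:
        base_config = NetworkConfig()
    # warm the steady-state cache once before any parallel fan-out
    build_network(base_config)
    points = list(grid.points())
    if n_jobs != 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_run_point)(p, grid, settings, base_config) for p in points)
    else:
        rows = [_run_point(p, grid, settings, base_config) for p in points]
    df = pd.DataFrame(rows)
    return df.sort_values(["g_elec", "g_gaba", "g_in2", "t_in2"],
                          kind="mergesort").reset_index(drop=True)


def gain(df: pd.DataFrame, metrics: Sequence[str] = GAINABLE) -> pd.DataFrame:
    """Per-point gain of each measure relative to the uncoupled slice.

    Gain[m](g_elec, b) = m(g_elec, b) - m(0, b) at matched
    (g_gaba, g_in2, t_in2).  NaN minus anything is NaN.  Raises if the
    baseline slice g_elec = 0 is missing.
    """
    base = df[df["g_elec"] == 0.0]
    if base.empty:
        raise ValueError("baseline slice g_elec = 0 missing from sweep")
    keys = ["g_gaba", "g_in2", "t_in2"]
    base = base.set_index(keys)
    out = df.copy()
    idx = pd.MultiIndex.from_frame(df[keys])
    for m in metrics:
        out[f"gain_{m}"] = df[m].to_numpy() - base[m].reindex(idx).to_numpy()
    return out


def input_difference_radius(d_g: float, d_t: float,
                            max_d_g: float, max_d_t: float) -> float:
    """Normalized Euclidean input difference r in [0, sqrt(2)].

    r = sqrt((dG/max dG)^2 + (dt/max dt)^2) with dG = G_in2 - G_in1 and
    dt = t_in2 - t_in1.
    """
    if max_d_g <= 0 or max_d_t <= 0:
        raise ValueError("maxima must be > 0")
    return math.sqrt((d_g / max_d_g) ** 2 + (d_t / max_d_t) ** 2)


def radius_stratum(r: float, r_max: float, n_strata: int = N_STRATA) -> int:
    """Equal-width stratum index in 1..n_strata over [0, r_max]; r=0 -> 1."""
    if r < 0 or r_max <= 0:
        raise ValueError("require r >= 0 and r_max > 0")
    k = int(r / r_max * n_strata) + 1
    return min(max(k, 1), n_strata)


def add_radius_strata(df: pd.DataFrame, grid: SweepGrid,
                      n_strata: int = N_STRATA) -> pd.DataFrame:
    """Annotate a sweep table with r and its stratum (per input difference)."""
    d_g = df["g_in2"].to_numpy() - grid.g_in1
    d_t = df["t_in2"].to_numpy() - grid.t_in1
    max_d_g = max(abs(v - grid.g_in1) for v in grid.g_in2_values)
    max_d_t = max(abs(v - grid.t_in1) for v in grid.t_in2_values)
    r = np.sqrt((d_g / max_d_g) ** 2 + (d_t / max_d_t) ** 2)
    out = df.copy()
    out["r_input_diff"] = r
    r_max = float(r.max()) if len(r) else 1.0
    out["stratum"] = [radius_stratum(x, r_max, n_strata) for x in r]
    return out


def percent_nonindependent(psi_values, threshold: float = 0.8) -> float:
    """Percent of simulations whose combined psi falls below ``threshold``.

    NaN psi values (no such value can arise from the metric layer, which
    maps silent cells to psi = 1, but sweeps may record failed points)
    are excluded from the denominator.
    """
    psi = np.asarray(psi_values, dtype=float).ravel()
    psi = psi[~np.isnan(psi)]
    if psi.size == 0:
        return math.nan
    return 100.0 * float(np.count_nonzero(psi < threshold)) / psi.size


def stratified_gain_summary(df: pd.DataFrame,
                            metrics: Sequence[str] = GAINABLE) -> pd.DataFrame:
    """Mean non-negative and non-positive gains per (g_elec, g_gaba, stratum).

    Missing (NaN) gains are excluded from the means and reported in
    ``n_missing_<m>``; ``n_points`` counts grid points in the group.  The
    top/bottom semi-arc display convention maps to the ``nonneg_gain_<m>``
    and ``nonpos_gain_<m>`` columns.
    """
    if "stratum" not in df.columns:
        raise ValueError("run add_radius_strata first")
    rows = []
    for (ge, gg, st), grp in df.groupby(["g_elec", "g_gaba", "stratum"],
                                        sort=True):
        row = {"g_elec": ge, "g_gaba": gg, "stratum": st,
               "n_points": len(grp)}
        for m in metrics:
            g = grp[f"gain_{m}"].to_numpy(dtype=float)
            miss = np.isnan(g)
            g = g[~miss]
            nn = g[g >= 0]
            npos = g[g <= 0]
            row[f"nonneg_gain_{m}"] = float(nn.mean()) if nn.size else math.nan
            row[f"nonpos_gain_{m}"] = float(npos.mean()) if npos.size else math.nan
            row[f"n_nonneg_{m}"] = int(nn.size)
            row[f"n_nonpos_{m}"] = int(npos.size)
            row[f"n_missing_{m}"] = int(miss.sum())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# named experiment presets


def preset_inhibition() -> SweepGrid:
    """Feedback-inhibition sweep: large early input to TC2, no gap junction.

    G_elec = 0; G_in2 = 0.09 mS/cm^2 at 40 ms; G_GABA swept 0..0.05.
    """
    return SweepGrid(g_elec_values=(0.0,),
                     g_gaba_values=_grid(0.0, 0.05, 0.005),
                     g_in2_values=(0.09,), t_in2_values=(40.0,))


def preset_latency() -> SweepGrid:
    """Delayed-input electrical sweep: equal-strength input to TC2 at 100 ms.

    G_in2 = 0.06 at 100 ms; G_GABA = 0.020; G_elec swept 0..0.025.
    """
    return SweepGrid(g_elec_values=_grid(0.0, 0.025, 0.001),
                     g_gaba_values=(0.020,),
                     g_in2_values=(0.06,), t_in2_values=(100.0,))


def preset_truncation() -> SweepGrid:
    """Train-truncation electrical sweep: weaker input to TC2 at 80 ms with
    strong inhibition.

    G_in2 = 0.05 at 80 ms; G_GABA = 0.045; G_elec swept 0..0.025.
    """
    return SweepGrid(g_elec_values=_grid(0.0, 0.025, 0.001),
                     g_gaba_values=(0.045,),
                     g_in2_values=(0.05,), t_in2_values=(80.0,))


def preset_input_grid(g_gaba: float = 0.025,
                      g_elec_values: tuple = (0.0, 0.005, 0.010, 0.015,
                                              0.020, 0.025)) -> SweepGrid:
    """Input-difference grid at fixed inhibition, coarse G_elec set."""
    return SweepGrid(g_elec_values=g_elec_values, g_gaba_values=(g_gaba,))


def preset_gain_map() -> SweepGrid:
    """Full study grid for gain maps (26 x 11 x 9 x 11 points)."""
    return SweepGrid()


PRESETS = {
    "inhibition": preset_inhibition,
    "latency": preset_latency,
    "truncation": preset_truncation,
    "input-grid": preset_input_grid,
    "gain-map": preset_gain_map,
}


def sweep_manifest(grid: SweepGrid, settings: SimulationSettings,
                   wall_clock_s: Optional[float] = None) -> dict:
    from dataclasses import asdict as _asdict
    from . import __version__
    return {"grid": asdict(grid), "settings": _asdict(settings),
            "version": __version__, "wall_clock_s": wall_clock_s}
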