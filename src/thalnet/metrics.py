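"""Spike-train windows, temporal independence and separation.

The spiking window of a TC cell runs from its first spike to its last spike
plus 5 ms (a tail allowing for EPSP decay in a downstream cortical cell); a
silent cell has an empty window of length zero.

Independence of the pair is measured per cell as one minus the fractional
overlap of the two windows,

    psi_i = 1 - |sigma_1 ∩ sigma_2| / |sigma_i|,

combined by root-mean-square, psi = sqrt((psi_1^2 + psi_2^2)/2).  If either
window is empty the trains are defined to be completely independent
(psi = psi_1 = psi_2 = 1).

Separation phi is the signed gap between the windows: the interval between
the end of the leading window and the start of the following one when the
trains are fully independent (phi >= 0), minus the overlap length when they
overlap (phi < 0), and undefined (NaN) when either cell is silent.
Undefined values propagate as NaN through all downstream aggregation; they
are never coerced to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

WINDOW_TAIL = 5.0  # ms appended after the last spike


@dataclass(frozen=True)
class SpikingWindow:
    """Closed interval [first spike, last spike + 5 ms], or empty."""

    start: float = math.nan
    end: float = math.nan
    empty: bool = True

    def __post_init__(self):
        if not self.empty and not (self.end >= self.start):
            raise ValueError("window end must be >= start")

    @property
    def length(self) -> float:
        """|sigma|: window length in ms (0 when empty)."""
        return 0.0 if self.empty else self.end - self.start


def spiking_window(spikes: Sequence[float]) -> SpikingWindow:
    """Window [t_first, t_last + 5] of a sorted spike train; empty if silent."""
    spikes = np.asarray(list(spikes), dtype=float)
    if spikes.size == 0:
        return SpikingWindow()
    if np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted")
    return SpikingWindow(float(spikes[0]), float(spikes[-1]) + WINDOW_TAIL,
                         empty=False)


def window_overlap(s1: SpikingWindow, s2: SpikingWindow) -> float:
    """|sigma_1 ∩ sigma_2| for closed intervals; 0 if either is empty.

    Touching endpoints (end of one equals start of the other) count as
    overlap 0, so psi = 1 and phi = 0 exactly at the boundary.
    """
    if s1.empty or s2.empty:
        return 0.0
    return max(0.0, min(s1.end, s2.end) - max(s1.start, s2.start))


def independence(sigma1: SpikingWindow, sigma2: SpikingWindow
                 ) -> Tuple[float, float, float]:
    """(psi_1, psi_2, psi); all equal 1 when either window is empty."""
    if sigma1.empty or sigma2.empty:
        return 1.0, 1.0, 1.0
    ov = window_overlap(sigma1, sigma2)
    psi1 = 1.0 - ov / sigma1.length
    psi2 = 1.0 - ov / sigma2.length
    psi = math.sqrt((psi1 * psi1 + psi2 * psi2) / 2.0)
    return psi1, psi2, psi


def separation(sigma1: SpikingWindow, sigma2: SpikingWindow) -> float:
    """Signed window separation phi (ms); NaN when either window is empty."""
    if sigma1.empty or sigma2.empty:
        return math.nan
    _, _, psi = independence(sigma1, sigma2)
    if psi < 1.0:
        return -window_overlap(sigma1, sigma2)
    lead, follow = (sigma1, sigma2) if sigma1.start <= sigma2.start \
        else (sigma2, sigma1)
    return follow.start - lead.end


def tc2_latency(spikes_tc2: Sequence[float], t_in2: float) -> float:
    """Latency of TC2's first spike after its input (ms); NaN if silent."""
    spikes = np.asarray(list(spikes_tc2), dtype=float)
    if spikes.size == 0:
        return math.nan
    return float(spikes[0]) - t_in2


@dataclass(frozen=True)
class TCPairMetrics:
    """All per-simulation spike-train measures for the TC pair."""

    psi_1: float
    psi_2: float
    psi: float
    phi: float            # ms; NaN when undefined
    latency_tc2: float    # ms; NaN when TC2 silent
    n_spikes_tc1: int
    n_spikes_tc2: int

    @property
    def psi_percent(self) -> float:
        """psi expressed as a percentage (user-facing convention)."""
        return 100.0 * self.psi


def pair_metrics(spikes_tc1: Sequence[float], spikes_tc2: Sequence[float],
                 t_in2: Optional[float] = None) -> TCPairMetrics:
    """Compute all pair measures from the two TC spike trains."""
    s1 = spiking_window(spikes_tc1)
    s2 = spiking_window(spikes_tc2)
    psi1, psi2, psi = independence(s1, s2)
    phi = separation(s1, s2)
    lat = math.nan if t_in2 is None else tc2_latency(spikes_tc2, t_in2)
    return TCPairMetrics(psi1, psi2, psi, phi, lat,
                         len(list(spikes_tc1)), len(list(spikes_tc2)))


def metrics_from_result(result, t_in2: Optional[float] = None) -> TCPairMetrics:
    """Pair metrics from a :class:`thalnet.network.SimulationResult`.

    ``t_in2`` defaults to the first external input of TC2 in the result's
    config snapshot (NaN latency if TC2 has no input).
    """
    if t_in2 is None:
        evs = result.config["network"]["inputs_tc2"]
        t_in2 = evs[0]["t_in"] if evs else None
    return pair_metrics(result.spikes["TC1"], result.spikes["TC2"], t_in2)
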