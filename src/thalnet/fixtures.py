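"""Synthetic spike trains with prescribed window geometry.

These fixtures exercise the metric layer (windows, independence, separation)
with exactly known geometry, independent of any simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .metrics import WINDOW_TAIL


class InfeasibleFixture(ValueError):
    """The requested window geometry cannot be realized."""


@dataclass(frozen=True)
class SpikeTrainFixture:
    """Two spike-time lists whose spiking windows have known geometry."""

    spikes_1: Tuple[float, ...]
    spikes_2: Tuple[float, ...]
    length_1: float
    length_2: float
    overlap: float  # |sigma_1 ∩ sigma_2|
    gap: float      # start_2 - end_1 when positive


def make_fixture(length_1: float, length_2: float,
                 overlap: Optional[float] = None,
                 gap: Optional[float] = None,
                 start_1: float = 60.0,
                 n_spikes: int = 3) -> SpikeTrainFixture:
    """Build two spike trains with windows of the requested lengths and
    either a requested overlap or a requested gap.

    ``length_i = 0`` requests an empty train.  Exactly one of ``overlap`` /
    ``gap`` may be positive (a gap g places window 2 to start g ms after
    window 1 ends; an overlap v makes the windows share v ms).  overlap=0 and
    gap=0 are the same touching-boundary geometry.
    """
    if (overlap is None) == (gap is None):
        raise InfeasibleFixture("specify exactly one of overlap or gap")
    offset = -overlap if overlap is not None else gap
    if overlap is not None and overlap < 0:
        raise InfeasibleFixture("overlap must be >= 0 (use gap for separation)")
    if gap is not None and gap < 0:
        raise InfeasibleFixture("gap must be >= 0 (use overlap instead)")

    def build(start, length):
        if length == 0:
            return ()
        if length < WINDOW_TAIL:
            raise InfeasibleFixture(
                f"non-empty windows have length >= {WINDOW_TAIL} ms")
        last = start + length - WINDOW_TAIL
        k = 1 if last == start else max(2, n_spikes)
        return tuple(np.linspace(start, last, k))

    s1 = build(start_1, length_1)
    end_1 = start_1 + length_1
    start_2 = end_1 + offset
    s2 = build(start_2, length_2)
    if s2 and s2[0] < 0:
        raise InfeasibleFixture("train 2 would start before t = 0")

    eff_overlap = 0.0
    eff_gap = 0.0
    if length_1 > 0 and length_2 > 0:
        eff_overlap = max(0.0, min(end_1, start_2 + length_2)
                          - max(start_1, start_2))
        eff_gap = max(0.0, start_2 - end_1)
    if overlap is not None and length_1 > 0 and length_2 > 0 \
            and abs(eff_overlap - overlap) > 1e-9:
        raise InfeasibleFixture(
            f"requested overlap {overlap} not realizable with window "
            f"lengths {length_1}, {length_2}")
    return SpikeTrainFixture(s1, s2, length_1, length_2, eff_overlap, eff_gap)
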