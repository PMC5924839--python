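"""Five-way spiking-pattern classification from a voltage trace.

Superficial dorsal horn neurons are conventionally sorted into five
patterns by their response to a sustained current step: *tonic*
(sustained firing), *single* (one early spike), *delayed* (late first
spike), *gap* (early spike, long pause, resumed firing) and *reluctant*
(no spikes).  The decision rules operate on the spike times relative to
stimulus onset and the first inter-spike intervals:

1. no spikes                                        -> RELUCTANT
2. one spike with first-spike delay > 100 ms        -> DELAYED
3. one spike otherwise                              -> SINGLE
4. >= 3 spikes and (t2 - t1) > 1.5 (t3 - t2)        -> GAP
5. >= 2 spikes and t1 > 1.5 (t2 - t1)               -> DELAYED
6. otherwise                                        -> TONIC

The gap rule is tested before the delayed rule, so a train satisfying
both is labelled GAP.  Two-spike trains cannot satisfy the gap rule
(there is no second ISI) and are eligible only for DELAYED or TONIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .model import SimulationResult
from .sweep import SpikeStats

__all__ = ["PatternLabel", "SpikeTrain", "detect_spikes", "classify",
           "classify_stats", "LABEL_ORDER"]


class PatternLabel(IntEnum):
    """The five spiking patterns, coded 1-5."""

    RELUCTANT = 1
    SINGLE = 2
    DELAYED = 3
    GAP = 4
    TONIC = 5


#: canonical index order (code i at position i-1) used by proportion vectors
LABEL_ORDER = tuple(PatternLabel(i) for i in range(1, 6))


@dataclass
class SpikeTrain:
    """Spike times in ms relative to stimulus onset, within the stimulus window."""

    spike_times: list[float] = field(default_factory=list)
    stim_duration: float = 400.0

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.stim_duration):
            raise ValueError("spike times must lie within [0, stim_duration]")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def isis(self) -> np.ndarray:
        return np.diff(np.asarray(self.spike_times, dtype=float))


def detect_spikes(trace: SimulationResult, threshold: float = 0.0,
                  reset: float | None = None) -> SpikeTrain:
    """Detect spikes as upward threshold crossings within the stimulus window.

    A crossing counts only if the trace has been below ``reset`` (default:
    the threshold) since the previous spike, which guards against double
    counting on noisy recorded traces.  Spike times are linearly
    interpolated between samples.  Samples outside the stimulus window are
    ignored.
    """
    if reset is None:
        reset = threshold
    t, V = trace.times, trace.V
    stim_dur = trace.protocol.stim_duration
    times: list[float] = []
    armed = True
    for i in range(1, len(V)):
        if V[i] < reset:
            armed = True
        if armed and V[i - 1] < threshold <= V[i]:
            frac = (threshold - V[i - 1]) / (V[i] - V[i - 1])
            tc = t[i - 1] + frac * (t[i] - t[i - 1])
            if 0.0 <= tc <= stim_dur:
                times.append(float(tc))
            armed = False
    return SpikeTrain(spike_times=times, stim_duration=stim_dur)


def classify(train: SpikeTrain) -> PatternLabel:
    """Assign one of the five pattern labels to a spike train."""
    t = train.spike_times
    n = len(t)
    if n == 0:
        return PatternLabel.RELUCTANT
    if n == 1:
        return PatternLabel.DELAYED if t[0] > 100.0 else PatternLabel.SINGLE
    if n >= 3 and (t[1] - t[0]) > 1.5 * (t[2] - t[1]):
        return PatternLabel.GAP
    if t[0] > 1.5 * (t[1] - t[0]):
        return PatternLabel.DELAYED
    return PatternLabel.TONIC


def classify_stats(stats: SpikeStats) -> np.ndarray:
    """Vectorized classification of sweep output; returns int codes 1-5."""
    n, t1, t2, t3 = stats.n_spikes, stats.t1, stats.t2, stats.t3
    with np.errstate(invalid="ignore"):
        conditions = [
            n == 0,
            (n == 1) & (t1 > 100.0),
            n == 1,
            (n >= 3) & ((t2 - t1) > 1.5 * (t3 - t2)),
            (n >= 2) & (t1 > 1.5 * (t2 - t1)),
        ]
    choices = [
        PatternLabel.RELUCTANT,
        PatternLabel.DELAYED,
        PatternLabel.SINGLE,
        PatternLabel.GAP,
        PatternLabel.DELAYED,
    ]
    return np.select(conditions, choices, default=PatternLabel.TONIC).astype(np.int8)
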