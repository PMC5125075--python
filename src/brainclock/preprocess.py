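"""Burst filtering of spike trains.

Giant pyramidal cells signal mostly in bursts — volleys of spikes a few
milliseconds apart — and clock structure is more visible in bursts than in
isolated spikes.  The filter keeps exactly those spikes that have at least one
*companion* spike from the same neuron within a short window (6 ms by
default), discarding isolated events.  Companionship is judged on the input
set in a single pass: removing an isolated spike never strips companionship
from the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_io import SpikeDataset, ms_to_ticks

__all__ = ["BurstFilterConfig", "burst_filter"]


@dataclass(frozen=True)
class BurstFilterConfig:
    """Companion-spike window, in ticks (120 ticks = 6 ms at 20 kHz).

    The window is inclusive: a companion exactly ``window`` ticks away counts.
    """

    window: int = 120

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")

    @classmethod
    def from_ms(cls, window_ms: float = 6.0, sample_rate: float = 20000.0) -> "BurstFilterConfig":
        return cls(window=ms_to_ticks(window_ms, sample_rate))


def burst_filter(dataset: SpikeDataset, config: BurstFilterConfig | None = None) -> SpikeDataset:
    """Keep only spikes with a same-neuron companion within ``config.window``.

    Returns a new dataset containing exactly those spikes ``j`` for which some
    other spike of the same neuron lies within ``window`` ticks (inclusive) of
    ``spiket[j]``.  Relative order is preserved; the output is a subset of the
    input.
    """
    if config is None:
        config = BurstFilterConfig(window=ms_to_ticks(6.0, dataset.sample_rate))
    w = config.window
    n = len(dataset)
    keep = np.zeros(n, dtype=bool)
    if n == 0:
        return SpikeDataset(
            dataset.spiket[keep], dataset.spikeind[keep],
            dataset.sample_rate, dict(dataset.neurons),
        )
    # Stable sort by neuron groups events per neuron while keeping each
    # neuron's times sorted (spiket is globally non-decreasing).
    order = np.argsort(dataset.spikeind, kind="stable")
    ids = dataset.spikeind[order]
    times = dataset.spiket[order]
    boundaries = np.flatnonzero(np.diff(ids)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for a, b in zip(starts, ends):
        ts = times[a:b]
        if ts.size == 1:
            continue
        gaps = np.diff(ts)
        has_prev = np.concatenate(([False], gaps <= w))
        has_next = np.concatenate((gaps <= w, [False]))
        keep[order[a:b]] = has_prev | has_next
    return SpikeDataset(
        dataset.spiket[keep], dataset.spikeind[keep],
        dataset.sample_rate, dict(dataset.neurons),
    )
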