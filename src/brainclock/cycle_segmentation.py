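"""Brain-cycle construction from quiet-window locations.

A *formal* clock cycle is an arbitrary tiling of a span into K intervals of
length δ; the *brain cycle* is anchored to physiology: it stretches from the
middle of the quiet period in one formal cycle to the middle of the quiet
period in the next, yielding K−1 brain cycles per span.  Each brain cycle
[t−, t+) is split at its exact midpoint t0 into an AM half [t−, t0) and a PM
half [t0, t+); a spike exactly at t0 belongs to PM.  Quiet-window midpoints
may fall on half ticks, so boundaries are computed in doubled-tick integer
arithmetic and carried exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock_scan import ClockScanConfig, QuietScanResult
from .spike_io import SpikeDataset

__all__ = ["BrainCycle", "CycleSet", "CycleSpikes", "AssignmentResult",
           "segment_cycles", "assign_spikes"]


@dataclass(frozen=True)
class BrainCycle:
    """One clock cycle [t_minus, t_plus) with midpoint t0 (exact half-ticks)."""

    t_minus: float
    t0: float
    t_plus: float
    span_index: int

    def __post_init__(self) -> None:
        if not (self.t_minus < self.t0 < self.t_plus):
            raise ValueError("cycle boundaries must satisfy t_minus < t0 < t_plus")


@dataclass
class CycleSet:
    """Ordered, non-overlapping brain cycles plus the scan that produced them."""

    cycles: list[BrainCycle]
    source_config: ClockScanConfig


@dataclass
class CycleSpikes:
    """Spike times of one brain cycle, per neuron, split into AM and PM."""

    cycle: BrainCycle
    am: dict[int, np.ndarray]
    pm: dict[int, np.ndarray]


@dataclass
class AssignmentResult:
    """Spikes assigned to cycles; spikes outside all cycles are tallied."""

    cycles: list[CycleSpikes]
    n_assigned: int
    n_dropped: int


def segment_cycles(scan: QuietScanResult) -> CycleSet:
    """Build brain cycles from per-span quiet-window offsets.

    For a span starting at ``s`` with quiet offset ``o``, the quiet midpoints
    are ``mid_i = s + i·δ + o + window/2`` for the span's formal cycles
    ``i = 0 .. n−1``; brain cycles are ``[mid_i, mid_{i+1})``.  A whole-record
    fallback span uses as many formal cycles as fit in its length.
    """
    cfg = scan.config
    if cfg.K < 2:
        raise ValueError("no brain cycles: K must be at least 2")
    cycles: list[BrainCycle] = []
    for span in scan.wherebin:
        length = span.span_end - span.span_start
        if length == cfg.span_length:
            ncycles = cfg.K
        else:
            ncycles = int(length // cfg.delta)
        if ncycles < 2:
            continue
        # doubled-tick arithmetic keeps half-integer midpoints exact
        base2 = 2 * (span.span_start + span.quiet_offset) + cfg.window
        mids2 = [base2 + 2 * i * cfg.delta for i in range(ncycles)]
        for i in range(ncycles - 1):
            t_minus2, t_plus2 = mids2[i], mids2[i + 1]
            t0_2 = (t_minus2 + t_plus2) // 2  # both mids share parity (even Δ)
            cycles.append(
                BrainCycle(
                    t_minus=t_minus2 / 2.0,
                    t0=t0_2 / 2.0,
                    t_plus=t_plus2 / 2.0,
                    span_index=span.span_index,
                )
            )
    if not cycles:
        raise ValueError("no brain cycles: record too short for the given (delta, K)")
    return CycleSet(cycles=cycles, source_config=cfg)


def assign_spikes(dataset: SpikeDataset, cycles: CycleSet) -> AssignmentResult:
    """Assign every spike to its brain cycle's AM or PM half.

    Spikes before the first quiet midpoint, after the last, or in span-seam
    gaps belong to no cycle; they are dropped and counted, so that
    ``n_assigned + n_dropped == len(dataset)``.
    """
    spiket = dataset.spiket
    spikeind = dataset.spikeind
    out: list[CycleSpikes] = []
    n_assigned = 0
    for cyc in cycles.cycles:
        lo = int(np.searchsorted(spiket, cyc.t_minus, side="left"))
        mid = int(np.searchsorted(spiket, cyc.t0, side="left"))
        hi = int(np.searchsorted(spiket, cyc.t_plus, side="left"))
        am = _group_by_neuron(spiket[lo:mid], spikeind[lo:mid])
        pm = _group_by_neuron(spiket[mid:hi], spikeind[mid:hi])
        out.append(CycleSpikes(cycle=cyc, am=am, pm=pm))
        n_assigned += hi - lo
    return AssignmentResult(
        cycles=out, n_assigned=n_assigned, n_dropped=len(dataset) - n_assigned
    )


def _group_by_neuron(times: np.ndarray, ids: np.ndarray) -> dict[int, np.ndarray]:
    if times.size == 0:
        return {}
    order = np.argsort(ids, kind="stable")  # times stay sorted within a neuron
    ids_s = ids[order]
    times_s = times[order]
    cuts = np.flatnonzero(np.diff(ids_s)) + 1
    starts = np.concatenate(([0], cuts))
    ends = np.concatenate((cuts, [ids_s.size]))
    return {int(ids_s[a]): times_s[a:b] for a, b in zip(starts, ends)}


def cycles_frame(cycles: CycleSet, sample_rate: float = 20000.0) -> pd.DataFrame:
    """Tabular view of a cycle set, in ticks and milliseconds."""
    tick_ms = 1000.0 / sample_rate
    return pd.DataFrame(
        [
            {
                "span_index": c.span_index,
                "t_minus": c.t_minus,
                "t0": c.t0,
                "t_plus": c.t_plus,
                "t_minus_ms": c.t_minus * tick_ms,
                "t0_ms": c.t0 * tick_ms,
                "t_plus_ms": c.t_plus * tick_ms,
            }
            for c in cycles.cycles
        ]
    )
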