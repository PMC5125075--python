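"""Mirror vs. repetition tests of signal-propagation direction.

Learning models of the backpropagation family predict that each clock cycle
alternates a forward pass with a backward pass: the firing sequence in the
second (PM) half of a brain cycle should look more like a time-reversed
*mirror* of the first (AM) half than like a *repetition* of it.  Purely
feed-forward dynamics predict the opposite.  Two families of error measures
discriminate the hypotheses; in both, the smaller error marks the
better-fitting hypothesis.

Interval measures (per neuron, per cycle)
    With t_AM−/t_AM+ the first/last AM spike of a neuron, t_PM−/t_PM+ its PM
    counterparts, N its total spike count, t0 the cycle midpoint and t+ the
    cycle end, the mirror error is

        e↓ = N·(|(t0 − t_AM+) − (t_PM− − t0)| + |(t0 − t_AM−) − (t_PM+ − t0)|)

    and the repetition error is

        e↑ = N·(|(t0 − t_AM+) − (t+ − t_PM+)| + |(t0 − t_AM−) − (t+ − t_PM−)|).

    Midpoint variants substitute the interval midpoints (t_AM− + t_AM+)/2 and
    (t_PM− + t_PM+)/2 for the extremes.

Sequence measures (per cycle)
    Active neurons (fired in both halves) are sorted by their AM and PM mean
    firing times.  The repetition error is the inversion number between the
    two orderings; the mirror error is the inversion number between the AM
    ordering and the *reversed* PM ordering.  Weighted versions multiply each
    cycle's inversion count by (total AM spikes) × (total PM spikes) of the
    active neurons.

Inertia measures quantify cycle-to-cycle stability of the active set and of
the AM/PM orders, which sharpens the clock-period estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clock_scan import ClockScanConfig, null_expectation, quiet_scan
from .cycle_segmentation import AssignmentResult, CycleSpikes, assign_spikes, segment_cycles
from .preprocess import BurstFilterConfig, burst_filter
from .spike_io import SpikeDataset

__all__ = [
    "Phase2Errors",
    "Phase3Stats",
    "InertiaMeasures",
    "inversion_number",
    "phase2_errors",
    "phase3_errors",
    "inertia_measures",
    "hypothesis_table",
]


@dataclass
class Phase2Errors:
    """Interval-based error accumulators (tick·spike units), summed over cycles.

    ``scale`` divides the raw accumulators for display; the published tables
    used 1e6 and rounded to the nearest integer.
    """

    e_down_ext: float = 0.0
    e_up_ext: float = 0.0
    e_down_mid: float = 0.0
    e_up_mid: float = 0.0
    scale: float = 1_000_000.0

    def _scaled(self, x: float) -> int:
        return int(round(x / self.scale))

    @property
    def scaled_e_down_ext(self) -> int:
        return self._scaled(self.e_down_ext)

    @property
    def scaled_e_up_ext(self) -> int:
        return self._scaled(self.e_up_ext)

    @property
    def scaled_e_down_mid(self) -> int:
        return self._scaled(self.e_down_mid)

    @property
    def scaled_e_up_mid(self) -> int:
        return self._scaled(self.e_up_mid)


@dataclass
class Phase3Stats:
    """Sequence-based error and inertia accumulators.

    ``report_scale`` divides values for table display only; raw integer
    accumulators are kept exact.
    """

    e_down_unweighted: int = 0
    e_up_unweighted: int = 0
    e_down_weighted: int = 0
    e_up_weighted: int = 0
    n_cycles_used: int = 0
    report_scale: float = 1.0

    def reported(self) -> dict[str, float]:
        s = self.report_scale
        return {
            "e_down_unweighted": self.e_down_unweighted / s,
            "e_up_unweighted": self.e_up_unweighted / s,
            "e_down_weighted": self.e_down_weighted / s,
            "e_up_weighted": self.e_up_weighted / s,
        }


@dataclass
class InertiaMeasures:
    """Cycle-to-cycle stability: active-set turnover and AM/PM order changes."""

    neuron_change: int = 0
    seq_am: int = 0
    seq_pm: int = 0


def _count_inversions(seq: list[int]) -> int:
    """Number of out-of-order pairs, by merge sort (O(n log n))."""
    n = len(seq)
    if n < 2:
        return 0
    buf = list(seq)
    tmp = [0] * n
    count = 0
    width = 1
    while width < n:
        for lo in range(0, n, 2 * width):
            mid = min(lo + width, n)
            hi = min(lo + 2 * width, n)
            i, j, k = lo, mid, lo
            while i < mid and j < hi:
                if buf[i] <= buf[j]:
                    tmp[k] = buf[i]
                    i += 1
                else:
                    tmp[k] = buf[j]
                    j += 1
                    count += mid - i
                k += 1
            while i < mid:
                tmp[k] = buf[i]
                i += 1
                k += 1
            while j < hi:
                tmp[k] = buf[j]
                j += 1
                k += 1
        buf, tmp = tmp, buf
        width *= 2
    return count


def inversion_number(perm_a: Sequence, perm_b: Sequence) -> int:
    """Count pairs ordered oppositely in two orderings of the same ID set.

    Equivalently, the minimal number of adjacent swaps turning ``perm_b``
    into ``perm_a``.  Identical orderings give 0; fully reversed orderings of
    n items give n(n−1)/2.
    """
    a = list(perm_a)
    b = list(perm_b)
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("orderings must not contain duplicate IDs")
    if set(a) != set(b):
        raise ValueError("orderings must be over the same ID set")
    pos = {item: i for i, item in enumerate(a)}
    return _count_inversions([pos[item] for item in b])


def phase2_errors(assigned: AssignmentResult, scale: float = 1_000_000.0) -> Phase2Errors:
    """Accumulate the interval-based mirror/repetition errors over all cycles.

    A neuron participates in a cycle iff it fired at least once in both the
    AM and the PM half; cycles with no participating neuron contribute zero.
    """
    acc = Phase2Errors(scale=scale)
    for cyc in assigned.cycles:
        t0 = cyc.cycle.t0
        t_plus = cyc.cycle.t_plus
        for nid in cyc.am.keys() & cyc.pm.keys():
            a = cyc.am[nid]
            p = cyc.pm[nid]
            ta_min, ta_max = float(a[0]), float(a[-1])
            tp_min, tp_max = float(p[0]), float(p[-1])
            n = int(a.size + p.size)
            acc.e_down_ext += n * (
                abs((t0 - ta_max) - (tp_min - t0)) + abs((t0 - ta_min) - (tp_max - t0))
            )
            acc.e_up_ext += n * (
                abs((t0 - ta_max) - (t_plus - tp_max))
                + abs((t0 - ta_min) - (t_plus - tp_min))
            )
            am_mean = (ta_min + ta_max) / 2.0
            pm_mean = (tp_min + tp_max) / 2.0
            acc.e_down_mid += n * abs((t0 - am_mean) - (pm_mean - t0))
            acc.e_up_mid += n * abs((t0 - am_mean) - (t_plus - pm_mean))
    return acc


def _cycle_orderings(cyc: CycleSpikes):
    """Active neurons of a cycle with their AM/PM orderings and spike counts.

    Active means fired in both halves.  Orders are by mean firing time
    (midpoint of first and last spike), ties broken by ascending neuron ID.
    """
    active = sorted(cyc.am.keys() & cyc.pm.keys())
    am_mean = {}
    pm_mean = {}
    n_am = 0
    n_pm = 0
    for nid in active:
        a, p = cyc.am[nid], cyc.pm[nid]
        am_mean[nid] = (float(a[0]) + float(a[-1])) / 2.0
        pm_mean[nid] = (float(p[0]) + float(p[-1])) / 2.0
        n_am += int(a.size)
        n_pm += int(p.size)
    am_order = sorted(active, key=lambda nid: (am_mean[nid], nid))
    pm_order = sorted(active, key=lambda nid: (pm_mean[nid], nid))
    return active, am_order, pm_order, n_am, n_pm


def phase3_errors(assigned: AssignmentResult, report_scale: float = 1.0) -> Phase3Stats:
    """Accumulate the inversion-number mirror/repetition errors over cycles.

    Cycles with fewer than two active neurons are skipped — there are no AM
    and PM sequences to compare.  The weighted accumulators multiply each
    cycle's inversion count by (total AM spikes) × (total PM spikes) over the
    cycle's active neurons.
    """
    stats = Phase3Stats(report_scale=report_scale)
    for cyc in assigned.cycles:
        active, am_order, pm_order, n_am, n_pm = _cycle_orderings(cyc)
        if len(active) < 2:
            continue
        e_up = inversion_number(am_order, pm_order)
        e_down = inversion_number(am_order, pm_order[::-1])
        weight = n_am * n_pm
        stats.e_up_unweighted += e_up
        stats.e_down_unweighted += e_down
        stats.e_up_weighted += e_up * weight
        stats.e_down_weighted += e_down * weight
        stats.n_cycles_used += 1
    return stats


def inertia_measures(assigned: AssignmentResult) -> InertiaMeasures:
    """Cycle-to-cycle stability over consecutive cycle pairs within a span.

    For each pair: the active-set turnover (size of the symmetric difference),
    and the inversion numbers of the AM and PM orderings restricted to the
    shared active set (pairs sharing fewer than two neurons contribute no
    sequence change).
    """
    out = InertiaMeasures()
    prev = None
    for cyc in assigned.cycles:
        cur = _cycle_orderings(cyc)
        if prev is not None and prev_span == cyc.cycle.span_index:
            p_active, p_am, p_pm, _, _ = prev
            c_active, c_am, c_pm, _, _ = cur
            shared = set(p_active) & set(c_active)
            out.neuron_change += len(set(p_active) ^ set(c_active))
            if len(shared) >= 2:
                out.seq_am += inversion_number(
                    [n for n in p_am if n in shared], [n for n in c_am if n in shared]
                )
                out.seq_pm += inversion_number(
                    [n for n in p_pm if n in shared], [n for n in c_pm if n in shared]
                )
        prev = cur
        prev_span = cyc.cycle.span_index
    return out


def hypothesis_table(
    dataset: SpikeDataset,
    delta_grid: Sequence[int],
    K: int,
    window: int = 200,
    offset_step: int = 40,
    clock_from: str = "pyramidal",
    apply_burst_filter: bool = True,
    burst_window: int | None = None,
    phase2_scale: float = 1_000_000.0,
    report_scale: float = 1.0,
) -> pd.DataFrame:
    """Full mirror-vs-repetition analysis over a grid of clock periods.

    For each candidate δ: the quiet windows are located on the burst-filtered
    pyramidal subset (``clock_from='pyramidal'``; fall back to all neurons if
    no pyramidal cells are classified), brain cycles are segmented, and all
    error and inertia measures are computed on the full (burst-filtered)
    dataset.  One row per δ, mirroring the published table layout.
    """
    if clock_from not in ("pyramidal", "all"):
        raise ValueError("clock_from must be 'pyramidal' or 'all'")
    ds = dataset
    if apply_burst_filter:
        cfg = BurstFilterConfig(
            window=burst_window
            if burst_window is not None
            else max(1, int(round(0.006 * dataset.sample_rate)))
        )
        ds = burst_filter(dataset, cfg)
    clock_ds = ds
    if clock_from == "pyramidal":
        pyr = ds.select(cell_class="pyramidal")
        if len(pyr) > 0:
            clock_ds = pyr
    tick_ms = 1000.0 / dataset.sample_rate
    rows = []
    for d in sorted(int(x) for x in delta_grid):
        cfg = ClockScanConfig(delta=d, K=K, window=window, offset_step=offset_step)
        scan = quiet_scan(clock_ds.spiket, cfg)
        cycles = segment_cycles(scan)
        assigned = assign_spikes(ds, cycles)
        p2 = phase2_errors(assigned, scale=phase2_scale)
        p3 = phase3_errors(assigned, report_scale=report_scale)
        inertia = inertia_measures(assigned)
        rows.append(
            {
                "delta": d,
                "delta_ms": d * tick_ms,
                "quiet_power": scan.quiet_power,
                "nspikes_clock": scan.nspikes,
                "null_expectation": null_expectation(
                    scan.nspikes, window * tick_ms, d * tick_ms
                ),
                "change_of_neurons": inertia.neuron_change,
                "seq_change_am": inertia.seq_am,
                "seq_change_pm": inertia.seq_pm,
                "e_down_unweighted": p3.e_down_unweighted / report_scale,
                "e_up_unweighted": p3.e_up_unweighted / report_scale,
                "e_down_weighted": p3.e_down_weighted / report_scale,
                "e_up_weighted": p3.e_up_weighted / report_scale,
                "e_down_ext": p2.e_down_ext,
                "e_up_ext": p2.e_up_ext,
                "e_down_mid": p2.e_down_mid,
                "e_up_mid": p2.e_up_mid,
                "e_down_ext_scaled": p2.scaled_e_down_ext,
                "e_up_ext_scaled": p2.scaled_e_up_ext,
                "e_down_mid_scaled": p2.scaled_e_down_mid,
                "e_up_mid_scaled": p2.scaled_e_up_mid,
            }
        )
    return pd.DataFrame(rows)
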