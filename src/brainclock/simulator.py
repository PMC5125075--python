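"""Synthetic clocked-burst spike-train generator with known ground truth.

The generator embodies the data-generating picture under test: pyramidal
cells emit bursts under a global clock of period δ; each formal cycle
contains a silent quiet window, and the remaining *active period* between
consecutive quiet windows splits into an AM half and a PM half.  Every
neuron active in a cycle fires one burst per half; the PM firing order
either mirrors the AM order (``mode='mirror'``, a backward pass), repeats it
(``'repetition'``, a second forward pass), or is re-drawn at random
(``'shuffled'``, no directional structure).  Ground truth — the clock
period, the quiet-window offset, the per-cycle firing orders and a
noise/signal label per spike — is returned alongside the dataset.

Construction details that make the generator exactly testable:

* Burst spikes are placed symmetrically around an event *center* with an
  even total extent, so a neuron's first/last-spike midpoint equals its
  scheduled center; in noiseless runs the recovered AM/PM orders therefore
  match the scheduled orders exactly.
* Consecutive intra-burst gaps are 1–3 ms, so every burst spike has a
  same-neuron companion within 6 ms.
* Background noise spikes are singletons by rejection sampling (farther than
  6 ms from any same-neuron spike), so the 6 ms burst filter removes exactly
  the noise and keeps exactly the burst spikes.

Defaults emulate the structure of a prefrontal-cortex spike-sorted session:
~100 neurons at 20 kHz, clock period 3068 ticks (153.4 ms), a 15 ms quiet
window (within the 10–20 ms range reported for cortical quiet periods).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spike_io import NeuronInfo, SpikeDataset

__all__ = ["SimConfig", "SimTruth", "simulate", "poisson_noise_dataset",
           "make_fixture", "fixture_names"]

_GAP_HALF_MIN = 10  # intra-burst gaps are 2*uniform(10..30) ticks = 1-3 ms
_GAP_HALF_MAX = 30
_ISOLATION = 120  # ticks a noise spike must keep from any same-neuron spike


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the clocked-burst generator (times in ticks).

    ``quiet_offset`` places the quiet window inside each formal cycle;
    ``participation_prob`` is the chance a neuron is active in a given
    cycle; ``jitter_sd`` is Gaussian jitter on burst centers; ``noise_rate``
    is the singleton background rate per neuron per second.
    """

    n_neurons: int = 100
    delta: int = 3068
    n_cycles: int = 500
    quiet_width: int = 300
    quiet_offset: int = 400
    mode: str = "mirror"
    participation_prob: float = 0.3
    jitter_sd: float = 20.0
    burst_size_range: tuple[int, int] = (2, 4)
    noise_rate: float = 0.5
    seed: int = 0
    sample_rate: float = 20000.0

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if self.delta <= 0 or self.n_cycles < 2:
            raise ValueError("delta must be positive and n_cycles >= 2")
        if not 0 < self.quiet_width < self.delta:
            raise ValueError("quiet_width must satisfy 0 < quiet_width < delta")
        if not 0 <= self.quiet_offset <= self.delta - self.quiet_width:
            raise ValueError("quiet window must fit inside a cycle")
        if self.mode not in ("mirror", "repetition", "shuffled"):
            raise ValueError("mode must be 'mirror', 'repetition' or 'shuffled'")
        if not 0 < self.participation_prob <= 1:
            raise ValueError("participation_prob must be in (0, 1]")
        if self.jitter_sd < 0 or self.noise_rate < 0:
            raise ValueError("jitter_sd and noise_rate must be non-negative")
        lo, hi = self.burst_size_range
        if not 1 <= lo <= hi:
            raise ValueError("burst_size_range must satisfy 1 <= min <= max")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def half_length(self) -> float:
        """Length of one AM or PM half of the active period, in ticks."""
        return (self.delta - self.quiet_width) / 2.0

    @property
    def max_burst_extent(self) -> int:
        return (self.burst_size_range[1] - 1) * 2 * _GAP_HALF_MAX

    @property
    def usable_length(self) -> float:
        """Room available for scheduling burst centers within one half."""
        return self.half_length - self.max_burst_extent - 2


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    config: SimConfig
    delta: int
    quiet_offset: int
    cycle_am_orders: list[list[int]]
    cycle_pm_orders: list[list[int]]
    is_noise: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def _emit_bursts(rng: np.random.Generator, centers: np.ndarray,
                 lo_lim: float, hi_lim: float, bmin: int, bmax: int,
                 round_up: bool):
    """Emit one burst per center, clipped into [lo_lim, hi_lim).

    Returns (spike_times, event_ids_index, midpoints): integer spike times,
    the index of the emitting event for each spike, and per-event first/last
    midpoints (equal to the clipped center up to rounding).  ``round_up``
    selects ceil rounding of the first spike (needed when lo_lim may be
    fractional, as for the PM half) versus floor (AM half, fractional hi_lim).
    """
    n = centers.size
    sizes = rng.integers(bmin, bmax + 1, n)
    width = max(bmax - 1, 1)
    gaps = 2 * rng.integers(_GAP_HALF_MIN, _GAP_HALF_MAX + 1, (n, width))
    active_gap = np.arange(width)[None, :] < (sizes - 1)[:, None]
    gaps = gaps * active_gap
    extents = gaps.sum(axis=1)
    c = np.clip(centers, lo_lim + extents / 2.0, hi_lim - 1 - extents / 2.0)
    rounder = np.ceil if round_up else np.floor
    firsts = rounder(c - extents / 2.0).astype(np.int64)
    times = []
    event_idx = []
    mids = np.empty(n)
    for i in range(n):
        offs = np.concatenate(([0], np.cumsum(gaps[i, : sizes[i] - 1])))
        ts = firsts[i] + offs
        times.append(ts)
        event_idx.append(np.full(ts.size, i))
        mids[i] = (ts[0] + ts[-1]) / 2.0
    if times:
        return np.concatenate(times), np.concatenate(event_idx), mids
    return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64), mids)


def simulate(config: SimConfig) -> tuple[SpikeDataset, SimTruth]:
    """Generate a clocked-burst dataset and its ground truth.

    Each active period (between consecutive quiet windows) splits into AM
    and PM halves; active neurons receive evenly spaced burst centers in a
    canonical (ascending-ID) order in the AM, and in a mode-dependent order
    in the PM, plus Gaussian jitter.  No signal spike ever falls inside a
    quiet window; noise spikes fall anywhere, as isolated singletons.
    """
    cfg = config
    if cfg.usable_length < cfg.n_neurons:
        raise ValueError(
            "infeasible geometry: the AM half is too short to schedule "
            f"{cfg.n_neurons} neurons (usable length {cfg.usable_length:.0f} ticks)"
        )
    rng = np.random.default_rng(cfg.seed)
    bmin, bmax = cfg.burst_size_range
    ext_max = cfg.max_burst_extent
    half = cfg.half_length
    usable = cfg.usable_length
    all_times: list[np.ndarray] = []
    all_ids: list[np.ndarray] = []
    am_orders: list[list[int]] = []
    pm_orders: list[list[int]] = []
    neuron_ids = np.arange(1, cfg.n_neurons + 1)
    for c in range(cfg.n_cycles - 1):
        act_start = c * cfg.delta + cfg.quiet_offset + cfg.quiet_width
        t0 = act_start + half
        act_end = act_start + 2 * half  # == (c+1)*delta + quiet_offset
        active = neuron_ids[rng.random(cfg.n_neurons) < cfg.participation_prob]
        n_act = active.size
        if n_act == 0:
            am_orders.append([])
            pm_orders.append([])
            continue
        slots = (np.arange(n_act) + 1) / (n_act + 1) * usable + ext_max / 2.0
        am_centers = act_start + slots + rng.normal(0.0, cfg.jitter_sd, n_act)
        if cfg.mode == "mirror":
            pm_rank = n_act - 1 - np.arange(n_act)
        elif cfg.mode == "repetition":
            pm_rank = np.arange(n_act)
        else:
            pm_rank = rng.permutation(n_act)
        # pm_rank[i] is the slot index of active neuron i within the PM half
        pm_centers = t0 + (pm_rank + 1) / (n_act + 1) * usable + ext_max / 2.0
        pm_centers = pm_centers + rng.normal(0.0, cfg.jitter_sd, n_act)
        am_t, am_ev, am_mid = _emit_bursts(rng, am_centers, act_start, t0,
                                           bmin, bmax, round_up=False)
        pm_t, pm_ev, pm_mid = _emit_bursts(rng, pm_centers, t0, act_end,
                                           bmin, bmax, round_up=True)
        all_times.append(am_t)
        all_ids.append(active[am_ev])
        all_times.append(pm_t)
        all_ids.append(active[pm_ev])
        am_orders.append([int(x) for x in active[np.argsort(am_mid, kind="stable")]])
        pm_orders.append([int(x) for x in active[np.argsort(pm_mid, kind="stable")]])
    sig_times = np.concatenate(all_times) if all_times else np.zeros(0, dtype=np.int64)
    sig_ids = np.concatenate(all_ids) if all_ids else np.zeros(0, dtype=np.int64)

    noise_times, noise_ids = _draw_noise(rng, cfg, sig_times, sig_ids)
    times = np.concatenate([sig_times, noise_times])
    ids = np.concatenate([sig_ids, noise_ids])
    is_noise = np.concatenate(
        [np.zeros(sig_times.size, dtype=bool), np.ones(noise_times.size, dtype=bool)]
    )
    order = np.argsort(times, kind="stable")
    neurons = {
        int(n): NeuronInfo(id=int(n), cell_class="pyramidal", region="pfc")
        for n in neuron_ids
    }
    dataset = SpikeDataset(times[order], ids[order], cfg.sample_rate, neurons)
    truth = SimTruth(
        config=cfg,
        delta=cfg.delta,
        quiet_offset=cfg.quiet_offset,
        cycle_am_orders=am_orders,
        cycle_pm_orders=pm_orders,
        is_noise=is_noise[order],
    )
    return dataset, truth


def _draw_noise(rng: np.random.Generator, cfg: SimConfig,
                sig_times: np.ndarray, sig_ids: np.ndarray):
    """Isolated singleton noise spikes, uniform over the whole record.

    Candidates closer than the isolation distance (6 ms) to any same-neuron
    spike — signal or already-kept noise — are rejected, so every kept noise
    spike has no companion and every burst spike keeps its companions.
    """
    if cfg.noise_rate == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    duration_ticks = cfg.n_cycles * cfg.delta
    duration_s = duration_ticks / cfg.sample_rate
    kept_t: list[int] = []
    kept_i: list[int] = []
    for nid in range(1, cfg.n_neurons + 1):
        n_noise = rng.poisson(cfg.noise_rate * duration_s)
        if n_noise == 0:
            continue
        cand = np.sort(rng.integers(0, duration_ticks, n_noise))
        own = np.sort(sig_times[sig_ids == nid])
        last_kept = None
        for t in cand.tolist():
            if own.size:
                j = np.searchsorted(own, t)
                near = min(
                    abs(t - own[j - 1]) if j > 0 else np.inf,
                    abs(own[j] - t) if j < own.size else np.inf,
                )
                if near <= _ISOLATION:
                    continue
            if last_kept is not None and t - last_kept <= _ISOLATION:
                continue
            kept_t.append(t)
            kept_i.append(nid)
            last_kept = t
    return np.asarray(kept_t, dtype=np.int64), np.asarray(kept_i, dtype=np.int64)


def poisson_noise_dataset(
    n_neurons: int = 20,
    rate: float = 5.0,
    duration_ticks: int = 400_000,
    seed: int = 0,
    sample_rate: float = 20000.0,
) -> SpikeDataset:
    """Homogeneous-Poisson spikes with no clock structure (negative control)."""
    rng = np.random.default_rng(seed)
    duration_s = duration_ticks / sample_rate
    times: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    for nid in range(1, n_neurons + 1):
        n = rng.poisson(rate * duration_s)
        times.append(rng.integers(0, duration_ticks, n))
        ids.append(np.full(n, nid))
    t = np.concatenate(times)
    i = np.concatenate(ids)
    neurons = {
        nid: NeuronInfo(id=nid, cell_class="pyramidal", region="pfc")
        for nid in range(1, n_neurons + 1)
    }
    return SpikeDataset.from_events(t, i, sample_rate=sample_rate, neurons=neurons)


_FIXTURE_CONFIGS: dict[str, SimConfig] = {
    "mirror-small": SimConfig(
        n_neurons=12, delta=1000, n_cycles=61, quiet_width=300, quiet_offset=150,
        mode="mirror", participation_prob=0.6, jitter_sd=10.0,
        burst_size_range=(2, 3), noise_rate=0.2, seed=101,
    ),
    "repetition-small": SimConfig(
        n_neurons=12, delta=1000, n_cycles=61, quiet_width=300, quiet_offset=150,
        mode="repetition", participation_prob=0.6, jitter_sd=10.0,
        burst_size_range=(2, 3), noise_rate=0.2, seed=102,
    ),
    "shuffled-small": SimConfig(
        n_neurons=12, delta=1000, n_cycles=61, quiet_width=300, quiet_offset=150,
        mode="shuffled", participation_prob=0.6, jitter_sd=10.0,
        burst_size_range=(2, 3), noise_rate=0.2, seed=103,
    ),
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURE_CONFIGS) + ["noise-only"]


def make_fixture(name: str) -> SpikeDataset:
    """Deterministic tiny datasets (< 10⁴ spikes) for tests and docs."""
    if name == "noise-only":
        return poisson_noise_dataset(seed=104)
    if name not in _FIXTURE_CONFIGS:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    dataset, _ = simulate(_FIXTURE_CONFIGS[name])
    return dataset


def fixture_config(name: str) -> SimConfig:
    """The SimConfig behind a named fixture (KeyError for 'noise-only')."""
    return _FIXTURE_CONFIGS[name]
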