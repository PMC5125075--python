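"""Mirror vs. repetition error measures and inertia statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainclock import (
    AssignmentResult,
    BrainCycle,
    CycleSpikes,
    SimConfig,
    SpikeDataset,
    hypothesis_table,
    inertia_measures,
    inversion_number,
    phase2_errors,
    phase3_errors,
    simulate,
)


def brute_force_inversions(perm_a, perm_b):
    """O(n^2) discordant-pair count, the independent oracle."""
    pos_a = {x: i for i, x in enumerate(perm_a)}
    pos_b = {x: i for i, x in enumerate(perm_b)}
    items = list(perm_a)
    count = 0
    for x, y in itertools.combinations(items, 2):
        if (pos_a[x] - pos_a[y]) * (pos_b[x] - pos_b[y]) < 0:
            count += 1
    return count


def _cycle(t_minus, t0, t_plus, am, pm, span_index=0):
    """Build a CycleSpikes from {neuron: [times]} dicts."""
    return CycleSpikes(
        cycle=BrainCycle(t_minus=t_minus, t0=t0, t_plus=t_plus, span_index=span_index),
        am={k: np.asarray(v) for k, v in am.items()},
        pm={k: np.asarray(v) for k, v in pm.items()},
    )


def _assignment(cycles):
    n = sum(
        sum(v.size for v in c.am.values()) + sum(v.size for v in c.pm.values())
        for c in cycles
    )
    return AssignmentResult(cycles=cycles, n_assigned=n, n_dropped=0)


class TestInversionNumber:
    def test_identical_orderings(self):
        assert inversion_number(["N1", "N2", "N3", "N4", "N5"],
                                ["N1", "N2", "N3", "N4", "N5"]) == 0

    def test_fully_reversed_five(self):
        assert inversion_number(["N1", "N2", "N3", "N4", "N5"],
                                ["N5", "N4", "N3", "N2", "N1"]) == 10

    def test_single_adjacent_swap(self):
        assert inversion_number([1, 2, 3], [2, 1, 3]) == 1

    def test_id_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            inversion_number([1, 2], [1, 3])
        with pytest.raises(ValueError):
            inversion_number([1, 1, 2], [1, 2, 1])

    def test_exhaustive_against_oracle_small_n(self):
        for n in range(1, 5):
            items = list(range(n))
            for a in itertools.permutations(items):
                for b in itertools.permutations(items):
                    assert inversion_number(a, b) == brute_force_inversions(a, b)

    @given(st.integers(2, 12), st.randoms(use_true_random=False))
    @settings(max_examples=60, deadline=None)
    def test_random_against_oracle(self, n, rnd):
        a = list(range(n))
        b = list(range(n))
        rnd.shuffle(a)
        rnd.shuffle(b)
        assert inversion_number(a, b) == brute_force_inversions(a, b)

    @given(st.integers(2, 10), st.randoms(use_true_random=False))
    @settings(max_examples=60, deadline=None)
    def test_mirror_repetition_conservation(self, n, rnd):
        """inv(a,b) + inv(a, reversed b) = n(n-1)/2 for distinct ranks."""
        a = list(range(n))
        b = list(range(n))
        rnd.shuffle(a)
        rnd.shuffle(b)
        assert inversion_number(a, b) + inversion_number(a, b[::-1]) == n * (n - 1) // 2


class TestPhase2:
    def test_perfect_mirror_has_zero_mirror_error(self):
        # AM extremes at t0-30, t0-10; PM at t0+10, t0+30: exact reflection
        # through t0, but asymmetric within the halves so repetition fails
        c = _cycle(50, 100, 150, am={1: [70, 90]}, pm={1: [110, 130]})
        errs = phase2_errors(_assignment([c]))
        assert errs.e_down_ext == 0
        assert errs.e_down_mid == 0
        assert errs.e_up_ext > 0

    def test_perfect_repetition_hand_worked(self):
        # half-length 50; AM extremes at t-+5 and t-+20 repeat at t0+5, t0+20.
        # Hand evaluation: both repetition terms vanish; each mirror term is
        # |(50-20)-5| = |(50-5)-20| = 25, times N=4 spikes.
        c = _cycle(0, 50, 100, am={1: [5, 20]}, pm={1: [55, 70]})
        errs = phase2_errors(_assignment([c]))
        assert errs.e_up_ext == 0
        assert errs.e_down_ext == 2 * 4 * 25
        assert errs.e_up_mid == 0
        assert errs.e_down_mid == 4 * 25

    def test_single_spike_halves_still_defined(self):
        c = _cycle(0, 50, 100, am={1: [30]}, pm={1: [60]})
        errs = phase2_errors(_assignment([c]))
        # N = 2; degenerate intervals collapse extremes onto the single spike
        assert errs.e_down_ext == 2 * 2 * abs((50 - 30) - (60 - 50))
        assert errs.e_down_mid == 2 * abs((50 - 30) - (60 - 50))

    def test_neuron_must_fire_in_both_halves(self):
        c = _cycle(0, 50, 100, am={1: [30]}, pm={2: [60]})
        errs = phase2_errors(_assignment([c]))
        assert errs.e_down_ext == errs.e_up_ext == 0

    def test_scaled_values_are_rounded_integers(self):
        c = _cycle(0, 50, 100, am={1: [5, 20]}, pm={1: [55, 70]})
        errs = phase2_errors(_assignment([c]), scale=100.0)
        assert errs.scaled_e_down_ext == round(errs.e_down_ext / 100.0)
        assert isinstance(errs.scaled_e_down_ext, int)

    def test_additive_over_cycles(self):
        cycles = [
            _cycle(0, 50, 100, am={1: [5, 20]}, pm={1: [55, 70]}),
            _cycle(100, 150, 200, am={1: [110], 2: [120, 130]},
                   pm={1: [160], 2: [155, 190]}),
        ]
        both = phase2_errors(_assignment(cycles))
        one = phase2_errors(_assignment(cycles[:1]))
        two = phase2_errors(_assignment(cycles[1:]))
        assert both.e_down_ext == one.e_down_ext + two.e_down_ext
        assert both.e_up_mid == one.e_up_mid + two.e_up_mid


class TestPhase3:
    def test_case_a_repetition(self):
        """Five neurons firing N1..N5 in both halves: e_up = 0, e_down = 10."""
        am = {i: [i * 5] for i in range(1, 6)}
        pm = {i: [50 + i * 5] for i in range(1, 6)}
        stats = phase3_errors(_assignment([_cycle(0, 50, 100, am, pm)]))
        assert stats.e_up_unweighted == 0
        assert stats.e_down_unweighted == 10

    def test_case_b_mirror(self):
        """N1..N5 in the AM, N5..N1 in the PM: e_down = 0, e_up = 10."""
        am = {i: [i * 5] for i in range(1, 6)}
        pm = {i: [50 + (6 - i) * 5] for i in range(1, 6)}
        stats = phase3_errors(_assignment([_cycle(0, 50, 100, am, pm)]))
        assert stats.e_down_unweighted == 0
        assert stats.e_up_unweighted == 10

    def test_single_active_neuron_skipped(self):
        c = _cycle(0, 50, 100, am={1: [10], 2: [20]}, pm={1: [60]})
        stats = phase3_errors(_assignment([c]))
        assert stats.n_cycles_used == 0
        assert stats.e_down_unweighted == stats.e_up_unweighted == 0

    def test_weighting_by_am_pm_spike_product(self):
        am = {1: [5, 6], 2: [20]}           # 3 AM spikes over active neurons
        pm = {1: [80], 2: [60, 61, 62]}     # 4 PM spikes
        stats = phase3_errors(_assignment([_cycle(0, 50, 100, am, pm)]))
        # AM order (1,2); PM order (2,1): e_up = 1, e_down = 0
        assert stats.e_up_unweighted == 1
        assert stats.e_up_weighted == 1 * (3 * 4)
        assert stats.e_down_weighted == 0

    def test_tie_break_by_neuron_id(self):
        am = {1: [10], 2: [10]}  # identical AM means -> order (1, 2)
        pm = {1: [90], 2: [60]}
        stats = phase3_errors(_assignment([_cycle(0, 50, 100, am, pm)]))
        assert stats.e_up_unweighted == 1


class TestInertia:
    def test_perfect_inertia(self):
        am = {1: [10], 2: [20], 3: [30]}
        pm = {1: [60], 2: [70], 3: [80]}
        cycles = [
            _cycle(0, 50, 100, am, pm),
            _cycle(100, 150, 200, {k: [v[0] + 100] for k, v in am.items()},
                   {k: [v[0] + 100] for k, v in pm.items()}),
        ]
        m = inertia_measures(_assignment(cycles))
        assert (m.neuron_change, m.seq_am, m.seq_pm) == (0, 0, 0)

    def test_symmetric_difference_of_active_sets(self):
        c1 = _cycle(0, 50, 100, {1: [10], 2: [20], 3: [30]},
                    {1: [60], 2: [70], 3: [80]})
        c2 = _cycle(100, 150, 200, {2: [110], 3: [120], 4: [130]},
                    {2: [160], 3: [170], 4: [180]})
        m = inertia_measures(_assignment([c1, c2]))
        assert m.neuron_change == 2  # {1} dropped, {4} added

    def test_shared_pair_order_swap(self):
        c1 = _cycle(0, 50, 100, {2: [10], 3: [20]}, {2: [60], 3: [70]})
        c2 = _cycle(100, 150, 200, {2: [130], 3: [120]}, {2: [160], 3: [170]})
        m = inertia_measures(_assignment([c1, c2]))
        assert m.seq_am == 1
        assert m.seq_pm == 0

    def test_pairs_never_straddle_span_boundaries(self):
        c1 = _cycle(0, 50, 100, {1: [10], 2: [20]}, {1: [60], 2: [70]}, span_index=0)
        c2 = _cycle(200, 250, 300, {3: [210], 4: [220]}, {3: [260], 4: [270]},
                    span_index=1)
        m = inertia_measures(_assignment([c1, c2]))
        assert (m.neuron_change, m.seq_am, m.seq_pm) == (0, 0, 0)


class TestOnSimulatedData:
    def test_mirror_mode_prefers_mirror(self):
        cfg = SimConfig(n_neurons=20, delta=2000, n_cycles=120, quiet_width=300,
                        quiet_offset=250, mode="mirror", participation_prob=0.5,
                        jitter_sd=15.0, burst_size_range=(2, 3), noise_rate=0.3,
                        seed=21)
        ds, _ = simulate(cfg)
        tab = hypothesis_table(ds, [2000], K=20)
        row = tab.iloc[0]
        assert row["e_down_unweighted"] < row["e_up_unweighted"]
        assert row["e_down_ext"] < row["e_up_ext"]

    def test_repetition_mode_reverses_preference(self):
        cfg = SimConfig(n_neurons=20, delta=2000, n_cycles=120, quiet_width=300,
                        quiet_offset=250, mode="repetition", participation_prob=0.5,
                        jitter_sd=15.0, burst_size_range=(2, 3), noise_rate=0.3,
                        seed=22)
        ds, _ = simulate(cfg)
        tab = hypothesis_table(ds, [2000], K=20)
        row = tab.iloc[0]
        assert row["e_up_unweighted"] < row["e_down_unweighted"]
        assert row["e_up_ext"] < row["e_down_ext"]

    def test_hypothesis_table_row_matches_individual_calls(self, small_sim_with_truth):
        from brainclock import (ClockScanConfig, assign_spikes, burst_filter,
                                quiet_scan, segment_cycles)

        ds, truth = small_sim_with_truth
        tab = hypothesis_table(ds, [truth.delta], K=10)
        f = burst_filter(ds)
        scan = quiet_scan(f.spiket, ClockScanConfig(delta=truth.delta, K=10))
        asg = assign_spikes(f, segment_cycles(scan))
        p3 = phase3_errors(asg)
        row = tab.iloc[0]
        assert row["e_down_unweighted"] == p3.e_down_unweighted
        assert row["e_up_unweighted"] == p3.e_up_unweighted
        assert row["quiet_power"] == scan.quiet_power
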