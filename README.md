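# brainclock

Clock-cycle detection and forward/backward propagation tests for
spike-sorted cortical recordings.

## The problem

Learning models of the backpropagation family predict two things about
cortical dynamics that purely asynchronous spiking models do not: a regular
global clock cycle, and an alternation within each cycle of a forward pass
of computation with a backward pass of error/derivative signals.  In
spike-sorted multielectrode data these predictions become concrete and
testable: there should be a short recurring *quiet period* at a fixed phase
of every clock cycle, and the sequence in which neurons fire in the second
half of a cycle should look more like a time-reversed *mirror* of the
first-half sequence than like a repetition of it.

`brainclock` implements the full nonparametric analysis chain for these
questions, for anyone working with spike-sorted event data (`spiket` time
stamps in integer sample ticks plus `spikeind` neuron IDs, e.g. the legacy
`.res`/`.clu` dialect at 20 kHz):

1. **Burst filtering** — keep only spikes with a same-neuron companion
   within 6 ms, since pyramidal-cell output is bursty and clock structure is
   stronger in bursts.
2. **Quiet-time clock scan** — for a candidate clock period δ and span size
   K, fold each span of K formal cycles to spike phase mod δ and find the
   10 ms window with the fewest spikes; *quiet power* (the sum of the
   minima over spans) is compared with the flat-phase null
   `nspikes · window/δ`.  A δ grid is scanned; the minimum marks the clock.
3. **Brain-cycle segmentation** — cycles run from one quiet-window midpoint
   to the next (K−1 brain cycles per span), each split at its midpoint t₀
   into AM and PM halves.
4. **Mirror vs. repetition tests** — per neuron and cycle, interval-based
   errors e↓ (mirror) and e↑ (repetition) built from the first/last spike
   times in each half; and per cycle, inversion-number errors comparing the
   AM firing order with the PM order (e↑) and with the reversed PM order
   (e↓), optionally weighted by spike counts.  For distinct ranks the two
   inversion errors are conserved, e↓ + e↑ = n(n−1)/2, so the information
   lies entirely in the split.  Three *inertia* measures (active-set
   turnover, AM/PM order changes between consecutive cycles) sharpen the
   clock estimate.
5. **A clocked-burst simulator** — generates data with a known clock, quiet
   window, burst structure, and AM/PM mode (`mirror`, `repetition`,
   `shuffled`), returning ground truth for every validation in the test
   suite.

## Worked example

```python
import brainclock as bc

# generate a mirror-mode session: 100 neurons, 153.4 ms clock, 500 cycles
ds, truth = bc.simulate(bc.SimConfig(mode="mirror", seed=1))
print(f"{len(ds)} spikes, {int(truth.is_noise.sum())} noise singletons")

filtered = bc.burst_filter(ds)
print(f"burst filter kept {len(filtered)} spikes")

table = bc.scan_grid(filtered.spiket, range(3060, 3077, 2), K=100)
print(table[["delta_ms", "quiet_power", "null_expectation"]].round(1).to_string(index=False))
print("best delta:", bc.best_delta(table), "ticks")

result = bc.hypothesis_table(ds, [3068], K=100).iloc[0]
print(f"e_down={result.e_down_unweighted:.0f}  e_up={result.e_up_unweighted:.0f}")
```

prints

```
93390 spikes, 3490 noise singletons
burst filter kept 89900 spikes
 delta_ms  quiet_power  null_expectation
    153.0         2663            5872.6
    153.1         1112            4727.6
    153.2          332            4727.2
    153.3           14            4728.2
    153.4            0            4726.6
    153.5            7            4726.9
    153.6          252            4726.7
    153.7         1110            4727.1
    153.8         2195            4725.6
best delta: 3068 ticks
e_down=1988  e_up=177015
```

Reading the output: the burst filter removed exactly the isolated noise
spikes.  Quiet power collapses to 0 at the true period of 3068 ticks
(153.4 ms at 20 kHz) and recovers toward the null expectation (~4727
spikes in a random 10 ms window) as the candidate period moves away — a
0.05 ms/cycle misestimate desynchronizes the phase fold by 50 ms over a
1000-cycle span, flattening the histogram.  At the recovered period, the
mirror error e↓ is two orders of magnitude below the repetition error e↑:
the PM sequences mirror the AM sequences, as this dataset was built to do.

The same pipeline is available from the shell:

```bash
brainclock simulate --mode mirror --seed 1 --out session.tsv
brainclock burst-filter --spikes session.tsv --out filtered.tsv
brainclock scan-clock --spikes filtered.tsv --delta-ms-min 153 --delta-ms-max 153.8 \
    --delta-ms-step 0.1 --k 100 --out scan.csv
brainclock test-phase3 --spikes session.tsv --delta-ms-min 153 --delta-ms-max 153.8 \
    --delta-ms-step 0.1 --k 100 --clock-from all --out phase3.csv
```

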