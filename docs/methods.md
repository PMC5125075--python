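# Methods

## Model and assumptions

The package operates on spike-sorted event data: an array `spiket` of event
times in integer sample ticks (20 000 ticks/s by default, so one tick is
0.05 ms) and a parallel array `spikeind` of neuron IDs, with an optional
classification table (pyramidal / interneuron / other; region; shank).  The
working hypothesis is that cortical pyramidal output is paced by a fixed
global clock of period δ: each formal clock cycle contains a short quiet
window during which pyramidal bursting is suppressed, and the active period
between consecutive quiet windows divides into an AM half (forward pass) and
a PM half, whose firing order either mirrors the AM order (a backward pass)
or repeats it (a second forward pass).  All analyses are nonparametric
counts and order statistics; no spectral estimation is used, because
activity outside the quiet window is experience-driven and oscillatory in
ways unrelated to the hardwired clock.

All internal arithmetic is on integer ticks (brain-cycle boundaries on exact
half-ticks, computed in doubled-tick integers); milliseconds appear only at
CLI/reporting boundaries, converted by rounding to the nearest tick.

## Burst filtering

A spike survives iff some other spike of the same neuron lies within the
companion window (default 6 ms = 120 ticks), judged inclusively
(|Δt| ≤ window) on the input set in a single pass.  Inclusive-vs-exclusive
at the exact boundary is not decidable from first principles; inclusive is
fixed and configurable so results are bit-stable.  Note that companionship
is symmetric, so iterating the filter to a fixed point would change nothing;
the single-pass semantics is stated for clarity, not as an approximation.

## Quiet-time clock scan

For candidate period δ (ticks) and span size K, the record is tiled from the
first spike time into spans of K·δ ticks; leftover time beyond the last
whole span is unused, and a record shorter than one span is treated as a
single whole-record span.  Within a span anchored at s, each spike folds to
phase (t − s) mod δ.  Candidate quiet windows of width w (default 200 ticks
= 10 ms) start at offsets 0, 2 ms, 4 ms, … with o + w ≤ δ — windows never
wrap past the cycle end, as wrap-around has no natural anchor when the span
phase origin is arbitrary.  The span's quiet window is the candidate with
the minimal spike count (ties → smallest offset); *quiet power* is the sum
of these minima over spans, and the per-span diagnostics (offset, quiet
count, total count — the `wherebin` record) are retained for drift checks.

The null reference is the flat-phase expectation `nspikes · w/δ` (in
matching units).  The scanner's resolution bound is the drift identity: a
per-cycle period error ε accumulates to ε·K of phase desynchronization
across a span (0.05 ms × 1000 = 50 ms), which is what flattens the fold at
wrong δ and makes the quiet-power minimum sharp.  Phases are computed from
exact tick times rather than binned histograms, avoiding an arbitrary bin
width.  A variant (`quiet_scan_power`) applies the identical algorithm to a
non-negative per-tick power series, with counts replaced by windowed sums.

## Brain cycles and AM/PM assignment

Quiet-window *midpoints* (offset + w/2, possibly a half-tick) within the
span's formal cycles define the brain-cycle boundaries: K formal cycles
yield K−1 brain cycles of exact length δ, never straddling span seams.
Each cycle [t−, t+) splits at t0 = (t− + t+)/2 into AM = [t−, t0) and
PM = [t0, t+); a spike exactly at t0 belongs to PM (the sources are silent
on this; half-open-with-t0-in-PM is fixed for determinism).  The
alternative reading of a brain cycle as quiet-middle-to-quiet-*start* was
rejected because only middle-to-middle yields length-δ cycles consistent
with K−1 cycles per span.  Spikes outside every cycle (span leftovers,
pre-first-midpoint) are dropped and tallied, so assignment conserves the
spike count.

Clock location is estimated from the burst-filtered pyramidal subset when
classifications are available, and spike assignment then uses the full
burst-filtered dataset — the pyramidal population carries the clock, but
the direction tests should see every recorded neuron.

## Error measures

*Interval-based* (per participating neuron — fired in both halves — per
cycle, N its AM+PM spike count):

    e↓ = N·(|(t0 − t_AM⁺) − (t_PM⁻ − t0)| + |(t0 − t_AM⁻) − (t_PM⁺ − t0)|)
    e↑ = N·(|(t0 − t_AM⁺) − (t⁺ − t_PM⁺)| + |(t0 − t_AM⁻) − (t⁺ − t_PM⁻)|)

Midpoint variants substitute the interval midpoints (t_AM⁻ + t_AM⁺)/2 and
(t_PM⁻ + t_PM⁺)/2, with one absolute term each; their exact form is a
design choice documented here because only "essentially the same" guidance
exists.  Totals are summed over cycles; for table display they are divided
by 10⁶ and rounded (raw accumulators are also reported, and the CLI verdict
uses the raw values so small datasets do not round to a 0/0 tie).

*Sequence-based* (per cycle with ≥ 2 active neurons; cycles with fewer are
skipped): active neurons are ordered by AM and by PM mean firing time (ties
→ ascending neuron ID).  e↑ is the inversion number between the two
orderings; e↓ the inversion number between the AM ordering and the reversed
PM ordering.  The inversion number is computed by merge-sort counting in
O(n log n) and cross-checked in the tests against exhaustive pair counting.
Weighted versions multiply each cycle's inversion count by (total AM
spikes) × (total PM spikes) over active neurons.  The display scale of the
weighted columns is configurable (`report_scale`, default 1: raw values),
since no fixed factor is canonical.

*Inertia*: over consecutive cycle pairs within a span — active-set turnover
(symmetric difference size), and AM/PM order changes as inversion numbers
restricted to the shared active set (pairs sharing < 2 neurons contribute
none).  Restricting to the shared subset, rather than ranking within full
sets, is the chosen reading of "those neurons active in both cycles".

## The simulator

`simulate(SimConfig)` realizes the data-generating picture directly: cycles
of δ ticks, a silent quiet window of `quiet_width` at `quiet_offset` in each
cycle, and an active period between consecutive quiet windows split into AM
and PM halves.  Active neurons (Bernoulli `participation_prob` per cycle)
receive evenly spaced burst centers in ascending-ID order in the AM and in
a mode-dependent order in the PM (`mirror` reverses, `repetition` repeats,
`shuffled` permutes), plus Gaussian center jitter.  Bursts are 2–4 spikes
with intra-burst gaps of 1–3 ms, placed symmetrically about the scheduled
center with even total extent, so the first/last midpoint recovered by the
analysis equals the scheduled center exactly — noiseless runs reproduce the
scheduled orders with zero error.  Background noise spikes are uniform over
the record (quiet windows included) and rejection-sampled to stay > 6 ms
from every same-neuron spike, so the burst filter provably removes exactly
the noise.

Defaults are chosen to emulate a prefrontal-cortex spike-sorted session:
100 neurons at 20 kHz, δ = 3068 ticks (153.4 ms), 500 cycles (~77 s of
record), participation 0.3, 1 ms jitter, 0.5 noise spikes/neuron/s, and a
15 ms quiet window — inside the 10–20 ms range reported for cortical quiet
periods, and at least one offset-grid step wider than the 10 ms detection
window so a grid-aligned window always fits inside the true silent gap.
All simulator neurons are labelled pyramidal/pfc.  What the simulator does
*not* emulate: rate heterogeneity across neurons, behavioural modulation,
clock drift between spans, overlapping assemblies, or spike-sorting errors
— passing tests demonstrate correctness of the measures under the model's
own assumptions, not that real cortex satisfies them.

A caveat discovered during validation and worth knowing when using the
scanner: with very few active neurons the active period itself contains
silent gaps wider than the 10 ms detection window (e.g. the seam between
the AM and PM event groups), and the blind scan may lock onto such a gap
instead of the true quiet window.  With realistic neuron counts
(≥ ~20 active per cycle) the true quiet window is the unique silent
candidate.

## Problem sizes and determinism

The bundled fixtures are < 10⁴ spikes; validation simulations use 100–500
cycles (≈ 90 000 spikes at the defaults), which resolve the clock period
exactly on a 0.1 ms grid and separate the mirror/repetition error sums by
two orders of magnitude.  Every random quantity flows from a single
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
datasets and CSV outputs.

## Known limitations

- Quiet windows never wrap past the formal-cycle end; a genuinely wrapping
  quiet phase is detected one cycle later at a shifted offset.
- Spans are anchored at the first spike time; absolute quiet offsets are
  therefore only meaningful modulo δ relative to that anchor.
- `.fet` feature files and full feature-space burst sorting are out of
  scope; the companion-window rule is the only burst criterion.
- No statistical significance machinery is attached to the error measures;
  the conservation identity e↓ + e↑ = n(n−1)/2 makes the split
  interpretable, but formal inference is left to the user.
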