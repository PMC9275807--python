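# Methods

## Model

Four nuclei of the electromotor command chain (CN, DP, PCN, VPd) are
each reduced to a single Izhikevich unit; five kinetic receptor-binding
synapses wire them into the known topology (DP and PCN excite CN, CN
excites VPd through the corollary-discharge projection, VPd inhibits DP
and PCN). Every CN spike is identified with one electric organ
discharge, so the model's output is the sequence of CN inter-pulse
intervals (IPIs). All synapses share a single reversal potential
(E_syn = −80 mV), threshold 0 mV and transmitter concentration T = 1;
excitation versus inhibition is carried entirely by the sign of the
conductance, matching the fitted parameter table shipped in
`data/reference_rga.yaml`. Conductances and currents are in the
dimensionless current units of the Izhikevich equation; no conversion
to physical units is attempted.

Integration is explicit Euler on a single clock shared by the nucleus
and receptor equations, with dt = 0.1 ms by default — fine enough that
halving dt changes a one-second spike count by at most one (tested per
regime). The after-spike reset is applied after the update: if the
post-step voltage reaches the fixed 30 mV cutoff, the spike is recorded
at the step's end time, v ← c, u ← u + d. Release windows open on an
upward threshold crossing of the *pre-reset* voltage (every spike
crosses once), close `t_max` ms later, and restart if a new crossing
arrives while open. The bound-receptor fraction is clamped to [0, 1]
as a safety net; at the shipped rates and dt the Euler step stays well
inside the stability region (the fastest synapse has rate
αT + β ≈ 6.2/ms, and dt·6.2 < 1).

Each nucleus starts at its zero-input stable equilibrium (lower root of
the voltage nullcline with u = bv), so an unstimulated network is
silent. Every simulation begins with a seed-determined random pre-roll
(uniform on 1,000–2,000 ms, rounded to the grid) under baseline inputs,
so the resting rhythm's phase at stimulus onset is randomised; spike
times are reported relative to the protocol start.

## Re-derived configuration

The published material fixes the five synapse rows and the behavioural
magnitudes of the displays, but not the nucleus coefficients or the
input currents. The shipped values are therefore this package's own
reconstruction, tuned once against the published anchors (resting
rhythm ~120 ms, scallop minimum ~40 ms, acceleration plateau ~85 ms,
cessation pause ~500 ms, scallop minimum below the acceleration
minimum) and then frozen:

| nucleus | a | b | c | d | regime | role in the rhythm |
|---|---|---|---|---|---|---|
| CN | 0.03 | 0.25 | −65 | 11 | phasic spiking | fires once per DP pulse at rest; free-runs at ~40 ms under sustained PCN drive; the large d gives a firm relative refractory period so coincident DP pulses cannot produce spurious very short intervals |
| DP | 0.015 | 0.2 | −65 | 8 | tonic spiking | period ≈ 120 ms at the baseline drive (5.0), ≈ 82 ms under the acceleration step (+2.0) |
| PCN | 0.003 | 0.2 | −65 | 25 | spike-frequency adaptation | bursts hard at the scallop step onset (+10.0) and adapts out within ~150 ms, producing the dive-and-recover shape |
| VPd | 0.003 | 0.0 | −65 | 6 | low-threshold spiking (burster) | silent at rest despite the tonic corollary-discharge drive (low b ⇒ high rheobase); a cessation step (+8.0 on a 4.0 standing current) fires a brief burst whose inhibition, decaying at the fitted IS kinetics, gates discharge off for ~500 ms |

One structural consequence deserves emphasis. The fitted inhibitory
synapses have release windows (t_max ≈ 167–177 ms) longer than the
120 ms resting cycle and near-saturating binding rates. If VPd burst
after *every* CN spike — as it does in the living fish — the
inhibitory receptors would sit pinned near r = 1 and additional VPd
firing during a cessation stimulus could not deepen the inhibition: no
pause could ever be evoked. With the synapse table fixed, a baseline
VPd burst and a workable cessation are mutually exclusive, and this
reconstruction resolves the conflict in favour of the behaving
displays: VPd is quiescent at rest, the resting rhythm is carried by
tonic DP firing, and the corollary-discharge diagnostic
(`corollary_discharge_check`) consequently reports missing VPd bursts
at baseline. The check remains available and is meaningful during
cessation stimulation.

VPd's standing current (4.0, subthreshold) exists so that robustness
cells at −50% step intensity still push VPd past threshold: without it
half-amplitude cessation cells evoke no pause at all and the cessation
class degenerates in the robustness summaries.

## Display comparison and fitness

A sequence of pulse intervals is turned into a comparable shape by
(1) normalising its cumulative time axis to 1,000 arbitrary units, with
each IPI's value anchored at the interval's *start* (the profile is
"the sequence starting at its first IPI"; past the last anchor it
extends flat), (2) sampling the piecewise-linear profile every 20 units
(50 points), and (3) differencing consecutive samples (49 values).
Linear interpolation is used; anchoring at interval starts pins
onset-locked display features to a common axis position, which matters
because the stimulation timing is fixed across all comparisons.

Fitness compares *display windows*, not whole recordings: the IPIs
beginning inside [onset, step end + 240 ms recovery], plus the
onset-straddling interval when it runs more than 100 ms into the
stimulus — which is exactly the cessation pause, the one display that
lengthens the ongoing interval rather than terminating it. Two reasons:
recorded displays are short snippets around the behaviour, and a
1,500 ms window is mostly resting rhythm, whose jitter would dominate
the 50-point transform and drown the display structure. The full-window
SPI is still what `simulate` returns and what the CSV outputs contain.

Per pattern, the simulated display is scored against every target
exemplar and the minimum MSE wins: f_pat = 1/(1 + MSE_min); the
configuration's fitness is the sum over the four patterns (∈ (0, 4]).
An untransformable display (fewer than two intervals) receives a large
sentinel MSE (1e6) instead of an error so optimisation runs never
abort.

## Synthetic targets

The generator emits display snippets with the stereotyped structure of
each pattern, anchored at resting 120 ms, acceleration plateau 85 ms,
scallop floor 40 ms, cessation pause 500 ms, on the fixed timing of the
simulation cases (evoked section sized to the 400 ms step plus a 240 ms
resting recovery). Exemplars differ by ±20% seeded jitter of the
display magnitudes and run lengths and ±10% in the resting level, with
only small (5%) interval-to-interval noise in the resting stretches:
the natural displays vary far more in their evoked structure than in
the background rhythm, and per-interval resting noise at display
amplitude would swamp the differenced profiles. The cessation pause is
floored at 3.3× the resting level so it dominates the sequence at every
jitter draw, and capped at 1 s.

What the generator does *not* emulate: recorded sequences' measurement
jitter, slow drifts of the resting rhythm, inter-individual magnitude
differences beyond ±20%, or displays embedded in long free-behaviour
context. Tests passing against these targets show the machinery and the
model's display repertoire are right, not that the configuration would
fit any particular animal's recordings.

## Genetic algorithm

Steady-state scheme over the 20-value genome (α, β, g, t_max for
IS_DP, IS_PCN, ES_DP, ES_PCN, ES_CDP, in that order): each generation
breeds an offspring pool equal to the population (default 100) by
binary-tournament selection, uniform per-gene crossover (probability
0.9, else clone) and per-gene Gaussian mutation (probability 0.1, SD =
0.1 of the bound interval), merges it with the parents, evaluates the
whole pool, ranks (ties broken by position) and truncates. Truncation
retains every top-ranked parent, so the configured 10% elite survives
unconditionally and best fitness is non-decreasing. Bounds keep ES
conductances ≥ 0 and IS conductances ≤ 0; all operators clip. Stopping:
a generation budget (default 200) or best fitness reaching 3× the seed
configuration's fitness — the published scheme stops on "a relative
increase of the initial fit" without printing the factor, so the ratio
is configurable. Evaluation is a pure function of (genome, simulation
seed): runs reproduce bit-identically and could be parallelised without
changing results. Staged runs (wide bounds, then bounds narrowed around
the incumbent best) are available via `evolve_staged`/`narrowed_bounds`.

## Robustness analysis

`run_grid` rescales every step input's intensity and duration by
relative offsets (default −0.5…0.5 in 0.05 steps: 21×21 = 441 cells per
pattern), re-simulates each cell with a seed derived deterministically
from (master seed, cell index), and reports per-pattern and total
fitness plus the relative change Δf = (f_i − f_0)/f_0 against the
unmodified centre cell (exactly 0 there by construction). Δf is
emitted both as a ratio and ×100 (percent); the partition summaries
(worse / similar / better, thresholds ±100 on the percent scale —
the threshold scale in the source material is ambiguous, so both
scales are exported) return mean ± SD interpolated profiles per
partition with the closest target exemplar. Failed cells are flagged
and skipped, not fatal.

`noise_robustness` adds seeded Gaussian noise to active step
amplitudes (SD = sigma × amplitude), per integration tick by default or
once per step event, over a list of sigmas with several repetitions.

The inter-pattern distance matrix averages Euclidean distances between
duration-normalised *interpolated profiles* (the transform chain up to,
but not including, the differencing step) of simulated displays and
target exemplars. On profiles, the diagonal-minimum property — every
simulated class closest to its own targets — holds across seeds, and
cessation distances sit an order of magnitude above the short displays;
on fully differenced vectors the property is structurally unattainable
(differencing erases sustained-interval levels, and narrow features
become near-orthogonal under one-sample shifts of the 20-unit grid).
The MSE fitness keeps the full chain including differencing, where
relative slopes are the point.

Known limitation: the hand-tuned reference's pattern fitness is
phase-sensitive (the pre-roll randomises where the resting rhythm meets
the stimulus, and the min-over-exemplars MSE of a short display moves
substantially with that phase). The robustness grid therefore shows
larger relative fitness swings than a configuration polished by a long
GA run would; the class-separability and anchor properties are stable
regardless.

## Calibration and measures

`calibrate_baseline` bisects the DP baseline current (the carrier of
the resting rhythm) until the mean CN IPI over a 5 s run lies within
tolerance of the target (default 120 ± 15 ms), returning the configured
baseline unchanged if it already qualifies and raising with the best
value found when the target is unreachable within bounds.

Display magnitudes are measured on display windows: scallop minimum =
min IPI; acceleration plateau = median of the IPIs wholly inside the
step; cessation pause = max IPI. Because the displays ride on a
randomly phased rhythm, headline numbers average these measures over
five independently seeded runs; at the shipped configuration they come
out at ≈120 ms resting, ≈38–42 ms scallop minimum, ≈82 ms acceleration
plateau and ≈505–560 ms cessation pause, inside ±25% of the published
anchors. The acceptance script (`scripts/acceptance.py`) recomputes all
of them, plus the robustness grid's centre relative fitness, from
scratch at whatever seed it is given; its problem sizes (five runs per
display, a 3×3 grid for the centre check, 5 s calibration runs) were
chosen to characterise the model compactly.
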