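# electromotor

A computational model of the electromotor command network of pulse
mormyrid fish (e.g. *Gnathonemus petersii*), together with the machinery
to fit its synaptic parameters against target firing patterns and to
assess the robustness of a fitted configuration to input variability.

Pulse mormyrids communicate and sense their surroundings with brief
electric organ discharges (EODs). The information is carried by the
*timing* between pulses: sequences of inter-pulse intervals (IPIs) form
stereotyped displays — **accelerations** (sustained runs of regular short
IPIs), **scallops** (a sudden dive to the shortest IPIs with immediate
recovery), **rasps** (a scallop-like drop followed by an
acceleration-like tail) and **cessations** (a pause of up to a second).
The timing originates in a small brainstem circuit: the command nucleus
(CN) fires once per EOD and integrates excitation from the thalamic
dorsal posterior nucleus (DP) and the mesencephalic precommand nucleus
(PCN); each CN spike also drives, via the corollary-discharge pathway,
the inhibitory ventroposterior nucleus (VPd), which silences DP and PCN.

## The model

Each nucleus is a single Izhikevich unit,

    dv/dt = 0.04 v² + 5 v + 140 − u + i_syn
    du/dt = a (b v − u),        if v ≥ 30 mV: v ← c, u ← u + d

and each of the five projections (ES_DP: DP→CN, ES_PCN: PCN→CN,
IS_DP: VPd⊣DP, IS_PCN: VPd⊣PCN, ES_CDP: CN→VPd) is a kinetic
receptor-binding synapse,

    ṙ = α[T](1 − r) − βr   while the release window is open,
    ṙ = −βr                otherwise,        i_syn = g · r · (v_post − E_syn)

with a window opened by a presynaptic threshold crossing and closed
`t_max` ms later. The shipped reference configuration carries the
published fitted (R-GA) synapse table; nucleus parameters and input
currents are re-derived so the network reproduces the published display
magnitudes (see `docs/methods.md`).

Displays are compared through a shape transform — normalise the sequence
to 1,000 arbitrary time units, interpolate the IPI profile at 50 points,
difference — and scored per pattern as `f_pat = 1/(1 + MSE)` against the
closest target exemplar; a configuration's fitness is the sum over the
four displays (4 = perfect). A steady-state genetic algorithm evolves
the 20 synaptic parameters (α, β, g, t_max for five synapses) against
the four simulation cases at once, and a robustness module perturbs the
stimulation (±50% intensity×duration grid, Gaussian input noise) to
verify the displays depend on *which* nucleus is stimulated rather than
on the exact input.

## A worked example

```sh
python examples/simulate_displays.py
```

prints, for the reference configuration:

```
resting rhythm: mean IPI = 120.0 ms

acceleration  IPIs (ms):    76    82    82    82   137   120   120
scallop       IPIs (ms):    27    51    66   119   120   120   120   120
rasp          IPIs (ms):    44    36    81    82    82   137   120   120
cessation     IPIs (ms):   579   145   130
```

One network, four inputs, four displays: a step current into DP holds CN
at a regular ~82 ms interval (acceleration); a step into PCN dives to
~27 ms and recovers within three intervals (scallop); both together give
the drop-plus-tail rasp; a step into VPd silences the circuit for about
half a second (cessation). The resting rhythm in between sits at the
fish's ~120 ms working point.

`examples/fitness_and_targets.py` scores these displays against
synthetic targets (total f(I) = 0.871 for the reference),
`examples/fit_synapses_ga.py` runs a small GA refinement
(0.871 → 1.210 in three demo generations), and
`examples/robustness_analysis.py` prints a reduced robustness grid and
the inter-pattern distance matrix, whose diagonal is the row minimum for
every display class.

A thin CLI wraps the same functionality:

```sh
electromotor --seed 1 --outdir out simulate --pattern scallop
electromotor --seed 1 --outdir out gen-targets
electromotor --seed 1 --outdir out fit --generations 5 --population 20
electromotor --seed 1 --outdir out robustness --grid-points 5
electromotor --seed 1 --outdir out check
```

All outputs are plain CSV plus a `manifest.json`; identical seeds give
byte-identical payloads.

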