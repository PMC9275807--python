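"""The electromotor command network: wiring, simulation and SPI extraction.

Four nuclei (CN, DP, PCN, VPd) are coupled by the five projections of the
command chain: DP and PCN excite CN (ES_DP, ES_PCN), CN excites VPd through
the corollary-discharge pathway (ES_CDP), and VPd inhibits DP and PCN
(IS_DP, IS_PCN).  Every CN action potential stands for one electric organ
discharge, so the network's output is the sequence of CN spike times and
the inter-pulse intervals (IPIs) between them.

Simulations run on a common explicit-Euler clock shared by the nucleus and
receptor equations.  Each run starts with a seed-determined random pre-roll
under baseline inputs so the resting rhythm is established before the
stimulation protocol begins; the reported SPI covers the protocol window
plus one resting interval before it, so the transition out of rest is part
of the pattern shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import CalibrationError, IntegrationError
from .nucleus import NUCLEUS_LABELS, SPIKE_CUTOFF, NucleusParams
from .synapse import PROJECTIONS, SYNAPSE_NAMES, SynapseParams

PATTERN_LABELS = ("acceleration", "scallop", "rasp", "cessation", "baseline")

#: Which nuclei each behavioural display stimulates.
PATTERN_TARGETS: dict[str, frozenset[str]] = {
    "acceleration": frozenset({"DP"}),
    "scallop": frozenset({"PCN"}),
    "rasp": frozenset({"DP", "PCN"}),
    "cessation": frozenset({"VPd"}),
    "baseline": frozenset(),
}


@dataclass(frozen=True)
class StepInput:
    """One constant-current step injected into a nucleus."""

    nucleus: str
    onset: float
    duration: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.nucleus not in ("DP", "PCN", "VPd"):
            raise ValueError(
                f"step inputs target DP, PCN or VPd, got {self.nucleus!r}"
            )
        if self.onset < 0:
            raise ValueError(f"step onset must be >= 0, got {self.onset}")
        if self.duration < 0:
            raise ValueError(f"step duration must be >= 0, got {self.duration}")


@dataclass(frozen=True)
class StimulationProtocol:
    """Step-current stimulation defining one simulation case.

    ``init_duration`` gives the [low, high] range (ms) of the randomised
    pre-roll under baseline inputs that precedes the protocol window.
    """

    pattern_label: str
    steps: tuple[StepInput, ...]
    total_duration: float
    init_duration: tuple[float, float] = (1000.0, 2000.0)

    def __post_init__(self) -> None:
        if self.pattern_label not in PATTERN_LABELS:
            raise ValueError(
                f"pattern_label must be one of {PATTERN_LABELS}, "
                f"got {self.pattern_label!r}"
            )
        object.__setattr__(self, "steps", tuple(self.steps))
        for s in self.steps:
            if s.onset + s.duration > self.total_duration:
                raise ValueError(
                    f"step on {s.nucleus} ends at {s.onset + s.duration} ms, "
                    f"beyond total_duration {self.total_duration} ms"
                )
        targets = {s.nucleus for s in self.steps}
        allowed = PATTERN_TARGETS[self.pattern_label]
        if not targets <= allowed:
            raise ValueError(
                f"pattern {self.pattern_label!r} may stimulate {sorted(allowed)}, "
                f"protocol stimulates {sorted(targets)}"
            )
        lo, hi = self.init_duration
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid init_duration range {self.init_duration}")

    def scaled(self, d_intensity: float = 0.0, d_duration: float = 0.0
               ) -> "StimulationProtocol":
        """Protocol with every step's amplitude and duration rescaled.

        ``d_intensity`` and ``d_duration`` are relative offsets: 0 keeps the
        step, +0.5 enlarges it by 50%, -0.5 shrinks it by 50%.  Used by the
        input-robustness grid.
        """
        steps = tuple(
            replace(
                s,
                amplitude=s.amplitude * (1.0 + d_intensity),
                duration=s.duration * (1.0 + d_duration),
            )
            for s in self.steps
        )
        return replace(self, steps=steps)


@dataclass(frozen=True)
class NetworkConfig:
    """Everything needed to simulate the network.

    ``nuclei`` maps the four nucleus labels to their parameters,
    ``synapses`` the five projection names to theirs, ``baseline_inputs``
    gives the per-nucleus constant currents that sustain the resting
    rhythm, and ``dt`` is the shared Euler step (ms).
    """

    nuclei: dict[str, NucleusParams]
    synapses: dict[str, SynapseParams]
    baseline_inputs: dict[str, float]
    dt: float = 0.1

    def __post_init__(self) -> None:
        if set(self.nuclei) != set(NUCLEUS_LABELS):
            raise ValueError(
                f"nuclei must be exactly {set(NUCLEUS_LABELS)}, got {set(self.nuclei)}"
            )
        for label, p in self.nuclei.items():
            if p.label != label:
                raise ValueError(f"nucleus key {label!r} holds params labelled {p.label!r}")
        if set(self.synapses) != set(SYNAPSE_NAMES):
            raise ValueError(
                f"synapses must be exactly {set(SYNAPSE_NAMES)}, got {set(self.synapses)}"
            )
        for name, s in self.synapses.items():
            if (s.pre_label, s.post_label) != PROJECTIONS[name]:
                raise ValueError(
                    f"synapse {name!r} must project {PROJECTIONS[name]}, "
                    f"got ({s.pre_label}, {s.post_label})"
                )
        unknown = set(self.baseline_inputs) - set(NUCLEUS_LABELS)
        if unknown:
            raise ValueError(f"baseline_inputs for unknown nuclei {sorted(unknown)}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    def with_baseline(self, baseline: dict[str, float]) -> "NetworkConfig":
        return replace(self, baseline_inputs=dict(baseline))


@dataclass
class SPISequence:
    """Ordered inter-pulse intervals extracted from CN spike times."""

    ipis: np.ndarray
    first_spike_time: float | None = None

    def __post_init__(self) -> None:
        self.ipis = np.asarray(self.ipis, dtype=float)
        if self.ipis.size and not np.all(self.ipis > 0):
            raise ValueError("all IPIs must be positive")

    def __len__(self) -> int:
        return int(self.ipis.size)

    @property
    def is_empty(self) -> bool:
        return self.ipis.size == 0


@dataclass
class SimulationResult:
    """Spike times, optional traces, and the extracted CN SPI."""

    spike_times: dict[str, np.ndarray]
    spi: SPISequence
    protocol_start: float
    total_duration: float
    pre_roll: float
    traces: dict[str, np.ndarray] | None = None


def _quiescent_voltage(b: float) -> float:
    """Stable zero-input rest voltage: the lower root of
    0.04 v^2 + (5 - b) v + 140 = 0 (falls back to -70 mV if none exists)."""
    disc = (5.0 - b) ** 2 - 4.0 * 0.04 * 140.0
    if disc <= 0:
        return -70.0
    return (-(5.0 - b) - math.sqrt(disc)) / (2.0 * 0.04)


def extract_spi(cn_spike_times) -> SPISequence:
    """Consecutive differences of strictly increasing CN spike times.

    Fewer than two spikes yield an empty sequence (meaningful for
    cessation runs).
    """
    times = np.asarray(list(cn_spike_times), dtype=float)
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError("spike times must be strictly increasing")
    if times.size < 2:
        return SPISequence(ipis=np.empty(0), first_spike_time=None)
    return SPISequence(ipis=np.diff(times), first_spike_time=float(times[0]))


def simulate(
    config: NetworkConfig,
    protocol: StimulationProtocol,
    seed: int,
    record_traces: bool = False,
    noise_sigma: float = 0.0,
    noise_mode: str = "tick",
) -> SimulationResult:
    """Run one simulation case.

    The run starts with a pre-roll of seed-determined random length (drawn
    uniformly from ``protocol.init_duration`` and rounded to the grid)
    under baseline inputs only, then the protocol plays out.  Nuclei and
    synapses advance on one clock; spike times are reported relative to the
    protocol start (the pre-roll occupies negative times).

    ``noise_sigma`` adds seeded Gaussian noise to the active step
    amplitudes, expressed as a fraction of each step's amplitude; with
    ``noise_mode="tick"`` an independent draw is made every integration
    step, with ``"event"`` one draw per step-input per run.

    Returns a :class:`SimulationResult` whose SPI is restricted to the
    window starting one resting interval before the protocol.
    """
    if noise_mode not in ("tick", "event"):
        raise ValueError(f"noise_mode must be 'tick' or 'event', got {noise_mode!r}")
    rng = np.random.default_rng(seed)
    dt = config.dt
    lo, hi = protocol.init_duration
    pre_roll = dt * round(float(rng.uniform(lo, hi)) / dt) if hi > 0 else 0.0

    labels = list(NUCLEUS_LABELS)
    index = {lab: i for i, lab in enumerate(labels)}
    nuc = [config.nuclei[lab] for lab in labels]
    a = [p.a for p in nuc]
    b = [p.b for p in nuc]
    c = [p.c for p in nuc]
    d = [p.d for p in nuc]
    base = [float(config.baseline_inputs.get(lab, 0.0)) for lab in labels]

    # Quiescent start: each nucleus at its zero-input stable equilibrium
    # (the lower root of the voltage nullcline with u = b v), receptors
    # unbound, so with no input there is no activity
    v = [_quiescent_voltage(b[i]) for i in range(4)]
    u = [b[i] * v[i] for i in range(4)]

    syn = [config.synapses[name] for name in SYNAPSE_NAMES]
    s_pre = [index[s.pre_label] for s in syn]
    s_post = [index[s.post_label] for s in syn]
    s_aT = [s.alpha * s.T for s in syn]
    s_beta = [s.beta for s in syn]
    s_g = [s.g_syn for s in syn]
    s_tmax = [s.t_max for s in syn]
    s_thr = [s.threshold for s in syn]
    s_E = [s.E_syn for s in syn]
    r = [0.0] * 5
    t_f: list[float | None] = [None] * 5

    steps_in = [
        (index[s.nucleus], s.onset, s.onset + s.duration, s.amplitude)
        for s in protocol.steps
    ]
    if noise_sigma > 0.0 and noise_mode == "event":
        event_noise = [
            float(rng.normal(0.0, noise_sigma * abs(amp)))
            for (_, _, _, amp) in steps_in
        ]
    else:
        event_noise = [0.0] * len(steps_in)

    n_ticks = int(round((pre_roll + protocol.total_duration) / dt))
    spikes: list[list[float]] = [[], [], [], []]
    if record_traces:
        trace_v = np.empty((n_ticks, 4))
        trace_r = np.empty((n_ticks, 5))
        trace_t = np.empty(n_ticks)

    tick_noise = noise_sigma > 0.0 and noise_mode == "tick"
    t = -pre_roll
    for k in range(n_ticks):
        t_new = t + dt
        # external input at this step
        i_ext = base.copy()
        for j, (ni, on, off, amp) in enumerate(steps_in):
            if on <= t < off:
                val = amp + event_noise[j]
                if tick_noise:
                    val += float(rng.normal(0.0, noise_sigma * abs(amp)))
                i_ext[ni] += val
        # synaptic currents from the state at time t
        for j in range(5):
            rj = r[j]
            if rj != 0.0:
                i_ext[s_post[j]] += s_g[j] * rj * (v[s_post[j]] - s_E[j])
        # nucleus update with after-spike reset; the pre-reset voltage is
        # kept for threshold-crossing detection
        v_prev = v.copy()
        v_raw_post = [0.0] * 4
        for i in range(4):
            vi, ui = v[i], u[i]
            v_raw = vi + dt * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + i_ext[i])
            u_new = ui + dt * (a[i] * (b[i] * vi - ui))
            if not (math.isfinite(v_raw) and math.isfinite(u_new)):
                raise IntegrationError(labels[i], t_new)
            if v_raw >= SPIKE_CUTOFF:
                spikes[i].append(t_new)
                v[i] = c[i]
                u[i] = u_new + d[i]
            else:
                v[i] = v_raw
                u[i] = u_new
            v_raw_post[i] = v_raw
        # release windows: upward crossings of the presynaptic threshold
        for j in range(5):
            pre = s_pre[j]
            if v_prev[pre] < s_thr[j] <= v_raw_post[pre]:
                t_f[j] = t_new
            elif t_f[j] is not None and t_new > t_f[j] + s_tmax[j]:
                t_f[j] = None
        # receptor kinetics on the same clock
        for j in range(5):
            tf = t_f[j]
            rj = r[j]
            if tf is not None and tf < t_new <= tf + s_tmax[j]:
                rj += dt * (s_aT[j] * (1.0 - rj) - s_beta[j] * rj)
            else:
                rj += dt * (-s_beta[j] * rj)
            r[j] = 1.0 if rj > 1.0 else (0.0 if rj < 0.0 else rj)
        if record_traces:
            trace_t[k] = t_new
            trace_v[k] = v
            trace_r[k] = r
        t = t_new

    spike_arrays = {lab: np.asarray(spikes[index[lab]]) for lab in labels}
    spi = _window_spi(spike_arrays["CN"], pre_roll)
    traces = None
    if record_traces:
        traces = {"t": trace_t, "v": trace_v, "r": trace_r}
    return SimulationResult(
        spike_times=spike_arrays,
        spi=spi,
        protocol_start=0.0,
        total_duration=protocol.total_duration,
        pre_roll=pre_roll,
        traces=traces,
    )


def _window_spi(cn_times: np.ndarray, pre_roll: float) -> SPISequence:
    """SPI restricted to the protocol window plus one resting interval.

    The window opens one median pre-roll IPI before the protocol start so
    the first reported IPI captures the transition out of rest; without at
    least two pre-roll spikes the window simply starts at the protocol.
    """
    if cn_times.size < 2:
        return SPISequence(ipis=np.empty(0), first_spike_time=None)
    pre_spikes = cn_times[cn_times < 0.0]
    margin = float(np.median(np.diff(pre_spikes))) if pre_spikes.size >= 2 else 0.0
    window = cn_times[cn_times >= -margin]
    return extract_spi(window)


def display_spi(
    result: SimulationResult,
    onset: float,
    end: float,
    straddle_grace: float = 100.0,
) -> SPISequence:
    """The SPI of the evoked display: IPIs inside [onset, end].

    This is the sequence compared against target displays: recorded
    displays are short snippets around the evoked behaviour, and with the
    stimulation timing fixed the surrounding resting rhythm carries no
    pattern information.

    An IPI belongs to the display when it starts in [onset, end).  The
    interval straddling the onset is included only if it runs more than
    ``straddle_grace`` ms into the stimulation: displays that shorten
    IPIs terminate the straddling interval almost immediately (it is
    resting rhythm, not display), while a cessation *lengthens* it — the
    pause itself starts at the last discharge before the stimulus.
    """
    cn = result.spike_times["CN"]
    if cn.size < 2:
        return SPISequence(ipis=np.empty(0), first_spike_time=None)
    starts, ends = cn[:-1], cn[1:]
    mask = (starts >= onset) & (starts < end)
    mask |= (starts < onset) & (ends > onset + straddle_grace)
    if not np.any(mask):
        return SPISequence(ipis=np.empty(0), first_spike_time=None)
    idx = np.nonzero(mask)[0]
    return SPISequence(
        ipis=ends[idx] - starts[idx], first_spike_time=float(starts[idx[0]])
    )


def protocol_display_window(
    protocol: StimulationProtocol, recovery: float = 240.0
) -> tuple[float, float]:
    """[onset, end] window of a protocol's evoked display: from the first
    step onset to the last step offset plus a recovery allowance (about
    two resting intervals by default)."""
    if not protocol.steps:
        return 0.0, protocol.total_duration
    onset = min(s.onset for s in protocol.steps)
    offset = max(s.onset + s.duration for s in protocol.steps)
    return onset, min(offset + recovery, protocol.total_duration)


def baseline_protocol(
    total_duration: float = 5000.0,
    init_duration: tuple[float, float] = (0.0, 0.0),
) -> StimulationProtocol:
    """A protocol with no step inputs, for resting-rhythm runs."""
    return StimulationProtocol(
        pattern_label="baseline",
        steps=(),
        total_duration=total_duration,
        init_duration=init_duration,
    )


def mean_baseline_ipi(
    config: NetworkConfig, duration: float = 5000.0, seed: int = 0
) -> float:
    """Mean CN IPI over a baseline run of ``duration`` ms (nan if < 2 spikes)."""
    result = simulate(config, baseline_protocol(total_duration=duration), seed=seed)
    if result.spi.is_empty:
        return float("nan")
    return float(np.mean(result.spi.ipis))


def calibrate_baseline(
    config: NetworkConfig,
    target_ipi: float = 120.0,
    tolerance: float = 15.0,
    seed: int = 0,
    duration: float = 5000.0,
    input_bounds: tuple[float, float] = (0.0, 30.0),
    max_iter: int = 40,
) -> dict[str, float]:
    """Find per-nucleus baseline currents giving the target resting rhythm.

    The resting rhythm is carried by the tonic DP drive, so calibration is
    a deterministic bisection on the DP baseline current (the other
    baseline entries are kept as configured): more drive means shorter
    IPIs.  If the configured baseline already achieves the target within
    tolerance it is returned unchanged.

    Raises
    ------
    CalibrationError
        If no current within ``input_bounds`` reaches the target, reporting
        the best mean IPI found.
    """
    if target_ipi <= 0:
        raise ValueError(f"target_ipi must be positive, got {target_ipi}")

    def mean_ipi_for(i_dp: float) -> float:
        cfg = config.with_baseline({**config.baseline_inputs, "DP": i_dp})
        return mean_baseline_ipi(cfg, duration=duration, seed=seed)

    current = float(config.baseline_inputs.get("DP", 0.0))
    achieved = mean_ipi_for(current)
    if math.isfinite(achieved) and abs(achieved - target_ipi) <= tolerance:
        return dict(config.baseline_inputs)

    lo, hi = input_bounds
    ipi_lo = mean_ipi_for(lo)  # weak drive: long IPIs or silence (nan)
    ipi_hi = mean_ipi_for(hi)  # strong drive: short IPIs
    best_input, best_ipi = hi, ipi_hi
    if math.isfinite(achieved) and abs(achieved - target_ipi) < abs(
        (best_ipi if math.isfinite(best_ipi) else math.inf) - target_ipi
    ):
        best_input, best_ipi = current, achieved
    # target must be bracketed: unreachable if even the strongest drive is
    # too slow or the weakest too fast
    hi_ok = math.isfinite(ipi_hi) and ipi_hi <= target_ipi + tolerance
    lo_ok = (not math.isfinite(ipi_lo)) or ipi_lo >= target_ipi - tolerance
    if not (hi_ok and lo_ok):
        raise CalibrationError(target_ipi, best_ipi, best_input)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        ipi_mid = mean_ipi_for(mid)
        if math.isfinite(ipi_mid) and abs(ipi_mid - target_ipi) < abs(
            (best_ipi if math.isfinite(best_ipi) else math.inf) - target_ipi
        ):
            best_input, best_ipi = mid, ipi_mid
        if math.isfinite(ipi_mid) and abs(ipi_mid - target_ipi) <= tolerance:
            return {**config.baseline_inputs, "DP": mid}
        if not math.isfinite(ipi_mid) or ipi_mid > target_ipi:
            lo = mid  # too slow: raise the drive
        else:
            hi = mid
    raise CalibrationError(target_ipi, best_ipi, best_input)


@dataclass
class CorollaryDischargeReport:
    """Diagnostic of the CN -> VPd corollary-discharge feedback.

    For each CN spike: latency (ms) to the first subsequent VPd spike
    before the next CN spike (None when VPd stayed silent), and whether DP
    and PCN were silent during that VPd burst.
    """

    latencies: list[float | None]
    dp_pcn_silent: list[bool]

    @property
    def median_latency(self) -> float:
        present = [x for x in self.latencies if x is not None]
        return float(np.median(present)) if present else float("nan")

    @property
    def fraction_missing(self) -> float:
        if not self.latencies:
            return float("nan")
        return sum(x is None for x in self.latencies) / len(self.latencies)


def corollary_discharge_check(result: SimulationResult) -> CorollaryDischargeReport:
    """Latency from each CN spike to the following VPd burst (diagnostic)."""
    cn = result.spike_times["CN"]
    vpd = result.spike_times["VPd"]
    dp = result.spike_times["DP"]
    pcn = result.spike_times["PCN"]
    latencies: list[float | None] = []
    silent: list[bool] = []
    for i, t_cn in enumerate(cn):
        t_next = cn[i + 1] if i + 1 < len(cn) else math.inf
        burst = vpd[(vpd > t_cn) & (vpd < t_next)]
        if burst.size == 0:
            latencies.append(None)
            silent.append(True)
            continue
        latencies.append(float(burst[0] - t_cn))
        b0, b1 = float(burst[0]), float(burst[-1])
        dp_act = np.any((dp >= b0) & (dp <= b1))
        pcn_act = np.any((pcn >= b0) & (pcn <= b1))
        silent.append(not (dp_act or pcn_act))
    return CorollaryDischargeReport(latencies=latencies, dp_pcn_silent=silent)
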