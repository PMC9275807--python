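"""Shape analysis and fitness of inter-pulse-interval sequences.

An SPI (sequence of pulse intervals) is compared to targets through a
three-step transform: the cumulative spike-time axis is normalised to a
fixed span of 1,000 arbitrary units, the IPI-versus-normalised-time profile
is sampled every 20 units (50 points), and consecutive samples are
differenced.  The resulting *shape vector* captures the relative
increase/decrease structure of the display rather than its absolute
timing.  Pattern fitness is ``1 / (1 + MSE)`` against the closest target
exemplar, and the overall fitness of a network configuration is the sum
over the four behavioural patterns, so a perfect four-pattern match scores
4.

The module also generates synthetic target SPIs with the stereotyped
temporal structure of the four displays of pulse mormyrids (accelerations,
scallops, rasps, cessations), standing in for recorded sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GenerationError, TransformError
from .network import SPISequence

#: MSE assigned when a simulated SPI cannot be transformed (fewer than two
#: CN spikes in a non-cessation case); keeps GA evaluation total while
#: driving the pattern fitness to ~0.
MSE_SENTINEL = 1.0e6

PATTERNS = ("acceleration", "scallop", "rasp", "cessation")


@dataclass
class ShapeVector:
    """Differenced, regularly interpolated, duration-normalised IPI profile."""

    values: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_points - 1:
            raise ValueError(
                f"shape vector must hold n_points-1 differences, "
                f"got {self.values.size} for n_points={self.n_points}"
            )


def transform_spi(
    spi: SPISequence,
    duration_units: float = 1000.0,
    step_units: float = 20.0,
) -> ShapeVector:
    """Normalise, interpolate and difference one SPI.

    The profile is the piecewise-linear function mapping normalised
    cumulative spike time to IPI duration, starting at the first IPI:
    each IPI is anchored at its start time (the first at 0), and past the
    last anchor the profile extends flat.  The time axis is normalised by
    the sequence's total duration.  With the defaults the profile is
    sampled at 50 points and 49 differences are returned.

    Anchoring at start times pins display features to the (fixed) input
    timing of the simulation cases, so sequences that share an onset but
    differ in later durations still align on the normalised axis.

    Raises
    ------
    TransformError
        If the SPI has fewer than two IPIs (no profile can be defined).
    """
    profile = interpolated_profile(spi, duration_units, step_units)
    return ShapeVector(values=np.diff(profile), n_points=profile.size)


def interpolated_profile(
    spi: SPISequence,
    duration_units: float = 1000.0,
    step_units: float = 20.0,
) -> np.ndarray:
    """The 50-point interpolated IPI profile (the transform before
    differencing); used for mean/SD display of robustness partitions."""
    ipis = np.asarray(spi.ipis, dtype=float)
    if ipis.size < 2:
        raise TransformError(
            f"cannot build a profile from {ipis.size} IPIs (need at least 2)"
        )
    total = float(np.sum(ipis))
    t_start = np.concatenate([[0.0], np.cumsum(ipis)[:-1]])
    x = t_start / total * duration_units
    n = int(round(duration_units / step_units))
    grid = np.arange(1, n + 1) * step_units
    return np.interp(grid, x, ipis)


def mse(a: ShapeVector, b: ShapeVector) -> float:
    """Mean squared componentwise difference of two shape vectors."""
    if a.values.size != b.values.size:
        raise ValueError(
            f"shape vectors differ in length: {a.values.size} vs {b.values.size}"
        )
    diff = a.values - b.values
    return float(np.mean(diff * diff))


@dataclass
class TargetSet:
    """Exemplar SPIs of one behavioural pattern."""

    pattern_label: str
    exemplars: list[SPISequence]

    def __post_init__(self) -> None:
        if self.pattern_label not in PATTERNS:
            raise ValueError(
                f"pattern_label must be one of {PATTERNS}, got {self.pattern_label!r}"
            )
        if not self.exemplars:
            raise ValueError("a TargetSet needs at least one exemplar")


@dataclass
class FitnessReport:
    """Per-pattern (mse, f_pat) and the summed total fitness."""

    per_pattern: dict[str, tuple[float, float]]
    total: float


def fitness_pattern(
    simulated: SPISequence, targets: TargetSet
) -> tuple[float, float]:
    """Fitness of one simulated SPI against a target set.

    Both the simulated SPI and every exemplar are transformed; the minimum
    MSE across exemplars (the closest target) defines the pattern fitness
    ``f_pat = 1 / (1 + mse_min)``.  An untransformable simulated SPI gets
    the sentinel MSE instead of raising, so a silent network scores ~0 for
    the pattern rather than aborting an optimisation run.
    """
    try:
        sim_vec = transform_spi(simulated)
    except TransformError:
        return MSE_SENTINEL, 1.0 / (1.0 + MSE_SENTINEL)
    mse_min = np.inf
    for exemplar in targets.exemplars:
        m = mse(sim_vec, transform_spi(exemplar))
        if m < mse_min:
            mse_min = m
    return float(mse_min), 1.0 / (1.0 + float(mse_min))


def fitness_total(
    simulated: dict[str, SPISequence], targets: dict[str, TargetSet]
) -> FitnessReport:
    """Summed four-pattern fitness of one network configuration."""
    missing = set(PATTERNS) - set(simulated)
    if missing:
        raise ValueError(f"missing simulated patterns: {sorted(missing)}")
    missing = set(PATTERNS) - set(targets)
    if missing:
        raise ValueError(f"missing target patterns: {sorted(missing)}")
    per: dict[str, tuple[float, float]] = {}
    total = 0.0
    for pat in PATTERNS:
        m, f = fitness_pattern(simulated[pat], targets[pat])
        per[pat] = (m, f)
        total += f
    return FitnessReport(per_pattern=per, total=total)


@dataclass(frozen=True)
class GeneratorSettings:
    """Anchors (ms) and spread of the synthetic-target generator.

    Magnitude defaults are the stereotyped values of the four displays:
    resting rhythm ~120 ms, acceleration plateau ~85 ms, scallop floor
    ~40 ms, cessation pause ~500 ms, with ±20% seeded jitter across
    exemplars.  Exemplars are display snippets, the way recorded displays
    are: one transition interval out of rest, the evoked section (sized
    by ``step_duration``, the length of the stimulation step in the
    simulation cases), and a recovery allowance of ``recovery`` ms of
    resting intervals.  Simulated SPIs are windowed the same way before
    comparison.
    """

    resting_ipi: float = 120.0
    acceleration_plateau: float = 85.0
    scallop_floor: float = 40.0
    cessation_pause: float = 500.0
    jitter: float = 0.2
    onset: float = 500.0
    step_duration: float = 400.0
    total_duration: float = 1500.0
    recovery: float = 240.0

    def __post_init__(self) -> None:
        if not 0 <= self.jitter < 1:
            raise GenerationError(f"jitter must be in [0, 1), got {self.jitter}")
        acc_min = self.acceleration_plateau * (1 - self.jitter)
        sca_max = self.scallop_floor * (1 + self.jitter)
        if sca_max >= acc_min:
            raise GenerationError(
                f"scallop floor (up to {sca_max:.1f} ms) must stay below the "
                f"acceleration minimum (down to {acc_min:.1f} ms)"
            )
        if self.cessation_pause * (1 + self.jitter) > 1000.0:
            raise GenerationError(
                "cessation pauses may not exceed 1 s even after jitter"
            )


def _exemplar(
    label: str, rng: np.random.Generator, s: GeneratorSettings
) -> SPISequence:
    """One display exemplar: transition out of rest, evoked section,
    resting recovery — the snippet a recording of the display would give.
    """
    j = s.jitter
    r0 = float(
        np.clip(s.resting_ipi * (1.0 + 0.5 * j * rng.uniform(-1, 1)), 100.0, 300.0)
    )
    if label == "acceleration":
        # near-regular short run, one longer recovery interval, rest;
        # the plateau stays distinctly below the resting rhythm
        level = min(
            s.acceleration_plateau * (1.0 + j * rng.uniform(-1, 1)), 0.82 * r0
        )
        n_run = max(3, int(round(s.step_duration / level)) - 1)
        run = np.clip(level * (1.0 + 0.05 * rng.uniform(-1, 1, size=n_run)), 21.0, None)
        ipis = np.concatenate([run, [1.13 * r0]])
    elif label == "scallop":
        # sudden drop to the floor, graded recovery within three IPIs
        floor = s.scallop_floor * (1.0 + j * rng.uniform(-1, 1))
        ipis = np.array([floor, min(1.3 * floor, r0), min(1.7 * floor, r0)])
    elif label == "rasp":
        # scallop-like drop, then an acceleration-like sustained tail
        floor = s.scallop_floor * (1.0 + j * rng.uniform(-1, 1))
        level = s.acceleration_plateau * (1.0 + j * rng.uniform(-1, 1))
        head = np.array([floor, 0.85 * floor])
        n_tail = max(2, int(round((s.step_duration - 3.0 * floor) / level)))
        tail = level * (1.0 + 0.05 * rng.uniform(-1, 1, size=n_tail))
        ipis = np.concatenate([head, tail, [1.13 * r0]])
    elif label == "cessation":
        # one long pause (straddling the onset, as in the simulation
        # cases), then a slowly shortening recovery tail
        pause = min(s.cessation_pause * (1.0 + j * rng.uniform(-1, 1)), 1000.0)
        # the pause must dominate the surrounding rhythm even at the low
        # end of its jitter range
        pause = max(pause, 3.3 * r0)
        ipis = np.array([pause, 1.2 * r0, 1.08 * r0])
    else:
        raise ValueError(f"unknown pattern label {label!r}")
    # resting recovery: fill with near-regular resting intervals until the
    # post-stimulus stretch covers the recovery allowance
    span_target = (
        s.step_duration + s.recovery
        if label != "cessation"
        else ipis[0] + s.recovery + 2.0 * r0
    )
    fill: list[float] = []
    while ipis.sum() + sum(fill) < span_target:
        fill.append(float(np.clip(r0 * (1.0 + 0.05 * rng.uniform(-1, 1)),
                                  100.0, 300.0)))
    if fill:
        ipis = np.concatenate([ipis, fill])
    return SPISequence(ipis=ipis, first_spike_time=0.0)


def generate_targets(
    pattern_label: str,
    count: int = 5,
    rng_seed: int = 0,
    settings: GeneratorSettings | None = None,
) -> TargetSet:
    """Generate ``count`` synthetic exemplars of one display pattern.

    Exemplars share the pattern's structural template and differ by seeded
    jitter of magnitudes and run lengths, emulating the natural
    variability of the displays.  Deterministic in ``rng_seed``.
    """
    if count < 1:
        raise GenerationError(f"count must be >= 1, got {count}")
    if pattern_label not in PATTERNS:
        raise ValueError(
            f"pattern_label must be one of {PATTERNS}, got {pattern_label!r}"
        )
    s = settings or GeneratorSettings()
    rng = np.random.default_rng([rng_seed, PATTERNS.index(pattern_label)])
    exemplars = [_exemplar(pattern_label, rng, s) for _ in range(count)]
    return TargetSet(pattern_label=pattern_label, exemplars=exemplars)


def generate_all_targets(
    count: int = 5,
    rng_seed: int = 0,
    settings: GeneratorSettings | None = None,
) -> dict[str, TargetSet]:
    """Target sets for all four patterns, keyed by label."""
    return {
        pat: generate_targets(pat, count=count, rng_seed=rng_seed, settings=settings)
        for pat in PATTERNS
    }
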