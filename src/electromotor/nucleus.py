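"""Izhikevich point-model dynamics for one electromotor nucleus.

Each nucleus of the command chain (CN, DP, PCN, VPd) is represented by a
single two-variable Izhikevich unit

    dv/dt = 0.04 v^2 + 5 v + 140 - u + i_syn
    du/dt = a (b v - u)

with the after-spike reset ``if v >= 30 mV: v <- c, u <- u + d``.  The
quadratic voltage nullcline gives integrator-like or phasic behaviour
depending on (a, b, c, d); the regimes used for the four nuclei are chosen
in the shipped configuration, not hard-coded here.

The 30 mV spike cutoff is part of the model definition and is deliberately
not a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import IntegrationError

#: Spike cutoff (mV) of the Izhikevich model; fixed by the model definition.
SPIKE_CUTOFF = 30.0

#: Valid nucleus labels in the electromotor command network.
NUCLEUS_LABELS = ("CN", "DP", "PCN", "VPd")


@dataclass(frozen=True)
class NucleusParams:
    """Izhikevich coefficients and reset rule for one nucleus.

    Parameters
    ----------
    a : float
        Recovery-variable time scale (1/ms in the model's dimensionless
        convention).  Smaller ``a`` means slower recovery.
    b : float
        Sensitivity of the recovery variable to subthreshold voltage.
    c : float
        After-spike reset voltage (mV); must lie below the 30 mV cutoff.
    d : float
        After-spike increment of the recovery variable.
    label : str
        One of ``CN``, ``DP``, ``PCN``, ``VPd``.
    regime : str
        Free-text tag describing the firing regime (e.g. "phasic spiking").
    """

    a: float
    b: float
    c: float
    d: float
    label: str
    regime: str = ""

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"nucleus {self.label!r}: a must be > 0, got {self.a}")
        if self.d < 0:
            raise ValueError(f"nucleus {self.label!r}: d must be >= 0, got {self.d}")
        if not self.c < SPIKE_CUTOFF:
            raise ValueError(
                f"nucleus {self.label!r}: reset voltage c={self.c} must be "
                f"below the {SPIKE_CUTOFF} mV cutoff"
            )
        if self.label not in NUCLEUS_LABELS:
            raise ValueError(
                f"unknown nucleus label {self.label!r}; expected one of {NUCLEUS_LABELS}"
            )


@dataclass
class NeuronState:
    """Instantaneous state of one nucleus.

    ``v`` is the membrane voltage (mV), ``u`` the recovery variable,
    ``last_spike_time`` the time (ms) of the most recent reset, or None.
    """

    v: float
    u: float
    last_spike_time: float | None = None


def resting_state(params: NucleusParams, v0: float = -70.0) -> NeuronState:
    """State at voltage ``v0`` with the recovery variable on its nullcline."""
    return NeuronState(v=v0, u=params.b * v0)


def derivatives(
    state: NeuronState, params: NucleusParams, i_syn: float
) -> tuple[float, float]:
    """Right-hand side (dv/dt, du/dt) of the nucleus model.

    Pure function; ``i_syn`` is the total input current (synaptic plus
    injected) in the model's dimensionless current units.
    """
    v, u = state.v, state.u
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_syn
    du = params.a * (params.b * v - u)
    return dv, du


def step(
    state: NeuronState,
    params: NucleusParams,
    i_syn: float,
    dt: float,
    t: float,
) -> tuple[NeuronState, bool]:
    """Advance one explicit-Euler step of length ``dt`` ending at time ``t``.

    The reset is tested after the update: if the post-step voltage reaches
    the 30 mV cutoff the spike is recorded at ``t``, ``v`` is set to ``c``
    and ``u`` incremented by ``d``.

    Returns the new state and a flag saying whether the reset fired.

    Raises
    ------
    IntegrationError
        If the state becomes non-finite.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    dv, du = derivatives(state, params, i_syn)
    v = state.v + dt * dv
    u = state.u + dt * du
    if not (math.isfinite(v) and math.isfinite(u)):
        raise IntegrationError(params.label, t)
    if v >= SPIKE_CUTOFF:
        return NeuronState(v=params.c, u=u + params.d, last_spike_time=t), True
    return NeuronState(v=v, u=u, last_spike_time=state.last_spike_time), False
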