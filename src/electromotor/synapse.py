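"""Kinetic (receptor-binding) model of the chemical projections.

Transmitter release follows the two-state receptor-binding scheme: while a
release window is open the bound-receptor fraction ``r`` relaxes towards
``alpha*T / (alpha*T + beta)``,

    dr/dt = alpha [T] (1 - r) - beta r        (window open)
    dr/dt = -beta r                           (window closed)

and the post-synaptic current is ``i_syn = g_syn * r * (v_post - E_syn)``.
A window opens when the presynaptic voltage crosses ``threshold`` upwards
and closes ``t_max`` ms later; a new crossing while a window is open
restarts it.  With a single reversal potential below rest (E_syn = -80 mV)
the sign of ``g_syn`` alone decides whether a projection is excitatory or
inhibitory, matching the shipped parameter table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: The five projections of the electromotor command network, keyed by the
#: conventional synapse names: (presynaptic, postsynaptic) nucleus labels.
PROJECTIONS: dict[str, tuple[str, str]] = {
    "ES_DP": ("DP", "CN"),
    "ES_PCN": ("PCN", "CN"),
    "IS_DP": ("VPd", "DP"),
    "IS_PCN": ("VPd", "PCN"),
    "ES_CDP": ("CN", "VPd"),
}

SYNAPSE_NAMES = tuple(PROJECTIONS)


@dataclass(frozen=True)
class SynapseParams:
    """Kinetics, conductance and release window of one projection.

    Parameters
    ----------
    alpha, beta : float
        Forward and backward receptor rate constants (1/ms; ``alpha`` is
        multiplied by the transmitter concentration ``T``).
    g_syn : float
        Synaptic conductance in the model's dimensionless current units.
        Signed: positive for excitatory, negative for inhibitory
        projections (single reversal potential convention).
    t_max : float
        Maximum release time (ms): a window opened at ``t_f`` closes at
        ``t_f + t_max``.
    threshold : float
        Presynaptic voltage (mV) whose upward crossing opens release.
    E_syn : float
        Synaptic reversal potential (mV).
    T : float
        Transmitter concentration during a pulse (dimensionless multiplier
        of ``alpha``).
    pre_label, post_label : str
        Nucleus labels; must form one of the five network projections.
    """

    alpha: float
    beta: float
    g_syn: float
    t_max: float
    pre_label: str
    post_label: str
    threshold: float = 0.0
    E_syn: float = -80.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not self.t_max > 0:
            raise ValueError(f"t_max must be > 0, got {self.t_max}")
        if not self.T > 0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if (self.pre_label, self.post_label) not in PROJECTIONS.values():
            raise ValueError(
                f"({self.pre_label}, {self.post_label}) is not one of the "
                f"five electromotor projections {sorted(PROJECTIONS.values())}"
            )

    @property
    def name(self) -> str:
        """Conventional synapse name (ES_DP, IS_PCN, ...)."""
        for name, pair in PROJECTIONS.items():
            if pair == (self.pre_label, self.post_label):
                return name
        raise AssertionError("unreachable: projection validated in __post_init__")


@dataclass
class SynapseState:
    """Bound-receptor fraction and the open release window, if any."""

    r: float = 0.0
    release_open_since: float | None = None


def update_release_window(
    state: SynapseState,
    v_pre: float,
    v_pre_prev: float,
    t: float,
    params: SynapseParams,
) -> SynapseState:
    """Open/close the release window from the presynaptic voltage.

    A window opens at ``t`` when ``v_pre`` crosses ``threshold`` upwards
    (``v_pre_prev < threshold <= v_pre``); a crossing while a window is
    open restarts it.  An open window expires once ``t`` passes
    ``t_f + t_max``.
    """
    t_f = state.release_open_since
    if v_pre_prev < params.threshold <= v_pre:
        t_f = t
    elif t_f is not None and t > t_f + params.t_max:
        t_f = None
    if t_f == state.release_open_since:
        return state
    return SynapseState(r=state.r, release_open_since=t_f)


def window_open(state: SynapseState, t: float, params: SynapseParams) -> bool:
    """Whether transmitter is being released at time ``t``."""
    t_f = state.release_open_since
    return t_f is not None and t_f < t <= t_f + params.t_max


def step_receptor(
    state: SynapseState, params: SynapseParams, t: float, dt: float
) -> SynapseState:
    """Advance the bound-receptor fraction one Euler step ending at ``t``.

    ``r`` is clamped to [0, 1] against floating-point overshoot; for the
    shipped rate constants and dt the Euler step is well inside the
    stability region, so the clamp is a safety net only.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    r = state.r
    if window_open(state, t, params):
        r += dt * (params.alpha * params.T * (1.0 - r) - params.beta * r)
    else:
        r += dt * (-params.beta * r)
    r = min(1.0, max(0.0, r))
    return SynapseState(r=r, release_open_since=state.release_open_since)


def synaptic_current(
    state: SynapseState, v_post: float, params: SynapseParams
) -> float:
    """Post-synaptic current ``g_syn * r * (v_post - E_syn)``.

    Contributions from multiple afferents onto one nucleus sum linearly;
    the current enters the nucleus equation with a positive sign, so with
    E_syn below rest a positive ``g_syn`` depolarises and a negative one
    hyperpolarises.
    """
    return params.g_syn * state.r * (v_post - params.E_syn)


def receptor_closed_form(
    r0: float, params: SynapseParams, elapsed: float, open_: bool
) -> float:
    """Analytic solution of the receptor ODE for a constant window state.

    With the window open ``r`` relaxes exponentially towards
    ``r_inf = alpha T / (alpha T + beta)`` at rate ``alpha T + beta``;
    closed, it decays to zero at rate ``beta``.  Used for validation.
    """
    if open_:
        k = params.alpha * params.T + params.beta
        r_inf = params.alpha * params.T / k
        return r_inf + (r0 - r_inf) * math.exp(-k * elapsed)
    return r0 * math.exp(-params.beta * elapsed)
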