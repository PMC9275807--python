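"""Behavioural summary measures of simulated displays.

These are the quantities the displays are characterised by in the
literature: the resting rhythm's mean IPI, the minimum IPI reached in a
scallop, the plateau (median) IPI of an acceleration run, and the length
of the pause in a cessation.  Each is measured on the display window of a
simulation; multi-seed helpers average over independent runs since the
displays ride on a randomly phased resting rhythm.
"""

from __future__ import annotations

import math

import numpy as np

from . import network as net


def display_of(
    config: net.NetworkConfig,
    protocol: net.StimulationProtocol,
    seed: int,
) -> net.SPISequence:
    """Simulate one case and return its display-window SPI."""
    result = net.simulate(config, protocol, seed=seed)
    onset, end = net.protocol_display_window(protocol)
    return net.display_spi(result, onset, end)


def scallop_min_ipi(
    config: net.NetworkConfig, protocol: net.StimulationProtocol, seed: int
) -> float:
    """Minimum IPI of the evoked scallop (nan if the display is empty)."""
    spi = display_of(config, protocol, seed)
    return float(np.min(spi.ipis)) if len(spi) else math.nan


def acceleration_plateau_ipi(
    config: net.NetworkConfig,
    protocol: net.StimulationProtocol,
    seed: int,
    margin: float = 60.0,
) -> float:
    """Median IPI of the accelerated run.

    The run is taken as the IPIs lying wholly within the stimulation step
    (with a small trailing margin), excluding the recovery interval back
    to rest.
    """
    result = net.simulate(config, protocol, seed=seed)
    onset = min(s.onset for s in protocol.steps)
    offset = max(s.onset + s.duration for s in protocol.steps)
    cn = result.spike_times["CN"]
    if cn.size < 2:
        return math.nan
    starts, ends = cn[:-1], cn[1:]
    mask = (starts >= onset) & (ends <= offset + margin)
    if not np.any(mask):
        return math.nan
    return float(np.median(ends[mask] - starts[mask]))


def cessation_pause(
    config: net.NetworkConfig, protocol: net.StimulationProtocol, seed: int
) -> float:
    """Maximum IPI of the evoked cessation — the pause itself."""
    spi = display_of(config, protocol, seed)
    return float(np.max(spi.ipis)) if len(spi) else math.nan


def mean_over_seeds(measure, seeds) -> float:
    """Mean of a per-seed measure over several runs (nan-aware)."""
    values = [measure(seed) for seed in seeds]
    return float(np.nanmean(values))
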