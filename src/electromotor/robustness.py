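"""Robustness of a fitted configuration to stimulation variability.

A fitted network should produce each display because the right nucleus is
stimulated, not because of the exact step-current amplitude or duration
used during fitting.  This module quantifies that claim three ways:

* an intensity x duration grid: every step input is rescaled by relative
  offsets on both axes (default -50%..+50% in 5% steps, a 21x21 grid) and
  the four-pattern fitness is recomputed per cell, summarised as the
  relative fitness change ``delta_f = (f_i - f_0) / f_0`` against the
  unmodified centre cell;
* Gaussian input noise: seeded noise on the active step amplitudes,
  repeated across several noise levels;
* an inter-pattern distance matrix: mean Euclidean distance between the
  shape vectors of simulated SPIs of each pattern and the target exemplars
  of every pattern — when the fit is robust, each simulated class sits
  closest to its own target (the diagonal is the row minimum).

``delta_f`` is a ratio; summaries report it both raw and x100 (percent),
and partition thresholds are applied on the percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import network as net
from . import patterns as pat
from .errors import ElectromotorError


def relative_fitness(f_i: float, f_0: float) -> float:
    """Relative fitness change ``(f_i - f_0) / f_0``; requires f_0 > 0."""
    if f_0 <= 0:
        raise ValueError(f"reference fitness must be positive, got {f_0}")
    return (f_i - f_0) / f_0


def default_offsets() -> np.ndarray:
    """Relative offsets -0.5..0.5 in steps of 0.05 (21 points)."""
    return np.round(np.arange(-10, 11) * 0.05, 10)


def cell_seed(seed: int, i: int, j: int, pattern_index: int) -> int:
    """Deterministic per-cell simulation seed, independent across cells."""
    return (seed * 1_000_003 + i * 8191 + j * 131 + pattern_index) % (2**31)


@dataclass
class RobustnessGrid:
    """Per-cell fitness of the intensity x duration grid.

    ``fitness[pattern]`` is a (n_duration, n_intensity) array of
    per-pattern fitness values; ``total`` the summed four-pattern fitness;
    ``delta_f`` its relative change against the centre cell (exactly 0
    there by construction).  ``spis`` keeps the simulated SPI of every
    cell for downstream partition/distance summaries.
    """

    intensity_offsets: np.ndarray
    duration_offsets: np.ndarray
    fitness: dict[str, np.ndarray]
    total: np.ndarray
    delta_f: np.ndarray
    delta_f_per_pattern: dict[str, np.ndarray]
    spis: dict[str, list[list[net.SPISequence | None]]]
    failed_cells: list[tuple[str, int, int]]

    @property
    def center_index(self) -> tuple[int, int]:
        i = int(np.argmin(np.abs(self.duration_offsets)))
        j = int(np.argmin(np.abs(self.intensity_offsets)))
        return i, j

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per (pattern, cell)."""
        rows = []
        i0, j0 = self.center_index
        for pattern, F in self.fitness.items():
            f0 = F[i0, j0]
            for i, dd in enumerate(self.duration_offsets):
                for j, di in enumerate(self.intensity_offsets):
                    dfp = self.delta_f_per_pattern[pattern][i, j]
                    rows.append(
                        {
                            "pattern": pattern,
                            "d_intensity": di,
                            "d_duration": dd,
                            "fitness": F[i, j],
                            "total_fitness": self.total[i, j],
                            "delta_f_ratio": self.delta_f[i, j],
                            "delta_f_pct": 100.0 * self.delta_f[i, j],
                            "delta_f_pattern_ratio": dfp,
                            "delta_f_pattern_pct": 100.0 * dfp,
                        }
                    )
        return pd.DataFrame(rows)


def run_grid(
    config: net.NetworkConfig,
    protocols: dict[str, net.StimulationProtocol],
    targets: dict[str, pat.TargetSet],
    seed: int = 0,
    offsets: np.ndarray | None = None,
) -> RobustnessGrid:
    """Simulate every (duration, intensity) offset cell for every pattern.

    Per-cell seeds are derived deterministically from ``seed`` and the
    cell index, so cells are independent yet the whole grid is
    reproducible.  A cell whose simulation fails is flagged and scored
    with the sentinel (near-zero) pattern fitness; the grid continues.
    """
    offs = default_offsets() if offsets is None else np.asarray(offsets, float)
    n = offs.size
    fitness = {p: np.zeros((n, n)) for p in pat.PATTERNS}
    spis: dict[str, list[list[net.SPISequence | None]]] = {
        p: [[None] * n for _ in range(n)] for p in pat.PATTERNS
    }
    failed: list[tuple[str, int, int]] = []
    for k, pattern in enumerate(pat.PATTERNS):
        proto = protocols[pattern]
        for i, dd in enumerate(offs):
            for j, di in enumerate(offs):
                scaled = proto.scaled(d_intensity=di, d_duration=dd)
                try:
                    result = net.simulate(
                        config, scaled, seed=cell_seed(seed, i, j, k)
                    )
                    onset, end = net.protocol_display_window(scaled)
                    spi = net.display_spi(result, onset, end)
                except ElectromotorError:
                    failed.append((pattern, i, j))
                    spi = None
                spis[pattern][i][j] = spi
                if spi is None:
                    fitness[pattern][i, j] = 1.0 / (1.0 + pat.MSE_SENTINEL)
                else:
                    _, f = pat.fitness_pattern(spi, targets[pattern])
                    fitness[pattern][i, j] = f
    total = sum(fitness.values())
    i0 = int(np.argmin(np.abs(offs)))
    f0 = total[i0, i0]
    delta = (total - f0) / f0
    delta[i0, i0] = 0.0  # centre is the reference itself: exact zero
    delta_per = {}
    for p in pat.PATTERNS:
        f0p = fitness[p][i0, i0]
        dp = (fitness[p] - f0p) / f0p if f0p > 0 else np.full((n, n), np.nan)
        if f0p > 0:
            dp[i0, i0] = 0.0
        delta_per[p] = dp
    return RobustnessGrid(
        intensity_offsets=offs,
        duration_offsets=offs.copy(),
        fitness=fitness,
        total=total,
        delta_f=delta,
        delta_f_per_pattern=delta_per,
        spis=spis,
        failed_cells=failed,
    )


@dataclass
class PartitionSummary:
    """Mean/SD interpolated SPI profiles of one fitness partition."""

    name: str
    count: int
    mean_profile: np.ndarray | None
    sd_profile: np.ndarray | None
    closest_target: np.ndarray | None


def partition_summaries(
    grid: RobustnessGrid,
    targets: dict[str, pat.TargetSet],
    thresholds: tuple[float, float] = (-100.0, 100.0),
) -> dict[str, dict[str, PartitionSummary]]:
    """Split each pattern's cells into worse/similar/better partitions.

    Thresholds are applied to the per-pattern ``delta_f`` on the percent
    scale (ratio x 100).  For each non-empty partition the mean and SD of
    the 50-point interpolated SPI profiles are returned together with the
    profile of the closest target exemplar (smallest shape-vector MSE to
    the partition mean).  Empty partitions are reported with count 0.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError(f"thresholds must be ordered, got {thresholds}")
    out: dict[str, dict[str, PartitionSummary]] = {}
    for pattern in pat.PATTERNS:
        dpct = 100.0 * grid.delta_f_per_pattern[pattern]
        masks = {
            "worse": dpct < lo,
            "similar": (dpct >= lo) & (dpct <= hi),
            "better": dpct > hi,
        }
        out[pattern] = {}
        for name, mask in masks.items():
            profiles = []
            for i, j in zip(*np.nonzero(mask)):
                spi = grid.spis[pattern][i][j]
                if spi is None or len(spi) < 2:
                    continue
                profiles.append(pat.interpolated_profile(spi))
            if not profiles:
                out[pattern][name] = PartitionSummary(name, 0, None, None, None)
                continue
            P = np.vstack(profiles)
            mean_profile = P.mean(axis=0)
            sd_profile = P.std(axis=0)
            mean_vec = pat.ShapeVector(np.diff(mean_profile), mean_profile.size)
            best, best_mse = None, np.inf
            for ex in targets[pattern].exemplars:
                m = pat.mse(mean_vec, pat.transform_spi(ex))
                if m < best_mse:
                    best_mse = m
                    best = pat.interpolated_profile(ex)
            out[pattern][name] = PartitionSummary(
                name, len(profiles), mean_profile, sd_profile, best
            )
    return out


def noise_robustness(
    config: net.NetworkConfig,
    protocols: dict[str, net.StimulationProtocol],
    targets: dict[str, pat.TargetSet],
    sigma_list=(0.0, 0.1, 0.2, 0.5),
    n_reps: int = 5,
    seed: int = 0,
    noise_mode: str = "tick",
) -> pd.DataFrame:
    """Four-pattern fitness under seeded Gaussian input noise.

    ``sigma`` is the noise SD as a fraction of each step amplitude,
    applied per integration tick (or once per step event).  Returns a
    long-format table (sigma, rep, pattern fitness columns, total).
    """
    rows = []
    for s_idx, sigma in enumerate(sigma_list):
        if sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {sigma}")
        for rep in range(n_reps):
            rep_seed = (seed * 9176 + s_idx * 257 + rep) % (2**31)
            simulated = {}
            for pattern in pat.PATTERNS:
                result = net.simulate(
                    config,
                    protocols[pattern],
                    seed=rep_seed,
                    noise_sigma=float(sigma),
                    noise_mode=noise_mode,
                )
                onset, end = net.protocol_display_window(protocols[pattern])
                simulated[pattern] = net.display_spi(result, onset, end)
            report = pat.fitness_total(simulated, targets)
            row = {"sigma": sigma, "rep": rep, "total": report.total}
            for p in pat.PATTERNS:
                row[f"f_{p}"] = report.per_pattern[p][1]
            rows.append(row)
    return pd.DataFrame(rows)


def pattern_distance_matrix(
    simulated: dict[str, list[net.SPISequence]],
    targets: dict[str, pat.TargetSet],
) -> pd.DataFrame:
    """Mean Euclidean distance between simulated and target displays.

    Entry (p, q) is the mean, over simulated SPIs of pattern p and target
    exemplars of pattern q, of the Euclidean distance between their
    duration-normalised interpolated IPI profiles (the comparison stage
    of the transform chain; the final differencing step belongs to the
    MSE fitness, where relative slopes matter — for class separation the
    interval durations themselves carry the discriminating structure).
    Untransformable SPIs are skipped.  Distances involving cessation
    rows/columns are included; display code may drop them (they sit on a
    larger scale than the other patterns).
    """
    sim_vecs: dict[str, list[np.ndarray]] = {}
    for p, spis in simulated.items():
        vecs = []
        for spi in spis:
            try:
                vecs.append(pat.interpolated_profile(spi))
            except Exception:
                continue
        sim_vecs[p] = vecs
    tgt_vecs = {
        q: [pat.interpolated_profile(ex) for ex in ts.exemplars]
        for q, ts in targets.items()
    }
    labels = [p for p in pat.PATTERNS if p in simulated]
    cols = [q for q in pat.PATTERNS if q in targets]
    M = np.full((len(labels), len(cols)), np.nan)
    for i, p in enumerate(labels):
        for j, q in enumerate(cols):
            ds = [
                float(np.linalg.norm(sv - tv))
                for sv in sim_vecs[p]
                for tv in tgt_vecs[q]
            ]
            if ds:
                M[i, j] = float(np.mean(ds))
    return pd.DataFrame(M, index=labels, columns=cols)


def grid_spis_by_pattern(
    grid: RobustnessGrid,
) -> dict[str, list[net.SPISequence]]:
    """Flatten the grid's per-cell SPIs into per-pattern lists (skipping
    failed and empty cells), ready for the distance matrix."""
    out: dict[str, list[net.SPISequence]] = {}
    for p in pat.PATTERNS:
        out[p] = [
            spi
            for row in grid.spis[p]
            for spi in row
            if spi is not None and len(spi) >= 2
        ]
    return out
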