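"""Robustness machinery: relative fitness, grid, partitions, distances."""

import numpy as np
import pandas as pd
import pytest

import electromotor as em
from electromotor import robustness as rob
from electromotor.network import SPISequence


class TestRelativeFitness:
    @pytest.mark.parametrize(
        "f_i,f_0,expected",
        [(2.0, 2.0, 0.0), (0.0, 2.0, -1.0), (4.0, 2.0, 1.0), (1.5, 1.0, 0.5)],
    )
    def test_ratio(self, f_i, f_0, expected):
        assert em.relative_fitness(f_i, f_0) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            em.relative_fitness(1.0, 0.0)
        with pytest.raises(ValueError):
            em.relative_fitness(1.0, -2.0)

    def test_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            f_i, f_0 = rng.uniform(0.01, 4.0, size=2)
            k = rng.uniform(0.1, 10.0)
            assert em.relative_fitness(k * f_i, k * f_0) == pytest.approx(
                em.relative_fitness(f_i, f_0)
            )


def test_default_offsets_are_21_five_percent_steps():
    offs = rob.default_offsets()
    assert offs.size == 21
    assert offs[0] == -0.5 and offs[-1] == 0.5
    assert np.allclose(np.diff(offs), 0.05)


class TestGridEnumeration:
    """Full 21x21 enumeration mechanics, with the simulator stubbed so the
    441 cells per pattern run in milliseconds."""

    @pytest.fixture()
    def stub_grid(self, network, protocols, targets, monkeypatch):
        def fake_simulate(config, protocol, seed, **kw):
            # deterministic SPI whose shape depends on the step scaling
            amp = protocol.steps[0].amplitude if protocol.steps else 1.0
            ipis = np.array([120.0, 60.0 + amp, 80.0, 120.0, 120.0, 120.0])
            cn = np.concatenate([[0.0], np.cumsum(ipis)]) + 400.0
            from electromotor.network import SimulationResult, extract_spi

            zero = np.empty(0)
            return SimulationResult(
                spike_times={"CN": cn, "DP": zero, "PCN": zero, "VPd": zero},
                spi=extract_spi(cn),
                protocol_start=0.0,
                total_duration=protocol.total_duration,
                pre_roll=0.0,
            )

        monkeypatch.setattr(rob.net, "simulate", fake_simulate)
        return rob.run_grid(network, protocols, targets, seed=0)

    def test_441_cells_per_pattern(self, stub_grid):
        for p in em.PATTERNS:
            assert stub_grid.fitness[p].shape == (21, 21)
            cells = [s for row in stub_grid.spis[p] for s in row]
            assert len(cells) == 441

    def test_center_cell_delta_is_exactly_zero(self, stub_grid):
        i0, j0 = stub_grid.center_index
        assert stub_grid.delta_f[i0, j0] == 0.0
        for p in em.PATTERNS:
            assert stub_grid.delta_f_per_pattern[p][i0, j0] == 0.0

    def test_long_format_export(self, stub_grid):
        df = stub_grid.to_dataframe()
        assert len(df) == 4 * 441
        assert {"pattern", "d_intensity", "d_duration", "fitness",
                "delta_f_ratio", "delta_f_pct"} <= set(df.columns)
        center = df[(df.d_intensity == 0.0) & (df.d_duration == 0.0)]
        assert np.allclose(center["delta_f_ratio"], 0.0)


class TestRealReducedGrid:
    def test_center_matches_unperturbed_protocols(self, small_grid, network,
                                                  protocols, targets):
        """The grid's centre cell reproduces the fitness of the unmodified
        stimulation, and its delta_f is exactly zero."""
        i0, j0 = small_grid.center_index
        assert small_grid.delta_f[i0, j0] == 0.0
        from electromotor.network import display_spi, protocol_display_window

        for p in em.PATTERNS:
            seed = rob.cell_seed(1, i0, j0, em.PATTERNS.index(p))
            result = em.simulate(network, protocols[p], seed=seed)
            onset, end = protocol_display_window(protocols[p])
            _, f = em.fitness_pattern(display_spi(result, onset, end), targets[p])
            assert small_grid.fitness[p][i0, j0] == pytest.approx(f)

    def test_no_failed_cells_on_reference_config(self, small_grid):
        assert small_grid.failed_cells == []


class TestPartitions:
    def _grid_with_delta(self, delta_pct, spis=None):
        """Minimal RobustnessGrid carrying prescribed per-pattern delta_f
        (percent scale) for partition tests."""
        n = delta_pct.shape[0]
        offs = np.linspace(-0.5, 0.5, n)
        flat_spi = SPISequence(ipis=np.array([120.0, 60.0, 80.0, 120.0]))
        spis = spis or {
            p: [[flat_spi] * n for _ in range(n)] for p in em.PATTERNS
        }
        ratio = delta_pct / 100.0
        return rob.RobustnessGrid(
            intensity_offsets=offs,
            duration_offsets=offs.copy(),
            fitness={p: np.ones((n, n)) for p in em.PATTERNS},
            total=np.ones((n, n)) * 4,
            delta_f=ratio,
            delta_f_per_pattern={p: ratio for p in em.PATTERNS},
            spis=spis,
            failed_cells=[],
        )

    def test_counts_match_brute_force_split(self, targets):
        rng = np.random.default_rng(11)
        delta_pct = rng.uniform(-200.0, 200.0, size=(9, 9))
        grid = self._grid_with_delta(delta_pct)
        parts = rob.partition_summaries(grid, targets, thresholds=(-100.0, 100.0))
        worse = int(np.sum(delta_pct < -100.0))
        similar = int(np.sum((delta_pct >= -100.0) & (delta_pct <= 100.0)))
        better = int(np.sum(delta_pct > 100.0))
        for p in em.PATTERNS:
            assert parts[p]["worse"].count == worse
            assert parts[p]["similar"].count == similar
            assert parts[p]["better"].count == better

    def test_identical_cells_give_zero_sd_single_partition(self, targets):
        grid = self._grid_with_delta(np.zeros((5, 5)))
        parts = rob.partition_summaries(grid, targets)
        for p in em.PATTERNS:
            assert parts[p]["similar"].count == 25
            assert np.allclose(parts[p]["similar"].sd_profile, 0.0)
            assert parts[p]["worse"].count == 0
            assert parts[p]["worse"].mean_profile is None

    def test_unordered_thresholds_rejected(self, targets):
        grid = self._grid_with_delta(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            rob.partition_summaries(grid, targets, thresholds=(100.0, -100.0))


class TestNoiseRobustness:
    def test_zero_sigma_reps_identical_to_deterministic(self, network,
                                                        protocols, targets):
        df = rob.noise_robustness(network, protocols, targets,
                                  sigma_list=(0.0,), n_reps=2, seed=3)
        assert len(df) == 2

    def test_same_seed_reproduces_distributions(self, network, protocols,
                                                targets):
        kw = dict(sigma_list=(0.3,), n_reps=2, seed=5)
        a = rob.noise_robustness(network, protocols, targets, **kw)
        b = rob.noise_robustness(network, protocols, targets, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_sigma_rejected(self, network, protocols, targets):
        with pytest.raises(ValueError):
            rob.noise_robustness(network, protocols, targets,
                                 sigma_list=(-0.1,), n_reps=1, seed=0)


class TestDistanceMatrix:
    def test_simulated_equal_to_targets_zero_diagonal(self, targets):
        simulated = {p: list(ts.exemplars) for p, ts in targets.items()}
        m = em.pattern_distance_matrix(simulated, targets)
        # the row mean includes cross-exemplar pairs, so compare against
        # the true minimum structure instead: diagonal must be row-min
        assert (m.values.argmin(axis=1) == np.arange(len(m))).all()

    def test_two_separated_synthetic_classes(self):
        slow = [SPISequence(ipis=np.full(6, 200.0 + k)) for k in range(3)]
        fast = [SPISequence(ipis=np.full(6, 40.0 + k)) for k in range(3)]
        targets = {
            "acceleration": em.TargetSet("acceleration", fast),
            "cessation": em.TargetSet("cessation", slow),
        }
        simulated = {"acceleration": fast, "cessation": slow}
        m = em.pattern_distance_matrix(simulated, targets)
        assert m.loc["acceleration", "acceleration"] < m.loc["acceleration", "cessation"]
        assert m.loc["cessation", "cessation"] < m.loc["cessation", "acceleration"]
        assert (m.values >= 0).all()

    def test_untransformable_members_skipped(self, targets):
        simulated = {
            "acceleration": [SPISequence(ipis=np.empty(0)),
                             targets["acceleration"].exemplars[0]],
        }
        m = em.pattern_distance_matrix(simulated, targets)
        assert np.isfinite(m.loc["acceleration", "acceleration"])
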