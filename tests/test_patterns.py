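"""Transform chain, fitness algebra and the synthetic target generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import electromotor as em
from electromotor.errors import GenerationError, TransformError
from electromotor.network import SPISequence
from electromotor.patterns import (
    MSE_SENTINEL,
    GeneratorSettings,
    ShapeVector,
    interpolated_profile,
)


def brute_force_transform(ipis, duration_units=1000.0, step_units=20.0):
    """Independent re-implementation of the transform chain: build the
    piecewise-linear profile (IPI value anchored at each interval's start,
    flat extension at the ends), sample it, difference it."""
    ipis = list(map(float, ipis))
    total = sum(ipis)
    anchors_x, anchors_y = [], []
    t = 0.0
    for p in ipis:
        anchors_x.append(t / total * duration_units)
        anchors_y.append(p)
        t += p
    samples = []
    n = int(round(duration_units / step_units))
    for k in range(1, n + 1):
        x = k * step_units
        if x <= anchors_x[0]:
            samples.append(anchors_y[0])
        elif x >= anchors_x[-1]:
            samples.append(anchors_y[-1])
        else:
            for i in range(len(anchors_x) - 1):
                if anchors_x[i] <= x <= anchors_x[i + 1]:
                    w = (x - anchors_x[i]) / (anchors_x[i + 1] - anchors_x[i])
                    samples.append(anchors_y[i] + w * (anchors_y[i + 1] - anchors_y[i]))
                    break
    return [samples[i + 1] - samples[i] for i in range(len(samples) - 1)]


class TestTransform:
    def test_constant_sequence_has_flat_shape(self):
        spi = SPISequence(ipis=[100.0, 100.0, 100.0, 100.0])
        vec = em.transform_spi(spi)
        assert np.allclose(vec.values, 0.0)

    def test_fifty_interpolation_points_by_default(self):
        spi = SPISequence(ipis=[120.0, 40.0, 60.0, 120.0])
        vec = em.transform_spi(spi)
        assert vec.n_points == 50
        assert vec.values.size == 49
        assert interpolated_profile(spi).size == 50

    @pytest.mark.parametrize(
        "ipis",
        [
            [100.0, 40.0, 40.0, 100.0, 100.0],
            [85.0, 90.0, 80.0, 85.0],
            [500.0, 140.0, 120.0],
            [33.0, 47.0, 150.0, 118.0, 122.0, 119.0],
        ],
    )
    def test_matches_independent_brute_force_oracle(self, ipis):
        vec = em.transform_spi(SPISequence(ipis=ipis))
        oracle = brute_force_transform(ipis)
        assert np.allclose(vec.values, oracle, atol=1e-9)

    def test_uniform_time_rescaling_scales_amplitude_only(self):
        """Multiplying all IPIs by a constant leaves the normalised axis
        unchanged and scales the shape vector linearly."""
        base = [120.0, 40.0, 60.0, 110.0, 125.0]
        v1 = em.transform_spi(SPISequence(ipis=base)).values
        v3 = em.transform_spi(SPISequence(ipis=[3.0 * x for x in base])).values
        assert np.allclose(v3, 3.0 * v1, atol=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        ipis=st.lists(st.floats(min_value=5.0, max_value=900.0),
                      min_size=2, max_size=30),
        k=st.floats(min_value=0.1, max_value=20.0),
    )
    def test_transform_properties_hold_for_arbitrary_sequences(self, ipis, k):
        """For any positive sequence: the shape vector has 49 entries, the
        flat tail of the profile matches the last IPI, and uniform time
        rescaling scales the vector linearly."""
        spi = SPISequence(ipis=np.asarray(ipis))
        vec = em.transform_spi(spi)
        assert vec.values.size == 49
        profile = interpolated_profile(spi)
        assert profile[-1] == pytest.approx(ipis[-1])
        scaled = em.transform_spi(SPISequence(ipis=k * np.asarray(ipis)))
        assert np.allclose(scaled.values, k * vec.values,
                           rtol=1e-9, atol=1e-7 * k)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(TransformError):
            em.transform_spi(SPISequence(ipis=[100.0]))
        with pytest.raises(TransformError):
            em.transform_spi(SPISequence(ipis=np.empty(0)))


class TestMse:
    def test_identical_vectors_zero(self):
        v = ShapeVector(values=np.arange(49, dtype=float), n_points=50)
        assert em.mse(v, v) == 0.0

    def test_unit_offset_vectors(self):
        a = ShapeVector(values=np.zeros(2), n_points=3)
        b = ShapeVector(values=np.ones(2), n_points=3)
        assert em.mse(a, b) == pytest.approx(1.0)

    def test_matches_independent_accumulation(self):
        rng = np.random.default_rng(42)
        a = ShapeVector(values=rng.normal(size=49), n_points=50)
        b = ShapeVector(values=rng.normal(size=49), n_points=50)
        acc = 0.0
        for x, y in zip(a.values, b.values):
            acc += (x - y) ** 2
        assert em.mse(a, b) == pytest.approx(acc / 49.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        a = ShapeVector(values=np.zeros(49), n_points=50)
        b = ShapeVector(values=np.zeros(24), n_points=25)
        with pytest.raises(ValueError):
            em.mse(a, b)


class TestFitness:
    def test_identity_match_scores_one(self, targets):
        ts = targets["scallop"]
        m, f = em.fitness_pattern(ts.exemplars[0], ts)
        assert m == pytest.approx(0.0, abs=1e-18)
        assert f == pytest.approx(1.0)

    def test_minimum_over_exemplars_drives_fitness(self, targets):
        """f_pat equals 1/(1+min MSE), the minimum taken over exemplars —
        cross-checked against per-exemplar MSEs computed independently."""
        simulated = SPISequence(ipis=[40.0, 52.0, 68.0, 120.0, 118.0, 122.0])
        ts = targets["scallop"]
        sim_vec = em.transform_spi(simulated)
        mses = [em.mse(sim_vec, em.transform_spi(e)) for e in ts.exemplars]
        m, f = em.fitness_pattern(simulated, ts)
        assert m == pytest.approx(min(mses))
        assert f == pytest.approx(1.0 / (1.0 + min(mses)))

    def test_half_fitness_at_unit_mse(self):
        assert 1.0 / (1.0 + 1.0) == 0.5  # the transfer law the code applies
        ts = em.TargetSet("scallop", [SPISequence(ipis=[100.0, 40.0, 80.0])])
        m, f = em.fitness_pattern(SPISequence(ipis=[100.0, 40.0, 80.0]), ts)
        assert f == 1.0 / (1.0 + m)

    def test_untransformable_simulation_gets_sentinel(self, targets):
        m, f = em.fitness_pattern(SPISequence(ipis=np.empty(0)),
                                  targets["acceleration"])
        assert m == MSE_SENTINEL
        assert 0.0 < f < 1e-5

    def test_four_perfect_matches_total_four(self, targets):
        simulated = {p: targets[p].exemplars[0] for p in em.PATTERNS}
        report = em.fitness_total(simulated, targets)
        assert report.total == pytest.approx(4.0)
        for p in em.PATTERNS:
            assert report.per_pattern[p][1] == pytest.approx(1.0)

    def test_total_is_sum_of_pattern_fitnesses(self, targets):
        rng = np.random.default_rng(3)
        simulated = {
            p: SPISequence(ipis=rng.uniform(30, 300, size=8)) for p in em.PATTERNS
        }
        report = em.fitness_total(simulated, targets)
        assert report.total == pytest.approx(
            sum(f for _, f in report.per_pattern.values())
        )
        assert 0.0 < report.total <= 4.0

    def test_missing_pattern_rejected(self, targets):
        simulated = {p: targets[p].exemplars[0] for p in em.PATTERNS[:3]}
        with pytest.raises(ValueError):
            em.fitness_total(simulated, targets)


class TestGenerator:
    def test_same_seed_reproduces_exemplars(self, reference):
        a = em.generate_targets("rasp", count=5, rng_seed=9,
                                settings=reference.generator)
        b = em.generate_targets("rasp", count=5, rng_seed=9,
                                settings=reference.generator)
        for x, y in zip(a.exemplars, b.exemplars):
            assert np.array_equal(x.ipis, y.ipis)

    def test_requested_count_generated(self, reference):
        ts = em.generate_targets("scallop", count=7, rng_seed=0,
                                 settings=reference.generator)
        assert len(ts.exemplars) == 7

    def test_scallop_minima_below_acceleration_minimum(self, reference):
        s = reference.generator
        sca = em.generate_targets("scallop", count=10, rng_seed=2, settings=s)
        acc_min = s.acceleration_plateau * (1.0 - s.jitter)
        for ex in sca.exemplars:
            assert np.min(ex.ipis) < acc_min

    def test_acceleration_run_regular_and_above_20ms(self, reference):
        """The accelerated run is near-regular (CV < 0.15) and every
        interval stays above 20 ms."""
        ts = em.generate_targets("acceleration", count=10, rng_seed=4,
                                 settings=reference.generator)
        for ex in ts.exemplars:
            assert np.all(ex.ipis > 20.0)
            run = ex.ipis[ex.ipis < 0.9 * reference.generator.resting_ipi]
            assert run.size >= 3
            assert np.std(run) / np.mean(run) < 0.15

    def test_cessation_pause_dominates_and_stays_under_one_second(self, reference):
        ts = em.generate_targets("cessation", count=10, rng_seed=5,
                                 settings=reference.generator)
        for ex in ts.exemplars:
            assert np.max(ex.ipis) / np.median(ex.ipis) >= 3.0
            assert np.max(ex.ipis) <= 1000.0

    def test_rasp_has_drop_then_sustained_tail(self, reference):
        s = reference.generator
        ts = em.generate_targets("rasp", count=6, rng_seed=6, settings=s)
        for ex in ts.exemplars:
            drop_at = int(np.argmin(ex.ipis))
            assert ex.ipis[drop_at] < s.scallop_floor * (1 + s.jitter) * 1.01
            tail = ex.ipis[drop_at + 1: drop_at + 4]
            assert np.all(tail < s.resting_ipi)

    def test_contradictory_floors_rejected(self):
        with pytest.raises(GenerationError):
            GeneratorSettings(scallop_floor=90.0, acceleration_plateau=85.0)

    def test_nonpositive_count_rejected(self, reference):
        with pytest.raises(GenerationError):
            em.generate_targets("scallop", count=0, rng_seed=0,
                                settings=reference.generator)


def test_shipped_targets_separate_by_pattern(targets):
    """Same-pattern exemplars sit closer to each other than to exemplars
    of other patterns (mean profile distance)."""
    profiles = {
        p: [interpolated_profile(e) for e in ts.exemplars]
        for p, ts in targets.items()
    }

    def mean_dist(a, b, same):
        ds = []
        for i, x in enumerate(a):
            for j, y in enumerate(b):
                if same and i == j:
                    continue
                ds.append(np.linalg.norm(x - y))
        return float(np.mean(ds))

    for p in em.PATTERNS:
        within = mean_dist(profiles[p], profiles[p], same=True)
        for q in em.PATTERNS:
            if q == p:
                continue
            assert within < mean_dist(profiles[p], profiles[q], same=False), (p, q)
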