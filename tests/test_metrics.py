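"""Fitting statistics: phases, Kuramoto order, coherence, FCD, KS distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroscales import (
    fc_matrix,
    fcd_distribution,
    instantaneous_phase,
    ks_distance,
    kuramoto_order,
    metastability,
    phase_coherence_matrix,
    phase_consistency_distribution,
)
from neuroscales.metrics import _order_series, phase_consistency_from_phases

DT = 0.72


def _sinusoids(freq=0.05, n=1, duration=1000.0, phase=0.0):
    t = np.arange(0, duration, DT)
    return np.tile(np.sin(2 * np.pi * freq * t + phase), (n, 1))


class TestInstantaneousPhase:
    def test_unwrapped_slope_matches_frequency(self):
        phases = instantaneous_phase(_sinusoids(0.05), DT).phases[0]
        interior = slice(100, -100)
        slope = np.polyfit(
            np.arange(phases.size)[interior] * DT, np.unwrap(phases)[interior], 1
        )[0]
        assert slope == pytest.approx(2 * np.pi * 0.05, rel=0.02)

    def test_quadrature_pair_offset(self):
        t = np.arange(0, 1000, DT)
        ts = np.vstack([np.sin(2 * np.pi * 0.05 * t), np.cos(2 * np.pi * 0.05 * t)])
        phases = instantaneous_phase(ts, DT).phases
        diff = np.angle(np.exp(1j * (phases[1] - phases[0])))[100:-100]
        assert np.abs(diff - np.pi / 2).max() < 0.05

    def test_output_range(self):
        rng = np.random.default_rng(0)
        phases = instantaneous_phase(rng.standard_normal((5, 400)), DT).phases
        assert phases.max() <= np.pi and phases.min() > -np.pi

    def test_constant_region_rejected_by_index(self):
        ts = np.random.default_rng(1).standard_normal((3, 200))
        ts[1] = 4.2
        with pytest.raises(ValueError, match=r"\[1\]"):
            instantaneous_phase(ts, DT)


class TestKuramotoOrder:
    def test_full_synchrony(self):
        assert kuramoto_order(np.full(50, 0.7)) == pytest.approx(1.0)

    def test_antipodal_cancellation(self):
        assert kuramoto_order(np.array([0.0, np.pi])) == pytest.approx(0.0, abs=1e-12)

    def test_fourfold_symmetry(self):
        phases = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert kuramoto_order(phases) == pytest.approx(0.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kuramoto_order(np.array([]))


class TestMetastability:
    def test_identical_series_gives_zero(self):
        ts = _sinusoids(0.05, n=8)
        assert metastability(ts, DT) == pytest.approx(0.0, abs=1e-9)

    def test_population_sd_convention(self):
        # the convention is pinned by SD({0.4, 0.6}) = 0.1 (divide by N)
        assert np.std([0.4, 0.6]) == pytest.approx(0.1)

    def test_independent_phases_fluctuate(self):
        rng = np.random.default_rng(2)
        t = np.arange(500) * DT
        ts = np.array(
            [np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi)) for _ in range(50)]
        )
        assert metastability(ts, DT) > 0

    def test_invariant_to_global_phase_rotation(self):
        rng = np.random.default_rng(3)
        phases = rng.uniform(-np.pi, np.pi, size=(20, 300))
        r0 = _order_series(phases)
        r1 = _order_series(phases + 1.234)
        assert np.allclose(r0, r1)
        assert np.std(r0) == pytest.approx(np.std(r1))


class TestPhaseCoherence:
    def test_equal_phases_all_ones(self):
        assert np.allclose(phase_coherence_matrix(np.full(6, 1.1)), 1.0)

    def test_quadrature_entry_zero(self):
        M = phase_coherence_matrix(np.array([0.0, np.pi / 2]))
        assert M[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.diag(M), 1.0)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(4)
        phi = rng.uniform(-np.pi, np.pi, size=5)
        M = phase_coherence_matrix(phi)
        for j in range(5):
            for k in range(5):
                assert M[j, k] == pytest.approx(np.cos(phi[j] - phi[k]))


class TestPhaseConsistency:
    def test_static_configuration_gives_all_ones(self):
        rng = np.random.default_rng(5)
        phi = rng.uniform(-np.pi, np.pi, size=6)
        phases = np.tile(phi[:, None], (1, 10))
        sample = phase_consistency_from_phases(phases)
        assert np.allclose(sample, 1.0)

    def test_values_bounded(self):
        rng = np.random.default_rng(6)
        ts = rng.standard_normal((8, 300))
        sample = phase_consistency_distribution(ts, DT)
        assert sample.min() >= -1.0 - 1e-12 and sample.max() <= 1.0 + 1e-12
        assert sample.size == 300 * 299 // 2

    def test_two_block_alternation_matches_enumeration(self):
        # two alternating phase configurations over 4 time points; oracle is
        # an explicit double loop over time pairs
        rng = np.random.default_rng(7)
        a = rng.uniform(-np.pi, np.pi, size=6)
        b = rng.uniform(-np.pi, np.pi, size=6)
        phases = np.column_stack([a, b, a, b])
        sample = sorted(phase_consistency_from_phases(phases))
        iu = np.triu_indices(6, k=1)
        vecs = [np.cos(p[:, None] - p[None, :])[iu] for p in (a, b, a, b)]
        expected = sorted(
            np.corrcoef(vecs[t1], vecs[t2])[0, 1]
            for t1 in range(4)
            for t2 in range(t1 + 1, 4)
        )
        assert np.allclose(sample, expected)


class TestFcMatrix:
    def test_identical_and_negated_regions(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(50)
        fc = fc_matrix(np.vstack([x, x, -x]))
        assert fc[0, 1] == pytest.approx(1.0)
        assert fc[0, 2] == pytest.approx(-1.0)

    def test_matches_pairwise_formula(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((4, 10))
        fc = fc_matrix(X)
        for i in range(4):
            for j in range(4):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert fc[i, j] == pytest.approx(expected)

    def test_zero_variance_region_rejected(self):
        X = np.random.default_rng(10).standard_normal((3, 20))
        X[2] = 1.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            fc_matrix(X)


class TestFcd:
    def test_window_count_for_15_minutes(self):
        # floor((900 - 80) / 40) + 1 = 21 windows
        rng = np.random.default_rng(11)
        bold = rng.standard_normal((10, int(900 / DT)))
        fcd, sample = fcd_distribution(bold, DT)
        assert fcd.shape == (21, 21)
        assert sample.size == 21 * 20 // 2

    def test_diagonal_is_one(self):
        rng = np.random.default_rng(12)
        fcd, _ = fcd_distribution(rng.standard_normal((8, 400)), DT)
        assert np.allclose(np.diag(fcd), 1.0)

    def test_two_state_series_has_wider_fcd_than_stationary(self):
        rng = np.random.default_rng(13)
        n, T = 10, 500
        shared = rng.standard_normal(T)
        stationary = 0.7 * shared + 0.3 * rng.standard_normal((n, T))
        half = T // 2
        twostate = np.empty((n, T))
        twostate[: n // 2, :half] = shared[:half] + 0.1 * rng.standard_normal((n // 2, half))
        twostate[n // 2 :, :half] = rng.standard_normal((n - n // 2, half))
        twostate[: n // 2, half:] = rng.standard_normal((n // 2, T - half))
        twostate[n // 2 :, half:] = shared[half:] + 0.1 * rng.standard_normal((n - n // 2, T - half))
        _, s_stat = fcd_distribution(stationary, DT)
        _, s_two = fcd_distribution(twostate, DT)
        assert np.std(s_two) > np.std(s_stat)

    def test_rejects_fewer_than_two_windows(self):
        with pytest.raises(ValueError, match="window"):
            fcd_distribution(np.random.default_rng(14).standard_normal((5, 100)), DT)

    def test_window_count_closed_form(self):
        # oracle: explicit enumeration of sliding-window start positions
        rng = np.random.default_rng(15)
        for _ in range(50):
            T = int(rng.integers(300, 1500))
            w_s = float(rng.integers(40, 120))
            s_s = float(rng.integers(20, 80))
            w, s = int(round(w_s / DT)), int(round(s_s / DT))
            expected = len([a for a in range(0, T - w + 1, s)])
            if expected < 2:
                continue
            bold = rng.standard_normal((6, T))
            fcd, _ = fcd_distribution(bold, DT, window_s=w_s, step_s=s_s)
            assert fcd.shape[0] == expected


class TestKsDistance:
    def test_identical_samples(self):
        x = np.array([0.1, 0.5, 0.9])
        assert ks_distance(x, x) == 0.0

    def test_disjoint_supports(self):
        assert ks_distance([0, 0, 0], [1, 1, 1]) == 1.0

    def test_shifted_integer_sample(self):
        assert ks_distance([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(0.25)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            ks_distance([], [1.0])

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_symmetry_and_triangle_inequality(self, data):
        sample = st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=20)
        a = np.array(data.draw(sample))
        b = np.array(data.draw(sample))
        c = np.array(data.draw(sample))
        assert ks_distance(a, b) == pytest.approx(ks_distance(b, a))
        assert ks_distance(a, c) <= ks_distance(a, b) + ks_distance(b, c) + 1e-12
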