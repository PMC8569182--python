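"""Point-process events, Marchenko–Pastur component count, ICA, projection."""

import numpy as np
import pytest

from neuroscales import (
    EventMatrix,
    NetworkSet,
    estimate_n_networks,
    extract_networks,
    normalize_events,
    point_process_binarize,
    project_activity,
)
from conftest import greedy_match


def _crossing_oracle(z, thr):
    """Hand-loop definition: event where z crosses thr from below."""
    out = np.zeros_like(z)
    for t in range(z.size):
        above = z[t] > thr
        was_above = z[t - 1] > thr if t > 0 else False
        out[t] = 1.0 if (above and not was_above) else 0.0
    return out


class TestPointProcessBinarize:
    def test_upward_crossings_match_hand_trace(self):
        # z-scored trace goes sub, sub, supra, supra, sub, supra, then stays
        # sub: onsets land at the two upward crossings only
        base = np.array([0.0, 0.0, 5.0, 5.0, 0.0, 5.0, 0.0, 0.0, 0.0, 0.0])
        z = (base - base.mean()) / base.std()
        assert (z > 1.0).tolist() == [False, False, True, True, False, True,
                                      False, False, False, False]
        em = point_process_binarize(base[None, :], threshold_sd=1.0)
        expected = [0, 0, 1, 0, 0, 1, 0, 0, 0, 0]
        assert em.events[0].tolist() == expected
        # consecutive supra-threshold samples yield a single onset event
        assert em.events[0].sum() == 2

    def test_crossing_matches_oracle_on_random_series(self):
        rng = np.random.default_rng(0)
        ts = rng.standard_normal((6, 300))
        em = point_process_binarize(ts, threshold_sd=1.0)
        for i in range(6):
            z = (ts[i] - ts[i].mean()) / ts[i].std()
            assert np.array_equal(em.events[i], _crossing_oracle(z, 1.0))

    def test_level_mode_marks_all_supra_threshold(self):
        rng = np.random.default_rng(1)
        ts = rng.standard_normal((3, 200))
        em = point_process_binarize(ts, mode="level")
        for i in range(3):
            z = (ts[i] - ts[i].mean()) / ts[i].std()
            assert np.array_equal(em.events[i], (z > 1.0).astype(float))

    def test_higher_threshold_never_adds_events(self):
        rng = np.random.default_rng(2)
        ts = rng.standard_normal((5, 500))
        counts = [
            point_process_binarize(ts, threshold_sd=thr).events.sum(axis=1)
            for thr in (0.5, 1.0, 1.5, 2.0)
        ]
        for lo, hi in zip(counts[:-1], counts[1:]):
            assert np.all(hi <= lo)

    def test_zero_variance_region_rejected(self):
        ts = np.random.default_rng(3).standard_normal((3, 50))
        ts[1] = 2.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            point_process_binarize(ts)


class TestNormalizeEvents:
    def test_alternating_row_z_scores_to_unit_pattern(self):
        em = EventMatrix(events=np.array([[0.0, 1.0, 0.0, 1.0]]), raw=True,
                         threshold_sd=1.0)
        out = normalize_events(em)
        assert np.allclose(out.events, [[-1.0, 1.0, -1.0, 1.0]])

    def test_zero_mean_unit_variance_contract(self):
        rng = np.random.default_rng(4)
        em = EventMatrix(events=(rng.random((8, 400)) < 0.1).astype(float),
                         raw=True, threshold_sd=1.0)
        out = normalize_events(em)
        assert np.abs(out.events.mean(axis=1)).max() < 1e-10
        assert np.abs(out.events.var(axis=1) - 1.0).max() < 1e-10
        assert out.normalization == "zscore"

    def test_constant_row_excluded_and_recorded(self):
        events = (np.random.default_rng(5).random((4, 100)) < 0.2).astype(float)
        events[2] = 0.0  # no events at all
        em = EventMatrix(events=events, raw=True, threshold_sd=1.0)
        with pytest.warns(UserWarning, match="constant event trains"):
            out = normalize_events(em)
        assert out.excluded_regions == [2]
        assert out.events.shape[0] == 3
        assert list(out.region_indices) == [0, 1, 3]

    def test_rejects_already_normalized_input(self):
        em = EventMatrix(events=np.array([[0.0, 1.0]]), raw=True, threshold_sd=1.0)
        out = normalize_events(em)
        with pytest.raises(ValueError):
            normalize_events(out)


class TestEstimateNNetworks:
    def test_pure_noise_rarely_exceeds_the_edge(self):
        # Monte-Carlo under the null: i.i.d. Gaussian rows, 100 x 5000
        counts = []
        for seed in range(10):
            E = np.random.default_rng(seed).standard_normal((100, 5000))
            E = (E - E.mean(1, keepdims=True)) / E.std(1, keepdims=True)
            counts.append(estimate_n_networks(E, enforce_min=False))
        assert sum(c == 0 for c in counts) >= 9

    def test_planted_rank_three_mixture_detected(self):
        rng = np.random.default_rng(7)
        n, T, k = 40, 4000, 3
        loadings = rng.standard_normal((n, k))
        sources = rng.standard_normal((k, T))
        E = loadings @ sources + 0.5 * rng.standard_normal((n, T))
        E = (E - E.mean(1, keepdims=True)) / E.std(1, keepdims=True)
        count = estimate_n_networks(E, enforce_min=False)
        assert count == 3
        assert count <= min(n, T)

    def test_zero_count_lifted_to_one_with_warning(self):
        E = np.random.default_rng(1).standard_normal((100, 5000))
        with pytest.warns(UserWarning, match="forcing one component"):
            assert estimate_n_networks(E) == 1

    def test_rejects_tiny_matrices(self):
        with pytest.raises(ValueError):
            estimate_n_networks(np.random.default_rng(0).standard_normal((5, 100)))


@pytest.fixture(scope="module")
def events_norm(ground_truth_small):
    raw = point_process_binarize(ground_truth_small.bold)
    return normalize_events(raw)


class TestExtractNetworks:

    def test_unit_norm_columns(self, events_norm):
        nets = extract_networks(events_norm, 3, seed=0)
        assert np.allclose(np.linalg.norm(nets.W, axis=0), 1.0, atol=1e-9)

    def test_same_seed_bit_identical(self, events_norm):
        a = extract_networks(events_norm, 3, seed=5)
        b = extract_networks(events_norm, 3, seed=5)
        assert np.array_equal(a.W, b.W)

    def test_recovers_planted_maps_at_snr_five(self):
        from neuroscales import generate_ground_truth_bold

        gt = generate_ground_truth_bold(60, 3, (0.5, 0.25, 0.25), dt=0.72,
                                        duration=7200.0, snr=5.0, seed=11)
        E = normalize_events(point_process_binarize(gt.bold))
        nets = extract_networks(E, 3, seed=0)
        matches = greedy_match(gt.networks_true, nets.W)
        assert min(matches) > 0.9

    def test_rejects_bad_component_counts(self, events_norm):
        with pytest.raises(ValueError):
            extract_networks(events_norm, 0, seed=0)
        with pytest.raises(ValueError):
            extract_networks(events_norm, 10_000, seed=0)


class TestProjectActivity:
    def test_self_and_orthogonal_projection(self):
        w = np.zeros((4, 2))
        w[0, 0] = 1.0
        w[1, 1] = 1.0
        nets = NetworkSet(W=w, n_networks=2, seed=0)
        E = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0], [0.0, 0.0]])
        A = project_activity(E, nets).A
        assert A[0, 0] == 1.0 and A[1, 0] == 0.0  # frame equals w_0
        assert A[0, 1] == 0.0 and A[1, 1] == 1.0  # frame orthogonal to w_0

    def test_matches_outer_product_bilinear_oracle(self):
        rng = np.random.default_rng(8)
        W = rng.standard_normal((5, 2))
        W /= np.linalg.norm(W, axis=0)
        nets = NetworkSet(W=W, n_networks=2, seed=0)
        E = rng.standard_normal((5, 7))
        A = project_activity(E, nets).A
        for c in range(2):
            P = np.outer(W[:, c], W[:, c])
            for b in range(7):
                assert A[c, b] == pytest.approx(E[:, b] @ P @ E[:, b])

    def test_sign_of_network_is_irrelevant(self):
        rng = np.random.default_rng(9)
        W = rng.standard_normal((6, 3))
        W /= np.linalg.norm(W, axis=0)
        E = rng.standard_normal((6, 20))
        a = project_activity(E, NetworkSet(W=W, n_networks=3, seed=0)).A
        b = project_activity(E, NetworkSet(W=-W, n_networks=3, seed=0)).A
        assert np.allclose(a, b)

    def test_dimension_mismatch_rejected(self):
        nets = NetworkSet(W=np.eye(4)[:, :2], n_networks=2, seed=0)
        with pytest.raises(ValueError, match="regions"):
            project_activity(np.zeros((5, 3)), nets)

    def test_nonnegative_by_construction(self):
        rng = np.random.default_rng(10)
        W = rng.standard_normal((8, 4))
        W /= np.linalg.norm(W, axis=0)
        A = project_activity(rng.standard_normal((8, 50)),
                             NetworkSet(W=W, n_networks=4, seed=0)).A
        assert A.min() >= 0.0
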