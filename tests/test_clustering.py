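"""Modified K-means, GEV, group aggregation and canonical ordering."""

from __future__ import annotations

import numpy as np
import pytest

import eegmicrostates as em
from eegmicrostates.clustering import spatial_correlation
from eegmicrostates.errors import ParameterError


def _orthonormal_maps(n_channels: int, k: int, rng) -> np.ndarray:
    """Random zero-mean orthonormal topographies (independent construction)."""
    x = rng.normal(size=(n_channels, k + 1))
    x -= x.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(x)
    maps = q[:, :k].T
    maps -= maps.mean(axis=1, keepdims=True)
    return maps / np.linalg.norm(maps, axis=1, keepdims=True)


def _matched_abs_corr(found: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Best |r| per true template under one-to-one matching."""
    import itertools

    c = np.abs(spatial_correlation(found, truth))
    best = None
    for perm in itertools.permutations(range(truth.shape[0])):
        vals = np.array([c[perm[j], j] for j in range(truth.shape[0])])
        if best is None or vals.sum() > best.sum():
            best = vals
    return best


class TestModifiedKmeans:
    def test_noise_free_recovery_with_polarity_flips(self, rng):
        truth = _orthonormal_maps(16, 4, rng)
        signs = rng.choice([-1.0, 1.0], size=200)
        samples = truth[rng.integers(0, 4, size=200)] * signs[:, None]
        maps = em.modified_kmeans(samples, k=4, n_restarts=5, seed=0)
        np.testing.assert_allclose(_matched_abs_corr(maps.maps, truth), 1.0,
                                   atol=1e-10)
        assert maps.gev == pytest.approx(1.0, abs=1e-10)

    def test_polarity_invariance_of_result(self, rng):
        truth = _orthonormal_maps(16, 4, rng)
        idx = rng.integers(0, 4, size=120)
        samples = truth[idx] + 0.05 * rng.normal(size=(120, 16))
        flipped = samples.copy()
        flipped[::2] *= -1
        a = em.modified_kmeans(samples, k=4, n_restarts=3, seed=7)
        b = em.modified_kmeans(flipped, k=4, n_restarts=3, seed=7)
        c = np.abs(spatial_correlation(a.maps, b.maps))
        np.testing.assert_allclose(_matched_abs_corr(a.maps, b.maps), 1.0,
                                   atol=1e-9)
        assert a.gev == pytest.approx(b.gev, abs=1e-12)

    def test_noisy_recovery_generator_conditions(self, templates64, rng):
        # 200 peak maps at the generator's default template-to-noise ratio
        idx = rng.integers(0, 4, size=200)
        noise = rng.normal(size=(200, 64))
        noise /= np.linalg.norm(noise, axis=1, keepdims=True)
        samples = templates64.maps[idx] + noise / 4.0
        maps = em.modified_kmeans(samples, k=4, n_restarts=20, seed=3)
        assert _matched_abs_corr(maps.maps, templates64.maps).min() >= 0.95

    def test_objective_nondecreasing(self, templates64, rng):
        idx = rng.integers(0, 4, size=300)
        samples = templates64.maps[idx] + 0.3 * rng.normal(size=(300, 64))
        maps = em.modified_kmeans(samples, k=4, n_restarts=1, max_iter=50, seed=1)
        hist = np.array(maps.gev_history)
        assert np.all(np.diff(hist) >= -1e-12)

    def test_scale_invariance(self, templates64, rng):
        idx = rng.integers(0, 4, size=100)
        samples = templates64.maps[idx] + 0.2 * rng.normal(size=(100, 64))
        a = em.modified_kmeans(samples, k=4, n_restarts=3, seed=5)
        b = em.modified_kmeans(samples * 17.3, k=4, n_restarts=3, seed=5)
        np.testing.assert_allclose(np.abs(a.maps), np.abs(b.maps), atol=1e-9)
        assert a.gev == pytest.approx(b.gev, abs=1e-12)

    def test_deterministic_for_fixed_seed(self, templates64, rng):
        idx = rng.integers(0, 4, size=80)
        samples = templates64.maps[idx] + 0.3 * rng.normal(size=(80, 64))
        a = em.modified_kmeans(samples, k=4, seed=11)
        b = em.modified_kmeans(samples, k=4, seed=11)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_k_larger_than_samples_rejected(self, rng):
        with pytest.raises(ParameterError):
            em.modified_kmeans(rng.normal(size=(3, 8)), k=4)

    def test_unit_norm_zero_mean_outputs(self, templates64, rng):
        idx = rng.integers(0, 4, size=60)
        samples = templates64.maps[idx] + 0.3 * rng.normal(size=(60, 64))
        maps = em.modified_kmeans(samples, k=4, seed=2)
        np.testing.assert_allclose(np.linalg.norm(maps.maps, axis=1), 1.0,
                                   atol=1e-10)
        np.testing.assert_allclose(maps.maps.mean(axis=1), 0.0, atol=1e-10)


class TestComputeGev:
    def test_identical_maps_give_one(self, templates64):
        gev = em.compute_gev(templates64, templates64.maps.copy())
        assert gev == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_maps_give_zero(self, rng):
        both = _orthonormal_maps(16, 8, rng)
        maps = em.MicrostateMaps(both[:4], list("ABCD"))
        gev = em.compute_gev(maps, both[4:])
        assert gev == pytest.approx(0.0, abs=1e-10)

    def test_matches_bruteforce_double_loop(self, rng):
        templates = _orthonormal_maps(10, 3, rng)
        maps = em.MicrostateMaps(templates, ["A", "B", "C"])
        peaks = rng.normal(size=(25, 10)) * rng.uniform(0.5, 3, size=(25, 1))
        got = em.compute_gev(maps, peaks)
        # independent evaluation straight from the GEV definition
        num = den = 0.0
        for t in range(25):
            v = peaks[t] - peaks[t].mean()
            gfp = np.sqrt(np.mean(v**2))
            best = 0.0
            for k in range(3):
                a = templates[k] - templates[k].mean()
                r = abs(
                    np.dot(v, a) / (np.linalg.norm(v) * np.linalg.norm(a))
                )
                best = max(best, r)
            num += gfp**2 * best**2
            den += gfp**2
        assert got == pytest.approx(num / den, abs=1e-12)


class TestAggregation:
    def test_identical_subject_maps_recovered(self, templates64):
        subject_maps = [
            em.MicrostateMaps(templates64.maps.copy(), list("ABCD"))
            for _ in range(5)
        ]
        group = em.aggregate_group_maps(subject_maps, k=4, seed=0)
        assert group.level == "group"
        np.testing.assert_allclose(
            _matched_abs_corr(group.maps, templates64.maps), 1.0, atol=1e-9
        )

    def test_noisy_subject_maps_recovered(self, templates64, rng):
        subject_maps = []
        for _ in range(12):
            noisy = templates64.maps + 0.05 * rng.normal(size=(4, 64))
            subject_maps.append(em.MicrostateMaps(noisy, list("ABCD")))
        group = em.aggregate_group_maps(subject_maps, k=4, seed=1)
        assert _matched_abs_corr(group.maps, templates64.maps).min() >= 0.98

    def test_single_subject_rejected(self, templates64):
        with pytest.raises(ParameterError):
            em.aggregate_group_maps(
                [em.MicrostateMaps(templates64.maps, list("ABCD"))], k=4
            )


class TestCanonicalOrdering:
    def test_identity_permutation(self, templates64):
        ordered = em.order_maps_canonical(templates64)
        assert ordered.labels == ["A", "B", "C", "D"]
        np.testing.assert_allclose(ordered.maps, templates64.maps, atol=1e-12)

    def test_reversed_order_recovered(self, templates64):
        shuffled = em.MicrostateMaps(templates64.maps[::-1].copy(),
                                     ["M1", "M2", "M3", "M4"])
        ordered = em.order_maps_canonical(shuffled)
        assert ordered.labels == ["A", "B", "C", "D"]
        np.testing.assert_allclose(ordered.maps, templates64.maps, atol=1e-12)

    def test_shuffle_with_noise_recovered_reliably(self, templates64):
        rng = np.random.default_rng(99)
        n_ok = 0
        trials = 1000
        for _ in range(trials):
            perm = rng.permutation(4)
            # per-channel noise sd 0.03 -> map-level perturbation norm ~0.24
            noisy = templates64.maps[perm] + 0.03 * rng.normal(size=(4, 64))
            signs = rng.choice([-1.0, 1.0], size=4)[:, None]
            ordered = em.order_maps_canonical(
                em.MicrostateMaps(noisy * signs, ["M1", "M2", "M3", "M4"])
            )
            # recovered map j should match canonical template j
            r = np.abs(
                np.diag(spatial_correlation(ordered.maps, templates64.maps))
            )
            n_ok += bool(r.min() > 0.8)
        assert n_ok / trials >= 0.99

    def test_exhaustive_matches_greedy_when_separated(self, templates64, rng):
        perm = rng.permutation(4)
        shuffled = em.MicrostateMaps(templates64.maps[perm].copy(),
                                     ["M1", "M2", "M3", "M4"])
        ordered = em.order_maps_canonical(shuffled)
        # greedy: per reference class, take the best-correlating map
        c = np.abs(spatial_correlation(shuffled.maps, templates64.maps))
        greedy = c.argmax(axis=0)
        np.testing.assert_array_equal(ordered.maps, shuffled.maps[greedy])

    def test_k_mismatch_rejected(self, templates64):
        three = em.MicrostateMaps(templates64.maps[:3].copy(), ["M1", "M2", "M3"])
        with pytest.raises(ParameterError):
            em.order_maps_canonical(three, templates64)
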