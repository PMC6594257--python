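"""Coherence, partial coherence, network efficiency, directed coherence."""

import itertools

import numpy as np
import pytest

from netdyn import (
    CoherenceGraph,
    MVARModel,
    MultichannelRecording,
    band_mean_pdc,
    coherence,
    coherence_graph,
    cross_spectral_matrix,
    extended_pdc,
    fit_mvar,
    gen_coupled_pair,
    gen_mvar_network,
    global_efficiency,
    partial_coherence,
    slice_epochs,
)

from conftest import FS, make_recording


def _epochs(data, epoch_s=8.0):
    return slice_epochs(make_recording(data), epoch_s)


def brute_force_efficiency(weights):
    """Oracle: exhaustive simple-path shortest distances, mean inverse."""
    n = len(weights)
    with np.errstate(divide="ignore"):
        dist = np.where(weights > 0, 1.0 / np.where(weights > 0, weights, 1), np.inf)
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            best = np.inf
            for k in range(0, n - 2 + 1):
                for mids in itertools.permutations(
                    [m for m in range(n) if m not in (i, j)], k
                ):
                    path = [i, *mids, j]
                    d = sum(dist[a][b] for a, b in zip(path, path[1:]))
                    best = min(best, d)
            total += 1.0 / best if np.isfinite(best) and best > 0 else 0.0
            pairs += 1
    return total / pairs


class TestCoherence:
    def test_self_coherence_is_one(self, white_recording):
        S = cross_spectral_matrix(slice_epochs(white_recording, 8.0))
        c = coherence(S, "ch0", "ch0")
        assert np.allclose(c.coh, 1.0)

    def test_shared_signal_closed_form(self):
        # x = s+n1, y = s+n2 → |S_xy|²/(S_xx·S_yy) = 1/4
        xy = gen_coupled_pair(FS, 220.0, 1.0, seed=8)
        S = cross_spectral_matrix(_epochs(xy))
        assert S.n_blocks_averaged >= 200
        c = coherence(S, "ch0", "ch1")
        assert c.coh.mean() == pytest.approx(0.25, abs=0.05)

    def test_independent_channels_estimator_bias(self, white_recording):
        S = cross_spectral_matrix(slice_epochs(white_recording, 8.0))
        c = coherence(S, "ch0", "ch1")
        assert c.coh.mean() < 0.02

    def test_symmetry_and_gain_invariance(self, rng):
        data = rng.standard_normal((int(FS * 40), 2))
        data[:, 1] += 0.5 * data[:, 0]
        S1 = cross_spectral_matrix(_epochs(data))
        scaled = data * np.array([3.0, 0.2])
        S2 = cross_spectral_matrix(_epochs(scaled))
        c_ab = coherence(S1, "ch0", "ch1").coh
        c_ba = coherence(S1, "ch1", "ch0").coh
        c_scaled = coherence(S2, "ch0", "ch1").coh
        assert np.allclose(c_ab, c_ba)
        assert np.allclose(c_ab, c_scaled, atol=1e-10)

    def test_monotone_in_shared_gain(self):
        means = []
        for g in (0.0, 0.5, 1.0, 2.0):
            xy = gen_coupled_pair(FS, 120.0, g, seed=5)
            S = cross_spectral_matrix(_epochs(xy))
            means.append(coherence(S, "ch0", "ch1").coh.mean())
        assert np.all(np.diff(means) > 0)
        # closed form (g²/(g²+1))²
        for g, got in zip((0.5, 1.0, 2.0), means[1:]):
            expect = (g**2 / (g**2 + 1)) ** 2
            assert got == pytest.approx(expect, abs=0.05)


class TestCoherenceGraph:
    def test_identical_channels_full_weights(self, rng):
        x = rng.standard_normal(int(FS * 40))
        S = cross_spectral_matrix(_epochs(np.column_stack([x, x, x])))
        g = coherence_graph(S, (4.0, 70.0))
        assert np.allclose(g.weights, 1.0, atol=1e-9)

    def test_band_splitting_weighted_average(self, rng):
        data = rng.standard_normal((int(FS * 60), 2))
        data[:, 1] += data[:, 0]
        S = cross_spectral_matrix(_epochs(data))
        full = coherence_graph(S, (4.0, 70.0)).weights[0, 1]
        lo = coherence_graph(S, (4.0, 30.0)).weights[0, 1]
        hi = coherence_graph(S, (30.0, 70.0)).weights[0, 1]
        n_lo, n_hi = 26, 40  # 1 Hz bins, half-open bands
        assert full == pytest.approx((n_lo * lo + n_hi * hi) / (n_lo + n_hi))

    def test_empty_band_rejected(self, white_recording):
        S = cross_spectral_matrix(slice_epochs(white_recording, 8.0))
        with pytest.raises(ValueError):
            coherence_graph(S, (400.0, 500.0))


class TestGlobalEfficiency:
    def test_complete_unit_graph(self):
        g = CoherenceGraph(list("abcd"), np.ones((4, 4)))
        assert global_efficiency(g) == pytest.approx(1.0)

    def test_vanishing_weights_limit(self):
        w = np.full((4, 4), 1e-9)
        np.fill_diagonal(w, 1.0)
        g = CoherenceGraph(list("abcd"), w)
        assert global_efficiency(g) < 1e-6

    def test_hand_worked_triangle(self):
        # w(AB)=w(BC)=1, w(AC)=0.1 → D(AC)=min(10, 2)=2 → (1+1+1/2)/3
        w = np.array([[1.0, 1.0, 0.1], [1.0, 1.0, 1.0], [0.1, 1.0, 1.0]])
        g = CoherenceGraph(list("abc"), w)
        assert global_efficiency(g) == pytest.approx(5 / 6)

    def test_matches_exhaustive_paths_on_random_graphs(self, rng):
        for _ in range(250):
            n = rng.integers(2, 6)
            w = rng.random((n, n))
            w = 0.5 * (w + w.T)
            w[rng.random((n, n)) < 0.2] = 0.0  # some absent edges
            w = 0.5 * (w + w.T)
            np.fill_diagonal(w, 1.0)
            g = CoherenceGraph([f"n{i}" for i in range(n)], w)
            assert global_efficiency(g) == pytest.approx(
                brute_force_efficiency(w), abs=1e-12
            )

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(CoherenceGraph(["a"], np.ones((1, 1))))


class TestPartialCoherence:
    def test_two_channel_reduces_to_sqrt_coherence(self, rng):
        data = rng.standard_normal((int(FS * 60), 2))
        data[:, 1] += 0.7 * data[:, 0]
        S = cross_spectral_matrix(_epochs(data))
        pc = partial_coherence(S, "ch0", "ch1")
        c = coherence(S, "ch0", "ch1")
        assert np.allclose(pc.coh, np.sqrt(c.coh), atol=1e-10)

    def test_chain_discrimination(self):
        # x1→x2→x3, no direct 1-3 link: ordinary coherence sees the relay,
        # partial coherence (given x2) does not
        A = np.zeros((1, 3, 3))
        A[0] = [[0.6, 0, 0], [0.8, 0.5, 0], [0, 0.8, 0.5]]
        sim = gen_mvar_network(A, np.eye(3), FS, 120.0, seed=5)
        S = cross_spectral_matrix(_epochs(sim))
        mask = (S.freqs >= 1) & (S.freqs < 15)
        coh13 = coherence(S, "ch0", "ch2").coh[mask].mean()
        pc13 = np.nanmean(partial_coherence(S, "ch0", "ch2").coh[mask])
        assert coh13 > 0.3
        assert pc13 < 0.1

    def test_independent_channels_vanish(self, rng):
        data = rng.standard_normal((int(FS * 120), 3))
        S = cross_spectral_matrix(_epochs(data))
        pc = np.nanmean(partial_coherence(S, "ch0", "ch2").coh)
        assert pc < 0.15  # |·| (not squared) estimator floor at ~200 blocks

    def test_values_bounded(self, rng):
        data = rng.standard_normal((int(FS * 40), 4))
        data[:, 1] += data[:, 0]
        S = cross_spectral_matrix(_epochs(data))
        pc = partial_coherence(S, "ch0", "ch1").coh
        valid = np.isfinite(pc)
        assert np.all((pc[valid] >= 0) & (pc[valid] <= 1))


class TestFitMvar:
    A_TRUE = np.array([[[0.5, 0.0], [0.5, 0.5]]])

    def test_parameter_recovery(self):
        sim = gen_mvar_network(self.A_TRUE, np.eye(2), FS, 60.0, seed=2)
        model = fit_mvar(_epochs(sim), max_order=8)
        assert model.order == 1
        rmse = np.sqrt(np.mean((model.coeffs[0] - self.A_TRUE[0]) ** 2))
        assert rmse < 0.05

    def test_white_noise_null_fit(self, rng):
        data = rng.standard_normal((int(FS * 60), 2))
        model = fit_mvar(_epochs(data), max_order=8)
        assert model.order <= 2
        assert np.max(np.abs(model.coeffs)) < 0.05

    def test_sigma_self_consistency(self):
        sigma = np.array([[1.0, 0.3], [0.3, 2.0]])
        sim = gen_mvar_network(self.A_TRUE, sigma, FS, 120.0, seed=9)
        model = fit_mvar(_epochs(sim), max_order=6)
        assert np.allclose(model.sigma, sigma, rtol=0.1, atol=0.05)

    def test_fitted_model_stable(self):
        sim = gen_mvar_network(self.A_TRUE, np.eye(2), FS, 30.0, seed=1)
        model = fit_mvar(_epochs(sim), max_order=6)
        assert model.is_stable()


class TestExtendedPdc:
    A_TRUE = np.array([[[0.5, 0.0], [0.5, 0.5]]])

    def _closed_form(self):
        return extended_pdc(MVARModel(self.A_TRUE, np.eye(2), FS, ["x1", "x2"]))

    def test_directionality_of_worked_model(self):
        d = self._closed_form()
        assert np.allclose(d.pdc[:, 0, 1], 0.0)       # no 2→1 influence
        assert d.pdc[:, 1, 0].min() > 0.1             # 1→2 present at all f

    def test_diagonal_model_no_cross_terms(self):
        A = np.array([[[0.5, 0.0], [0.0, -0.3]]])
        d = extended_pdc(MVARModel(A, np.diag([1.0, 2.0]), FS, ["a", "b"]))
        assert np.allclose(d.pdc[:, 0, 1], 0.0)
        assert np.allclose(d.pdc[:, 1, 0], 0.0)

    def test_column_normalization(self, rng):
        A = 0.1 * rng.standard_normal((2, 3, 3))
        sigma = np.diag(rng.random(3) + 0.5)
        d = extended_pdc(MVARModel(A, sigma, FS, list("abc")))
        colsum = np.sum(d.pdc**2, axis=1)
        assert np.allclose(colsum, 1.0)

    def test_fit_matches_closed_form(self):
        sim = gen_mvar_network(self.A_TRUE, np.eye(2), FS, 60.0, seed=3)
        model = fit_mvar(_epochs(sim), max_order=8)
        d_fit = extended_pdc(model)
        d_ref = self._closed_form()
        mask = d_fit.freqs <= 100
        rms = np.sqrt(np.mean((d_fit.pdc[mask] - d_ref.pdc[mask]) ** 2))
        assert rms < 0.05

    def test_recovers_sparse_network_adjacency(self, rng):
        hits = 0
        total = 0
        for trial in range(5):
            n = int(rng.integers(4, 7))
            while True:
                A = np.zeros((1, n, n))
                A[0][np.diag_indices(n)] = 0.4
                mask = rng.random((n, n)) < 0.25
                np.fill_diagonal(mask, False)
                A[0][mask] = 0.4
                m = MVARModel(A, np.eye(n), FS, [f"c{i}" for i in range(n)])
                if m.is_stable():
                    break
            sim = gen_mvar_network(A, np.eye(n), FS, 60.0, seed=100 + trial)
            fit = fit_mvar(_epochs(sim), max_order=4)
            d = extended_pdc(fit)
            band = (d.freqs >= 1) & (d.freqs < 100)
            strength = d.pdc[band].mean(axis=0)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    total += 1
                    hits += (strength[i, j] > 0.1) == bool(A[0, i, j])
        assert hits / total >= 0.95

    def test_band_means(self):
        d = self._closed_form()
        # half-open 1 Hz bands: 30–50 → 20 bins, 50–100 → 50 bins
        assert np.sum((d.freqs >= 30) & (d.freqs < 50)) == 20
        assert np.sum((d.freqs >= 50) & (d.freqs < 100)) == 50
        assert band_mean_pdc(d, (30, 50), "x2", "x1") == pytest.approx(0.0)
        assert band_mean_pdc(d, (30, 50), "x1", "x2") > 0.1
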