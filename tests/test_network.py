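"""PLV construction, analytic phases, and weighted graph metrics vs brute force."""

import numpy as np
import pytest

from rseeg.io import Band, EpochSet, ValidationError
from rseeg import network as nw

FS = 500.0
THETA = Band("theta", 4.0, 8.0)


def _epochs(arrs, labels):
    return EpochSet(np.asarray(arrs, dtype=float), FS, arrs.shape[-1] / FS, labels)


class TestAnalyticPhase:
    t = np.arange(2500) / FS

    def test_cosine_phase_advances_at_carrier_frequency(self):
        phi = nw.analytic_phase(np.cos(2 * np.pi * 6.0 * self.t))
        slope = np.diff(np.unwrap(phi))[200:-200].mean() * FS / (2 * np.pi)
        assert slope == pytest.approx(6.0, rel=0.01)

    def test_sine_lags_cosine_by_quarter_cycle(self):
        phi_cos = nw.analytic_phase(np.cos(2 * np.pi * 6.0 * self.t))
        phi_sin = nw.analytic_phase(np.sin(2 * np.pi * 6.0 * self.t))
        lag = np.angle(np.exp(1j * (phi_cos - phi_sin)))[200:-200]
        assert np.allclose(lag, np.pi / 2, atol=0.02)

    def test_slow_positive_envelope_leaves_phase_unchanged(self):
        carrier = np.cos(2 * np.pi * 6.0 * self.t)
        envelope = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * self.t)
        phi_mod = nw.analytic_phase(envelope * carrier)
        phi_ref = nw.analytic_phase(carrier)
        diff = np.angle(np.exp(1j * (phi_mod - phi_ref)))[300:-300]
        assert np.abs(diff).max() < 0.05

    def test_constant_signal_has_undefined_phase(self):
        with pytest.raises(ValidationError):
            nw.analytic_phase(np.ones(100))


class TestPlv:
    def test_identical_phases_lock_perfectly(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 500)
        assert nw.plv(phi, phi) == pytest.approx(1.0)

    def test_constant_lag_locks_perfectly(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 500)
        assert nw.plv(phi, phi + np.pi / 2) == pytest.approx(1.0)

    def test_antiphase_pair_cancels(self):
        assert nw.plv(np.array([0.0, np.pi]), np.array([0.0, 0.0])) == pytest.approx(0.0, abs=1e-12)

    def test_independent_phases_follow_rayleigh_scale(self, rng):
        n = 2500
        vals = [
            nw.plv(rng.uniform(-np.pi, np.pi, n), rng.uniform(-np.pi, np.pi, n))
            for _ in range(300)
        ]
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert np.mean(vals) == pytest.approx(expected, rel=0.15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            nw.plv(np.zeros(10), np.zeros(11))


class TestBuildNetwork:
    def test_identical_channels_have_unit_weight(self, rng):
        x = rng.standard_normal(2500)
        ep = _epochs(np.stack([np.stack([x, x])] * 3), ["Fz", "Cz"])
        net = nw.build_network(ep, THETA)
        assert net.W[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_scaling_both_signals_leaves_plv_unchanged(self, rng):
        x = rng.standard_normal((4, 2, 2500))
        a = nw.build_network(_epochs(x, ["Fz", "Cz"]), THETA).W
        b = nw.build_network(_epochs(x * 37.5, ["Fz", "Cz"]), THETA).W
        assert np.allclose(a, b, atol=1e-6)

    def test_fft_and_sos_paths_agree(self, rng):
        x = rng.standard_normal((6, 3, 2500))
        ep = _epochs(x, ["Fz", "Cz", "Pz"])
        w_fft = nw.build_network(ep, THETA, method="fft").W
        w_sos = nw.build_network(ep, THETA, method="sos").W
        assert np.abs(w_fft - w_sos).max() < 0.05

    def test_independent_noise_stays_near_band_limited_null(self, rng):
        # null PLV of band-limited noise ~ sqrt(pi)/2 / sqrt(2 B T) with
        # B the bandwidth and T the (trimmed) epoch length
        x = rng.standard_normal((12, 2, 2500))
        ep = _epochs(x, ["Fz", "Cz"])
        t_eff = 4.5  # 5 s epoch minus 2 x 0.25 s trim
        for f1, f2 in [(0.5, 4.0), (4.0, 8.0), (13.0, 30.0), (30.0, 45.0)]:
            w = nw.build_network(ep, Band("b", f1, f2)).W[0, 1]
            rayleigh = np.sqrt(np.pi) / (2 * np.sqrt(2 * (f2 - f1) * t_eff))
            assert w < 2.5 * rayleigh
            assert w > 0.25 * rayleigh  # and not spuriously locked at 0 either

    def test_empty_epochs_rejected(self):
        ep = EpochSet(np.zeros((1, 2, 2500)), FS, 5.0, ["Fz", "Cz"])
        ep.epochs = ep.epochs[:0]
        with pytest.raises(ValidationError):
            nw.build_network(ep, THETA)


from _oracles import brute_clustering, brute_path_length  # noqa: E402


def _random_graph(rng, n):
    w = np.triu(rng.uniform(0.05, 1.0, (n, n)), 1)
    drop = np.triu(rng.random((n, n)) < 0.2, 1)
    w[drop] = 0.0
    return w + w.T


class TestGraphMetrics:
    def test_perfect_triangle(self):
        k3 = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        assert nw.clustering_coefficient(k3) == pytest.approx(1.0)
        assert nw.char_path_length(k3) == pytest.approx(1.0)

    def test_open_chain(self):
        chain = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert nw.clustering_coefficient(chain) == 0.0
        assert nw.char_path_length(chain) == pytest.approx(4.0 / 3.0)

    def test_uniform_scaling_homogeneity(self, rng):
        w = _random_graph(rng, 6)
        w[w == 0] = 0.3  # keep it connected
        np.fill_diagonal(w, 0)
        base = nw.char_path_length(w)
        assert nw.char_path_length(0.5 * w) == pytest.approx(2.0 * base)

    @pytest.mark.parametrize("formula", ["bct", "strength"])
    def test_matches_bruteforce_on_random_graphs(self, formula, rng):
        for _ in range(40):
            n = int(rng.integers(3, 8))
            w = _random_graph(rng, n)
            assert nw.clustering_coefficient(w, formula=formula) == pytest.approx(
                brute_clustering(w, formula), abs=1e-12
            )

    def test_path_length_matches_floyd_warshall(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 8))
            w = _random_graph(rng, n)
            w[w == 0] = rng.uniform(0.05, 1.0)  # fully connected for the oracle
            w = np.triu(w, 1) + np.triu(w, 1).T
            assert nw.char_path_length(w) == pytest.approx(brute_path_length(w), abs=1e-12)

    def test_disconnected_graph_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(nw.DisconnectedGraphError):
            nw.char_path_length(w)

    def test_asymmetric_matrix_rejected(self):
        w = np.array([[0, 0.5, 0], [0.4, 0, 0], [0, 0, 0]], dtype=float)
        with pytest.raises(ValidationError):
            nw.clustering_coefficient(w)

    def test_negative_weight_rejected(self):
        w = np.array([[0, -0.5], [-0.5, 0]])
        with pytest.raises(ValidationError):
            nw.char_path_length(w)
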