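"""Network tests: connectome construction and I/O, coupling identities,
delay discretization, synchronization."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from slowbrain import (
    Connectome,
    NodeParams,
    integrate_node,
    load_connectome,
    node_seeds,
    simulate_network,
    synthetic_connectome,
)


def _toy_connectome(N=3, weight=1.0, delay_ms=5.0):
    C = np.full((N, N), weight)
    np.fill_diagonal(C, 0.0)
    L = np.full((N, N), delay_ms * 20.0)  # v_gl = 20 m/s -> D = delay_ms
    np.fill_diagonal(L, 0.0)
    coords = np.arange(N * 3, dtype=float).reshape(N, 3)
    labels = [f"n{i}" for i in range(N)]
    return Connectome(C=C, L=L, D=L / 20.0, labels=labels, coords=coords)


class TestConnectomeConstruction:
    def test_text_file_loading_and_unit_arithmetic(self, tmp_path):
        # 100 mm fiber at 20 m/s gives a 5 ms delay
        C = np.array([[0.0, 2.0], [2.0, 0.0]])
        L = np.array([[0.0, 100.0], [100.0, 0.0]])
        coords = np.zeros((2, 3))
        np.savetxt(tmp_path / "w.txt", C)
        np.savetxt(tmp_path / "l.txt", L)
        np.savetxt(tmp_path / "c.txt", coords)
        (tmp_path / "labels.txt").write_text("A\nB\n")
        conn = load_connectome(tmp_path / "w.txt", tmp_path / "l.txt",
                               tmp_path / "labels.txt", tmp_path / "c.txt")
        assert conn.D[0, 1] == pytest.approx(5.0)
        assert conn.C.max() == 1.0

    def test_symmetric_normalized_input_unchanged(self, tmp_path):
        C = np.array([[0.0, 1.0, 0.5], [1.0, 0.0, 0.25], [0.5, 0.25, 0.0]])
        L = np.ones((3, 3)) * 10.0
        np.savetxt(tmp_path / "w.txt", C)
        np.savetxt(tmp_path / "l.txt", L)
        np.savetxt(tmp_path / "c.txt", np.zeros((3, 3)))
        (tmp_path / "labels.txt").write_text("A\nB\nC\n")
        conn = load_connectome(tmp_path / "w.txt", tmp_path / "l.txt",
                               tmp_path / "labels.txt", tmp_path / "c.txt")
        assert np.allclose(conn.C, C)

    def test_invalid_inputs_rejected(self, tmp_path):
        np.savetxt(tmp_path / "neg.txt", np.array([[0.0, -1.0], [-1.0, 0.0]]))
        np.savetxt(tmp_path / "l2.txt", np.zeros((2, 2)))
        np.savetxt(tmp_path / "l3.txt", np.zeros((3, 3)))
        np.savetxt(tmp_path / "c2.txt", np.zeros((2, 3)))
        (tmp_path / "lab2.txt").write_text("A\nB\n")
        with pytest.raises(ValueError):
            load_connectome(tmp_path / "neg.txt", tmp_path / "l2.txt",
                            tmp_path / "lab2.txt", tmp_path / "c2.txt")
        np.savetxt(tmp_path / "w2.txt", np.abs(np.eye(2) - 1))
        with pytest.raises(ValueError):
            load_connectome(tmp_path / "w2.txt", tmp_path / "l3.txt",
                            tmp_path / "lab2.txt", tmp_path / "c2.txt")

    def test_save_load_roundtrip_preserves_structure(self, tmp_path):
        conn = synthetic_connectome(20, seed=3)
        conn.save(tmp_path / "bundle.h5")
        back = Connectome.load(tmp_path / "bundle.h5")
        assert np.allclose(back.C, conn.C)
        assert np.allclose(back.coords, conn.coords)
        assert back.labels == conn.labels
        assert back.C.max() == 1.0
        assert np.allclose(back.C, back.C.T)
        assert np.all(np.diag(back.C) == 0.0)


class TestSyntheticConnectome:
    def test_deterministic_given_seed(self):
        a = synthetic_connectome(30, seed=5)
        b = synthetic_connectome(30, seed=5)
        assert np.array_equal(a.C, b.C)
        assert np.array_equal(a.coords, b.coords)

    def test_degree_gradient_along_ap_axis(self):
        conn = synthetic_connectome(80, seed=1, gradient_strength=1.0)
        rho, p = spearmanr(conn.ap_coordinate, conn.degree)
        # anterior (large y) regions are less connected
        assert rho < -0.3 and p < 1e-3

    def test_no_gradient_when_disabled(self):
        conn = synthetic_connectome(80, seed=1, gradient_strength=0.0)
        rho, _ = spearmanr(conn.ap_coordinate, conn.degree)
        assert abs(rho) < 0.25

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            synthetic_connectome(1)


class TestCoupling:
    def test_decoupled_network_matches_isolated_nodes(self, table):
        """With K_gl = 0 every node's trajectory is bit-identical to an
        isolated node driven by the same spawned noise stream."""
        p = NodeParams(mu_E_ext=2.0, mu_I_ext=1.5, b=5.0, sigma_ou=0.3)
        conn = _toy_connectome(3)
        net = simulate_network(conn, p, table, K_gl=0.0, duration=2000.0,
                               seed=11, transient=500.0)
        seeds = node_seeds(11, 3)
        for i in range(3):
            single = integrate_node(p, table, duration=2000.0, seed=seeds[i],
                                    transient=500.0)
            assert np.array_equal(net.rE[i], single.rE[0])
            assert np.array_equal(net.IA[i], single.IA[0])

    def test_delay_discretization_shifts_response_onset_exactly(self, table):
        """Increasing all inter-node delays by 5 ms delays the first coupled
        response of a target node by exactly 50 integration steps."""
        p = NodeParams(mu_E_ext=0.5, mu_I_ext=1.0, b=0.0, sigma_ou=0.0)
        n = 20_000  # 2 s at dt = 0.1
        stim = np.zeros((3, n))
        stim[0, 5000:5200] = 3.0  # 20 ms pulse into node 0 only
        onsets = []
        for delay_ms in (5.0, 10.0):
            conn = _toy_connectome(3, delay_ms=delay_ms)
            kw = dict(duration=2000.0, dt=0.1, seed=12, transient=0.0,
                      init=(0.0, 0.0))
            coupled = simulate_network(conn, p, table, K_gl=50.0,
                                       stimulus=stim, **kw)
            free = simulate_network(conn, p, table, K_gl=50.0, **kw)
            dev = np.flatnonzero(coupled.rE[1] != free.rE[1])
            onsets.append(dev[0])
        assert onsets[1] - onsets[0] == 50

    def test_symmetric_pair_phase_locks_in_slow_cycle(self, table):
        """Two identical nodes with symmetric delayed coupling and no noise
        synchronize their slow oscillation (cross-correlation peak within
        the coupling delay)."""
        p = NodeParams(mu_E_ext=2.6, mu_I_ext=1.8, b=20.0, tau_A=600.0,
                       sigma_ou=0.0)
        conn = _toy_connectome(2, delay_ms=10.0)
        tr = simulate_network(conn, p, table, K_gl=10.0, duration=20_000.0,
                              seed=13, transient=0.0, rec_dt=1.0,
                              init=np.array([[1.0, 1.0], [2.5, 1.5]]))
        a = tr.rE[0, tr.t >= 10_000.0]
        b = tr.rE[1, tr.t >= 10_000.0]
        assert a.max() - a.min() > 10.0
        a = a - a.mean()
        b = b - b.mean()
        xc = np.correlate(a, b, mode="full")
        lag = np.argmax(xc) - (len(a) - 1)
        assert abs(lag) * tr.rec_dt <= 10.0

    def test_max_delay_must_fit_simulation(self, table):
        conn = _toy_connectome(3, delay_ms=500.0)
        with pytest.raises(ValueError):
            simulate_network(conn, NodeParams(), table, K_gl=10.0,
                             duration=100.0, transient=0.0)

    def test_trace_save_load_roundtrip(self, table, tmp_path):
        p = NodeParams(mu_E_ext=2.0, mu_I_ext=1.5, sigma_ou=0.1)
        tr = simulate_network(_toy_connectome(2), p, table, K_gl=5.0,
                              duration=1000.0, seed=14)
        tr.save(tmp_path / "trace.h5")
        from slowbrain import NetworkTrace

        back = NetworkTrace.load(tmp_path / "trace.h5")
        assert np.array_equal(back.rE, tr.rE)
        assert back.rec_dt == tr.rec_dt
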