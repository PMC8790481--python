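"""Connectome handling and whole-brain network simulation.

The network couples N mean-field E-I nodes exclusively through their
excitatory populations, with connection weights from a max-normalized,
symmetrized fiber-count matrix and per-pair delays D = L / v_gl from the
fiber-length matrix.  A synthetic connectome generator provides fixtures
that emulate the salient structural features of a cortical DTI connectome:
distance-dependent, heavy-tailed weights and an in-degree gradient along
the anterior-posterior axis (anterior regions less connected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernel
from .params import NodeParams
from .transfer import TransferTable

__all__ = [
    "Connectome",
    "load_connectome",
    "synthetic_connectome",
    "simulate_network",
    "NetworkTrace",
    "node_seeds",
]

#: anterior-posterior axis is column 1 (y) of the centroid coordinates,
#: larger y = more anterior.
AP_AXIS = 1


@dataclass
class Connectome:
    """Structural connectivity of the brain network.

    C is symmetric, non-negative, zero-diagonal and max-normalized to 1;
    D (ms) derives from fiber lengths L (mm) and the global signal speed.
    """

    C: np.ndarray
    L: np.ndarray
    D: np.ndarray
    labels: list[str]
    coords: np.ndarray
    v_gl: float = 20.0  # m/s

    @property
    def N(self) -> int:
        return self.C.shape[0]

    @property
    def ap_coordinate(self) -> np.ndarray:
        """Anterior-posterior centroid coordinate (larger = anterior)."""
        return self.coords[:, AP_AXIS]

    @property
    def degree(self) -> np.ndarray:
        """Weighted in-degree (row sum of C)."""
        return self.C.sum(axis=1)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("C", data=self.C)
            f.create_dataset("L", data=self.L)
            f.create_dataset("coords", data=self.coords)
            f.create_dataset(
                "labels", data=np.array(self.labels, dtype=h5py.string_dtype())
            )
            f.attrs["v_gl"] = self.v_gl

    @classmethod
    def load(cls, path) -> "Connectome":
        with h5py.File(path, "r") as f:
            C = f["C"][:]
            L = f["L"][:]
            coords = f["coords"][:]
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in f["labels"][:]]
            v_gl = float(f.attrs["v_gl"])
        return _build_connectome(C, L, labels, coords, v_gl)


def _build_connectome(C, L, labels, coords, v_gl) -> Connectome:
    C = np.asarray(C, dtype=float)
    L = np.asarray(L, dtype=float)
    coords = np.asarray(coords, dtype=float)
    N = C.shape[0]
    if C.shape != (N, N) or L.shape != (N, N):
        raise ValueError("weight and length matrices must be square and equal-size")
    if coords.shape != (N, 3) or len(labels) != N:
        raise ValueError(f"labels/coords do not match N={N}")
    if np.any(C < 0):
        raise ValueError("connectome weights must be non-negative")
    C = 0.5 * (C + C.T)
    L = 0.5 * (L + L.T)
    np.fill_diagonal(C, 0.0)
    cmax = C.max()
    if cmax > 0:
        C = C / cmax
    # v_gl in m/s == mm/ms, so D[ms] = L[mm] / v_gl
    D = L / v_gl
    return Connectome(C=C, L=L, D=D, labels=list(labels), coords=coords, v_gl=v_gl)


def load_connectome(
    weights_path, lengths_path, labels_path, coords_path, v_gl: float = 20.0
) -> Connectome:
    """Load a connectome from plain-text matrix/table files.

    Weights and lengths are dense whitespace- or comma-delimited matrices,
    labels one region name per line, coords an N x 3 table (mm).  The weight
    matrix is symmetrized via (C + C^T)/2, its diagonal zeroed and entries
    max-normalized; delays are computed as L / v_gl.
    """
    def _read(p):
        try:
            return np.loadtxt(p)
        except ValueError:
            return np.loadtxt(p, delimiter=",")

    C = _read(weights_path)
    L = _read(lengths_path)
    coords = _read(coords_path)
    with open(labels_path) as fh:
        labels = [line.strip() for line in fh if line.strip()]
    return _build_connectome(C, L, labels, coords, v_gl)


def synthetic_connectome(
    N: int = 80,
    seed: int = 0,
    gradient_strength: float = 1.0,
    decay_mm: float = 30.0,
    weight_sigma: float = 1.0,
    inter_hemisphere: float = 0.4,
    detour: float = 1.3,
) -> Connectome:
    """Generate a random geometric surrogate connectome.

    The generator emulates the structural features of a cortical DTI
    connectome that shape slow-wave propagation: region centroids in a
    brain-shaped ellipsoid split into two hemispheres, weights decaying
    exponentially with inter-centroid distance (length scale ``decay_mm``)
    with lognormal heterogeneity, weaker callosal (inter-hemispheric)
    than intra-hemispheric connectivity (factor ``inter_hemisphere``),
    and an in-degree gradient along the anterior-posterior axis: the
    in-degree increases toward posterior regions by a factor controlled by
    ``gradient_strength`` (0 disables the gradient), leaving anterior
    regions more weakly connected as in empirical tractography.  Fiber
    lengths are Euclidean distances times a constant detour factor.
    Deterministic given the seed.
    """
    if N < 2:
        raise ValueError("need at least two regions")
    rng = np.random.default_rng(seed)
    # ellipsoid semi-axes (x: left-right, y: anterior-posterior, z: axial), mm
    semi = np.array([60.0, 80.0, 50.0])
    pts = []
    while len(pts) < N:
        cand = rng.uniform(-1, 1, size=(N, 3))
        keep = (cand**2).sum(axis=1) <= 1.0
        pts.extend(cand[keep])
    coords = np.array(pts[:N]) * semi
    # keep centroids off the midline so hemispheres are well defined
    coords[:, 0] = np.where(np.abs(coords[:, 0]) < 5.0,
                            np.sign(coords[:, 0] + 1e-9) * 5.0, coords[:, 0])

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    W = np.exp(-dist / decay_mm)
    het = rng.lognormal(mean=0.0, sigma=weight_sigma, size=(N, N))
    W = W * 0.5 * (het + het.T)

    hemi = np.sign(coords[:, 0])
    cross = hemi[:, None] != hemi[None, :]
    W = np.where(cross, inter_hemisphere * W, W)

    if gradient_strength != 0.0:
        y = coords[:, AP_AXIS]
        # posteriorness in [0, 1]: 1 at the most posterior (lowest y) region
        post = (y.max() - y) / (y.max() - y.min())
        g = 1.0 + gradient_strength * post
        W = W * np.outer(g, g)

    L = dist * detour
    labels = [f"synthetic_region_{i:03d}" for i in range(N)]
    return _build_connectome(W, L, labels, coords, 20.0)


def single_node_connectome() -> Connectome:
    """Trivial 1-node connectome for isolated-node simulations."""
    return Connectome(
        C=np.zeros((1, 1)), L=np.zeros((1, 1)), D=np.zeros((1, 1)),
        labels=["node"], coords=np.zeros((1, 3)),
    )


@dataclass
class NetworkTrace:
    """Recorded simulation output.

    Rates are in Hz, adaptation current in pA, time in ms.  ``mean_rE`` is
    the across-node mean excitatory rate recorded at the full integration
    step (for spectral analysis), while the per-node arrays are sampled
    every ``rec_dt`` ms.
    """

    t: np.ndarray            # ms, per-node sampling times
    rE: np.ndarray           # (N, T) Hz
    rI: np.ndarray           # (N, T) Hz
    IA: np.ndarray           # (N, T) pA
    VE: np.ndarray           # (N, T) mV
    dt: float                # integration step, ms
    rec_dt: float            # per-node recording step, ms
    mean_rE: np.ndarray      # (T_full,) Hz at dt resolution
    params: NodeParams = field(repr=False, default=None)
    K_gl: float = 0.0

    @property
    def N(self) -> int:
        return self.rE.shape[0]

    @property
    def duration(self) -> float:
        return self.t[-1] - self.t[0] + self.rec_dt

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("t", "rE", "rI", "IA", "VE", "mean_rE"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["dt"] = self.dt
            f.attrs["rec_dt"] = self.rec_dt
            f.attrs["K_gl"] = self.K_gl
            f.attrs["units"] = "t: ms, rE/rI: Hz, IA: pA, VE: mV"

    @classmethod
    def load(cls, path) -> "NetworkTrace":
        with h5py.File(path, "r") as f:
            data = {k: f[k][:] for k in ("t", "rE", "rI", "IA", "VE", "mean_rE")}
            return cls(
                dt=float(f.attrs["dt"]), rec_dt=float(f.attrs["rec_dt"]),
                K_gl=float(f.attrs["K_gl"]), **data,
            )

    def save_tsv(self, path, node: int = 0) -> None:
        """Columnar plain-text export of one node's trace."""
        import pandas as pd

        pd.DataFrame({
            "t_ms": self.t,
            "rE_Hz": self.rE[node],
            "rI_Hz": self.rI[node],
            "IA_pA": self.IA[node],
            "VE_mV": self.VE[node],
        }).to_csv(path, sep="\t", index=False)


def node_seeds(seed, N: int):
    """Per-node random streams derived from one master seed.

    An N-node simulation spawns N child sequences from the master; a
    one-node simulation consumes the given sequence directly.  Passing
    child i of an N-node master to an isolated-node run therefore
    reproduces node i of a decoupled (K_gl = 0) network bit for bit.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    if N == 1:
        return [ss]
    return ss.spawn(N)


_CHUNK_STEPS = 50_000


def simulate_network(
    connectome: Connectome,
    params: NodeParams,
    table: TransferTable,
    K_gl: float = 0.0,
    duration: float = 1000.0,
    dt: float = 0.1,
    seed=0,
    stimulus: np.ndarray | None = None,
    transient: float = 1000.0,
    rec_dt: float | None = None,
    init: str | tuple = "random",
) -> NetworkTrace:
    """Integrate the coupled network with forward Euler.

    Parameters
    ----------
    K_gl
        Global coupling strength; 0 decouples all nodes exactly.
    duration, transient
        Recorded duration and discarded initial transient, ms.
    seed
        Master seed (int or SeedSequence); per-node noise streams are
        spawned from it (see :func:`node_seeds`).
    stimulus
        Optional mean-current time series (mV/ms) added to the excitatory
        external input over the recorded window; shape (duration/dt,) for
        a common stimulus or (N, duration/dt) for per-node stimuli.
    rec_dt
        Per-node recording interval, ms (defaults to dt).
    init
        "random" draws initial mean currents uniformly from [0, 3] mV/ms
        per node; a tuple (mu_E0, mu_I0) fixes them for all nodes; an
        (N, 2) array sets them per node.
    """
    N = connectome.N
    if duration < dt:
        raise ValueError("duration must be at least dt")
    rec_dt = dt if rec_dt is None else rec_dt
    rec_every = max(1, int(round(rec_dt / dt)))
    rec_dt = rec_every * dt

    n_trans = int(round(transient / dt))
    n_dur = int(round(duration / dt))
    n_total = n_trans + n_dur
    if stimulus is not None:
        stimulus = np.atleast_2d(np.asarray(stimulus, dtype=float))
        if stimulus.shape[1] != n_dur or stimulus.shape[0] not in (1, N):
            raise ValueError(
                f"stimulus must have shape ({n_dur},) or ({N}, {n_dur})"
            )
        stim_full = np.zeros((stimulus.shape[0], n_total))
        stim_full[:, n_trans:] = stimulus
    else:
        stim_full = np.zeros((1, n_total))

    # delays in integration steps; sub-step delays count as one step
    sdE = max(1, int(round(params.d_E / dt)))
    sdI = max(1, int(round(params.d_I / dt)))
    Dsteps = np.maximum(1, np.round(connectome.D / dt)).astype(np.int64)
    if K_gl > 0 and Dsteps.max() * dt >= duration + transient:
        raise ValueError("max delay exceeds simulation length")
    L = int(max(sdE, sdI, Dsteps.max() if K_gl > 0 else 1)) + 1

    # state initialization
    seqs = node_seeds(seed, N)
    gens = [np.random.default_rng(s) for s in seqs]
    if isinstance(init, str):
        if init != "random":
            raise ValueError("init must be 'random', a (mu_E0, mu_I0) pair "
                             "or an (N, 2) array")
        inits = np.array([g.uniform(0.0, 3.0, size=2) for g in gens])
        mu_E0, mu_I0 = inits[:, 0].copy(), inits[:, 1].copy()
    else:
        init = np.asarray(init, dtype=float)
        if init.shape == (2,):
            mu_E0 = np.full(N, init[0])
            mu_I0 = np.full(N, init[1])
        elif init.shape == (N, 2):
            mu_E0 = init[:, 0].copy()
            mu_I0 = init[:, 1].copy()
        else:
            raise ValueError("init array must have shape (2,) or (N, 2)")
    state = {
        "mu_E": mu_E0, "mu_I": mu_I0,
        "ou_E": np.zeros(N), "ou_I": np.zeros(N),
        "seem": np.zeros(N), "seim": np.zeros(N),
        "siem": np.zeros(N), "siim": np.zeros(N),
        "seev": np.zeros(N), "seiv": np.zeros(N),
        "siev": np.zeros(N), "siiv": np.zeros(N),
        "IA": np.zeros(N),
    }
    rE_buf = np.empty((N, L))
    rI_buf = np.empty((N, L))
    _kernel.prefill_buffers(
        rE_buf, rI_buf, state["mu_E"], state["mu_I"], state["IA"],
        params.adex.C, table.mu_grid, table.sigma_grid, table.r,
        params.sigma_ext,
    )

    n_rec = (n_dur + rec_every - 1) // rec_every
    rec_rE = np.zeros((N, n_rec))
    rec_rI = np.zeros((N, n_rec))
    rec_IA = np.zeros((N, n_rec))
    rec_VE = np.zeros((N, n_rec))
    mean_rE = np.zeros(n_dur)

    p = params
    aEE = p.c_EE * p.tau_s_E / abs(p.J_EE)
    aEI = p.c_EI * p.tau_s_I / abs(p.J_EI)
    aIE = p.c_IE * p.tau_s_E / abs(p.J_IE)
    aII = p.c_II * p.tau_s_I / abs(p.J_II)
    C2 = connectome.C**2

    t0 = 0
    while t0 < n_total:
        n = min(_CHUNK_STEPS, n_total - t0)
        noise = np.empty((N, 2, n))
        for i, g in enumerate(gens):
            noise[i] = g.standard_normal((2, n))
        status, node, step = _kernel.integrate_chunk(
            state["mu_E"], state["mu_I"], state["ou_E"], state["ou_I"],
            state["seem"], state["seim"], state["siem"], state["siim"],
            state["seev"], state["seiv"], state["siev"], state["siiv"],
            state["IA"],
            rE_buf, rI_buf,
            connectome.C, C2, Dsteps,
            noise, stim_full[:, t0:t0 + n],
            table.mu_grid, table.sigma_grid, table.r, table.tau, table.V,
            dt, t0, n, n_trans, rec_every,
            sdE, sdI,
            aEE, aEI, aIE, aII,
            p.K_e, p.K_i, float(K_gl),
            p.J_EE, p.J_EI, p.J_IE, p.J_II,
            p.tau_s_E, p.tau_s_I, p.adex.tau_m,
            p.sigma_ext**2,
            p.mu_E_ext, p.mu_I_ext,
            p.adex.C, p.b, p.tau_A, p.a, p.E_A,
            p.sigma_ou, p.tau_ou,
            rec_rE, rec_rI, rec_IA, rec_VE,
            mean_rE,
        )
        if status == _kernel.ERR_NAN:
            raise FloatingPointError(
                f"non-finite state in node {node} at step {step} "
                f"(t = {step * dt:.1f} ms)"
            )
        if status == _kernel.ERR_RATE:
            raise FloatingPointError(
                f"firing rate exceeded the refractory bound in node {node} "
                f"at step {step}"
            )
        t0 += n

    t = np.arange(n_rec) * rec_dt
    return NetworkTrace(
        t=t, rE=rec_rE * 1e3, rI=rec_rI * 1e3, IA=rec_IA, VE=rec_VE,
        dt=dt, rec_dt=rec_dt, mean_rE=mean_rE * 1e3, params=params,
        K_gl=float(K_gl),
    )
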