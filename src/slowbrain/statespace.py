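"""Dynamical-regime classification over grids of external input currents.

For each (mu_E_ext, mu_I_ext) point the node (or network) is simulated
noiselessly for 20 s with a decaying bidirectional stimulus probe: a negative
exponentially decaying pulse pushes the system toward the low-activity branch,
a positive one (starting at 10 s) toward the high-activity branch.  A point is

* ``oscillatory`` if the firing-rate oscillation amplitude (max - min) of any
  node exceeds 10 Hz after all transients have decayed (8 s),
* ``bistable``    if the 2 s-mean rates reached after the two probes differ by
  at least 10 Hz in any node (and the point is not oscillatory),
* ``up`` / ``down`` otherwise, split by a 10 Hz mean-rate threshold.

Two limit cycles coexist in the model: a fast excitation-inhibition cycle
(LC_EI, 15-35 Hz) present without adaptation, and a slow excitation-
adaptation cycle (LC_EA, 0.5-2 Hz) induced by spike-triggered adaptation
next to the bistable wedge.  Adaptation destabilizes only the high-activity
branch of the bistable pair, so the self-sustained slow cycle lives where
the low-activity branch is *not* stable on its own -- the flank of the
formerly bistable region.  A point is attributed to LC_EA if it oscillates
at finite adaptation but not without it, and the oscillation is a genuine
relaxation between up- and down-states, i.e. both states survive the 50 ms
minimum-duration cleaning of the up/down detection.  Fast cycles (period
< 100 ms) cannot produce 50 ms down-states and are excluded automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy.signal import periodogram

from .analysis import detect_states
from .network import Connectome, simulate_network, single_node_connectome
from .params import NodeParams
from .transfer import TransferTable

__all__ = [
    "StateMap",
    "probe_stimulus",
    "classify_point",
    "scan_grid",
    "dominant_frequency",
    "limit_cycle_masks",
]

#: classification thresholds of the probe protocol, Hz
RATE_DIFF_THRESHOLD = 10.0
OSC_AMP_THRESHOLD = 10.0
SETTLE_MS = 8000.0
PROBE_HALF_MS = 10_000.0


def probe_stimulus(
    dt: float, amp: float = 2.0, decay_ms: float = 1000.0
) -> np.ndarray:
    """Bidirectional decaying stimulus: -amp exp(-t/tau) then +amp exp(-t/tau)
    starting at 10 s; total length 20 s."""
    n_half = int(round(PROBE_HALF_MS / dt))
    t = np.arange(n_half) * dt
    pulse = np.exp(-t / decay_ms)
    return np.concatenate([-amp * pulse, amp * pulse])


def dominant_frequency(
    rate_hz: np.ndarray,
    dt_ms: float,
    discard_ms: float = SETTLE_MS,
    amp_threshold_hz: float = OSC_AMP_THRESHOLD,
) -> float:
    """Peak frequency (Hz) of the periodogram of a rate trace after
    transient discard; 0 if the residual oscillation amplitude is below
    the threshold."""
    x = np.asarray(rate_hz, dtype=float)
    n0 = int(round(discard_ms / dt_ms))
    x = x[n0:]
    if x.size < 16 or (x.max() - x.min()) <= amp_threshold_hz:
        return 0.0
    freqs, power = periodogram(x - x.mean(), fs=1000.0 / dt_ms)
    return float(freqs[np.argmax(power)])


def _window_slices(t: np.ndarray):
    w1 = (t >= SETTLE_MS) & (t < PROBE_HALF_MS)
    w2 = t >= PROBE_HALF_MS + SETTLE_MS
    return w1, w2


def classify_point(
    params: NodeParams,
    table: TransferTable,
    mu_E_ext: float,
    mu_I_ext: float,
    connectome: Connectome | None = None,
    K_gl: float = 0.0,
    dt: float = 0.1,
    seed: int = 0,
    rec_dt: float = 1.0,
    measure_frequency: bool = True,
    freq_duration: float = 40_000.0,
    freq_discard: float = 16_000.0,
) -> dict:
    """Classify one state-space point with the noiseless probe protocol.

    Returns a dict with ``label`` in {down, up, bistable, oscillatory} and
    the metrics ``max_rate`` (Hz), ``osc_amp`` (Hz), ``rate_diff`` (Hz),
    ``dominant_freq`` (Hz) and ``alternating`` (whether the oscillation is
    an up/down relaxation).  Frequency and alternation are measured in a
    separate stimulus-free run of ``freq_duration`` ms whose first
    ``freq_discard`` ms are discarded, long enough to settle the slow
    adaptation transients and to resolve sub-Hz cycles.
    """
    conn = connectome if connectome is not None else single_node_connectome()
    p = params.with_(mu_E_ext=mu_E_ext, mu_I_ext=mu_I_ext, sigma_ou=0.0)
    stim = probe_stimulus(dt)
    trace = simulate_network(
        conn, p, table, K_gl=K_gl, duration=2 * PROBE_HALF_MS, dt=dt,
        seed=seed, stimulus=stim, transient=0.0, rec_dt=rec_dt,
    )
    w1, w2 = _window_slices(trace.t)
    # per-node oscillation amplitude in each settled window
    amp1 = trace.rE[:, w1].max(axis=1) - trace.rE[:, w1].min(axis=1)
    amp2 = trace.rE[:, w2].max(axis=1) - trace.rE[:, w2].min(axis=1)
    osc_amp = float(np.maximum(amp1, amp2).max())
    # 2 s-mean rates reached after each probe
    last2_w1 = (trace.t >= PROBE_HALF_MS - 2000.0) & (trace.t < PROBE_HALF_MS)
    last2_w2 = trace.t >= 2 * PROBE_HALF_MS - 2000.0
    m1 = trace.rE[:, last2_w1].mean(axis=1)
    m2 = trace.rE[:, last2_w2].mean(axis=1)
    rate_diff = float(np.abs(m2 - m1).max())
    max_rate = float(trace.rE[:, w1 | w2].max())

    oscillatory = osc_amp > OSC_AMP_THRESHOLD
    bistable = (not oscillatory) and rate_diff >= RATE_DIFF_THRESHOLD
    if oscillatory:
        label = "oscillatory"
    elif bistable:
        label = "bistable"
    else:
        label = "up" if m2.max() > RATE_DIFF_THRESHOLD else "down"

    freq = 0.0
    alternating = False
    if oscillatory and measure_frequency:
        # the frequency run starts from an up-state initial condition:
        # limit cycles here coexist with stable down fixed points whose
        # basin a random initialization may land in
        free = simulate_network(
            conn, p, table, K_gl=K_gl, duration=freq_duration, dt=dt,
            seed=seed, transient=0.0, rec_dt=rec_dt, init=(3.0, 1.0),
        )
        settled = free.t >= freq_discard
        node = int(np.argmax(
            free.rE[:, settled].max(axis=1) - free.rE[:, settled].min(axis=1)
        ))
        freq = dominant_frequency(free.rE[node], rec_dt,
                                  discard_ms=freq_discard)
        seg = free.rE[node, settled]
        raster = detect_states(seg[None, :], rec_dt)
        alternating = bool(raster.up.any() and (~raster.up).any())
    return {
        "label": label,
        "max_rate": max_rate,
        "osc_amp": osc_amp,
        "rate_diff": rate_diff,
        "dominant_freq": freq,
        "alternating": alternating,
    }


@dataclass
class StateMap:
    """Grid classification result (labels exhaustive and exclusive)."""

    mu_E_grid: np.ndarray
    mu_I_grid: np.ndarray
    label: np.ndarray          # (nE, nI) unicode
    max_rate: np.ndarray       # Hz
    dominant_freq: np.ndarray  # Hz, 0 where not oscillatory
    osc_amp: np.ndarray        # Hz
    rate_diff: np.ndarray      # Hz
    alternating: np.ndarray    # bool, up/down relaxation oscillation
    b: float

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mu_E_grid", data=self.mu_E_grid)
            f.create_dataset("mu_I_grid", data=self.mu_I_grid)
            f.create_dataset(
                "label",
                data=np.char.encode(self.label.astype(str), "utf-8"),
            )
            for name in ("max_rate", "dominant_freq", "osc_amp", "rate_diff",
                         "alternating"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["b"] = self.b

    @classmethod
    def load(cls, path) -> "StateMap":
        with h5py.File(path, "r") as f:
            return cls(
                mu_E_grid=f["mu_E_grid"][:],
                mu_I_grid=f["mu_I_grid"][:],
                label=np.char.decode(f["label"][:], "utf-8"),
                max_rate=f["max_rate"][:],
                dominant_freq=f["dominant_freq"][:],
                osc_amp=f["osc_amp"][:],
                rate_diff=f["rate_diff"][:],
                alternating=f["alternating"][:].astype(bool),
                b=float(f.attrs["b"]),
            )


def scan_grid(
    params: NodeParams,
    table: TransferTable,
    mu_E_grid: np.ndarray | None = None,
    mu_I_grid: np.ndarray | None = None,
    resolution: int = 21,
    b: float | None = None,
    connectome: Connectome | None = None,
    K_gl: float = 0.0,
    dt: float = 0.1,
    seed: int = 0,
    measure_frequency: bool = True,
) -> StateMap:
    """Classify every point of a (mu_E_ext, mu_I_ext) grid in [0, 4] mV/ms.

    Points are independent; the same seed policy (master seed + grid index)
    makes repeated scans identical.
    """
    if mu_E_grid is None:
        mu_E_grid = np.linspace(0.0, 4.0, resolution)
    if mu_I_grid is None:
        mu_I_grid = np.linspace(0.0, 4.0, resolution)
    if b is not None:
        params = params.with_(b=b)
    nE, nI = len(mu_E_grid), len(mu_I_grid)
    label = np.empty((nE, nI), dtype="U12")
    max_rate = np.zeros((nE, nI))
    freq = np.zeros((nE, nI))
    osc_amp = np.zeros((nE, nI))
    rate_diff = np.zeros((nE, nI))
    alternating = np.zeros((nE, nI), dtype=bool)
    for i, muE in enumerate(mu_E_grid):
        for j, muI in enumerate(mu_I_grid):
            res = classify_point(
                params, table, muE, muI, connectome=connectome, K_gl=K_gl,
                dt=dt, seed=seed + i * nI + j,
                measure_frequency=measure_frequency,
            )
            label[i, j] = res["label"]
            max_rate[i, j] = res["max_rate"]
            freq[i, j] = res["dominant_freq"]
            osc_amp[i, j] = res["osc_amp"]
            rate_diff[i, j] = res["rate_diff"]
            alternating[i, j] = res["alternating"]
    return StateMap(
        mu_E_grid=np.asarray(mu_E_grid), mu_I_grid=np.asarray(mu_I_grid),
        label=label, max_rate=max_rate, dominant_freq=freq,
        osc_amp=osc_amp, rate_diff=rate_diff, alternating=alternating,
        b=params.b,
    )


def limit_cycle_masks(map_b0: StateMap, map_adapt: StateMap):
    """(LC_EI, LC_EA) boolean masks from scans without / with adaptation.

    LC_EI: oscillatory already without adaptation.  LC_EA: oscillatory only
    with adaptation, and alternating between up- and down-states (a slow
    relaxation cycle rather than an adaptation-shifted fast cycle).
    """
    if map_b0.label.shape != map_adapt.label.shape:
        raise ValueError("state maps must share the same grid")
    osc0 = map_b0.label == "oscillatory"
    lc_ei = osc0
    lc_ea = (map_adapt.label == "oscillatory") & ~osc0 & map_adapt.alternating
    return lc_ei, lc_ea
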