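"""Balloon-Windkessel hemodynamic model: firing rates to BOLD signals.

Each region's excitatory rate drives a four-state hemodynamic system
(vasodilatory signal s, blood inflow f, blood volume v, deoxyhemoglobin
content q) followed by the nonlinear BOLD readout:

    ds/dt = x - kappa s - gamma (f - 1)
    df/dt = s
    tau dv/dt = f - v^(1/alpha)
    tau dq/dt = f (1 - (1 - rho)^(1/f)) / rho - v^(1/alpha) q / v
    y = V0 (k1 (1 - q) + k2 (1 - q / v) + k3 (1 - v))

with the canonical constants (signal decay kappa = 0.65 s^-1, autoregulation
gamma = 0.41 s^-1, transit time tau = 0.98 s, vessel stiffness alpha = 0.32,
resting oxygen extraction rho = 0.34, resting venous volume V0 = 0.02).
The neural drive x is the rate normalized by a reference rate so it is O(1);
FC/FCD objectives are correlation- and distribution-based and therefore
insensitive to this global scaling.  The BOLD output is subsampled to 0.5 Hz
(2 s bin means) to match typical fMRI sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["BoldParams", "BoldTrace", "bold_transform"]


@dataclass(frozen=True)
class BoldParams:
    kappa: float = 0.65      # vasodilatory signal decay, s^-1
    gamma: float = 0.41      # flow autoregulation, s^-1
    tau: float = 0.98        # hemodynamic transit time, s
    alpha: float = 0.32      # vessel stiffness exponent
    rho: float = 0.34        # resting oxygen extraction fraction
    V0: float = 0.02         # resting venous volume fraction
    ref_rate_hz: float = 100.0  # neural drive normalization

    @property
    def k1(self) -> float:
        return 7.0 * self.rho

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.rho - 0.2


@dataclass
class BoldTrace:
    """Dimensionless BOLD signals at fs Hz (default 0.5 Hz)."""

    t: np.ndarray       # s
    y: np.ndarray       # (N, T_b)
    fs: float           # Hz

    @property
    def N(self) -> int:
        return self.y.shape[0]

    def save_tsv(self, path) -> None:
        """Plain-text export: first column time (s), one column per region."""
        import pandas as pd

        df = pd.DataFrame(self.y.T,
                          columns=[f"region_{i}" for i in range(self.N)])
        df.insert(0, "t_s", self.t)
        df.to_csv(path, sep="\t", index=False)


@njit(cache=True)
def _integrate_bold(x, dt_s, kappa, gamma, tau, alpha, rho, V0, k1, k2, k3):
    N, T = x.shape
    y = np.empty((N, T))
    ia = 1.0 / alpha
    for i in range(N):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            y[i, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
            ds = x[i, t] - kappa * s - gamma * (f - 1.0)
            df = s
            dv = (f - v**ia) / tau
            dq = (f * (1.0 - (1.0 - rho) ** (1.0 / f)) / rho - v**ia * q / v) / tau
            s += dt_s * ds
            f += dt_s * df
            v += dt_s * dv
            q += dt_s * dq
            if f < 1e-4:
                f = 1e-4
            if v < 1e-4:
                v = 1e-4
            if q < 1e-4:
                q = 1e-4
    return y


def bold_transform(
    rE_hz: np.ndarray,
    dt: float,
    params: BoldParams | None = None,
    out_fs: float = 0.5,
    discard_s: float = 20.0,
) -> BoldTrace:
    """Convert excitatory rates (N x T, Hz, sampled every ``dt`` ms) to BOLD.

    The hemodynamic ODEs are integrated with Euler at the neural sampling
    step; the readout is averaged over 1/out_fs bins (anti-aliased
    decimation) and an initial ``discard_s`` transient is dropped.
    Each region's BOLD depends only on that region's rate.
    """
    params = params or BoldParams()
    rE_hz = np.atleast_2d(np.asarray(rE_hz, dtype=float))
    if not np.all(np.isfinite(rE_hz)):
        raise ValueError("rate input must be finite")
    N, T = rE_hz.shape
    if T * dt < 30_000.0:
        raise ValueError("need at least 30 s of input for the hemodynamic transient")
    dt_s = dt / 1000.0
    x = rE_hz / params.ref_rate_hz
    y = _integrate_bold(
        x, dt_s, params.kappa, params.gamma, params.tau, params.alpha,
        params.rho, params.V0, params.k1, params.k2, params.k3,
    )
    bin_steps = int(round(1000.0 / (out_fs * dt)))
    n_bins = T // bin_steps
    yb = y[:, : n_bins * bin_steps].reshape(N, n_bins, bin_steps).mean(axis=2)
    tb = (np.arange(n_bins) + 0.5) * bin_steps * dt_s
    keep = tb >= discard_s
    return BoldTrace(t=tb[keep], y=yb[:, keep], fs=out_fs)
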