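"""Isolated cortical node: one excitatory-inhibitory mean-field pair.

The node shares its integration kernel with the full network; an isolated
node is a one-node network without global coupling, so a node driven with
stream i of :func:`slowbrain.network.node_seeds` reproduces node i of a
decoupled network exactly.
"""

from __future__ import annotations

import numpy as np

from .network import NetworkTrace, simulate_network, single_node_connectome
from .params import NodeParams
from .transfer import TransferTable

__all__ = ["ou_step", "ou_trajectory", "integrate_node"]


def ou_step(mu_ou, sigma_ou, tau_ou, dt, rng):
    """One Euler-Maruyama update of the zero-mean Ornstein-Uhlenbeck input.

    d(mu) = -mu / tau_ou * dt + sigma_ou * sqrt(dt) * xi,  xi ~ N(0, 1).
    Stationary variance is sigma_ou^2 * tau_ou / 2.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    xi = rng.standard_normal(np.shape(mu_ou)) if np.ndim(mu_ou) else rng.standard_normal()
    return mu_ou - mu_ou / tau_ou * dt + sigma_ou * np.sqrt(dt) * xi


def ou_trajectory(sigma_ou, tau_ou, duration, dt, rng, mu0=0.0):
    """Full OU sample path (vectorized over steps), for calibration tests."""
    n = int(round(duration / dt))
    xi = rng.standard_normal(n)
    out = np.empty(n + 1)
    out[0] = mu0
    decay = 1.0 - dt / tau_ou
    amp = sigma_ou * np.sqrt(dt)
    x = mu0
    for k in range(n):
        x = x * decay + amp * xi[k]
        out[k + 1] = x
    return out


def integrate_node(
    params: NodeParams,
    table: TransferTable,
    duration: float = 1000.0,
    dt: float = 0.1,
    seed=0,
    stimulus: np.ndarray | None = None,
    transient: float = 1000.0,
    rec_dt: float | None = None,
    init: str | tuple = "random",
) -> NetworkTrace:
    """Integrate a single isolated node (see :func:`simulate_network`).

    Returns a one-node trace: rates in Hz, adaptation current in pA,
    sampled every ``rec_dt`` ms over the recorded window.
    """
    return simulate_network(
        single_node_connectome(), params, table,
        K_gl=0.0, duration=duration, dt=dt, seed=seed,
        stimulus=stimulus, transient=transient, rec_dt=rec_dt, init=init,
    )
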