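"""Steady-state transfer functions of an AdEx/EIF population.

The mean-field node evaluates three precomputed maps over the plane of mean
membrane current mu (mV/ms) and current noise amplitude sigma (mV/sqrt(ms)):

* ``Phi_r(mu, sigma)``   -- stationary population firing rate (kHz),
* ``Phi_tau(mu, sigma)`` -- effective timescale of the linear-nonlinear
  cascade (ms), i.e. the exponential-filter time constant that reproduces the
  low-frequency attenuation of the population rate response,
* ``Phi_V(mu, sigma)``   -- mean membrane potential of the non-refractory
  population (mV).

All three are obtained from the stationary Fokker-Planck equation of the
exponential integrate-and-fire neuron driven by white noise, solved by
threshold integration on a voltage grid: the stationary density is integrated
backwards from the spike cutoff ``V_s`` with a unit probability flux between
reset and cutoff, and the rate follows from normalization with a refractory
correction r = r0 / (1 + r0 * T_ref).  The cascade timescale is extracted
from the linearized Fokker-Planck operator: the complex rate response to a
small sinusoidal modulation of mu is computed at several probe frequencies,
and tau is the least-squares time constant of the one-pole filter
R0 / (1 + i w tau).  Where the rate response is too small to fit (deep
subthreshold), tau falls back to the membrane time constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from numba import njit, prange

from .params import AdexParams

__all__ = [
    "TransferTable",
    "compute_transfer_tables",
    "cached_transfer_tables",
    "default_grids",
]

_OVERFLOW = 1e290


@njit(cache=True)
def _steady_state_point(mu, sigma, V, dV, iVr, tau_m, E_L, Delta_T, V_T, T_ref):
    """Unit-flux stationary density -> (rate kHz, mean voltage mV).

    Integrates D p' = F p - j downward from V_s with p(V_s) = 0 and unit flux
    j = 1 on (V_r, V_s], using an exponential (integrating-factor) step.
    """
    n = V.shape[0]
    D = 0.5 * sigma * sigma
    integ = 0.0
    vinteg = 0.0
    p_hi = 0.0
    overflowed = False
    for k in range(n - 1, 0, -1):
        Vmid = 0.5 * (V[k] + V[k - 1])
        F = (E_L - Vmid + Delta_T * np.exp((Vmid - V_T) / Delta_T)) / tau_m + mu
        G = F / D
        j = 1.0 if (k - 1) >= iVr else 0.0
        Gh = G * dV
        if np.abs(Gh) > 1e-10:
            eGh = np.exp(-Gh)
            p_lo = p_hi * eGh + (j / D) * (1.0 - eGh) / G
        else:
            p_lo = p_hi * (1.0 - Gh) + (j / D) * dV
        if p_lo > _OVERFLOW:
            p_lo = _OVERFLOW
            overflowed = True
        if p_lo < 0.0:
            p_lo = 0.0
        integ += 0.5 * (p_hi + p_lo) * dV
        vinteg += 0.5 * (p_hi * V[k] + p_lo * V[k - 1]) * dV
        p_hi = p_lo
    if overflowed or integ > _OVERFLOW:
        return 0.0, np.nan
    r = 1.0 / (integ + T_ref)
    return r, vinteg / integ


@njit(cache=True)
def _rate_response_point(
    mu, sigma, omega, r, V, dV, iVr, tau_m, E_L, Delta_T, V_T, T_ref
):
    """Linear rate response R(omega) = r_hat / mu_hat of the FP operator.

    Solves the two backward systems of the linearized stationary problem
    (reinjection system A and drive system B, the latter sourced by the
    normalized stationary density) and matches the zero-flux condition at the
    lower voltage bound.  Returns the complex response in kHz per mV/ms;
    0 if the stationary rate vanishes.
    """
    if r <= 0.0:
        return 0.0 + 0.0j
    n = V.shape[0]
    D = 0.5 * sigma * sigma
    # system A: (pA, jA), reinjection at V_r with refractory phase lag
    pA = 0.0 + 0.0j
    jA = 1.0 + 0.0j
    # system B: (pB, jB), sourced by stationary density P0 = r * p_tilde
    pB = 0.0 + 0.0j
    jB = 0.0 + 0.0j
    p0_hi = 0.0  # unit-flux stationary density, rebuilt on the fly
    reinj = np.exp(-1j * omega * T_ref)
    iw = 1j * omega
    for k in range(n - 1, 0, -1):
        Vmid = 0.5 * (V[k] + V[k - 1])
        F = (E_L - Vmid + Delta_T * np.exp((Vmid - V_T) / Delta_T)) / tau_m + mu
        G = F / D
        Gh = G * dV
        j0 = 1.0 if (k - 1) >= iVr else 0.0
        if np.abs(Gh) > 1e-10:
            eGh = np.exp(-Gh)
            gfac = (1.0 - eGh) / G
        else:
            eGh = 1.0 - Gh
            gfac = dV
        # flux updates (dj/dV = -i w p, downward step)
        jA_lo = jA + dV * iw * pA
        jB_lo = jB + dV * iw * pB
        # density updates: D p' = F p + S - j  with S_A = 0, S_B = P0
        SB = r * p0_hi
        pA = pA * eGh + (jA / D) * gfac
        pB = pB * eGh + ((jB - SB) / D) * gfac
        jA = jA_lo
        jB = jB_lo
        if k - 1 == iVr:
            jA = jA - reinj
        # advance stationary density
        p0_lo = p0_hi * eGh + (j0 / D) * gfac
        if p0_lo > _OVERFLOW:
            p0_lo = _OVERFLOW
        if p0_lo < 0.0:
            p0_lo = 0.0
        p0_hi = p0_lo
        if not (np.isfinite(pA.real) and np.isfinite(pB.real)):
            return 0.0 + 0.0j
    if np.abs(jA) < 1e-300:
        return 0.0 + 0.0j
    return -jB / jA


@njit(cache=True)
def _fit_one_pole_tau(R0, Rs, omegas, tau_max):
    """Least-squares time constant of the one-pole cascade filter.

    Minimizes sum_k |R_k - R0 / (1 + i w_k tau)|^2 over tau by a coarse
    grid scan followed by local refinement.  The complex (amplitude and
    phase) residual is essential: in the mean-driven regime the EIF
    amplitude response is resonant rather than low-pass, and only the
    phase lag pins down a meaningful filter timescale.
    """
    nf = omegas.shape[0]
    best_tau = 0.0
    best_err = 1e300
    # coarse scan
    n_coarse = 121
    for a in range(n_coarse):
        tau = tau_max * a / (n_coarse - 1)
        err = 0.0
        for k in range(nf):
            err += np.abs(Rs[k] - R0 / (1.0 + 1j * omegas[k] * tau)) ** 2
        if err < best_err:
            best_err = err
            best_tau = tau
    # refine around the coarse optimum
    half = tau_max / (n_coarse - 1)
    lo = best_tau - half
    hi = best_tau + half
    for a in range(41):
        tau = lo + (hi - lo) * a / 40.0
        if tau < 0.0:
            continue
        err = 0.0
        for k in range(nf):
            err += np.abs(Rs[k] - R0 / (1.0 + 1j * omegas[k] * tau)) ** 2
        if err < best_err:
            best_err = err
            best_tau = tau
    return best_tau


@njit(parallel=True, cache=True)
def _fill_tables(
    mu_grid, sigma_grid, V, dV, iVr, tau_m, E_L, Delta_T, V_T, T_ref,
    omega0, omegas, tau_max,
):
    """Tabulate rate, cascade timescale and mean voltage over the grid."""
    nm = mu_grid.shape[0]
    ns = sigma_grid.shape[0]
    nf = omegas.shape[0]
    r_tab = np.empty((nm, ns))
    tau_tab = np.empty((nm, ns))
    V_tab = np.empty((nm, ns))
    for i in prange(nm):
        mu = mu_grid[i]
        Rs = np.empty(nf, dtype=np.complex128)
        for j in range(ns):
            sigma = sigma_grid[j]
            r, Vm = _steady_state_point(
                mu, sigma, V, dV, iVr, tau_m, E_L, Delta_T, V_T, T_ref
            )
            r_tab[i, j] = r
            V_tab[i, j] = Vm
            R0 = np.abs(_rate_response_point(
                mu, sigma, omega0, r, V, dV, iVr, tau_m, E_L, Delta_T, V_T,
                T_ref,
            ))
            if R0 > 1e-9:
                for k in range(nf):
                    Rs[k] = _rate_response_point(
                        mu, sigma, omegas[k], r, V, dV, iVr, tau_m, E_L,
                        Delta_T, V_T, T_ref,
                    )
                tau_tab[i, j] = _fit_one_pole_tau(R0, Rs, omegas, tau_max)
            else:
                # deep subthreshold: response too small to fit, membrane
                # relaxation sets the scale
                tau_tab[i, j] = tau_m
    return r_tab, tau_tab, V_tab


@njit(cache=True)
def bilinear_lookup(mu_grid, sigma_grid, table, mu, sigma):
    """Bilinear interpolation with clamping to the grid edges."""
    nm = mu_grid.shape[0]
    ns = sigma_grid.shape[0]
    if mu <= mu_grid[0]:
        i, fx = 0, 0.0
    elif mu >= mu_grid[nm - 1]:
        i, fx = nm - 2, 1.0
    else:
        i = np.searchsorted(mu_grid, mu) - 1
        fx = (mu - mu_grid[i]) / (mu_grid[i + 1] - mu_grid[i])
    if sigma <= sigma_grid[0]:
        j, fy = 0, 0.0
    elif sigma >= sigma_grid[ns - 1]:
        j, fy = ns - 2, 1.0
    else:
        j = np.searchsorted(sigma_grid, sigma) - 1
        fy = (sigma - sigma_grid[j]) / (sigma_grid[j + 1] - sigma_grid[j])
    t00 = table[i, j]
    t10 = table[i + 1, j]
    t01 = table[i, j + 1]
    t11 = table[i + 1, j + 1]
    return (
        t00 * (1 - fx) * (1 - fy)
        + t10 * fx * (1 - fy)
        + t01 * (1 - fx) * fy
        + t11 * fx * fy
    )


def default_grids(
    mu_min: float = -2.0,
    mu_max: float = 6.0,
    mu_step: float = 0.05,
    sigma_min: float = 0.05,
    sigma_max: float = 5.0,
    sigma_step: float = 0.05,
):
    """Default (mu, sigma) grids covering the state-space scans of the model
    (external inputs 0-4 mV/ms) plus synaptic and adaptation offsets."""
    mu = np.round(np.arange(mu_min, mu_max + mu_step / 2, mu_step), 10)
    sigma = np.round(np.arange(sigma_min, sigma_max + sigma_step / 2, sigma_step), 10)
    return mu, sigma


@dataclass
class TransferTable:
    """Gridded steady-state maps Phi_r (kHz), Phi_tau (ms), Phi_V (mV)."""

    mu_grid: np.ndarray
    sigma_grid: np.ndarray
    r: np.ndarray
    tau: np.ndarray
    V: np.ndarray
    adex: AdexParams

    def lookup(self, mu_eff: float, sigma: float):
        """Interpolated (rate kHz, tau ms, V mV) at a single query point.

        Queries outside the grid are clamped to the nearest edge value.
        """
        if not (np.isfinite(mu_eff) and np.isfinite(sigma)):
            raise ValueError("NaN/inf query to transfer table")
        r = bilinear_lookup(self.mu_grid, self.sigma_grid, self.r, mu_eff, sigma)
        t = bilinear_lookup(self.mu_grid, self.sigma_grid, self.tau, mu_eff, sigma)
        v = bilinear_lookup(self.mu_grid, self.sigma_grid, self.V, mu_eff, sigma)
        return r, t, v

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mu_grid", data=self.mu_grid)
            f.create_dataset("sigma_grid", data=self.sigma_grid)
            f.create_dataset("r", data=self.r)
            f.create_dataset("tau", data=self.tau)
            f.create_dataset("V", data=self.V)
            for key, val in vars(self.adex).items():
                f.attrs[key] = val
            f.attrs["adex_digest"] = self.adex.digest()

    @classmethod
    def load(cls, path, adex: AdexParams | None = None) -> "TransferTable":
        with h5py.File(path, "r") as f:
            stored = AdexParams(
                **{
                    k: float(f.attrs[k])
                    for k in (
                        "C", "g_L", "E_L", "Delta_T", "V_T", "V_s", "V_r",
                        "T_ref", "E_A", "a",
                    )
                }
            )
            if adex is not None and adex.digest() != stored.digest():
                raise ValueError(
                    "cached transfer table was computed for different AdEx "
                    "parameters; recompute required"
                )
            return cls(
                mu_grid=f["mu_grid"][:],
                sigma_grid=f["sigma_grid"][:],
                r=f["r"][:],
                tau=f["tau"][:],
                V=f["V"][:],
                adex=stored,
            )


def _check_grid(name: str, g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.ndim != 1 or g.size < 2 or not np.all(np.diff(g) > 0):
        raise ValueError(f"{name} must be a strictly increasing 1-D vector")
    return g


def compute_transfer_tables(
    params: AdexParams | None = None,
    mu_grid: np.ndarray | None = None,
    sigma_grid: np.ndarray | None = None,
    dV: float = 0.01,
    V_lb: float = -200.0,
    fit_freqs_hz: tuple = (1.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0),
    tau_clamp: tuple[float, float] = (0.2, 100.0),
) -> TransferTable:
    """Compute Phi_r, Phi_tau, Phi_V on a (mu, sigma) grid.

    Parameters
    ----------
    params
        Single-neuron parameters; defaults to the reference set.
    mu_grid, sigma_grid
        Strictly increasing grids (mV/ms and mV/sqrt(ms)); sigma must be > 0.
    dV
        Voltage discretization of the threshold integration, mV.
    V_lb
        Lower bound of the voltage grid, mV.
    fit_freqs_hz
        Frequencies (Hz) at which the complex linear rate response is
        evaluated for the least-squares one-pole fit of the cascade
        timescale.
    tau_clamp
        (min, max) clamp of the tabulated timescale in ms; the lower clamp
        keeps the forward-Euler current relaxation stable at dt = 0.1 ms.
    """
    params = params or AdexParams()
    if mu_grid is None or sigma_grid is None:
        dmu, dsg = default_grids()
        mu_grid = dmu if mu_grid is None else mu_grid
        sigma_grid = dsg if sigma_grid is None else sigma_grid
    mu_grid = _check_grid("mu_grid", mu_grid)
    sigma_grid = _check_grid("sigma_grid", sigma_grid)
    if sigma_grid[0] <= 0:
        raise ValueError("sigma_grid must be positive")

    V = np.arange(V_lb, params.V_s + dV / 2, dV)
    iVr = int(np.argmin(np.abs(V - params.V_r)))
    omega0 = 2 * np.pi * 0.5e-3  # 0.5 Hz: quasi-static reference, rad/ms
    omegas = 2 * np.pi * 1e-3 * np.asarray(fit_freqs_hz, dtype=float)

    r_tab, tau_tab, V_tab = _fill_tables(
        mu_grid, sigma_grid, V, dV, iVr,
        params.tau_m, params.E_L, params.Delta_T, params.V_T, params.T_ref,
        omega0, omegas, tau_clamp[1] * 0.3,
    )
    # mean voltage is undefined where the density normalization overflowed
    # (deep subthreshold, vanishing rate): fall back to the noise-free
    # equilibrium potential, clipped to the reset.
    bad = ~np.isfinite(V_tab)
    if np.any(bad):
        mu_col = np.broadcast_to(mu_grid[:, None], V_tab.shape)
        V_eq = np.clip(params.E_L + mu_col * params.tau_m, V_lb, params.V_r)
        V_tab = np.where(bad, V_eq, V_tab)
    if not (np.all(np.isfinite(r_tab)) and np.all(np.isfinite(tau_tab))):
        i, j = np.argwhere(~(np.isfinite(r_tab) & np.isfinite(tau_tab)))[0]
        raise ArithmeticError(
            f"threshold integration failed at mu={mu_grid[i]}, "
            f"sigma={sigma_grid[j]}"
        )
    return TransferTable(
        mu_grid=mu_grid, sigma_grid=sigma_grid,
        r=r_tab, tau=np.clip(tau_tab, *tau_clamp), V=V_tab, adex=params,
    )


def cached_transfer_tables(
    params: AdexParams | None = None,
    cache_dir=None,
    **kwargs,
) -> TransferTable:
    """Compute the default-grid tables, or load them from an HDF5 cache.

    The cache file name embeds a hash of the AdEx parameters, so a parameter
    change forces recomputation.  With ``cache_dir=None`` a per-user cache
    directory is used.
    """
    import os
    from pathlib import Path

    params = params or AdexParams()
    if cache_dir is None:
        cache_dir = Path(
            os.environ.get("XDG_CACHE_HOME", Path.home() / ".cache")
        ) / "slowbrain"
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"transfer_{params.digest()}.h5"
    if path.exists():
        try:
            return TransferTable.load(path, adex=params)
        except (OSError, ValueError, KeyError):
            path.unlink(missing_ok=True)
    table = compute_transfer_tables(params, **kwargs)
    table.save(path)
    return table
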