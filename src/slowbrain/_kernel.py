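"""Forward-Euler integration kernel for the delayed E-I mean-field network.

One compiled kernel serves both the isolated node (N = 1, K_gl = 0) and the
connectome-coupled network.  Rates are carried in kHz; the synaptic drive
variables z1 (dimensionless) and z2 (ms) are the delay-weighted presynaptic
rate sums of the second-moment closure.  Inter-areal coupling is E-to-E only,
with per-pair delays read from a ring buffer of past excitatory rates.
"""

import numpy as np
from numba import njit

from .transfer import bilinear_lookup

OK = 0
ERR_NAN = 1
ERR_RATE = 2


@njit(cache=True)
def integrate_chunk(
    # per-node state, length N (updated in place)
    mu_E, mu_I, ou_E, ou_I,
    seem, seim, siem, siim,
    seev, seiv, siev, siiv,
    IA,
    # ring buffers (N, L) of past rates in kHz, written at slot t % L
    rE_buf, rI_buf,
    # connectivity: weights, squared weights, integer delay steps
    Cmat, C2mat, Dsteps,
    # chunk inputs
    noise,            # (N, 2, n) standard normals
    stim,             # (1, n) or (N, n), added to mu_E_ext, mV/ms
    # transfer tables
    mu_grid, sigma_grid, r_tab, tau_tab, V_tab,
    # integration control
    dt, t0, n, t_rec_start, rec_every,
    # local delay steps
    sdE, sdI,
    # synaptic constants
    aEE, aEI, aIE, aII,       # c_ab * tau_s_b / |J_ab|
    Ke, Ki, Kgl,
    JEE, JEI, JIE, JII,
    tausE, tausI, taum,
    sigma_ext2,
    muEext, muIext,
    Cap, b, tauA, a_sub, E_A,
    sigma_ou, tau_ou,
    # outputs
    rec_rE, rec_rI, rec_IA, rec_VE,   # (N, n_rec)
    mean_rE,                          # (n_mean,) kHz at full dt
):
    N = mu_E.shape[0]
    L = rE_buf.shape[1]
    # refractory bound: rate cannot exceed 1/T_ref; tables already enforce it
    # and interpolation cannot exceed the table max.
    rbound = r_tab.max() * 1.001 + 1e-12
    sqdt = np.sqrt(dt)
    ou_decay = dt / tau_ou

    for s in range(n):
        tg = t0 + s
        slot = tg % L
        # ring-buffer read positions: all delays are < L, so a single
        # conditional wrap replaces the modulo
        iE = slot - sdE
        if iE < 0:
            iE += L
        iI = slot - sdI
        if iI < 0:
            iI += L
        # --- delayed presynaptic drive -------------------------------------
        for i in range(N):
            rE_dE = rE_buf[i, iE]
            rE_dI = rE_buf[i, iI]
            rI_dE = rI_buf[i, iE]
            rI_dI = rI_buf[i, iI]
            gsum = 0.0
            g2sum = 0.0
            if Kgl > 0.0:
                for j in range(N):
                    c = Cmat[i, j]
                    if c != 0.0:
                        idx = slot - Dsteps[i, j]
                        if idx < 0:
                            idx += L
                        rdel = rE_buf[j, idx]
                        gsum += c * rdel
                        g2sum += C2mat[i, j] * rdel
            z1ee = aEE * (Ke * rE_dE + Kgl * gsum)
            z1ei = aEI * Ki * rI_dE
            z1ie = aIE * (Ke * rE_dI + 0.0)
            z1ii = aII * Ki * rI_dI
            z2ee = aEE * aEE * (Ke * rE_dE + Kgl * g2sum)
            z2ei = aEI * aEI * Ki * rI_dE
            z2ie = aIE * aIE * Ke * rE_dI
            z2ii = aII * aII * Ki * rI_dI

            # --- membrane-current noise amplitudes (second moments) --------
            sigE2 = (
                2.0 * JEE * JEE * seev[i] * tausE * taum
                / ((1.0 + z1ee) * taum + tausE)
                + 2.0 * JEI * JEI * seiv[i] * tausI * taum
                / ((1.0 + z1ei) * taum + tausI)
                + sigma_ext2
            )
            sigI2 = (
                2.0 * JIE * JIE * siev[i] * tausE * taum
                / ((1.0 + z1ie) * taum + tausE)
                + 2.0 * JII * JII * siiv[i] * tausI * taum
                / ((1.0 + z1ii) * taum + tausI)
                + sigma_ext2
            )
            sigE = np.sqrt(sigE2)
            sigI = np.sqrt(sigI2)

            # --- transfer-function lookups ----------------------------------
            mu_eff = mu_E[i] - IA[i] / Cap
            rE = bilinear_lookup(mu_grid, sigma_grid, r_tab, mu_eff, sigE)
            tauE = bilinear_lookup(mu_grid, sigma_grid, tau_tab, mu_eff, sigE)
            VE = bilinear_lookup(mu_grid, sigma_grid, V_tab, mu_eff, sigE)
            rI = bilinear_lookup(mu_grid, sigma_grid, r_tab, mu_I[i], sigI)
            tauI = bilinear_lookup(mu_grid, sigma_grid, tau_tab, mu_I[i], sigI)

            if not (np.isfinite(rE) and np.isfinite(rI) and np.isfinite(mu_E[i])):
                return ERR_NAN, i, tg
            if rE > rbound or rI > rbound:
                return ERR_RATE, i, tg

            rE_buf[i, slot] = rE
            rI_buf[i, slot] = rI
            if tg >= t_rec_start:
                k = tg - t_rec_start
                mean_rE[k] += rE / N
                if k % rec_every == 0:
                    kr = k // rec_every
                    rec_rE[i, kr] = rE
                    rec_rI[i, kr] = rI
                    rec_IA[i, kr] = IA[i]
                    rec_VE[i, kr] = VE

            # --- Euler update ----------------------------------------------
            stim_t = stim[i, s] if stim.shape[0] > 1 else stim[0, s]
            d_muE = (
                JEE * seem[i] + JEI * seim[i] + muEext + stim_t + ou_E[i]
                - mu_E[i]
            ) / tauE
            d_muI = (
                JIE * siem[i] + JII * siim[i] + muIext + ou_I[i] - mu_I[i]
            ) / tauI
            mu_E[i] += dt * d_muE
            mu_I[i] += dt * d_muI

            seem[i] += dt * ((1.0 - seem[i]) * z1ee - seem[i]) / tausE
            seim[i] += dt * ((1.0 - seim[i]) * z1ei - seim[i]) / tausI
            siem[i] += dt * ((1.0 - siem[i]) * z1ie - siem[i]) / tausE
            siim[i] += dt * ((1.0 - siim[i]) * z1ii - siim[i]) / tausI

            seev[i] += dt * (
                (1.0 - seem[i]) ** 2 * z2ee
                + (z2ee - 2.0 * tausE * (z1ee + 1.0)) * seev[i]
            ) / (tausE * tausE)
            seiv[i] += dt * (
                (1.0 - seim[i]) ** 2 * z2ei
                + (z2ei - 2.0 * tausI * (z1ei + 1.0)) * seiv[i]
            ) / (tausI * tausI)
            siev[i] += dt * (
                (1.0 - siem[i]) ** 2 * z2ie
                + (z2ie - 2.0 * tausE * (z1ie + 1.0)) * siev[i]
            ) / (tausE * tausE)
            siiv[i] += dt * (
                (1.0 - siim[i]) ** 2 * z2ii
                + (z2ii - 2.0 * tausI * (z1ii + 1.0)) * siiv[i]
            ) / (tausI * tausI)
            if seev[i] < 0.0:
                seev[i] = 0.0
            if seiv[i] < 0.0:
                seiv[i] = 0.0
            if siev[i] < 0.0:
                siev[i] = 0.0
            if siiv[i] < 0.0:
                siiv[i] = 0.0

            IA[i] += dt * ((a_sub * (VE - E_A) - IA[i]) / tauA + b * rE)

            ou_E[i] += -ou_E[i] * ou_decay + sigma_ou * sqdt * noise[i, 0, s]
            ou_I[i] += -ou_I[i] * ou_decay + sigma_ou * sqdt * noise[i, 1, s]
    return OK, -1, t0 + n


@njit(cache=True)
def prefill_buffers(
    rE_buf, rI_buf, mu_E, mu_I, IA, Cap,
    mu_grid, sigma_grid, r_tab, sigma_ext,
):
    """Constant-history initialization: fill the delay buffers with the rates
    implied by the initial state (synapses silent, sigma = sigma_ext)."""
    N = mu_E.shape[0]
    for i in range(N):
        rE0 = bilinear_lookup(
            mu_grid, sigma_grid, r_tab, mu_E[i] - IA[i] / Cap, sigma_ext
        )
        rI0 = bilinear_lookup(mu_grid, sigma_grid, r_tab, mu_I[i], sigma_ext)
        rE_buf[i, :] = rE0
        rI_buf[i, :] = rI0
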