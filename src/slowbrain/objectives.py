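"""Fitness objectives: FC correlation, FCD distance, EEG-spectrum correlation.

Three complementary measures link the simulated activity to empirical
recordings: the static functional connectivity (Pearson correlations of BOLD
time series), its temporal dynamics (the FCD matrix of correlations between
sliding-window FCs, compared by Kolmogorov-Smirnov distance of their
off-diagonal distributions), and the power spectrum of the mean excitatory
rate compared against an EEG power spectrum over 0-40 Hz.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import welch
from scipy.stats import ks_2samp, pearsonr

from .bold import BoldTrace

__all__ = [
    "compute_fc",
    "fc_similarity",
    "compute_fcd",
    "fcd_distance",
    "spectrum_fit",
    "rate_spectrum",
    "FitnessVector",
]


def _as_bold_array(bold) -> np.ndarray:
    if isinstance(bold, BoldTrace):
        return bold.y
    return np.atleast_2d(np.asarray(bold, dtype=float))


def compute_fc(bold) -> np.ndarray:
    """Pearson correlation matrix of the per-region BOLD time series.

    Zero-variance regions yield zero rows/columns (with a warning) rather
    than NaN; the diagonal is always 1.
    """
    y = _as_bold_array(bold)
    if y.shape[1] < 2:
        raise ValueError("need at least 2 samples per region")
    sd = y.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance region(s) set to 0 in FC")
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(y)
    fc[np.isnan(fc)] = 0.0
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices_from(m, k=-1)
    return m[i, j]


def fc_similarity(sim_fc: np.ndarray, emp_fcs) -> float:
    """Mean Pearson correlation of lower-triangular FC elements across
    subjects (diagonal omitted); higher is better, range [-1, 1]."""
    if isinstance(emp_fcs, np.ndarray) and emp_fcs.ndim == 2:
        emp_fcs = [emp_fcs]
    sim_lt = _lower_triangle(np.asarray(sim_fc))
    scores = []
    for emp in emp_fcs:
        emp = np.asarray(emp)
        if emp.shape != sim_fc.shape:
            raise ValueError("FC matrices must have equal size")
        scores.append(pearsonr(sim_lt, _lower_triangle(emp)).statistic)
    return float(np.mean(scores))


def compute_fcd(
    bold, window_s: float = 60.0, step_s: float = 10.0
) -> np.ndarray:
    """Functional connectivity dynamics matrix.

    A rolling window (default 60 s, step 10 s) yields windowed FC matrices;
    the FCD is the matrix of Pearson correlations between the lower
    triangles of all window pairs.  Windows start at t = 0 and a trailing
    partial window is dropped.
    """
    y = _as_bold_array(bold)
    fs = bold.fs if isinstance(bold, BoldTrace) else 0.5
    wlen = int(round(window_s * fs))
    step = int(round(step_s * fs))
    T = y.shape[1]
    if T < wlen + step:
        raise ValueError("BOLD series shorter than one window plus one step")
    n_win = (T - wlen) // step + 1
    lts = []
    for w in range(n_win):
        seg = y[:, w * step : w * step + wlen]
        lts.append(_lower_triangle(compute_fc(seg)))
    lts = np.array(lts)
    fcd = np.corrcoef(lts)
    fcd[np.isnan(fcd)] = 0.0
    np.fill_diagonal(fcd, 1.0)
    return fcd


def fcd_distance(sim_fcd: np.ndarray, emp_fcds) -> float:
    """Two-sample KS distance between the off-diagonal FCD distributions,
    averaged over subjects; 0 = identical, 1 = maximally different."""
    if isinstance(emp_fcds, np.ndarray) and emp_fcds.ndim == 2:
        emp_fcds = [emp_fcds]
    sim_vals = _lower_triangle(np.asarray(sim_fcd))
    ds = []
    for emp in emp_fcds:
        emp_vals = _lower_triangle(np.asarray(emp))
        if sim_vals.size == 0 or emp_vals.size == 0:
            raise ValueError("FCD matrices too small")
        ds.append(ks_2samp(sim_vals, emp_vals).statistic)
    return float(np.mean(ds))


def rate_spectrum(
    rate_hz: np.ndarray, dt: float, window_s: float = 10.0
):
    """Welch power spectrum of a rate signal (Hann window, default 10 s),
    giving 1/window_s Hz resolution.  Returns (freqs Hz, power)."""
    x = np.asarray(rate_hz, dtype=float)
    fs = 1000.0 / dt
    nper = int(round(window_s * fs))
    if x.size < nper:
        nper = x.size
    freqs, power = welch(x - x.mean(), fs=fs, window="hann", nperseg=nper)
    return freqs, power


def spectrum_fit(
    sim_rate_hz: np.ndarray,
    dt: float,
    emp_freqs: np.ndarray,
    emp_power: np.ndarray,
    fmax: float = 40.0,
    last_s: float = 60.0,
) -> float:
    """Pearson correlation between simulated and empirical power spectra
    over 0-``fmax`` Hz (linear power).

    The simulated side uses the last ``last_s`` seconds of the across-region
    mean excitatory rate; the empirical spectrum is interpolated onto the
    simulated frequency grid before correlating.
    """
    x = np.asarray(sim_rate_hz, dtype=float)
    n_need = int(round(last_s * 1000.0 / dt))
    if x.size < n_need:
        raise ValueError(f"need at least {last_s} s of simulated rate")
    freqs, power = rate_spectrum(x[-n_need:], dt)
    band = (freqs > 0) & (freqs <= fmax)
    emp_freqs = np.asarray(emp_freqs, dtype=float)
    emp_power = np.asarray(emp_power, dtype=float)
    if emp_freqs[0] > freqs[band][0] or emp_freqs[-1] < freqs[band][-1]:
        warnings.warn("empirical spectrum does not cover 0-40 Hz; resampling "
                      "restricted to the overlap")
        band &= (freqs >= emp_freqs[0]) & (freqs <= emp_freqs[-1])
    emp_i = np.interp(freqs[band], emp_freqs, emp_power)
    return float(pearsonr(power[band], emp_i).statistic)


class FitnessVector:
    """Fitness of one simulated parameterization.

    fc_corr and spec_corr are maximized, fcd_ks is minimized; ``valid``
    marks individuals that survived the screening filters.
    """

    __slots__ = ("fc_corr", "fcd_ks", "spec_corr", "valid")

    def __init__(self, fc_corr=np.nan, fcd_ks=np.nan, spec_corr=np.nan,
                 valid=False):
        self.fc_corr = float(fc_corr)
        self.fcd_ks = float(fcd_ks)
        self.spec_corr = float(spec_corr)
        self.valid = bool(valid)

    def as_minimization(self, use_spectrum: bool = True) -> tuple:
        """Objective tuple for the minimizing optimizer."""
        if use_spectrum:
            return (-self.fc_corr, self.fcd_ks, -self.spec_corr)
        return (-self.fc_corr, self.fcd_ks)

    def __repr__(self) -> str:
        return (f"FitnessVector(fc={self.fc_corr:.3f}, ks={self.fcd_ks:.3f}, "
                f"spec={self.spec_corr:.3f}, valid={self.valid})")
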