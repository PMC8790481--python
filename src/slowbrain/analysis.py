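"""Slow-oscillation statistics: up/down states, involvement, waves, phases.

The pipeline quantifies the spatiotemporal organization of slow oscillations
in a simulated rate trace:

1. per-region binary up/down rasters by rate thresholding,
2. the involvement time series I(t) = n(t)/N (fraction of regions in a
   given state),
3. local (25-50 % involvement) and global (> 50 %) wave events from peaks
   of the smoothed involvement,
4. state-duration and inter-event-interval statistics,
5. a whole-brain oscillation phase from the band-passed, Hilbert-transformed
   involvement, per-region mean transition phases, and their regression
   against the anterior-posterior coordinate (traveling-wave direction),
6. Kuramoto order parameter and metastability of down-transition timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt
from scipy.stats import linregress

__all__ = [
    "StateRaster",
    "detect_states",
    "involvement",
    "WaveEvent",
    "detect_waves",
    "state_durations",
    "state_statistics",
    "global_phase",
    "transition_phases",
    "kuramoto",
    "ap_regression",
    "circular_mean",
]

#: default up-state detection threshold as a fraction of each region's
#: maximum rate
THETA = 0.01
#: minimum state duration, ms; shorter runs are replaced by the preceding
#: state
MIN_STATE_MS = 50.0


def _clean_runs(states: np.ndarray, min_len: int) -> np.ndarray:
    """Replace runs shorter than ``min_len`` samples with the preceding
    state, scanning left to right (the leading run is always kept)."""
    s = states.copy()
    n = s.size
    i = 0
    # leading run is kept regardless of length
    first = s[0]
    while i < n and s[i] == first:
        i += 1
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        if j - i < min_len:
            s[i:j] = s[i - 1]
            # do not advance: the merged run may still be short relative
            # to what follows; rescan from the merge point
        i = j
    return s


@dataclass
class StateRaster:
    """Binary up/down raster (True = up) with the thresholds used."""

    up: np.ndarray          # (N, T) bool
    dt: float               # sampling interval, ms
    max_rate: np.ndarray    # per-region max rate used for thresholding, Hz
    theta: float = THETA

    @property
    def N(self) -> int:
        return self.up.shape[0]

    @property
    def T(self) -> int:
        return self.up.shape[1]


def detect_states(
    rE_hz: np.ndarray,
    dt: float,
    theta: float = THETA,
    min_dur: float = MIN_STATE_MS,
) -> StateRaster:
    """Threshold each region's rate into up/down states and clean short runs.

    A region is up where r_E(t) > theta * max_t r_E(t); states shorter than
    ``min_dur`` ms are replaced by the preceding state.  An all-zero region
    is reported all-down.
    """
    rE_hz = np.atleast_2d(np.asarray(rE_hz, dtype=float))
    if not np.all(np.isfinite(rE_hz)):
        raise ValueError("rates must be finite")
    N, T = rE_hz.shape
    max_rate = rE_hz.max(axis=1)
    up = np.zeros((N, T), dtype=bool)
    min_len = max(1, int(round(min_dur / dt)))
    for i in range(N):
        if max_rate[i] <= 0.0:
            continue
        raw = rE_hz[i] > theta * max_rate[i]
        up[i] = _clean_runs(raw, min_len)
    return StateRaster(up=up, dt=dt, max_rate=max_rate, theta=theta)


def involvement(raster: StateRaster, polarity: str = "down") -> np.ndarray:
    """Involvement time series I(t) = n(t)/N of regions in the given state.

    Down-involvement is the default (the down-state onset marks the start
    of a slow oscillation); up- and down-involvement sum to 1 at every t.
    """
    if polarity == "down":
        return (~raster.up).mean(axis=0)
    if polarity == "up":
        return raster.up.mean(axis=0)
    raise ValueError("polarity must be 'down' or 'up'")


@dataclass
class WaveEvent:
    """One slow-oscillation event detected as a peak of smoothed involvement."""

    t_peak: float            # ms
    involvement: float       # peak involvement, fraction of regions
    kind: str                # "local" (0.25-0.5), "global" (> 0.5) or "sub"
    regions: np.ndarray = field(default_factory=lambda: np.array([], int))


def detect_waves(
    I: np.ndarray,
    dt: float,
    smooth_ms: float = 200.0,
    min_height: float = 0.10,
    min_dist_ms: float = 100.0,
    raster: StateRaster | None = None,
) -> list[WaveEvent]:
    """Detect slow-wave events as peaks of the Gaussian-smoothed involvement.

    Peaks below ``min_height`` involvement are ignored and peaks closer than
    ``min_dist_ms`` are merged.  Events are classified global if the peak
    involvement exceeds 50 %, local if between 25 and 50 %, and "sub"
    otherwise (kept for the involvement histogram but excluded from the
    local/global statistics).  If a raster is given, the regions that are in
    the down-state at the peak are attached to each event.
    """
    I = np.asarray(I, dtype=float)
    sm = gaussian_filter1d(I, sigma=smooth_ms / dt)
    idx, _ = find_peaks(sm, height=min_height, distance=max(1, int(round(min_dist_ms / dt))))
    events = []
    for k in idx:
        amp = sm[k]
        if amp > 0.5:
            kind = "global"
        elif amp > 0.25:
            kind = "local"
        else:
            kind = "sub"
        regions = (
            np.flatnonzero(~raster.up[:, k]) if raster is not None
            else np.array([], int)
        )
        events.append(
            WaveEvent(t_peak=k * dt, involvement=float(amp), kind=kind,
                      regions=regions)
        )
    return events


def state_durations(raster: StateRaster):
    """Pooled up- and down-state durations (ms) across regions.

    Leading and trailing runs are censored (their true duration is unknown).
    """
    ups, downs = [], []
    for i in range(raster.N):
        s = raster.up[i]
        change = np.flatnonzero(np.diff(s.astype(np.int8)))
        if change.size < 2:
            continue
        bounds = change + 1
        for a, b in zip(bounds[:-1], bounds[1:]):
            dur = (b - a) * raster.dt
            (ups if s[a] else downs).append(dur)
    return np.asarray(ups), np.asarray(downs)


def _interval_stats(times_ms: np.ndarray) -> dict:
    if times_ms.size < 2:
        return {"n": int(times_ms.size), "mean": np.nan, "intervals": np.array([])}
    iv = np.diff(np.sort(times_ms))
    return {"n": int(times_ms.size), "mean": float(iv.mean()), "intervals": iv}


def state_statistics(
    raster: StateRaster,
    waves: list[WaveEvent],
    rE_hz: np.ndarray | None = None,
    classified_only: bool = False,
) -> dict:
    """Summary statistics of the slow-oscillation dynamics.

    Returns duration distributions with exponential-fit rates, per-class
    inter-event intervals, the event-involvement histogram, mean state
    duration and mean rate as functions of involvement, and per-region
    down-time fractions.  Quantities with too few events are NaN, not zero.

    ``classified_only`` restricts the event-based involvement statistics
    (mean involvement, fraction below half) to local/global events
    (peak involvement >= 25 %); by default every detected event above the
    10 % peak threshold counts.
    """
    if classified_only:
        waves = [w for w in waves if w.kind != "sub"]
    ups, downs = state_durations(raster)

    def _expfit(d):
        if d.size < 5:
            return {"n": int(d.size), "mean": np.nan, "rate_per_s": np.nan}
        m = d.mean()
        return {"n": int(d.size), "mean": float(m), "rate_per_s": 1000.0 / m}

    ev_loc = np.array([w.t_peak for w in waves if w.kind == "local"])
    ev_glo = np.array([w.t_peak for w in waves if w.kind == "global"])
    inv = np.array([w.involvement for w in waves])

    T_s = raster.T * raster.dt / 1000.0
    out = {
        "up_durations": _expfit(ups),
        "down_durations": _expfit(downs),
        "n_events": len(waves),
        "local": _interval_stats(ev_loc),
        "global": _interval_stats(ev_glo),
        "local_rate_per_min": 60.0 * ev_loc.size / T_s,
        "global_rate_per_min": 60.0 * ev_glo.size / T_s,
        "mean_event_involvement": float(inv.mean()) if inv.size else np.nan,
        "frac_events_below_half": (
            float((inv < 0.5).mean()) if inv.size else np.nan
        ),
        "down_time_fraction": (~raster.up).mean(axis=1),
    }

    # involvement-resolved curves (event-based down durations; pointwise rate)
    if inv.size:
        bins = np.linspace(0.0, 1.0, 11)
        mids = 0.5 * (bins[:-1] + bins[1:])
        dur_curve = np.full(10, np.nan)
        for k in range(10):
            sel = [w for w in waves
                   if bins[k] <= w.involvement < bins[k + 1] and w.regions.size]
            if sel:
                # mean duration of the down-states ongoing at each event peak
                durs = []
                for w in sel:
                    kpk = int(round(w.t_peak / raster.dt))
                    for i in w.regions:
                        durs.append(_ongoing_run_length(raster.up[i], kpk) * raster.dt)
                if durs:
                    dur_curve[k] = float(np.mean(durs))
        out["involvement_bins"] = mids
        out["down_duration_vs_involvement"] = dur_curve
    if rE_hz is not None:
        up_inv = involvement(raster, "up")
        out["rate_vs_up_involvement"] = _binned_mean(
            up_inv, np.asarray(rE_hz).mean(axis=0)
        )
    return out


def _ongoing_run_length(up_row: np.ndarray, k: int) -> int:
    """Length (samples) of the state run containing sample k."""
    s = up_row[k]
    a = k
    while a > 0 and up_row[a - 1] == s:
        a -= 1
    b = k
    n = up_row.size
    while b < n - 1 and up_row[b + 1] == s:
        b += 1
    return b - a + 1


def _binned_mean(x, y, nbins: int = 10):
    bins = np.linspace(0.0, 1.0, nbins + 1)
    mids = 0.5 * (bins[:-1] + bins[1:])
    out = np.full(nbins, np.nan)
    which = np.clip(np.digitize(x, bins) - 1, 0, nbins - 1)
    for k in range(nbins):
        m = which == k
        if m.any():
            out[k] = float(np.mean(y[m]))
    return mids, out


def global_phase(
    I: np.ndarray,
    dt: float,
    band_hz: tuple[float, float] = (0.5, 2.0),
    order: int = 8,
) -> np.ndarray:
    """Instantaneous phase of the whole-brain slow oscillation.

    The involvement series is band-pass filtered (Butterworth, zero-phase
    forward-backward) in the slow-oscillation band and converted to an
    analytic signal; the returned phase is its argument in (-pi, pi].
    Raises if the series is degenerate (constant).
    """
    I = np.asarray(I, dtype=float)
    if I.size * dt < 10_000.0:
        raise ValueError("need at least 10 s of involvement data")
    if np.ptp(I) == 0:
        raise ValueError("constant involvement: phase undefined")
    fs = 1000.0 / dt
    # order is the effective (forward+backward) order; sosfiltfilt applies
    # the filter twice
    sos = butter(order // 2, band_hz, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, I - I.mean())
    return np.angle(hilbert(x))


def circular_mean(angles: np.ndarray) -> float:
    """Argument of the resultant vector of unit phasors, in (-pi, pi]."""
    angles = np.asarray(angles, dtype=float)
    return float(np.angle(np.exp(1j * angles).mean()))


def _transition_times(up_row: np.ndarray, direction: str) -> np.ndarray:
    d = np.diff(up_row.astype(np.int8))
    if direction == "up_to_down":
        return np.flatnonzero(d == -1) + 1
    return np.flatnonzero(d == 1) + 1


def transition_phases(
    raster: StateRaster,
    phi: np.ndarray,
    direction: str = "up_to_down",
    min_transitions: int = 5,
) -> np.ndarray:
    """Per-region circular mean of the global phase at state transitions.

    Regions with fewer than ``min_transitions`` transitions get NaN.
    """
    if direction not in ("up_to_down", "down_to_up"):
        raise ValueError("direction must be 'up_to_down' or 'down_to_up'")
    out = np.full(raster.N, np.nan)
    for i in range(raster.N):
        idx = _transition_times(raster.up[i], direction)
        if idx.size >= min_transitions:
            out[i] = circular_mean(phi[idx])
    return out


def kuramoto(raster: StateRaster):
    """Kuramoto order parameter of down-transition timing.

    Each region's phase is phi_j(t) = 2 pi (t - t_n) / (t_n - t_{n-1}),
    where t_n is the most recent down transition before t and t_{n-1} the
    one before it, i.e. the previous inter-transition interval serves as
    the instantaneous frequency estimate (the phase may exceed 2 pi when
    the ongoing interval is longer than the previous one).  Returns
    (R(t), mean R, metastability = temporal SD of R); R is NaN-masked
    where any region has seen fewer than two transitions.
    """
    N, T = raster.up.shape
    phases = np.full((N, T), np.nan)
    for i in range(N):
        tr = _transition_times(raster.up[i], "up_to_down")
        if tr.size < 2:
            continue
        for k in range(1, tr.size):
            last = tr[k]
            prev_iv = tr[k] - tr[k - 1]
            stop = tr[k + 1] if k + 1 < tr.size else T
            t = np.arange(last, stop)
            phases[i, last:stop] = 2.0 * np.pi * (t - last) / prev_iv
        # before the second transition no interval estimate exists; those
        # samples stay NaN and are masked out of R(t)
    valid = ~np.isnan(phases).any(axis=0)
    R = np.full(T, np.nan)
    if valid.any():
        z = np.exp(1j * phases[:, valid]).mean(axis=0)
        R[valid] = np.abs(z)
    Rv = R[valid]
    mean_R = float(Rv.mean()) if Rv.size else np.nan
    meta = float(Rv.std()) if Rv.size else np.nan
    return R, mean_R, meta


def ap_regression(phases: np.ndarray, coords_ap: np.ndarray):
    """OLS regression of per-region mean transition phase on the
    anterior-posterior coordinate.

    Returns (slope, Pearson R, two-sided p).  NaN phases are dropped;
    requires at least 10 regions with defined phases and a non-degenerate
    coordinate.
    """
    phases = np.asarray(phases, dtype=float)
    coords_ap = np.asarray(coords_ap, dtype=float)
    ok = np.isfinite(phases) & np.isfinite(coords_ap)
    if ok.sum() < 10:
        raise ValueError("need >= 10 regions with defined phases")
    if np.ptp(coords_ap[ok]) == 0:
        raise ValueError("anterior-posterior coordinate has zero variance")
    res = linregress(coords_ap[ok], phases[ok])
    return float(res.slope), float(res.rvalue), float(res.pvalue)


def critical_adaptation(
    connectome,
    params,
    table,
    K_gl: float,
    b_grid=None,
    duration: float = 60_000.0,
    n_seeds: int = 2,
    seed: int = 0,
    onset_per_min: float = 0.5,
):
    """Critical adaptation strength b_c of a network: onset of global waves.

    Below b_c all nodes fire tonically (no global down-states); above it the
    number of global waves per minute rises steeply.  Scans ``b_grid``
    (pA), counting waves with > 50 % down-state involvement in
    ``n_seeds`` noise realizations per value, and returns
    (b_c, {"b": ..., "global_per_min": ..., "local_per_min": ...}).
    b_c is the smallest b whose mean global-wave rate exceeds
    ``onset_per_min``; NaN if none does.
    """
    from .network import simulate_network

    if b_grid is None:
        b_grid = np.arange(1.0, 8.1, 0.5)
    b_grid = np.asarray(b_grid, dtype=float)
    glob = np.zeros(b_grid.size)
    loc = np.zeros(b_grid.size)
    for k, b in enumerate(b_grid):
        g_rates, l_rates = [], []
        for s in range(n_seeds):
            trace = simulate_network(
                connectome, params.with_(b=float(b)), table, K_gl=K_gl,
                duration=duration, seed=seed + 1000 * s, rec_dt=1.0,
            )
            raster = detect_states(trace.rE, trace.rec_dt)
            waves = detect_waves(involvement(raster), trace.rec_dt)
            T_min = duration / 60_000.0
            g_rates.append(sum(w.kind == "global" for w in waves) / T_min)
            l_rates.append(sum(w.kind == "local" for w in waves) / T_min)
        glob[k] = np.mean(g_rates)
        loc[k] = np.mean(l_rates)
    above = np.flatnonzero(glob > onset_per_min)
    b_c = float(b_grid[above[0]]) if above.size else float("nan")
    return b_c, {"b": b_grid, "global_per_min": glob, "local_per_min": loc}
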