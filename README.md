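# slowbrain

A whole-brain model of slow-wave sleep: a network of adaptive
excitatory–inhibitory mean-field nodes coupled through a structural
connectome, with the machinery to fit it to fMRI/EEG features and to
quantify the spatiotemporal statistics of the slow oscillations it
produces.

**Who it is for.** Computational neuroscientists studying how <1 Hz slow
oscillations (SOs) — the alternation between high-firing *up-states* and
near-silent *down-states* of deep sleep — emerge locally from
spike-frequency adaptation and are organized brain-wide by the connectome.

## The model

Each cortical region is an E–I pair of adaptive exponential
integrate-and-fire (AdEx) populations in the mean-field limit. The mean
membrane current of population α ∈ {E, I} relaxes toward its synaptic,
external and noise input,

    τ_α dμ_α/dt = μ_α^syn + μ_α^ext + μ_α^ou − μ_α,

and the population rate, effective timescale and mean voltage are read off
precomputed transfer functions of the stationary Fokker–Planck equation,
r_α = Φ_r(μ_α, σ_α), τ_α = Φ_τ(μ_α, σ_α), V̄ = Φ_V(μ_α, σ_α), where σ_α is
the membrane-current noise amplitude from a second-moment closure of the
synaptic dynamics. A slow adaptation current on E,

    dĪ_A/dt = −Ī_A/τ_A + b·r_E,

enters as a hyperpolarizing shift Φ(μ_E − Ī_A/C, σ_E). Regions couple
E-to-E through a max-normalized fiber-count matrix C_ij with axonal delays
D_ij = L_ij / v_gl, scaled by a global coupling K_gl. Without adaptation
the node is bistable between up- and down-states over a wedge of the
external-input plane; spike-triggered adaptation (b > 0) destabilizes the
up branch and creates a slow (≈0.3–1.3 Hz) relaxation limit cycle next to
the wedge, alongside the fast (≈15–30 Hz) E–I cycle. Near the critical
adaptation strength, noise produces irregular up↔down switching — the
sleep-like regime.

On top of the simulator the package provides: the Balloon–Windkessel
hemodynamic transform; FC / FCD / EEG-spectrum objectives; an NSGA-II
multi-objective fitter over the six free parameters (μ_E^ext, μ_I^ext, b,
τ_A, K_gl, σ_ou); the full SO analysis pipeline (up/down rasters,
involvement, local vs. global waves, traveling-wave phases, Kuramoto
synchrony and metastability, anterior–posterior regressions); and a
synthetic fixture generator (surrogate connectome, subject FCs, N3-like
EEG spectrum) so everything is testable without subject data.

## Worked example

```python
import numpy as np
from slowbrain import (NodeParams, cached_transfer_tables, classify_point,
                       simulate_network, synthetic_connectome)
from slowbrain.analysis import (detect_states, detect_waves, involvement,
                                state_statistics)
from slowbrain.params import SLEEP_MODEL_SURROGATE

table = cached_transfer_tables()          # Fokker-Planck transfer maps

# 1. a bistable point of the isolated node (noiseless probe protocol)
res = classify_point(NodeParams(b=0.0), table, 2.3, 2.8)
print(f"(2.3, 2.8) mV/ms, b=0:  {res['label']}  "
      f"(branch separation {res['rate_diff']:.1f} Hz)")

# 2. with strong adaptation the flank of the wedge becomes a slow cycle
res = classify_point(NodeParams(b=20.0, tau_A=600.0), table, 2.6, 1.8)
print(f"(2.6, 1.8) mV/ms, b=20: {res['label']} at "
      f"{res['dominant_freq']:.2f} Hz")

# 3. whole-brain sleep regime on the surrogate connectome
conn = synthetic_connectome(N=80, seed=1)
params = NodeParams(**{k: v for k, v in SLEEP_MODEL_SURROGATE.items()
                       if k != "K_gl"})
trace = simulate_network(conn, params, table,
                         K_gl=SLEEP_MODEL_SURROGATE["K_gl"],
                         duration=90_000.0, seed=0, rec_dt=1.0)
raster = detect_states(trace.rE, trace.rec_dt)
waves = detect_waves(involvement(raster), trace.rec_dt, raster=raster)
stats = state_statistics(raster, waves)
print(f"sleep regime: mean up {stats['up_durations']['mean']:.0f} ms, "
      f"mean down {stats['down_durations']['mean']:.0f} ms")
print(f"  {stats['n_events']} slow-wave events, mean involvement "
      f"{stats['mean_event_involvement']:.2f}, "
      f"{stats['frac_events_below_half']:.0%} below half the brain")
```

Output:

```
(2.3, 2.8) mV/ms, b=0:  bistable  (branch separation 35.8 Hz)
(2.6, 1.8) mV/ms, b=20: oscillatory at 1.12 Hz
sleep regime: mean up 1014 ms, mean down 431 ms
  53 slow-wave events, mean involvement 0.35, 77% below half the brain
```

The first two lines show the state-space building blocks: at external
drive (2.3, 2.8) mV/ms the node holds either a silent or a tonic-firing
state (separated by 35.8 Hz); switching on adaptation converts the
neighboring regime into a ~1 Hz up↔down relaxation oscillation. The last
lines are the whole-brain sleep regime at the surrogate connectome's
critical adaptation strength: tonic firing with irregular down-state
excursions, up-states about twice as long as down-states, and most
slow-wave events recruiting less than half of the regions.

The first call computes the transfer tables (about two minutes) and caches
them; subsequent runs start instantly. A command-line interface wraps the
same functionality: `slowbrain fixtures | simulate | statespace | fit |
analyze | smoke` (see `slowbrain --help`).

Fitting to a user's own data takes a connectome (dense weight/length
matrices), per-subject FC matrices or BOLD series, and an EEG power
spectrum; see `slowbrain fit --config ...` and `slowbrain.evolve`. The
headline connectome-dependent statistics of the sleep model are only
meaningful on the study's own 80-region connectome, which is not
redistributable here: place its plain-text matrices under `data/empirical/`
(weights.txt, lengths.txt, labels.txt, coords.txt) to activate those
checks.

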