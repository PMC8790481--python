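# Methods

`slowbrain` simulates the human cortex during slow-wave sleep as a network
of N adaptive excitatory-inhibitory (E-I) mean-field nodes coupled by a
structural connectome, fits the model's free parameters to fMRI/EEG-derived
features with a multi-objective evolutionary algorithm, and quantifies the
spatiotemporal statistics of the simulated slow oscillations (SOs). This
note records the model, the numerical choices, and the design decisions
that were genuinely open, together with what the synthetic test conditions
do and do not establish.

## The mean-field node

Each cortical region is a pair of excitatory (E) and inhibitory (I)
populations of adaptive exponential integrate-and-fire (AdEx) neurons in
the mean-field limit, reduced to a linear-nonlinear cascade: the mean
membrane current `mu_a` (a in {E, I}) relaxes toward the summed synaptic,
external, and noise currents with an input-dependent timescale
`tau_a = Phi_tau(mu_a, sigma_a)`, and the population rate is read out
instantaneously through the stationary transfer function
`r_a = Phi_r(mu_a, sigma_a)`. Currents are expressed as current densities
in mV/ms (1 mV/ms x C = 0.2 nA at C = 200 pF); rates are carried in kHz
internally and converted to Hz at I/O boundaries.

State per node: mean currents `mu_E, mu_I`; Ornstein-Uhlenbeck (OU) noise
currents per population (`d mu_ou = -mu_ou/tau_ou dt + sigma_ou sqrt(dt) xi`);
mean synaptic activations `s_ab` (fraction of active synapses, in [0, 1])
and their variances for the four pathways EE, EI, IE, II; and the mean
spike-triggered adaptation current `I_A` on E
(`dI_A/dt = (a (V_E - E_A) - I_A)/tau_A + b r_E`, with the subthreshold
coupling `a = 0` so only the spike-triggered increment `b` acts).
Adaptation enters the transfer functions as a hyperpolarizing shift of the
effective mean input, `Phi(mu_E - I_A/C, sigma_E)`.

The synaptic drive of pathway a<-b is the delay-weighted presynaptic rate
sum

    z1_ab = (c_ab tau_s_b / |J_ab|) (K_b r_b(t - d_a)
            + delta_abE K_gl sum_j C_ij r_E,j(t - D_ij)),

which is dimensionless: `c_ab` is the unitary PSC amplitude, `J_ab` the
maximal synaptic current (inhibitory J are negative; the ratio uses the
magnitude), `tau_s_b` the synaptic time constant, `K_b` the within-node
in-degree, and the Kronecker delta restricts inter-areal coupling to
E-to-E. Its second-moment companion `z2_ab` carries the squared weights
(`C_ij^2` for the network term) and feeds the synaptic-variance equation.
The membrane-current variance combines the four pathway variances with the
always-on external-input variance floor `sigma_ext^2` (sigma_ext =
1.5 mV/ms). Printed forms of these sums are dimensionally ambiguous
(flattened fractions); the convention above is the unique dimensionally
consistent reading and is validated operationally: it reproduces the
published state-space topology (bistability at external drive
(2.3, 2.8) mV/ms, a slow adaptation cycle at (2.5, 2.0) with b = 20 pA,
fast E-I cycles at low inhibitory drive).

## Transfer functions from the Fokker-Planck steady state

`Phi_r`, `Phi_tau`, `Phi_V` are tabulated over a grid of mean input
mu in [-2, 6] mV/ms and noise amplitude sigma in [0.05, 5] mV/sqrt(ms)
(step 0.05 in both; the range covers the external-input scans of 0-4 mV/ms
plus synaptic and adaptation offsets) by threshold integration of the
stationary Fokker-Planck equation of the exponential integrate-and-fire
neuron: the density is integrated backwards from the spike cutoff
V_s = -40 mV to -200 mV (step 0.01 mV) with a unit probability flux
between reset and cutoff, using an exponential integrating-factor step;
the rate follows from normalization with the refractory correction
r = r0/(1 + r0 T_ref). Deep subthreshold points whose density
normalization overflows are assigned rate 0 and the noise-free equilibrium
voltage. Against a 4,000-10,000-neuron Euler-Maruyama spiking simulation,
tabulated rates agree to well under 1 % in all tested regimes (the test
suite asserts 5 %).

The cascade timescale `Phi_tau` is the least-squares time constant of a
one-pole filter `R0 / (1 + i w tau)` fitted to the complex linear rate
response of the linearized Fokker-Planck operator at eight log-spaced
probe frequencies (1-320 Hz), computed by the same threshold-integration
machinery (two backward systems: reinjection and stationary-density
drive). Fitting the complex response rather than its modulus is essential:
in the mean-driven regime the amplitude response is resonant near the
firing rate rather than low-pass, an amplitude-only fit collapses tau to
zero, and the resulting unfiltered delay loop produces a spurious
~190 Hz network oscillation; the phase lag pins tau to 0.3-6 ms in active
regimes and ~tau_m = 20 ms subthreshold. tau is clamped to [0.2, 100] ms
(the lower clamp keeps forward Euler at dt = 0.1 ms stable), and falls
back to tau_m where the response is too small to fit. `Phi_V` is the mean
voltage of the non-refractory density; with a = 0 it does not feed back
into the dynamics and is diagnostic only.

Tables are cached in HDF5 keyed by a hash of the neuron parameters, so a
parameter change forces recomputation.

## Network integration

Forward Euler at dt = 0.1 ms. Delayed rates are read from per-node ring
buffers; inter-areal delays D = L / v_gl (fiber length over global signal
speed, default 20 m/s) are rounded to the nearest integer step with a
one-step floor, and the delay history is initialized constant at each
node's initial rate to avoid onset transients. Initial mean currents are
drawn uniformly from [0, 3] mV/ms per node unless fixed. Per-node noise
streams are spawned from one master seed independently of N, which makes
the decoupled network (K_gl = 0) bit-identical to isolated nodes and keeps
results independent of evaluation order. Synaptic-variance states are
clipped at zero (the Euler step can undershoot transiently). The mean
excitatory rate across nodes is always recorded at full resolution for
spectral analysis; per-node traces are recorded at a configurable interval
(1 ms in most analyses here, which resolves everything up to the fast
limit cycle at < 40 Hz).

## State-space classification

Each point of the (mu_E_ext, mu_I_ext) plane is simulated noiselessly for
20 s with a decaying bidirectional stimulus (amplitude -2 then +2 mV/ms
from 10 s, decay constant 1 s; the amplitude is not printed in the source
protocol and was chosen large enough to cross every basin boundary in the
scanned plane). A point is oscillatory if any node's rate amplitude
(max - min) exceeds 10 Hz in the settled windows (after 8 s of each
probe), bistable if the 2-s mean rates reached after the two probes differ
by >= 10 Hz (and it is not oscillatory), otherwise up or down by a 10 Hz
mean-rate threshold. Oscillation frequency and the up/down-alternation
flag are measured in a separate stimulus-free 40 s run discarding 16 s:
slow adaptation transients (tau_A up to 5 s) are not settled at 8 s, and a
24 s window resolves sub-Hz cycles (periodogram bin 0.042 Hz).  The
frequency run starts from an up-state initial condition ((3, 1) mV/ms)
because limit cycles in this plane coexist with stable down fixed points
whose basin a random initialization can land in; points whose probed
transients exceeded the amplitude criterion but whose free attractor is a
fixed point then report frequency 0 and are excluded from the limit-cycle
masks.

Two limit cycles are distinguished mechanistically. The fast E-I cycle
(LC_EI) exists without adaptation. The slow excitation-adaptation cycle
(LC_EA) appears only with adaptation — but not, as one might read the
Hopf-replacement picture, *inside* the formerly bistable wedge: a point
whose down-state is stable without adaptation keeps that stable fixed
point (I_A decays to zero in the down-state), so the self-sustained slow
cycle lives on the adjacent monostable-up flank, where the down-state can
only be escaped. LC_EA is therefore identified as: oscillatory with
adaptation, not oscillatory without, and alternating between up- and
down-states that survive the 50 ms minimum-duration cleaning of the state
detection. The duration requirement automatically excludes
adaptation-shifted fast cycles (period < 100 ms cannot contain a 50 ms
down-state). On the 21 x 21 scan this yields a contiguous band of slow
cycles (~0.3-1.3 Hz) hugging the bistable wedge, with fast cycles at
15-28 Hz in the low-inhibition corner; the extreme boundary points of both
bands oscillate somewhat slower (~10 Hz at the fast-cycle onset, ~0.3 Hz
at the slow-cycle edge) than the nominal 15-35 Hz and 0.5-2 Hz ranges,
which is expected for Hopf/homoclinic onset frequencies and sensitive to
the exact tau fit.

## Hemodynamics and objectives

Excitatory rates drive the four-state hemodynamic (balloon) model with the
canonical constants (signal decay 0.65 s^-1, autoregulation 0.41 s^-1,
transit time 0.98 s, stiffness 0.32, resting extraction 0.34, resting
volume 0.02); the neural drive is the rate divided by a 100 Hz reference
so it is O(1) — FC/FCD are correlation- and distribution-based and
insensitive to this scale. Euler integration at the neural sampling step,
2 s bin-mean decimation to 0.5 Hz, 20 s transient discard. An independent
adaptive-solver integration of the same ODEs places the response peak
3.2 s after a brief pulse with these constants, with the characteristic
post-stimulus undershoot.

Fitness has three dimensions: (i) FC fit — Pearson correlation of
lower-triangular static FC entries against each subject, averaged;
(ii) FCD fit — two-sample Kolmogorov-Smirnov distance between
off-diagonal distributions of the functional-connectivity-dynamics
matrices (60 s windows, 10 s steps, windows anchored at t = 0, trailing
partial window dropped, all window pairs included); (iii) spectral fit —
Pearson correlation over 0-40 Hz between Welch spectra (10 s Hann windows,
linear power, which weights the dominant SO peak) of the across-region
mean rate (last 60 s) and the target EEG spectrum, interpolated to the
simulated frequency grid.

## Evolutionary fitting

NSGA-II over the six free parameters (external drives in [0, 4] mV/ms,
b in [0, 20] pA, tau_A in [5, 5000] ms, K_gl in [100, 400], sigma_ou in
[0, 0.5] mV/ms^1.5): non-dominated sorting, crowded tournament selection
(size 2), simulated binary crossover (eta = 20, rate 0.9), polynomial
mutation (eta = 20, per-gene rate 1/6), elitist merge-then-truncate
survival, plus a global archive of never-dominated individuals (whose
hypervolume is non-decreasing by construction; the working population's
is not, because crowding truncation may drop extremes). The operator
constants are the canonical defaults; the source protocol names the
operators without values. Candidate evaluation is stage-wise: a 10 s
screen (1 s transient) discards runs whose maximum rate never exceeds
10 Hz and — when fitting toward tonic-firing ("up-to-down") solutions —
runs whose median rate over nodes and time leaves [1, 15] Hz; survivors
get the full-length simulation. Per-individual seeds are derived from the
master seed and the individual's global index, so fitness does not depend
on scheduling. Post-hoc scalar ranking (to pick one reference model from a
front) is an equal-weight sum of objectives normalized to [0, 1] over the
population; the weights are not specified in the source and equal weights
are the neutral choice.

## Slow-oscillation analysis

Up/down detection thresholds each region at 1 % of its own maximum rate;
runs shorter than 50 ms are replaced by the preceding state, scanning left
to right (leading run kept; the cleaning is idempotent). Down-state
involvement I(t) is the fraction of regions in the down-state. Wave events
are peaks of the Gaussian-smoothed involvement (kernel SD 200 ms — the
named filter's width parameter is its standard deviation — minimum height
10 %, minimum peak separation 100 ms); events above 50 % involvement are
global, 25-50 % local, below 25 % excluded from the local/global classes
but retained in the involvement histogram. The headline involvement
statistics (mean event involvement, fraction below half) are event-based
(means over detected peaks >= 10 %), not time averages. Duration
statistics censor the leading and trailing run of each region.

The whole-brain SO phase is the Hilbert phase of the involvement after
zero-phase Butterworth band-passing in 0.5-2 Hz (order 8 combined
forward-backward). Per-region transition phases are circular means
(resultant-vector argument) of the global phase sampled at each region's
up-to-down or down-to-up transitions (regions with < 5 transitions are
excluded); the regression of these phases on the anterior-posterior
centroid coordinate (column y, larger = anterior) uses ordinary least
squares on the wrapped values. The Kuramoto order parameter assigns each
region the phase 2 pi (t - t_n)/(t_n - t_{n-1}) from its two most recent
down transitions (the previous interval is the frequency estimate, so the
phase may exceed 2 pi); R(t) is masked wherever any region has seen fewer
than two transitions, and metastability is the temporal SD of R.

## Synthetic study conditions

No subject data ship with the package; the fixture generator emulates the
study inputs. The surrogate connectome samples N = 80 centroids in a
brain-shaped ellipsoid (semi-axes 60/80/50 mm), weights decay
exponentially with distance (length constant 30 mm) with lognormal
heterogeneity (sigma = 1), callosal (inter-hemispheric) connections are
scaled by 0.4, and an anterior-posterior factor makes posterior in-degrees
larger (anterior regions weakly connected, as in tractography); the matrix
is symmetrized, zero-diagonal, max-normalized. These choices were fixed on
matrix-level realism — per-node normalized strength of order 1-2, weight
spread of ~3 decades, weakened callosal links — before any dynamical
acceptance checks. Subject FC/BOLD fixtures share a latent Gaussian
process whose covariance blends spatial proximity and structural coupling,
plus per-subject noise (0.6 relative amplitude keeps inter-subject FC
correlations above 0.5); the EEG target is 1/f-like with a Gaussian SO
peak at 1 Hz.

The sleep regime of the surrogate is the reference fitted parameter set
with the adaptation strength moved to the surrogate's own critical value
b = 3.6 pA (onset of global waves under the published criterion; the
critical value is connectome-specific). There the surrogate reproduces
the tonic up-to-down phenomenology: median rate in the 1-15 Hz band,
up-states (~1 s) outlasting down-states (~0.4 s), mean event involvement
~0.35 with ~77 % of events below half involvement, and near-exponential
duration distributions.

**Known limitation.** The surrogate does *not* reproduce the empirical
ordering "local waves more frequent than global waves": across the whole
critical region global waves dominate (~8/min vs ~2-3/min). Partial
(25-50 %) recruitment appears to require mesoscale modular structure
(lobe-level clusters with weak bridges) that a distance-decay +
two-hemisphere surrogate lacks — waves either stay below 25 % involvement
or recruit the whole network. Passing synthetic-condition tests therefore
establish the pipeline and the within-regime orderings they assert, not
that surrogate dynamics match real-connectome dynamics in every statistic;
the connectome-dependent headline numbers (mean involvement 32 %, 83 %
below half, critical b ~ 3.2 pA, anterior-posterior phase correlation
R ~ 0.46) are only meaningful on the study's own connectome, which users
must supply under `data/empirical/`.

## Numerical and scale choices

dt = 0.1 ms (halving changes steady rates < 1 %); per-node recording at
1 ms; state-space scans 21 x 21 for routine use (the published diagrams
use 161 x 161; classification is pointwise-parallel and resolution only
affects contour smoothness); frequency runs 40 s; surrogate sleep-regime
statistics from 3 x 90 s noise realizations; evolution smoke configurations
use 6-8 nodes, 100 s stage-2 simulations, and single-digit populations.
These sizes are the package's desk-scale defaults; all of them scale up by
configuration. OU noise uses tau_ou = 5 ms (fast relative to the 20 ms
membrane time constant; not listed in the published parameter table).
Ties and degenerate inputs: zero-variance regions yield zero FC rows with
a warning; involvement phase is undefined (error) for constant
involvement; statistics with too few events are NaN, never silently zero.
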