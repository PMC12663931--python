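# Methods

## Neuron model

The readout neuron is a current-based leaky integrate-and-fire unit. Its
membrane potential is the weighted sum of causal, unit-amplitude
double-exponential postsynaptic potentials (PSPs),

    V(t) = sum_i sum_{t_ij < t} W_i({t_i1..t_ij}) K(t - t_ij) + V_rest,
    K(s) = V0 (exp(-s/tau_m) - exp(-s/tau_s)),    s >= 0,

with membrane and synaptic time constants tau_m and tau_s, V0 fixed so
that max_s K(s) = 1, V_rest = 0 and spike threshold theta = 1.  An output
spike triggers a *shunt reset*: all input spikes arriving after the
output spike contribute nothing, so the voltage relaxes back to rest
along the tails of the PSPs already integrated.  Nothing else about the
reset is modelled (no truncation of in-flight PSPs); for binary
classification this is exactly equivalent to thresholding the unreset
voltage maximum.

The ratio tau_m/tau_s is fixed at 2 (capacity depends only weakly on it
in the physiological range 1-4); the characteristic integration scale
tau = sqrt(tau_m tau_s) is matched to the input spike density as

    tau = 5.67 T / (N n_spikes),

where T is the pattern duration (0.5 s throughout), N the number of
afferents and n_spikes the spikes per afferent.  Both the coefficient and
the ratio are config keys (`tau_scale_coeff`, `tau_ratio`).

### Event-based voltage maximization

Between input spikes V(t) = V0 (A e^{-s/tau_m} - B e^{-s/tau_s}) with
running sums A, B updated by decay-and-add at each spike, so each
inter-spike interval has at most one interior stationary point with a
closed form.  The global maximum over the simulation window
[0, T + 5 tau_m] is found exactly in O(n_spikes); ties resolve to the
earliest maximizer.  One deliberate convention: the flat zero-voltage
segment before the first input spike is excluded from the maximization.
On error trials whose voltage never exceeds rest, the supremum would
otherwise sit at t = 0 with no spikes before it, all gradients would
vanish identically and learning would stall permanently (this occurs
readily at small N).  With the convention, t_max always has input spikes
before it and v_max may be negative on silent trials.

## Synapse models

Per-spike instantaneous efficacies W follow four models:

- **static**: W_ij = omega_i; the classical scalar-weight case.
- **ordinal**: W_ij = omega_ij, one free weight per spike rank; an
  idealized synapse whose short-term plasticity is rich enough to weight
  each successive spike independently.  It is implemented by the exact
  mapping onto static weights of the rank-order-expanded pattern
  (N x n_spikes single-spike afferents with fixed within-group rank
  order), so ordinal training *is* static training in the expanded space.
- **sign-constrained ordinal**: W_ij = omega_i z_ij / ||z_i||_1 with
  z_ij >= 0; one sign per afferent, free per-rank magnitudes.
- **Tsodyks-Markram (TM)**: W_ij = omega_i u_ij x_ij with the
  facilitation/depression recursions

      u_i1 = x_i1 = 1,
      u_ij = u_{i,j-1} (1 - U_i) exp(-dt/tau_fac_i) + 1,
      x_ij = x_{i,j-1} (1 - U_i u_{i,j-1}) exp(-dt/tau_rec_i) + 1 - exp(-dt/tau_rec_i),

  where dt is the preceding inter-spike interval.  This is the refactored
  parameterization in which the utilization scale is absorbed into
  omega_i, so both state variables start at the unit baseline and a
  single-spike train reduces exactly to a static synapse.  State is reset
  at pattern onset (each pattern is an independent trial).

## Tempotron learning

On each error trial the cost E = -V(t_max) (missed target) or +V(t_max)
(false alarm) is reduced by a gradient step with momentum,

    delta = +/- eta dV(t_max)/dtheta + mu delta_prev,

applied online (immediately per misclassified pattern).  The voltage
gradients are exact:

- static/ordinal: dV/domega_i = sum_{t_ij < t_max} K(t_max - t_ij);
- sign-constrained: dV/domega_i = (1/||z_i||_1) sum z_ij K_ij and
  dV/dz_ij = (omega_i/||z_i||_1)(K_ij - dV/domega_i); the second term is
  the exact derivative of the L1 normalization, so z entries of an active
  afferent carry nonzero gradients even for ranks after t_max;
- TM: the four components weight K(t_max - t_ij) with the per-spike
  dynamic factors u x (for omega), u dx/dU + x du/dU (for U),
  u dx/dtau_rec, and u dx/dtau_fac + x du/dtau_fac, the latter three
  scaled by omega_i; the partials follow their own recursions with zero
  initial conditions.  All gradients are verified against central finite
  differences and the state partials against complex-step derivatives of
  a reference recursion.

Momentum invocation is model-specific: for static/ordinal (and both
parameter groups of the sign-constrained model) it fires only where the
gradient contribution is nonzero — silent afferents keep both their
weight and their momentum memory.  For TM synapses momentum fires for all
four parameters of every afferent active before t_max, regardless of the
individual gradient values, enforcing concurrent updates of the
parameters that jointly shape the efficacy dynamics.

After every TM update, parameters are projected to valid ranges: U into
[1e-3, 1], both time constants into [1e-3 s, 10 s].  z magnitudes are
floored at 0; if flooring would zero an afferent's entire z vector the
z step of that afferent is reverted (the normalization would otherwise
be undefined).

### Hyperparameters and initialization

The published study tuned learning hyperparameters per task with
Bayesian optimization; this package instead exposes documented defaults
chosen on pilot stability runs:

- batch (storage/robustness) tasks: eta_omega = 3e-3 theta / N,
  eta_U = eta_tau = eta_omega / 10, mu = 0.99;
- online-generation correlation tasks: mu = 0.9 and
  eta_U = eta_tau = eta_omega (with the batch defaults the XOR task
  descends far too slowly at desk scales);
- eta_z = 3e-3 theta: z magnitudes are O(1) rather than O(1/N).

Initial parameters: omega ~ N(0, (theta/(N n_spikes))^2); TM dynamics
U ~ Uniform(0.1, 0.9), tau_rec, tau_fac ~ LogUniform(10 ms, 1 s);
z ~ Uniform(0.5, 1.5).  Every rate, momentum factor and the trainable
parameter subset (for partial-training controls) are config fields.

Presentation order is a fresh random permutation per epoch, reseeded
deterministically from the run seed, so identical (config, seed) produce
identical trajectories.

## Storage capacity estimation

For load alpha, a batch of p = round(alpha N) latency patterns (every
afferent firing n_spikes uniform random times in [0, T], labels fair
coins) is trained until the first error-free pass; the convergence time
CT is the number of error epochs before that pass, censored at a cutoff
L_max.  The critical capacity alpha_c is the pole of

    Gamma(alpha) = Gamma_0 / (1 - alpha/alpha_c)^gamma

fitted by nonlinear least squares to the staged sweep of median
convergence times: loads grow multiplicatively until the median CT (over
many independent realizations) reaches the stage cutoff, the cutoff is
raised over successive stages, and the curve is fitted to the highest
n_data consecutive uncensored loads, each record averaging several
independent median measurements.  Fit initial guesses: Gamma_0 = smallest
windowed CT, alpha_c = 1.05x the largest fitted load, multistart over
gamma in {1, 2, 3} keeping the fit with the lowest mean absolute
relative error.  A flat window is flagged degenerate (pole
unidentifiable).  Window-shifted refits quantify estimator stability,
and `robust_alpha_c` reports the median pole over a few shifted windows:
the top records sit closest to the censoring cutoff and carry the
largest sampling noise, so single-window fits occasionally extrapolate a
spurious distant pole that the window median discards.  Because gradient
training carries no convergence proof, every alpha_c is a lower bound;
estimates approach the asymptotic value from below as the cutoff grows.

The published protocol (cutoffs 1e4/1e5/1e6, 1,001 realizations, 10
repeats, 20-point windows, N = 100) is the config default.  The test
suite and the acceptance script run a scaled-down protocol — N = 30,
cutoffs 300/1000, 25 realizations, 5 repeats, 8-point windows with the
5-window median pole — chosen
so the full experiment suite completes on a desktop core.  At this scale
the absolute capacities are smaller than the full-scale values (lower
cutoff, finite-size effects), but the *scaling* of capacity with spikes
per afferent — the scientific claim — is preserved: normalized capacity
alpha_c/n_spikes falls off as ~1/n_spikes for static synapses and stays
flat for ordinal synapses.

## Noise robustness

Template batches are never shown directly: each presentation corrupts
its template with fresh noise — Gaussian spike-time jitter (SD sigma,
clipped to the window so counts are preserved), independent spike
deletion (probability p_del), or deletion plus homogeneous Poisson
background at rate p_del x n_spikes per afferent (expected count
preserved).  Generalization error is measured periodically on freshly
corrupted presentations without learning; the reported value averages
the final measurement over independent realizations (each regenerating
its own template batch).  The published sizes (1e6 cycles, measurements
every 5e4 cycles, 50 realizations) are available via
`RobustnessConfig.full_scale()`; desk defaults are smaller.

## Spatiotemporal correlation tasks

N/2 fixed afferent pairs fire synchronously at a uniform random time t
and again at t + Delta, with Delta shared across the pairs of a pattern.
Two pairings (adjacent, and stride-N/2) and two delays (10 ms, 20 ms)
define four binary tasks: pairing (spatial), short-delay and long-delay
(temporal), and XOR (respond to pairing 1 with the short delay and
pairing 2 with the long delay only).  Training patterns are generated
online with 1 ms Gaussian delay noise; response curves report the
fraction of noise-free test patterns eliciting an output spike per
(pairing, Delta).  The simulation window is extended past the
first-spike window so delayed second spikes are never truncated.

Pair-PSP analysis sums the four PSPs of one pair (two spikes per member,
TM efficacies) on a dense grid, extracting trace extrema and each
member's second-spike drive omega u_2 x_2.  Extrema with magnitude below
1e-3 are excluded from population histograms.

## Electrophysiology-style STP analysis

The 12-pulse protocol (8 + 4 pulses at 50 Hz, 250 ms gap; pulse times
0..140 ms and 390..450 ms) is simulated as A_j = omega u_j x_j.
Recordings are trial x 12 amplitude tables; quality control drops tables
flagged by the source, tables with fewer than 4 valid trials on any
pulse, and tables whose mean amplitude contradicts the connection's
polarity.  Response amplitudes are per-pulse trial medians.  STP_ind and
STP_rec (see module docstring) divide signed group differences by the
*signed* maximal-magnitude amplitude, so depression is negative for both
polarities — dividing by |A_max| would invert the reading for inhibitory
connections.

TM fitting minimizes the MSE over all 12 amplitudes with L-BFGS-B from
the full 6 x 7 x 3 x 3 grid of initial guesses (omega in {0.01, 0.05,
0.5, 1.0, 5.0, 10.0} with the data's sign, U in {0.01, 0.1, 0.25, 0.5,
0.75, 0.9, 0.99}, tau's in {0.01, 0.1, 1.0} s), bounds U in (0, 1],
tau's in [1 ms, 10 s], omega unbounded; the lowest-MSE solution wins.
On noise-free synthetic recordings the generating parameters are
recovered to well under 1% (omega) / 0.02 (U).

Real neurophysiology archives are not parsed; the ingestion contract is
a documented CSV schema (`trial, pulse_1..pulse_12, polarity, species,
type, qc_pass`), and a synthetic-recording generator (labelled synthetic)
produces tables of the same shape for end-to-end tests.  Population
analysis of trained TM parameter sets (splitting by the sign of omega
and computing the STP statistics per synapse) uses the same pipeline.

## What the synthetic data do and do not show

All experiments run on internally generated patterns whose statistics
are fully specified above: uniform latency codes with exactly equal
spike counts, fair-coin labels, stationary noise.  Passing tests
demonstrate the learning rules, capacity scaling and robustness *under
these statistics*; they say nothing about temporal codes with rate
fluctuations, correlated afferents beyond the constructed pairings, or
biological trial-to-trial variability beyond iid Gaussian amplitude
noise.  The 12-pulse analysis is validated on synthetic tables only; on
real recordings the QC rates and fit quality will differ.

## Numerical choices and degenerate inputs

- Kernel normalization V0 is computed from the closed-form peak delay,
  exact to machine precision.
- Jittered spike times are clipped to [0, T] (counts preserved) and
  re-sorted; the boundary-clipping choice is a convention the source
  protocol leaves open, and its effect should be measured, not assumed.
- p = round-half-up(alpha N); the multiplicative load grid never lands
  on ties at the default steps.
- Convergence time of a pre-solved batch is 0 epochs.
- A capacity window with zero spread is degenerate (no pole); fit
  failures raise, they are never silently swallowed.
- All randomness flows from integer seeds through either
  `numpy.random.Generator` (generation, initialization) or the
  per-epoch-reseeded Mersenne generator inside the compiled training
  loops; realization seeds are spawned with `SeedSequence` and kept
  below 2^31.

## Known limitations

- Single facilitation and single depression time constant per synapse;
  no multi-timescale or vesicle-pool mechanisms.
- No analytic capacity theory; all capacity numbers are simulation lower
  bounds.
- The desk-scale protocols trade absolute accuracy of alpha_c for
  runtime; full-scale protocol constants are provided but take cluster
  time.
- The robustness protocol supports the static and TM models only (the
  ordinal models are storage-capacity references).
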