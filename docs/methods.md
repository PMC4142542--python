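# Methods

This note documents the model, the estimators, the numerical choices and
the study conditions built into `critnet`, in the package's own words.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The network model

The core object is a randomly coupled recurrent network of `N` leaky
integrate-and-fire neurons modeling a visual-cortex (V4) population:

    tau_mem dV_i/dt = -(V_i - V_R)
                      + J_ext  * sum_k delta(t - t'_ik)
                      + J_exc  * sum_{j<=N_exc} w_ij delta(t - t_jk)
                      - J_inh  * sum_{j>N_exc}  w_ij delta(t - t_jk)

Each presynaptic spike depolarizes its target instantaneously by the
coupling strength; crossing the threshold `V_theta` emits a spike and
resets the potential to `V_R`.  The adjacency `w` is a directed
Erdös–Rényi graph (independent ordered pairs, self-connections allowed);
the first 80% of indices are excitatory, the rest inhibitory
(`eps = N_exc/N_inh = 4`).  Inhibition is always parametrized relative to
excitation, `J_inh = eps * J_exc * j_inh`, so the dimensionless scaling
factor `j_inh` and the excitatory strength `J_exc` span the coupling
phase space.  "Attention" is a global excitability increase, implemented
as a reduction of `j_inh` (default contrast 0.80 → 0.72).

Defaults (all in `NetworkConfig`):

| parameter    | value          | unit | meaning                                  |
|--------------|----------------|------|------------------------------------------|
| `n_neurons`  | 2500 (full) / 1000 (reduced) | – | population size        |
| `n_active`   | 1000           | –    | externally driven subset per stimulus    |
| `p_connect`  | 0.02           | –    | connection probability                   |
| `eps`        | 4              | –    | excitatory/inhibitory count ratio        |
| `v_rest` / `v_theta` | −60 / −50 | mV | reset and threshold                    |
| `tau_mem`    | 10             | ms   | membrane time constant                   |
| `j_ext`      | 0.1            | mV   | depolarization per external spike        |
| `f_max`      | 10             | kHz  | external Poisson rate per driven neuron  |
| `dt`         | 0.1            | ms   | Euler step                               |
| `t_total`    | 2500 (full) / 12000 (reduced) | ms | simulated duration |
| `t_transient`| 500            | ms   | discarded initial interval               |

A stimulus is a uniform-random subset of `n_active` neurons receiving
independent Poisson input (subsets for different stimuli may overlap);
in the full model stimulus identity is therefore encoded purely in the
connectivity of the activated subnetwork.  The mean external drive
`tau_mem * j_ext * f_max = 10 mV` exactly reaches the threshold distance,
so isolated driven neurons are fluctuation-driven — this balance is a
deliberate property of the parameter set and is asserted in the tests.

**Initial conditions.**  Potentials are initialized at a uniform-random
phase of the periodic trajectory of an isolated neuron under a constant
suprathreshold drive.  The constant current is not pinned down by the
model definition, and the mean stimulus drive itself is degenerate for
this purpose (its asymptote sits exactly at threshold, giving an infinite
period).  We use an asymptote two threshold distances above rest
(period `tau_mem * ln 2`); the induced sojourn density of `V(0)` is
verified against its closed form by a KS test.

**Two integration modes.**
`simulate_full` integrates with an explicit Euler scheme and delivers
recurrent spikes at the next step (the minimal causal delay on the grid).
`simulate_avalanche_mode` — used for all criticality analyses — delivers
recurrent spikes instantaneously within the step: every threshold
crossing triggers a cascade resolved generation by generation until no
new neuron crosses; a neuron fires at most once per cascade and is held
at reset for its remainder.  Each cascade is one *neuronal avalanche*
with size `s` (distinct neurons fired) and duration `T` (generation
count); this separation of timescales makes cascade membership exact.
Simultaneous threshold crossings within one step are merged into
generation 1 of a single avalanche — with ~0.3 external triggers per
step this merging is not rare, and it is the main respect in which the
avalanche ensemble deviates from an idealized branching process (see
Limitations).

The inner loops are numba-compiled.  External Poisson counts are sampled
by a compiled inverse-CDF lookup driven by a splitmix64 counter RNG (two
24-bit uniforms per word; the ~6e-8 quantile granularity is far below
any statistic resolved here); the stream seed is drawn from the caller's
`numpy` Generator, so a fixed seed fixes the realization bit-for-bit, and
two simulations given the same seed receive identical input — that is
how the attended/non-attended conditions are paired.

## LFP synthesis and spectra

The model LFP is the causal exponential filtering (kernel time constant
`tau_k = 15 ms`, normalized to unit integral, truncated at `10 tau_k`)
of the per-step spike-count signal: all recurrent spikes plus `c_mix`
times all delivered external spikes.  `c_mix = 0.2` in the full model —
the external stream then dominates the signal and provides the 1/f
background — and `c_mix = 0` in the reduced model, where the external
spikes still drive the neurons but are excluded from the signal.  A
50 ms margin (~3.3 `tau_k`) is trimmed from both ends.

Spectra are squared moduli of the continuous Morlet transform
(`omega_0 = 6` rad, the standard admissible choice; implemented through
PyWavelets' `cmor` family with bandwidth 2 and center frequency
`6/(2*pi)` cycles) at 20 logarithmically spaced frequencies between 5
and 200 Hz.  Samples inside the cone of influence — within one e-folding
time `sqrt(2) * s` of either trace edge at Morlet scale `s` — are
excluded before time averaging; a frequency whose every sample falls
inside the cone is flagged invalid and excluded from all downstream
statistics.  Absolute power values are convention-dependent (they scale
with the wavelet normalization); every downstream statistic is invariant
under per-frequency monotone rescaling, which the tests assert for the
discriminability index.

## Decoding

`svm_loo_accuracy` is a multi-class linear SVM (libsvm-backed
`sklearn.svm.SVC`, `C = 1`, one-vs-one) evaluated leave-one-out over
trials: each of `N_tr` folds trains on `N_tr − 1` trials of every
stimulus and tests the held-out one of each.  Features are the raw
per-frequency time-averaged powers — no log transform and no
normalization, since the decoding target is the spectra as generated.

The discriminability index scores every unordered stimulus pair at every
frequency and trial by the Gaussian-overlap (ROC-area) statistic
`Phi(Z) = (erf(Z/sqrt(2)) + 1)/2` with
`Z = |p_i − p_j| / (sd_i + sd_j)`, `sd` being the across-trial *sample*
standard deviation (ddof = 1), and averages over pairs, frequencies and
trials.  A vanishing denominator gives score 1 for a positive gap and
0.5 for a zero gap.  Under the null of identically distributed spectra
the score converges to `(1 + (2/pi) arctan(2^{-1/2}))/2 ≈ 0.6959` — `Z`
tends to half the modulus of a standard normal ratio — which is the
finite-trial bias visible in all DI maps; the acceptance suite
reproduces it to three digits.

## Avalanche statistics

Size and duration exponents are fitted by discrete maximum likelihood on
a grid over `[1.1, 4]` (step 0.001, ties toward the smaller exponent),
restricted to windows `s ∈ [N/100, 0.6N]` and `T ∈ [5, 30]`.  The
likelihood is normalized over the truncated support,
`Z(tau) = zeta(tau, x_min) − zeta(tau, x_max + 1)` with `zeta` the
Hurwitz zeta function (SciPy's routine, checked against partial sums
with integral tail bounds).  Normalizing by `zeta(tau, x_min)` alone
while windowing the data — a formulation sometimes written down for this
estimator — is inconsistent for windowed samples (bias ≈ +0.2 at
τ = 1.5 with 10⁵ draws); the truncated normalization recovers τ to
±0.005 at that sample size, and the recovery is part of the acceptance
suite.  The `⟨s⟩(T)` exponent `1/σνz` is the closed-form least-squares
slope of `ln⟨s⟩` on `ln T` over `T ∈ [2, 20]`, using only durations with
at least one event.

Goodness of fit and criticality classification use the fitted power law
normalized by `zeta(tau_hat, s_min)` on `[s_min, ∞)` and the *empirical
CDF conditioned on `s ≥ s_min`* (the standard windowed-KS footing; it
also makes subcritical ensembles yield small D, since their in-window
bulk is steep and well fitted).  The KS statistic is the maximum CDF gap
over integer `s ∈ [N/100, N]`.  The binary supercriticality indicator γ
is 1 iff the empirical tail mass beyond `0.6N − 1` exceeds that of the
fitted CDF rescaled to match the empirical CDF at `N/100`.  When *no*
event falls inside the fit window the fit is undefined; such ensembles
are classified directly: γ = 1 if events beyond `0.6N` exist (every
cascade system-spanning — the extreme supercritical regime), else γ = 0.
Points of the coupling plane with stimulus-averaged `0 < ⟨γ⟩ < 1` form
the transition region.

`CriticalityAnalysis(avalanches).fit()` bundles the exponent triple, D,
γ, the crackling-noise residual `(α−1)/(τ−1) − 1/σνz` and optional iid
bootstrap standard errors into a results object with a `summary()`
table.

## Pattern entropy

Spike patterns are coarse-grained at observation scale `K`: neurons are
permuted by a fixed random channel order (drawn once per network and
reused across every `K` and every coupling point) and summed in
consecutive blocks of `K`, giving `N/K` channels with values in
`[0, K]`.  `H(X)` is the plug-in Shannon entropy of the empirical state
distribution over post-transient steps — no bias correction, so the
`K = 1` regime is undersampled by construction and only relative
comparisons across coupling space are meaningful.  In avalanche mode an
entire cascade occupies one step's pattern.  The default ladder is
`K ∈ {1, 2, 5, 10, 50, 100, 250, 500, 1000}`.

## Phase-space drivers and seeds

`run_coupling_sweep` evaluates the reduced model (`N = N_active = 1000`,
`c_mix = 0`) on a rectangular `(J_exc, j_inh)` grid.  Distinct random
architectures stand in for distinct stimuli; they are shared across grid
points, and every run's randomness derives from
`SeedSequence(master_seed, spawn_key=...)` keyed by the grid coordinates
and architecture index, so the sweep is a pure function of
(configuration, grid, master seed) and insensitive to execution order.
Per point the driver records ⟨γ⟩, mean D, the DI of segment-wise LFP
spectra (the post-transient run is cut into `n_trials` contiguous
equal-length segments *before* wavelet analysis, so each trial excludes
its own cone of influence), stimulus-averaged exponents, and entropy per
`K`.  Default grid ranges are `J_exc ∈ [0.05, 3]` mV and
`j_inh ∈ [0, 1]`.

**Operating point of the full model.**  The full model has no cascade
refractoriness, so recurrent excitation compounds: beyond a fairly sharp
coupling border the stimulus-nonspecific (undriven) neurons are
recruited and the network enters a pathological high-rate regime.  The
reduced avalanche-mode model *is* protected by refractoriness and
tolerates roughly 2.5× stronger excitation before its γ indicator flips;
its transition border therefore cannot be transplanted onto the full
model (probing confirms the full model is already epileptic there, with
undriven rates in the kHz range).  `tune_operating_point` instead places
the operating point at the full model's own subcritical border: the
largest coupling on a 0.05 mV grid at which the undriven population
stays below 1 Hz in the non-attended condition (1 Hz is the same
threshold the phase-space maps use to flag unphysiological points).
Probe architectures are drawn from the same seed path as the contrast
itself.  At this border the γ-band spectral peak is just emerging, and
lowering `j_inh` to the attended value pushes the activated subnetwork
toward synchrony — the regime in which the attention contrast expresses
itself.  The reduced-model γ-border routine is retained as
`tune_operating_point_reduced` for reduced-model work.

`run_attention_contrast` runs both conditions with shared architectures,
stimulus sets, initial states and external-input realizations (paired
design; only `j_inh` differs), computes spectra per trial for each
requested `c_mix`, and reports leave-one-out SVM accuracy and DI per
condition, averaged over architectures.

## Study conditions in the tests and the acceptance script

Problem sizes are scaled so the whole suite runs comfortably on one CPU;
they are package choices, fixed once:

- *Reduced sweep* (phase-space and scaling-relation checks): 6×6 grid,
  `J_exc ∈ {0.1, 0.2, 0.4, 0.8, 1.6, 3.0}` mV (geometric, spanning the
  default range), `j_inh ∈ {0, 0.2, …, 1.0}`, 3 architectures, 4 s runs,
  8 LFP segments per run, `K ∈ {1, 10, 100, 1000}`.
- *Attention contrast*: `N = 2500`, 6 stimuli, operating point auto-tuned
  as above; the acceptance script uses `N_w = 3` architectures and
  `N_tr = 10` trials; the test suite uses one `N_w = 2` estimate plus
  nine single-architecture seed replicates of the paired direction
  comparison.
- *DI null bias*: 200 replicates of `N_a = 6`, `N_tr = 36`, `N_f = 20`
  Gaussian spectra.
- *Exponent recovery*: 10⁵ truncated discrete power-law draws on
  `[10, 600]`.

What the synthetic conditions do *not* emulate: structured (non-random)
cortical connectivity, conductance-based synapses, transmission delays
beyond one step, heterogeneous synaptic weights, and any property of
real LFP recordings beyond the 1/f-plus-γ-band phenomenology.  Passing
tests therefore validate the internal consistency of the model and its
estimators, not their fit to physiological data.

## Known limitations

- **Trigger merging.**  External Poisson input launches a cascade every
  few steps; simultaneous crossings are merged into one avalanche, so a
  minority of recorded events are superpositions of independent
  cascades.  This inflates `⟨s⟩(T)` mildly at small `T`.
- **Scaling relation off criticality.**  The crackling-noise identity
  `(α−1)/(τ−1) = 1/σνz` is satisfied to within a few hundredths at an
  architecture's own critical coupling (asserted in the tests via
  bisection), but at coarse-grid transition points — where some
  architectures are already supercritical — the bump inflates the
  `⟨s⟩(T)` slope and the pooled residual reaches ≈ −0.1 … −0.5, far
  beyond the iid bootstrap spread of `(α−1)/(τ−1)` (which shrinks with
  sample count while the bias does not).  The corresponding acceptance
  check is implemented exactly as specified and is expected to fail at
  such points; this is a property of the estimator windows and the
  mixed-γ ensembles, not a sampling artifact.
- **Architecture-level decoding variance.**  At small numbers of
  coupling realizations the SVM accuracy of the full model varies by
  ~±10 percentage points across architecture draws; accuracies from few
  realizations inherit that spread.
- **Degenerate exponent fits.**  In extreme supercritical ensembles the
  grid argmax saturates at a boundary (1.1 or 4); such values are
  reported as-is and make the scaling residual meaningless there.
- **Absolute spectral power** is convention-dependent (wavelet
  normalization); only per-frequency-monotone-invariant statistics are
  compared.
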