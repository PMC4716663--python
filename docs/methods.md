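# Methods

This note documents the model implemented by `grandloop`: its equations,
parameter defaults, numerical choices, the design decisions that were
genuinely open, and what the simulations do and do not show.

## Overview

The simulator couples four component networks — cortical layer 5 (binary
self-organizing recurrent network), cortical layer 2/3 (Infomax), striatum
(winnerless FitzHugh–Nagumo), and dopamine neurons (adaptive-threshold
integrate-and-fire) — around a ring of four cortical areas, with thalamic
relay modeled as stateless gated sums.  One simulator step is 1 ms.  The
standard schedule is: *development* (layer 5 alone self-organizes its ring,
200,000 steps), *bias phase* (closed loop, 50,000 steps, with the
cholinergic parameter Ach resampled each step from |N(0,1)| clipped to 1,
letting the layer-2/3 biases adapt), then a *main phase* at fixed
Ach ∈ {0.25, 0.5, 0.75} and dopamine window τ_DA ∈ {25, 100} ms.

All randomness flows from a single seed through named
`numpy.random.SeedSequence` children (layer-5 membrane noise, striatal
wiring, corticostriatal wiring, dopamine assignments, mixing matrices, bias-
phase Ach), so a (config, seed) pair replays bit-for-bit.

## Cortical layer 5

Binary threshold units, N_E = 400 excitatory and N_I = 80 inhibitory.
Excitatory update (1-ms step):

    x_i(t+1) = H[ U_i * Σ_j W_EE[i,j] x_j(t) − Σ_k W_EI[i,k] y_k(t)
                  + ξ_i(t) − T_E[i] ]

with ξ ~ N(0, σξ² = 0.01) independent per unit and step, and gain U from
layer 2/3 (all-ones when uncoupled).  Inhibitory units respond to the new
excitatory state: y_k(t+1) = H[Σ_i W_IE[k,i] x_i(t+1) − T_I[k]].

Plasticity, applied once per step in this fixed order (the order matters at
these rates and is part of the model definition):

1. **STDP** (existing synapses only):
   ΔW_EE[i,j] = η_STDP [x_i(t) x_j(t−1) − x_i(t−1) x_j(t)], η_STDP = 0.004.
2. **Inhibitory STDP**: ΔW_EI[i,k] = −η_inhib y_k(t−1) [1 − x_i(t)·η_iSTDP]
   with η_inhib = 0.001 and η_iSTDP = 11.0.  Note 11 = 1 + 1/μ_IP at the
   homeostatic target μ_IP = 0.1: the rule's fixed point is postsynaptic
   firing at the target rate.  W_EI is clipped to [0.001, 1] and
   row-renormalized.
3. **Intrinsic plasticity**: T_E ← T_E + η_IP (x(t) − μ_IP), η_IP = 0.01,
   threshold noise σ_HIP = 0.  This pins the long-run firing probability at
   μ_IP per step, i.e. 100 spikes/s.
4. **Row normalization**: each unit's incoming excitatory weights are
   rescaled to sum to 1 (only rows touched this step need rescaling).
   Negative weights are clipped to zero first and pruned.
5. **Structural plasticity** (development only): with probability 0.1 per
   step one random new connection is created at weight 0.001.

Initial connectivity: directed Erdős–Rényi at 10% density with uniform
weights (row-normalized); W_EI, W_IE dense, row-normalized; thresholds
uniform in [0, TEmax = 1] and [0, TImax = 0.5].

**Development and area identification.**  After 200,000 steps of
self-organization at unit gain, weights ≤ 1e-6 of the row target are
frozen at zero for the remainder of every simulation.  A 5,000-step probe
raster is then recorded and units are clustered into N_A = 4 groups by
average-linkage hierarchical clustering of the spike-train correlation
matrix; the groups are put into cyclic order by maximizing the summed
block-to-block weight along the ring (label k projects most strongly to
label k+1).  Clustering on correlations was chosen over first-spike phase
sorting because it is robust to membrane noise and directly expresses the
validation criterion (correlated propagation layers); the weight-based
cyclic ordering recovers the propagation sequence.  The four blocks are
named (M1, M_sup, S_sec, S1) in propagation (feedback) order; block sizes
are whatever development produces (they need not be equal).

## Cortical layer 2/3 (Infomax)

One instance per area, dimension = that area's unit count.  Forward:
x_I = x̂_I − x0, u = C x_I, y = σ(u + w0) with the logistic σ.  Learning
(every step; rates from the defaults table below):

    Δx0 = β_x0 (x̂_I − x0)          running input mean
    Δw0 = β_w0 (1 − 2y)             bias toward mean output 1/2
    ΔC  = β_C [A + (1 − 2y) x_Iᵀ]   anti-redundancy + Hebbian term
    ΔQ̂  = β_Q (u uᵀ − Q̂)            lateral Hebbian estimate of <u uᵀ>

`A` is the anti-redundancy term, asymptotically (Cᵀ)⁻¹.  Two modes:

* **direct** (default): A = (Cᵀ)⁻¹ computed by matrix inverse.  The
  inverse is cached and refreshed every 10 steps (`inverse_refresh`); C
  moves by O(β_C) per step so the cached inverse is accurate to ~1% between
  refreshes.  Set `inverse_refresh: 1` for the exact per-step inverse.
* **lateral**: iterate v ← v + u − α Q̂ v to its fixed point
  (u = α Q̂ v∞) and use A = α v∞ x_Iᵀ, whose stationary average equals
  (Cᵀ)⁻¹.  Convergence requires α < 2/λ_max(Q̂); the implementation sets
  α = 1/λ_max(Q̂), refreshed every 1,000 steps, and raises a diagnostic
  error (reporting α and the spectral radius) on divergence.  v restarts
  from zero each presentation (any start converges to the same fixed
  point).

C is initialized at identity plus N(0, 0.01²) jitter (full rank by
construction); its condition number is monitored periodically and learning
halts with an error above 1e12.  The Hebbian (1−2y)x_Iᵀ term can be
disabled for ablation (`hebbian_term: false`).  Learning runs every 1-ms
step throughout all closed-loop phases, including the bias phase (a
bias-only interpretation of that phase can be emulated by setting β_C and
β_Q to zero for those steps).

## Striatum

100 MSNs (first 50 labeled D1/direct, last 50 D2/indirect), each a
FitzHugh–Nagumo unit in dimensionless time:

    τ₁ ẋ = x − x³/3 − y − z (x − ν) + I_bias + I_cortex
       ẏ = x − b y + a
    τ₂ ż = Σ_j W_Str[i,j] H(x_j) − z

with a = 0.7, b = 0.8, τ₁ = 0.08, τ₂ = 4.1, ν = −1.5 (inhibitory reversal)
and initial state (−1.2, −1.62, 0).  `I_bias = 0.35` is the constant
depolarizing drive of the cited winnerless formulation; it places each
uncoupled unit just past the oscillation threshold so the network bursts
spontaneously, which the lateral inhibition then organizes into
turn-taking.  Lateral wiring: directed Erdős–Rényi at 15% density (the
midpoint of the 10–20% transition range for winnerless encoding), weights
uniform in [g_min, g_max] = [0, 0.25], zero diagonal, with D1→D2 links
present at a boosted 30% (direct-pathway MSNs inhibit indirect-pathway
ones).  Because z relaxes toward a non-negative rectified sum, z ≥ 0
throughout.

**Time scaling.**  The equations are dimensionless; one 1-ms simulator
step advances model time by h.  h was calibrated once by sweeping it on a
separate network realization until the mean positive-transient duration of
x_f was ~350 ms, then frozen at **h = 0.003** in the default configuration.
Integration is explicit Euler at h/10 sub-steps (τ₁ = 0.08 needs the
sub-stepping); |x| > 100 raises an integration error naming the step size.

**Burst output.**  P = max(x_f, 0); the derivative signal is the sign of
the one-step difference of P.

**Corticostriatal synapses.**  Each MSN has 20 input slots wired to layer-5
units drawn from the area whose thalamic relay it gates plus that area's
feed-forward and feedback neighbors, at initial weight 0.005 = 0.1/20
(every MSN starts exactly at the 0.1 normalization cap).  Plasticity per
step, learning rate 0.002: a cortical spike at a synapse counts as a
*pre-post* pairing if the MSN's P′ > 0 and *post-pre* if P′ < 0.  The
signed gate applied to each pairing depends on (MSN type × dopamine
present), and high GABA — z_f > 0.00707 — flips the sign of every active
entry:

| condition      | pre-post | post-pre |
|----------------|----------|----------|
| D1, dopamine   | LTP      | LTD      |
| D1, no dopamine| off      | off      |
| D2, dopamine   | LTD      | off      |
| D2, no dopamine| LTP      | LTD      |

The table is a configuration item (`ModulationTable`) so alternatives can
be tested; this default expresses the differential D1/D2 dopamine
modulation with GABA reversal.  "A multiple of the pairing value" is
implemented as a constant multiple.  After each update, weights are clipped
at zero, zero-weight synapses are pruned (slot deactivated), per-MSN sums
are rescaled down to the 0.1 cap (a hard invariant at all times), and each
MSN with a free slot gains at most one new synapse per step with
probability 0.2 at the initial weight.  Each slot carries a fixed dopamine-
neuron assignment drawn without replacement within the MSN, so no dopamine
neuron governs two synapses of the same MSN.

## Dopamine neurons

20 neurons, SI units (volts, seconds), Δt = 1 ms:

    İ_j = −k_j I_j                       k₁ = 200, k₂ = 20
    V̇   = (I_e + I₁ + I₂) − (G/C)(V − E_L)
    Θ̇   = a (V − E_L) − b (Θ − Θ_inf)

Spike on V > Θ (strict), with instantaneous resets I_j ← R_j I_j + A_j,
V ← V_R, Θ ← max(Θ_r, Θ).  Parameters: G/C = 50 s⁻¹, Θ_inf = −0.05 V,
E_L = V_R = −0.07 V, Θ_r = −0.06 V, a = 1, b = 1, R₁ = 0, R₂ = 1,
A₁ = 5, A₂ = −0.3.  Only the ratio G/C is specified, so currents are
expressed in V/s and the −2.25 striatal weight absorbs the scale:
I_e = −2.25 × Σ(assigned MSN burst outputs), 20 MSNs per neuron drawn
without replacement from the whole population.

**Integration.**  The model is linear between spikes, so each 1-ms step is
propagated in closed form (matrix exponential written out per variable).
This matters: forward Euler at 1 ms misorders the tightly spaced spikes
inside a rebound burst and yields five spikes where the continuous dynamics
yields four (verified against a 0.01-ms reference integration; the exact
step reproduces the reference's spike times within ±2 ms).  Mechanism of
the rebound: sustained hyperpolarization drags Θ below Θ_inf
(a(V−E_L) < 0 with a 1-s threshold time constant); on release V relaxes to
E_L within ~20 ms, crosses the depressed threshold, and the
R₂ = 1 current accumulates −0.3 V/s per spike until it terminates the
burst — always after four spikes, independent of hyperpolarization depth
beyond the minimal depth that triggers rebound (depth ≈ −4.5 V/s sustained
~500 ms; −2.25 is subthreshold, and longer-weaker hyperpolarization also
works).

**Dopamine release** is a projection to synapses, not neurons: a spike sets
dopamine-present on the neuron's assigned corticostriatal synapses until
now + τ_DA; overlapping stamps extend the window rather than stack.

## Closed-loop step

Per 1-ms iteration, in fixed order: (1) layer 5 steps under gain U from the
previous layer-2/3 outputs, plasticity applied; (2) trailing τ_X = 100 ms
spike-count windows update; (3) striatum steps under corticostriatal drive,
burst outputs read; (4) pallido-thalamic gates Ĝ = H[D·P] evaluate, with
H(0) = 0 (tonic pallidal inhibition closes the relay at exact balance;
disinhibition must be strictly positive); (5) thalamic relay
x_FF = Ĝ ⊙ (M_FF x̂_FF) and layer-4 combination x̂_I = x_FB + x_FF per area;
(6) layer-2/3 forward + learning; (7) corticostriatal STDP under the
current GABA/dopamine conditions; (8) dopamine neurons step under summed
MSN inhibition; (9) dopamine stamping.  The mixing matrices M_FB, M_FF are
fixed lognormal with unit mean and unit standard deviation of the
distribution itself (σ² = ln 2, μ = −ln2/2 in log space), guaranteeing the
full-rank mixing the Infomax stage needs.  Each relay neuron of a gated
(frontal) area draws N_Str,Th = 11 MSNs from those homing on that area,
sign +1 for D1 and −1 for D2; sensory areas relay ungated.  MSN "home"
areas alternate over the two gated areas so both pathways cover both.

## Measurements

* **Population entropy**: plug-in (maximum-likelihood) estimate over
  per-time-step binary population words, hashed to counts.  An optional
  subsampling report re-estimates on data fractions and extrapolates in
  1/samples for a bias check.  The plug-in choice is deliberate: at the
  durations used (10⁴–10⁵ samples) and with small word alphabets it is
  accurate; for the full 400-unit population the words essentially never
  repeat (membrane noise), the estimate saturates at log2(samples), and no
  condition comparison is possible — so trend analyses measure entropy on
  a fixed random 20-unit cortical subpopulation, where word counts are
  estimable.  This subsampling is the scaled-down operationalization used
  by the acceptance checks.
* **Mutual information**: I = H(A) + H(B) − H(A,B) with concatenated joint
  words, clipped at zero.  For weak dependencies the plug-in MI is
  dominated by estimator bias; trend tests therefore subtract a shuffle
  control (MI against a half-length circular shift of one stream).
* **Spike–burst correlations**: Pearson r per (cortical unit, MSN) pair at
  1-ms bins, two-sided t-test at α = 0.05 with no multiple-testing
  correction, non-significant entries zeroed; zero-variance pairs are
  reported as zero with a flag.  Group comparison: Welch t-test between D1
  and D2 coefficient distributions per area.
* **Burst/rate statistics**: mean rates; positive-transient durations of
  x_f (onset above 0, offset at return, incomplete transients discarded);
  bursts-of-bursts merged at a 500-ms gap; dopamine ISI mean and CV.
* **Dwell times**: the raster is averaged over non-overlapping 50-ms
  windows and a dwell ends when consecutive window vectors correlate below
  0.8.  Both constants are configuration-exposed; dwell comparisons are
  trend-level only (the quantity has no absolute calibration).

## Problem sizes used by the tests and the acceptance script

Chosen as the package's standard verification sizes: the layer-5 set point
uses the final 20,000 of a 50,000-step run at full size; striatal burst
duration uses two fresh 100-MSN realizations of 100 s each; the closed-loop
dopamine rate uses the full development (200,000 steps) and bias (50,000)
phases followed by a 100,000-step main phase; trend comparisons across Ach
use 30,000-step main phases from a shared developed model.  Infomax mode
equivalence is verified at small dimension over 10,000 steps with the
per-step exact inverse.

## Known limitations

* The emergent propagation layers are unequal in size and their traversal
  patterns cycle faster than a few hundred milliseconds; smoothed
  population vectors decorrelate within 50–100 ms at all Ach levels, so
  dwell-time statistics sit at the one-window floor and do not separate
  neuromodulatory conditions at these run lengths.
* The closed-loop dopamine population rate settles near 3 Hz (clean
  four-spike rebound bursts; the rate is set by the frequency of striatal
  release events, i.e. bout turnover in the winnerless network under the
  calibrated time scaling and 15% lateral density).
* Cortex→dopamine mutual information per 1-ms word is below the plug-in
  bias floor at these durations; only the shuffle-corrected value is
  meaningful, and it is indistinguishable from zero here.
* No biophysical neurons, no axonal delays beyond the 1-step update, no
  sensory environment or motor readout (the layer-4 sensory term and
  pyramidal-tract taps exist as unused hooks), no reward encoding in the
  dopamine pathway, and no within-burst spike structure in MSNs.
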