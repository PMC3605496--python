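# Methods

## Model

Neurons are leaky integrate-and-fire units with instantaneous synaptic
responses. Between inputs the membrane potential V decays toward the resting
potential V_P with time constant τ_P; a presynaptic spike produces a jump

* conductance model: V ← V + g_X (V_X − V), X ∈ {E, I},
* current model: V ← V + a_X,

and a spike is emitted at V ≥ V_Θ, after which V is clamped at V_R for an
absolute refractory period τ_ref during which inputs are discarded. Default
constants (mV, ms, dimensionless conductances): V_E = 0, V_I = −80,
V_P = V_R = −70, V_Θ = −55, τ_P = 20, τ_ref = 2, g_E = 0.005, g_I = 0.11.
The conductance form confines V to [V_I, V_E] and shortens the effective
membrane time constant under bombardment (1/τ = 1/τ_P + λ_E g_E + λ_I g_I),
which is the high-conductance state responsible for the model's favorable
signal-to-background contrast.

The embedding places p excitatory pools of n_E neurons (and paired
inhibitory shadow pools of n_I = γ n_E neurons, γ = 1/4) into populations of
N_E and N_I = γ N_E neurons, ordered into one ring. Every excitatory synapse
is part of an all-to-all pool-to-pool link (E-pool μ → E-pool μ+1 and
I-pool μ+1), so the number of excitatory inputs per neuron is
C_E = p n_E²/N_E and the embedding level is α = p/N_E = C_E/n_E². Pool
membership is balanced to ⌊p n_E/N_E⌋ or ⌈p n_E/N_E⌉ pools per neuron with
distinct members inside any one pool (repair by swapping across pools).
Inhibitory neurons project to uniformly random targets such that every
neuron's inhibitory in-degree is round(γ′ × its excitatory in-degree),
γ′ = 1/4. Excitatory link delays are τ_A(μ) + τ_B(μ,i,j) with
τ_A ~ U[0.5, 4.5) ms per link and τ_B ~ U[0, 0.5) ms per synapse;
inhibitory synapses draw both components independently. (The distribution
mean is 2.75 ms; measured pool-to-pool propagation locks to a fixed quantile
of each link's τ_B spread, so the observed per-pool time tracks the
realization's mean link delay with a near-zero additional lag.)

The network receives no tonic external drive. Waves are initiated by
packets of n_E input spikes, normally distributed with σ = 0.1 ms, delivered
to every neuron of a target E-pool and its shadow I-pool with independent
τ_B delays, repeated every T_stim = 40 ms from t = 200 ms. An optional
E/I-balanced Poisson ramp (four equal decrements over the first four
stimuli) is available but off by default; the model works without it.

## Integration scheme

All simulation is time-stepped at dt = 0.1 ms; delays and spike times live
on this grid (delays rounded half-up, minimum one step). Per step and
neuron: leak decay, then all excitatory jumps, then all inhibitory jumps,
then one threshold test; spike times are recorded at the step end. n
same-type conductance jumps compose to V ← V_X + (V − V_X)(1 − g_X)^n. The
E-before-I ordering of simultaneous events is a convention this package
fixes (delta synapses leave it open); same-type jumps commute. Inputs
landing during refractoriness are discarded, including the boundary step at
which refractoriness ends being the first integrating step.

The step discretization matters quantitatively: against an exact
event-driven integrator the endpoint potential converges at first order in
dt, and the stochastic firing rate under strong bombardment converges from
below (at λ_E = 100 kHz the 0.1 ms grid yields ≈1 Hz versus ≈6.4 Hz in the
continuum). This is why the stochastic-rate function f_S used by the
mean-field closure is *measured* on the same grid with the same scheme as
the network simulations rather than taken from a continuum formula — the
closure must describe the simulated dynamics, not the continuum limit. A
consequence is that the measured f̂_S rises with λ_E only up to ≈100 kHz at
the default inhibition and declines beyond; monotonicity holds on the
rising branch, which contains all operating points used here.

Delivery uses a circular calendar of depth max-delay/dt; Poisson background
counts are drawn per neuron and step (alias-method sampler for the fixed
background means). Batched trials share the network but consume
independent noise, and all randomness derives from one master seed by
hashed stream tags, so every result is bit-reproducible given its seed.

## Measured mean-field inputs

f_S(λ_E, γ′λ_E) is tabulated from single-neuron simulations on a λ_E grid
(reference protocol 100 runs × 5000 ms, first 1000 ms discarded; tests use
20–60 runs × 2–3 s) and linearly interpolated. Packet propagation is
characterized on a non-embedded control chain of disjoint pools (reference:
100 pools; desk-scale tests use 50 pools, which is equivalent because the
per-pool failure rate, log(1/P_S)/L, is length-invariant) with uniform
Poisson background: after a 100 ms warm-up a packet is injected into the
third pool; P_S is the fraction of trials with a packet detected in the
last pool, p_f the mean packet size over surviving trials divided by n_E,
and T the mean time between the packets ten pools apart at the chain end,
divided by ten. Trials are retired early once the wave has provably
finished or has left no suprathreshold 3 ms window anywhere for a 50 ms
segment (a packet chain cannot bridge such a gap given the 6 ms link
window); this changes no detection outcome and saves most of the simulated
time.

## Packet detection

Per pool, every spike time t_k opens a window [t_k, t_k + T_w), T_w = 3 ms;
windows with more than n_θ spikes are suprathreshold, with
n_θ = round(0.4 n_E) by default (the published rule places n_θ midway
between expected packet size and background count; only the ≈0.4 n_E
outcome is specified, so that is the exposed default). Maximal runs of at
least 6 suprathreshold windows yield one packet each: among the run's
maximal-count windows the middle one (0-based index ⌊m/2⌋) is the packet,
timed at the median of its spikes (lower-middle element for even counts).
Packets on consecutive pools link into waves when their interval lies in
[0.5, 6] ms, greedily and earliest-first (relevant when waves lap on the
ring); each packet joins at most one wave. A wave counts as alive from its
first packet to its last packet plus one mean inter-packet interval (3 ms
for single-packet waves). Equilibrium statistics start at
t_start = max(1000 ms, first time h(t) reaches its mean over [1000 ms, end])
— "reaches" rather than "exceeds", so a flat h(t) is handled. Packet-member
spikes are deduplicated by (neuron, time) before entering ν_W, because a
neuron belonging to several pools contributes its train to each of them.
The detector assumes low background rates inside the detection window; it
is not a general synchrony detector.

## Mean-field analysis

With λ_I/λ_E = γ′ fixed, the stationary state for h waves solves
λ_E = C_E[(h/N_E) n_E p_f(λ_E)/T(λ_E) + f_S(λ_E)] (rates in kHz; rate
tables store Hz and are converted). The residual is scanned on a fine grid
over the joint table support; the first sign change is polished by Brent's
method (bracket tolerance 10⁻³ kHz, polished to 10⁻¹⁰, so the residual at
the root vanishes to rounding). The smallest root is returned — the
physical low-rate branch — with a stability flag from the naive
balanced-network criterion |C_E df̂_S/dλ_E| < 1, the derivative taken as the
slope of the tabulated interpolant over one grid interval (central at
interior nodes). P_S is clipped to [10⁻⁶, 1−10⁻⁶] inside all lifetime
formulas; exactly degenerate P_S ∈ {0, 1} raises instead of silently
saturating. The driven equilibrium solves
L n_E p_f/(T_stim log(1/P_S) N_E) = λ_E/C_E − f_S(λ_E) by bisection, and the
cheap λ_E,max shortcut (evaluate everything at P_S = 0.5) is reported
alongside; on tables with the measured cliff steepness the two agree within
one grid interval. Capacity curves condition either on the equilibrium
firing rate (λ_E = C_E ν_eq, α_max = C_E/n²_E,min, with limits
C_E,max1 = 1/(df̂_S/dλ_E) and C_E,max2 = λ_E,max/(2 f_S(λ_E,max))) or on the
waves-per-neuron level, in which case the lifetime relation is inverted
numerically per pool size and the curve is parametric in n_E. Unmeasured
table cells are NaN; each pool size may be characterized on its own
background bracket and merged.

## Diffusion approximation and model comparison

The simplified analysis assumes zero intra-link delay spread and Gaussian
free-potential statistics. Conductance moments use the effective-time-
constant form: 1/τ = 1/τ_P + λ_E g_E + λ_I g_I,
μ = τ(V_P/τ_P + λ_E g_E V_E + λ_I g_I V_I),
σ² = (τ/2)(λ_E g_E²(V_E−μ)² + λ_I g_I²(V_I−μ)²); current moments take
τ = τ_P, μ = V_P + τ_P(λ_E a_E + λ_I a_I), σ² = (τ_P/2)(λ_E a_E² + λ_I a_I²).
The exact moment expressions for conductance synapses admit more than one
published form; the σ² used here is the standard effective-time-constant
reading and is cross-validated against threshold-free ensemble simulations
for the current kind. The Siegert rate
f_S = [τ_ref + τ ∫_{(V_R−μ)/√2σ}^{(V_Θ−μ)/√2σ} √π e^{z²}(1+erf z) dz]⁻¹ is
evaluated with erfcx up to z = 5, a two-term −1/z asymptotic antiderivative
for the deep subthreshold stretch, and an e^{z²}·dawsn-based log-space tail
above — no overflow for arbitrarily deep thresholds.

The minimum pool size uses the 95 % criterion
n_E,min a_eff = V_Θ − (μ − 1.645σ), with a_eff = a_E for current synapses
and a_eff = g_E(V_E − V_avg), V_avg = (V_R + V_Θ)/2 = −62.5 mV, for
conductance synapses (hence the matched amplitude a_E = 0.3125 mV at
g_E = 0.005). Sweeps hold ν = 5 Hz, set λ_E = C_E ν, and truncate at the
first of: fixed-point instability, ν_S ≥ ν/2, or non-increasing α_max.
Current models can also be *fitted* to a conductance model at its maximal
connectivity: τ_P set to the conductance τ, and (a_E, a_I) solved from the
two moment constraints given V_P; the choice V_P = μ zeroes the mean drive
(a_E λ_E + a_I λ_I = 0). Reference sweep lists: g_I ∈ {0.02, …, 0.10},
a_I ∈ {0.25, …, 1.5} mV, 21 V_P values in [−88.4, −56.6] mV. The stability
derivative here uses one connectivity-grid interval in λ; the scheme is a
documented package choice, not canonical.

## Synthetic data and what the tests show

All test inputs are generated in-process: planted-packet rasters (packets
of ≥0.8 n_E spikes over ≤5 Hz background — the regime the detector is
specified for), miniature embeddings (e.g. C_E = 96, n_E = 16, N_E = 960,
preserving N_E = 10 C_E and γ = 1/4), and control chains. Smooth synthetic
rate/propagation tables (sigmoid survival cliffs of the measured ~0.3 kHz
width, weakly varying p_f and T) exercise the solver numerics with known
geometry; they are labelled synthetic and stand in for measured tables only
where the check concerns the numerics, never the dynamics. Simulation-backed
tests use desk-scale problem sizes chosen as the package's defaults for
interactive work: 50-pool chains, 6–16 trials per table cell, pool sizes
80 and 112, and a C_E = 500, N_E = 5000, n_E = 80 embedding run for 5 s.

These sizes support every qualitative conclusion (threshold-rate and
capacity orderings in g_I, monotonicity in n_E, stationary driven
equilibria) but not the quantitative mean-field accuracy reported at
cortical scale. The analysis neglects input correlations: each neuron's
"background" is in fact a superposition of synchronous volleys from the
other pools it belongs to, and the dropped share of the excitatory
background scales as n_E/(C_E(1+ν_S/ν_W)). At C_E = 8000 this is a percent-
level correction and the prediction overshoots simulated rates by only
10–20 %; at the desk scale C_E = 500 it is ≈16 %, and the measured
overshoot grows to ≈1.6–1.7× on both ν and h_eq (≈1.4× at C_E = 1000,
consistent with the trend toward the cortical-scale figure). The suite
therefore carries two cross-validation tests: a strict ±20 % comparison,
which documents this finite-scale breakdown, and a qualitative one
(prediction above simulation, within a factor 3, stationary equilibrium)
which passes at desk scale.

## Known limitations

* No synaptic rise times, no adaptation, single-compartment neurons;
  delta synapses make the intra-link delay spread the only integration
  window.
* The detector fails by design when background rates inside 3 ms windows
  approach 0.4 n_E.
* f̂_S beyond its discretization peak (≈100 kHz at dt = 0.1 ms) is
  non-monotone; capacity machinery should be driven with tables covering
  the operating range only.
* The Poisson-background treatment of the control chain ignores the
  common-input correlations of the real embedding; see above for the
  scale-dependent consequences.
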