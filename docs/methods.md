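# Methods

`v1circuit` implements three consistent renderings of an eight-population
model of layered rodent primary visual cortex — a spiking network, a
neuron-resolved mean-field model, and a linearized network model — together
with the analysis machinery (pathway decomposition, eigenmodes, stimulus
design, orientation-tuning measures) that connects them.

## The network model

The circuit contains 77 169 leaky integrate-and-fire neurons in eight
populations (L2/3e … L6i).  Connectivity is *fixed in-degree*: every neuron
of population P receives exactly K[P, T] synapses from distinct, uniformly
drawn neurons of population T; self-connections and multapses are excluded.
Synaptic efficacies are Gaussian, SD = 10% of the mean, hard-clipped at zero
toward the wrong sign (Dale's principle); means are J_e = 0.15 mV for
excitatory and −g·J_e (g = 4) for inhibitory sources, with the L4e → L2/3e
projection doubled.  Delays are Gaussian (1.5 ± 0.75 ms excitatory,
0.7 ± 0.35 ms inhibitory), clipped below at the simulation step dt = 0.1 ms.

Every neuron receives a compound Poisson background of rate K_bg·ν_bg
(ν_bg = 8 spikes/s) at efficacy J_e.  L4 and L6 additionally receive tuned
thalamic drive

    ν_th,i(θ) = K_th · ν0_th · [1 + m cos 2(θ − θ̂_i)] ,

with ν0_th = 30 spikes/s, m = 0.3, per-neuron preferred orientations θ̂_i
uniform on [0°, 180°), and twelve stimulus angles 0°…165°.  Compound
sources are modeled as a single Poisson process of the summed rate, which is
exact for superposed Poisson inputs.  In the spontaneous condition the
thalamic drive is untuned at the background intensity (m = 0,
ν_th = K_th·ν_bg).

Six parameter sets are provided: standard, background rate ×2 and ÷2,
g ×2, all recurrent efficacies ×2, and all recurrent in-degrees ÷2.

## Model A — spiking simulation

Clock-driven at dt = 0.1 ms with delta synapses and the exact exponential
propagator for the leak (no integration error between events).  Recurrent
spikes are delivered on the grid (delays rounded to grid multiples, minimum
one step) through a ring buffer.  External Poisson input is
*event-resolved*: within each step, jump times are drawn from the exact
exponential inter-arrival distribution, the membrane decays analytically
between jumps, and the threshold is checked after every jump.  Plain
per-step binning of external input effectively raises the threshold by
O(σ√(dt/τ_m)) because excursions shorter than dt are missed; with
event-resolved input the simulator reproduces the stationary first-passage
rate of a Poisson-driven neuron to ~1% at the standard efficacies (a unit
test pins this against the Siegert formula).  Spikes reset the membrane to
V_r and clamp it for τ_ref = 2 ms; input arriving during the clamp is
discarded.  Initial potentials are uniform on [V_r, V_thr) — the model
statement is silent here, and a 200 ms warm-up (discarded) removes the
residual transient.  Structure, orientation assignment and input noise use
independent seed streams; per-angle substreams derive deterministically from
the input seed.

## Model B — mean-field rates

Each neuron's input is summarized by its mean μ_i and variance σ_i²
(recurrent sums over realized synapses τ_m ΣJ_ij ν_j and τ_m ΣJ_ij² ν_j,
plus compound background and thalamic terms).  Stationary rates solve
ν_i = F_i(ν) with the first-passage transfer function

    F = 1/Φ,   Φ = τ_ref + τ_m √π ∫_{(V_r−μ)/σ}^{(V_thr−μ)/σ} erfcx(−x) dx ,

evaluated with Gauss–Legendre quadrature (order 200, split at x = 0) on the
erfcx form, values capped at 1e280 so that deeply subthreshold neurons
return ~0 without overflow.  The √π prefactor is the standard first-passage
normalization; it is pinned independently by the spiking cross-check above.
The fixed point is reached by pseudo-time relaxation dν/ds = −ν + F(ν)
integrated with adaptive RK45 (rtol 1e-8) from ν = 1 spike/s, in chunks of
25 pseudo-time units until ‖F(ν) − ν‖∞ < 1e-6 spikes/s (budget: 400 units).
The relaxation rate is set by 1 − λ of the effective-connectivity spectrum;
for the inhibition-dominated sets used here convergence takes a few tens of
units.

## Model C — linear response

At the operating point (thalamus silenced, background active — so thalamic
perturbations equal thalamic rates), the Jacobian of F gives the effective
connectivity on the synaptic pattern

    W_ij = ∂F_i/∂μ_i · τ_m J_ij + ∂F_i/∂σ_i · τ_m J_ij² / (2σ_i)

with closed-form erfcx derivatives (verified against finite differences of
the full Model B map to <1e-4 relative), and a diagonal thalamic sensitivity
B with single-axon efficacy J_e (the in-degree lives inside ν_th).  The
stationary response is Δν = (1 − W)^{-1}Δβ, solved by GMRES to a residual of
1e-8·‖Δβ‖∞ (dense solve below N = 2000).

W decomposes into Q + S where Q holds the *empirical block means of the
realized W over all ordered pairs, zeros included*.  This realization-level
definition (rather than the ensemble expectation) makes the block means of
S vanish identically, which the baseline/modulation separation argument
requires; S is never materialized (S·x = W·x − Q·x with Q applied through
population sums).  The baseline system is solved exactly through the
collapsed 8×8 matrix Q̂_PT = q_PT·N_T; the modulation system through
(1 − S).  Interference is quantified by the mean magnitudes of Q·Δν_M and
S·Δν_B against mean |Δβ|.

Eigenmodes operate on Q̂ only (Q has rank ≤ 8).  Coefficients ξ solve the
8×8 system Ψξ = Δβ_B, exact for non-orthogonal eigenvectors; eigenvectors
are unit-norm with the largest entry rotated to the positive real axis, and
gains are λ̃ = (1 − λ)^{-1}.  A *population-level ensemble linearization*
(`ensemble_collapsed_model`) evaluates Q̂ from the analytic expected synapse
(K_PT × E[W entry]) at the population mean-field operating point; because it
never touches individual synapses it is exact at any scale, including the
full-scale model, and is how full-scale spectral statements (seven
large-magnitude eigenvalues, one small-magnitude mode whose gain dominates
and carries the L5e rate excess) are checked on a laptop.  The bulk radius
of W is estimated from block-entry variances (circular-law scaling) with a
configurable exceptional margin of 1.2.

Current stimuli enter as zero-variance drive μ = R·I, i.e. effective
perturbations Δγ_i = (∂F_i/∂μ_i)·R·I_i.  Mode deletion sets Δγ = −ξ_k Ψ_k;
selective suppression sets Δγ = (1 − W)Δν_target, which changes non-target
population rates only at the solver tolerance.  Reported absolute rates are
clipped at zero with a rectification flag; the linear solve itself is never
clipped.

## Tuning measures

OSV = Σ_θ ν(θ)e^{i2θ} / Σ_θ ν(θ); OSI = |OSV|; PO = arg(OSV)/2.  F0 is the
mean rate and F1 the magnitude of the first complex Fourier coefficient,
|Σ ν e^{i2θ}|/n, so that OSI = F1/F0 holds exactly and a perfect cosine with
modulation m gives OSI = m/2 (machine-precision identity on the 12-angle
grid, where Σe^{i2θ} and Σe^{i4θ} vanish).  OSI* fits a + b·cos 2(θ − φ) in
the linear cos/sin basis and reports (max − min)/(max + min) of the fit
(= m for the same cosine).  All-zero curves have undefined OSV; they are
excluded from population statistics and counted.  Input currents are
I_ij = C_m J_ij ν̄_j (pA), tuning vectors TV_ij = C_m J_ij ν̄_j OSV_j; the
aggregate |TV| per projection equals the F1 of the summed input current for
cosine-like curves.  ISI CV uses neurons with ≥3 spikes; pairwise
correlations are Pearson coefficients of 10 ms binned counts on a seeded
random sample of pairs (the full pair set is quadratic).

## Downscaling

Desk-scale work uses reduced networks: population sizes and recurrent
in-degrees scale by f (rounded, minimum 1).  A naive reduction would
collapse the operating point — at f = 0.1 the background mean drive drops
from ~19 mV to ~2 mV against a 15 mV threshold distance and the network
falls silent.  The package therefore preserves input statistics: recurrent
efficacies scale by 1/√f (keeping the input *variance* exact), and a
per-population DC compensation restores the recurrent *mean*, evaluated at
the full-scale population mean-field rates of the spontaneous condition.
External in-degrees are not scaled at all: background and thalamic drive are
compound Poisson rates whose simulation cost is independent of K, so scaling
them would distort the dynamics for no benefit.  With this construction the
reduced model reproduces the full-scale spontaneous population rates to a
few percent and stays in the asynchronous-irregular regime.

What the reduced model does *not* preserve: the recurrent loop gain scales
by √f, so the operating point drifts in conditions away from the
compensation reference, the mode-gain hierarchy of Q̂ flattens, and the
synaptic jumps grow by 1/√f, degrading the diffusion approximation behind
Model B (inhibitory jumps reach 1.9 mV at f = 0.1).  Consequences adopted in
the test suite: spiking-vs-mean-field rate agreement is checked at f = 0.4
(jumps ≤ 1.6× full scale; agreement within 15% per population), linear-model
pathway separation at f = 0.1 (it is exact linear algebra at any scale), and
full-scale-specific qualitative claims via the ensemble collapsed model.

## Problem sizes and tolerances

Test and acceptance runs use factor 0.1 (7 717 neurons, ~3×10⁶ synapses;
spiking 15 s per condition) and factor 0.4 for the cross-model rate
check (~4.8×10⁷ synapses, 1.5 s).  The mean ISI CV in these windows carries a
small negative bias from finite spike counts (the SD/mean estimator on few
ISIs), which shrinks with the analysis window; window lengths were chosen
so that population statistics are stable.  Fixed-point tolerance is 1e-6
spikes/s (∞-norm); linear solves 1e-8 relative; mode reconstruction and
designed-stimulus targets hold to 1e-8–1e-10.  The full-scale network
(~3×10⁸ synapses) is a workstation-class object: building its synapse table
and the W/J/J² sparse matrices needs tens of GB, and `network.build` checks
the estimated footprint against available physical memory (including cgroup
limits) and refuses early rather than thrashing.

## Known limitations

* No temporal structure of the grating (no F1/F0 spiking modulation, no
  direction selectivity), no plasticity, no conductance or exponential-PSC
  synapses, no spatial geometry or retinotopy.
* Model B/C assume Poisson statistics and negligible correlations; at
  strong downscaling the enlarged jumps violate the diffusion limit
  systematically (low-rate populations are most sensitive).
* Spike times are reported on the dt grid; sub-step timing is used only for
  threshold dynamics, not for delivery times.
* The synthetic (downscaled) networks emulate the full model's operating
  point, not its fluctuation structure at criticality; passing reduced-scale
  tests demonstrates correctness of the machinery and regime, not exact
  full-scale numbers.
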