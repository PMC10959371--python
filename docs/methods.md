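# Methods

This note records the models, conventions and numerical choices behind the
package, and what its synthetic data can and cannot establish.

## Morphology representation

A reconstruction is a rooted tree of SWC samples; each inter-sample edge is
a truncated cone, so lateral areas and volumes are exactly additive under
any re-partition (the basis of the discretization invariants).  Coincident
samples carry no membrane.  Sections run between branch points; a
first-order section leaves the soma and each daughter is one order higher.
Path distance is measured along the tree from the first non-somatic sample
of each primary dendrite; the soma-to-first-sample edge is not part of the
dendritic cable.  The soma is an equivalent cylinder of the somatic
surface (a single soma sample reads as a sphere); an EM-measured somatic
surface can override it through `metadata["soma_surface_um2"]`.

Sholl analysis uses Euclidean distance from the soma centroid (concentric
spheres, 50 µm default shell width); edge lengths are clipped analytically
against the shell boundaries, and per-shell areas and volumes are
apportioned by in-shell length fraction.

Shrinkage correction applies the diamond-knife decompression factor (cf3)
to exactly one axis, then one isotropic factor (cf1·cf2)^(1/3) so that
volumes scale by cf1·cf2; radii take only the isotropic step.

## Discretization

The d-lambda rule: each section receives enough compartments that every
compartment is shorter than d_lambda (default 0.1) times the local space
constant, computed per section from its equal-surface diameter.  The AC
constant at 100 Hz is the default (λ_f = 10⁵·√(d/(4πf·Ra·cm)) µm in mixed
units); a DC option (λ = 10²·√(d·Rm/4Ra)) exists because the
state-specific choice is ultimately a modelling convention.  Degenerate
zero-length sections (a branch at the first sample) alias to the parent's
attachment compartment.

## Electrical model

Units: mV, ms, nA, µS, nF internally; parameters are specified in the
field's customary S/cm², µF/cm², Ω·cm.  The membrane carries a leak
(g_pas, e_pas), optional tonic excitatory/inhibitory fields, the
hyperpolarization-activated current Ih, event-driven synapses and generic
voltage-gated channels; axial coupling uses series half-cylinder
resistances with resistivity Ra (default 100 Ω·cm for passive models,
300 Ω·cm conventional for active ones).

Integration is first-order implicit (backward Euler, default dt 0.025 ms)
with an O(n) symmetric Hines elimination over the tree, unconditionally
stable.  Gates relax exponentially toward their steady state using the
voltage at the start of the step; the voltage equation, linear for frozen
gates, is then solved implicitly.  The inner loop is a numba kernel.
Validation is by closed forms: single-compartment RC step (<0.1%),
sealed-end cable cosh profile (<1%), DC nodal current balance (<1e-9 of
injected current), and input-resistance convergence under grid refinement
(<0.5% on doubling).

**Ih.**  Two activation components share one Boltzmann curve (defaults
V½ = −82 mV, slope 9 mV) and differ in time constant (40 ms fast, 300 ms
slow); fastRatio_H weights them, and fastRatio_H = 1 provably inactivates
the slow gate.  The kinetic constants are documented placeholders in the
range reported for hippocampal interneuron Ih — the time constants are
voltage-independent here, a deliberate simplification — and are meant to
be replaced by measured values through configuration for quantitative
work.

**Synapses.**  Difference-of-exponentials conductances normalized to peak
at gmax; analytic per-step state decay makes event handling exact up to
the voltage discretization.  Defaults (excitatory 0.3/3 ms, 1 nS, 0 mV;
inhibitory 0.5/8 ms, 1 nS, −75 mV) are likewise placeholders — the
measured unitary parameters these cells call for are not printed in the
summary statistics this package reproduces.  Inhibitory synapses onto HS
cells are 15% stronger (their synaptic areas are ~15% larger); the factor
is a first-class configuration field.

**High-conductance state.**  Background bombardment enters as ohmic tonic
fields with their own reversals (no added capacitance), at conductance per
area = synapse density × presynaptic rate × peak conductance × decay tau,
with default rates 3 Hz (excitatory) and 30 Hz (inhibitory).  Local
equilibrium potentials are conductance-weighted means of the reversal
potentials of leak and tonic currents; Ih is excluded by default because
it is voltage dependent (an option evaluates it at its steady state).

**Mitochondria.**  Mitochondria reduce the cross-section available to
axial current; the correction multiplies Ra by 1/(1 − mitochondrial volume
fraction), applied uniformly per cell type (~9.3% OLM, ~12.3% HS).  Its
effect on somatic PSPs is small and bounded, matching the finding that it
does not change model behaviour qualitatively.

**Active channels.**  A generic plug-in: up to two Boltzmann gates per
channel with power, sigmoid steady state and bell-shaped (or constant)
time constant.  The bundled fast-Na/delayed-rectifier pair produces
repetitive firing with a monotone f-I curve and is a demonstration of the
framework, not a fit to measured interneuron kinetics; quantitative active
modelling should supply its own channel set.

## Synapse-density model

Density (synapses per µm² of membrane) is linear in somatic distance and
segment diameter, fitted by unweighted OLS pooled across cells within a
cell type, with adjusted-R² ranking for alternative predictor sets.  The
"diameter" of a measured segment defaults to its equal-surface equivalent
diameter (the density is an area-referenced quantity); equal-volume and
mean-perimeter variants are available.  Predicted densities are clipped at
zero.  Expected counts stay real-valued; integerization happens only in
the stochastic placement sampler, which draws compartments with
probability proportional to expected count (restricted to a distance range
when requested) with replacement, reproducibly under a seed.  Distance
distributions use 50 µm bins and count-weighted Fisher–Pearson skewness;
a degenerate (≤2 occupied bins) distribution reports skewness 0 and is
flagged.

## Protocols and features

Spike detection is an upward crossing of −20 mV with a ≥5 mV/ms slope
guard and 1 ms refractory period.  Standardized steps: rheobase (smallest
step with ≥1 spike), standard negative (closest to −100 pA, ties toward
smaller magnitude), steady state (smallest step with ≥8 spikes), maximal
activity (most spikes, ties toward the smaller amplitude).  Sag amplitude
is steady-state minus minimum voltage; the sag ratio divides by the
base-to-minimum deflection; the sag time constant is a log-linear fit of
the recovery.  Spike-dependent features are undefined (None), never zero,
without spikes.  The feature registry covers the subset used for fitting
and validation and is extensible; it does not attempt an exhaustive
re-implementation of a full feature-extraction library.

Theta drive uses inhomogeneous Poisson trains (thinning) whose rate swings
sinusoidally (default 1–21 Hz at 7 Hz); phase 0 is the rate minimum — a
stated convention, since the reference phase is otherwise arbitrary.  The
mean vector length R = |Σe^{iθ}|/n and the Rayleigh large-sample
approximation test uniformity.  When a model fires no spikes, R is
undefined and flagged; the standard remedy is to raise the activated
fraction (5% → 15%).

## Evolutionary fitting

The feature error is Σ|model − mean|/SD with an SD floor of 10⁻³·|mean|
(and 10⁻⁹ absolute); a missing feature contributes a fixed finite penalty
(250) so non-spiking or diverging candidates are strongly disfavoured
without infinities.  The optimizer is a classical (µ+λ) evolutionary
strategy, µ = λ/2, with per-parameter self-adaptive log-normal step sizes,
box constraints (log-scaled for conductances), stable sorting, and seeded
bitwise reproducibility; convention-default population 128 × 100
generations, scaled down where the problem is small.  Multi-start
restarts use consecutive seeds; best-of-runs is kept.

## Synthetic data: what it emulates, and what it does not

The generators target the published summary statistics: excitatory/
inhibitory surface-density medians (0.522/0.075 µm⁻² OLM-like,
0.763/0.135 HS-like), mitochondrial fractions (9.3% vs 12.3%), log-normal
synapse sizes whose log-median drifts upward with distance for OLM-like
and downward for HS-like cells, spine-targeting fractions rising distally
with smaller spine synapses, diameter taper with strong multiplicative
log-normal variability (thickness is highly variable at any distance),
total dendritic length and first-order counts in the reported ranges, and
the Euclidean-extent difference (HS-like arbors reach beyond 500 µm, OLM-
like do not, enforced by a nearly straight principal dendrite for HS).
Densities embed a planted linear model whose intercept is set so the
median lands on target; counts are Poisson by default, with Gaussian-
density and exact-count modes for calibration oracles.  Reference feature
tables jitter a known model's features with the mean constrained within
1.5 SD, so the generating model passes the 2-SD criterion by construction.

What passing tests on these data do **not** show: recovery of the real
biological correlation structure beyond the second-order statistics
targeted; realistic axonal arbors or postsynaptic target statistics;
measured synaptic or channel kinetics.  In particular, the in vitro
feature values and the published model-validation counts (79/81 features
within 2 SD, etc.) require the recordings and fitted models and are
covered here only by self-consistency analogues.

One consequence is quantitative: with the placeholder synaptic kinetics,
the high-conductance state attenuates proximal somatic PSPs 3–8× (and
≥10× only beyond ~75 µm), because the silent-state PSP of a proximal
synapse is capacitively limited, bounding the silent/HCS ratio near the
soma by roughly τ_syn/τ_eff.  A ten-fold proximal reduction — and a tonic
conductance several orders of magnitude above leak — requires the measured
synaptic parameters (larger gmax·τ products) that the summary statistics
do not contain.  The acceptance script reports the ratios as measured.

## Problem sizes

Tests and the acceptance script run the study's statistics at the
published sample sizes (47/35 segments, 4+4 cells) but scale the
simulation-heavy stages to compact configurations — a few-hundred-
compartment synthetic cells, a 21-compartment cable for fitting, ES
population 16 × 12 generations × 20 seeds — chosen so the full pipeline
(morphology → densities → cable → protocols → fit) is exercised end to end
with comfortable numerical margins.
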