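# Methods

This note documents the models, algorithms and numerical choices behind
`phenosig`, what the synthetic data generators emulate, and the limits of
what the package's tests demonstrate.

## Specific growth rate

Optical density is sampled on a uniform grid (10-minute intervals by
default).  The specific growth rate at interior points is the discrete
per-capita rate

    mu_i = (OD_{i+1} - OD_{i-1}) / (2 Δt OD_i),

the central-difference estimate of (1/OD) dOD/dt; the endpoints are
dropped.  For exponential growth OD = c·exp(rt) this estimator equals
sinh(r Δt)/Δt, so its truncation error is r³Δt²/6 + O(Δt⁴).  The logarithmic
variant (central differences of ln OD, exact for exponentials) is available
via `log_od=True`; the OD-based form is the default because it is the direct
discrete reading of "specific growth rate".  Wells containing non-positive
optical densities are rejected rather than clipped, unless a permissive
flag masks them as NaN.

## Wavelet denoising

`denoise_curve` applies multilevel discrete db4 wavelet shrinkage: all
detail coefficients are soft-thresholded at the universal threshold
σ·sqrt(2 ln N), with one global σ estimated from the finest-level details
as MAD/0.6745.  Decomposition depth defaults to floor(log2 N) − 2 levels
and boundaries use symmetric extension; both are configurable.  Denoising
is offered for display and preprocessing; the classification pipeline
operates on growth rates from raw optical densities, since the wavelet
transform itself isolates the informative periods.

## The continuous-style db4 scaleogram

Signatures are maps of absolute wavelet-coefficient amplitudes over a
(period, time) grid.  Daubechies-4 has no closed-form mother function, so
ψ is materialized by the cascade algorithm at refinement level 10 and
resampled at each scale; the coefficient row for period p is the
convolution of the signal with ψ(t/a)/a at scale a = p·f_c/Δt, where
f_c ≈ 0.714 is the wavelet's spectral center frequency.  Choices that
matter:

* **L1 normalization** (kernel divided by a, not sqrt(a)).  With L2
  normalization the scaleogram argmax for a pure sinusoid lands 9–14%
  above the true period — more than one step of the default grid — because
  the sqrt(a) amplitude factor tilts the response toward long periods.
  With L1 the argmax is within one grid step across the tested range.
* **Period grid**: 64 log-spaced periods from 4Δt to the record duration.
* **Boundaries**: zero padding; cells whose kernel overlaps the record
  edge are retained (full-width maps) but flagged in a boundary mask.
* A Morlet dialect (`wavelet="morl"`) is available as a cross-check.

Feature reductions: `signature_vector` takes the coefficient row at one
period (snapping to the nearest grid point with a logged warning);
`expression_features` returns the time and period at which the summed
coefficient mass C_total peaks, with ties broken toward the earlier time
and smaller period, and a degeneracy flag for all-zero profiles.

## Classification and period selection

Clustering is agglomerative with average linkage and the Euclidean metric
(SciPy's implementation; deterministic given the input).  Cluster quality
is the Davies–Bouldin index, DB = (1/K) Σ_i max_{j≠i} (S_i+S_j)/M_ij with
S_i the mean member–centroid distance and M_ij the centroid distance;
coincident centroids score +inf.  `choose_period` scores the signature
rows at every period against the known groups and picks the minimum (ties
break toward the smaller period; an exclusion mask can remove period
ranges known to be uninformative).  Misclassification counts are
permutation-minimal, computed by optimal assignment on the confusion
matrix, so they do not depend on arbitrary cluster numbering.  The
leave-one-out analysis re-clusters after dropping each sample in turn and
reports the count distribution.  Dendrograms export to Newick with the
ultrametric convention (children of a node merged at height h sit at depth
h/2), so cophenetic distances are preserved.

## Identifiability of random linear flux models

Models have three cellular components P, Q, R connected by six distinct
mass-action flux edges (X→Y moves material, so the state matrix A is
columnwise conservative) with rates Uniform(0.1, 1).  The input into P is
either a constant flux of known magnitude or a cell-coupled nutrient state
N consumed into P at rate k0 — in the latter case N is part of the model
and k0 one of its unknown parameters.  Local identifiability is scored
from H, the Jacobian of the transfer functions g(s) = C(sI−A)⁻¹B with
respect to the parameters (analytic, via the resolvent identity
∂g/∂k = −C M⁻¹ (∂M/∂k) M⁻¹ B), evaluated on 32 log-spaced frequencies in
[1e−2, 1e2] rad/h with real and imaginary parts stacked.  A parameter is
identifiable when the largest pairwise Pearson correlation of its
sensitivity column with any other stays below 0.99 in absolute value and
the column is not numerically zero.

Numerical choices and caveats:

* **Relative sensitivities.**  Mass conservation gives A a zero eigenvalue,
  so raw sensitivities diverge as s→0 and the lowest grid frequencies
  dominate every correlation (all |R| → 1).  Each frequency block of H is
  therefore normalized by ‖g(iω)‖ by default; `normalize=False` exposes
  the raw behavior.
* **Observed outputs** default to all of P, Q, R; the alternative N, Q, R
  (with N informative only in the cell-coupled mode) is a configuration
  option, as are thresholds 0.95/0.999 for sensitivity analysis.
* **What the comparison shows.**  With full observation, the six shared
  edge rates are identifiable in both input modes and the cell-coupled
  advantage is exactly the consumption rate k0, which the fluctuating
  nutrient renders identifiable while a constant input has no analogous
  learnable parameter.  Under partial observation the counts vary model to
  model and the comparison depends on the threshold.
* **Non-monotonicity.**  The thresholded-correlation count is not monotone
  in the observed set: adding an output channel can push a pairwise
  correlation above threshold (measured in roughly 20% of random models).
  Fisher information itself is monotone — HᵀH of a nested observation set
  is dominated in the positive-semidefinite order — and that is the
  property the test suite asserts.

## Network inference from nonlinear models

Random models draw six distinct links over all four nodes from mass-action
fluxes, Michaelis–Menten activation/repression (rates Uniform(0.1, 1),
half-saturations Uniform(0.5, 2)) and multiplicative two-species reactions
(the pair feeds the third node and is consumed).  In the constant mode N is
clamped at 1 (reactions it feeds become constant fluxes); in the
cell-coupled mode N is consumed into P at a random rate.  Trajectories
(all initial conditions 1, LSODA, 10 h at Δt = 0.1 h) receive 20%
multiplicative Gaussian noise (floored at zero; an additive option is not
provided because the multiplicative reading matches plate-reader error
scaling), derivatives are estimated by central differences, and a linear
model dy/dt = Ay is fit by ordinary least squares without intercept.
Influences are read from |A_ij| > 0.005 (absolute value, so repression is
detectable) and scored as n/m, the fraction of true source→target
influences recovered; a multiplicative link contributes both its sources.
The constant mode regresses only P, Q, R — a clamped regressor carries no
dynamical information — so influences out of N are undetectable there,
which is precisely the information the cell-coupled signal adds.  Note the
n/m metric has no precision penalty: noise that inflates weak entries can
only add detected true edges, so noise does not strictly degrade n/m in
the near-ceiling cell-coupled regime (it clearly degrades the constant
mode).  False-positive counts are reported alongside in the per-model
edge sets for users who need them.

## The growth model

The reference batch-growth ODE couples nutrient N, two molecular-species
groups P and Q, and a growth-rate modulator G, with mu(t) = G(t):

    dN/dt = -k1 N G/(k9 + G)
    dP/dt =  k2 G gate(N) - k4 P
    dQ/dt =  k5 G - k6 Q
    dG/dt =  k7 P gate(N) k10/(k10 + Q) - k8 G,     gate(N) = N^8/(k3^8 + N^8)

G→P→G is a positive feedback loop with gain k2k7/(k4k8) whose take-off
produces the lag-then-surge shape of real growth rates; Q integrates
recent growth and represses G production, saturating the loop at a plateau
mu* ≈ (k6 k10/k5)(k2k7/(k4k8) − 1); the sharp (Hill-8) nutrient gate makes
stationary entry a nutrient clock, t* ≈ ln(N0/k3)/k1, after which mu decays
at rate k8.  Nutrient uptake saturates in G at a very small k9, so the
depletion clock is insensitive to the mu scale.  This architecture is what
produces the two perturbation phenotypes:

* **Plasmid load** (k4 → 1.2): the loop gain and hence the plateau drop,
  but the depletion clock (k1, k3) and the decay rate (k8) are untouched,
  so the maximum growth rate falls while stationary entry is preserved.
* **Low temperature** (all k_i × 0.7): the clock runs slower (entry
  delayed) and the plateau prefactor k6k10/k5 scales by 0.7 (peak lowered).
  Because k3, k9, k10 enter nonlinearly, the 30% reduction is not a pure
  time rescaling.

Default constants (k1..k10 = 0.42, 1.55, 0.06, 0.45, 0.85, 0.52, 3.0,
1.25, 0.001, 0.16; initial state N=1, P=Q=0, G=0.05; od0=0.05) were chosen
by randomized search over these qualitative constraints plus realism bounds
(peak mu ≈ 0.57/h, stationary entry ≈ 9.3 h, final OD ≈ 0.78) and are
config-overridable; nothing downstream assumes these particular values.
Optical density is od0·exp(∫mu dt), integrated as an extra ODE state so
the quadrature is solver-accurate.  "Summation of differences" in
`summary_metrics` is the total variation of the growth-rate series (an
OD-based variant is exposed as an option).  Stationary entry is defined as
the first time after the peak at which mu falls below 5% of its maximum.

## Swarm search

The inner optimizer is a standard global-best particle swarm (inertia
0.72, cognitive and social coefficients 1.49 — common constriction-type
values — positions clipped to bounds, log-uniform initialization in
[1e−3, 10] to span kinetic scales, non-finite fitness treated as +inf).
Fitness is the mean absolute growth-rate error per time point (1/hour),
averaged over strains when several series are fitted (one shared
structure, strain-specific parameters).  Candidate fitness evaluation
integrates whole particle batches with a vectorized fixed-step RK4
(states clipped to [0, 1e6]; divergent candidates are penalized, not
fatal), which agrees with the adaptive reference solver to ~1e−4 in mu.

Because particle batches are evaluated vectorized, width is cheap and
iterations are the serial cost; wide-and-short swarms (the default inner
configuration is 150 particles × 60 iterations with 2 restarts) are far
more reliable at escaping deceptive broad basins of these fitting
landscapes than the conventional narrow-and-long settings.  On the
reference growth ODE the self-fit converges to a mean absolute μ error of
roughly 1–4 × 10⁻³ 1/h; the residual floor reflects parameter sloppiness
(many kinetic combinations produce nearly identical growth-rate curves)
and the slow fine-scale convergence of global-best PSO rather than model
mismatch.

The outer structure search assembles models from a library of 12 equation
components — the rate-law templates c, c·X, c·X², c·X·Y, c·X/(K+X),
c·K/(K+X), each usable as production or consumption — over a fixed
scaffold with variable slots.  After each round the non-best structures
adopt each slot of the current best with probability 0.5 and otherwise
resample; the best structure is kept unchanged.  Structures whose fitness
ties within 1e−4 are ranked by term count (parsimony).  Exhaustive
enumeration over small spaces is provided as the independent optimum for
validation.

## Synthetic data

No growth-curve or promoter-activity dataset accompanies the analyses, so
pipelines are exercised on generators that are pure functions of
(spec, seed):

* **Strain panels**: per strain, the reference kinetic constants are
  jittered log-normally (default 10%); per condition, the strain model is
  perturbed (plasmid, low temperature, or a halved initial nutrient), with
  a per-strain log-normal response factor (default 15%) because real
  strains do not respond identically to the same perturbation — without
  such strain-by-condition interaction, concatenating conditions could
  only dilute, never sharpen, strain separation; per replicate,
  multiplicative measurement noise (default 2% CV, plate-reader-like) on
  the optical density at 10-minute sampling over 24 h.
* **Expression datasets**: groups of promoters share a latent
  condition-specific burst (a Gaussian-windowed sinusoid whose period and
  timing are group- and condition-specific); each promoter reads it
  through its own gain (Uniform(0.5, 1.5), constant across conditions,
  i.e. strong versus weak regulation) plus independent Gaussian noise.

What passing tests show — and do not.  The generators reproduce the
*statistical structure* the analyses assume: smooth strain-specific
dynamics under multiplicative noise, strain-specific condition responses,
shared latent regulator signals.  They do not emulate pipetting artifacts,
blank drift, evaporation, well-position effects, diauxic shifts, or
promoter crosstalk; success on these panels demonstrates the machinery and
its discriminative logic, not field performance on any particular
instrument's data.

## Problem sizes

Simulation studies run at 100 random models per input mode; classification
panels are 4 strains × 3 replicates (144-point curves); the swarm self-fit
uses 50 particles × 300 iterations and the toy structure space 3
candidate structures at 30 × 120 × 2 restarts.  These sizes give stable
directions and tight reproducibility while keeping a full run of the test
suite and the acceptance script in the minutes range on one CPU; all are
parameters, not constants.

## Known limitations

* The growth ODE is a phenomenological stand-in with one parameterization
  family; its constants are defaults, not fitted to any published strain.
* The correlation-threshold identifiability score is threshold-dependent
  and not monotone in the observed set (see above); conclusions should be
  checked at several thresholds, for which the report machinery has
  built-in options.
* The linear regression estimator is deliberately simple (no
  regularization, no intercept); it is the method under study, not a
  recommendation for network inference at scale.
* Leave-one-out is the stability analysis implemented (`loo_bootstrap`);
  resampling with replacement is not.
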