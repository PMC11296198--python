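# Methods

## Problem and model

`pronyfit` converts frequency-domain DMA measurements of a hyper-viscoelastic
material into a time-domain material description: a normalized Prony series
(generalized Maxwell model) layered on a fixed Ogden hyperelastic law.

The Prony spectrum is the vector (g_1..g_N, tau_1..tau_N, g_inf) with

* `g_k` — dimensionless relaxation strengths, 0 < g_k < 1, sum g_k <= 1;
* `tau_k` — relaxation times in seconds, sorted ascending;
* `g_inf = 1 - sum g_k` — the equilibrium fraction (enforced identity).

Because the spectrum is normalized (the Abaqus `*VISCOELASTIC, TIME=PRONY`
convention), measured moduli in MPa must be divided by an
instantaneous-modulus scale `E_inst` before they can be compared with the
dimensionless storage/loss forms.  The default is `E_inst = 3 * sum(mu_i)`
(MPa), the incompressible small-strain Young's modulus of the Ogden set —
which is also the exact small-strain slope of the package's own uniaxial
stress function, so the frequency- and time-domain routes share one scale.
A different scale (e.g. a compressible 2(1+nu)G conversion with the
configured Poisson ratio) can be set through `GlobalConfig.e_inst_mpa`.

Angular frequency is used throughout the Prony forms; dataset frequencies in
Hz are converted via w = 2 pi f.

## DMA reduction

Raw load/displacement records are steady-state sinusoids, so amplitude and
phase are read off the single drive-frequency DFT bin with no window; records
are truncated to the largest integer number of drive periods first.  Records
must cover >= 4 periods at >= 16 samples/period, and the drive frequency must
sit at least 2 bins below Nyquist.  The shape factor uses the area/thickness
convention SF = pi (d/2)^2 / h, chosen so that stiffness (N/mm) divided by SF
(mm) is a pressure (MPa); it is exposed for override since other geometric
conventions exist.  Raw-waveform processing is optional — the pipeline also
consumes pre-computed (f, E′, E″) tables directly.

## Forward model (time domain)

The finite-element stage of the original workflow is replaced by the exact
homogeneous solution of the same boundary-value problem: a uniform bar under
uniform uniaxial stress has a spatially constant state, so a single material
point suffices and mesh-refinement options become time-step refinement
options (`GlobalConfig.dt_preset`: coarse/medium/fine = dt x 1.0/0.5/0.25).

Kinematics are incompressible uniaxial compression (lateral stretches
lambda^(-1/2), pressure eliminated by the traction-free lateral condition),
giving the Ogden Cauchy stress

    sigma0(lam) = | sum_i (2 mu_i / alpha_i)(lam^alpha_i - lam^(-alpha_i/2)) |.

The configured Poisson ratio (0.45) is retained for unit conversions only;
the O(1 - 2 nu) error of the incompressible reduction is accepted in place of
guessing an unspecified volumetric law.

Viscoelasticity acts through a quasi-linear hereditary integral on sigma0
with the normalized Prony relaxation function, discretized with the standard
exponential recursive update (exact for piecewise-linear sigma0 histories):

    h_k[n+1] = e_k h_k[n] + g_k (1 - e_k)/(dt/tau_k) (sigma0[n+1] - sigma0[n])
    sigma[n+1] = g_inf sigma0[n+1] + sum_k h_k[n+1],   e_k = exp(-dt/tau_k).

Loading is stress-controlled (the experiments are load-led), so each step
solves sigma(lambda) = applied stress by a safeguarded Newton iteration with
a bracketed bisection fallback (sigma0 is strictly monotone on
lambda in [0.05, 2]); an applied stress outside the material capacity on that
interval signals a non-physical candidate, which the fitness layer scores
worst-in-generation rather than aborting.  An initial stress jump is handled
as the exact glassy step response (h_k = g_k sigma0).

The default step obeys dt <= min(tau_k)/5, dt <= 1/(50 f), and additionally
>= 200 samples per sine cycle so that pointwise branch statistics approximate
their continuous averages (with ~50 samples/cycle, a single sample entering
or leaving a fit domain shifts a branch-mean error by ~0.2%, enough to
scramble fine rankings).

The loading program is the study protocol: a 1 s ramp from 0 to 1.225 MPa
followed by a 1 s sinusoid a(t) = 1.225 + 0.493 cos(2 pi f (t - t0)) at 1 Hz
(0.732–1.718 MPa).  As printed, the sinusoid starts at its maximum, i.e. a
stress jump at the stage boundary; this is implemented literally, with
`LoadingProfile.phase_continuous` available to start the sinusoid at the
ramp end value instead.  The hysteresis loop is taken from the final
simulated cycle (the most nearly steady-state one), displacement-normalized
so the loop minimum is 0, and split at the turning points of the applied
stress: rising-stress samples form the loading (upper) branch, falling-stress
the unloading (lower) branch.

## Validation curves and model error

Six replicate load-controlled ramp tests are averaged pointwise on a common
100-point stress grid over their overlapping stress range, then fitted to
y = a1 log(b1 x); the loop's loading branch is fitted to the same log form
and the unloading branch to y = a2 exp(b2 x) (y stress in MPa, x displacement
in mm).  The log fit is linear least squares in (a, a log b); the exponential
fit is nonlinear least squares started from its log-linearization.  Curves
are frozen at run start and used unaltered for every generation.

These two-parameter forms cannot represent an arbitrary response everywhere:
the log diverges at x -> 0 (and the normalized loop minimum is exactly
x = 0), and over the protocol's fixed stress ratio the exponential has an
irreducible convexity that near-linear small-strain responses lack.  Each
fit is therefore restricted to a data-driven validity window: the widest
fraction-of-range displacement window in which the fitted form's maximum
relative residual stays within 1% (falling back to the minimum-residual
window, never narrower than 40% of the range).  The window becomes the
curve's `domain`, and model errors are evaluated only inside it.  On real
cartilage-like (toe-region) data the forms fit well and the windows stay
wide; on the synthetic fixtures they exclude the seating region of the ramp
and the reversal transitions of the loop, leaving a lack-of-fit floor of
roughly 0.3–1% per component that bounds how small a model error any
candidate — including the generating truth — can achieve.

Model error against one curve is the averaged percentage difference in the
stress direction at the model's displacements,
mean |sigma_model - curve(d_model)| / |curve(d_model)| x 100 — stress-wise
because loading is stress-controlled, so displacement is the model's free
output.  The mean model error is the arithmetic mean of the ramp, loading
and unloading components.

## Equation objective

For each tuple i of a split, with measured moduli normalized by E_inst,

    r_i = (u'(w_i)/u_i' - 1)^2 + (u''(w_i)/u_i'' - 1)^2

and the objective is the mean of r_i over the split (mean rather than raw
sum so values are comparable across split sizes).

## Interior-point seeding

The constrained minimization of the equation objective on the training split
is solved by a log-barrier method: free vector x = [g, log tau], slacks g_k,
1-g_k, 1-sum g, and the ordering gaps tau_{k+1}-tau_k; barrier weight
mu_0 = 1 reduced by x0.2 per outer iteration to a floor of 1e-8.  Inner
minimizations use a derivative-free Nelder-Mead simplex (<= 300 iterations,
ftol 1e-10) — the downstream contract is descent (never worse than the
start) and strict interiority, not a particular inner solver.  `n_restarts`
independent random viable starts (g = flat simplex draw scaled by U(0,1),
tau log-uniform on [1e-4, 1e2] s, sorted) are solved, deduplicated at 1e-9
and sorted by objective; this set seeds generation zero.  Seeding is
reproducible through an explicit RNG seed; the wall clock is used only when
no seed is given.

## Genetic engine

Chromosome: [g_inf, g_1..g_N, tau_1..tau_N], length 2N+1.  Each generation:
the `elite_count` (default 3) best are copied unchanged; the remainder is
three equal shares of (i) crossover children — 50:50 single-point (cut
uniform on {1..2N+1}; the boundary cut copies the parents) and K-point
(k distinct interior cuts, alternating segments), parents drawn with
probability proportional to rank; (ii) Gaussian mutants of rank-selected
members — additive noise on g/g_inf, multiplicative (lognormal) on tau so
the spread scales with the gene's magnitude; (iii) fresh random individuals.
Every child passes a repair step (strengths clipped into (0,1) and rescaled
onto the simplex, g_inf reset to 1 - sum g, tau clipped positive and
sorted), which keeps the operators closed over the constraint set; a bounded
retry (50) with parent-copy fallback guarantees generation construction
terminates even if repair could fail.

Fitness is evaluated two-track (all members screened by equation error, the
best `NumInGen` simulated); survivor ranking uses mean model error when
available, else equation error.  `NumInGen` has a protocol floor of 100
enforced at the shell (`--allow-small-gen` bypasses it for small studies);
the engine itself only requires it to fit in the population.  The population
size (default 999 = 3 x 333, divisible by 3 so the operator shares are
exact) is an internal parameter.  Termination: `num_iteration` generations,
best mean error <= `min_error`, or no change of the best mean error within
`no_change_tol` over `no_change_window` generations.

Every generation is appended to a JSON-lines backup (population, fitness
reports, cumulative best, RNG state, timestamp) before the loop proceeds;
runs are resumable from the last record's RNG state and bit-reproducible for
a fixed seed (timestamps aside).  The cumulative best mean error is
non-increasing by construction.

## Synthetic data generator

The generator emulates the shape of the cartilage study's dataset from known
ground-truth parameters: 168 (f, E′, E″) tuples on a log-spaced 1–90 Hz sweep
(~3 replicates per frequency), split 128/40 into training/validation
uniformly at random per seed; six replicate ramp series and one steady-state
hysteresis loop obtained by forward-simulating the truth through the study
protocol.  Modulus noise is multiplicative lognormal with a configurable
coefficient of variation (moduli are positive and vary over orders of
magnitude, which additive noise would violate); ramp displacement noise is
additive Gaussian with sigma = 0.5% of the peak ramp displacement by default.
The default fixture is N=3, g = (0.1, 0.15, 0.2), tau = (0.005, 0.05, 0.5) s
with the packaged cartilage Ogden set (mu = 26.133, 12.922, 13.227 MPa,
alpha = 2.719, 3.996, 1.504), placing the relaxation transitions inside the
1–90 Hz window.

What the generator does **not** emulate: inter-donor variability and damage
grades, poroelastic (fluid-flow) creep, the toe-region nonlinearity of real
cartilage at large strain, or measurement noise correlations.  Passing tests
on this data therefore demonstrate the correctness of the machinery
(constraint handling, convergence, frequency/time consistency, recovery of a
realizable truth), not that real tissue satisfies the model.  In particular
the synthetic strains are small (~1.5% at 1.225 MPa for the packaged Ogden
set), so the validation series are near-linear and the log/exp validation
forms carry the lack-of-fit floor discussed above — against real toe-region
data the same forms fit much better.

## Numerical choices and problem sizes

* Stress inversion tolerance 1e-10 relative; stretch search interval
  [0.05, 2].
* Barrier solutions clamp tau to [1e-12, 1e12] s against log-parametrization
  under/overflow; GA repair clips tau to [1e-8, 1e6] s.
* Dedup tolerance for seed populations: 1e-9 on the parameter vector.
* The dynamic-moduli readout (`measure_dynamic_moduli`) uses a relative
  stress amplitude of 1e-4 about a 1e-3 mean (of E_inst), >= 400 samples per
  cycle, and integrates past the stress-controlled transient, which decays
  with the creep (retardation) time ~ tau/g_inf rather than the relaxation
  time.
* Test and acceptance runs use deliberately small search sizes (populations
  33–99, 5–20 generations, 2–16 interior-point restarts) — large enough for
  the convergence, integrity and recovery properties they check while
  keeping the suite quick; production-scale defaults (population 999,
  NumInGen >= 100, 100 restarts) remain the config defaults.

## Known limitations

* Single-material-point forward model: valid exactly for the homogeneous
  unconfined-compression problem; it cannot represent friction, edge
  effects or heterogeneous fields.
* Incompressibility in the stress closed form (see above).
* The log/exp validation forms are empirical; their validity windows shrink
  on data they describe poorly, reducing validation coverage there.
* Identifiability: distinct Prony spectra can fit one dataset comparably
  well (the motivation for the two-track fitness); for orders N > 1 the
  recovered spectrum should be read as an equivalent spectrum, not a unique
  one.
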