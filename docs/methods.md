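# Methods

This note records the models, numerical choices, and known limits of
`pmfbind`, in the order the pipeline runs.

## Free-energy curves and biases

Energies are carried internally in kT at a single configured temperature;
conversion to kcal/mol happens only at the I/O boundary, where the unit and
bias dialect (`kT`/`kcal/mol`, `half-k`/`full-k`) must be declared
explicitly.  The internal bias convention is E = ½k(z−z0)² with k in
kT/Å²; a `full-k` file (E = kΔ²) is converted by doubling k on load, and
kcal/mol springs divide by k_B T with k_B = 0.0019872041 kcal/(mol·K).
Evaluating a potential outside its declared domain raises an error rather
than clamping — a clamped tail would silently corrupt Boltzmann weights.

The parametric curve families are: a flat baseline, a square well (for
closed-form Kd work only; it is discontinuous and has no force), a
harmonic well, a smooth "double well" built from two Gaussian wells plus
an optional Gaussian barrier midway, and tabulated curves with linear
interpolation.  The Gaussian-mixture double well was chosen over a quartic
because a binding PMF must decay to zero in bulk, which a quartic cannot
do; its parameters (depths in kT, centres in Å, common Gaussian width,
barrier height) map directly onto the features one reads off a binding
profile.  Tabulated forces use central differences on the grid, one-sided
at the ends, so no smoothness beyond the data is assumed.

The flat-bottom restraint is zero inside a bound b and harmonic (stiffness
k_fb, default 10 kT/Å² — a configurable placeholder) beyond it; with a
schedule, b shrinks linearly from b_start to b_end over t_ramp and stays
constant after.  Energy and first derivative are continuous at d = b.

## Synthetic umbrella sampling

`simulate_window` integrates the overdamped Langevin equation with
Euler–Maruyama:

    z ← z + (D·dt)·F(z)/kT + sqrt(2·D·dt)·ξ,  ξ ~ N(0,1)

The defaults emulate the statistics of biased MD output, not its physics:
D = 0.1 Å²/ps (a typical small-solute diffusivity in water), dt = 0.002 ps
with samples saved every 500 steps (1 ps), temperature 298.15 K.  The
generator reproduces the features that matter to the estimators —
Boltzmann-distributed, serially correlated samples with stiffness-dependent
correlation times τ ≈ kT/(D·k) — and none that it does not: no inertia, no
solvent memory, no orthogonal degrees of freedom, no force-field error.
Passing tests therefore validate the *estimators*, not any claim about a
specific channel–ligand system.

Numerical safeguards: a stability bound dt·D·k_max < 0.1 (k_max = bias
spring plus the truth's maximum curvature, estimated on a dense grid) is
checked before stepping; trajectories reflect at the domain edges
(zero-flux boundaries preserve the stationary distribution); forces are
linearly interpolated from a 4001-point grid inside a JIT-compiled kernel
fed by noise chunks from a numpy Generator, so runs are bitwise
reproducible given the seed.  Window i of a set uses seed + i.  The first
10% of saved samples are flagged as equilibration and excluded from all
downstream analysis (configurable per series); file-loaded data is assumed
to be production.  Adjacent windows whose histograms share < 5% of their
mass trigger a warning, since WHAM cannot bridge disconnected windows.

Euler–Maruyama's stationary distribution carries an O(dt) bias; at the
default settings dt·D·k ≲ 0.01, which is far below the statistical
resolution of every test in the suite.

## WHAM

Self-consistent iteration of the two standard equations (all in kT),
anchored at f_0 = 0, stopping when max_i|Δf_i| ≤ tol (default 1e-7 kT,
max 1e5 sweeps — tight enough that iteration error is negligible against
statistical error).  The sweep runs in linear space on precomputed
exp(−c_ij) weights, with an automatic log-sum-exp fallback if any constant
leaves a safe range.  Histogram bins are half-open [lo, hi) on a regular
grid (default width 0.5 Å; the paper-style recovery study uses 0.25 Å so
that discretization bias ~Δz²·W′²/24 stays an order below the statistical
error).  Bins with zero total count keep a +∞ sentinel and are excluded
from re-zeroing and integration; smoothing them over would bias the Kd
integral.  Two re-zeroing conventions exist: `bulk` (zero at the largest
finite-z bin — required for Kd) and `min`.

Two estimator facts worth knowing: WHAM weights windows by their sample
counts, so feeding the same window twice is *not* a no-op — it is exactly
equivalent to doubling that window's counts (the test suite asserts this
exact identity); and the fixed-point residual is monotone only after a
short transient (the suite checks monotone decay after a 50-iteration
warmup).

## Decorrelation, bootstrap, convergence

The ACF uses the standard biased estimator (denominator n, via
statsmodels); τ_e is the smallest lag with ρ(l) ≤ 1/e, *inclusive* at the
threshold.  The bootstrap resamples decorrelated samples — production data
strided by the largest τ_e across windows — independently within each
window, with replacement, N_i draws per window; 10 pseudo-datasets by
default, each re-solved by WHAM.  Resampling raw correlated points would
understate the variance, hence the stride.  Replicate profiles are
re-anchored at the largest-z bin finite in every replicate before the
pointwise SD (n−1 denominator) is taken; σ_max is the maximum SD over the
commonly finite bins and is the profile's single-number uncertainty.

Profile depth is defined as min_j W_j minus W at the bulk anchor (so a
binding well has negative depth).  The convergence diagnostic recomputes
the depth on the first ⌈φ·N_i⌉ retained samples for each fraction φ and
reports the max pairwise spread (drift); stationary data keeps the drift
within a few σ_max, while an injected coordinate ramp — the positive
control in the tests — blows well past it.

## Kd and uncertainty propagation

The Boltzmann integral I = ∫exp(−W)dz runs by trapezoid over the finite
bins in [z_min, z_max] (defaults: the profile's finite extremes), and

    Kd⁻¹ [1/M] = π R² I [Å³] × 10⁻²⁷ [L/Å³] × N_A

which is algebraically identical to the SI form 1000·π·R²·N_A·∫dz — a unit
test asserts the identity numerically rather than trusting the algebra.
The profile must be bulk-anchored; an empty integration range yields
Kd = +∞ (no binding).  Kd bounds come from shifting the whole profile by
±σ_max, which factors out of the integral as exp(∓σ_max) — a conservative
bound consistent with reporting a single worst-case profile uncertainty,
chosen over pointwise resampling.  Fractional block is the single-site
isotherm C/(C+Kd); Hill fitting and voltage dependence are out of scope.

## Study sizes

The validation studies use 8–12 windows, spring 4 kT/Å², 1–1.5 Å spacing,
5×10³–5×10⁴ samples per window saved every 3 ps (≈2–3 relaxation times of
a biased window, so saved points are near-decorrelated by the 1/e rule),
and 0.25 Å bins.  The bootstrap calibration compares σ_max against the
depth SD over 20 independently re-seeded regenerations at the 5×10³ scale.
Sampler fidelity uses 10⁵ saved points strided far enough (15–50 ps) to
span the slowest mode present, including inter-well hopping in the
double-well fixture.

## Known limitations

1D, non-periodic coordinates only; no binless estimator (MBAR) — the
histogram method matches the cited workflow, and bin width is an explicit
knob; uniform-shift Kd bounds ignore the z-structure of the error; the
Langevin generator shares no failure modes with all-atom MD (force-field
bias, hidden slow coordinates), so real-data error budgets need the
convergence diagnostic, not just the bootstrap.
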