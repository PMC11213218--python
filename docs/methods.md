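# Methods

## Forward models and quadrature

All three nested models act on a shared uniform acquisition grid (default
400 frames, 1.55 s spacing, bolus arrival at frame 39 ≈ 60 s, first 20
frames excluded from analysis so the spin system's approach to saturation
equilibrium never enters the fits). Time is kept in seconds internally;
`Ktrans` and `kep` cross the API boundary in 1/min, the unit the field
reports.

The Patlak integral `∫ C_a` is trapezoidal on the acquisition grid. The
back-flux term `∫ C_a(u) e^{−kep(t−u)} du` uses the analytically exact
recursion for a piecewise-linear interpolation of the AIF between frames:
with `E = e^{−k·dt}` the update is `y_i = E·y_{i−1} + A·c_{i−1} + B·c_i`,
with `A`, `B` the exact segment integrals (formulated with `expm1` so the
small-`k·dt` regime does not lose precision; below `k·dt = 1e−12` the
recursion switches to the trapezoidal limit, which is its exact `k → 0`
limit). The recursion is evaluated as a first-order IIR filter, O(n) and
unconditionally stable for `k ≥ 0`. Validated against a 1 ms-grid
brute-force Riemann oracle at 1e−4 relative tolerance.

## Conventional nested model selection

Model 1 is a closed-form no-intercept regression of the trace on the AIF;
Model 2 a two-column linear fit on `[C_a, ∫C_a]`; Model 3 separable least
squares — linear in `(vp, Ktrans)` at fixed `kep`, with `kep` located by a
60-point log-spaced scan over [1e−3, 5] /min followed by golden-section
refinement of the profiled RSS (interval tolerance 1e−5 /min, ties to the
smallest `kep`). The scan always includes the degenerate `kep = 0`
candidate, which reproduces Model 2 through the identical linear-algebra
path, so `RSS(M3) ≤ RSS(M2)` holds bitwise and the nested-RSS monotonicity
contract can be asserted rather than hoped for.

Selection is by sequential partial F-tests (1 numerator dof), Model 1→2
then — only on rejection — 2→3, at confidence level 0.95 by default. Two
deliberate choices:

- **OLS residuals drive the F-test; reported parameters are projected.**
  Negative `vp`/`Ktrans` are unphysical, so reported estimates are
  clipped-and-refit onto the non-negative orthant (the constrained optimum
  of a 2-parameter fit lies on one of the two single-column boundaries).
  The RSS entering the F statistic, however, is the unconstrained OLS
  residual: projecting first would zero the improvement whenever the null
  pushes the estimate negative (about half the time), halving the test's
  effective size. With OLS residuals the statistic follows its classical
  F(1, n−p) null distribution, and the measured type-I error on 10,000
  null traces is 5% ± 1% at CL = 95%.
- **A rounding floor on RSS improvements.** Improvements below
  `1e−12 × Σy²` are treated as zero. On noiseless data every nested fit is
  exact and all residuals are rounding noise; without the floor the F
  ratio of two rounding-level numbers is arbitrary. At any realistic noise
  level true improvements exceed the floor by ≥6 orders of magnitude.

All three fits are computed and stored for every voxel regardless of the
selected label, because model averaging needs `vp` from every model,
`Ktrans` from Models 2–3 and `kep` from Model 3.

## Self-organizing map

8×8 hexagonal lattice (offset rows, interior nearest-neighbor distance 1),
batch training, Gaussian neighborhood kernel over lattice distance with
σ = current radius. The radius decays linearly from 3 to 1 over the first
100 "ordering" epochs and stays at 1 for the remaining "tuning" epochs (250
maximum) — the classic two-phase schedule these parameter names come from.
Training stops early once the BMU assignment repeats with the radius at
its final value; that is a fixed point of the batch update, so the early
exit returns exactly the weights further epochs would.

Initialization is deterministic "linear" init: prototypes laid out on the
data's top-two principal directions, spanning ±2√λ along each; eigenvalues
at the rounding level of the dominant one are zeroed so rank-1 data yields
prototypes exactly on the data line. Random initialization (uniform in the
per-feature data range, mandatory seed) is available behind
`SOMConfig(init="random")`. Determinism of the default path is what makes
the probability maps reproducible artifact-for-artifact.

Ties in BMU lookup break to the lowest neuron index. Neurons that never
win (interpolating units) are permitted; downstream they borrow the
probabilities of the nearest hit-bearing neuron (lattice distance, ties to
the lowest index), with provenance recorded.

## Probabilities, thresholding and model averaging

Neuron probabilities are the empirical per-label fractions of each
neuron's tagged hits. A voxel's probabilities are exactly its BMU's — no
neighborhood smoothing, since only BMU tagging is part of the described
procedure. Region masks use a strict `P > τ` at τ = 0.5, which makes the
three masks automatically disjoint; a voxel with all probabilities ≤ 0.5
belongs to no region, and the Model-1 mask is applied first to mask out
intact tissue before the Model-2/3 regions are read off.

Degenerate-voxel conventions (the data dictate none): `Ktrans = 0` when
`P2 + P3 = 0` (a certainly non-leaky voxel); `ve` undefined (NaN) when the
Model-3 `kep` falls below 1e−3 /min — no measurable back-flux makes the
ratio meaningless — except that a zero averaged `Ktrans` gives `ve = 0`.

## Synthetic phantoms

Each phantom is a 32×32×3 volume (three slices): background = Model 1,
tumor core (disc, radius 5.5) = Model 2, rim (annulus to radius 9) =
Model 3. Parameters per voxel: `vp ~ U[0.01, 0.04]`,
`Ktrans ~ U[0.05, 0.3] /min`, `kep ~ U[0.5, 2.5] /min` — spanning the
magnitudes typical of normal brain and enhancing glioma tissue. The AIF is
a population curve shared by all voxels: gamma-variate bolus (α = 3, peak
8 s post injection, peak amplitude 2.5 1/s) plus a recirculation tail
(fraction 0.25, 25 s rise, 300 s decay), exactly zero pre-injection; the
functional form and its parameters are this package's choice of a
realistic rodent bolus, not measured values. Noise is i.i.d. Gaussian on
ΔR1 with sd = 5% of the global phantom peak by default ("SNR 20" at the
brightest enhancing voxel) — Gaussian, not Rician, because ΔR1 is a
derived relaxivity change rather than a magnitude signal. Cohorts jitter
the tumor center (±2 voxels) and radii (±1) per animal, with all seeds
derived from one root seed.

Consequences a user should know: because noise scales with the *global*
peak, dim Model-1 voxels see a much lower per-voxel SNR than the tumor —
vp recovery error (~15% median) is accordingly larger than the Patlak
slope's (<1%). And the phantom's regions are geometric discs with sharp
parameter boundaries; a green cross-validation test establishes that the
SOM probability machinery reproduces F-test regions under the assumed
noise model, not that it handles real-tissue heterogeneity, partial
volume, motion, or AIF dispersion.

Profile normalization (the analysis' most consequential unstated detail)
is baseline subtraction (mean of the retained pre-injection frames)
followed by division by the peak absolute value — a pure *shape*
normalization, so the SOM clusters kinetic shape rather than amplitude. A
unit-L2 variant is available (`method="l2"`).

## Cross-validation and statistics

Folds are at animal level only (test folds are contiguous blocks of one
random permutation; training sets are drawn from the remainder to honor
the 0.66 train fraction, reproducing a 44/22 split for 66 animals at
k = 10). The described inner/outer loop collapses to train-on-train /
apply-on-test because the default SOM has no tuned hyperparameters; the
harness accepts a custom `SOMConfig` per run as the hook for a true inner
search. Dice of two empty regions is defined as 1 (both methods agree
there is no region); a fold where a region is empty under both methods is
excluded from that model's average with a logged warning. Confidence
intervals are percentile bootstrap over fold values (10,000 resamples,
seeded); the method is this package's choice. Cohort parameter means: vp
over the whole brain, Ktrans over each method's leaky region, ve over the
Model-3 region where defined, with non-physical ve > 1 excluded for both
methods (a volume fraction cannot exceed 1; near-floor kep estimates
otherwise dominate the mean). MPDs are computed from the fold-averaged
means.

## Known limitations

- The conversion from raw dual-echo gradient-echo signals to ΔR1, T1
  mapping, hematocrit correction and water-exchange effects are out of
  scope; inputs are assumed to already be ΔR1 (∝ concentration).
- One population AIF for all voxels and animals; no delay/dispersion
  modeling.
- The F-test realization of "95% confidence" selection and the golden
  section/grid `kep` search are standard choices, stated here as this
  package's own; alternatives (AIC-family criteria, growing/hierarchical
  map variants) are not implemented.
- Published cohort-scale results from the 66-animal dataset are not
  reproducible here (data unavailable); the package claims formula-level
  agreement and qualitative orderings on synthetic cohorts only.
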