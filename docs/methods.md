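# Methods

This note records the models implemented in `ribomech`, the conventions and
numerical choices behind them, what the synthetic-data generators emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Kinetic models

Progress curves are band fractions from gel densitometry, so values may
fall slightly outside [0, 1]; they are accepted in [−0.2, 1.2] and never
clipped before fitting.

**Single exponential** `f(t) = P(1 − e^{−kt})`. Fit by damped least
squares (trust-region reflective) in log-rate space with multi-start over a
log-spaced grid of rate guesses (10⁻⁵–10² min⁻¹) plus a data-driven
initial-slope guess; cost tolerance 10⁻¹⁴. Standard errors come from the
Jacobian at the optimum. A constant signal is returned as a flagged,
non-converged fit (rate unidentifiable), never an exception.

*Partial-completion convention.* For very slow reactions followed to well
under half completion, the free (k, P) pair is strongly anti-correlated and
the per-dataset estimate of k is heavily right-skewed. The standard remedy,
implemented as `fit_single_exponential(..., fix_plateau=...)`, pins the
plateau to the endpoint measured on a fast reference reaction of the same
substrate. The pipeline uses this for six-day time courses of the
proton-transfer-blocked variant.

**Double exponential (shared plateau)**
`f(t) = P[a(1 − e^{−k_f t}) + (1 − a)(1 − e^{−k_s t})]`. The fast phase is
the chemical step and is the reported rate; the slow phase is refolding of
an initially inactive fraction. Two conventions are built into the
parametrization rather than patched afterwards:

- *Ordering*: the fit optimizes (ln k_f, d, a, P) with
  k_s = k_f·e^{−d}, d ≥ 0, so k_fast ≥ k_slow by construction and the
  reported rate does not depend on optimizer slot labels.
- *Minimum phase separation* (default 20-fold, `separation_min`): the
  biphasic chemistry-vs-refolding interpretation presupposes kinetically
  separated phases (the systems modelled here are ~60-fold separated).
  Without the bound, the model is ill-posed whenever the slow phase moves
  only a few noise standard deviations inside the observation window: the
  global least-squares solution can place a tiny-amplitude, unresolvably
  fast "spike" phase on a single noisy point and contaminate the reported
  rate. With the bound, Monte-Carlo recovery at the study noise scale is
  unbiased (the acceptance tests measure this).

The multi-start set always contains the single-exponential solution
(a = 1), which guarantees the nesting property: the double fit never ends
with a larger residual RMS than the single fit on the same data.

**Model selection** (`select_kinetic_model`): report the biphasic fit only
if its k_fast ≥ 0.01 min⁻¹ (slower reactions are monophasic because
refolding outruns chemistry) *and* it reduces residual RMS by more than
20%; ties go to the single-exponential model. The second criterion prevents
fitting a noise-only second phase.

**Replicates**: reported rate constants are the arithmetic mean and sample
standard deviation of at least three converged fits; fewer than three is an
error, not a silent small-n summary.

At the noise scale used throughout (additive σ = 0.02 per point, 20 points
per curve), the information floor for a single biphasic fit is a rate
standard error of roughly 2–5%, so replicate scatter of the reported rate
is of order 0.01–0.03 min⁻¹ for a 0.6 min⁻¹ rate — the same scale as, but
not identical to, a ±0.01 replicate s.d. obtained from denser data.

## Activity–pH models

Single ionization (general acid must be protonated):
`k_obs = k_int / (1 + 10^{pH − pKa})`, monotone non-increasing in pH and
bounded by k_int. Double ionization adds a deprotonated-nucleophile factor
`1/(1 + 10^{pKa_nuc − pH})`, giving a bell curve; with the nucleophile
ionization far below the measured window it reduces to the single-pKa form,
which is the default model.

Fits minimize residuals of log₁₀(k_obs) — rates span five orders of
magnitude across variants — with multi-start over pKa guesses 3–10. A fit
is flagged `ph_independent` (pKa unidentifiable) when the pKa standard
error exceeds 2 units *or* the fitted inflection lies above the measured pH
window: a dataset with no observed ionization supports only a bound on the
pKa, not a value. The buffers' ~0.15-unit temperature error on pH is not
propagated by default.

Relative-rate tables divide each (variant, pH) mean rate by the reference
(unmodified ribozyme at pH 6.0); ratios are unit-invariant, displayed at 2
significant figures with full precision kept internally.

Computed activity-pH curves combine an Eyring rate from a free-energy
barrier with the protonation factor at the calculated ribozyme-environment
pKa; at pH = pKa the curve is exactly half the intrinsic rate. Computed
curves are aligned to experiment by a single scalar
max(experimental)/max(computed) derived from the reference variant and
applied unchanged to all variants, preserving computed rate ratios.

## Thermodynamic conversions

R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹; k_B/h = 2.0837×10¹⁰ s⁻¹ K⁻¹, so the
Eyring prefactor at 298.15 K is 6.212×10¹² s⁻¹. Temperature conventions:
free-energy simulations and all barrier/pKa conversions at 298.15 K;
experimental kinetics at 310.15 K. Both live in `ThermoContext` and are
never mixed silently; 298.15 K is the default because the tabulated
relative intrinsic rates round-trip most closely at that temperature.
ΔpKa = ΔΔG/(RT ln10) with RT·ln10 = 1.364 kcal/mol at 298.15 K. The
Brønsted slope is the OLS slope of log₁₀(rate) against nucleophile pKa
(exact two-point slope for two points; standard error reported for more).

## Free-energy surfaces and the string method

Surfaces are uniform rectangular grids of G(ξ_PT, ξ_AT) in kcal/mol over
the two difference-of-distances coordinates (Å), reactant quadrant
negative, with the reactant-basin minimum defining zero. Interpolation is
a bicubic spline with analytic gradients; points outside the grid hull are
errors naming the offending coordinate. The plain-text grid format stores
three header lines (axes and units) and row-major values at 12 significant
digits; write→read→write round-trips byte-identically.

The string method discretizes the path into images (default 32),
initialized on the straight segment between the fixed endpoints, and
iterates: perpendicular gradient descent, then equal-arc-length
reparameterization (iterated chord equalization, uniform to 10⁻⁹ of the
total length). Numerical controls: default descent step 0.01 Å per unit
force with a 0.1 Å per-image displacement cap, halving when the energy
rises on more than half the interior images (error after 10 consecutive
halvings) and 5% regrowth after clean iterations. These defaults are set
by stability: explicit descent oscillates when step × curvature exceeds
~2, and the preset basins have curvatures of order 25 kcal mol⁻¹ Å⁻².
Convergence is a maximum image displacement below 10⁻⁴ Å; the conventional
30-iteration budget is the default, with `max_iter` raised for full
convergence.

Profiles are sampled on a cubic spline through the images (20 points per
segment) so saddle tops between images are not missed. Stationary states
are labeled from alternating extrema along the arc — first minimum R, last
P, interior minima I, maxima TS1, TS2, … (leftmost point on plateaus) —
and the rate-controlling barrier is the profile maximum over the reactant
zero. TS coordinates are read off the path spline; a negative ξ_AT marks
an "early" transition state (nucleophilic attack less advanced than
leaving-group departure).

## The MTR1-like surface preset

`mtr1_surface_spec` builds a three-basin Gaussian mixture: reactant R at
(−1.5, −2.5) Å, intermediate I (proton transferred, alkyl not yet) near
(1.35, −2.6), product P at (1.5, 2.5), with the proton-transfer saddle TS1
between R and I and the rate-controlling alkyl-transfer saddle TS2 between
I and P. Because the saddle height of a Gaussian mixture is not available
in closed form, the preset calibrates itself deterministically on the
*continuous* mixture (no grids, no sampling): a fixed-point iteration
solves the reactant depth so TS2 sits exactly at the requested barrier
above the reactant minimum (default 16.3 kcal/mol) and shifts the
intermediate basin so the saddle lands at the requested ξ_AT (default
−0.24 Å). Saddles are located by a gradient root-find (analytic Hessian)
started from the inter-center line maximum. The calibration raises an
error if it fails to close to 10⁻⁶. Barriers of other magnitudes (for
variants with blocked proton transfer) are presets of the same family.

## Sampling and free-energy estimation

**Langevin generator.** Overdamped Euler–Maruyama on G plus the harmonic
window bias ½k|ξ−c|², all windows propagated in lock-step with independent
per-window noise streams spawned from one seed; first 10% of steps
discarded as burn-in; even thinning to the requested sample count. For a
harmonic target the discretization bias of the stationary covariance is
O(κ·Δt), so the default Δt = 0.002 keeps it ≲ 1% at the stiffnesses used.
Escaping the grid hull or producing non-finite energies raises an error
advising a smaller step. This sampler is plumbing: it provides ergodic,
exactly reproducible samples, not molecular dynamics.

**MBAR.** Reduced units u = G/kT internally; kcal/mol only at module
boundaries. The self-consistent equations are solved by SCF warm-up
followed by damped Newton on the convex objective (gauge f₁ = 0),
SCF fallback, residual tolerance 10⁻⁸, iteration cap 10⁴. Uncertainties
use the asymptotic weight-matrix covariance computed in the K-dimensional
SVD basis (validated in the tests against the dense formula and against
seed-to-seed scatter). Diagnostics: the pairwise overlap matrix is
reported with its minimum eigenvalue, but the *flag* is connectivity of
the overlap graph (edges above 10⁻³), because a perfectly healthy chain of
K pairwise-overlapping windows legitimately has a tiny smallest eigenvalue
while a disconnected network invalidates the estimate; disconnected
results carry a 10× inflated, floored uncertainty rather than failing
silently.

**2D PMFs** reweight pooled umbrella samples into bins,
−kT ln Σ w_n per bin, minimum shifted to zero; empty bins are NaN-masked
and more than 50% empty bins is an error advising wider windows.

**Alchemical chains** use per-λ Gaussian reduced-energy states (default 25
windows) whose analytic end-to-end free-energy difference is exact by
construction; only the estimator is under test, not softcore potentials or
enhanced sampling. ΔΔG converts to a pKa shift and then to the
ribozyme-environment pKa by addition to the solution pKa.

## Synthetic data: what is and is not emulated

The generators reproduce the *statistical structure* of the study's data:
biphasic first-order progress with an inactive-fold fraction, additive
Gaussian noise on gel fractions (σ 0.02–0.03), multiplicative log-normal
noise on rates (median-unbiased, CV 10%) over pH 5.5–8.5 with 3
replicates, surfaces with the R/I/P topology and controllable saddles, and
per-window biased samples. They do not emulate molecular coordinates,
force fields, QM/MM sampling noise structure, gel-image quantification, or
buffer chemistry. Passing recovery tests therefore demonstrates estimator
correctness under the stated noise models, not robustness to systematic
experimental artifacts.

Sampling schedules: time points for fast reactions are geometrically
spaced (e.g. 0.25–30 min for a ~1 min half-life), as aliquots are taken in
practice — a uniform grid leaves the entire fast-phase rise between two
points. Slow six-day courses use 15 uniformly spaced points.

## Problem sizes

Defaults are desk-scale and chosen for statistical adequacy: 100-seed
recovery studies for the acceptance quantities; 25 λ-windows × 300–500
samples for alchemical chains; 5×5 umbrella windows × ~2000 samples for
PMF reconstruction; 101×141–181 surface grids at 0.05 Å spacing; string
relaxation to convergence within a few thousand iterations.

## Known limitations

- The computed activity-pH curve is a documented reconstruction (Eyring
  rate × protonation factor); the original rate expressions behind the
  tabulated intrinsic-rate columns are more detailed, and one published
  derived factor (a ~47-fold rate increase attributed to a 1.1 kcal/mol
  barrier difference) is not reproducible from the plain TST relation,
  which gives ~6.4-fold.
- The string solver replaces sampled mean forces with interpolated surface
  gradients; it is a deterministic stand-in for the sampled-force variant.
- MBAR subsampling for correlated inputs is limited to the generator's
  thinning stride; no autocorrelation-time estimation is performed.
- 2D surfaces only; no climbing-image refinement, no committor analysis.
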