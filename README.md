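# ribomech

Mechanistic analysis of general-acid catalysis in the MTR1 alkyl-transferase
ribozyme: a desk-scale Python pipeline that connects reaction kinetics
(progress curves, pH-rate profiles, Brønsted analysis) with free-energy
landscapes (minimum free-energy paths, umbrella sampling/MBAR, alchemical
pKa shifts) to characterize a two-step general-acid mechanism.

## The science

MTR1 is an in-vitro-selected ribozyme that transfers an alkyl group from
*O*⁶-alkylguanine to N1 of a target adenine (A63). Catalysis proceeds in two
steps: cytosine C10, protonated at N3, first acts as a general acid and
protonates the *O*⁶-alkylguanine N1 (via TS1); alkyl transfer to A63 N1 then
follows through the rate-controlling transition state TS2. The package
implements the quantitative scaffolding of that argument:

- **Kinetics** — biphasic progress curves
  `f(t) = P·[a(1−e^(−k_fast t)) + (1−a)(1−e^(−k_slow t))]`, where the fast
  phase is the chemical step and the slow phase refolding of an initially
  inactive fraction; replicate summaries as mean ± s.d. of ≥ 3 experiments.
- **pH-rate profiles** — the single-pKa model
  `k_obs = k_int / (1 + 10^(pH − pKa))` (protonated-acid fraction × intrinsic
  rate), a two-ionization bell variant, and apparent-pKa fitting in
  log-rate space.
- **Thermodynamic conversions** — Eyring TST `k = κ(k_BT/h)·e^(−ΔG‡/RT)`,
  relative intrinsic rates `e^(ΔΔG‡/RT)`, pKa shifts
  `ΔpKa = ΔΔG/(RT ln10)`, and the Brønsted slope
  `β_nuc = d log₁₀k / d pKa_nuc`.
- **Free-energy landscapes** — gridded surfaces over the proton-transfer and
  alkyl-transfer coordinates (ξ_PT, ξ_AT, in Å), a string-method minimum
  free-energy path solver (32 images, perpendicular descent plus
  equal-arc-length reparameterization), and stationary-state labelling
  (R, TS1, I, TS2, P).
- **Free-energy estimation** — the MBAR estimator solved from its
  self-consistent equations, umbrella-window 2D PMF reconstruction, and
  25-λ-window alchemical ΔΔG → ΔpKa chains.
- **Synthetic data** — generators for all of the above with known ground
  truth (an MTR1-like surface preset with configurable barrier, overdamped
  Langevin sampling under harmonic restraints, Gaussian per-λ alchemical
  states), so every estimator is tested by parameter recovery.

## Worked example

```python
import numpy as np
import ribomech as rm

ctx = rm.ThermoContext()          # 298.15 K

# TST: barriers 16.3 vs 15.7 kcal/mol -> relative intrinsic rate
rm.relative_rate_from_barriers(16.3, 15.7, ctx)   # 2.75

# Bronsted slope from the A63(n7c) nucleophile perturbation
rm.bronsted_beta(rm.BronstedInput([(3.7, 1.0), (5.3, 6.1)])).beta_nuc  # 0.49

# alchemical pKa chain: 25 lambda windows, MBAR, shift, ribozyme pKa
ds = rm.gen_alchemical_samples(2.86, 25, 500, seed=17)
ddg, se = rm.alchemical_ddg(ds)                   # 2.82 +/- 0.13 kcal/mol
shift = rm.delta_pka_from_ddg(ddg, ctx)           # 2.07
rm.ribozyme_pka(4.2, shift)                       # 6.27

# landscape: preset surface, string MFEP, barrier and TS2 position
surf = rm.gen_surface(rm.mtr1_surface_spec())
path = rm.string_mfep(surf, (-1.5, -2.5), (1.5, 2.5), n_images=32, max_iter=3000)
prof = rm.profile_along_path(surf, path)
prof.rate_controlling_barrier                     # 16.30 kcal/mol
rm.ts_coordinates(prof, path)["TS2"]              # xi_AT = -0.24 A ("early" TS)

# pH-rate fit on synthetic replicate data (truth: pKa 6.4, 0.60/min at pH 6)
data = rm.gen_ph_rate_data(rm.k_int_from_point(0.60, 6.0, 6.4), 6.4,
                           np.arange(5.5, 8.51, 0.5), cv=0.1, n_reps=3, seed=1)
fit = rm.fit_ph_profile(data)                     # pKa 6.37 +/- 0.02
```

The numbers on the right are the outputs of this exact session. Reading
them together: the variant with the 0.6 kcal/mol lower barrier is predicted
2.75× faster; the 6.1-fold rate increase per 1.6 pKa units of nucleophile
basicity gives β_nuc ≈ 0.5 (substantial C–N bond formation in the TS); the
alchemical chain turns a simulated deprotonation ΔΔG into the
ribozyme-environment pKa (6.3) that matches the apparent pKa fitted from
rate data (6.4); and the landscape route finds the alkyl-transfer saddle at
ξ_AT = −0.24 Å, an early transition state.

## Command line

```sh
ribomech --seed 1 --outdir out run-all        # full synthetic pipeline
ribomech tables                               # recompute + diff summary tables
ribomech surface --barrier 16.3 --out surf.txt
ribomech string surf.txt
ribomech thermo params.json
```

`run-all` writes every intermediate (CSV/TSV/JSON, surface grids, a sha256
manifest); identical seed and config give byte-identical outputs. A demo
configuration ships at `src/ribomech/data/demo_config.yaml`.

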