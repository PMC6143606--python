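# Methods

## The kinetic model

A planar lipid bilayer is discretised into three layers: the *cis* leaflet,
which carries a membrane-adsorbed photosensitizer (PS) at surface density
`PS` (molecules·m⁻²), the hydrophobic *middle* layer, and the *trans*
leaflet.  Under illumination the PS generates singlet oxygen (SO) in the cis
layer at rate `k_gen·PS`.  SO hops between adjacent layers (`k_ctm` outer →
middle, `k_mct` middle → outer; the factor-2 on `k_mct` in the middle-layer
balance reflects its two exit directions), escapes into water or is quenched
at an interface (`k_w`), and is quenched in the core (`k_w0`).

The observable is supplied by a dipolar target dye that spans one leaflet
and the core.  Its two SO-susceptible moieties act differently:

* **T** (dipole-carrying aniline/naphthalene group, middle layer): oxidation
  by middle-layer SO at `k_to` erases the molecule's contribution to the
  membrane dipole potential — this is what the electrical measurement sees;
* **S** (unsaturated chain, in the adsorbing leaflet): quenches SO at `k_so`
  with no electrical signature.

Writing `O_c, O_m, O_t` for the SO surface concentrations and `T, S` for the
visible/quenching target densities, the cis-configuration system is

```
dT/dt  = k_ads·T_aq − k_des·T − k_to·T·O_m
dO_c/dt = k_gen·PS − k_so·S·O_c − (k_pso·PS + k_ctm + k_w)·O_c + k_mct·O_m
dO_m/dt = k_ctm·(O_c + O_t) − (2·k_mct + k_w0)·O_m − k_to·T·O_m
dO_t/dt = k_mct·O_m − (k_ctm + k_w)·O_t
```

with the S-quenching term moved to the `O_t` equation in the trans
configuration.  The S pool is not depleted (initial-rate regime; the model
carries no dS/dt), and `S = T + S₀`, where `S₀` is a density of
already-oxidised, electrically invisible molecules that still quench.

**Quasi-steady state.**  SO equilibrates within tens of nanoseconds while
the target bleaches over seconds, so the SO sub-system is solved as an exact
3×3 linear system for frozen `T, S` (`steady_state_so`; residuals are at
machine level, far below the 1e-10·`k_gen·PS` contract).  The initial
photo-oxidation rate is `R = k_to·O_m`.  Time courses
(`integrate_photobleaching`) integrate only dT/dt with `O_m` recomputed at
every evaluation (LSODA, rtol 1e-8); in the dark `O_m = 0` and the target
re-adsorbs at `k_des`.

**Closed form.**  Eliminating the linear system symbolically gives
`1/R_cis = a₁φ² + a₂φ + a₃` in the adsorption potential `φ = α·T₀`
(α = 4.65·10⁻¹⁹ V·m², the measured potential-per-density conversion), and

```
R_cis/R_trans = (k_ctm + k_w) / (k_ctm + k_w + k_so·(T₀ + S₀))  < 1
```

exactly.  The package's `ClosedFormCoefficients` are the exact symbolic
coefficients (cross-checked in the tests against an independent sympy
elimination and against the numeric solve at rtol 1e-12).  In the
traditional presentation of these coefficients an offset potential φ₀
appears whose definition is ambiguous; the exact a₂ corresponds to reading
φ₀ = α·S₀/2 (recorded in `interpretation_phi0`), the ratio law to
φ₀ = α·T₀, and no single reading reproduces the traditional a₃ — which is
why the symbolic elimination, not the traditional coefficient block, is
canonical here.  The numeric 3×3 solve is always the model of record; the
closed form exists for insight and cross-checking.

**Transfer rates from permeability.**  With membrane permeability
`P_M = K_p·D_M/d`, the Einstein relation, layer spacing d/3 and oxygen
partition coefficient `K_p`, the hop rates are `k_ctm = 6·P_M/(K_p·d)` and
`k_mct = k_ctm/K_p`.  With d = 4 nm, K_p = 4.4, P_M = 80 cm/s the formula
gives ≈ 2.7·10⁸ s⁻¹; the reference fits pin the rounded pair
(2.4·10⁸, 5.5·10⁷) s⁻¹ (`use_printed=True`), and both routes are exposed.

## Reference constants (packaged default configuration)

| constant | AlPcS₄ | AlPcS₂ | units | role |
|---|---|---|---|---|
| k_gen | 0.6 | 2.4 | m²s⁻¹ | SO generation per PS molecule (local) |
| k_so | 1.5·10⁻¹⁰ | 6.0·10⁻¹⁰ | m²s⁻¹ | S-moiety quenching (local) |
| k_to | 6.0·10⁻¹⁰ (reported one-sided) | | m²s⁻¹ | T-moiety oxidation (global) |
| k_w | 5.0·10⁷ | | s⁻¹ | outer-layer loss (global) |
| k_w0 | 2.9·10⁷ | | s⁻¹ | middle-layer quenching (global) |
| k_ctm, k_mct | 2.4·10⁸, 5.5·10⁷ | | s⁻¹ | transfer (fixed from P_M) |
| α·S₀ | 30 mV | | | invisible-target potential (global) |

`k_des = 5·10⁻³ s⁻¹` (dark-recovery time constant of ~3 min, the magnitude
seen in illumination/recovery traces) is the package's own choice — no value
is published; it affects only time-course simulation and recovery, never the
initial rates.

## The global fit and its identifiability structure

Datasets are 1/R-vs-φ curves for both membrane sides and several PS
densities.  The loss is weighted least squares on 1/R with weights ∝ R²
(equalising the relative influence of points whose inverse rates span
orders of magnitude), parameters in log₁₀ space, 16 seeded multi-starts
drawn log-uniformly within bounds (±3 decades around the reference values),
`scipy.optimize.least_squares` (TRF).  Model predictions always go through
the batched 3×3 steady-state solve.

**Exact ridge.**  The curves determine only combinations of the constants.
With the transfer rates fixed, scaling `u = k_ctm + k_w` while moving
`k_gen, k_so ∝ u`, `k_to ∝ 1/u` and compensating `k_w0` leaves every curve
coefficient — and therefore the entire likelihood — exactly unchanged.
Identifiable quantities include α·S₀, the k_gen ratio between
photosensitizers, `k_so/(k_ctm+k_w)`, `k_gen·k_to` and `(k_ctm+k_w)·k_to`;
individual constants are not identifiable from these curves alone.

The estimator therefore anchors the scale explicitly: a weak log-space
Tikhonov penalty (weight `reg_strength = 0.3` relative to the rms rate
signal) tethers `k_w`, `k_w0` and `k_to` — the constants with independent
physical reference magnitudes (the permeability-derived dwell-time scale
~10⁷–10⁸ s⁻¹; the k_to ≈ k_so reference) — to their configured initial
values.  The measured quantities `k_gen`, `k_so` and α·S₀ are never
penalised.  Consequences, verified in the test suite:

* noiseless synthetic curves return the generating parameters (the ridge is
  pinned at the reference point; identifiable combinations are recovered to
  ~1e-6, individual constants to ≪0.1%);
* at 5% multiplicative noise, k_gen is recovered with ~7% median error and
  k_w, k_w0 within a few %, while **k_so is the weakest-identified quantity
  (~25–35% median error)** — its information lives in the φ² curvature
  (~10% of the curve amplitude) and in the curvature of the trans/cis
  ratio, both noise-limited.  Reported per-parameter errors are meaningful
  only relative to the anchoring; the ridge extent across the
  indistinguishable multi-start solutions is exposed in
  `diagnostics["ridge_extent_log10"]`.

Without the cis/trans contrast the fit is rank-deficient; this is diagnosed
(warning + `rank_deficient` flag) rather than silently converged.

**One-sided k_to.**  When T-moiety oxidation is fast, the curves bound k_to
only from below.  If the estimate is dragged more than half a decade above
its anchor (or onto a bound), the fit reports a profile-likelihood lower
bound — the k_to below which the loss rises by one χ² unit — instead of a
symmetric error, mirroring a "> value" table entry.

**Uncertainties.**  Covariance-based standard errors (from the regularised
Jacobian) and a residual-resampling bootstrap (relative residuals, which are
homoscedastic under multiplicative noise; central 68% half-widths;
deterministic per seed) are both reported.  At 5% noise the bootstrap
half-width for k_gen(AlPcS₂) is ~0.2 m²s⁻¹, consistent with the Monte-Carlo
replicate spread within a factor ~1.5.

**Initial-rate extraction.**  `R = |dφ/dt|_{t=0}/φ_ads` by weighted linear
fit over the initial window: the samples within the first 10% of the total
decay amplitude or the first `window_fraction` of post-light-on samples,
whichever is smaller (≥5 points).  A least-squares line over `[0, w]` of an
exponential decay underestimates the initial slope by ~`k·w/2`, so the
default 10%-amplitude window carries a ~5% systematic bias toward slower
rates; slopes not resolved from zero at 2σ are flagged low-confidence.

## FCS calibration chain

The one-component 2D translational model `G(τ) = 1 + 1/(N(1+τ/τ_D))` is
fitted by weighted least squares (lmfit); no triplet/blinking term is
included, matching the measurement model.  Focus calibration uses a free-dye
standard: `ω_r² = 4·D·τ` and the ellipsoidal-Gaussian confocal volume
`V = π^{3/2}(ω_r²)^{3/2}·S` with structural parameter S (FITC: 565 µm²/s,
18 µs, S = 5; Cy5: 280 µm²/s, 31.6 µs, S = 8).  Membrane-dye diffusion then
follows from `D = ω_r²/(4τ_D)`.  Two routes to the 488-channel waist are
exposed: the raw FITC calibration (V recomputes to 0.228 fl) and the waist
back-computed from the reported rounded volume 0.22 fl; only the latter
reproduces the reported D_DT = 7.6 µm²/s to two significant figures.
Density conversions are linear: 30 molecules·µm⁻²·nM⁻¹ for the target dye,
57 for the PS (the directly observed 1700 µm⁻² at 30 nM differs by ~0.6%,
both exposed), and φ = α·T for the potential.  A lag-1 autocorrelation of
the fit residuals is emitted as a model-mismatch diagnostic (a 3D-diffusion
trace fitted with the 2D model gives |ρ₁| > 0.5).

## Synthetic data

The generator is the package's stand-in for the planar-bilayer experiments
(no raw data are deposited).  It emulates:

* **rate curves**: both sides × two PS densities per photosensitizer, φ from
  5 to 60 mV in 5 mV steps.  AlPcS₂ densities (228, 11 400 µm⁻²) follow its
  57 µm⁻²·nM⁻¹ adsorption coefficient at 4 and 200 nM aqueous; the AlPcS₄
  aqueous figures are dimensionally inconsistent in the source record, so
  round densities (1000, 10 000 µm⁻²) inside the sub/near-saturation range
  of the rate-vs-density relation are used instead;
* **potential traces**: QSSA integration of an illumination schedule,
  scaled by φ_ads = α·t₀, uniformly resampled;
* **FCS decays**: the 2D model on a 64-point log grid (1 µs – 10 s), noise
  applied to the correlation amplitude G − 1.

Default noise: 5% multiplicative lognormal on rates, 2% on G − 1, 0.3 mV
additive Gaussian on potentials.  All generators are pure functions of
(parameters, seed).

What passing tests do **not** show about real data: the generator draws
independent noise per point (no drift, no membrane-to-membrane variability),
uses the model itself as ground truth (no model error), and samples exactly
the designed φ grid.  Recovery results are therefore statements about the
estimator under the stated noise model, not about experimental accuracy.

## Numerical choices and degenerate inputs

* Steady state: direct 3×3 solve with partial pivoting (vectorised batch
  solve over curves); a finite source with all loss channels closed raises
  `NoSteadyStateError`.
* QSSA integration: LSODA, rtol 1e-8, absolute floor 1e-12·t₀.
* t₀ = 0 is allowed (the rate per molecule remains defined) although the
  relative-potential normalisation of the measurement is then degenerate.
* Optimiser tolerances 1e-14 (ftol/xtol/gtol); multi-start tie-breaking:
  among solutions within Δχ² ≤ 1 (machine floor for exact data), the one
  closest in log space to the initial values.
* Unit policy: strict SI internally; mV, µm⁻², nM conversions only at the
  CSV/CLI/config boundary.

## Problem sizes

The default test suite runs in ~25 s on one core: recovery replicates use
20 seeded 5%-noise fits with 4 optimiser starts each; the full 16-start
policy is exercised in the noiseless-determinism and acceptance paths; the
bootstrap tests use 25–60 resamples.  `scripts/acceptance.py` performs one
noiseless 96-point global fit (~2 s).

## Known limitations

* Individual rate constants are meaningful only jointly with the anchoring
  scheme; analyses needing pure likelihood inference should set
  `reg_strength = 0` and work with the identifiable combinations.
* No electrostatics (surface-potential/ζ corrections), no PS adsorption
  isotherms, no particle-level SO transport, no FCS photophysics
  corrections — all outside the model's scope.
* The ± semantics of the reference constants are unspecified in the source
  record; the bootstrap half-widths reported here are defined (central 68%)
  but need not coincide with them.
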