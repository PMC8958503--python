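# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `hepdcl`, in the order of the pipeline.

## Exact-mass layer

Masses are neutral monoisotopic masses computed from principal-isotope
atomic masses tabulated to ≥ 6 decimals (C 12.000000, H 1.0078250319,
N 14.0030740, O 15.9949146, Br 78.9183376; ⁸¹Br 80.9162906).  An adduct
arm contributes `aldehyde + H₂ − H₂O` to the core formula — imine
condensation followed by reduction — which is equivalent to `aldehyde − O`.
Comparisons against 4-decimal ESI-MS "Calculated" values use a 0.0005 Da
tolerance.  For brominated members the full ⁷⁹Br→⁸¹Br substitution ladder
is reported because both MS peaks are used in peak assignment.  Detected
ions are matched as [M+H]⁺ with a proton mass of 1.007276 Da.

The bundled registry fixes the identities of the core (spermine,
C₁₀H₂₆N₄) and of the aldehydes that were individually characterized as
products: A (2-hydroxybenzaldehyde), C (9H-fluorene-2-carbaldehyde),
F (2-hydroxy-1-naphthaldehyde), G (1-hydroxy-2-naphthaldehyde),
J (4-hydroxybenzaldehyde), K (2-methoxy-1-naphthaldehyde),
L (1-naphthaldehyde), N (2-naphthaldehyde) and
O (5-bromo-2-hydroxy-3-methoxybenzaldehyde).  The remaining six panel
slots (B, D, E, H, I, M) are representative assignments chosen once to
span the same design space — plain and methoxy/hydroxy-substituted
benzaldehydes, a third hydroxynaphthaldehyde isomer for E (so that E, F
and G form an isomer triple), an extended aromatic (anthracene), and one
dialdehyde (isophthalaldehyde) standing for the oligomer-capable blocks.
No reported mass depends on these six.  Dialdehydes are enumerated as
single-attachment adducts only; oligomer enumeration is out of scope.

## Sublibrary design

Members whose monoisotopic masses differ by ≤ tol (default 0.02 Da,
transitive closure) cannot be told apart by LC-MS in one mixture.
`design_sublibraries` runs a deterministic greedy set cover: seed a
sublibrary with the lexicographically smallest uncovered aldehyde pair,
grow it with the aldehyde adding the most uncovered pairs subject to
validation (all implied mono- and bis-adducts pairwise > tol apart), up to
`max_size` (default 6, keeping the per-run member count small).  Pairs
degenerate in their own two-aldehyde context are degenerate in every
larger context (adding aldehydes only adds members) and are reported
uncovered rather than raising.  The algorithm is deterministic by
tie-break, so the `seed` argument has no effect; it exists for interface
symmetry.  Minimality of the sublibrary count is a non-goal — validity
and pair coverage are the contracts.

## Amplification factors

Per replicate, AF = A_T/A_0 with both areas taken from paired injections
of the same sublibrary.  A per-replicate AF is discarded (flag
`low_control`) when the control area falls below `a0_floor_rel` (default
1%) of the median control area of that injection — ratios against barely
detected controls are artificially high.  Pooling is the arithmetic mean
of per-replicate AFs across replicates and sublibraries, never a ratio of
pooled areas.  Per-injection total-area normalization (on by default)
cancels injection-volume and detector drift exactly; note it assumes
total material is comparable between templated and control injections,
so on data where amplification strongly re-weights the mixture it trades
a small redistribution bias for drift immunity.  Ranking is by AF
descending; records without a defined AF or carrying the artifact flag
sort last, ties by member id.

## Speciation

Binding models list complexes L_lH_h with cumulative formation constants
log₁₀ β(l,h), reference state 1 M; heparin enters per disaccharide
repeating unit, its molar binding motif.  Stepwise constants follow as
K₁ = β₁₁, K₂ = β₁₂/β₁₁, K₃ = β₂₁/β₁₁.  The apparent dissociation constant
is reported as K_D^app = 1/K₁ by documented convention — a multi-step
scheme does not define it uniquely.

Free concentrations solve the two mass balances in (ln[L], ln[H]):
a damped log fixed-point sweep (free-concentration update, step ½) lands
in the Newton basin even for β spanning many decades, then damped Newton
steps (analytic Jacobian, trust clip of 3 log units, halving line search)
polish to a relative residual ≤ 1e-12; any point that still misses 1e-10
falls back to nested per-coordinate bisection, which is unconditionally
convergent because each calculated total is strictly increasing in its
own free concentration.  Mass-balance residuals are verified before a
state is returned, never assumed.  A vectorized variant solves whole
titration schedules at once (same sweep + Newton with a closed-form 2×2
solve; stragglers re-solved scalar-wise), which is what the fitting
routines call.

## Fluorescence global fit

The emission matrix factorizes as E(λ,i) = Σ_s ε_s(λ)·[s]_i over the
ligand-containing species; the free heparin unit is optically silent at
280 nm excitation (no chromophore), configurable by supplying a spectrum
for "H".  Fitting is variable projection: the nonlinear search runs over
the free log β only and each evaluation solves the linear ε exactly per
wavelength block.  The inner solve is *unconstrained* linear least
squares: constraining ε ≥ 0 (NNLS) during the search measurably biases
the constants upward (several hundredths of a log unit at realistic
noise) whenever a nearly dark species sits at the noise floor, because
the clipped coefficients are compensated by inflated concentrations; the
unconstrained estimator is unbiased and reaches the linearized Cramér–Rao
bound on synthetic data.  Physical non-negativity is imposed on the
reported spectra, and `nonneg_inner=True` restores the constrained mode.

Starts: a coarse grid (default 3 values per free constant) is screened on
the projected objective and the best 3 starts are refined by bounded
least squares (log β ∈ [0, 14]); ties go to the earlier start, making the
fit deterministic.  Refining only the top starts keeps the cost of a
three-constant fit below a second without changing the optimum found in
practice.  Uncertainties come from the Jacobian at the optimum
(linearized); identifiability requires at least as many titration points
as species plus free constants, enforced with an explicit error.

## SPR two-state kinetics

Within each phase the two-state system is a linear constant-coefficient
ODE, so sensorgrams are computed with the exact eigendecomposition
propagator rather than an adaptive stepper — machine-precision accuracy
with no step-size failure mode; an adaptive integrator serves as an
independent cross-check in the tests.  Association runs at constant
analyte concentration C; dissociation continues from the association
endpoint with C = 0; regeneration between cycles is a hard reset.
Mass-transport limitation and bulk refractive-index shifts are not
modeled.  The global fit shares (k_a1, k_d1, k_a2, k_d2, R_max) across
≥ 3 concentrations, searching rates in log₁₀ space (±6 decades around
the start) with data-derived heuristic starts (R_max from the response
ceiling, k_d1 from the early dissociation decay, half-saturation at the
middle concentration).  Diagnostics include propagated uncertainty on
K_D^app and a flat-direction flag (Jacobian singular-value ratio > 1e8),
the classic symptom of an unresolved isomerization step.

## Anti-Xa assay

Percent hydrolysis is the bounded, injection-volume-invariant ratio
100·A_c/(A_c+A_s); the 4-nitroaniline internal standard validates
injections (positive area required) but does not enter the metric.  The
30-minute potency is the exact sample when present, else linear
interpolation; curves decreasing by more than a tolerance (default 1
point) raise a warning.  The AF–potency relation is ordinary least
squares; outliers are flagged in a single pass by externally studentized
residual > 2 on the all-points fit, then the line is refit without them —
re-running on the cleaned set reproduces the same line (idempotence).
Points lying exactly on a line produce 0/0 studentized residuals and are
never flagged.  No mechanistic enzyme model is fitted.

## Synthetic data: what it emulates, what it does not

All generators draw from per-stream `numpy` generators seeded from the
scenario seed, so identical configurations are byte-reproducible.

* **Peak tables** — log-normal areas (multiplicative chromatographic
  noise, default CV 10%, triplicate), templated = control × true AF, an
  optional common per-injection drift factor, and a configurable set of
  members with near-zero control levels to exercise the artifact filter.
  Totals are *not* conserved across conditions (areas scale member-wise),
  so AF recovery against these tables is exact with normalization off;
  the drift term is what normalization is for.
* **Titrations** — the speciation forward model with Gaussian spectral
  bands on a 1 nm grid (the usual fluorimeter emission-scan step),
  290–390 nm, 50 points over 0–5 equivalents at 10 µM ligand.  True
  constants log β = 6.301/11.3/11.8 anchor K₁ at 2×10⁶ M⁻¹ (K_D^app
  0.50 µM) and were chosen so each complex peaks at 45–76% of the ligand
  — a recovery study is only meaningful when the titration populates
  every postulated species.  Spectra encode the quench/recovery
  phenotype: bright free ligand, strongly quenched LH, quenched L₂H with
  a weak red-shifted excimer-like band (stacked chromophores), partially
  emissive LH₂; no two species are exactly proportional, as in real
  systems.  Detector noise is additive Gaussian (SNR 100 at the peak in
  the recovery studies).
* **Sensorgrams** — two-state traces at 0.1×/1×/10× K_D^app
  (50 nM/0.5 µM/5 µM), 600 s per phase at 2 s sampling, R_max 100 RU,
  additive Gaussian noise (1 RU = 1% of R_max in recovery studies).
* **Hydrolysis curves** — exponential progress pct(t) = 100(1−e^(−kt))
  sampled at 5/10/15/20/30/50/80/120 min, with per-condition rate
  constants encoding the potency ladder (heparin-only slowest, then
  3AL ≤ 3AG < 3AF < 3FF < 3AC, no-heparin fastest) and optional
  multiplicative area noise.

What passing recovery tests show is that the estimators are correct and
efficient under these noise models; they do not certify behavior under
real-data pathologies the generators omit — ligand aggregation (a known
issue for the symmetric naphthol binder), inner-filter effects, baseline
drift in sensorgrams, heparin polydispersity and chain-length effects, or
co-eluting peaks in the screen.

Default concentration scales mirror the screening conditions the
analyses target: 1 mM building blocks against ~17–18 mM heparin repeating
units in the screen, 10 µM ligand titrations, 0.1 IU/mL heparin in the
enzymatic assay.

## Problem sizes

The test suite and acceptance checks run at desk scale by design: 100
random models for the speciation oracle sweep, 20 seeds for each recovery
study, 50-point titrations on a 100-wavelength grid, three-trace SPR
series at 2 s sampling.  These sizes put every stochastic claim at a few
seconds to a minute while leaving the medians well clear of their
thresholds.

## Known limitations

* The registry identities of aldehydes B, D, E, H, I, M are
  representative, not authoritative; masses and degeneracy structure for
  the characterized members do not depend on them.
* K_D^app = 1/K₁ is a convention; other collapses of the three-complex
  scheme give different apparent constants.
* The greedy covering design is not minimal and may use more sublibraries
  than a hand-optimized deconvolution.
* The two-state SPR fit assumes the labelled phases are exact and noise
  is white; correlated drift will leak into k_a2/k_d2.
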