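# Methods

This note records the models, the numerical choices behind the fits, what the
synthetic generator does and does not emulate, and the design decisions taken
where the conventional presentation of these methods leaves the details open.

## Mass-transfer quantities

Raw observations are gravimetric: initial sample weight w₀ (g), initial dry
matter u₀, dry matter u after treatment, initial water mass w_w0 and water
mass w_w at time t, plus optionally the water activity a_w of the treated
sample. Solid gain and water loss are normalised per unit *initial* sample
mass:

    SG = (u − u₀)/w₀        WL = (w_w0 − w_w)/w₀

Hard invariants (w₀ > 0, 0 < u₀ < w₀, u > 0, w_w ≥ 0, 0 < a_w ≤ 1) reject a
row; the wet-weight balance w_w0 + u₀ = w₀ is checked to 1e-6 relative and
only *warns* on violation, since real gravimetric data rarely balance
exactly. Negative WL or SG produced by measurement noise are retained with a
warning, never clipped — clipping would bias the least-squares fits.

Replicates are averaged per time point before fitting; the replicate sample
SD (ddof = 1) is carried for reporting only. WL/SG series always contain the
exact anchor (t = 0, Y = 0): at time zero no transfer has occurred by
definition, so any time-zero rows are replaced by the anchor.

## Peleg kinetics

The modified Peleg model Y(t) = t/(k₁ + k₂t) is fitted by bounded nonlinear
least squares (scipy's trust-region reflective) over the positive orthant.
Numerical choices:

* **Initialisation** — ordinary least squares on the linearised form
  t/Y = k₁ + k₂t over strictly positive responses, falling back to
  (k₁, k₂) = (1, 1/max Y) when the linearisation is unusable.
* **Restarts** — a deterministic schedule of ten multiplicative
  perturbations of the start (×{0.25, 0.5, 2, 4} on each coordinate plus the
  two joint extremes); the lowest-SSE solution wins. Non-convergence raises
  a fit-failure error carrying the best incumbent.
* **Degrees of freedom** — the model passes through the origin identically,
  so the zero-time anchor constrains nothing and carries no noise. It is
  excluded from the regression and from N; residual df = N − 2 with N the
  number of positive-time points. At the study design (three sampling times)
  df = 1; the heavy t(1) quantile is what keeps the asymptotic (Jacobian)
  95% intervals honest — Monte Carlo coverage at the study design is ≈ 95%,
  whereas counting the anchor would drop coverage to ≈ 80%.
* **Derived quantities** — initial rate 1/k₁ and equilibrium 1/k₂ are
  properties recomputed from the constants, never stored, so the
  reparameterisation identities hold to machine precision.

Fit diagnostics are computed over the full series *including* the anchor
(which the published per-fit RMSE values imply), with the relative-deviation
metrics (MPE, AARD) taken over nonzero experimental responses only, since
the structural zero anchor makes the relative deviation 0/0.

The original moisture form X_w(t) = X_w0 ± t/(k₁ + k₂t) is supported with
the sign fixed by a declared direction (absorption/desorption); a data trend
contradicting the declared direction triggers a fit-quality warning.

## GAB isotherm

The three-parameter GAB model is fitted by unweighted SSE minimisation in
moisture under box bounds X_m ∈ (1e-6, 1], C ∈ (1e-6, 10³] and
K ∈ (1e-6, min(0.9999, 0.9999/max a_w)] — the K cap keeps the denominator
positive on every data point; it applies to the point estimate only, and
confidence intervals may cross it. The optimiser runs a seeded Latin-
hypercube multistart (C sampled log-uniformly because its bounds span nine
decades; X_m and K uniformly) plus one data-driven heuristic start, each
solved with an analytic-Jacobian bounded least-squares pass, and the best
incumbent is polished to full precision. The fit is declared *stable* when
the two best restarts agree to 1e-6 relative in every parameter; identical
points, restart count and seed give bit-identical results. Parameter SDs and
CIs are asymptotic (Jacobian, t-quantile, df = N − 3).

Because the field's tables are ambiguous about whether "Ck" denotes the C
constant or the product C·K, the package reports C, K and the derived
product C·K as three separate columns.

`invert_gab` recovers a_w from moisture by bracketed Brent root-finding on
(0, min(1, 1/K)); the predict∘invert round trip is identity to ~1e-10.

## Diffusivity and activation energy

Only the first term of the Fick slab series is used, exactly as the standard
reduction does: MR = (8/π²)exp(−π²·D_eff·t/4L²) for a slab of
**half-thickness** L dried from both faces. D_eff comes from OLS of ln MR on
t (hours at the interface, seconds internally); points with MR outside
(0, 1) are excluded with a reported count, and a non-negative slope raises a
nonphysical-diffusivity error. The regression intercept is reported against
its theoretical value ln(8/π²) ≈ −0.210 as a model-adequacy diagnostic. The
slab geometry reported for the source experiment is internally inconsistent
(thickness exceeding diameter), so L is a required configuration value,
default 0.0025 m, always echoed in reports.

Activation energy: OLS of ln D_eff on 1/(T + 273.15), R = 8.314 J/(mol·K)
(the source prints kJ/(mol·K), an evident units typo), E_a = −slope·R
reported in kJ/mol with SD/CI from the slope standard error (t, df = N − 2;
undefined at N = 2, where the fit instead equals the closed-form two-point
expression to machine precision).

In the full pipeline the equilibrium moisture Mₑ for the moisture-ratio
reduction is derived from the condition's Peleg equilibria,
Mₑ = (w_w0 − WL∞·w₀)/(u₀ + SG∞·w₀), unless supplied explicitly.

## Error battery

χ² = SSE/(N − n), RMSE = √(SSE/N), MBE = mean(x_pre − x_exp),
SSE = Σ(x_pre − x_exp)², AARD = mean|Δ/x_exp|, MPE = 100·AARD, and
r² = 1 − SSE/SST (the coefficient-of-determination form; the published
tables pair r² with SSE, which this definition matches). MPE and AARD differ
only by the ×100 factor and are both reported. Metrics undefined for an
input (zero experimental values for MPE/AARD, constant experimental vector
for r²) are reported as NaN with a warning, never silently dropped.

## Synthetic generator

The generator forward-simulates the full factorial study design from known
truths, whose defaults are the study's own reported constants (Peleg
constants per condition, GAB coefficients per condition, activation energies
per variety with D₀ anchored at each variety's reported 20 °C diffusivity).

* **Kinetic noise** — additive Gaussian on WL (sd 0.01) and SG (sd 0.002).
  The SG noise is set five-fold smaller because SG signals are ~5× smaller
  than WL and the study's own per-fit RMSE values for SG sit near 10⁻³;
  these defaults place synthetic r² inside the published 0.990–1.000 band.
  No noise is added at t = 0: the time-zero measurement is the initial state
  itself.
* **Mass reconstruction** — w₀ fixed (10 g), water fraction 0.8 (u₀ = 2 g,
  w_w0 = 8 g, balance exact), u = u₀ + SG·w₀ and w_w = w_w0 − WL·w₀ — exact
  inverses of the SG/WL definitions, so the mass-transfer stage recovers the
  simulated responses identically.
* **Water activity** — emitted by inverting the condition's GAB isotherm at
  the simulated dry-basis moisture divided by a sorption scale (default
  100). The reported isotherm coefficients describe a low-moisture sorption
  regime whose attainable moisture range lies two orders of magnitude below
  osmotic dry-basis moistures (~0.1–4 kg/kg); the fixed scale maps one onto
  the other while preserving the isotherm shape exactly, so the pipeline's
  GAB stage (which applies the same scale) recovers the generating
  coefficients to machine precision at zero noise. Gaussian noise (sd 0.01)
  is added to a_w, clipped to (0, 1).
* **Drying curves** — first-term slab MR curves with multiplicative
  log-normal noise (log-sd 0.02) and moisture reconstructed as
  M = Mₑ + MR·(M₀ − Mₑ).
* **Determinism** — a single seeded generator fixes every draw; identical
  config + seed give byte-identical outputs.

What passing recovery tests on these data shows: the estimators invert their
own generating models correctly and are robust at the stated noise levels.
What it does not show: robustness to features of real osmotic data the
generator omits — between-sample biological variation beyond i.i.d. noise,
shrinkage and geometry changes, solution-side concentration decay, and any
mismatch between the Peleg/GAB/Fick forms and real tissue behaviour.

## Problem sizes

Defaults used by the tests: 500 simulated series for the Peleg
recovery/coverage study, 200 seeded draws for GAB recovery, 500 replicates
for the activation-energy noise study, 64 multistart restarts for production
GAB fits (16 in the recovery studies, where noiseless 4-point designs
converge from any reasonable start). These sizes give Monte-Carlo standard
errors well below the margins being tested.

## Known limitations

* The first-term slab solution is biased at short times (MR near 1) and the
  Fick reduction is applied to osmotic curves that are better described by
  the Peleg form — exactly as in the conventional workflow this package
  mirrors; the intercept diagnostic and r² expose the mismatch.
* Asymptotic CIs at df = 1 are individually erratic (very wide or very
  narrow) even though their coverage is calibrated; replicate-level fitting
  would give better-behaved intervals but the replicate-averaging convention
  matches the source workflow.
* The GAB stage of the pipeline fits (a_w, scaled moisture) pairs pooled
  across soak times at one condition, treating them as equilibrium isotherm
  points; that is a modelling convention inherited from the source design,
  not a physical equilibrium claim.
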