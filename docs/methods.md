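# Methods

This note documents the models, numerical choices and limitations behind
`gutflux`, in the package's own terms.

## Natural-abundance correction

A fragment with `n` carbons of which `j` carry tracer ¹³C is observed at
mass shift `i ≥ j` with probability `Binom(i − j; n − j, p)`, where
`p = 0.0107` is the natural fractional abundance of ¹³C. Stacking these
probabilities gives a square, invertible, column-stochastic convolution
matrix `M` with `M[i, j] = 0` for `i < j`; the excess distribution is the
solution of `M·x = raw`. The correction considers ¹³C on carbon only. The
abundance model is a pluggable object so corrections including
derivatization heteroatoms (Si, O in TBDMS adducts) can be added later;
they are not implemented. Luminal SCFA spectra are conventionally left
uncorrected (the pipeline's per-dataset flag defaults that way for luminal
inputs).

Inversion: the exact linear solve is used first; only when measurement
noise drives a labeled entry below −1e-12 does a bounded least-squares pass
(M⁺¹..M⁺ⁿ ≥ 0, M⁰ free) replace it. M⁰ is left unconstrained because noise
in a nearly unlabeled sample legitimately pushes the excess M⁰ slightly
negative; constraining it would bias the labeled fractions upward. The
output is renormalized to sum 1.

## Expected-labeling attribution

Design columns (per labeled product molecule) follow gluconeogenic
stoichiometry with carbon scrambling at the symmetric fumarate
intermediate:

| source | glucose column | citrate column | stoichiometry |
|---|---|---|---|
| [1-¹³C₁]-acetate | ½ M⁰ + ½ M⁺¹ | M⁺¹ | 1 |
| [1,2,3-¹³C₃]-propionate | ½ M⁺² + ½ M⁺³ | — | 1 |
| [1,2,3,4-¹³C₄]-butyrate | ½ M⁺¹ + ½ M⁺² | M⁺² | 2 |

The regression solves `excess ≈ Σ c_j · column_j` by non-negative least
squares over M⁺¹..M⁺ⁿ only. The M⁰ row is excluded because excess M⁰ is
the complement of the labeled entries and would double-count information;
the acetate column keeps its M⁺¹ weight of ½ so coefficients stay on the
per-molecule scale. Non-negativity reflects that contributions are physical
amounts; an unconstrained solution is available behind a flag. With the M⁰
row dropped the glucose design has overlapping columns (butyrate shares
M⁺¹ with acetate and M⁺² with propionate) but retains full column rank;
the solver reports the design's condition number (≈ 4) with every result.
Dose normalization uses the per-mmol reading:
`normalized_j = c_j / (stoich_j · dose_j) · dose_acetate`.

Metabolites without a stated labeling route (amino acids, fatty acids,
acyl-carnitines) get a pass-through screen that flags any labeled
isotopologue whose excess exceeds a threshold (default 0.005); this is how
M⁺³ propionyl-carnitine detection is represented, not as a regression.

## Compartment model

Seven states: gut pools `A_gut, P_gut, B_gut` (mmol), hepatic acetate
`A_liver` (mmol), and plasma ¹³C-glucose pools `G_a, G_p, G_b` (mM
labeled-glucose equivalents per source — the linear equations are agnostic
about molecule- vs carbon-equivalent bookkeeping, and values are documented
as labeled-glucose equivalents). The liver compartment exists only for
acetate, whose appearance in glucose is visibly biphasic; for propionate
and butyrate, uptake and conversion are lumped into single constants. The
plasma volume is `0.15 L/kg × body weight` (overridable). Time zero is the
moment of tracer delivery; bolus offsets of other study events are
metadata only.

Integration: LSODA with the exact (constant) Jacobian, `rtol 1e-8`,
`atol 1e-12` — the constants span more than two orders of magnitude, so a
stiff-capable method with tight tolerances is the safe default. Negative
round-off below 10·atol is clipped to zero. Tests check the integrator
against the matrix-exponential solution of the full linear system and the
two-exponential (Bateman) closed form of the propionate branch, and verify
label conservation (losses + clearance + remaining pools = dose) to 1e-6
relative.

## Parameter estimation

Two-stage, matching the identifiability structure:

1. **Grid search** for the two fixed constants (default kLa, k0p) on a
   grid in [0, 1] min⁻¹, default 50 log-spaced nodes on [1e-4, 1] plus 0
   (rate constants are scale parameters). At each node the six free
   constants are refitted and the node with the smallest unweighted sum of
   squared residuals wins; ties break toward smaller values. Both the
   plain sum of squares and the conventional √(SSR/n) are exposed — any
   monotone transform ranks nodes identically, so the choice cannot change
   the selected pair.
2. **Weighted least squares** for the six free constants:
   `SSE = Σ((Ŷᵢ−Yᵢ)/sᵢ)²` with `sᵢ` the per-point standard deviation
   (across subjects for a fit to averaged curves). When no per-point sd is
   available, a pooled per-curve scale (standard deviation of the observed
   values) is used so each curve contributes on a comparable footing.
   Optimizer: trust-region reflective least squares with bounds [0, 1]
   min⁻¹, start 0.01, `xtol/ftol/gtol 1e-12`, Jacobian column scaling.
   Standard errors come from `(JᵀJ)⁻¹·s²` at the optimum with
   `s² = SSE/(n−p)`; p-values from the asymptotic normal distribution of
   estimate/SE. Per-subject fits reuse the averaged-data fixed pair by
   default; a per-subject grid search is available.

Fractional incorporation of each SCFA into glucose is `k1x/(k1x+k0x)`
(undefined and reported as missing when `k1x+k0x = 0`).

## Identifiability

Scaled sensitivities `S[i,j] = (∂Ŷᵢ/∂θⱼ)·θⱼ/wᵢ` by central differences
with relative step 1e-6; `wᵢ` is the per-point sd when given, else the
curve maximum. Parameter scaling by θⱼ (relative sensitivities) is the
variant used and is recorded here; θⱼ = 0 produces a structurally zero
column, flagged as unidentifiable at that point. The collinearity index of
a subset is `1/√λ_min` of the Gram matrix of its unit-normalized columns;
all subsets of sizes 2..8 (≤ 247) are enumerated exhaustively. The
threshold defaults to 20. The "second parameter to fix" is chosen as the
one minimizing the collinearity index of the six parameters that remain
free — one concrete reading of minimizing collinearity "if fixed together
with kLa".

Under the default synthetic conditions (below) the full eight-parameter
set is collinear (index ≈ 28–30) but the scan finds a seven-parameter
subset (all but k1a) with index ≈ 7–8, i.e. one more than the six the
two-stage estimation scheme assumes. The 210-min window resolves the slow
hepatic acetate timescale (1/kLa ≈ 141 min) rather well; shorter or
noisier real-world coverage of the acetate curve plausibly degrades exactly
that subset. The estimation scheme conservatively keeps two constants
fixed regardless.

## Fractional dose contribution

`fraction = AUC × CL / dose` with `CL = k2·V`. The AUC is taken over the
whole fitted curve: the model is simulated densely to the time where every
gut pool is below 1e-6 of its dose, integrated by composite Simpson (step
≤ min(1, 0.05/k_max) min, keeping the quadrature error far below the 1e-6
agreement tolerance; plain trapezoids cannot reach that accuracy at any
practical step), and completed with the exact analytic tail obtained by
integrating the linear branch equations from the terminal state to
infinity. A raw-data trapezoid mode exists for diagnostics. For every
non-degenerate set of constants the result equals `k1x/(k1x+k0x)` to
< 1e-6; a truncated AUC (no tail) always underestimates.

## Synthetic-data generator

The generator emulates the study conditions and is the package's test bed:

* dose 9.6 / 4 / 0.9 mmol of ¹³C-acetate/propionate/butyrate at t = 0
  (from 0.96/0.40/0.09 M in 10 mL); 8 subjects, body weight
  ~ N(75, 10²) kg truncated at 50 kg;
* sampling every 15 min from −15 to 210 min (pre-delivery points carry
  zero signal);
* truth constants: kLa = 0.0071 and k0p = 0.0109 min⁻¹ (the fixed-pair
  values), k1p = 0.0109·0.23/0.77, k1a = 0.003, k0a = 0.022, k1b = 0.0395,
  k0b = 0.0105 — so the fractional incorporations are exactly
  (0.12, 0.23, 0.79) with butyrate uptake fastest and butyrate loss
  slowest — and k2 = 0.02 min⁻¹, a realistic plasma glucose turnover of
  2%/min. These are generator conventions producing curve shapes with the
  right ordering (acetate-derived glucose slowest to peak), not estimates
  of any cohort;
* inter-subject log-normal variation (unit-mean factors, CV 0.2) on every
  constant; additive Gaussian noise with sd = 5% of each curve's maximum,
  clipped at zero;
* raw MIDs composed from configurable per-SCFA contributions through the
  design columns, convolved with natural abundance, with 1% multiplicative
  noise; propionyl-carnitine carries excess only at M⁺³.

All randomness flows through a single NumPy PCG64 generator seeded from
the config, so datasets are bit-reproducible across platforms.

What the generator does *not* emulate: correlated (autocorrelated or
heteroscedastic beyond scale) measurement error, missing samples and
irregular per-subject schedules, drifts in plasma volume or glucose
concentration, isotopic impurity of the tracers, and any dependence
between a subject's rate constants. Passing recovery tests therefore shows
the estimator is correct and stable under the stated error model, not that
real clinical data meet that model.

## Problem sizes

Default test and acceptance runs use 8-subject datasets on the 16-point
schedule, 50-seed Monte-Carlo recovery at one replicate, 100 random
constant draws for the AUC-equivalence check, and a two-stage grid search
(9×9 coarse log nodes, then a 7×7 refinement around the coarse optimum)
— sizes chosen so a full from-scratch run stays in the minutes range while
keeping Monte-Carlo error well below the tolerances asserted.

## Known limitations

* The model is linear and first-order by construction; saturation of SCFA
  uptake or gluconeogenesis, recycling of label through breath CO₂, and
  SCFA interconversion (not observed in the motivating setting) are out of
  scope.
* Inference is asymptotic (normal-theory standard errors); no
  profile-likelihood or Bayesian uncertainty is provided.
* The attribution designs encode single-pass labeling; multi-turn TCA
  cycling that would spread label into higher isotopologues is not
  modelled.
* Structural (symbolic) identifiability is not analysed; the collinearity
  index is a local, data-dependent diagnostic.
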