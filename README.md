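# gutflux

Kinetics of intraintestinal ¹³C-SCFA incorporation into plasma glucose.

`gutflux` is a Python library for analysing stable-isotope tracer
experiments in which ¹³C-labeled short-chain fatty acids (SCFA) — acetate,
propionate and butyrate — are delivered directly into the human intestinal
lumen and their label is followed into plasma metabolites by GC-MS. It is
aimed at researchers quantifying the metabolic fate of microbial
fermentation products: how much of each delivered SCFA the host converts to
glucose, and how fast.

## What it computes

**Isotopologue correction and source attribution.** Raw mass-isotopologue
distributions (MIDs, fractional abundances m0..m+n) are corrected for
natural ¹³C abundance by inverting the binomial convolution matrix
(entry *(i, j)* = probability that a molecule with *j* tracer carbons is
observed at shift *i*), yielding excess distributions M⁰..M⁺ⁿ. Excess
glucose/citrate labeling is then decomposed by non-negative least squares
onto the expected fingerprint of each SCFA, fixed by gluconeogenic
stoichiometry and carbon scrambling at fumarate — e.g. [1,2,3-¹³C₃]-propionate
contributes equally to M⁺³ and M⁺² glucose, and one [1,2,3,4-¹³C₄]-butyrate
yields two labeled acetyl units (stoichiometry 2). Contributions are
normalized per mmol delivered, relative to acetate.

**Compartmental kinetics.** A linear three-compartment model
(gut → liver → plasma for acetate; gut → plasma for propionate and
butyrate) with eight apparent first-order rate constants (min⁻¹):

    dA_gut/dt   = −(k1a + k0a)·A_gut
    dA_liver/dt = k1a·A_gut − kLa·A_liver
    dG_a/dt     = (kLa·A_liver − k2·V·G_a) / V
    dP_gut/dt   = −(k1p + k0p)·P_gut
    dG_p/dt     = (k1p·P_gut − k2·V·G_p) / V        (butyrate analogous)

with V = 0.15 L plasma per kg body weight. Because the three glucose curves
cannot identify all eight constants at once (collinearity index of the full
set > 20), two constants (kLa, k0p) are fixed by grid search on the
unweighted sum of squares and the remaining six fitted by weighted least
squares, SSE = Σ((Ŷᵢ−Yᵢ)/sᵢ)², with asymptotic standard errors and
p-values.

**Identifiability and dose fractions.** Practical identifiability is
scored by the collinearity index 1/√λ_min of normalized sensitivity
subsets, enumerated exhaustively over all 247 subsets. The fraction of each
delivered SCFA incorporated into glucose is computed both as
k1x/(k1x+k0x) and as AUC × CL / dose (CL = k2·V); the two agree to < 1e-6
for the fitted linear model.

**Synthetic data.** Since no clinical data accompany the study design, a
seeded generator produces per-subject curves (default: 8 subjects, 9.6/4/0.9
mmol doses, 15-min sampling from −15 to 210 min, 5% noise, log-normal
inter-subject variation) and raw MID tables, each with a truth sidecar for
recovery testing.

## Worked example

```python
import gutflux as gf

cfg = gf.GeneratorConfig(seed=1)            # study-condition defaults
ds = gf.generate_enrichment_curves(cfg)     # 8 noisy subjects + truth
result = gf.fit(ds.average(), cfg.dose, gf.SubjectProfile())
print(result.fractions)
```

prints

```
{'acetate': 0.1205..., 'propionate': 0.2287..., 'butyrate': 0.8301...}
```

— the fractional incorporations of acetate, propionate and butyrate into
plasma glucose implied by the fitted constants, recovering the generator
truth (0.12, 0.23, 0.79) to within the 5% measurement noise. The
`examples/` directory has one short script per capability (correction +
attribution, simulation, fitting, identifiability scan, dose fractions,
dataset generation), each printing the numbers it computes and what they
mean. A thin CLI mirrors the stages:

```bash
gutflux generate --seed 1 --out-dir data
gutflux fit --curves data/curves.csv --out fit.json
gutflux fractions --fit fit.json --out fractions.csv
gutflux run --seed 1 --out-dir out     # whole pipeline end to end
```

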