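"""Simulate the gut–liver–plasma compartment model for one subject.

Delivers the study dose (9.6/4/0.9 mmol of 13C-acetate/propionate/butyrate)
into the gut at t = 0 and integrates the label chains into plasma
13C-glucose for a 75-kg subject (V_plasma = 0.15 L/kg).
"""

import numpy as np

import gutflux as gf

k = gf.PAPER_REGIME_K
dose = gf.TracerDose()
subject = gf.SubjectProfile(body_weight_kg=75.0)
times = np.arange(0.0, 211.0, 30.0)

res = gf.simulate(k, dose, subject, times)

print(f"rate constants (min^-1): {k.to_dict()}")
print(f"plasma volume: {subject.v_plasma_L:.2f} L\n")
print("time_min  G_acetate_mM  G_propionate_mM  G_butyrate_mM")
for i, t in enumerate(times):
    ga, gp, gb = res.states[i, 2], res.states[i, 4], res.states[i, 6]
    print(f"{t:8.0f}  {ga:12.5f}  {gp:15.5f}  {gb:13.5f}")

print(
    "\nEach column is the plasma 13C-glucose pool (mM labeled-glucose\n"
    "equivalents) attributable to one delivered SCFA.  Butyrate-derived\n"
    "glucose peaks earliest and highest per mmol delivered; acetate-derived\n"
    "glucose rises slowest because it passes through the hepatic acetate\n"
    "pool (kLa = 0.0071 min^-1) before reaching plasma."
)
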