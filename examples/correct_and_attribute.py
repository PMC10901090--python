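"""Correct a raw glucose isotopologue distribution and attribute it to SCFA.

Builds a raw plasma-glucose MID by convolving a known tracer-labeling
pattern with natural 13C abundance, removes the natural component, and
decomposes the excess labeling onto the expected fingerprints of acetate,
propionate and butyrate.
"""

import numpy as np

import gutflux as gf
from gutflux.mid import build_correction_matrix

# true tracer contributions per labeled-product molecule
truth = {"acetate": 0.012, "propionate": 0.020, "butyrate": 0.016}

design = gf.glucose_design()
excess = np.zeros(7)
for scfa, c in truth.items():
    excess += c * design.column(scfa)
excess[0] += 1 - excess.sum()

# what the mass spectrometer would report: excess convolved with natural 13C
M = build_correction_matrix(6, gf.NaturalAbundanceModel())
raw = gf.MassIsotopologueDistribution("glucose", 6, M @ excess)
print("raw m0..m+6:     ", np.array2string(raw.values, precision=4))

corrected = gf.correct_natural_abundance(raw)
print("excess M0..M+6:  ", np.array2string(corrected.values, precision=4))

result = gf.attribute_sources(corrected, design, dose=gf.TracerDose())
print("\nper-SCFA coefficients (labeled glucose fraction contributed):")
for scfa, c in result.coefficients.items():
    print(f"  {scfa:11s} {c:.4f}   (truth {truth[scfa]:.4f})")
print("\ndose-normalized contributions (per mmol, relative to acetate):")
for scfa, c in result.normalized_contribution.items():
    print(f"  {scfa:11s} {c:.4f}")
print(f"\ndesign condition number over M+1..M+6: {result.condition_number:.2f}")
print(
    "The coefficients recover the generating contributions; after dose\n"
    "normalization butyrate is by far the most efficient label donor per\n"
    "mmol delivered, as only 0.9 mmol of it produced its share of labeling."
)
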