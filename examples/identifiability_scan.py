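"""Collinearity-index identifiability scan of all parameter subsets.

Computes parameter-scaled sensitivities of the three glucose curves on the
study sampling schedule and enumerates all 247 parameter subsets of sizes
2..8.  Subsets with collinearity index below 20 are considered jointly
identifiable in practice.
"""

import gutflux as gf
from gutflux.identifiability import choose_fixed_pair

cfg = gf.GeneratorConfig(seed=1)
ds = gf.generate_enrichment_curves(cfg)
avg = ds.average()
subject = gf.SubjectProfile(subject="average")

times = avg["acetate"].times_min
post = times >= 0
weights = {s: avg[s].sd[post] for s in gf.SOURCES}
S, zero_cols = gf.sensitivity_matrix(gf.PAPER_REGIME_K, cfg.dose, subject, times[post], weights=weights)
report = gf.identifiable_subsets(S, threshold=20.0)

print(f"subsets scanned: {len(report.records)} (sizes 2..8)")
print(f"max jointly identifiable subset size: {report.max_identifiable_size}\n")
print("best subset per size (collinearity index, < 20 = identifiable):")
for size in range(2, 9):
    best = report.best_subset(size)
    mark = "identifiable" if best["identifiable"] else "NOT identifiable"
    print(f"  {size}: index {best['index']:6.2f}  {mark:17s}  {'+'.join(best['subset'])}")

partner, gamma = choose_fixed_pair(S, first="kLa")
print(
    f"\nfixing kLa, the partner whose additional fixing leaves the most\n"
    f"identifiable six-parameter set is {partner} (remaining index {gamma:.2f})."
)
print(
    "\nThe full eight-parameter set is collinear (index > 20): the three\n"
    "glucose curves cannot pin down all constants at once, which is why the\n"
    "estimation scheme fixes two of them before fitting."
)
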