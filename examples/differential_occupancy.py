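"""Classify DRM sites by occupancy change in the pocket-protein-null mutant.

Runs the NB Wald test on the synthetic (site, subunit) count matrix,
applies BH FDR per subunit, and splits sites into Class I (>= 1 subunit
significantly decreased) and Class II (none).
"""

from drmchip import PipelineConfig, classify_peaks, nb_wald_table, size_factors
from drmchip.simulate import ScenarioParams, generate_scenario

config = PipelineConfig()
bundle = generate_scenario(ScenarioParams(), seed=42)

factors = size_factors(bundle.counts.counts)
print("estimated size factors:")
for sample, f in factors.items():
    print(f"  {sample}: {f:.3f}")
print("(mutant factors sit well below WT ones: median-of-ratios absorbs part of")
print(" the genome-wide occupancy drop, so per-site fold changes are relative)")

results = nb_wald_table(bundle.counts, config)
calls = classify_peaks(results, config)

n1 = sum(c.class_label == "I" for c in calls)
n2 = len(calls) - n1
at_least_3 = sum(c.n_subunits_decreased >= 3 for c in calls if c.class_label == "I")
all6 = sum(c.all_six_decreased for c in calls)
any_inc = sum(c.any_increased for c in calls if c.class_label == "II")
print(f"\nClass I (decreased for >= 1 subunit at FDR < {config.fdr_alpha}): {n1}")
print(f"Class II (no significant decrease): {n2}")
print(f"Class I with >= 3 of 6 subunits decreased: {100 * at_least_3 / max(n1, 1):.0f}%")
print(f"Class I with all 6 subunits decreased: {100 * all6 / max(n1, 1):.0f}%")
print(f"Class II with a significant increase in >= 1 subunit: {any_inc}")

truth = {s.site_id: s.class_label for s in bundle.truth.sites}
recall = sum(
    1 for c in calls if c.class_label == "I" and truth[c.peak_id] == "I"
) / sum(1 for v in truth.values() if v == "I")
spec = sum(
    1 for c in calls if c.class_label == "II" and truth[c.peak_id] == "II"
) / sum(1 for v in truth.values() if v == "II")
print(f"\nAgainst planted truth: Class I recall {recall:.2f}, "
      f"Class II specificity {spec:.2f}")
print("Strong planted drops (log2FC ~ -2) are caught on at least one subunit;")
print("weak drops (~ -0.3) never cross the FDR threshold as decreases. Because")
print("fold changes are relative to the library scale, weakly affected sites")
print("can even register apparent increases once the global drop is absorbed")
print("into the mutant size factors.")
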