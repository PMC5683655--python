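"""Map DRM sites to promoters, introns, TTS windows or intergenic space.

Annotates consensus peaks by their center against strand-aware promoter
windows (-1000/+100 bp around each TSS) and reports the category
partition, then extracts the promoter-bound "DRM target genes".
"""

from drmchip import (
    SUBUNITS,
    PipelineConfig,
    annotate_peaks,
    consensus_drm,
    extract_target_genes,
    reproducible_peaks,
    summarize_annotation,
)
from drmchip.simulate import ScenarioParams, generate_scenario

config = PipelineConfig()
bundle = generate_scenario(ScenarioParams(detection_prob=1.0), seed=42)

wt = {s: reproducible_peaks(bundle.wt_peaks[s], config.min_replicates) for s in SUBUNITS}
drm = consensus_drm(wt, config)
annotations = annotate_peaks(drm, bundle.genes, config)
summary = summarize_annotation(annotations)

print("peak location categories:")
for cat, n in summary["counts"].items():
    print(f"  {cat:>22}: {n}")
print(f"promoter share: {summary['promoter_percentage']}% of {summary['total']} peaks")
print("(every synthetic site is planted inside a promoter window, so the")
print(" promoter share is 100%; bidirectional peaks sit between divergent TSSs)")

targets = extract_target_genes(annotations)
bidir = [a for a in annotations if a.category == "promoter_bidirectional"]
print(f"\nDRM target genes (promoter-bound): {len(targets)}")
print(f"bidirectional-promoter peaks: {len(bidir)}, each naming 2 target genes")
print(f"matches the generator's bound-gene truth: "
      f"{targets == set(bundle.truth.bound_genes)}")
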