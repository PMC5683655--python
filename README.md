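# drmchip

Analysis of chromatin occupancy by the *C. elegans* DRM complex — the worm
homolog of the mammalian DREAM (Dp/Rb-like/E2F/MuvB) transcriptional
repressor. DRM contains three functional components read out by seven
subunit ChIPs: the E2F-DP heterodimer (DPL-1, EFL-1), the sole worm pocket
protein LIN-35, and the MuvB core (LIN-9, LIN-37, LIN-52, LIN-54). The
central questions this pipeline supports: where does the full complex bind,
how does occupancy change when the pocket protein is removed
(*lin-35* null), and which bound genes does the complex actually repress?

`drmchip` is a library (plus `examples/` scripts) implementing the
analysis end to end:

1. **Consensus binding sites.** Per-subunit replicate peak calls pass a
   reproducibility filter (single-linkage overlap clusters present in ≥ 2
   of 3 replicates), then a tiered vote: E2F-DP regions require both
   DPL-1 and EFL-1; MuvB regions require ≥ 3 of 4 MuvB subunits; a
   high-confidence DRM site is the triple overlap of an E2F-DP region, a
   LIN-35 peak, and a MuvB region.
2. **Differential occupancy.** Fragment counts per (site, subunit) are
   normalized by median-of-ratios size factors
   s_j = median_i c_ij / (Π_j c_ij)^(1/m) and tested with a
   negative-binomial Wald test: log2FC = log2((μ_mut + ½)/(μ_WT + ½)),
   SE² = (1/ln 2)² [ (1/n_WT)(1/(μ_WT+½) + α̂) + (1/n_mut)(1/(μ_mut+½) + α̂) ],
   with a method-of-moments dispersion α̂. Benjamini–Hochberg FDR is
   applied per subunit; a site is **Class I** if ≥ 1 subunit decreases
   significantly (FDR < 0.05), else **Class II**. Retention calls
   (lost/retained E2F-DP and MuvB in the mutant) come from overlap with
   mutant consensus regions.
3. **Annotation.** Each site's center is assigned, with precedence, to a
   bidirectional promoter (center inside ≥ 2 strand-aware −1000/+100 bp
   TSS windows), a single-gene promoter, an intron, a ±1000 bp TTS
   window, or intergenic space. Promoter-bound genes are the "DRM target
   genes".
4. **Motifs.** IUPAC scanning for the E2F-DP element CDE (`BSSSSS`, ≤ 1
   mismatch) and the LIN-54 element CHR (`TTYRAA`, exact) on both
   strands, filtered by mean per-base conservation > 0.7; hypergeometric
   upper-tail enrichment P(X ≥ k) against background promoters and a 2×2
   chi-squared for Class I vs Class II association.
5. **Target expression.** DE tables thresholded at q < 0.05 and fold
   change > 1.5 split targets into **Group A** (upregulated in ≥ 1
   mutant experiment) and **Group B**; RT-qPCR relative quantities use
   efficiency-corrected ΔCt against *act-2*
   (Rq = E_ref^Ct_ref / E_tgt^Ct_tgt) and ChIP-qPCR signals are log₂ fold
   enrichment over a negative control region.
6. **Synthetic data.** A seeded generator (`drmchip.simulate`) builds a
   toy genome, gene catalogue, per-subunit replicate narrowPeak files in
   two genotypes, NB count matrices, conservation track, DE and qPCR
   tables — with a machine-readable truth object so every stage is
   testable without external data.

## Worked example

```python
from drmchip import (SUBUNITS, PipelineConfig, consensus_drm,
                     reproducible_peaks, nb_wald_table, classify_peaks)
from drmchip.simulate import ScenarioParams, generate_scenario

config = PipelineConfig()
bundle = generate_scenario(ScenarioParams(), seed=42)
wt = {s: reproducible_peaks(bundle.wt_peaks[s], config.min_replicates)
      for s in SUBUNITS}
drm = consensus_drm(wt, config)
calls = classify_peaks(nb_wald_table(bundle.counts, config), config)
print(len(drm), sum(c.class_label == "I" for c in calls))
```

prints `128 89`: of 150 planted co-bound sites, 128 survive the
replicate filter and three-way vote at per-subunit detection probability
0.9, and 89 of the 90 sites planted with a strong occupancy drop
(log2FC ≈ −2 per subunit) are called Class I. Running
`python examples/differential_occupancy.py` shows the full readout,
including the estimated size factors (WT ≈ 1.2–1.9, mutant ≈ 0.6–0.7:
median-of-ratios normalization absorbs part of the genome-wide occupancy
drop, so per-site fold changes are relative to the library scale) and
Class I recall 0.99 / Class II specificity 1.00 against the planted
truth. The other `examples/` scripts walk through annotation (100% of
synthetic sites are promoter-planted; 22 bidirectional), conserved-motif
enrichment (90/150 sites carry a conserved CHR vs 0/228 background
promoters, p ≈ 7.5e−47), and Group A/B classification (68 Group A genes,
hypergeometric p ≈ 3e−12 for enrichment among upregulated genes).

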