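"""Assign consensus peaks to genomic categories and promoter target genes.

A peak is judged by its center with precedence promoter > intron > TTS >
intergenic.  Promoter windows are strand-aware: -1000/+100 bp around the
TSS (clipped at the chromosome start).  A center inside >= 2 promoter
windows marks a bidirectional-promoter peak (both genes become targets);
inside exactly one, a single-gene promoter peak.  Otherwise the center may
fall in an intron, within +-1000 bp of a transcription termination site,
or be intergenic.  "DRM target genes" are the genes whose promoters carry a
peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .consensus import ConsensusPeak
from .genomic_io import GeneModel, GenomicInterval, PipelineConfig

__all__ = [
    "CATEGORIES",
    "PeakAnnotation",
    "promoter_window",
    "annotate_peak",
    "annotate_peaks",
    "summarize_annotation",
    "extract_target_genes",
]

CATEGORIES = (
    "promoter_bidirectional",
    "promoter_single",
    "intron",
    "tts",
    "intergenic",
)


@dataclass(frozen=True)
class PeakAnnotation:
    """One peak's genomic category, target genes and signed TSS distances.

    ``distance_to_tss`` is reported per gene in gene orientation: positive
    when the peak center lies downstream of the TSS.
    """

    peak_id: str
    category: str
    gene_ids: tuple[str, ...] = ()
    distance_to_tss: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "promoter_bidirectional" and len(self.gene_ids) < 2:
            raise ValueError("bidirectional promoter needs >= 2 genes")
        if self.category == "promoter_single" and len(self.gene_ids) != 1:
            raise ValueError("single promoter needs exactly 1 gene")
        if self.category == "intergenic" and self.gene_ids:
            raise ValueError("intergenic peaks carry no genes")


def promoter_window(gene: GeneModel, config: PipelineConfig | None = None) -> GenomicInterval:
    """The -upstream/+downstream window around the TSS, strand-aware.

    On + strands: [tss - upstream, tss + downstream); on - strands the
    mirror image [tss - downstream, tss + upstream).  Clipped at 0.
    """
    config = config or PipelineConfig()
    up, down = config.promoter_upstream, config.promoter_downstream
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down, gene.tss + up
    return GenomicInterval(gene.interval.chrom, max(start, 0), end)


def _signed_tss_distance(gene: GeneModel, chrom: str, pos: int) -> int:
    d = pos - gene.tss
    return d if gene.strand == "+" else -d


def annotate_peak(
    peak: ConsensusPeak,
    genes: Sequence[GeneModel],
    config: PipelineConfig | None = None,
) -> PeakAnnotation:
    """Categorize one peak by its center position."""
    config = config or PipelineConfig()
    chrom, center = peak.interval.chrom, peak.center

    promoter_hits = [
        g for g in genes if promoter_window(g, config).contains(chrom, center)
    ]
    if promoter_hits:
        promoter_hits.sort(key=lambda g: g.gene_id)
        category = (
            "promoter_bidirectional" if len(promoter_hits) >= 2 else "promoter_single"
        )
        return PeakAnnotation(
            peak_id=peak.id,
            category=category,
            gene_ids=tuple(g.gene_id for g in promoter_hits),
            distance_to_tss=tuple(
                _signed_tss_distance(g, chrom, center) for g in promoter_hits
            ),
        )

    intron_hits = [
        g
        for g in genes
        if g.interval.chrom == chrom
        and any(i.contains(chrom, center) for i in g.introns)
    ]
    if intron_hits:
        intron_hits.sort(key=lambda g: g.gene_id)
        return PeakAnnotation(
            peak_id=peak.id,
            category="intron",
            gene_ids=tuple(g.gene_id for g in intron_hits),
            distance_to_tss=tuple(
                _signed_tss_distance(g, chrom, center) for g in intron_hits
            ),
        )

    tts_hits = [
        g
        for g in genes
        if g.interval.chrom == chrom and abs(center - g.tts) <= config.tts_window
    ]
    if tts_hits:
        tts_hits.sort(key=lambda g: g.gene_id)
        return PeakAnnotation(
            peak_id=peak.id,
            category="tts",
            gene_ids=tuple(g.gene_id for g in tts_hits),
            distance_to_tss=tuple(
                _signed_tss_distance(g, chrom, center) for g in tts_hits
            ),
        )

    return PeakAnnotation(peak_id=peak.id, category="intergenic")


def annotate_peaks(
    peaks: Sequence[ConsensusPeak],
    genes: Sequence[GeneModel],
    config: PipelineConfig | None = None,
) -> list[PeakAnnotation]:
    return [annotate_peak(p, genes, config) for p in peaks]


def summarize_annotation(
    annotations: Sequence[PeakAnnotation],
) -> dict:
    """Category counts plus the promoter percentage.

    ``promoter_percentage`` = 100 * (bidirectional + single) / total,
    rounded to the nearest integer; absent (None) for empty input.
    """
    counts = {c: 0 for c in CATEGORIES}
    for a in annotations:
        counts[a.category] += 1
    total = len(annotations)
    promoter = counts["promoter_bidirectional"] + counts["promoter_single"]
    return {
        "counts": counts,
        "total": total,
        "promoter_percentage": round(100 * promoter / total) if total else None,
    }


def extract_target_genes(annotations: Iterable[PeakAnnotation]) -> set[str]:
    """Union of genes with a peak in their promoter (other categories excluded)."""
    targets: set[str] = set()
    for a in annotations:
        if a.category in ("promoter_bidirectional", "promoter_single"):
            targets.update(a.gene_ids)
    return targets
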