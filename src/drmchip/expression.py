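"""DRM target-gene expression classification and qPCR quantities.

Genes with a DRM peak in their promoter ("DRM target genes") are split
into Group A (upregulated in at least one DRM-mutant expression experiment
at q < 0.05 and fold change > 1.5) and Group B (the rest).  Enrichment of
targets among differentially expressed genes uses the hypergeometric upper
tail.  RT-qPCR relative quantities use efficiency-corrected delta-Ct
against the act-2 reference gene; ChIP-qPCR signals are log2 fold
enrichment over a negative control region assuming amplification
efficiency 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import PipelineConfig
from .motifs import EnrichmentResult, hypergeom_upper_tail

__all__ = [
    "ExpressionCall",
    "TargetGroupCall",
    "QpcrRecord",
    "apply_de_thresholds",
    "group_targets",
    "group_enrichment",
    "qpcr_relative_quantity",
    "chipqpcr_log2_enrichment",
]


@dataclass(frozen=True)
class ExpressionCall:
    """A thresholded differential-expression call for one gene/experiment."""

    gene_id: str
    experiment_label: str
    log2fc: float
    q_value: float
    direction: str  # up | down | unchanged


@dataclass(frozen=True)
class TargetGroupCall:
    """Group A/B membership of a DRM target gene."""

    gene_id: str
    group: str  # A | B
    supporting_experiments: tuple[str, ...] = ()


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: threshold cycle and amplification efficiency."""

    sample_id: str
    gene_id: str
    ct: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("Ct must be positive")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must be in (1, 2]")


def apply_de_thresholds(
    stats: pd.DataFrame, config: PipelineConfig | None = None
) -> list[ExpressionCall]:
    """Threshold a gene table (gene_id, experiment, log2fc, q_value).

    ``direction`` is "up" when q < q_threshold and 2**log2fc >
    fc_threshold, "down" symmetrically (2**(-log2fc) > fc_threshold), else
    "unchanged".  The fold-change cut is applied on the linear scale,
    symmetrically in both directions.
    """
    config = config or PipelineConfig()
    required = {"gene_id", "experiment", "log2fc", "q_value"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if ((stats["q_value"] <= 0) | (stats["q_value"] > 1)).any():
        raise ValueError("q-values must lie in (0, 1]")
    lfc_cut = math.log2(config.de_fc_threshold)
    calls = []
    for row in stats.itertuples(index=False):
        significant = row.q_value < config.de_q_threshold and abs(row.log2fc) > lfc_cut
        if significant:
            direction = "up" if row.log2fc > 0 else "down"
        else:
            direction = "unchanged"
        calls.append(
            ExpressionCall(
                gene_id=row.gene_id,
                experiment_label=row.experiment,
                log2fc=float(row.log2fc),
                q_value=float(row.q_value),
                direction=direction,
            )
        )
    return calls


def group_targets(
    drm_targets: Iterable[str], calls: Sequence[ExpressionCall]
) -> list[TargetGroupCall]:
    """Partition DRM target genes into Group A / Group B.

    Group A: upregulated ("up") in >= 1 experiment; the supporting
    experiment labels are recorded.  Group B: every other target gene.
    """
    up_by_gene: dict[str, list[str]] = {}
    for c in calls:
        if c.direction == "up":
            up_by_gene.setdefault(c.gene_id, []).append(c.experiment_label)
    out = []
    for gene in sorted(set(drm_targets)):
        support = tuple(sorted(up_by_gene.get(gene, [])))
        out.append(
            TargetGroupCall(
                gene_id=gene,
                group="A" if support else "B",
                supporting_experiments=support,
            )
        )
    return out


def group_enrichment(
    targets: set[str], de_set: set[str], universe: set[str]
) -> EnrichmentResult:
    """Hypergeometric enrichment of DRM targets among DE genes.

    k = |targets & de_set| observed among n = |de_set| draws from a
    universe of N genes containing K = |targets| positives.
    """
    if not targets <= universe or not de_set <= universe:
        raise ValueError("targets and de_set must be subsets of the universe")
    return hypergeom_upper_tail(
        k=len(targets & de_set), K=len(targets), n=len(de_set), N=len(universe)
    )


def qpcr_relative_quantity(
    records: Sequence[QpcrRecord], target_gene: str, reference_gene: str
) -> tuple[dict[str, float], float, float]:
    """Efficiency-corrected delta-Ct relative quantity per sample.

    ``Rq = E_ref ** Ct_ref / E_target ** Ct_target`` (with equal
    efficiencies this reduces to ``E ** (Ct_ref - Ct_target)``).  Returns
    (per-sample Rq, mean, SEM); SEM is NaN with fewer than two samples.
    """
    by_sample: dict[str, dict[str, QpcrRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, {})[r.gene_id] = r
    rq: dict[str, float] = {}
    for sample, genes in sorted(by_sample.items()):
        if reference_gene not in genes:
            raise ValueError(f"sample {sample}: reference gene {reference_gene} missing")
        if target_gene not in genes:
            raise ValueError(f"sample {sample}: target gene {target_gene} missing")
        ref, tgt = genes[reference_gene], genes[target_gene]
        rq[sample] = ref.efficiency**ref.ct / tgt.efficiency**tgt.ct
    values = np.array(list(rq.values()))
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else float("nan")
    return rq, mean, sem


def chipqpcr_log2_enrichment(
    ct_chip_target: float,
    ct_input_target: float,
    ct_chip_ctrl: float,
    ct_input_ctrl: float,
) -> float:
    """log2 fold enrichment of ChIP signal at a target vs a control region.

    With amplification efficiency 2 at every amplicon:
    ``(Ct_chip_ctrl - Ct_input_ctrl) - (Ct_chip_target - Ct_input_target)``.
    Antisymmetric under swapping target and control.
    """
    return (ct_chip_ctrl - ct_input_ctrl) - (ct_chip_target - ct_input_target)
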