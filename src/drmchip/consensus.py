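"""High-confidence DRM peak construction by replicate filtering and subunit voting.

The DRM repressor complex is assayed through seven subunit ChIPs (E2F-DP:
DPL-1, EFL-1; the pocket protein LIN-35; MuvB: LIN-9, LIN-37, LIN-52,
LIN-54).  A genomic site counts as DRM-bound when the E2F-DP pair, LIN-35,
and at least k of the four MuvB subunits all leave overlapping peaks there.

Merging is single-linkage: peaks connected by a chain of >= 1 bp overlaps
form one cluster, whose consensus interval is the union span and whose
center is the integer median of member centers (summit when present, else
midpoint).  Replicate reproducibility is the same clustering applied across
replicates of one subunit, keeping clusters seen in >= ``min_replicates``
distinct replicates — a deliberately simple stand-in for an IDR-style
consistency filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic_io import (
    E2FDP_SUBUNITS,
    MUVB_SUBUNITS,
    GenomicInterval,
    Peak,
    PipelineConfig,
)

__all__ = [
    "ConsensusPeak",
    "RetentionCall",
    "cluster_peaks",
    "reproducible_peaks",
    "overlap_vote",
    "consensus_drm",
    "retention_classify",
    "count_region_overlaps",
]


@dataclass
class ConsensusPeak:
    """A merged multi-subunit binding site.

    ``members`` maps each contributing subunit to the names of its member
    peaks; ``n_subunits`` is the number of subunits with >= 1 member.
    """

    id: str
    interval: GenomicInterval
    center: int
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_subunits(self) -> int:
        return sum(1 for v in self.members.values() if v)


@dataclass(frozen=True)
class RetentionCall:
    """Whether a WT DRM peak keeps E2F-DP and/or MuvB occupancy in the mutant."""

    peak_id: str
    e2fdp_retained: bool
    muvb_retained: bool

    @property
    def category(self) -> str:
        if self.e2fdp_retained and self.muvb_retained:
            return "retained_both"
        if self.e2fdp_retained or self.muvb_retained:
            return "retained_one"
        return "lost_both"


def cluster_peaks(peaks: Sequence[Peak]) -> list[list[Peak]]:
    """Single-linkage clusters of overlapping peaks (>= 1 bp, per chromosome).

    For intervals, transitive-overlap components are exactly the runs found
    by a sorted sweep that extends the current cluster while the next
    peak starts before the running maximum end.
    """
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    clusters: list[list[Peak]] = []
    current: list[Peak] = []
    cur_chrom, cur_end = None, -1
    for p in ordered:
        if current and p.interval.chrom == cur_chrom and p.interval.start < cur_end:
            current.append(p)
            cur_end = max(cur_end, p.interval.end)
        else:
            if current:
                clusters.append(current)
            current = [p]
            cur_chrom, cur_end = p.interval.chrom, p.interval.end
    if current:
        clusters.append(current)
    return clusters


def _union_span(members: Sequence[Peak]) -> GenomicInterval:
    return GenomicInterval(
        members[0].interval.chrom,
        min(p.interval.start for p in members),
        max(p.interval.end for p in members),
    )


def _median_int(values: Sequence[int]) -> int:
    return int(np.median(np.asarray(values)))


def reproducible_peaks(
    replicate_sets: Sequence[Sequence[Peak]], min_replicates: int
) -> list[Peak]:
    """Merge one subunit's replicate peak sets, keeping reproducible clusters.

    Clusters whose members come from >= ``min_replicates`` distinct
    replicates emit one merged peak: the union span, with summit at the
    median of member summits (members without a summit contribute their
    midpoint).  Tags (subunit/condition) of the first member are kept.
    """
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    if not replicate_sets:
        raise ValueError("need at least one replicate set")
    if min_replicates > len(replicate_sets):
        raise ValueError("min_replicates exceeds the number of replicates")
    tagged = [
        p.tagged(replicate=str(i))
        for i, rep in enumerate(replicate_sets)
        for p in rep
    ]
    merged: list[Peak] = []
    for cluster in cluster_peaks(tagged):
        if len({p.replicate for p in cluster}) < min_replicates:
            continue
        span = _union_span(cluster)
        summit = _median_int([p.center for p in cluster]) - span.start
        summit = min(max(summit, 0), span.width - 1)
        first = cluster[0]
        merged.append(
            Peak(
                interval=span,
                score=float(np.median([p.score for p in cluster])),
                summit_offset=summit,
                subunit=first.subunit,
                condition=first.condition,
            )
        )
    return merged


def overlap_vote(
    subunit_sets: Mapping[str, Sequence[Peak]], min_subunits: int
) -> list[ConsensusPeak]:
    """Single-linkage merge across subunit peak sets with a k-of-n vote.

    Each cluster with >= ``min_subunits`` distinct subunits represented
    becomes one :class:`ConsensusPeak`; a subunit contributing several peaks
    to a cluster still counts once.
    """
    if min_subunits < 1:
        raise ValueError("min_subunits must be >= 1")
    if min_subunits > len(subunit_sets):
        raise ValueError("min_subunits exceeds the number of subunit sets")
    tagged = [
        p.tagged(subunit=name)
        for name, peaks in subunit_sets.items()
        for p in peaks
    ]
    out: list[ConsensusPeak] = []
    for cluster in cluster_peaks(tagged):
        members: dict[str, list[str]] = {}
        for p in cluster:
            label = p.name if p.name != "." else (
                f"{p.subunit}:{p.interval.chrom}:{p.interval.start}-{p.interval.end}"
            )
            members.setdefault(p.subunit, []).append(label)
        if len(members) < min_subunits:
            continue
        span = _union_span(cluster)
        out.append(
            ConsensusPeak(
                id="",
                interval=span,
                center=_median_int([p.center for p in cluster]),
                members=members,
            )
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    for i, c in enumerate(out):
        c.id = f"peak_{i + 1:05d}"
    return out


def _as_peaks(consensus: Sequence[ConsensusPeak], subunit: str) -> list[Peak]:
    """Represent consensus regions as peaks so they can enter another vote."""
    return [
        Peak(
            interval=c.interval,
            summit_offset=min(max(c.center - c.interval.start, 0), c.interval.width - 1),
            subunit=subunit,
            name=c.id,
        )
        for c in consensus
    ]


def consensus_drm(
    subunit_sets: Mapping[str, Sequence[Peak]],
    config: PipelineConfig | None = None,
) -> list[ConsensusPeak]:
    """Define high-confidence DRM binding sites from the seven subunit sets.

    Three-stage vote: E2F-DP regions require both DPL-1 and EFL-1; MuvB
    regions require >= ``config.muvb_vote_k`` of the four MuvB subunits; a
    DRM site requires the triple overlap of an E2F-DP region, a LIN-35
    peak, and a MuvB region.  The membership map of each DRM peak records
    all original subunits, so every DRM peak carries LIN-35, both E2F-DP
    subunits, and >= k MuvB subunits.
    """
    config = config or PipelineConfig()
    missing = [s for s in E2FDP_SUBUNITS + ("LIN-35",) + MUVB_SUBUNITS if s not in subunit_sets]
    if missing:
        raise ValueError(f"missing subunit peak sets: {missing}")
    e2fdp = overlap_vote({s: subunit_sets[s] for s in E2FDP_SUBUNITS}, 2)
    muvb = overlap_vote({s: subunit_sets[s] for s in MUVB_SUBUNITS}, config.muvb_vote_k)
    e2fdp_by_id = {c.id: c for c in e2fdp}
    muvb_by_id = {c.id: c for c in muvb}
    top = overlap_vote(
        {
            "E2F-DP": _as_peaks(e2fdp, "E2F-DP"),
            "LIN-35": list(subunit_sets["LIN-35"]),
            "MuvB": _as_peaks(muvb, "MuvB"),
        },
        3,
    )
    # Expand the component membership back to original subunits.
    for c in top:
        members: dict[str, list[str]] = {}
        for cid in c.members.get("E2F-DP", []):
            for subunit, names in e2fdp_by_id[cid].members.items():
                members.setdefault(subunit, []).extend(names)
        for cid in c.members.get("MuvB", []):
            for subunit, names in muvb_by_id[cid].members.items():
                members.setdefault(subunit, []).extend(names)
        members["LIN-35"] = list(c.members.get("LIN-35", []))
        c.members = members
    return top


def retention_classify(
    wt_drm: Sequence[ConsensusPeak],
    mut_e2fdp: Sequence[ConsensusPeak] | Sequence[Peak],
    mut_muvb: Sequence[ConsensusPeak] | Sequence[Peak],
) -> list[RetentionCall]:
    """Classify WT DRM peaks by detectable mutant E2F-DP / MuvB occupancy.

    A component is retained when the WT peak overlaps (>= 1 bp) at least
    one mutant consensus region for that component.  The mutant inputs must
    already be consensus regions (E2F-DP pair overlap; MuvB k-of-4 vote)
    built from mutant replicates.
    """

    def _intervals(regions) -> list[GenomicInterval]:
        return [r.interval for r in regions]

    e2fdp_iv = _intervals(mut_e2fdp)
    muvb_iv = _intervals(mut_muvb)
    calls = []
    for peak in wt_drm:
        calls.append(
            RetentionCall(
                peak_id=peak.id,
                e2fdp_retained=any(peak.interval.overlaps(iv) for iv in e2fdp_iv),
                muvb_retained=any(peak.interval.overlaps(iv) for iv in muvb_iv),
            )
        )
    return calls


def count_region_overlaps(
    peaks: Sequence[ConsensusPeak], regions: Sequence[GenomicInterval]
) -> int:
    """Number of peaks overlapping >= 1 region (e.g. embryonic HOT regions)."""
    return sum(
        1 for p in peaks if any(p.interval.overlaps(r) for r in regions)
    )
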