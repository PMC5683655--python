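"""IUPAC motif scanning with a mismatch budget, conservation filtering, and
enrichment statistics.

The two motifs of interest are the E2F-DP binding element (CDE, IUPAC
``BSSSSS``, one mismatch allowed) and the LIN-54/MuvB binding element (CHR,
``TTYRAA``, exact).  Scans cover both strands by default; a reverse-strand
hit is a match of the reverse-complemented pattern against the + sequence,
reported in + coordinates.  ``N`` bases never match any pattern symbol.

Hits can be filtered by phylogenetic conservation: the mean (or minimum)
per-base score over the match span must exceed a threshold (phastCons 0.7
by default).  Region-level presence plus a hypergeometric upper tail give
motif enrichment against background promoters; a 2x2 Pearson chi-squared
compares presence between peak classes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2_contingency, hypergeom

from .genomic_io import ConservationTrack, GenomicInterval, PipelineConfig

__all__ = [
    "IUPAC",
    "MotifPattern",
    "MotifHit",
    "EnrichmentResult",
    "cde_pattern",
    "chr_pattern",
    "reverse_complement",
    "scan_iupac",
    "filter_conserved",
    "region_motif_presence",
    "hypergeom_upper_tail",
    "class_association_chi2",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate DNA motif with a mismatch budget."""

    id: str
    iupac: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty pattern")
        bad = [c for c in self.iupac.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC letters: {bad}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)


def cde_pattern(config: PipelineConfig | None = None) -> MotifPattern:
    config = config or PipelineConfig()
    return MotifPattern("CDE", config.cde_pattern, config.cde_max_mismatch)


def chr_pattern(config: PipelineConfig | None = None) -> MotifPattern:
    config = config or PipelineConfig()
    return MotifPattern("CHR", config.chr_pattern, config.chr_max_mismatch)


@dataclass(frozen=True)
class MotifHit:
    """A motif match at ``chrom:position`` (+ coordinates, 0-based start)."""

    region_id: str
    chrom: str
    position: int
    strand: str
    mismatches: int
    mean_conservation: float = float("nan")
    length: int = 0

    @property
    def end(self) -> int:
        return self.position + self.length


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric upper-tail enrichment of a feature in a target set.

    ``k`` of the ``n`` targets carry the feature, out of ``K``
    feature-positive elements in a universe of ``N``; ``expected = n*K/N``.
    """

    k: int
    K: int
    n: int
    N: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n <= self.N and self.k <= self.K <= self.N):
            raise ValueError("inconsistent counts")

    @property
    def expected(self) -> float:
        return self.n * self.K / self.N


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


def _pattern_table(iupac: str) -> np.ndarray:
    """Boolean (pattern_len, 5) table: does base b match pattern position j?

    Column 4 represents N/unknown bases, which never match.
    """
    table = np.zeros((len(iupac), 5), dtype=bool)
    for j, sym in enumerate(iupac):
        for base in IUPAC[sym]:
            table[j, _BASE_INDEX[base]] = True
    return table


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _mismatch_counts(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Mismatches of every length-L window of ``codes`` against the table."""
    L = table.shape[0]
    n_win = codes.shape[0] - L + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    mism = np.zeros(n_win, dtype=np.int64)
    for j in range(L):
        mism += ~table[j][codes[j : j + n_win]]
    return mism


def scan_iupac(
    sequence: str,
    pattern: MotifPattern,
    strands: str = "both",
    chrom: str = ".",
    offset: int = 0,
    region_id: str = ".",
) -> list[MotifHit]:
    """All windows matching the pattern within the mismatch budget.

    ``offset`` shifts reported positions into genome coordinates when
    ``sequence`` is a slice of a chromosome.  With ``strands="both"``, the
    reverse strand is scanned by matching the reverse-complemented pattern
    against the + sequence; positions stay in + coordinates.
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    bad = set(sequence.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    codes = _encode(sequence)
    hits: list[MotifHit] = []
    jobs = [("+", pattern.iupac)]
    if strands == "both":
        jobs.append(("-", reverse_complement(pattern.iupac)))
    for strand, iupac in jobs:
        mism = _mismatch_counts(codes, _pattern_table(iupac))
        for pos in np.flatnonzero(mism <= pattern.max_mismatch):
            hits.append(
                MotifHit(
                    region_id=region_id,
                    chrom=chrom,
                    position=offset + int(pos),
                    strand=strand,
                    mismatches=int(mism[pos]),
                    length=len(pattern),
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def filter_conserved(
    hits: Sequence[MotifHit],
    track: ConservationTrack,
    threshold: float,
    aggregate: str = "mean",
) -> list[MotifHit]:
    """Keep hits whose aggregated per-base conservation exceeds ``threshold``.

    The aggregate over the match span is the mean by default ("min" gives
    an every-base criterion); the value is stored on the returned hits.
    Comparison is strict (> threshold).
    """
    if aggregate not in ("mean", "min"):
        raise ValueError("aggregate must be 'mean' or 'min'")
    kept = []
    for h in hits:
        fn = track.mean if aggregate == "mean" else track.minimum
        score = fn(h.chrom, h.position, h.position + h.length)
        if score > threshold:
            kept.append(replace(h, mean_conservation=score))
    return kept


def region_motif_presence(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, object],
    pattern: MotifPattern,
    track: ConservationTrack | None = None,
    config: PipelineConfig | None = None,
    region_ids: Sequence[str] | None = None,
) -> list[bool]:
    """Per-region motif presence: >= 1 (conserved) hit fully inside the region.

    ``genome`` is any chrom -> sequence mapping (e.g. a ``pyfaidx.Fasta``).
    A region extending beyond its chromosome raises.
    """
    config = config or PipelineConfig()
    ids = region_ids or [f"region_{i}" for i in range(len(regions))]
    out: list[bool] = []
    for region, rid in zip(regions, ids):
        if region.chrom not in genome:
            raise ValueError(f"unknown chromosome {region.chrom!r}")
        record = genome[region.chrom]
        if region.end > len(record):
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} beyond "
                f"chromosome end ({len(record)})"
            )
        seq = str(record[region.start : region.end])
        hits = scan_iupac(
            seq, pattern, chrom=region.chrom, offset=region.start, region_id=rid
        )
        if track is not None:
            hits = filter_conserved(
                hits,
                track,
                config.conservation_threshold,
                aggregate=config.conservation_aggregate,
            )
        out.append(bool(hits))
    return out


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> EnrichmentResult:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    The universe holds N elements, K of them feature-positive; n are drawn
    (the target set) and k carry the feature.  k = 0 gives p = 1.
    """
    result = EnrichmentResult(k=k, K=K, n=n, N=N, p_value=1.0)  # validates counts
    p = float(hypergeom.sf(k - 1, N, K, n))
    return replace(result, p_value=min(max(p, np.finfo(float).tiny), 1.0))


def class_association_chi2(
    presence: Sequence[bool], classes: Sequence[str]
) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2 table
    of motif presence vs peak class.

    Returns ``(statistic, p)``.  Raises on a zero marginal, where an exact
    test would be needed instead.
    """
    if len(presence) != len(classes):
        raise ValueError("presence and classes must align")
    labels = sorted(set(classes))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 classes, got {labels}")
    table = np.zeros((2, 2), dtype=np.int64)
    for has, cls in zip(presence, classes):
        table[labels.index(cls), 0 if has else 1] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(
            "zero marginal in 2x2 table; use an exact test (not implemented)"
        )
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)
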