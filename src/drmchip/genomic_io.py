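"""Genomic domain types and readers/writers for the tabular formats the pipeline touches.

All coordinates are 0-based, half-open (BED convention).  Any 1-based input
dialect would be converted at the reader boundary; the dialects implemented
here (BED3, BED6, narrowPeak, bedGraph) are already half-open.

Overlap between two intervals means sharing at least one base pair on the
same chromosome; strand is ignored for interval overlap and honoured only
where promoter windows are built (see :mod:`drmchip.annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "ConservationTrack",
    "PipelineConfig",
    "SUBUNITS",
    "MUVB_SUBUNITS",
    "E2FDP_SUBUNITS",
    "read_regions",
    "write_regions",
    "read_gene_models",
    "write_gene_models",
    "read_conservation",
    "query_overlaps",
]

#: The seven DRM subunits assayed by ChIP.
SUBUNITS = ("DPL-1", "EFL-1", "LIN-35", "LIN-9", "LIN-37", "LIN-52", "LIN-54")
E2FDP_SUBUNITS = ("DPL-1", "EFL-1")
MUVB_SUBUNITS = ("LIN-9", "LIN-37", "LIN-52", "LIN-54")


class ParseError(ValueError):
    """A malformed row in a tabular genomic file."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located genomic feature: ``chrom:[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + self.width // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share >= 1 bp (half-open; strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A called ChIP peak: an interval plus optional summit and sample tags."""

    interval: GenomicInterval
    score: float = 0.0
    summit_offset: int | None = None
    subunit: str | None = None
    replicate: str | None = None
    condition: str | None = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.width
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of width "
                f"{self.interval.width}"
            )

    @property
    def center(self) -> int:
        """Summit position when known, otherwise the interval midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint

    def tagged(self, **kwargs) -> "Peak":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware TSS/TTS and an exon chain."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand is required")
        prev_end = None
        for exon in self.exons:
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = exon.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (txStart on +, txEnd on -)."""
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tts(self) -> int:
        """Strand-aware 3' end."""
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.chrom, a.end, b.start))
        return tuple(out)


class ConservationTrack:
    """Per-base conservation scores in [0, 1]; uncovered positions score 0.

    Stored as one dense array per chromosome (sized to the last covered
    base).  Overlapping bedGraph rows are resolved last-wins.
    """

    def __init__(self, arrays: Mapping[str, np.ndarray] | None = None) -> None:
        self._arrays: dict[str, np.ndarray] = dict(arrays or {})

    def score(self, chrom: str, pos: int) -> float:
        arr = self._arrays.get(chrom)
        if arr is None or pos < 0 or pos >= arr.shape[0]:
            return 0.0
        return float(arr[pos])

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base score over [start, end); absent bases count as 0."""
        if end <= start:
            raise ValueError("empty span")
        arr = self._arrays.get(chrom)
        if arr is None:
            return 0.0
        lo, hi = max(start, 0), min(end, arr.shape[0])
        total = float(arr[lo:hi].sum()) if hi > lo else 0.0
        return total / (end - start)

    def minimum(self, chrom: str, start: int, end: int) -> float:
        """Minimum per-base score over [start, end); absent bases count as 0."""
        if end <= start:
            raise ValueError("empty span")
        arr = self._arrays.get(chrom)
        if arr is None:
            return 0.0
        if start < 0 or end > arr.shape[0]:
            return 0.0
        return float(arr[start:end].min())


@dataclass
class PipelineConfig:
    """Every numeric threshold used by the pipeline, in one place.

    Defaults mirror the analysis conditions: a promoter window of
    -1000/+100 bp around the TSS, a +-1000 bp TTS window, FDR alpha 0.05,
    a 3-of-4 MuvB subunit vote, a 2-replicate reproducibility filter, the
    CDE (BSSSSS, <=1 mismatch) and CHR (TTYRAA, exact) motifs, a phastCons
    0.7 conservation cutoff, and q < 0.05 / fold-change > 1.5 expression
    thresholds.
    """

    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    tts_window: int = 1000
    fdr_alpha: float = 0.05
    muvb_vote_k: int = 3
    min_replicates: int = 2
    cde_pattern: str = "BSSSSS"
    cde_max_mismatch: int = 1
    chr_pattern: str = "TTYRAA"
    chr_max_mismatch: int = 0
    conservation_threshold: float = 0.7
    conservation_aggregate: str = "mean"  # "mean" or "min" over the match span
    de_q_threshold: float = 0.05
    de_fc_threshold: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0, 1)")
        if not (0 <= self.conservation_threshold <= 1):
            raise ValueError("conservation_threshold must be in [0, 1]")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")
        if self.muvb_vote_k < 1 or self.muvb_vote_k > len(MUVB_SUBUNITS):
            raise ValueError("muvb_vote_k must be in 1..4")
        if self.conservation_aggregate not in ("mean", "min"):
            raise ValueError("conservation_aggregate must be 'mean' or 'min'")
        if not (0 < self.de_q_threshold <= 1) or self.de_fc_threshold < 1:
            raise ValueError("bad expression thresholds")


# ---------------------------------------------------------------------------
# Readers / writers


def _split_row(line: str, lineno: int, min_fields: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_fields:
        raise ParseError(f"line {lineno}: expected >= {min_fields} fields")
    return fields


def _parse_coords(fields: Sequence[str], lineno: int) -> tuple[str, int, int]:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinate") from exc
    if start >= end or start < 0:
        raise ParseError(f"line {lineno}: invalid interval [{start}, {end})")
    return fields[0], start, end


def read_regions(path: str | Path, dialect: str = "BED3") -> list[Peak]:
    """Read a BED3/BED6/narrowPeak file into a list of :class:`Peak`.

    narrowPeak column 10 (0-based summit offset) becomes ``summit_offset``;
    the sentinel value -1 means no summit was called.
    """
    if dialect not in ("BED3", "BED6", "narrowPeak"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    min_fields = {"BED3": 3, "BED6": 6, "narrowPeak": 10}[dialect]
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_row(line, lineno, min_fields)
            chrom, start, end = _parse_coords(fields, lineno)
            interval_kw = {}
            name, score, summit = ".", 0.0, None
            if dialect in ("BED6", "narrowPeak"):
                name = fields[3]
                score = float(fields[4]) if fields[4] != "." else 0.0
                if fields[5] in ("+", "-"):
                    interval_kw["strand"] = fields[5]
            if dialect == "narrowPeak":
                try:
                    raw = int(fields[9])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: non-integer summit") from exc
                if raw != -1:
                    if not (0 <= raw < end - start):
                        raise ParseError(f"line {lineno}: summit outside peak")
                    summit = raw
                score = float(fields[6])  # signalValue is the usual score column
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, **interval_kw),
                    score=score,
                    summit_offset=summit,
                    name=name,
                )
            )
    return peaks


def write_regions(peaks: Iterable[Peak], path: str | Path, dialect: str = "BED3") -> None:
    """Write peaks in the given dialect (inverse of :func:`read_regions`)."""
    if dialect not in ("BED3", "BED6", "narrowPeak"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if dialect == "BED3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "BED6":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}\t"
                    f"{iv.strand if iv.strand != '.' else '.'}\n"
                )
            else:
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t.\t"
                    f"{p.score:g}\t-1\t-1\t{summit}\n"
                )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a TSV of
    ``gene_id  chrom  strand  txStart  txEnd  exonStarts  exonEnds``
    with comma-separated exon lists (trailing commas tolerated).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_row(line, lineno, 7)
            gene_id, chrom, strand = fields[0], fields[1], fields[2]
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: strand must be + or -")
            try:
                tx_start, tx_end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            starts = [int(x) for x in fields[5].rstrip(",").split(",") if x]
            ends = [int(x) for x in fields[6].rstrip(",").split(",") if x]
            if len(starts) != len(ends):
                raise ParseError(f"line {lineno}: exon start/end lists differ in length")
            exons = tuple(GenomicInterval(chrom, s, e) for s, e in zip(starts, ends))
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    interval=GenomicInterval(chrom, tx_start, tx_end, strand),
                    exons=exons,
                )
            )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\n")
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons)
            ends = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.interval.chrom}\t{g.strand}\t"
                f"{g.interval.start}\t{g.interval.end}\t{starts}\t{ends}\n"
            )


def read_conservation(path: str | Path) -> ConservationTrack:
    """Read a bedGraph (chrom, start, end, value; half-open) into a track.

    Every covered base maps to the row's value; where rows overlap, the
    later row wins.  Values must lie in [0, 1].
    """
    rows: dict[str, list[tuple[int, int, float]]] = {}
    maxend: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split_row(line, lineno, 4)
            chrom, start, end = _parse_coords(fields, lineno)
            value = float(fields[3])
            if not (0.0 <= value <= 1.0):
                raise ParseError(f"line {lineno}: score {value} outside [0, 1]")
            rows.setdefault(chrom, []).append((start, end, value))
            maxend[chrom] = max(maxend.get(chrom, 0), end)
    arrays = {}
    for chrom, chrom_rows in rows.items():
        arr = np.zeros(maxend[chrom], dtype=np.float32)
        for start, end, value in chrom_rows:  # file order => last wins
            arr[start:end] = value
        arrays[chrom] = arr
    return ConservationTrack(arrays)


# ---------------------------------------------------------------------------
# Interval queries


def query_overlaps(
    query: GenomicInterval, subjects: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Subjects sharing >= 1 bp with the query (half-open, strand ignored)."""
    return [s for s in subjects if query.overlaps(s)]
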