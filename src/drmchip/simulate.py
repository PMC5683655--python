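"""Seeded generator of a complete toy dataset with machine-readable truth.

The generator emulates the statistical structure of a two-genotype,
seven-subunit DRM ChIP experiment on a miniature diploid-free genome:

* a gene catalogue on 2 chromosomes of 1 Mb, 400 genes, 30% of them in
  divergent (head-to-head) pairs whose promoter windows share sequence;
* 150 co-bound sites planted inside promoter windows, each detected
  independently by every subunit in every replicate with probability 0.9
  (WT), with Gaussian boundary jitter (sd 50 bp) and peak widths
  N(300, 100), plus 30 random noise peaks per subunit and replicate;
* genotype-dependent occupancy: 60% of sites drop strongly in the mutant
  (per-subunit log2 fold change ~ N(-2, 0.5); truth Class I), the rest
  weakly (N(-0.3, 0.2); truth Class II), realized as negative-binomial
  fragment counts (baseline mean 200, dispersion 0.05, 3 replicates per
  genotype, per-sample size factors ~ U(0.7, 1.4));
* mutant peak calls that follow a planted retention pattern (40% of sites
  keep both E2F-DP and MuvB, 45% keep neither, 15% keep one);
* CHR motifs planted in 60% and CDE motifs in 45% of sites, as exact
  pattern instances on a GC ~= 0.36 background, with per-base conservation
  U(0.8, 1.0) over planted spans and Beta(1, 3) elsewhere near sites
  (bases far from any site are simply absent from the track, scoring 0);
* an expression table in which 40% of bound genes are upregulated in at
  least one of three mutant-vs-WT experiments (log2FC ~ N(1.2, 0.3),
  q ~ U(0.001, 0.04)), defining the true Group A set;
* RT-qPCR and ChIP-qPCR Ct tables consistent with the planted effects,
  and a toy HOT-region BED.

Determinism: each component draws from ``numpy.random.default_rng([seed,
component_id])`` with fixed component ids, so identical (params, seed)
produce byte-identical output files and components can be regenerated
independently.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    MUVB_SUBUNITS,
    E2FDP_SUBUNITS,
    SUBUNITS,
    GeneModel,
    GenomicInterval,
    Peak,
    write_gene_models,
    write_regions,
)
from .occupancy import TESTED_SUBUNITS, CountMatrix

__all__ = [
    "ScenarioParams",
    "SiteTruth",
    "SyntheticTruth",
    "SyntheticBundle",
    "generate_scenario",
    "generate_counts",
    "generate_sequences",
    "null_truth",
    "write_bundle",
]

# Component ids for derived RNG streams.
_RNG_GENES, _RNG_SITES, _RNG_PEAKS, _RNG_COUNTS = 0, 1, 2, 3
_RNG_SEQ, _RNG_EXPR, _RNG_QPCR, _RNG_HOT = 4, 5, 6, 7

_SITE_HALF_WIDTH = 75  # planted site span = center +- 75 bp
_CDE_OFFSET = -40  # motif plant positions relative to the site center
_CHR_OFFSET = 20
_CONS_MARGIN = 100  # conservation is emitted over site span +- margin


@dataclass
class ScenarioParams:
    """Generator parameters; defaults define the standard study conditions."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 400
    divergent_pair_fraction: float = 0.3
    n_sites: int = 150
    detection_prob: float = 0.9
    detection_prob_mut: float | None = None  # None => same as detection_prob
    jitter_sd: float = 50.0
    peak_width_mean: float = 300.0
    peak_width_sd: float = 100.0
    noise_peaks: int = 30
    n_replicates: int = 3
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    strong_fraction: float = 0.6
    strong_lfc_mean: float = -2.0
    strong_lfc_sd: float = 0.5
    weak_lfc_mean: float = -0.3
    weak_lfc_sd: float = 0.2
    retention_both: float = 0.40
    retention_none: float = 0.45
    retention_one: float = 0.15
    motif_rate_chr: float = 0.6
    motif_rate_cde: float = 0.45
    cons_planted_low: float = 0.8
    cons_planted_high: float = 1.0
    cons_background_a: float = 1.0
    cons_background_b: float = 3.0
    gc_content: float = 0.36
    group_a_fraction: float = 0.4
    group_a_lfc_mean: float = 1.2
    group_a_lfc_sd: float = 0.3
    group_a_q_low: float = 0.001
    group_a_q_high: float = 0.04
    background_up_fraction: float = 0.1
    size_factor_low: float = 0.7
    size_factor_high: float = 1.4
    hot_fraction: float = 0.3

    def __post_init__(self) -> None:
        probs = [
            self.divergent_pair_fraction,
            self.detection_prob,
            self.strong_fraction,
            self.retention_both,
            self.retention_none,
            self.retention_one,
            self.motif_rate_chr,
            self.motif_rate_cde,
            self.group_a_fraction,
            self.background_up_fraction,
            self.hot_fraction,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(self.retention_both + self.retention_none + self.retention_one - 1.0) > 1e-9:
            raise ValueError("retention fractions must sum to 1")


@dataclass
class SiteTruth:
    """Everything planted at one co-bound site."""

    site_id: str
    chrom: str
    center: int
    start: int
    end: int
    target_genes: list[str]
    class_label: str  # I (strong drop) | II (weak drop)
    lfc_per_subunit: dict[str, float]
    retention: str  # retained_both | lost_both | retained_one
    retained_component: str | None  # e2fdp | muvb, set when retention_one
    cde_planted: bool
    chr_planted: bool
    cde_position: int | None = None
    chr_position: int | None = None
    cde_sequence: str | None = None
    chr_sequence: str | None = None
    is_hot: bool = False

    @property
    def e2fdp_retained(self) -> bool:
        return self.retention == "retained_both" or self.retained_component == "e2fdp"

    @property
    def muvb_retained(self) -> bool:
        return self.retention == "retained_both" or self.retained_component == "muvb"


@dataclass
class SyntheticTruth:
    """The planted ground truth: the oracle for every pipeline stage."""

    seed: int
    params: ScenarioParams
    sites: list[SiteTruth]
    bound_genes: list[str]
    group_a_genes: list[str]
    size_factors: dict[str, float]
    version: int = 1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "params": asdict(self.params),
            "sites": [asdict(s) for s in self.sites],
            "bound_genes": self.bound_genes,
            "group_a_genes": self.group_a_genes,
            "size_factors": self.size_factors,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            seed=payload["seed"],
            params=ScenarioParams(**payload["params"]),
            sites=[SiteTruth(**s) for s in payload["sites"]],
            bound_genes=payload["bound_genes"],
            group_a_genes=payload["group_a_genes"],
            size_factors=payload["size_factors"],
            version=payload["version"],
        )


@dataclass
class SyntheticBundle:
    """In-memory view of the generated dataset."""

    truth: SyntheticTruth
    genes: list[GeneModel]
    wt_peaks: dict[str, list[list[Peak]]]  # subunit -> per-replicate peak lists
    mut_peaks: dict[str, list[list[Peak]]]
    counts: CountMatrix
    genome: dict[str, str]
    conservation_rows: list[tuple[str, int, int, float]]
    expression: pd.DataFrame
    rt_qpcr: pd.DataFrame
    chip_qpcr: pd.DataFrame
    hot_regions: list[GenomicInterval]


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(component)])


def _exact_subset(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean mask with round(fraction * n) True entries, randomly placed."""
    k = round(fraction * n)
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:k]] = True
    return mask


# ---------------------------------------------------------------------------
# Gene catalogue and sites


def _generate_genes(params: ScenarioParams, seed: int):
    """Lay out genes in fixed-width slots; some slots host divergent pairs.

    Returns (genes, hosts) where hosts is a list of candidate site hosts:
    ('single', gene) or ('pair', left_gene, right_gene).
    """
    rng = _rng(seed, _RNG_GENES)
    n_pairs = round(params.divergent_pair_fraction * params.n_genes / 2)
    n_single = params.n_genes - 2 * n_pairs
    n_slots = n_single + n_pairs
    total_len = params.n_chroms * params.chrom_length
    slots_per_chrom = [n_slots // params.n_chroms] * params.n_chroms
    for i in range(n_slots % params.n_chroms):
        slots_per_chrom[i] += 1
    slot_len = params.chrom_length // max(slots_per_chrom)
    if slot_len < 4200:  # pair: 2 genes (>= 800) + gap (<= 800) + margins
        raise ValueError(
            f"infeasible packing: {params.n_genes} genes on {total_len} bp"
        )
    pair_mask = np.zeros(n_slots, dtype=bool)
    pair_mask[rng.permutation(n_slots)[:n_pairs]] = True

    genes: list[GeneModel] = []
    hosts: list[tuple] = []
    slot_idx = 0
    gene_idx = 0

    def _exons(chrom: str, start: int, end: int) -> tuple[GenomicInterval, ...]:
        length = end - start
        if length < 300:
            return (GenomicInterval(chrom, start, end),)
        e1 = start + int(rng.integers(80, length // 3))
        i1 = e1 + int(rng.integers(40, 120))
        e2 = i1 + int(rng.integers(80, max(81, (end - i1) // 2)))
        i2 = min(e2 + int(rng.integers(40, 120)), end - 80)
        if i2 <= e2:
            return (
                GenomicInterval(chrom, start, e1),
                GenomicInterval(chrom, i1, end),
            )
        return (
            GenomicInterval(chrom, start, e1),
            GenomicInterval(chrom, i1, e2),
            GenomicInterval(chrom, i2, end),
        )

    for c in range(params.n_chroms):
        chrom = f"chr{'I' * (c + 1)}"
        for s in range(slots_per_chrom[c]):
            a = s * slot_len
            if pair_mask[slot_idx]:
                gap = int(rng.integers(200, 800))
                gene_len_l = int(rng.integers(800, 2000))
                gene_len_r = int(rng.integers(800, 2000))
                mid = a + slot_len // 2
                tss_l = mid - gap // 2
                left = GeneModel(
                    gene_id=f"gene_{gene_idx + 1:04d}",
                    interval=GenomicInterval(chrom, tss_l - gene_len_l, tss_l, "-"),
                    exons=_exons(chrom, tss_l - gene_len_l, tss_l),
                )
                tss_r = tss_l + gap
                right = GeneModel(
                    gene_id=f"gene_{gene_idx + 2:04d}",
                    interval=GenomicInterval(chrom, tss_r, tss_r + gene_len_r, "+"),
                    exons=_exons(chrom, tss_r, tss_r + gene_len_r),
                )
                genes.extend([left, right])
                hosts.append(("pair", left, right))
                gene_idx += 2
            else:
                gene_len = int(rng.integers(800, 2400))
                strand = "+" if rng.random() < 0.5 else "-"
                start = a + (slot_len - gene_len) // 2
                gene = GeneModel(
                    gene_id=f"gene_{gene_idx + 1:04d}",
                    interval=GenomicInterval(chrom, start, start + gene_len, strand),
                    exons=_exons(chrom, start, start + gene_len),
                )
                genes.append(gene)
                hosts.append(("single", gene))
                gene_idx += 1
            slot_idx += 1
    return genes, hosts


def _generate_sites(params: ScenarioParams, seed: int, hosts: list[tuple]) -> list[SiteTruth]:
    rng = _rng(seed, _RNG_SITES)
    if params.n_sites > len(hosts):
        raise ValueError("more sites than available gene hosts")
    chosen = rng.choice(len(hosts), size=params.n_sites, replace=False)
    chosen.sort()
    strong = _exact_subset(rng, params.n_sites, params.strong_fraction)
    # Retention: exact planted proportions, assigned by one permutation.
    n_both = round(params.retention_both * params.n_sites)
    n_none = round(params.retention_none * params.n_sites)
    order = rng.permutation(params.n_sites)
    retention = np.full(params.n_sites, "retained_one", dtype=object)
    retention[order[:n_both]] = "retained_both"
    retention[order[n_both : n_both + n_none]] = "lost_both"
    cde_mask = _exact_subset(rng, params.n_sites, params.motif_rate_cde)
    chr_mask = _exact_subset(rng, params.n_sites, params.motif_rate_chr)

    sites: list[SiteTruth] = []
    for i, host_idx in enumerate(chosen):
        host = hosts[host_idx]
        if host[0] == "pair":
            left, right = host[1], host[2]
            chrom = left.interval.chrom
            center = (left.tss + right.tss) // 2
            targets = [left.gene_id, right.gene_id]
        else:
            gene = host[1]
            chrom = gene.interval.chrom
            offset = int(rng.integers(150, 900))
            center = gene.tss - offset if gene.strand == "+" else gene.tss + offset
            targets = [gene.gene_id]
        if strong[i]:
            lfc = rng.normal(params.strong_lfc_mean, params.strong_lfc_sd, len(TESTED_SUBUNITS))
            label = "I"
        else:
            lfc = rng.normal(params.weak_lfc_mean, params.weak_lfc_sd, len(TESTED_SUBUNITS))
            label = "II"
        retained_component = None
        if retention[i] == "retained_one":
            retained_component = "e2fdp" if rng.random() < 0.5 else "muvb"
        sites.append(
            SiteTruth(
                site_id=f"site_{i + 1:04d}",
                chrom=chrom,
                center=center,
                start=center - _SITE_HALF_WIDTH,
                end=center + _SITE_HALF_WIDTH,
                target_genes=targets,
                class_label=label,
                lfc_per_subunit={
                    s: float(v) for s, v in zip(TESTED_SUBUNITS, lfc)
                },
                retention=str(retention[i]),
                retained_component=retained_component,
                cde_planted=bool(cde_mask[i]),
                chr_planted=bool(chr_mask[i]),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Peaks


def _site_peak(
    rng: np.random.Generator,
    chrom: str,
    center: int,
    width: int,
    params: ScenarioParams,
    subunit: str,
    replicate: int,
    condition: str,
) -> Peak:
    """One replicate's call of a planted site: fixed width, jittered span.

    The summit always points at the true site center, so consensus centers
    are exact; jitter only moves the boundaries.
    """
    jitter = int(round(rng.normal(0.0, params.jitter_sd))) if params.jitter_sd > 0 else 0
    start = max(0, center - width // 2 + jitter)
    summit = min(max(center - start, 0), width - 1)
    return Peak(
        interval=GenomicInterval(chrom, start, start + width),
        score=10.0,
        summit_offset=summit,
        subunit=subunit,
        replicate=f"rep{replicate + 1}",
        condition=condition,
    )


def _noise_peak(
    rng: np.random.Generator,
    params: ScenarioParams,
    subunit: str,
    replicate: int,
    condition: str,
) -> Peak:
    c = int(rng.integers(0, params.n_chroms))
    chrom = f"chr{'I' * (c + 1)}"
    width = max(60, int(round(rng.normal(params.peak_width_mean, params.peak_width_sd))))
    center = int(rng.integers(500, params.chrom_length - 500))
    start = max(0, center - width // 2)
    return Peak(
        interval=GenomicInterval(chrom, start, start + width),
        score=float(np.round(rng.uniform(2.0, 20.0), 3)),
        summit_offset=width // 2,
        subunit=subunit,
        replicate=f"rep{replicate + 1}",
        condition=condition,
    )


def _generate_peaks(params: ScenarioParams, seed: int, sites: Sequence[SiteTruth]):
    rng = _rng(seed, _RNG_PEAKS)
    p_mut = params.detection_prob_mut
    if p_mut is None:
        p_mut = params.detection_prob
    # Width is a property of the (site, subunit) pair; replicates only jitter
    # boundaries.  With detection 1.0 and zero jitter, replicate peak sets
    # at planted sites are identical.
    widths = {
        (site.site_id, subunit): max(
            60, int(round(rng.normal(params.peak_width_mean, params.peak_width_sd)))
        )
        for site in sites
        for subunit in SUBUNITS
    }
    wt: dict[str, list[list[Peak]]] = {}
    mut: dict[str, list[list[Peak]]] = {}
    for subunit in SUBUNITS:
        wt[subunit] = []
        mut[subunit] = []
        for rep in range(params.n_replicates):
            for condition, store, p_detect in (
                ("WT", wt, params.detection_prob),
                ("mutant", mut, p_mut),
            ):
                peaks: list[Peak] = []
                for site in sites:
                    present = condition == "WT" or (
                        subunit in E2FDP_SUBUNITS and site.e2fdp_retained
                    ) or (subunit in MUVB_SUBUNITS and site.muvb_retained)
                    # LIN-35 is a protein null in the mutant: never present.
                    if condition == "mutant" and subunit == "LIN-35":
                        present = False
                    if present and rng.random() < p_detect:
                        peaks.append(
                            _site_peak(
                                rng,
                                site.chrom,
                                site.center,
                                widths[(site.site_id, subunit)],
                                params,
                                subunit,
                                rep,
                                condition,
                            )
                        )
                for _ in range(params.noise_peaks):
                    peaks.append(_noise_peak(rng, params, subunit, rep, condition))
                peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
                store[subunit].append(peaks)
    return wt, mut


# ---------------------------------------------------------------------------
# Counts


def generate_counts(
    truth: SyntheticTruth, params: ScenarioParams | None = None, seed: int | None = None
) -> CountMatrix:
    """Negative-binomial fragment counts for (site, subunit) rows.

    ``counts ~ NB(mean = baseline * 2^(lfc * is_mutant) * size_factor_j,
    dispersion)`` via the gamma-Poisson mixture.  Per-sample size factors
    are drawn U(0.7, 1.4) and recorded in ``truth.size_factors``.
    """
    params = params or truth.params
    seed = truth.seed if seed is None else seed
    rng = _rng(seed, _RNG_COUNTS)
    samples = [f"wt_{r + 1}" for r in range(params.n_replicates)] + [
        f"mut_{r + 1}" for r in range(params.n_replicates)
    ]
    conditions = ["WT"] * params.n_replicates + ["mutant"] * params.n_replicates
    sf = rng.uniform(params.size_factor_low, params.size_factor_high, len(samples))
    truth.size_factors = {s: float(np.round(v, 6)) for s, v in zip(samples, sf)}
    index = pd.MultiIndex.from_tuples(
        [(site.site_id, su) for site in truth.sites for su in TESTED_SUBUNITS],
        names=["peak_id", "subunit"],
    )
    shape = 1.0 / params.dispersion
    data = np.zeros((len(index), len(samples)), dtype=np.int64)
    for i, (site_id, subunit) in enumerate(index):
        site = truth.sites[i // len(TESTED_SUBUNITS)]
        lfc = site.lfc_per_subunit[subunit]
        for j, (sample, cond) in enumerate(zip(samples, conditions)):
            mean = params.baseline_mean * sf[j]
            if cond == "mutant":
                mean *= 2.0**lfc
            lam = rng.gamma(shape=shape, scale=mean / shape)
            data[i, j] = rng.poisson(lam)
    counts = pd.DataFrame(data, index=index, columns=samples)
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "replicate": [s.split("_")[1] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(counts, meta)


# ---------------------------------------------------------------------------
# Genome sequence and conservation


def _instantiate(rng: np.random.Generator, iupac: str) -> str:
    from .motifs import IUPAC

    return "".join(rng.choice(sorted(IUPAC[sym])) for sym in iupac)


def generate_sequences(
    truth: SyntheticTruth, params: ScenarioParams | None = None, seed: int | None = None
):
    """Random genome (GC ~= gc_content) with planted motif instances, plus
    per-base conservation rows near sites.

    Planted motifs are exact (0-mismatch) instances of the CDE/CHR
    patterns; conservation over planted spans is drawn U(0.8, 1.0) per
    base, and Beta(1, 3) over the rest of each site neighbourhood.  Bases
    outside site neighbourhoods are absent from the track (score 0).
    Returns ``(genome, conservation_rows)`` and records plant positions and
    instantiated sequences on the truth sites.
    """
    params = params or truth.params
    seed = truth.seed if seed is None else seed
    rng = _rng(seed, _RNG_SEQ)
    gc = params.gc_content
    base_probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: dict[str, np.ndarray] = {}
    for c in range(params.n_chroms):
        chrom = f"chr{'I' * (c + 1)}"
        idx = rng.choice(4, size=params.chrom_length, p=base_probs)
        genome[chrom] = base_codes[idx]
    cde = PipelineDefaults.cde
    chrm = PipelineDefaults.chr_
    cons_rows: list[tuple[str, int, int, float]] = []
    for site in truth.sites:
        arr = genome[site.chrom]
        if site.cde_planted:
            pos = site.center + _CDE_OFFSET
            inst = _instantiate(rng, cde)
            arr[pos : pos + len(inst)] = np.frombuffer(inst.encode(), dtype=np.uint8)
            site.cde_position, site.cde_sequence = pos, inst
        if site.chr_planted:
            pos = site.center + _CHR_OFFSET
            inst = _instantiate(rng, chrm)
            arr[pos : pos + len(inst)] = np.frombuffer(inst.encode(), dtype=np.uint8)
            site.chr_position, site.chr_sequence = pos, inst
        lo = max(0, site.start - _CONS_MARGIN)
        hi = min(params.chrom_length, site.end + _CONS_MARGIN)
        scores = rng.beta(params.cons_background_a, params.cons_background_b, hi - lo)
        for pos, length in (
            (site.cde_position, len(cde) if site.cde_planted else 0),
            (site.chr_position, len(chrm) if site.chr_planted else 0),
        ):
            if pos is not None and length:
                scores[pos - lo : pos - lo + length] = rng.uniform(
                    params.cons_planted_low, params.cons_planted_high, length
                )
        for offset, value in enumerate(scores):
            cons_rows.append((site.chrom, lo + offset, lo + offset + 1, float(np.round(value, 4))))
    genome_str = {chrom: arr.tobytes().decode("ascii") for chrom, arr in genome.items()}
    return genome_str, cons_rows


class PipelineDefaults:
    """Motif strings used by the generator (kept in sync with PipelineConfig)."""

    cde = "BSSSSS"
    chr_ = "TTYRAA"


# ---------------------------------------------------------------------------
# Expression and qPCR


def _generate_expression(
    params: ScenarioParams, seed: int, truth: SyntheticTruth, all_genes: Sequence[str]
) -> pd.DataFrame:
    rng = _rng(seed, _RNG_EXPR)
    experiments = ("lin35_EE", "lin35_L1", "lin54_ME")
    bound = sorted({g for s in truth.sites for g in s.target_genes})
    truth.bound_genes = bound
    up_mask = _exact_subset(rng, len(bound), params.group_a_fraction)
    planted_up = {g for g, m in zip(bound, up_mask) if m}
    unbound = [g for g in all_genes if g not in set(bound)]
    bg_mask = _exact_subset(rng, len(unbound), params.background_up_fraction)
    background_up = {g for g, m in zip(unbound, bg_mask) if m}

    lfc_cut = math.log2(1.5)
    rows = []
    group_a: set[str] = set()
    for gene in all_genes:
        if gene in planted_up or gene in background_up:
            n_exp = int(rng.integers(1, len(experiments) + 1))
            chosen = set(rng.choice(len(experiments), size=n_exp, replace=False))
        else:
            chosen = set()
        for e_idx, exp in enumerate(experiments):
            if e_idx in chosen:
                lfc = float(rng.normal(params.group_a_lfc_mean, params.group_a_lfc_sd))
                q = float(rng.uniform(params.group_a_q_low, params.group_a_q_high))
            else:
                lfc = float(rng.normal(0.0, 0.2))
                q = float(rng.uniform(0.1, 1.0))
            rows.append((gene, exp, round(lfc, 4), round(q, 5)))
            if gene in set(truth.bound_genes) and q < 0.05 and lfc > lfc_cut:
                group_a.add(gene)
    truth.group_a_genes = sorted(group_a)
    return pd.DataFrame(rows, columns=["gene_id", "experiment", "log2fc", "q_value"])


def _generate_qpcr(params: ScenarioParams, seed: int, truth: SyntheticTruth):
    rng = _rng(seed, _RNG_QPCR)
    genes = truth.group_a_genes[:4] or truth.bound_genes[:4]
    rt_rows = []
    for gene in genes:
        lfc = float(rng.uniform(1.0, 2.5))  # planted late-embryo upregulation
        for cond, shift in (("WT", 0.0), ("mutant", -lfc)):
            for r in range(4):
                sample = f"{cond}_{r + 1}"
                rt_rows.append((sample, "act-2", round(float(rng.normal(15.0, 0.15)), 3), 2.0, cond))
                rt_rows.append(
                    (sample, gene, round(float(rng.normal(22.0 + shift, 0.15)), 3), 2.0, cond)
                )
    rt = pd.DataFrame(
        rt_rows, columns=["sample_id", "gene_id", "ct", "efficiency", "condition"]
    ).drop_duplicates(subset=["sample_id", "gene_id"], keep="first")

    chip_rows = []
    for site in truth.sites[:6]:
        for cond in ("WT", "mutant"):
            log2fe = float(rng.uniform(2.0, 5.0))
            if cond == "mutant":
                log2fe = max(0.0, log2fe + float(np.mean(list(site.lfc_per_subunit.values()))))
            ct_input_t, ct_input_c = 20.0, 20.0
            ct_chip_c = 30.0
            ct_chip_t = ct_chip_c - log2fe  # efficiency-2 arithmetic
            chip_rows.append(
                (
                    site.site_id,
                    cond,
                    round(ct_chip_t, 3),
                    round(ct_input_t, 3),
                    round(ct_chip_c, 3),
                    round(ct_input_c, 3),
                    round(log2fe, 3),
                )
            )
    chip = pd.DataFrame(
        chip_rows,
        columns=[
            "region",
            "condition",
            "ct_chip_target",
            "ct_input_target",
            "ct_chip_ctrl",
            "ct_input_ctrl",
            "true_log2fe",
        ],
    )
    return rt, chip


def _generate_hot(params: ScenarioParams, seed: int, truth: SyntheticTruth) -> list[GenomicInterval]:
    rng = _rng(seed, _RNG_HOT)
    mask = _exact_subset(rng, len(truth.sites), params.hot_fraction)
    regions = []
    for site, is_hot in zip(truth.sites, mask):
        site.is_hot = bool(is_hot)
        if is_hot:
            regions.append(GenomicInterval(site.chrom, max(0, site.start - 200), site.end + 200))
    # A few HOT regions away from any site (rejection-sampled so they never
    # touch a planted site's neighbourhood).
    placed = 0
    while placed < 10:
        c = int(rng.integers(0, params.n_chroms))
        chrom = f"chr{'I' * (c + 1)}"
        start = int(rng.integers(0, params.chrom_length - 600))
        candidate = GenomicInterval(chrom, start, start + 500)
        near_site = any(
            s.chrom == chrom and start < s.end + 400 and s.start - 400 < start + 500
            for s in truth.sites
        )
        if not near_site:
            regions.append(candidate)
            placed += 1
    regions.sort()
    return regions


def null_truth(n_sites: int, params: ScenarioParams, seed: int) -> SyntheticTruth:
    """A truth object with zero planted effects at every site.

    Useful for calibration runs: counts generated from it are null rows
    (no occupancy change), the regime where type-I error and size-factor
    recovery are well defined.
    """
    sites = [
        SiteTruth(
            site_id=f"null_{i:04d}",
            chrom="chrI",
            start=i * 1000,
            end=i * 1000 + 150,
            center=i * 1000 + 75,
            target_genes=[],
            class_label="II",
            lfc_per_subunit={s: 0.0 for s in TESTED_SUBUNITS},
            retention="retained_both",
            retained_component=None,
            cde_planted=False,
            chr_planted=False,
        )
        for i in range(n_sites)
    ]
    return SyntheticTruth(
        seed=seed, params=params, sites=sites, bound_genes=[], group_a_genes=[], size_factors={}
    )


# ---------------------------------------------------------------------------
# Top-level


def generate_scenario(
    params: ScenarioParams | None = None, seed: int = 0
) -> SyntheticBundle:
    """Generate the full synthetic dataset and its truth object."""
    params = params or ScenarioParams()
    genes, hosts = _generate_genes(params, seed)
    sites = _generate_sites(params, seed, hosts)
    truth = SyntheticTruth(
        seed=seed,
        params=params,
        sites=sites,
        bound_genes=[],
        group_a_genes=[],
        size_factors={},
    )
    wt_peaks, mut_peaks = _generate_peaks(params, seed, sites)
    counts = generate_counts(truth, params, seed)
    genome, cons_rows = generate_sequences(truth, params, seed)
    expression = _generate_expression(params, seed, truth, [g.gene_id for g in genes])
    rt_qpcr, chip_qpcr = _generate_qpcr(params, seed, truth)
    hot = _generate_hot(params, seed, truth)
    return SyntheticBundle(
        truth=truth,
        genes=genes,
        wt_peaks=wt_peaks,
        mut_peaks=mut_peaks,
        counts=counts,
        genome=genome,
        conservation_rows=cons_rows,
        expression=expression,
        rt_qpcr=rt_qpcr,
        chip_qpcr=chip_qpcr,
        hot_regions=hot,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom in sorted(bundle.genome):
            fh.write(f">{chrom}\n")
            seq = bundle.genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["genome"] = fasta

    genes_path = outdir / "genes.tsv"
    write_gene_models(bundle.genes, genes_path)
    paths["genes"] = genes_path

    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for cond, store in (("wt", bundle.wt_peaks), ("mut", bundle.mut_peaks)):
        for subunit, reps in store.items():
            for r, peaks in enumerate(reps):
                p = peak_dir / f"{cond}_{subunit}_rep{r + 1}.narrowPeak"
                write_regions(peaks, p, dialect="narrowPeak")
                paths[f"peaks/{cond}/{subunit}/rep{r + 1}"] = p

    bundle.counts.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    paths["counts"] = outdir / "counts.tsv"
    paths["samples"] = outdir / "samples.tsv"

    cons_path = outdir / "conservation.bedGraph"
    with open(cons_path, "w") as fh:
        for chrom, start, end, value in bundle.conservation_rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.4f}\n")
    paths["conservation"] = cons_path

    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    bundle.rt_qpcr.to_csv(outdir / "qpcr_rt.tsv", sep="\t", index=False)
    bundle.chip_qpcr.to_csv(outdir / "qpcr_chip.tsv", sep="\t", index=False)
    paths["expression"] = outdir / "expression.tsv"
    paths["qpcr_rt"] = outdir / "qpcr_rt.tsv"
    paths["qpcr_chip"] = outdir / "qpcr_chip.tsv"

    hot_path = outdir / "hot_regions.bed"
    with open(hot_path, "w") as fh:
        for r in bundle.hot_regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    paths["hot"] = hot_path

    bundle.truth.to_json(outdir / "truth.json")
    paths["truth"] = outdir / "truth.json"
    return paths
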