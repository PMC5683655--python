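"""Differential chromatin occupancy between genotypes at consensus peaks.

Counts of ChIP fragments per (peak, subunit) row and per sample are
normalized by median-of-ratios size factors and tested for a genotype
effect with a negative-binomial Wald test using a method-of-moments
dispersion estimate.  Peaks are then classified: Class I when at least one
subunit shows a significant occupancy decrease in the mutant at
BH FDR < alpha, Class II otherwise.  LIN-35 is excluded from testing in a
LIN-35 protein-null mutant, leaving six tested subunits.

Statistical model, per row: normalized counts ``y_ij = c_ij / s_j``; group
means ``mu_WT``, ``mu_mut``; dispersion
``alpha_hat = max(eps, (pooled within-group variance - pooled mean) / pooled mean^2)``
with ``eps = 1e-8``; ``log2fc = log2((mu_mut + 0.5) / (mu_WT + 0.5))``;
``SE^2 = (1/ln2)^2 * [(1/n_WT)(1/(mu_WT + 0.5) + alpha_hat)
+ (1/n_mut)(1/(mu_mut + 0.5) + alpha_hat)]``; ``z = log2fc / SE``; p is the
two-sided standard-normal tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .consensus import ConsensusPeak
from .genomic_io import GenomicInterval, PipelineConfig

__all__ = [
    "TESTED_SUBUNITS",
    "CountMatrix",
    "DifferentialResult",
    "PeakClassCall",
    "count_fragments",
    "size_factors",
    "nb_wald_test",
    "nb_wald_table",
    "bh_fdr",
    "classify_peaks",
]

#: Subunits tested for differential occupancy in the pocket-protein null
#: (LIN-35 is excluded: its ChIP in the null genotype is a negative control).
TESTED_SUBUNITS = ("DPL-1", "EFL-1", "LIN-9", "LIN-37", "LIN-52", "LIN-54")

_DISPERSION_EPS = 1e-8
_PSEUDOCOUNT = 0.5


class CountMatrix:
    """Fragment counts per (peak_id, subunit) row and sample column.

    ``counts`` is an integer DataFrame indexed by a (peak_id, subunit)
    MultiIndex; ``samples`` is a DataFrame indexed by sample id with
    ``condition`` (WT / mutant) and ``replicate`` columns.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame) -> None:
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not set(counts.columns) <= set(samples.index):
            raise ValueError("count columns missing from sample table")
        bad = set(samples.loc[list(counts.columns), "condition"]) - {"WT", "mutant"}
        if bad:
            raise ValueError(f"unknown conditions: {bad}")
        self.counts = counts
        self.samples = samples.loc[list(counts.columns)]

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])

    def subset_samples(self, keep: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(keep)], self.samples.loc[list(keep)])

    def to_tsv(self, counts_path, samples_path) -> None:
        flat = self.counts.copy()
        flat.index = [f"{p}:{s}" for p, s in self.counts.index]
        flat.index.name = "row"
        flat.to_csv(counts_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        flat = pd.read_csv(counts_path, sep="\t", index_col=0)
        idx = pd.MultiIndex.from_tuples(
            [tuple(r.rsplit(":", 1)) for r in flat.index], names=["peak_id", "subunit"]
        )
        flat.index = idx
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(flat, samples)


@dataclass(frozen=True)
class DifferentialResult:
    """Per-(peak, subunit) NB Wald test outcome (mutant vs WT)."""

    peak_id: str
    subunit: str
    log2fc: float
    p_value: float
    fdr: float = float("nan")

    def significant_decrease(self, alpha: float) -> bool:
        return self.fdr < alpha and self.log2fc < 0

    def significant_increase(self, alpha: float) -> bool:
        return self.fdr < alpha and self.log2fc > 0


@dataclass(frozen=True)
class PeakClassCall:
    """Class I/II call for one peak with subunit-vote counters."""

    peak_id: str
    class_label: str
    n_subunits_decreased: int
    all_six_decreased: bool
    any_increased: bool


def count_fragments(
    fragments: Mapping[str, Sequence[GenomicInterval]],
    peaks: Sequence[ConsensusPeak],
    subunit: str,
) -> pd.DataFrame:
    """Count fragments whose midpoint falls inside each peak (half-open).

    ``fragments`` maps sample id to that sample's fragment intervals.
    Midpoint assignment guarantees each fragment is counted at most once
    even for adjacent peaks.  Returns a (peak_id, subunit)-indexed frame.
    """
    index = pd.MultiIndex.from_tuples(
        [(p.id, subunit) for p in peaks], names=["peak_id", "subunit"]
    )
    out = pd.DataFrame(0, index=index, columns=list(fragments), dtype=np.int64)
    for sample, frags in fragments.items():
        mids: dict[str, list[int]] = {}
        for f in frags:
            mids.setdefault(f.chrom, []).append(f.midpoint)
        sorted_mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}
        col = np.zeros(len(peaks), dtype=np.int64)
        for i, p in enumerate(peaks):
            arr = sorted_mids.get(p.interval.chrom)
            if arr is None:
                continue
            lo = np.searchsorted(arr, p.interval.start, side="left")
            hi = np.searchsorted(arr, p.interval.end, side="left")
            col[i] = hi - lo
        out[sample] = col
    return out


def size_factors(counts: pd.DataFrame, pseudocount: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each row i with all-positive counts, the ratio
    ``c_ij / (prod_j c_ij)^(1/m)`` is formed; sample j's factor is the
    median ratio over those rows.  Factors are then divided by their own
    geometric mean so that identical samples yield factors of exactly 1 and
    scaling one sample scales only (up to this renormalization) its factor.

    Raises if no row has all-positive counts, unless ``pseudocount`` is
    set, in which case +1 is added to every cell first.
    """
    mat = counts.to_numpy(dtype=float)
    if pseudocount:
        mat = mat + 1.0
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no row with all-positive counts; re-run with pseudocount=True "
            "to add +1 to every cell"
        )
    sub = mat[positive]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _row_stats(
    y_wt: np.ndarray, y_mut: np.ndarray
) -> tuple[float, float]:
    """log2fc and two-sided p for one row of normalized counts."""
    n_wt, n_mut = y_wt.shape[0], y_mut.shape[0]
    mu_wt, mu_mut = y_wt.mean(), y_mut.mean()
    ss = ((y_wt - mu_wt) ** 2).sum() + ((y_mut - mu_mut) ** 2).sum()
    pooled_var = ss / (n_wt + n_mut - 2)
    pooled_mean = (y_wt.sum() + y_mut.sum()) / (n_wt + n_mut)
    if pooled_mean > 0:
        alpha_hat = max(_DISPERSION_EPS, (pooled_var - pooled_mean) / pooled_mean**2)
    else:
        alpha_hat = _DISPERSION_EPS
    log2fc = float(np.log2((mu_mut + _PSEUDOCOUNT) / (mu_wt + _PSEUDOCOUNT)))
    se2 = (1.0 / np.log(2.0)) ** 2 * (
        (1.0 / n_wt) * (1.0 / (mu_wt + _PSEUDOCOUNT) + alpha_hat)
        + (1.0 / n_mut) * (1.0 / (mu_mut + _PSEUDOCOUNT) + alpha_hat)
    )
    z = log2fc / np.sqrt(se2)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return log2fc, max(p, np.finfo(float).tiny)


def nb_wald_test(
    cm: CountMatrix,
    row: tuple[str, str],
    config: PipelineConfig | None = None,
    factors: pd.Series | None = None,
) -> DifferentialResult:
    """NB Wald test of mutant-vs-WT occupancy for one (peak, subunit) row."""
    wt = cm.condition_samples("WT")
    mut = cm.condition_samples("mutant")
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if factors is None:
        factors = size_factors(cm.counts)
    c = cm.counts.loc[row]
    y = c / factors
    log2fc, p = _row_stats(
        y[wt].to_numpy(dtype=float), y[mut].to_numpy(dtype=float)
    )
    return DifferentialResult(peak_id=row[0], subunit=row[1], log2fc=log2fc, p_value=p)


def nb_wald_table(
    cm: CountMatrix, config: PipelineConfig | None = None
) -> list[DifferentialResult]:
    """NB Wald tests for all rows, with BH FDR applied per subunit.

    The multiplicity family is per subunit (all peaks for one subunit),
    because Class I/II membership is defined subunit by subunit.
    """
    wt = cm.condition_samples("WT")
    mut = cm.condition_samples("mutant")
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError("need >= 2 replicates per condition")
    factors = size_factors(cm.counts)
    y = cm.counts / factors
    y_wt = y[wt].to_numpy(dtype=float)
    y_mut = y[mut].to_numpy(dtype=float)
    raw: list[DifferentialResult] = []
    for i, (peak_id, subunit) in enumerate(cm.counts.index):
        log2fc, p = _row_stats(y_wt[i], y_mut[i])
        raw.append(DifferentialResult(peak_id, subunit, log2fc, p))
    out: list[DifferentialResult] = []
    by_subunit: dict[str, list[DifferentialResult]] = {}
    for r in raw:
        by_subunit.setdefault(r.subunit, []).append(r)
    for subunit, rows in by_subunit.items():
        qs = bh_fdr([r.p_value for r in rows])
        out.extend(
            DifferentialResult(r.peak_id, r.subunit, r.log2fc, r.p_value, q)
            for r, q in zip(rows, qs)
        )
    order = {row: i for i, row in enumerate(cm.counts.index)}
    out.sort(key=lambda r: order[(r.peak_id, r.subunit)])
    return out


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (order preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def classify_peaks(
    results: Sequence[DifferentialResult],
    config: PipelineConfig | None = None,
    subunits: Sequence[str] = TESTED_SUBUNITS,
) -> list[PeakClassCall]:
    """Partition peaks into Class I (>= 1 subunit significantly decreased
    at FDR < alpha) and Class II (no significant decrease).

    Every peak must carry a result for each tested subunit.
    """
    config = config or PipelineConfig()
    by_peak: dict[str, dict[str, DifferentialResult]] = {}
    for r in results:
        by_peak.setdefault(r.peak_id, {})[r.subunit] = r
    calls: list[PeakClassCall] = []
    for peak_id, rows in by_peak.items():
        missing = [s for s in subunits if s not in rows]
        if missing:
            raise ValueError(f"peak {peak_id}: missing subunit results {missing}")
        n_dec = sum(
            rows[s].significant_decrease(config.fdr_alpha) for s in subunits
        )
        any_inc = any(rows[s].significant_increase(config.fdr_alpha) for s in subunits)
        calls.append(
            PeakClassCall(
                peak_id=peak_id,
                class_label="I" if n_dec >= 1 else "II",
                n_subunits_decreased=n_dec,
                all_six_decreased=n_dec == len(subunits),
                any_increased=any_inc,
            )
        )
    return calls
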