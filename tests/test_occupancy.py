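"""Fragment counting, normalization, the NB Wald test and Class I/II calls."""

import numpy as np
import pandas as pd
import pytest

from drmchip.consensus import ConsensusPeak
from drmchip.genomic_io import GenomicInterval, PipelineConfig
from drmchip.occupancy import (
    TESTED_SUBUNITS,
    CountMatrix,
    DifferentialResult,
    bh_fdr,
    classify_peaks,
    count_fragments,
    nb_wald_table,
    nb_wald_test,
    size_factors,
)


def make_cm(data, n_wt=3, n_mut=3, subunit="LIN-54"):
    """CountMatrix from a (rows, n_wt + n_mut) array."""
    data = np.atleast_2d(np.asarray(data))
    samples = [f"wt_{i}" for i in range(n_wt)] + [f"mut_{i}" for i in range(n_mut)]
    idx = pd.MultiIndex.from_tuples(
        [(f"p{i}", subunit) for i in range(data.shape[0])], names=["peak_id", "subunit"]
    )
    counts = pd.DataFrame(data, index=idx, columns=samples)
    meta = pd.DataFrame(
        {"condition": ["WT"] * n_wt + ["mutant"] * n_mut, "replicate": list(range(n_wt)) + list(range(n_mut))},
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(counts, meta)


def nb_counts(rng, mean, dispersion, size):
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=size)
    return rng.poisson(lam)


class TestCountFragments:
    def _peak(self, start=100, end=200):
        return ConsensusPeak("pk", GenomicInterval("chrI", start, end), (start + end) // 2)

    def test_midpoints_inside_are_counted(self):
        frags = {"s1": [GenomicInterval("chrI", 120, 160)] * 10}
        out = count_fragments(frags, [self._peak()], "LIN-9")
        assert out.loc[("pk", "LIN-9"), "s1"] == 10

    def test_midpoint_at_exclusive_end_not_counted(self):
        # fragment [180, 220): midpoint 200 == peak end -> excluded
        frags = {"s1": [GenomicInterval("chrI", 180, 220)]}
        out = count_fragments(frags, [self._peak()], "LIN-9")
        assert out.loc[("pk", "LIN-9"), "s1"] == 0

    def test_random_fragments_match_brute_force(self, rng):
        peaks = [
            ConsensusPeak(f"p{i}", GenomicInterval("chrI", s, s + 150), s + 75)
            for i, s in enumerate(range(0, 5000, 400))
        ]
        frags = [
            GenomicInterval("chrI", int(a := rng.integers(0, 5200)), int(a + rng.integers(1, 300)))
            for _ in range(500)
        ]
        out = count_fragments({"s": frags}, peaks, "LIN-9")
        for p in peaks:
            expected = sum(
                1 for f in frags if p.interval.start <= f.midpoint < p.interval.end
            )
            assert out.loc[(p.id, "LIN-9"), "s"] == expected


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = make_cm(np.tile([[100], [50], [200]], (1, 6)))
        np.testing.assert_allclose(size_factors(cm.counts), np.ones(6))

    def test_doubled_sample_has_double_factor(self):
        counts = np.column_stack([np.array([100, 40, 250]), np.array([200, 80, 500])])
        cm = make_cm(counts, n_wt=1, n_mut=1)
        f = size_factors(cm.counts).to_numpy()
        assert f[1] / f[0] == pytest.approx(2.0)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_matches_independent_formula_on_random_matrix(self, rng):
        mat = nb_counts(rng, 100, 0.1, (300, 6)) + 1  # avoid zero rows
        cm = make_cm(mat)
        # independent direct transcription of the median-of-ratios formula
        logg = np.log(mat).mean(axis=1)
        expected = np.array(
            [np.median(mat[:, j] / np.exp(logg)) for j in range(6)]
        )
        expected /= np.exp(np.log(expected).mean())
        np.testing.assert_allclose(size_factors(cm.counts), expected, rtol=1e-12)

    def test_all_zero_row_matrix_requires_pseudocount(self):
        mat = np.zeros((3, 6), dtype=int)
        mat[:, 0] = 5  # every row has a zero somewhere
        cm = make_cm(mat)
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(cm.counts)
        f = size_factors(cm.counts, pseudocount=True)
        assert (f > 0).all()


class TestNbWaldTest:
    def test_constant_counts_are_null(self):
        cm = make_cm(np.full((1, 6), 150))
        r = nb_wald_test(cm, ("p0", "LIN-54"))
        assert r.log2fc == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_sign_matches_group_ordering(self, rng):
        wt = nb_counts(rng, 400, 0.05, 3)
        mut = nb_counts(rng, 50, 0.05, 3)
        cm = make_cm(np.concatenate([wt, mut])[None, :])
        r = nb_wald_test(cm, ("p0", "LIN-54"), factors=pd.Series(1.0, index=cm.counts.columns))
        assert r.log2fc < 0

    def test_single_condition_rejected(self):
        cm = make_cm(np.full((1, 4), 100), n_wt=4, n_mut=0)
        with pytest.raises(ValueError):
            nb_wald_test(cm, ("p0", "LIN-54"))

    def test_power_on_planted_fourfold_decrease(self, rng):
        """3v3, baseline 200, dispersion 0.05, 4-fold drop: a strong decrease
        (p < 0.01 and log2fc < -1.5) is called in ~95% of simulations.

        Asserted within 2 binomial standard errors of the target fraction.
        """
        n_sim = 500
        wt = nb_counts(rng, 200, 0.05, (n_sim, 3))
        mut = nb_counts(rng, 50, 0.05, (n_sim, 3))
        cm = make_cm(np.hstack([wt, mut]))
        ones = pd.Series(1.0, index=cm.counts.columns)
        hits = 0
        for i in range(n_sim):
            r = nb_wald_test(cm, (f"p{i}", "LIN-54"), factors=ones)
            hits += r.p_value < 0.01 and r.log2fc < -1.5
        mc_se = np.sqrt(0.95 * 0.05 / n_sim)
        assert hits / n_sim >= 0.95 - 2 * mc_se

    def test_table_matches_row_wise_calls(self, rng):
        mat = nb_counts(rng, 200, 0.05, (40, 6))
        cm = make_cm(mat)
        table = nb_wald_table(cm)
        factors = size_factors(cm.counts)
        for r in table[:10]:
            single = nb_wald_test(cm, (r.peak_id, r.subunit), factors=factors)
            assert r.log2fc == pytest.approx(single.log2fc)
            assert r.p_value == pytest.approx(single.p_value)


class TestBhFdr:
    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.037]) == [pytest.approx(0.037)]

    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_independent_step_up(self, rng):
        def step_up(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p)
            q_sorted = p[order] * n / np.arange(1, n + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            q = np.empty(n)
            q[order] = np.minimum(q_sorted, 1.0)
            return q

        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_fdr(p), step_up(p), rtol=1e-12)

    def test_invariant_under_permutation(self, rng):
        p = rng.uniform(0.001, 1, 30)
        perm = rng.permutation(30)
        q = np.asarray(bh_fdr(p))
        q_perm = np.asarray(bh_fdr(p[perm]))
        np.testing.assert_allclose(q[perm], q_perm)

    def test_q_dominates_p(self, rng):
        p = rng.uniform(0.001, 1, 100)
        assert (np.asarray(bh_fdr(p)) >= p - 1e-15).all()

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestClassifyPeaks:
    def _results(self, peak_id, qs, lfcs):
        return [
            DifferentialResult(peak_id, s, lfc, p_value=q, fdr=q)
            for s, q, lfc in zip(TESTED_SUBUNITS, qs, lfcs)
        ]

    def test_all_six_decreased(self, config):
        res = self._results("p1", [0.001] * 6, [-2.0] * 6)
        (call,) = classify_peaks(res, config)
        assert call.class_label == "I"
        assert call.n_subunits_decreased == 6 and call.all_six_decreased

    def test_no_significance_is_class_ii(self, config):
        res = self._results("p1", [0.5] * 6, [-0.2] * 6)
        (call,) = classify_peaks(res, config)
        assert call.class_label == "II" and call.n_subunits_decreased == 0

    def test_significant_increase_flag(self, config):
        res = self._results("p1", [0.001] + [0.9] * 5, [1.5] + [0.0] * 5)
        (call,) = classify_peaks(res, config)
        assert call.class_label == "II" and call.any_increased

    def test_missing_subunit_names_the_peak(self, config):
        res = self._results("p7", [0.5] * 6, [0.0] * 6)[:5]
        with pytest.raises(ValueError, match="p7"):
            classify_peaks(res, config)

    def test_partition_on_synthetic_counts(self, default_bundle, config):
        calls = classify_peaks(nb_wald_table(default_bundle.counts), config)
        n1 = sum(1 for c in calls if c.class_label == "I")
        n2 = sum(1 for c in calls if c.class_label == "II")
        assert n1 + n2 == len(calls) == len(default_bundle.truth.sites)

    def test_recall_monotone_in_effect_size(self, rng, config):
        """Stronger planted drops never reduce Class I recall (3 levels).

        100 affected peaks sit among 200 null peaks so that the size-factor
        estimate stays anchored to unchanged rows.
        """
        n_eff, n_null = 100, 200
        recalls = []
        for lfc in (-0.5, -1.0, -2.0):
            rows, index = [], []
            for i in range(n_eff + n_null):
                mut_mean = 200 * 2.0**lfc if i < n_eff else 200
                for s in TESTED_SUBUNITS:
                    rows.append(
                        np.concatenate(
                            [nb_counts(rng, 200, 0.05, 3), nb_counts(rng, mut_mean, 0.05, 3)]
                        )
                    )
                    index.append((f"p{i}", s))
            samples = [f"wt_{i}" for i in range(3)] + [f"mut_{i}" for i in range(3)]
            counts = pd.DataFrame(
                np.vstack(rows),
                index=pd.MultiIndex.from_tuples(index, names=["peak_id", "subunit"]),
                columns=samples,
            )
            meta = pd.DataFrame(
                {"condition": ["WT"] * 3 + ["mutant"] * 3, "replicate": [0, 1, 2, 0, 1, 2]},
                index=pd.Index(samples, name="sample"),
            )
            calls = classify_peaks(nb_wald_table(CountMatrix(counts, meta)), config)
            class1 = {c.peak_id for c in calls if c.class_label == "I"}
            recalls.append(
                sum(1 for i in range(n_eff) if f"p{i}" in class1) / n_eff
            )
        assert recalls == sorted(recalls)
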