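"""Replicate filtering, subunit voting, DRM consensus and retention calls."""

import numpy as np
import pytest

from drmchip.consensus import (
    ConsensusPeak,
    cluster_peaks,
    consensus_drm,
    count_region_overlaps,
    overlap_vote,
    reproducible_peaks,
    retention_classify,
)
from drmchip.genomic_io import (
    E2FDP_SUBUNITS,
    MUVB_SUBUNITS,
    SUBUNITS,
    GenomicInterval,
    Peak,
    PipelineConfig,
)


def mk(start, width=100, chrom="chrI", **kw):
    return Peak(interval=GenomicInterval(chrom, start, start + width), **kw)


def brute_force_clusters(peaks):
    """Independent transitive-overlap clustering by repeated set expansion."""
    remaining = list(peaks)
    clusters = []
    while remaining:
        cluster = [remaining.pop()]
        changed = True
        while changed:
            changed = False
            for p in list(remaining):
                if any(p.interval.overlaps(q.interval) for q in cluster):
                    cluster.append(p)
                    remaining.remove(p)
                    changed = True
        clusters.append(cluster)
    return clusters


def _cluster_key(cluster):
    return sorted((p.interval.chrom, p.interval.start, p.interval.end) for p in cluster)


class TestClustering:
    def test_single_linkage_matches_brute_force(self, rng):
        peaks = [
            mk(int(rng.integers(0, 3000)), int(rng.integers(20, 200)),
               chrom=str(rng.choice(["chrI", "chrII"])))
            for _ in range(120)
        ]
        ours = sorted(map(_cluster_key, cluster_peaks(peaks)))
        oracle = sorted(map(_cluster_key, brute_force_clusters(peaks)))
        assert ours == oracle

    def test_chained_overlap_is_one_cluster(self):
        # a-b overlap, b-c overlap, a-c do not: still one component
        peaks = [mk(0, 100), mk(80, 100), mk(160, 100)]
        assert len(cluster_peaks(peaks)) == 1


class TestReproduciblePeaks:
    def test_identical_replicates_pass_through(self):
        reps = [[mk(0), mk(500)] for _ in range(3)]
        merged = reproducible_peaks(reps, min_replicates=2)
        assert [p.interval for p in merged] == [mk(0).interval, mk(500).interval]

    def test_peak_in_one_replicate_dropped(self):
        reps = [[mk(0), mk(500)], [mk(0)], [mk(0)]]
        merged = reproducible_peaks(reps, min_replicates=2)
        assert [p.interval for p in merged] == [mk(0).interval]

    def test_min_replicates_validation(self):
        with pytest.raises(ValueError):
            reproducible_peaks([[mk(0)]], min_replicates=0)
        with pytest.raises(ValueError):
            reproducible_peaks([[mk(0)]], min_replicates=2)

    def test_jittered_sites_match_clustering_oracle(self, rng):
        centers = np.sort(rng.choice(np.arange(500, 100_000, 600), 100, replace=False))
        reps = []
        for _ in range(3):
            reps.append(
                [mk(int(c - 50 + rng.integers(-50, 51)), 100) for c in centers]
            )
        merged = reproducible_peaks(reps, min_replicates=2)
        oracle = brute_force_clusters([p for rep in reps for p in rep])
        kept = [c for c in oracle if len(c) >= 2]  # jitter < spacing: 1 peak per rep
        assert len(merged) == len(kept) == 100
        spans = sorted(
            (min(p.interval.start for p in c), max(p.interval.end for p in c))
            for c in kept
        )
        assert [(p.interval.start, p.interval.end) for p in merged] == spans


class TestOverlapVote:
    def test_identical_sets_full_membership(self):
        sets = {f"s{i}": [mk(0), mk(500)] for i in range(4)}
        out = overlap_vote(sets, 3)
        assert len(out) == 2
        assert all(c.n_subunits == 4 for c in out)

    def test_k_equal_to_n_is_full_intersection(self):
        sets = {"a": [mk(0), mk(500)], "b": [mk(0)], "c": [mk(20)]}
        out = overlap_vote(sets, 3)
        assert len(out) == 1 and out[0].interval.start == 0

    def test_vote_monotonicity_in_k(self, rng):
        sets = {
            f"s{i}": [mk(int(rng.integers(0, 5000)), 150) for _ in range(30)]
            for i in range(5)
        }
        counts = [len(overlap_vote(sets, k)) for k in range(1, 6)]
        assert counts == sorted(counts, reverse=True)

    def test_idempotent_at_k1(self, rng):
        sets = {
            f"s{i}": [mk(int(rng.integers(0, 4000)), 120) for _ in range(25)]
            for i in range(3)
        }
        first = overlap_vote(sets, 1)
        again = overlap_vote(
            {"merged": [Peak(interval=c.interval) for c in first]}, 1
        )
        assert [c.interval for c in again] == [c.interval for c in first]

    def test_random_sets_match_clustering_oracle(self, rng):
        sets = {
            f"s{i}": [mk(int(rng.integers(0, 3000)), 100) for _ in range(20)]
            for i in range(4)
        }
        out = overlap_vote(sets, 2)
        tagged = [p.tagged(subunit=k) for k, ps in sets.items() for p in ps]
        oracle = [
            c for c in brute_force_clusters(tagged)
            if len({p.subunit for p in c}) >= 2
        ]
        assert sorted(c.interval for c in out) == sorted(
            GenomicInterval("chrI", min(p.interval.start for p in c), max(p.interval.end for p in c))
            for c in oracle
        )

    def test_k_larger_than_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_vote({"a": [mk(0)]}, 2)


class TestConsensusDrm:
    def test_identical_sets_give_full_seven_subunit_peaks(self, config):
        sets = {s: [mk(0), mk(500), mk(1200)] for s in SUBUNITS}
        out = consensus_drm(sets, config)
        assert len(out) == 3
        assert all(c.n_subunits == 7 for c in out)

    def test_empty_lin35_gives_no_drm_peaks(self, config):
        sets = {s: [mk(0), mk(500)] for s in SUBUNITS}
        sets["LIN-35"] = []
        assert consensus_drm(sets, config) == []

    def test_membership_contains_required_components(self, config, rng):
        sets = {
            s: [mk(int(rng.integers(0, 50_000)), 200) for _ in range(40)]
            for s in SUBUNITS
        }
        for c in consensus_drm(sets, config):
            assert c.members.get("LIN-35")
            assert all(c.members.get(s) for s in E2FDP_SUBUNITS)
            assert sum(1 for s in MUVB_SUBUNITS if c.members.get(s)) >= config.muvb_vote_k

    def test_perfect_detection_recovers_every_planted_site(self, perfect_bundle, config):
        b = perfect_bundle
        sets = {
            s: reproducible_peaks(b.wt_peaks[s], config.min_replicates) for s in SUBUNITS
        }
        drm = consensus_drm(sets, config)
        assert len(drm) == len(b.truth.sites) == 150
        site_ivs = [GenomicInterval(s.chrom, s.start, s.end) for s in b.truth.sites]
        assert all(any(d.interval.overlaps(iv) for iv in site_ivs) for d in drm)


class TestRetention:
    def _wt(self):
        return [
            ConsensusPeak(f"p{i}", GenomicInterval("chrI", i * 1000, i * 1000 + 200), i * 1000 + 100)
            for i in range(5)
        ]

    def test_empty_mutant_sets_lose_everything(self):
        calls = retention_classify(self._wt(), [], [])
        assert all(c.category == "lost_both" for c in calls)

    def test_mutant_equal_to_wt_retains_everything(self):
        wt = self._wt()
        calls = retention_classify(wt, wt, wt)
        assert all(c.category == "retained_both" for c in calls)

    def test_categories_partition_wt_peaks(self, rng):
        wt = self._wt()
        mut_e = [wt[i] for i in [0, 2]]
        mut_m = [wt[i] for i in [0, 3]]
        calls = retention_classify(wt, mut_e, mut_m)
        counts = {}
        for c in calls:
            counts[c.category] = counts.get(c.category, 0) + 1
        assert sum(counts.values()) == len(wt)
        assert counts == {"retained_both": 1, "retained_one": 2, "lost_both": 2}

    def test_planted_retention_recovered_exactly_at_full_detection(self, perfect_bundle, config):
        b = perfect_bundle
        sets = {
            s: reproducible_peaks(b.wt_peaks[s], config.min_replicates) for s in SUBUNITS
        }
        drm = consensus_drm(sets, config)
        mut_reps = {
            s: reproducible_peaks(b.mut_peaks[s], config.min_replicates)
            for s in SUBUNITS
            if s != "LIN-35"
        }
        mut_e2fdp = overlap_vote({s: mut_reps[s] for s in E2FDP_SUBUNITS}, 2)
        mut_muvb = overlap_vote({s: mut_reps[s] for s in MUVB_SUBUNITS}, config.muvb_vote_k)
        calls = retention_classify(drm, mut_e2fdp, mut_muvb)
        truth_by_site = {
            (s.chrom, s.start, s.end): s.retention for s in b.truth.sites
        }
        matched = 0
        for d, call in zip(drm, calls):
            hits = [
                r for (chrom, st, en), r in truth_by_site.items()
                if d.interval.overlaps(GenomicInterval(chrom, st, en))
            ]
            assert len(hits) == 1
            if call.category == hits[0]:
                matched += 1
        assert matched == len(drm)


def test_hot_region_overlap_count(default_bundle):
    b = default_bundle
    peaks = [
        ConsensusPeak(s.site_id, GenomicInterval(s.chrom, s.start, s.end), s.center)
        for s in b.truth.sites
    ]
    n_hot_truth = sum(1 for s in b.truth.sites if s.is_hot)
    assert count_region_overlaps(peaks, b.hot_regions) == n_hot_truth
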