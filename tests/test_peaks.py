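"""Replicate-concordance clustering and TSS-proximity assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cenreg.io_formats import GenomicInterval, Peak, TranscriptionalUnit, ValidationError
from cenreg.peaks import (
    assign_to_tss,
    cluster_replicate_peaks,
    filter_by_support,
)
from cenreg.synthetic_data import (
    SimulationConfig,
    plant_sites,
    simulate_genome_and_annotations,
    simulate_peaks,
)


def mk_peak(center, strain="WT", replicate="rep1", replicon="chr1", enrich=2.0, name=""):
    return Peak(
        GenomicInterval(replicon, max(0, center - 100), center + 100),
        enrich,
        strain,
        replicate,
        name=name or f"{strain}:{replicate}:{center}",
        center=center,
    )


def brute_force_clusters(peaks, max_dist):
    """Independent O(n^2) single-linkage oracle via union-find."""
    parent = list(range(len(peaks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(peaks)), 2):
        if (
            peaks[i].replicon == peaks[j].replicon
            and abs(peaks[i].center - peaks[j].center) <= max_dist
        ):
            parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(peaks):
        groups.setdefault(find(i), []).append(p)
    return {
        frozenset((p.center, p.strain, p.replicate, p.name) for p in grp)
        for grp in groups.values()
    }


class TestClustering:
    def test_empty_input(self):
        assert cluster_replicate_peaks([]) == []

    def test_three_close_one_far(self):
        peaks = [
            mk_peak(100, replicate="rep1"),
            mk_peak(102, replicate="rep2"),
            mk_peak(98, replicate="rep3"),
            mk_peak(300, replicate="rep4"),
        ]
        consensus = cluster_replicate_peaks(peaks, max_center_distance=50)
        assert sorted(c.support for c in consensus) == [1, 3]
        big = max(consensus, key=lambda c: c.support)
        assert big.center == 100  # lower median of {98, 100, 102}

    def test_same_replicate_counts_once(self):
        peaks = [mk_peak(100, replicate="rep1"), mk_peak(101, replicate="rep1")]
        (c,) = cluster_replicate_peaks(peaks, 50)
        assert c.support == 1 and len(c.member_peaks) == 2

    def test_per_strain_enrichment_averaged_and_missing_strains_absent(self):
        peaks = [
            mk_peak(100, strain="D56E", replicate="rep1", enrich=4.0),
            mk_peak(105, strain="D56E", replicate="rep2", enrich=5.0),
            mk_peak(102, strain="WT", replicate="rep1", enrich=3.0),
        ]
        (c,) = cluster_replicate_peaks(peaks, 50)
        assert c.per_strain_enrichment == {"D56E": 4.5, "WT": 3.0}
        assert "dcenK" not in c.per_strain_enrichment

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        peaks = [
            mk_peak(int(c), strain=s, replicate=r)
            for c, s, r in zip(
                rng.integers(100, 5000, 30),
                rng.choice(["WT", "D56E"], 30),
                rng.choice(["rep1", "rep2", "rep3"], 30),
            )
        ]
        ref = cluster_replicate_peaks(peaks, 100)
        for seed in range(3):
            rng2 = np.random.default_rng(seed)
            shuffled = list(peaks)
            rng2.shuffle(shuffled)
            assert cluster_replicate_peaks(shuffled, 100) == ref

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            cluster_replicate_peaks([], -1)

    @settings(max_examples=60, deadline=None)
    @given(
        centers=st.lists(st.integers(min_value=100, max_value=2000), min_size=0, max_size=25),
        max_dist=st.integers(min_value=0, max_value=200),
    )
    def test_matches_brute_force_oracle(self, centers, max_dist):
        peaks = [
            mk_peak(c, replicate=f"rep{i % 4}", name=f"p{i}")
            for i, c in enumerate(centers)
        ]
        got = {
            frozenset((p.center, p.strain, p.replicate, p.name) for p in c.member_peaks)
            for c in cluster_replicate_peaks(peaks, max_dist)
        }
        assert got == brute_force_clusters(peaks, max_dist)


class TestSupportFilter:
    def test_threshold_arithmetic(self):
        peaks = []
        for c, n in ((1000, 4), (3000, 3), (5000, 2), (7000, 1)):
            for i in range(n):
                peaks.append(mk_peak(c + i, replicate=f"rep{i + 1}"))
        consensus = cluster_replicate_peaks(peaks, 50)
        assert sorted(c.support for c in consensus) == [1, 2, 3, 4]
        assert len(filter_by_support(consensus, 3)) == 2
        assert filter_by_support(consensus, 1) == consensus

    def test_nested_in_min_replicates(self):
        rng = np.random.default_rng(1)
        peaks = [
            mk_peak(int(c), replicate=f"rep{int(r)}")
            for c, r in zip(rng.integers(0, 20000, 60), rng.integers(1, 5, 60))
        ]
        consensus = cluster_replicate_peaks(peaks, 100)
        for k in range(1, 4):
            strict = {c.center for c in filter_by_support(consensus, k + 1)}
            loose = {c.center for c in filter_by_support(consensus, k)}
            assert strict <= loose

    def test_true_sites_pass_at_binomial_rate(self):
        """At fixed per-replicate power, the fraction of true sites that
        survive the >=3-replicate filter is at least the single-strain
        Binomial(4, p) tail (support pools all strains, so this is a
        lower bound)."""
        cfg = SimulationConfig(
            seed=7, n_tus=200, n_direct_targets=200, detection_power=0.9, peak_fpr=2.0
        )
        genome, tus = simulate_genome_and_annotations(cfg)
        _, truth = plant_sites(genome, tus, cfg)
        peaks = [p for plist in simulate_peaks(truth, cfg).values() for p in plist]
        kept = filter_by_support(cluster_replicate_peaks(peaks, 100), 3)
        kept_centers = sorted(c.center for c in kept)
        n_recovered = sum(
            any(abs(e.site.center - c) <= 50 for c in kept_centers)
            for e in truth.direct_targets()
        )
        predicted = stats.binom.sf(2, 4, 0.9)
        assert n_recovered / 200 >= predicted


def mk_tu(tu_id, tss, strand, start, end, genes=(), replicon="chr1"):
    tu = TranscriptionalUnit(
        tu_id, GenomicInterval(replicon, start, end, strand), tss
    )
    for gid, gs, ge in genes:
        tu.genes[gid] = GenomicInterval(replicon, gs, ge, strand)
    return tu


class TestAssignToTSS:
    def test_peak_upstream_of_tss_is_assigned(self):
        tu = mk_tu("tolQ", tss=2414000, strand="+", start=2414000, end=2416000)
        peak = cluster_replicate_peaks([mk_peak(2413901)], 50)[0]
        (a,) = assign_to_tss([peak], [tu])
        assert a.classification == "upstream"
        assert a.tu_id == "tolQ" and a.distance_to_tss == -99

    def test_divergent_promoter_shared_assignment(self):
        plus = mk_tu("A", tss=1100, strand="+", start=1100, end=2000)
        minus = mk_tu("B", tss=900, strand="-", start=200, end=901)
        peak = cluster_replicate_peaks([mk_peak(1000)], 50)[0]
        assignments = assign_to_tss([peak], [plus, minus])
        assert {a.tu_id for a in assignments} == {"A", "B"}
        assert all(a.shared and a.classification == "upstream" for a in assignments)
        assert all(a.distance_to_tss == -100 for a in assignments)

    def test_peak_inside_long_cds_is_intragenic(self):
        tu = mk_tu(
            "big", tss=1000, strand="+", start=1000, end=4200,
            genes=[("g1", 1100, 4100)],
        )
        peak = cluster_replicate_peaks([mk_peak(2600)], 50)[0]
        (a,) = assign_to_tss([peak], [tu])
        assert a.classification == "intragenic" and a.tu_id is None

    def test_convergent_intergenic_exclusion(self):
        left = mk_tu("L", tss=200, strand="+", start=200, end=1000, genes=[("gl", 300, 1000)])
        right = mk_tu("R", tss=2900, strand="-", start=2000, end=2901, genes=[("gr", 2000, 2800)])
        peak = cluster_replicate_peaks([mk_peak(1500)], 50)[0]
        (a,) = assign_to_tss([peak], [left, right])
        assert a.classification == "convergent_intergenic"

    def test_orphan_when_no_context(self):
        tu = mk_tu("T", tss=50000, strand="+", start=50000, end=51000)
        peak = cluster_replicate_peaks([mk_peak(10000)], 50)[0]
        (a,) = assign_to_tss([peak], [tu])
        assert a.classification == "orphan"

    def test_tu_without_tss_raises(self):
        tu = mk_tu("X", tss=None, strand="+", start=100, end=1000)
        peak = cluster_replicate_peaks([mk_peak(50)], 50)[0]
        with pytest.raises(ValidationError, match="X"):
            assign_to_tss([peak], [tu])

    def test_noiseless_upstream_peaks_are_exactly_planted_loci(self, noiseless_dataset):
        d = noiseless_dataset
        kept = filter_by_support(cluster_replicate_peaks(d.all_peaks()), 3)
        assignments = assign_to_tss(kept, d.tus)
        upstream_centers = {
            a.peak.center for a in assignments if a.classification == "upstream"
        }
        planted = {e.site.center for e in d.truth.direct_targets()}
        assert upstream_centers == planted
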