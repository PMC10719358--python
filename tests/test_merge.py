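"""Matching rule, consensus, and nonredundant merging."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svpopscan import (
    Cohort,
    Genotype,
    MergeParams,
    SVType,
    compare_callsets,
    filter_raw_calls,
    merge_cohort,
    sv_match,
    within_sample_consensus,
)

from conftest import make_sv, random_sv_set

P = MergeParams()


class TestRawFilter:
    def test_each_criterion(self):
        calls = [
            make_sv(id="low_af", af_read=0.25, depth=20.0),
            make_sv(id="deep", af_read=0.9, depth=45.0),
            make_sv(id="short", start=100, end=130, af_read=0.9, depth=20.0),
            make_sv(id="ok", af_read=0.9, depth=20.0),
        ]
        kept, counts = filter_raw_calls(calls, mean_depth=20.0)
        assert [c.id for c in kept] == ["ok"]
        assert (counts.low_af, counts.high_depth, counts.bad_length) == (1, 1, 1)

    def test_af_boundary_is_strict(self):
        kept, _ = filter_raw_calls([make_sv(af_read=0.3, depth=10.0)], 20.0)
        assert kept == []

    def test_depth_boundary_is_strict(self):
        kept, _ = filter_raw_calls([make_sv(af_read=0.5, depth=40.0)], 20.0)
        assert kept == []

    def test_bad_mean_depth(self):
        with pytest.raises(ValueError):
            filter_raw_calls([], 0)


class TestSvMatch:
    def test_del_overlap_examples(self):
        a = make_sv(start=1000, end=2000)
        assert sv_match(a, make_sv(start=1100, end=2100), P)  # 0.9 reciprocal overlap
        assert not sv_match(a, make_sv(start=1000, end=1200), P)  # 0.2 < 0.4

    def test_ins_length_rule_and_type_mismatch(self):
        i1 = make_sv(svtype=SVType.INS, start=1000, length=300)
        i2 = make_sv(svtype=SVType.INS, start=1500, length=320)
        assert sv_match(i1, i2, P)
        dup = make_sv(svtype=SVType.DUP, start=1000, end=2000)
        dele = make_sv(svtype=SVType.DEL, start=1000, end=2000)
        assert not sv_match(dup, dele, P)

    def test_distance_boundary_strict(self):
        a = make_sv(start=0, end=10_000)
        b = make_sv(start=1000, end=11_000)  # distance exactly 1000
        assert not sv_match(a, b, P)

    def test_cross_chromosome_false_not_error(self):
        a = make_sv(chrom="chr1")
        b = make_sv(chrom="chr2")
        assert sv_match(a, b, P) is False

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        s1=st.integers(0, 100_000),
        l1=st.integers(50, 5000),
        s2=st.integers(0, 100_000),
        l2=st.integers(50, 5000),
        t=st.sampled_from(list(SVType)),
    )
    def test_symmetric_and_reflexive(self, s1, l1, s2, l2, t):
        a = make_sv(id="a", svtype=t, start=s1, end=s1 + l1, length=l1)
        b = make_sv(id="b", svtype=t, start=s2, end=s2 + l2, length=l2)
        assert sv_match(a, b, P) == sv_match(b, a, P)
        assert sv_match(a, a, P)


class TestConsensus:
    def _call(self, caller, hq=False, gt=Genotype.HET):
        return make_sv(id=f"c_{caller}", caller=caller, hq_flag=hq, sample="S1", genotype=gt)

    @pytest.mark.parametrize(
        "present,hq", itertools.product(itertools.product([0, 1], repeat=3), [False, True])
    )
    def test_exhaustive_retention_rule(self, present, hq):
        """All 2^3 caller-presence combinations x cuteSV-HQ flag."""
        callers = ["cuteSV", "sniffles", "nanovar"]
        calls = {
            c: [self._call(c, hq=(hq and c == "cuteSV"))] for c, p in zip(callers, present) if p
        }
        out = within_sample_consensus(calls)
        n_callers = sum(present)
        expect_kept = n_callers >= 2 or (hq and present[0])
        assert (len(out) == 1) == expect_kept
        if expect_kept:
            highest = next(c for c, p in zip(callers, present) if p)
            assert out[0].caller == highest

    def test_genotype_from_highest_priority_caller(self):
        calls = {
            "cuteSV": [self._call("cuteSV", gt=Genotype.HET)],
            "sniffles": [self._call("sniffles", gt=Genotype.HOM_ALT)],
        }
        out = within_sample_consensus(calls)
        assert out[0].genotype is Genotype.HET

    def test_two_samples_rejected(self):
        a = make_sv(sample="S1", caller="cuteSV")
        b = make_sv(sample="S2", caller="sniffles")
        with pytest.raises(ValueError, match="multiple samples"):
            within_sample_consensus({"cuteSV": [a], "sniffles": [b]})


def brute_force_partition(records, params):
    """Oracle: all-pairs match graph + connected components."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if sv_match(records[i], records[j], params):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(
            (records[i].chrom, records[i].start, records[i].end, records[i].svtype.value, records[i].id)
        )
    return frozenset(frozenset(g) for g in groups.values())


def cluster_partition(clusters):
    return frozenset(
        frozenset(
            (m.chrom, m.start, m.end, m.svtype.value, m.id) for m in cl.members
        )
        for cl in clusters
    )


class TestMergeCohort:
    def _cohort(self, n):
        return Cohort.from_items([(f"S{i}", "A") for i in range(n)])

    def test_jittered_del_one_cluster(self):
        cohort = self._cohort(3)
        per_sample = {
            f"S{i}": [make_sv(id=f"d{i}", start=1000 + 20 * i, end=2000 + 20 * i,
                              sample=f"S{i}", genotype=Genotype.HET)]
            for i in range(3)
        }
        clusters, matrix = merge_cohort(per_sample, cohort)
        assert len(clusters) == 1
        assert clusters[0].carrier_samples == {"S0", "S1", "S2"}
        assert matrix.presence.sum() == 3

    def test_partition_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            base = random_sv_set(rng, 40, chrom_size=500_000)
            noisy = base + random_sv_set(rng, 0, jitter_from=base)
            records = [r.with_(id=f"t{trial}_{k}", sample="S0") for k, r in enumerate(noisy)]
            clusters, _ = merge_cohort({"S0": records}, self._cohort(1))
            assert cluster_partition(clusters) == brute_force_partition(records, P)

    def test_idempotence(self):
        rng = np.random.default_rng(11)
        base = random_sv_set(rng, 100, chrom_size=2_000_000)
        per_sample = {
            "S0": [r.with_(sample="S0", genotype=Genotype.HET) for r in base]
        }
        clusters, _ = merge_cohort(per_sample, self._cohort(1))
        reps = [c.representative for c in clusters]
        refed = {f"P{i}": [r.with_(sample=f"P{i}", genotype=Genotype.HET)] for i, r in enumerate(reps)}
        cohort2 = Cohort.from_items([(f"P{i}", "A") for i in range(len(reps))])
        clusters2, _ = merge_cohort(refed, cohort2)
        key = lambda rs: sorted((r.chrom, r.start, r.end, r.svtype.value) for r in rs)
        assert key(c.representative for c in clusters2) == key(reps)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        base = random_sv_set(rng, 30, chrom_size=300_000)
        samples = [f"S{i}" for i in range(4)]
        per_sample = {}
        for s in samples:
            jit = random_sv_set(rng, 0, jitter_from=base)
            per_sample[s] = [r.with_(id=f"{s}_{r.id}", sample=s, genotype=Genotype.HET) for r in jit]
        cohort = Cohort.from_items([(s, "A") for s in samples])
        ref_clusters, ref_matrix = merge_cohort(per_sample, cohort)
        for perm_seed in range(5):
            order = list(per_sample)
            np.random.default_rng(perm_seed).shuffle(order)
            shuffled = {s: per_sample[s] for s in order}
            clusters, matrix = merge_cohort(shuffled, cohort)
            assert len(clusters) == len(ref_clusters)
            assert np.array_equal(matrix.dosage, ref_matrix.dosage)

    def test_monotonicity_in_params(self):
        rng = np.random.default_rng(5)
        records = [r.with_(sample="S0") for r in random_sv_set(rng, 150, chrom_size=1_000_000)]
        cohort = self._cohort(1)
        base_n = len(merge_cohort({"S0": records}, cohort, MergeParams())[0])
        tighter_dist = len(merge_cohort({"S0": records}, cohort, MergeParams(max_dist=200))[0])
        tighter_ov = len(merge_cohort({"S0": records}, cohort, MergeParams(min_overlap=0.8))[0])
        assert tighter_dist >= base_n
        assert tighter_ov >= base_n


class TestCompareCallsets:
    def test_shared_and_novel(self):
        q = [make_sv(id="q", start=1000, end=2000)]
        r = [make_sv(id="r", start=1100, end=2100)]
        shared, novel, pairs = compare_callsets(q, r)
        assert (shared, novel) == (1, 0)
        assert pairs[0][1].id == "r"

    def test_length_window_applied(self):
        q = [make_sv(id="huge", start=0, end=60_000)]
        shared, novel, _ = compare_callsets(q, q)
        assert (shared, novel) == (0, 0)

    def test_empty_reference_all_novel(self):
        q = [make_sv(id="q")]
        shared, novel, _ = compare_callsets(q, [])
        assert (shared, novel) == (0, 1)

    def test_best_match_by_distance(self):
        q = [make_sv(id="q", start=1000, end=2000)]
        refs = [
            make_sv(id="far", start=1400, end=2400),
            make_sv(id="near", start=1050, end=2050),
        ]
        _, _, pairs = compare_callsets(q, refs)
        assert pairs[0][1].id == "near"
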