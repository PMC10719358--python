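"""Synthetic cohort generator: determinism, frequency conservation, noise model."""

import dataclasses

import numpy as np
import pytest

from svpopscan import (
    CallerModel,
    SimParams,
    merge_cohort,
    r2_dosage,
    simulate_annotations,
    simulate_caller_calls,
    simulate_cohort_truth,
    simulate_linked_snps,
    within_sample_consensus,
)

SMALL = SimParams(n_pop_a=30, n_pop_b=30, m_svs=150, n_selected=6, seed=7)


def noise_free(params):
    models = {
        c: CallerModel(sensitivity=1.0, fp_per_mb=0.0, breakpoint_jitter_sd=0.0,
                       length_jitter_sd=0.0, hq_prob=m.hq_prob)
        for c, m in params.caller_models.items()
    }
    return dataclasses.replace(params, caller_models=models)


class TestCohortTruth:
    def test_deterministic_given_seed(self):
        t1, m1, c1 = simulate_cohort_truth(SMALL)
        t2, m2, c2 = simulate_cohort_truth(SMALL)
        assert np.array_equal(m1.dosage, m2.dosage)
        assert np.array_equal(t1.freq_a, t2.freq_a)
        assert [r.start for r in t1.records] == [r.start for r in t2.records]

    def test_different_seed_differs(self):
        _, m1, _ = simulate_cohort_truth(SMALL)
        _, m2, _ = simulate_cohort_truth(dataclasses.replace(SMALL, seed=8))
        assert not np.array_equal(m1.dosage, m2.dosage)

    def test_frequency_conservation_zscore(self):
        """Realized per-population allele frequencies match truth within binomial error."""
        params = dataclasses.replace(SMALL, n_pop_a=150, n_pop_b=150, m_svs=400)
        truth, matrix, cohort = simulate_cohort_truth(params)
        idx_a = cohort.indices("POP_A")
        d = matrix.dosage[idx_a].astype(float)
        realized = d.sum(axis=0) / (2 * len(idx_a))
        se = np.sqrt(truth.freq_a * (1 - truth.freq_a) / (2 * len(idx_a)))
        z = np.abs(realized - truth.freq_a) / np.maximum(se, 1e-9)
        assert (z < 4).mean() > 0.99

    def test_selected_loci_directions(self):
        truth, _, _ = simulate_cohort_truth(SMALL)
        sel = truth.selected
        assert sel.sum() == 6
        dirs = {truth.expected_direction[i] for i in np.nonzero(sel)[0]}
        assert dirs == {"A_specific", "B_specific"}

    def test_fst_zero_shares_frequencies(self):
        params = dataclasses.replace(SMALL, fst_param=0.0, n_selected=0)
        truth, _, _ = simulate_cohort_truth(params)
        assert np.allclose(truth.freq_a, truth.freq_b)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            SimParams(fst_param=1.0)


class TestCallerNoise:
    def test_noise_free_reconstruction(self):
        """With perfect callers, consensus + merge reproduces the truth set exactly."""
        params = noise_free(SMALL)
        truth, matrix, cohort = simulate_cohort_truth(params)
        calls = simulate_caller_calls(truth, matrix, params)
        consensus = {s: within_sample_consensus(calls[s]) for s in cohort.samples}
        clusters, merged = merge_cohort(consensus, cohort)
        carried = (matrix.presence.sum(axis=0) > 0)
        assert len(clusters) == int(carried.sum())
        truth_keys = {
            (r.chrom, r.start, r.end, r.svtype.value)
            for r, c in zip(truth.records, carried)
            if c
        }
        rep_keys = {
            (c.representative.chrom, c.representative.start, c.representative.end,
             c.representative.svtype.value)
            for c in clusters
        }
        assert rep_keys == truth_keys
        assert np.array_equal(np.sort(merged.presence.sum(axis=0)),
                              np.sort(matrix.presence.sum(axis=0)[carried]))

    def test_independent_false_calls_removed_by_consensus(self):
        models = {
            c: CallerModel(sensitivity=1.0, fp_per_mb=1.0, breakpoint_jitter_sd=0.0,
                           length_jitter_sd=0.0, hq_prob=0.0)
            for c in ("cuteSV", "sniffles", "nanovar")
        }
        params = dataclasses.replace(SMALL, caller_models=models)
        truth, matrix, cohort = simulate_cohort_truth(params)
        calls = simulate_caller_calls(truth, matrix, params)
        s = cohort.samples[0]
        out = within_sample_consensus(calls[s])
        assert all("fp" not in r.id for r in out)

    def test_vcf_files_deterministic(self, tmp_path):
        from svpopscan import simulate_caller_vcfs

        params = dataclasses.replace(SMALL, n_pop_a=2, n_pop_b=2, m_svs=30)
        truth, matrix, cohort = simulate_cohort_truth(params)
        p1 = simulate_caller_vcfs(truth, matrix, params, tmp_path / "a")
        p2 = simulate_caller_vcfs(truth, matrix, params, tmp_path / "b")
        f1 = p1[cohort.samples[0]]["cuteSV"]
        f2 = p2[cohort.samples[0]]["cuteSV"]
        body = lambda p: [l for l in open(p) if not l.startswith("##")]
        assert body(f1) == body(f2)


class TestLinkedSnps:
    def test_perfect_tag_r2_one(self):
        params = dataclasses.replace(SMALL, tag_r2=1.0, n_background_snps=0)
        truth, matrix, _ = simulate_cohort_truth(params)
        snps = simulate_linked_snps(matrix, truth, params)
        for snp_id, (sv_id, _t) in truth.snp_tags.items():
            r2 = r2_dosage(matrix.dosage_of(sv_id), snps.dosage_of(snp_id))
            assert r2 == pytest.approx(1.0)

    def test_target_r2_realized_on_average(self):
        params = dataclasses.replace(
            SMALL, n_pop_a=150, n_pop_b=150, tag_r2=0.8, n_background_snps=0, n_selected=10
        )
        vals = []
        for seed in range(10):
            p = dataclasses.replace(params, seed=seed)
            truth, matrix, _ = simulate_cohort_truth(p)
            snps = simulate_linked_snps(matrix, truth, p)
            for snp_id, (sv_id, _t) in truth.snp_tags.items():
                r2 = r2_dosage(matrix.dosage_of(sv_id), snps.dosage_of(snp_id))
                if r2 is not None:
                    vals.append(r2)
        assert 0.75 <= np.mean(vals) <= 0.85

    def test_background_snps_unlinked(self):
        params = dataclasses.replace(SMALL, n_pop_a=100, n_pop_b=100, n_background_snps=50)
        truth, matrix, _ = simulate_cohort_truth(params)
        snps = simulate_linked_snps(matrix, truth, params)
        rng = np.random.default_rng(0)
        vals = []
        bg = [v for v in snps.variant_ids if v.startswith("bg")]
        for snp_id in bg[:30]:
            sv_id = truth.sv_ids[int(rng.integers(len(truth.sv_ids)))]
            r2 = r2_dosage(matrix.dosage_of(sv_id), snps.dosage_of(snp_id))
            if r2 is not None:
                vals.append(r2)
        assert np.mean(vals) < 0.05


class TestEndToEndBridgeRecovery:
    def test_default_cohort_recovers_implanted_bridges(self):
        """>= 95% of implanted SV-phenotype bridges survive the noisy pipeline:
        merged genotypes keep r2 >= 0.8 with their tag SNP and inherit the
        catalog phenotype."""
        from svpopscan import (
            ld_scan,
            merge_cohort,
            phenotype_bridge,
            simulate_annotations,
            sv_match,
        )
        from svpopscan.ld import LdParams

        params = SimParams(n_pop_a=60, n_pop_b=60, m_svs=400, n_selected=20, seed=123)
        truth, true_matrix, cohort = simulate_cohort_truth(params)
        calls = simulate_caller_calls(truth, true_matrix, params)
        consensus = {s: within_sample_consensus(calls[s]) for s in cohort.samples}
        clusters, matrix = merge_cohort(consensus, cohort)
        snps = simulate_linked_snps(true_matrix, truth, params)
        _tracks, catalog = simulate_annotations(params, truth)
        pairs = ld_scan(matrix, snps, LdParams())
        assoc = phenotype_bridge(pairs, catalog)
        bridged = {a.sv_id for a in assoc}
        rep_by_id = {c.representative.id: c.representative for c in clusters}
        hits = sum(
            1
            for _snp, (sv_id, _t) in truth.snp_tags.items()
            if any(
                sv_match(next(r for r in truth.records if r.id == sv_id), rep_by_id[v])
                for v in bridged
            )
        )
        assert hits >= 0.95 * len(truth.snp_tags), f"{hits}/{len(truth.snp_tags)}"


class TestAnnotations:
    def test_repeat_coverage_fraction(self):
        tracks, _ = simulate_annotations(SMALL, repeat_fraction=0.5)
        genome_bp = sum(s for _c, s in SMALL.genome)
        frac = tracks["repeats"].covered_bp() / genome_bp
        assert 0.49 <= frac <= 0.51

    def test_enhancer_near_selected_sv_found_with_pad(self):
        from svpopscan import RegulatoryParams, intersect_elements

        truth, _, _ = simulate_cohort_truth(SMALL)
        tracks, _ = simulate_annotations(SMALL, truth)
        sel = [truth.records[i] for i in np.nonzero(truth.selected)[0]]
        table, summary = intersect_elements(
            sel, RegulatoryParams(pad=100, tracks=[tracks["enhancers"]])
        )
        assert summary["enhancers"] == len(sel)

    def test_catalog_covers_tag_snps(self):
        params = dataclasses.replace(SMALL)
        truth, matrix, _ = simulate_cohort_truth(params)
        simulate_linked_snps(matrix, truth, params)
        _, catalog = simulate_annotations(params, truth)
        for snp_id in truth.snp_tags:
            assert catalog.phenotypes_of(snp_id)

    def test_deterministic_tracks(self):
        t1, _ = simulate_annotations(SMALL, repeat_fraction=0.4)
        t2, _ = simulate_annotations(SMALL, repeat_fraction=0.4)
        assert t1["repeats"].intervals == t2["repeats"].intervals
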