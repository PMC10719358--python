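"""Cohort statistics: frequencies, HWE, F_ST, power law, PCA, clustering."""

import numpy as np
import pytest

from svpopscan import (
    Cohort,
    GenotypeMatrix,
    SVType,
    af_spectrum,
    carrier_frequency,
    cluster_tree,
    gc_content_profile,
    hwe_test,
    powerlaw_fit,
    presence_pca,
    saturation_curve,
    weir_cockerham_fst,
)
from svpopscan.popgen import _hwe_chi2, hudson_fst

from conftest import make_sv


def matrix_from(dosages, pops=None):
    d = np.asarray(dosages, dtype=np.int8)
    samples = [f"s{i}" for i in range(d.shape[0])]
    m = GenotypeMatrix(d, samples, [f"v{j}" for j in range(d.shape[1])])
    if pops is None:
        return m
    cohort = Cohort.from_items([(s, p) for s, p in zip(samples, pops)])
    return m, cohort


class TestCarrierFrequency:
    def test_fraction_of_carriers(self):
        m = matrix_from([[1], [0], [2], [0], [-1]])
        freqs = carrier_frequency(m)
        assert freqs["v0"] == pytest.approx(2 / 5)  # missing counts as non-carrier

    def test_empty_population_rejected(self):
        m = matrix_from([[1]])
        with pytest.raises(ValueError):
            carrier_frequency(m, [])

    def test_extremes(self):
        m = matrix_from([[0, 2], [0, 1]])
        freqs = carrier_frequency(m)
        assert freqs["v0"] == 0 and freqs["v1"] == 1


class TestAfSpectrum:
    def test_level_boundaries(self):
        spec = af_spectrum({"a": 0.05, "b": 0.1, "c": 0.2, "d": 0.4, "e": 0.5, "f": 1.0})
        # 0.1 belongs to the low class (left-open right-closed), 0.4 to intermediate
        assert spec.bins == (2, 2, 1, 1)

    def test_singleton_counted(self):
        m = matrix_from([[1], [0], [0]])
        spec = af_spectrum({"v0": 1 / 3}, m)
        assert spec.singletons == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            af_spectrum({"a": 1.2})


class TestHwe:
    def test_perfect_hwe_chi2_zero(self):
        assert _hwe_chi2(25, 50, 25) == (0.0, 1.0)

    def test_worked_chi2_values(self):
        chi2, p = _hwe_chi2(30, 40, 30)
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(0.0455, abs=1e-3)
        assert _hwe_chi2(50, 0, 50)[0] == pytest.approx(100.0)

    def test_bonferroni_and_fraction(self):
        d = np.array([[0] * 2] * 25 + [[1] * 2] * 50 + [[2] * 2] * 25, dtype=np.int8)
        m = GenotypeMatrix(d, [f"s{i}" for i in range(100)], ["v0", "v1"])
        results, frac = hwe_test(m)
        assert frac == 1.0
        assert all(r.bonferroni_p == min(1.0, r.p * 2) for r in results)

    def test_all_missing_excluded(self):
        d = np.array([[-1, 1], [-1, 1], [-1, 0], [-1, 0]], dtype=np.int8)
        m = GenotypeMatrix(d, list("abcd"), ["v0", "v1"])
        results, _ = hwe_test(m)
        assert [r.variant_id for r in results] == ["v1"]


class TestWeirCockerham:
    def test_fixed_difference_components(self):
        m, cohort = matrix_from([[2]] * 10 + [[0]] * 10, ["A"] * 10 + ["B"] * 10)
        res = weir_cockerham_fst(m, cohort)
        comp = res.per_site["v0"]
        assert comp.a == pytest.approx(0.5)
        assert comp.b == pytest.approx(0.0)
        assert comp.c == pytest.approx(0.0)
        assert comp.theta == pytest.approx(1.0)
        assert res.weighted == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        col = [0] * 5 + [1] * 10 + [2] * 5
        m, cohort = matrix_from([[c] for c in col + col], ["A"] * 20 + ["B"] * 20)
        res = weir_cockerham_fst(m, cohort)
        assert res.per_site["v0"].theta <= 0

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(40, 30)).astype(np.int8)
        pops = ["A"] * 20 + ["B"] * 20
        m, cohort = matrix_from(d, pops)
        m2, _ = matrix_from(2 - d, pops)
        r1 = weir_cockerham_fst(m, cohort)
        r2 = weir_cockerham_fst(m2, cohort)
        for v in r1.per_site:
            t1, t2 = r1.per_site[v].theta, r2.per_site[v].theta
            assert (t1 is None) == (t2 is None)
            if t1 is not None:
                assert t1 == pytest.approx(t2, abs=1e-12)

    def test_monomorphic_site_undefined(self):
        m, cohort = matrix_from([[0, 1]] * 4 + [[0, 1]] * 4, ["A"] * 4 + ["B"] * 4)
        res = weir_cockerham_fst(m, cohort)
        assert res.per_site["v0"].theta is None
        assert res.n_undefined >= 1

    def test_three_populations_rejected(self):
        m, cohort = matrix_from([[1]] * 3, ["A", "B", "C"])
        with pytest.raises(ValueError, match="2 populations"):
            weir_cockerham_fst(m, cohort)

    def test_hudson_differs_but_correlates(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(60, 50)).astype(np.int8)
        m, cohort = matrix_from(d, ["A"] * 30 + ["B"] * 30)
        wc = weir_cockerham_fst(m, cohort)
        hud = hudson_fst(m, cohort)
        assert set(hud) <= set(m.variant_ids)
        assert len(hud) > 30


class TestPowerLaw:
    def test_alpha_recovery_single_seed(self):
        rng = np.random.default_rng(0)
        x = 1.0 * (1 - rng.random(5000)) ** (-1 / 1.5)  # alpha = 2.5, xmin = 1
        fit = powerlaw_fit(x, n_bootstrap=0, seed=0)
        assert 2.3 <= fit.alpha <= 2.7
        assert fit.n_tail >= 100

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            powerlaw_fit([3.0] * 100, n_bootstrap=0, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x = (1 - rng.random(500)) ** (-1 / 1.5)
        f1 = powerlaw_fit(x, n_bootstrap=20, seed=5)
        f2 = powerlaw_fit(x, n_bootstrap=20, seed=5)
        assert (f1.alpha, f1.xmin, f1.gof_p) == (f2.alpha, f2.xmin, f2.gof_p)


class TestSaturation:
    def test_cumulative_union_example(self):
        # sample SV sets {A,B}, {B,C}, {C}
        m = matrix_from([[1, 1, 0], [0, 1, 1], [0, 0, 1]])
        mean, curves = saturation_curve(m, n_orders=6, seed=0)
        assert all(curves[k, -1] == 3 for k in range(6))
        assert all(np.all(np.diff(curves[k]) >= 0) for k in range(6))

    def test_single_sample(self):
        m = matrix_from([[1, 0, 1]])
        mean, _ = saturation_curve(m, 1, 0)
        assert list(mean) == [2]


class TestGcContent:
    def test_gc_fractions(self):
        ref = {"chr1": "GGCCATATGATC"}
        svs = [
            make_sv(id="gc", chrom="chr1", start=0, end=4),
            make_sv(id="at", chrom="chr1", start=4, end=8),
            make_sv(id="half", chrom="chr1", start=8, end=12),
        ]
        gc, share = gc_content_profile(svs, ref)
        assert gc["gc"] == 1.0 and gc["at"] == 0.0 and gc["half"] == 0.5
        assert share == pytest.approx(1 / 3)  # only "gc" is >= 0.55

    def test_span_outside_reference_errors(self):
        with pytest.raises(ValueError):
            gc_content_profile([make_sv(start=0, end=100)], {"chr1": "ACGT"})


class TestPcaAndTree:
    def test_two_blocks_separate_on_pc1(self, two_block_matrix):
        scores, ratio = presence_pca(two_block_matrix, 2)
        pc1 = scores[:, 0]
        assert (np.sign(pc1[:10]) == np.sign(pc1[0])).all()
        assert (np.sign(pc1[10:]) == -np.sign(pc1[0])).all()
        assert ratio[0] > ratio[1] > 0

    def test_scores_orthogonal(self, two_block_matrix):
        scores, _ = presence_pca(two_block_matrix, 3)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_k_too_large_rejected(self, two_block_matrix):
        with pytest.raises(ValueError):
            presence_pca(two_block_matrix, 20)

    def test_tree_is_valid_newick_and_splits_blocks(self, two_block_matrix):
        import dendropy

        nwk = cluster_tree(two_block_matrix, "average")
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 20
        # top split separates the two blocks
        children = tree.seed_node.child_nodes()
        sides = [
            {leaf.taxon.label for leaf in child.leaf_iter()} for child in children
        ]
        blocks = {frozenset(two_block_matrix.samples[:10]), frozenset(two_block_matrix.samples[10:])}
        assert {frozenset(s) for s in sides} == blocks

    def test_single_sample_rejected(self):
        m = matrix_from([[1]])
        with pytest.raises(ValueError):
            cluster_tree(m)
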