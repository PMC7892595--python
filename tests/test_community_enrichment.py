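import numpy as np
import pandas as pd
import pytest

from sipdenit.community_enrichment import (
    bray_curtis_matrix,
    call_labeled,
    diversity_table,
    enrichment_test,
    goods_coverage,
    inverse_simpson,
    pcoa,
    size_factors,
)
from sipdenit.pipeline import sip_call
from sipdenit.synthetic_data import SipScenario, simulate_gradient_counts

from conftest import planted_fold_tables


class TestGoodsCoverage:
    @pytest.mark.parametrize(
        "counts,expected",
        [([2, 2], 100.0), ([1, 1, 1, 1], 0.0), ([5, 3, 1, 1], 80.0)],
    )
    def test_values(self, counts, expected):
        assert goods_coverage(counts) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            goods_coverage([])


class TestInverseSimpson:
    @pytest.mark.parametrize(
        "counts,expected",
        [([37], 1.0), ([50, 50], 2.0), ([70, 30], 1.7241)],
    )
    def test_values(self, counts, expected):
        assert inverse_simpson(counts).inverse_simpson == pytest.approx(
            expected, abs=1e-4
        )

    def test_scale_invariant_and_maximal_on_uniform(self):
        d1 = inverse_simpson([10, 20, 30]).inverse_simpson
        d2 = inverse_simpson([100, 200, 300]).inverse_simpson
        assert d1 == pytest.approx(d2)
        uniform = inverse_simpson([50, 50, 50]).inverse_simpson
        assert uniform == pytest.approx(3.0)  # equals richness
        assert d1 < uniform

    def test_bootstrap_ci_brackets_estimate(self):
        summ = inverse_simpson([70, 30, 55, 12, 3], n_boot=300, seed=1)
        lo, hi = summ.inv_simpson_ci
        assert lo <= summ.inverse_simpson <= hi

    def test_ci_requires_positive_n_boot(self):
        with pytest.raises(ValueError):
            inverse_simpson([5, 5], n_boot=-1)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = pd.DataFrame({"a": [3, 1], "b": [3, 1]}, index=["x", "y"])
        d = bray_curtis_matrix(t)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        t = pd.DataFrame({"a": [5, 0], "b": [0, 9]}, index=["x", "y"])
        assert bray_curtis_matrix(t).loc["a", "b"] == pytest.approx(1.0)

    def test_unnormalized_worked_example(self):
        t = pd.DataFrame({"a": [6, 2], "b": [2, 2]}, index=["x", "y"])
        d = bray_curtis_matrix(t, normalization="none")
        assert d.loc["a", "b"] == pytest.approx(1 - 8 / 12, abs=1e-4)

    def test_all_zero_sample_named(self):
        t = pd.DataFrame({"a": [1, 1], "bad": [0, 0]}, index=["x", "y"])
        with pytest.raises(ValueError, match="bad"):
            bray_curtis_matrix(t)

    def test_bounded_symmetric(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(0, 100, (20, 6)) + 1)
        d = bray_curtis_matrix(t).to_numpy()
        assert ((d >= 0) & (d <= 1)).all()
        np.testing.assert_allclose(d, d.T)


class TestPCoA:
    def test_all_zero_matrix_gives_zero_coordinates(self):
        res = pcoa(np.zeros((4, 4)))
        assert (res.coordinates.to_numpy() == 0).all()

    def test_planar_point_set_roundtrip(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        d2 = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_percent_variance_sums_to_100(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        assert pcoa(d).percent_variance.sum() == pytest.approx(100.0)

    def test_asymmetric_errors(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)

    def test_negative_eigenvalues_reported(self):
        # a metric but non-Euclidean configuration: four points with two
        # long opposite pairs cannot be embedded, so classical scaling
        # yields a negative eigenvalue that must be reported as-is
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.9
        d[2, 3] = d[3, 2] = 1.9
        res = pcoa(d)
        assert res.eigenvalues.min() < -1e-6
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_agrees_with_skbio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(6)
        t = pd.DataFrame(
            rng.integers(1, 80, (25, 7)),
            columns=[f"s{i}" for i in range(7)],
        )
        d = bray_curtis_matrix(t)
        ours = pcoa(d)
        import skbio

        theirs = skbio_ord.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates.iloc[:, 0].to_numpy()),
            np.abs(theirs.samples.iloc[:, 0].to_numpy()),
            atol=1e-6,
        )


class TestSizeFactors:
    def test_depth_difference_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.integers(20, 200, size=(50, 1))
        counts = np.hstack([base, base * 3])
        sf = size_factors(counts.astype(float))
        assert sf[1] / sf[0] == pytest.approx(3.0, rel=1e-6)

    def test_sparse_table_falls_back_to_library_size(self):
        counts = np.array([[10, 0, 20], [0, 10, 20], [5, 5, 0], [1, 1, 1.0]])
        sf = size_factors(counts)
        lib = counts.sum(axis=0)
        expected = lib / np.exp(np.mean(np.log(lib)))
        np.testing.assert_allclose(sf, expected)


class TestEnrichmentTest:
    def test_identical_sides_give_null(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.integers(0, 100, (40, 3)))
        res = enrichment_test(mat, mat.copy())
        np.testing.assert_allclose(res["log2fc"].to_numpy(), 0.0, atol=1e-12)
        assert not (res["padj"] < 0.05).any()

    def test_planted_eightfold_enrichment_recovered(self):
        heavy, light = planted_fold_tables(fold=8.0, seed=1)
        res = enrichment_test(heavy, light, n_perm=10_000, seed=1)
        planted = res.loc["OTU_000"]
        assert 2.5 <= planted["log2fc"] <= 3.5
        assert planted["padj"] < 0.05

    def test_mean_log2fc_unbiased_over_seeds(self):
        fcs = []
        for seed in range(8):
            heavy, light = planted_fold_tables(fold=8.0, seed=seed)
            res = enrichment_test(heavy, light, n_perm=2_000, seed=seed)
            fcs.append(res.loc["OTU_000", "log2fc"])
        assert abs(np.mean(fcs) - 3.0) < 0.25

    def test_all_zero_otus_excluded_and_counted(self):
        heavy, light = planted_fold_tables(seed=3, n_otus=30)
        heavy.loc["OTU_005"] = 0
        light.loc["OTU_005"] = 0
        res = enrichment_test(heavy, light, n_perm=200, seed=0)
        assert res.attrs["n_excluded"] == 1
        assert np.isnan(res.loc["OTU_005", "p"])

    def test_too_few_replicates_error(self):
        heavy, light = planted_fold_tables(seed=0, n_replicates=1,
                                           fractions_per_rep=1)
        with pytest.raises(ValueError, match="2 replicates"):
            enrichment_test(heavy, light)

    def test_exact_enumeration_for_small_designs(self):
        heavy, light = planted_fold_tables(seed=0, n_replicates=1,
                                           fractions_per_rep=3)
        res = enrichment_test(heavy, light)
        assert res.attrs["mode"] == "exact"
        assert res["p"].dropna().min() >= 1 / 20


class TestCallLabeled:
    def test_identical_results_empty(self):
        heavy, light = planted_fold_tables(seed=4)
        res = enrichment_test(heavy, light, n_perm=500, seed=0)
        call = call_labeled(res, res, res)
        assert call.labeled_otus == frozenset()

    def test_mismatched_universe_errors(self):
        heavy, light = planted_fold_tables(seed=4, n_otus=20)
        res = enrichment_test(heavy, light, n_perm=200, seed=0)
        with pytest.raises(ValueError, match="universe"):
            call_labeled(res, res.iloc[:-1], res)

    def test_single_planted_assimilator_called(self):
        fc, truth = simulate_gradient_counts(SipScenario(seed=11))
        call = sip_call(fc, seed=11)
        assert call.labeled_otus == frozenset(truth["labeled_otus"])

    def test_two_planted_assimilators_called(self):
        scn = SipScenario(
            seed=5, labeled_otus={"OTU_001": 0.9, "OTU_010": 0.8}
        )
        fc, truth = simulate_gradient_counts(scn)
        call = sip_call(fc, seed=5)
        assert call.labeled_otus == frozenset({"OTU_001", "OTU_010"})

    def test_no_shift_gives_empty_call(self):
        fc, _ = simulate_gradient_counts(SipScenario(seed=6, labeled_otus={}))
        call = sip_call(fc, seed=6)
        assert call.labeled_otus == frozenset()


def test_diversity_table_layout():
    fc, _ = simulate_gradient_counts(SipScenario(seed=0, n_otus=30))
    table = diversity_table(fc.counts, fc.sample_meta, n_boot=50, seed=0)
    assert {"treatment", "label", "inv_simpson", "lci", "hci"} <= set(
        table.columns
    )
    heavy_13c = table[(table["treatment"] == "13C") & (table["label"] == "heavy")]
    light_13c = table[(table["treatment"] == "13C") & (table["label"] == "light")]
    # labeled-treatment heavy fractions are near-monocultures of the
    # assimilator: much lower diversity than the light fractions
    assert float(heavy_13c["inv_simpson"]) < float(light_13c["inv_simpson"])
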