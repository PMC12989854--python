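"""Imputation, stacking, and Mahalanobis outlier detection."""

import numpy as np
import pytest

from genepace.distances import DistanceTensor
from genepace.outliers import (
    DegenerateMatrix,
    DetectionParams,
    chi2_pvalue,
    detect_outliers,
    flag_driver_taxa,
    flag_outlier_genes,
    impute_diagonal,
    impute_missing,
    log_transform,
    mahalanobis_sq,
    stack_genes,
)
from conftest import random_tensor


def brute_force_imputation(tensor):
    """Two-pass mean recomputation, cell by cell, in plain loops."""
    v = tensor.values
    g_count, n, _ = v.shape
    out = v.copy()
    for g in range(g_count):
        gene_vals = [
            v[g, a, b]
            for a in range(n)
            for b in range(a + 1, n)
            if not np.isnan(v[g, a, b])
        ]
        gene_mean = np.mean(gene_vals) if gene_vals else np.nan
        for a in range(n):
            for b in range(a + 1, n):
                if not np.isnan(v[g, a, b]):
                    continue
                pair_vals = [
                    v[h, a, b] for h in range(g_count) if not np.isnan(v[h, a, b])
                ]
                pair_mean = np.mean(pair_vals) if pair_vals else np.nan
                parts = [m for m in (gene_mean, pair_mean) if not np.isnan(m)]
                out[g, a, b] = out[g, b, a] = np.mean(parts)
    return out


class TestImputation:
    def test_blended_mean_of_gene_and_pair_components(self):
        values = np.full((2, 3, 3), np.nan)
        for g in range(2):
            np.fill_diagonal(values[g], 0.0)
        # gene 0: all pairs observed at 0.2 -> gene mean 0.2
        values[0][np.triu_indices(3, 1)] = 0.2
        values[0] = np.triu(values[0]) + np.triu(values[0], 1).T
        # gene 1: pair (0,1) missing; its cross-gene pair mean is 0.2;
        # gene 1's own mean over (0,2),(1,2) is (0.5+0.3)/2 = 0.4
        values[1, 0, 2] = values[1, 2, 0] = 0.5
        values[1, 1, 2] = values[1, 2, 1] = 0.3
        t = DistanceTensor("m", ("a", "b", "c"), ("g1", "g2"), values)
        out = impute_missing(t)
        assert out.values[1, 0, 1] == pytest.approx((0.2 + 0.4) / 2)
        assert out.values[1, 1, 0] == out.values[1, 0, 1]

    def test_no_missing_is_identity(self, rng):
        t = random_tensor(rng, missing_frac=0.0)
        out = impute_missing(t)
        np.testing.assert_array_equal(out.values, t.values)

    def test_matches_brute_force_on_random_missingness(self, rng):
        t = random_tensor(rng, n_genes=15, n_taxa=6, missing_frac=0.05)
        out = impute_missing(t)
        np.testing.assert_allclose(out.values, brute_force_imputation(t), atol=1e-12)

    def test_diagonal_is_row_mean(self, rng):
        t = impute_missing(random_tensor(rng, n_genes=8, n_taxa=5))
        out = impute_diagonal(t)
        v = out.values
        for g in range(8):
            for a in range(5):
                others = [v[g, a, b] for b in range(5) if b != a]
                assert v[g, a, a] == pytest.approx(np.mean(others))

    def test_constant_tensor_diagonal(self):
        values = np.full((2, 4, 4), 0.7)
        t = DistanceTensor("m", tuple("abcd"), ("g1", "g2"), values)
        out = impute_diagonal(t)
        assert np.allclose(out.values, 0.7)


class TestLogAndStack:
    def test_log_of_zero_is_log_eps(self, rng):
        t = random_tensor(rng, n_genes=3, n_taxa=4)
        t.values[0, 0, 1] = t.values[0, 1, 0] = 0.0
        out = log_transform(t, eps=1e-6)
        assert out.values[0, 0, 1] == pytest.approx(np.log(1e-6))

    def test_log_preserves_ordering(self, rng):
        t = random_tensor(rng, n_genes=5, n_taxa=5)
        out = log_transform(t)
        iu = np.triu_indices(5, 1)
        orig = t.values[:, iu[0], iu[1]].ravel()
        logged = out.values[:, iu[0], iu[1]].ravel()
        assert np.array_equal(np.argsort(orig), np.argsort(logged))

    def test_stack_column_count_and_order(self, rng):
        t = random_tensor(rng, n_genes=4, n_taxa=18)
        stacked = stack_genes(t)
        assert stacked.values.shape == (4, 18 * 17 // 2)
        t3 = random_tensor(rng, n_genes=1, n_taxa=3)
        s3 = stack_genes(t3)
        v = t3.values[0]
        np.testing.assert_array_equal(s3.values[0], [v[0, 1], v[0, 2], v[1, 2]])

    def test_stack_round_trip(self, rng):
        t = random_tensor(rng, n_genes=5, n_taxa=6)
        stacked = stack_genes(t)
        iu = np.triu_indices(6, 1)
        rebuilt = np.zeros_like(t.values)
        rebuilt[:, iu[0], iu[1]] = stacked.values
        rebuilt[:, iu[1], iu[0]] = stacked.values
        np.testing.assert_array_equal(rebuilt, t.values)


class TestMahalanobis:
    def test_row_at_mean_scores_zero(self, rng):
        # data symmetric about a centre, plus the centre itself: the
        # column mean is exactly the centre, whose D2 must vanish
        centre = np.array([1.0, 2.0, 3.0, 4.0])
        half = np.vstack([centre + rng.normal(size=4) for _ in range(6)])
        x = np.vstack([half, 2 * centre - half, centre])
        d2 = mahalanobis_sq(x)
        assert d2[-1] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_single_column(self):
        d2 = mahalanobis_sq(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(d2, [0.5, 0.5])

    def test_matches_explicit_formula(self, rng):
        x = rng.normal(size=(200, 10))
        mu = x.mean(axis=0)
        cov = np.cov(x, rowvar=False)
        inv = np.linalg.inv(cov)
        expected = np.array([(r - mu) @ inv @ (r - mu) for r in x])
        np.testing.assert_allclose(mahalanobis_sq(x), expected, atol=1e-8)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(80, 6))
        d2 = mahalanobis_sq(x)
        a = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        shift = rng.normal(size=6)
        d2t = mahalanobis_sq(x @ a + shift)
        np.testing.assert_allclose(d2, d2t, atol=1e-6)

    def test_ray_monotonicity(self, rng):
        x = rng.normal(size=(60, 5))
        mu = x.mean(axis=0)
        v = rng.normal(size=5)
        scores = []
        for c in np.linspace(0, 4, 9):
            probe = np.vstack([x, mu + c * v])
            # score the probe against the fixed base distribution
            cov = np.cov(x, rowvar=False)
            inv = np.linalg.inv(cov)
            diff = probe[-1] - mu
            scores.append(diff @ inv @ diff)
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_identical_rows_degenerate(self):
        with pytest.raises(DegenerateMatrix):
            mahalanobis_sq(np.ones((5, 3)))

    def test_rank_deficient_uses_pseudo_inverse(self, rng):
        base = rng.normal(size=(30, 2))
        x = np.hstack([base, base[:, :1] + base[:, 1:]])  # third col dependent
        with pytest.warns(RuntimeWarning, match="pseudo-inverse"):
            d2 = mahalanobis_sq(x)
        assert np.isfinite(d2).all()


class TestChi2AndFlags:
    def test_zero_distance_gives_p_one(self):
        assert chi2_pvalue(0.0, 10) == 1.0

    def test_df1_quantile_matches_inverse(self):
        from scipy import stats

        q95 = stats.chi2.ppf(0.95, 1)
        assert chi2_pvalue(q95, 1) == pytest.approx(0.05, abs=1e-12)

    def test_monotone_decreasing_in_d2(self):
        assert chi2_pvalue(5.0, 3) > chi2_pvalue(9.0, 3)

    @pytest.mark.parametrize("n,expected", [(100, 5), (20, 1)])
    def test_distinct_values_flag_count(self, n, expected):
        d2 = np.arange(n, dtype=float)
        report = flag_outlier_genes(d2, [f"g{k}" for k in range(n)], df=3)
        assert int(report["is_outlier"].sum()) == expected

    def test_ties_at_threshold_excluded(self):
        report = flag_outlier_genes(np.ones(50), [f"g{k}" for k in range(50)], df=3)
        assert int(report["is_outlier"].sum()) == 0

    def test_bonferroni_capped_at_one(self):
        report = flag_outlier_genes(
            np.array([0.1, 0.2, 30.0]), ["a", "b", "c"], df=2
        )
        assert (report["bonferroni_p"] <= 1).all()


class TestDriversAndPipeline:
    def test_driver_row_count_and_flag_arithmetic(self, rng):
        t = impute_diagonal(impute_missing(random_tensor(rng, n_genes=40, n_taxa=6)))
        genes = list(t.gene_ids[:10])
        report = flag_driver_taxa(t, genes)
        assert len(report) == 60
        assert int(report["is_driver"].sum()) == 3

    def test_drivers_concentrate_in_accelerated_clades(self, small_sim):
        tensors, truth = small_sim
        _, taxon_report = detect_outliers(tensors["omega"])
        clade_rows = {
            (g, t)
            for g, t, inside in zip(
                truth.drivers["gene_id"],
                truth.drivers["taxon"],
                truth.drivers["in_focal_clade"],
            )
            if inside
        }
        flagged = taxon_report[taxon_report["is_driver"]]
        flagged_pairs = list(zip(flagged["gene_id"], flagged["taxon"]))
        hit_rate = np.mean([pair in clade_rows for pair in flagged_pairs])
        # baseline: fraction of clade rows among all scored rows
        scored = list(zip(taxon_report["gene_id"], taxon_report["taxon"]))
        base_rate = np.mean([pair in clade_rows for pair in scored])
        assert hit_rate > base_rate

    def test_pipeline_matches_stage_by_stage(self, small_sim):
        tensors, _ = small_sim
        tensor = tensors["omega"]
        params = DetectionParams()
        gene_report, _ = detect_outliers(tensor, params)
        manual = log_transform(
            impute_diagonal(impute_missing(tensor)), params.log_eps
        )
        d2 = mahalanobis_sq(stack_genes(manual).values)
        expected = flag_outlier_genes(
            d2, tensor.gene_ids, df=len(stack_genes(manual).pair_labels)
        )
        np.testing.assert_allclose(gene_report["D2"], expected["D2"])
        assert list(gene_report["gene_id"]) == list(expected["gene_id"])

    def test_rerun_is_deterministic(self, small_sim):
        tensors, _ = small_sim
        r1 = detect_outliers(tensors["dN"])
        r2 = detect_outliers(tensors["dN"])
        for a, b in zip(r1, r2):
            assert a.equals(b)

    def test_no_flagged_genes_gives_empty_driver_report(self, rng):
        t = random_tensor(rng, n_genes=30, n_taxa=4)
        params = DetectionParams(quantile=1.0)
        gene_report, taxon_report = detect_outliers(t, params)
        assert int(gene_report["is_outlier"].sum()) == 0
        assert len(taxon_report) == 0

    def test_gene_flags_invariant_under_taxon_relabeling(self, rng):
        t = random_tensor(rng, n_genes=50, n_taxa=5)
        perm = rng.permutation(5)
        permuted = DistanceTensor(
            t.metric,
            tuple(t.taxa[k] for k in perm),
            t.gene_ids,
            t.values[:, perm][:, :, perm],
        )
        r1, _ = detect_outliers(t)
        r2, _ = detect_outliers(permuted)
        s1 = set(r1.loc[r1["is_outlier"], "gene_id"])
        s2 = set(r2.loc[r2["is_outlier"], "gene_id"])
        assert s1 == s2
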