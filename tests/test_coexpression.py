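"""Correlation statistics: sign splits, ratios, binomial tails, LOD/TRM."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from coregnet.coexpression import (CorrelationAccessor, ExpressionMatrix,
                                   binomial_tail, lod, pearson_all_pairs,
                                   percent_increase_by_shared,
                                   ratio_enrichment_test, sign_fractions,
                                   tf_pair_trend, tf_ratio_table,
                                   tf_target_ratio, trm_lod_profile)
from coregnet.promoterome import PMatrix, cross_product

from conftest import make_pmatrix


def make_expression(values, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i+1}" for i in range(len(values))]
    conds = [f"C{c+1}" for c in range(values.shape[1])]
    return ExpressionMatrix(genes, conds, values)


class TestCorrelationAccessor:
    def test_duplicate_and_negated_gene(self):
        base = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        E = make_expression([base, base, -base], genes=["a", "b", "c"])
        acc = pearson_all_pairs(E)
        assert acc.r("a", "b") == pytest.approx(1.0)
        assert acc.r("a", "c") == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 5))
        acc = pearson_all_pairs(make_expression(X))
        for i in range(10):
            for j in range(i + 1, 10):
                xi, xj = X[i], X[j]
                cov = ((xi - xi.mean()) * (xj - xj.mean())).mean()
                r_naive = cov / (xi.std() * xj.std())
                assert acc.r(f"g{i+1}", f"g{j+1}") == pytest.approx(r_naive, abs=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 8))
        acc = pearson_all_pairs(make_expression(X))
        assert acc.r("g1", "g4") == pytest.approx(pearsonr(X[0], X[3])[0], abs=1e-12)

    def test_zero_variance_flagged(self):
        E = make_expression([[1, 2, 3], [5, 5, 5]])
        acc = pearson_all_pairs(E)
        assert not acc.defined[1]
        assert math.isnan(acc.r("g1", "g2"))
        assert len(acc.upper_triangle()) == 0

    def test_too_few_conditions(self):
        with pytest.raises(ValueError):
            make_expression([[1, 2], [3, 4]])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            make_expression([[1, np.nan, 3]])


class TestSignFractions:
    def test_all_positive(self):
        assert sign_fractions(np.array([0.2, 0.5, 0.0])) == (100.0, 0.0)

    def test_symmetric_toy(self):
        assert sign_fractions(np.array([0.5, -0.5])) == (50.0, 50.0)

    def test_tally_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 6))
        acc = pearson_all_pairs(make_expression(X))
        vals = acc.upper_triangle()
        pos, neg = sign_fractions(acc)
        assert pos == pytest.approx(100 * (vals >= 0).mean())
        assert pos + neg == pytest.approx(100.0)


class TestPercentIncrease:
    def test_null_curve_flat(self, small_dataset):
        """Shuffling P-matrix columns breaks the sharing/co-expression link:
        the percent-increase curve should be 0 within noise."""
        P = small_dataset.pmatrix
        acc = pearson_all_pairs(small_dataset.expression.subset(P.genes))
        rng = np.random.default_rng(0)
        curves = []
        for _ in range(20):
            vals = P.values.copy()
            for j in range(vals.shape[1]):
                rng.shuffle(vals[:, j])
            Pn = PMatrix(P.genes, P.tfs, vals)
            curves.append(percent_increase_by_shared(acc, Pn, "absolute", max_k=4)
                          ["pct_increase"].to_numpy())
        curves = np.array(curves)
        mean = np.nanmean(curves, axis=0)
        se = np.nanstd(curves, axis=0, ddof=1) / np.sqrt(20)
        for k in range(1, 5):
            if np.isfinite(mean[k]) and se[k] > 0:
                assert abs(mean[k]) < 3 * se[k] + 1e-9

    def test_activator_driven_signal_increases(self, small_dataset):
        P = small_dataset.pmatrix
        acc = pearson_all_pairs(small_dataset.expression.subset(P.genes))
        curve = percent_increase_by_shared(acc, P, "absolute", max_k=4)
        vals = curve["pct_increase"].to_numpy()
        assert vals[0] == pytest.approx(0.0)
        assert np.all(np.diff(vals[:5]) > 0)

    def test_single_bin_is_zero(self):
        P = make_pmatrix([[1], [1], [1]])
        rng = np.random.default_rng(1)
        acc = pearson_all_pairs(make_expression(rng.normal(size=(3, 5))))
        curve = percent_increase_by_shared(acc, P, max_k=1)
        assert curve.loc[0, "pct_increase"] == pytest.approx(0.0)
        assert curve.loc[1, "pct_increase"] == pytest.approx(0.0)  # all pairs share 1


class TestTFPairTrend:
    def test_no_sharing_single_point(self):
        P = make_pmatrix([[1, 0], [0, 1]], tfs=["A", "B"])
        rng = np.random.default_rng(0)
        E = make_expression(rng.normal(size=(2, 6)), genes=["A", "B"])
        trend = tf_pair_trend(pearson_all_pairs(E), cross_product(P), ["A", "B"])
        assert len(trend) == 1
        assert trend.loc[0, "pct_increase"] == pytest.approx(0.0)
        assert trend.loc[0, "cum_freq"] == 1.0

    def test_hand_computation(self):
        # 3 TFs; targets A={w,x}, B={w,x,y}, C={y,z}: shared A-B=2, A-C=0, B-C=1
        P = make_pmatrix([[1, 1, 0], [1, 1, 0], [0, 1, 1], [0, 0, 1]],
                         genes=list("wxyz"), tfs=["A", "B", "C"])
        base = np.array([1.0, 2.0, 3.0, 5.0, 4.0, 7.0])
        rng = np.random.default_rng(5)
        E = make_expression([base, base + rng.normal(0, 0.5, 6),
                             rng.normal(size=6)], genes=["A", "B", "C"])
        acc = pearson_all_pairs(E)
        X = cross_product(P)
        trend = tf_pair_trend(acc, X, ["A", "B", "C"], thresholds=[0, 1, 2])
        r = {p: abs(acc.r(*p)) for p in [("A", "B"), ("A", "C"), ("B", "C")]}
        overall = np.mean(list(r.values()))
        exp_t1 = np.mean([r[("A", "B")], r[("B", "C")]])
        assert trend.loc[0, "mean_abs_corr"] == pytest.approx(overall)
        assert trend.loc[1, "mean_abs_corr"] == pytest.approx(exp_t1)
        assert trend.loc[1, "pct_increase"] == pytest.approx(100 * (exp_t1 / overall - 1))
        assert trend.loc[2, "mean_abs_corr"] == pytest.approx(r[("A", "B")])
        assert trend.loc[2, "cum_freq"] == pytest.approx(1 / 3)

    def test_duplicated_tf_columns(self):
        P = make_pmatrix([[1, 1, 0], [1, 1, 0], [1, 1, 1]], tfs=["A", "B", "C"])
        base = np.arange(6.0)
        E = make_expression([base, base * 2 + 1, base[::-1].copy()],
                            genes=["A", "B", "C"])
        acc = pearson_all_pairs(E)
        trend = tf_pair_trend(acc, cross_product(P), ["A", "B", "C"])
        # A and B share all 3 targets and are perfectly correlated
        top = trend[trend["min_shared_targets"] == 3]
        assert top["n_pairs"].iloc[0] == 1
        assert top["mean_abs_corr"].iloc[0] == pytest.approx(1.0)


class TestTFTargetRatio:
    def test_background_equal_targets_gives_one(self):
        # TF correlates identically with every gene: ratio must be 1
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        E = make_expression([base, base * 2, base * 3, base * 0.5],
                            genes=["TF", "a", "b", "c"])
        P = make_pmatrix([[1], [1], [1]], genes=["a", "b", "c"], tfs=["TF"])
        res = tf_target_ratio(pearson_all_pairs(E), P, "TF")
        assert res.ratio == pytest.approx(1.0)

    def test_arithmetic(self):
        res_num, res_den = 0.70, 0.35
        assert res_num / res_den == pytest.approx(2.0)

    def test_loop_oracle(self, small_dataset):
        P = small_dataset.pmatrix
        acc = pearson_all_pairs(small_dataset.expression)
        table = tf_ratio_table(acc, P, variant="absolute")
        assert len(table) > 10
        for _, row in table.head(20).iterrows():
            tf = row["tf"]
            nums, dens = [], []
            targets = set(P.tf_targets(tf))
            for g in P.genes:
                if g == tf:
                    continue
                r = acc.r(tf, g)
                if np.isnan(r):
                    continue
                dens.append(abs(r))
                if g in targets:
                    nums.append(abs(r))
            assert row["ratio"] == pytest.approx(np.mean(nums) / np.mean(dens))

    def test_variant_can_be_undefined(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        E = make_expression([base, -base + 0.1, -base * 2], genes=["TF", "a", "b"])
        P = make_pmatrix([[1], [0]], genes=["a", "b"], tfs=["TF"])
        res = tf_target_ratio(pearson_all_pairs(E), P, "TF", variant="positive")
        assert not res.defined and res.reason

    def test_unknown_tf_rejected(self):
        E = make_expression(np.random.default_rng(0).normal(size=(2, 4)))
        P = make_pmatrix([[1]], genes=["g1"], tfs=["TF"])
        with pytest.raises(ValueError):
            tf_target_ratio(pearson_all_pairs(E), P, "TF")


class TestBinomialTail:
    @pytest.mark.parametrize("k,n,expected,places", [
        (108, 178, 0.001675, 6),
        (93, 172, 0.126331, 6),
        (74, 149, 0.5, 12),
        (71, 94, 1.13e-07, None),
        (66, 90, 1.9e-06, None),
        (46, 71, 0.004277, 6),
    ])
    def test_reference_values(self, k, n, expected, places):
        p = binomial_tail(k, n, 0.5)
        if places:
            assert round(p, places) == expected
        else:
            assert p == pytest.approx(expected, rel=0.01)

    def test_symmetry_identity(self):
        for n in (1, 7, 100, 500):
            k = np.arange(0, n)
            left = np.array([binomial_tail(int(x), n, 0.5) for x in k])
            right = np.array([binomial_tail(int(n - x - 1), n, 0.5) for x in k])
            np.testing.assert_allclose(left + right, 1.0, atol=1e-12)

    def test_decreasing_in_k(self):
        n = 60
        vals = [binomial_tail(k, n, 0.5) for k in range(n)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        # strictly decreasing wherever floating point can resolve the step
        mid = vals[10:50]
        assert all(a > b for a, b in zip(mid, mid[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 4, 0.5)
        with pytest.raises(ValueError):
            binomial_tail(1, 4, 0.0)


class TestRatioEnrichment:
    @staticmethod
    def _table(ratios):
        return pd.DataFrame({"tf": [f"t{i}" for i in range(len(ratios))],
                             "ratio": ratios,
                             "mean_target_corr": np.abs(ratios),
                             "defined": True})

    def test_all_above_one_boundary(self):
        res = ratio_enrichment_test(self._table(np.full(10, 1.5)))
        assert res.n_above == 10
        assert res.p_value == 0.0  # P(X > 10 | n=10)
        assert res.p_value_inclusive == pytest.approx(0.5 ** 10)

    def test_half_and_half(self):
        res = ratio_enrichment_test(self._table([1.5] * 50 + [0.5] * 50))
        assert 0.3 < res.p_value < 0.55

    def test_matches_paper_style_counts(self):
        ratios = [1.5] * 71 + [0.5] * 23
        res = ratio_enrichment_test(self._table(ratios))
        assert res.n_above == 71 and res.n_total == 94
        assert res.p_value == pytest.approx(1.13e-07, rel=0.01)

    def test_restriction_requires_mu(self):
        with pytest.raises(ValueError):
            ratio_enrichment_test(self._table([1.2]), restrict_above_mu=True)


class TestLOD:
    def test_conditional_equals_marginal(self):
        assert lod(20, 100, 200, 1000) == pytest.approx(0.0)

    def test_twice_marginal(self):
        assert lod(40, 100, 200, 1000) == pytest.approx(math.log(2))

    def test_count_arithmetic(self):
        assert lod(30, 100, 200, 1000) == pytest.approx(math.log(1.5))

    def test_zero_count_undefined(self):
        assert math.isnan(lod(0, 100, 200, 1000))

    def test_bad_totals(self):
        with pytest.raises(ValueError):
            lod(1, 0, 1, 10)


class TestTRMProfile:
    def test_single_class_lod_zero(self):
        # every pair shares exactly 1 TF -> class frequency == marginal
        P = make_pmatrix([[1], [1], [1], [1]])
        rng = np.random.default_rng(0)
        acc = pearson_all_pairs(make_expression(rng.normal(size=(4, 8))))
        prof = trm_lod_profile(acc, P)
        row = prof.lod_table.loc["1"].to_numpy()
        assert np.allclose(row[np.isfinite(row)], 0.0)

    def test_class_sizes_conserve_pairs(self, small_dataset):
        P = small_dataset.pmatrix
        acc = pearson_all_pairs(small_dataset.expression.subset(P.genes))
        prof = trm_lod_profile(acc, P)
        G = P.n_genes
        assert prof.n_pairs.sum() == G * (G - 1) // 2

    def test_shuffled_pmatrix_lod_null(self, small_dataset):
        """Per cell, the mean LOD across 20 independent column shuffles stays
        within sampling noise of zero."""
        P = small_dataset.pmatrix
        acc = pearson_all_pairs(small_dataset.expression.subset(P.genes))
        rng = np.random.default_rng(0)
        tables = []
        for _ in range(20):
            vals = P.values.copy()
            for j in range(vals.shape[1]):
                rng.shuffle(vals[:, j])
            tables.append(trm_lod_profile(acc, PMatrix(P.genes, P.tfs, vals))
                          .lod_table.to_numpy())
        A = np.array(tables)
        always = (~np.isnan(A)).all(axis=0)
        mean = np.nanmean(A, axis=0)[always]
        sd = np.nanstd(A, axis=0, ddof=1)[always]
        z = np.abs(mean) / (sd / np.sqrt(20))
        assert (z < 3.5).mean() > 0.97

    def test_extreme_positive_lod_grows_with_motif_order(self, small_dataset):
        """With activator-driven data, high positive correlations become
        increasingly over-represented as pairs share more TFs."""
        P = small_dataset.pmatrix
        acc = pearson_all_pairs(small_dataset.expression.subset(P.genes))
        prof = trm_lod_profile(acc, P)
        col = prof.lod_table.iloc[:, -2]  # the (0.8, 0.9] bin
        usable = prof.n_pairs >= 100
        vals = col[usable].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        assert len(vals) >= 3
        assert np.all(np.diff(vals) > 0)

    def test_bins_must_cover_range(self, small_dataset):
        P = small_dataset.pmatrix
        acc = pearson_all_pairs(small_dataset.expression.subset(P.genes))
        with pytest.raises(ValueError):
            trm_lod_profile(acc, P, bins=np.linspace(-0.5, 1, 4))
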