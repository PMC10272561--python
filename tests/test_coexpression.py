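"""Co-expression chain: bicor, soft threshold, TOM, detection, eigengenes."""

import numpy as np
import pandas as pd
import pytest

from coexscreen import coexpression as cx
from coexscreen import synthetic


def _df(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


class TestFilterVariableGenes:
    def test_varying_gene_beats_constant(self):
        expr = _df([[1, 1, 1, 1], [1, 5, 2, 9]])
        kept = cx.filter_variable_genes(expr, 1)
        assert list(kept.index) == ["g1"]
        assert list(kept.columns) == list(expr.columns)

    def test_k_equals_n_genes_is_identity(self, bulk):
        kept = cx.filter_variable_genes(bulk.expression, bulk.expression.shape[0])
        pd.testing.assert_frame_equal(kept, bulk.expression)

    def test_module_genes_outvary_background(self, bulk):
        # module variance loading^2 + noise^2 > background noise^2
        n_mod = sum(m != "background" for m in bulk.gene_modules.values())
        kept = cx.filter_variable_genes(bulk.expression, n_mod)
        frac = np.mean([bulk.gene_modules[g] != "background" for g in kept.index])
        assert frac >= 0.95

    @pytest.mark.parametrize("k", [0, -3])
    def test_nonpositive_k_rejected(self, bulk, k):
        with pytest.raises(ValueError):
            cx.filter_variable_genes(bulk.expression, k)


class TestOutlierRemoval:
    def test_planted_outlier_is_removed(self, rng):
        X = rng.standard_normal((30, 12))
        X[:, 4] += 50.0
        expr = _df(X)
        kept, dropped = cx.remove_outlier_samples(expr, height_threshold=10,
                                                  min_cluster_size=3)
        assert dropped == ["s4"]
        assert "s4" not in kept.columns

    def test_infinite_threshold_removes_nothing(self, rng):
        expr = _df(rng.standard_normal((20, 8)))
        kept, dropped = cx.remove_outlier_samples(expr, np.inf,
                                                  min_cluster_size=2)
        assert dropped == []
        pd.testing.assert_frame_equal(kept, expr)

    def test_decisions_deterministic(self, rng):
        X = rng.standard_normal((25, 10))
        X[:, 2] += 40
        a = cx.remove_outlier_samples(_df(X), 25, 3)[1]
        b = cx.remove_outlier_samples(_df(X), 25, 3)[1]
        assert a == b


class TestBicor:
    def test_self_and_antisymmetry(self, rng):
        x = rng.standard_normal(50)
        assert cx.bicor(x, x) == pytest.approx(1.0)
        assert cx.bicor(x, -x) == pytest.approx(-1.0)

    def test_agrees_with_pearson_on_clean_gaussian(self):
        rng = np.random.default_rng(77)
        cov = [[1, 0.6], [0.6, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=1000)
        b = cx.bicor(xy[:, 0], xy[:, 1])
        p = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
        assert abs(b - p) < 0.05

    def test_more_robust_than_pearson_under_outliers(self):
        rng = np.random.default_rng(78)
        cov = [[1, 0.6], [0.6, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=1000)
        idx = rng.choice(1000, 20, replace=False)
        xy[idx, 0] += rng.choice([-30, 30], size=20)
        b = cx.bicor(xy[:, 0], xy[:, 1])
        p = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
        assert abs(b - 0.6) < abs(p - 0.6)

    def test_mad_zero_falls_back_to_pearson(self):
        # x has MAD 0 (majority identical) but is not constant
        x = np.array([1.0, 1, 1, 1, 1, 9, 1, 1])
        y = np.arange(8, dtype=float)
        expected = np.corrcoef(x - x.mean(), y)[0, 1]
        # y has positive MAD, so only x uses the Pearson fallback weights
        got = cx.bicor(x, y)
        assert np.isfinite(got)
        assert -1 <= got <= 1
        assert np.sign(got) == np.sign(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            cx.bicor([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            cx.bicor([1, 2], [3, 4])

    def test_matrix_matches_pairwise(self, rng):
        X = rng.standard_normal((6, 40))
        M = cx.bicor_matrix(X)
        for i in range(6):
            for j in range(6):
                assert M[i, j] == pytest.approx(cx.bicor(X[i], X[j]), abs=1e-12)


class TestSoftThreshold:
    def test_fit_values_bounded_and_connectivity_decreasing(self, bulk):
        scan = cx.pick_soft_threshold(bulk.expression.iloc[:150],
                                      powers=[1, 3, 6, 9])
        assert all(-1 <= f <= 1 for f in scan.fit_r2)
        assert all(np.diff(scan.mean_connectivity) < 0)
        assert scan.chosen_power in scan.powers

    def test_empty_powers_rejected(self, bulk):
        with pytest.raises(ValueError):
            cx.pick_soft_threshold(bulk.expression.iloc[:50], powers=[])


class TestAdjacencyTom:
    def test_power_one_unsigned_is_abs_bicor(self, rng):
        expr = _df(rng.standard_normal((8, 30)))
        A = cx.adjacency(expr, 1).to_numpy()
        C = np.abs(cx.bicor_matrix(expr))
        np.fill_diagonal(C, 1.0)
        assert np.allclose(A, C)

    def test_entries_bounded_and_monotone_in_power(self, rng):
        expr = _df(rng.standard_normal((10, 25)))
        A2 = cx.adjacency(expr, 2).to_numpy()
        A4 = cx.adjacency(expr, 4).to_numpy()
        assert ((A2 >= 0) & (A2 <= 1)).all()
        off = ~np.eye(10, dtype=bool)
        assert (A4[off] <= A2[off] + 1e-12).all()

    def test_signed_adjacency_formula(self, rng):
        expr = _df(rng.standard_normal((5, 20)))
        A = cx.adjacency(expr, 2, network_type="signed").to_numpy()
        C = cx.bicor_matrix(expr)
        expected = ((1 + C) / 2) ** 2
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(A, expected)

    def test_tom_three_node_hand_computation(self):
        A = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]])
        tom = cx.tom_similarity(A)
        # L_12 = 0.25, k = 1 each: (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)

    def test_tom_perfect_overlap(self):
        # fully shared binary neighborhood and a_ij = 1 give TOM 1
        A = np.ones((3, 3))
        tom = cx.tom_similarity(A)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_tom_bounded_symmetric(self, rng):
        expr = _df(rng.standard_normal((12, 30)))
        tom = cx.tom_similarity(cx.adjacency(expr, 3))
        assert np.allclose(tom, tom.T)
        assert ((tom >= 0) & (tom <= 1)).all()

    def test_tom_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            cx.tom_similarity(np.array([[1.0, 0.2], [0.8, 1.0]]))


class TestDetectModules:
    def test_two_perfect_blocks(self):
        D = np.ones((6, 6))
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        np.fill_diagonal(D, 0.0)
        labels = cx.detect_modules(D, min_module_size=2, cut_height=0.5,
                                   gene_ids=list("abcdef"))
        assert labels.nunique() == 2
        assert (labels != cx.GREY).all()

    def test_zero_cut_everything_grey(self, rng):
        X = rng.standard_normal((10, 10))
        D = (X + X.T) / 10 + 0.5
        np.fill_diagonal(D, 0)
        with pytest.warns(UserWarning):
            labels = cx.detect_modules(np.abs(D), min_module_size=2,
                                       cut_height=0.0)
        assert (labels == cx.GREY).all()

    def test_planted_modules_recovered(self, bulk):
        A = cx.adjacency(bulk.expression, 6)
        labels = cx.detect_modules(1 - cx.tom_similarity(A),
                                   gene_ids=list(bulk.expression.index))
        truth = pd.Series(bulk.gene_modules)
        for m in sorted(set(truth) - {"background"}):
            tset = set(truth.index[truth == m])
            best = max(
                len(tset & set(labels.index[labels == l]))
                / len(tset | set(labels.index[labels == l]))
                for l in labels.unique() if l != cx.GREY)
            assert best >= 0.8


class TestEigengene:
    def test_affine_scaled_genes_correlate_one(self, rng):
        base = rng.standard_normal(30)
        expr = _df([2 * base + 1, 0.5 * base - 3, base])
        e = cx.module_eigengene(expr, list(expr.index))
        for g in expr.index:
            assert np.corrcoef(e, expr.loc[g])[0, 1] == pytest.approx(1.0)

    def test_sign_convention_and_unit_variance(self, bulk):
        genes = [g for g, m in bulk.gene_modules.items()
                 if m == bulk.trait_module]
        e = cx.module_eigengene(bulk.expression, genes)
        assert e.std(ddof=1) == pytest.approx(1.0)
        cors = [np.corrcoef(e, bulk.expression.loc[g])[0, 1] for g in genes]
        assert np.mean(cors) >= 0

    def test_recovers_latent_factor(self, bulk):
        genes = [g for g, m in bulk.gene_modules.items()
                 if m == bulk.trait_module]
        e = cx.module_eigengene(bulk.expression, genes)
        r = np.corrcoef(e, bulk.factors[bulk.trait_module])[0, 1]
        assert abs(r) >= 0.95

    def test_missing_genes_reported(self, bulk):
        with pytest.raises(KeyError, match="NOPE"):
            cx.module_eigengene(bulk.expression, ["NOPE"])


@pytest.fixture(scope="module")
def fitted(bulk):
    est = cx.CoexpressionModules(power=6, min_module_size=20)
    est.fit(bulk.expression.T, bulk.trait)
    return est


class TestMergeDropTraitKmeHubs:

    def test_split_modules_from_same_factor_are_merged(self, bulk):
        genes = [g for g, m in bulk.gene_modules.items()
                 if m == bulk.trait_module]
        labels = pd.Series(cx.GREY, index=bulk.expression.index)
        labels[genes[:25]] = "module_1"
        labels[genes[25:]] = "module_2"
        merged = cx.merge_close_modules(bulk.expression, labels)
        non_grey = merged[merged != cx.GREY]
        assert non_grey.nunique() == 1

    def test_zero_merge_height_is_identity(self, bulk, fitted):
        merged = cx.merge_close_modules(bulk.expression, fitted.labels_,
                                        merge_cut_height=0.0)
        assert (merged.value_counts().sort_index()
                == fitted.labels_.value_counts().sort_index()).all()

    def test_drop_invalid_modules_boundaries(self):
        labels = pd.Series(
            ["big"] * 1001 + ["ok"] * 1000 + [cx.GREY] * 5,
            index=[f"g{i}" for i in range(2006)])
        retained = cx.drop_invalid_modules(labels, max_size=1000)
        assert retained == ["ok"]

    def test_trait_module_has_largest_correlation(self, bulk, fitted):
        tc = fitted.trait_correlation_["r"].abs()
        best = tc.idxmax()
        best_genes = set(fitted.labels_.index[fitted.labels_ == best])
        truth_genes = {g for g, m in bulk.gene_modules.items()
                       if m == bulk.trait_module}
        jac = len(best_genes & truth_genes) / len(best_genes | truth_genes)
        assert jac >= 0.8

    def test_kme_matches_factor_model_closed_form(self, bulk, fitted):
        # E[kME] ~ loading / sqrt(loading^2 + noise^2) per gene
        tc = fitted.trait_correlation_["r"].abs()
        best = tc.idxmax()
        genes = fitted.labels_.index[fitted.labels_ == best]
        lam = bulk.loadings[genes]
        expected = lam / np.sqrt(lam**2 + 0.6**2)
        got = fitted.kme_.loc[genes, best]
        assert abs((got - expected).mean()) < 0.05
        assert got.between(-1, 1).all()

    def test_hub_genes_are_high_loading(self, bulk, fitted):
        tc = fitted.trait_correlation_["r"].abs()
        best = tc.idxmax()
        hubs = cx.hub_genes(fitted.kme_, fitted.labels_, best, 10)
        assert len(hubs) == 10
        members = fitted.labels_.index[fitted.labels_ == best]
        lam = bulk.loadings[members]
        # kME ranking tracks the planted loading ranking
        assert lam.corr(fitted.kme_.loc[members, best],
                        method="spearman") > 0.5
        top_true = set(lam.nlargest(10).index)
        assert len(set(hubs) & top_true) >= 3

    def test_hub_genes_n_one_is_argmax(self, fitted):
        m = fitted.retained_modules_[0]
        members = fitted.labels_.index[fitted.labels_ == m]
        top = cx.hub_genes(fitted.kme_, fitted.labels_, m, 1)
        assert top == [fitted.kme_.loc[members, m].idxmax()]

    def test_hub_count_capped_by_module_size(self, fitted):
        m = fitted.retained_modules_[0]
        size = (fitted.labels_ == m).sum()
        hubs = cx.hub_genes(fitted.kme_, fitted.labels_, m, size + 50)
        assert len(hubs) == size


class TestPipelineInvariants:
    def test_affine_invariance_of_assignment(self, bulk):
        expr = bulk.expression.iloc[:120]
        est1 = cx.CoexpressionModules(power=6, min_module_size=20).fit(expr.T)
        expr2 = expr.copy()
        g = expr2.index[0]
        expr2.loc[g] = expr2.loc[g] * 3.0 + 10.0
        est2 = cx.CoexpressionModules(power=6, min_module_size=20).fit(expr2.T)
        # same partition (labels may permute): compare co-membership of g
        mod1 = set(est1.labels_.index[est1.labels_ == est1.labels_[g]])
        mod2 = set(est2.labels_.index[est2.labels_ == est2.labels_[g]])
        assert mod1 == mod2

    def test_determinism_of_full_fit(self, bulk):
        a = cx.CoexpressionModules(power=6).fit(bulk.expression.T)
        b = cx.CoexpressionModules(power=6).fit(bulk.expression.T)
        pd.testing.assert_series_equal(a.labels_, b.labels_)

    def test_module_trait_null_case(self):
        spec = synthetic.ModulePlantSpec(trait_effect=0.0, seed=21)
        nullbulk = synthetic.generate_bulk_expression(spec)
        est = cx.CoexpressionModules(power=6).fit(nullbulk.expression.T,
                                                  nullbulk.trait)
        assert (est.trait_correlation_["r"].abs() < 0.2).all()

    def test_constant_eigengene_rejected(self):
        eig = pd.DataFrame({"m1": np.ones(10)},
                           index=[f"s{i}" for i in range(10)])
        trait = pd.Series([0, 1] * 5, index=eig.index)
        with pytest.raises(ValueError):
            cx.module_trait_correlation(eig, trait)
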