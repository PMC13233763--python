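import numpy as np
import pandas as pd
import pytest

from glytrace.core_io import SampleMeta, SchemaError
from glytrace.multivariate import build_lda_design, lda_importance, pca, top_k
from glytrace.preprocess import NormalizedTable


def _nt(values: pd.DataFrame) -> NormalizedTable:
    return NormalizedTable(values, ["test"])


def _meta(models, conditions, n_rep) -> SampleMeta:
    rows = []
    for m in models:
        for c in conditions:
            for r in range(1, n_rep + 1):
                rows.append(
                    {"sample_id": f"{m}_{c}_r{r}", "cell_model": m, "condition": c,
                     "carbon_source": "none", "dose_mM": None, "replicate": r,
                     "batch": "B1", "dna_ug": 1.0, "cell_count": 1000}
                )
    return SampleMeta(pd.DataFrame(rows))


class TestPca:
    def test_constant_matrix_degenerate(self):
        values = pd.DataFrame(3.0, index=list("AB"), columns=[f"s{i}" for i in range(4)])
        res = pca(_nt(values))
        assert np.allclose(res.explained_variance_ratio, 0)
        assert np.allclose(res.scores.to_numpy(), 0)

    def test_rank_one_single_component(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([1.0, 0.5])
        values = pd.DataFrame(np.outer(v, u), index=list("AB"), columns=[f"s{i}" for i in range(4)])
        res = pca(_nt(values))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_and_orthonormal_loadings(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.uniform(1, 5, size=(4, 10)), index=list("ABCD"), columns=[f"s{i}" for i in range(10)]
        )
        res = pca(_nt(values))
        X = values.T.to_numpy()
        Xc = X - X.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Xc, atol=1e-9)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            rng.uniform(1, 5, size=(5, 12)), index=list("ABCDE"), columns=[f"s{i}" for i in range(12)]
        )
        res = pca(_nt(values))
        ref = sk.PCA().fit(values.T.to_numpy())
        np.testing.assert_allclose(
            res.explained_variance_ratio[:4], ref.explained_variance_ratio_[:4], atol=1e-9
        )

    def test_missing_values_rejected(self):
        values = pd.DataFrame([[1.0, np.nan]], index=["A"], columns=["s0", "s1"])
        with pytest.raises(SchemaError, match="drop_incomplete"):
            pca(_nt(values))


class TestBuildLdaDesign:
    def test_full_design_shape(self):
        models = ["HepG2", "mHepG2", "HLC_d22", "HLC_d44"]
        conditions = [f"C{i}" for i in range(10)]
        meta = _meta(models, conditions, 3)
        rng = np.random.default_rng(2)
        mets = [f"met{i}" for i in range(64)]
        values = pd.DataFrame(
            rng.uniform(0.5, 2, size=(64, len(meta))), index=mets, columns=meta.sample_ids
        )
        design, labels, info = build_lda_design(_nt(values), meta)
        assert design.shape == (64 * 3 * 4, 10)
        assert labels.value_counts().to_dict() == {m: 64 * 3 for m in models}

    def test_small_design_shape(self):
        meta = _meta(["M1", "M2"], ["C1", "C2", "C3"], 1)
        values = pd.DataFrame(
            np.arange(12.0).reshape(2, 6) + 1, index=["x", "y"], columns=meta.sample_ids
        )
        design, labels, info = build_lda_design(_nt(values), meta)
        assert design.shape == (4, 3)
        # value placement: metabolite x, model M1, replicate 1, condition C2
        row = info[(info["metabolite"] == "x") & (info["cell_model"] == "M1")].index[0]
        assert design.loc[row, "C2"] == values.loc["x", "M1_C2_r1"]

    def test_missing_replicate_rows_dropped(self):
        meta = _meta(["M1", "M2"], ["C1", "C2"], 2)
        values = pd.DataFrame(1.0, index=["x", "y"], columns=meta.sample_ids)
        values.loc["x", "M1_C2_r2"] = np.nan
        design, labels, info = build_lda_design(_nt(values), meta)
        assert design.shape == (7, 2)  # 8 (met, rep, model) rows minus the incomplete one
        assert not ((info["metabolite"] == "x") & (info["cell_model"] == "M1")
                    & (info["replicate"] == 2)).any()

    def test_condition_missing_for_model_errors(self):
        meta = _meta(["M1", "M2"], ["C1", "C2"], 1)
        sub = SampleMeta(meta.table[meta.table["sample_id"] != "M2_C2_r1"])
        values = pd.DataFrame(1.0, index=["x"], columns=sub.sample_ids)
        with pytest.raises(SchemaError, match="entirely missing"):
            build_lda_design(_nt(values), sub)


def _two_class_design(n=60, signal=3.0, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(["a", "b"], n // 2)
    A = np.where(y == "a", 0.0, signal) + rng.normal(0, noise, n)
    B = rng.normal(0, 1.0, n)
    return pd.DataFrame({"A": A, "B": B}), pd.Series(y, name="label")


class TestLdaImportance:
    def test_signal_feature_ranks_first(self):
        design, labels = _two_class_design()
        imp = lda_importance(design, labels)
        assert imp.ranking == ["A", "B"]
        assert imp.proportion_of_trace == pytest.approx([1.0])

    def test_matches_closed_form_fisher_direction(self):
        """2-class Fisher direction has the closed form Sw^-1 (mu1 - mu2)."""
        rng = np.random.default_rng(4)
        n = 40
        y = np.repeat(["a", "b"], n // 2)
        X = rng.normal(0, 1, size=(n, 3))
        X[y == "b"] += np.array([2.0, 1.0, 0.0])
        design = pd.DataFrame(X, columns=["f1", "f2", "f3"])
        labels = pd.Series(y)
        mu_a, mu_b = X[y == "a"].mean(axis=0), X[y == "b"].mean(axis=0)
        Sw = sum(
            (X[y == c] - X[y == c].mean(axis=0)).T @ (X[y == c] - X[y == c].mean(axis=0))
            for c in ("a", "b")
        )
        w_ref = np.linalg.solve(Sw, mu_a - mu_b)
        w = lda_importance(design, labels).coefficients.to_numpy()[:, 0]
        cos = abs(w @ w_ref) / (np.linalg.norm(w) * np.linalg.norm(w_ref))
        assert cos > 0.999

    def test_identical_columns_symmetric_scores(self):
        rng = np.random.default_rng(5)
        col = rng.normal(0, 1, 30) + np.repeat([0.0, 2.0], 15)
        design = pd.DataFrame({"b_col": col, "a_col": col, "c_col": col})
        labels = pd.Series(np.repeat(["x", "y"], 15))
        imp = lda_importance(design, labels)  # singular Sw -> automatic ridge
        scores = list(imp.condition_scores.values())
        assert max(scores) - min(scores) == pytest.approx(0.0, abs=1e-6 * max(scores))
        assert imp.ranking == ["a_col", "b_col", "c_col"]

    def test_four_classes_three_discriminants(self):
        rng = np.random.default_rng(6)
        n = 80
        y = np.repeat(list("abcd"), n // 4)
        X = rng.normal(0, 0.3, size=(n, 5))
        for i, c in enumerate("abcd"):
            X[y == c, i % 5] += i
        imp = lda_importance(pd.DataFrame(X, columns=list("vwxyz")), pd.Series(y))
        assert len(imp.proportion_of_trace) == 3
        assert imp.proportion_of_trace.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(imp.proportion_of_trace >= 0)

    def test_proportion_of_trace_matches_sklearn(self):
        skl = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(7)
        n = 90
        y = np.repeat(list("abc"), n // 3)
        X = rng.normal(0, 1, size=(n, 4))
        X[y == "b", 0] += 2
        X[y == "c", 1] += 3
        imp = lda_importance(pd.DataFrame(X, columns=list("pqrs")), pd.Series(y))
        ref = skl.LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
        np.testing.assert_allclose(
            imp.proportion_of_trace, ref.explained_variance_ratio_, atol=1e-6
        )

    def test_scores_invariant_under_row_reordering(self):
        design, labels = _two_class_design(seed=8)
        perm = np.random.default_rng(9).permutation(len(design))
        a = lda_importance(design, labels).condition_scores
        b = lda_importance(design.iloc[perm].reset_index(drop=True),
                           labels.iloc[perm].reset_index(drop=True)).condition_scores
        assert a.keys() == b.keys()
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9)

    def test_weighting_modes_both_valid(self):
        design, labels = _two_class_design(seed=10)
        w_on = lda_importance(design, labels, weight_by_trace=True)
        w_off = lda_importance(design, labels, weight_by_trace=False)
        assert w_on.ranking == w_off.ranking  # single discriminant: same order

    def test_needs_two_classes(self):
        design = pd.DataFrame({"A": [1.0, 2.0, 3.0]})
        with pytest.raises(SchemaError, match="2 classes"):
            lda_importance(design, pd.Series(["a", "a", "a"]))


class TestTopK:
    def _imp(self, scores):
        from glytrace.multivariate import LdaImportance
        return LdaImportance(
            coefficients=pd.DataFrame({"LD1": [1.0]}, index=["c"]),
            proportion_of_trace=np.array([1.0]),
            condition_scores={"c": 1.0},
            metabolite_scores=scores,
            ranking=["c"],
        )

    def test_order_ties_and_overflow(self):
        imp = self._imp({"b": 2.0, "a": 2.0, "c": 1.0})
        assert top_k(imp, 2) == ["a", "b"]       # tie -> lexicographic
        assert top_k(imp, 10) == ["a", "b", "c"]  # k past the end -> all
        assert top_k(imp, 1) == ["a"]
        with pytest.raises(ValueError):
            top_k(imp, 0)
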