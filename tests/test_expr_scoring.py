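import numpy as np
import pandas as pd
import pytest

from mixhet import expr_scoring as es
from mixhet.io_formats import ExpressionMatrix, GeneSet
from mixhet.oracles import ssgsea_running_sum_reference


def profile(values):
    return pd.Series(values, index=[f"g{i}" for i in range(len(values))])


class TestSsgseaScore:
    def test_top_gene_positive(self):
        s = profile(range(10, 0, -1))  # g0 highest
        score = es.ssgsea_score(s, GeneSet("S", ("g0",)))
        assert score.value > 0

    def test_bottom_gene_negative(self):
        s = profile(range(10, 0, -1))
        score = es.ssgsea_score(s, GeneSet("S", ("g9",)))
        assert score.value < 0

    def test_matches_running_sum_enumeration_small(self):
        s = profile([5, 4, 3, 2, 1])
        members = ("g0", "g1")
        ours = es.ssgsea_score(s, GeneSet("S", members), alpha=1.0).value
        oracle = ssgsea_running_sum_reference(dict(s), members, alpha=1.0)
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_matches_oracle_on_random_instances(self):
        """Implementation equals the literal running-sum route to 1e-9."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            G = int(rng.integers(5, 51))
            s = pd.Series(rng.normal(size=G),
                          index=[f"g{i}" for i in range(G)])
            m = int(rng.integers(1, G))
            members = tuple(rng.choice(s.index, size=m, replace=False))
            alpha = float(rng.choice([0.0, 0.25, 1.0]))
            ours = es.ssgsea_score(s, GeneSet("S", members), alpha=alpha).value
            oracle = ssgsea_running_sum_reference(dict(s), members, alpha)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_rank_only_invariance_at_alpha_zero(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.uniform(1, 10, size=20),
                      index=[f"g{i}" for i in range(20)])
        gs = GeneSet("S", ("g3", "g7", "g11"))
        base = es.ssgsea_score(s, gs, alpha=0.0).value
        assert es.ssgsea_score(np.exp(s / 3), gs, alpha=0.0).value == \
            pytest.approx(base, abs=1e-12)
        assert es.ssgsea_score(s * 100 + 7, gs, alpha=0.0).value == \
            pytest.approx(base, abs=1e-12)

    def test_tied_values_break_by_gene_id(self):
        s = pd.Series([1.0, 1.0, 1.0], index=["gb", "ga", "gc"])
        # lexicographic order at equal values: ga ranks first
        assert es.ssgsea_score(s, GeneSet("S", ("ga",))).value > \
            es.ssgsea_score(s, GeneSet("S", ("gc",))).value

    def test_empty_effective_set_rejected(self):
        with pytest.raises(ValueError, match="empty effective set"):
            es.ssgsea_score(profile([1, 2, 3]), GeneSet("S", ("absent",)))


class TestSsgseaMatrix:
    @pytest.fixture()
    def expr(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(0, 10, size=(20, 3)),
                          index=[f"g{i}" for i in range(20)],
                          columns=["s1", "s2", "s3"])
        return ExpressionMatrix(df)

    def test_shape(self, expr):
        sets = [GeneSet("A", ("g0", "g1")), GeneSet("B", ("g5",))]
        out = es.ssgsea_matrix(expr, sets)
        assert out.shape == (2, 3)

    def test_duplicate_sample_column_identical_scores(self, expr):
        df = expr.data.copy()
        df["s4"] = df["s1"]
        out = es.ssgsea_matrix(ExpressionMatrix(df),
                               [GeneSet("A", ("g0", "g1", "g2"))])
        assert out["s4"].tolist() == out["s1"].tolist()

    def test_zero_overlap_set_dropped_with_warning(self, expr):
        with pytest.warns(UserWarning, match="no overlap"):
            out = es.ssgsea_matrix(expr, [GeneSet("A", ("g0",)),
                                          GeneSet("Z", ("nope",))])
        assert list(out.index) == ["A"]

    def test_normalized_scores_bounded(self, expr):
        # top and bottom sets give scores of both signs, so the global
        # max-min normalization bounds everything in [-1, 1]
        sets = [GeneSet("TOP", tuple(expr.data["s1"].nlargest(3).index)),
                GeneSet("BOT", tuple(expr.data["s1"].nsmallest(3).index))]
        out = es.ssgsea_matrix(expr, sets, normalize=True)
        assert out.values.min() >= -1.0 and out.values.max() <= 1.0


class TestCentroids:
    def test_shifted_genes_selected(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(10)]
        samples = [f"s{i}" for i in range(8)]
        df = pd.DataFrame(rng.normal(5, 0.3, size=(10, 8)), index=genes,
                          columns=samples)
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=samples)
        df.loc[["g0", "g1", "g2"], labels == "A"] += 5.0
        cents = es.build_centroids(df, labels, genes_per_class=3)
        assert set(cents.selected["A"]) == {"g0", "g1", "g2"}

    def test_panel_all_genes_when_k_equals_gene_count(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(6, 6)),
                          index=[f"g{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(6)])
        labels = pd.Series(["A", "A", "A", "B", "B", "B"], index=df.columns)
        cents = es.build_centroids(df, labels, genes_per_class=6)
        assert sorted(cents.panel) == sorted(df.index)

    def test_deterministic_under_identical_classes(self):
        df = pd.DataFrame(np.ones((4, 4)),
                          index=[f"g{i}" for i in range(4)],
                          columns=[f"s{i}" for i in range(4)])
        labels = pd.Series(["A", "A", "B", "B"], index=df.columns)
        c1 = es.build_centroids(df, labels, genes_per_class=2)
        c2 = es.build_centroids(df, labels, genes_per_class=2)
        assert c1.selected == c2.selected  # lexicographic tie-break

    def test_small_class_rejected(self):
        df = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("xyz"))
        labels = pd.Series(["A", "A", "B"], index=df.columns)
        with pytest.raises(ValueError, match="fewer than 2"):
            es.build_centroids(df, labels, genes_per_class=1)


class TestClassify:
    @pytest.fixture()
    def centroids(self):
        df = pd.DataFrame(
            {"L": [1.0, 2.0, 3.0, 4.0], "M": [4.0, 3.0, 2.0, 1.0]},
            index=["g0", "g1", "g2", "g3"],
        )
        return es.CentroidSet(centroids=df,
                              selected={"L": tuple(df.index),
                                        "M": tuple(df.index)})

    def test_identical_to_centroid(self, centroids):
        label, dists = es.classify_nearest_centroid(
            pd.Series([1.0, 2.0, 3.0, 4.0], index=["g0", "g1", "g2", "g3"]),
            centroids,
        )
        assert label == "L" and dists["L"] == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self, centroids):
        label, dists = es.classify_nearest_centroid(
            pd.Series([9.0, 11.0, 13.0, 15.0],
                      index=["g0", "g1", "g2", "g3"]),  # 2*centroid L + 7
            centroids,
        )
        assert label == "L" and dists["L"] == pytest.approx(0.0, abs=1e-12)

    def test_explicit_distance_computation(self, centroids):
        s = pd.Series([4.0, 3.0, 2.0, 1.0], index=["g0", "g1", "g2", "g3"])
        label, dists = es.classify_nearest_centroid(s, centroids)
        assert label == "M"
        assert dists["L"] == pytest.approx(2.0)  # perfectly anti-correlated

    def test_degenerate_profile_rejected(self, centroids):
        flat = pd.Series([2.0] * 4, index=["g0", "g1", "g2", "g3"])
        with pytest.raises(ValueError, match="degenerate"):
            es.classify_nearest_centroid(flat, centroids)


class TestRegulonActivity:
    def test_sign_and_antisymmetry(self):
        s = profile(range(20, 0, -1))
        pos = GeneSet("pos", ("g0", "g1", "g2"))
        neg = GeneSet("neg", ("g17", "g18", "g19"))
        reg = es.Regulon("TF", pos, neg)
        act = es.regulon_activity(s, reg)
        assert act > 0
        swapped = es.Regulon("TF", neg, pos)
        assert es.regulon_activity(s, swapped) == pytest.approx(-act, abs=1e-12)

    def test_mirrored_targets_double_single_score(self):
        """At alpha=0 the score is antisymmetric under rank reversal, so a
        regulon with rank-mirrored target sets scores twice the single set."""
        s = profile(range(10, 0, -1))
        pos = GeneSet("pos", ("g0", "g1"))
        neg = GeneSet("neg", ("g8", "g9"))  # mirror ranks of pos
        single = es.ssgsea_score(s, pos, alpha=0.0).value
        act = es.regulon_activity(s, es.Regulon("TF", pos, neg), alpha=0.0)
        assert act == pytest.approx(2 * single, abs=1e-12)

    def test_overlapping_targets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            es.Regulon("TF", GeneSet("p", ("a", "b")), GeneSet("n", ("b",)))


class TestDeFilter:
    def test_threshold_rule(self):
        df = pd.DataFrame({
            "gene": [f"g{i}" for i in range(1, 6)],
            "log2fc": [2.0, 1.5, 0.5, -3.0, -1.2],
            "fdr": [0.01, 0.2, 0.01, 0.01, 0.04],
        })
        up, down = es.de_filter(df, 1.0, 0.05)
        assert up == ["g1"] and down == ["g4", "g5"]

    def test_empty_table(self):
        df = pd.DataFrame(columns=["gene", "log2fc", "fdr"])
        assert es.de_filter(df) == ([], [])

    def test_boundary_strict(self):
        df = pd.DataFrame({"gene": ["g"], "log2fc": [1.0], "fdr": [0.001]})
        assert es.de_filter(df, 1.0, 0.05) == ([], [])

    def test_missing_column(self):
        with pytest.raises(ValueError, match="fdr"):
            es.de_filter(pd.DataFrame({"gene": [], "log2fc": []}))
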