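"""Abundance, filtering, the DE stand-in, bias calling and summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import exact_mwu_two_sided
from sexarch import expression as expr


def _counts(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i+1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"), columns=samples)


class TestAbundance:
    def test_single_gene_fpkm_and_tpm_are_1e6(self):
        counts = _counts([[10]])
        lengths = pd.Series([1000], index=["g1"])
        ab = expr.compute_abundance(counts, lengths)
        assert ab.fpkm.iloc[0, 0] == pytest.approx(1e6)
        assert ab.tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_zero_counts_give_zero_fpkm(self):
        ab = expr.compute_abundance(_counts([[0], [0]]), pd.Series([500, 800], index=["g1", "g2"]))
        assert (ab.fpkm.to_numpy() == 0).all()

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(1)
        counts = _counts(rng.integers(0, 500, size=(7, 4)))
        lengths = pd.Series(rng.integers(300, 5000, size=7), index=counts.index)
        ab = expr.compute_abundance(counts, lengths)
        for j, col in enumerate(counts.columns):
            total = counts[col].sum()
            rates = counts[col] / lengths
            for i, g in enumerate(counts.index):
                assert ab.fpkm.loc[g, col] == pytest.approx(
                    counts.loc[g, col] * 1e9 / (lengths[g] * total)
                )
                assert ab.tpm.loc[g, col] == pytest.approx(
                    rates[g] / rates.sum() * 1e6
                )
        assert np.allclose(ab.tpm.sum(axis=0), 1e6)


class TestExpressionFilter:
    @staticmethod
    def _design():
        return pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "sex": ["M", "M", "F", "F"],
                "leg": [1, 1, 1, 1],
                "line": ["big"] * 4,
                "replicate": [1, 2, 1, 2],
            }
        )

    def test_exactly_at_threshold_is_retained(self):
        fpkm = _counts(np.full((1, 4), 2.0), samples=list("abcd")).astype(float)
        out = expr.filter_expressed(fpkm, self._design())
        assert out[1] == {"g1"}

    def test_all_zero_removed(self):
        fpkm = _counts(np.zeros((1, 4)), samples=list("abcd"))
        assert expr.filter_expressed(fpkm, self._design())[1] == set()

    def test_toy_matrix_matches_hand_rule(self):
        # g1: low in 3/4 samples (>half) -> out; g2: low in 2/4 (not >half),
        # male mean 5 >= 2 -> in; g3: low in 2/4 but both sex means < 2 -> out
        fpkm = _counts(
            [[1.0, 1.0, 1.0, 9.0], [5.0, 5.0, 0.0, 0.0], [1.9, 1.9, 1.0, 1.0]],
            samples=list("abcd"),
        )
        assert expr.filter_expressed(fpkm, self._design())[1] == {"g2"}

    def test_missing_leg_errors(self):
        fpkm = _counts(np.ones((1, 4)), samples=list("abcd"))
        design = self._design()
        design.loc[:, "sample_id"] = ["a", "b", "x", "y"]  # columns absent
        with pytest.raises(KeyError):
            expr.filter_expressed(fpkm, design)


class TestDeStandin:
    @staticmethod
    def _design(n_per=6):
        rows = []
        for sex in ("M", "F"):
            for i in range(n_per):
                rows.append(
                    {
                        "sample_id": f"{sex}{i}",
                        "sex": sex,
                        "leg": 1,
                        "line": "big" if i < n_per // 2 else "small",
                        "replicate": i,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 150, size=(200, 1))
        counts = _counts(np.repeat(base, 12, axis=1), samples=self._design()["sample_id"].tolist())
        de = expr.run_de_standin(counts, self._design(), ("sex", 1))
        assert np.allclose(de["log2FC"], 0, atol=1e-9)
        assert (de["pvalue"] > 0.9).all()

    def test_ranksum_matches_exact_enumeration_3v3(self):
        design = pd.DataFrame(
            {
                "sample_id": list("abcdef"),
                "sex": ["M"] * 3 + ["F"] * 3,
                "leg": [1] * 6,
                "line": ["big"] * 6,
                "replicate": [1, 2, 3, 1, 2, 3],
            }
        )
        counts = _counts([[11, 25, 3, 8, 19, 30], [100, 90, 80, 10, 20, 30]],
                         samples=list("abcdef"))
        de = expr.run_de_standin(counts, design, ("sex", 1), sf=pd.Series(1.0, index=list("abcdef")))
        for i in range(2):
            a = counts.iloc[i, :3].to_numpy(float)
            b = counts.iloc[i, 3:].to_numpy(float)
            assert de["pvalue"].iloc[i] == pytest.approx(exact_mwu_two_sided(a, b))

    def test_recovery_auc_above_09(self, dataset, calls_leg3):
        from sklearn.metrics import roc_auc_score

        _, de, _ = calls_leg3
        truth = dataset["truth"].labels_for_leg(3)
        y = truth.reindex(de["gene_id"]).isin(["male", "female"]).to_numpy()
        score = -np.log10(de["pvalue"].to_numpy() + 1e-300)
        assert roc_auc_score(y, score) > 0.9

    def test_degenerate_all_zero_groups(self):
        counts = _counts(np.zeros((3, 12), dtype=int), samples=self._design()["sample_id"].tolist())
        de = expr.run_de_standin(counts, self._design(), ("sex", 1))
        assert (de["log2FC"] == 0).all()
        assert (de["pvalue"] == 1).all()


class TestBiasCalls:
    @staticmethod
    def _de(rows):
        return pd.DataFrame(
            [
                {"gene_id": f"g{i+1}", "contrast": "sex_leg1", "baseMean": 100.0,
                 "log2FC": lfc, "pvalue": p, "padj": p}
                for i, (lfc, p) in enumerate(rows)
            ]
        )

    def test_threshold_rules(self):
        de = self._de([(0.70, 0.01), (3.0, 0.06), (-0.60, 0.04), (0.30, 0.001)])
        calls = expr.call_sex_bias(de, expressed={"g1", "g2", "g3", "g4"}, leg=1)
        assert list(calls["label"]) == ["male", "unbiased", "female", "unbiased"]

    def test_unexpressed_overrides(self):
        de = self._de([(2.0, 0.001)])
        calls = expr.call_sex_bias(de, expressed=set(), leg=1)
        assert list(calls["label"]) == ["unexpressed"]

    def test_missing_padj_treated_as_one(self):
        de = self._de([(2.0, np.nan)])
        calls = expr.call_sex_bias(de, expressed={"g1"}, leg=1)
        assert list(calls["label"]) == ["unbiased"]

    def test_reassignment_rules_and_idempotence(self):
        de = self._de([(0.3, 0.5), (1.2, 0.01), (2.0, 0.001)])
        calls = expr.call_sex_bias(de, expressed={"g1", "g2"}, leg=1)  # g3 unexpressed
        out = expr.reassign_log2fc(calls)
        assert list(out["reassigned_log2fc"]) == [0.0, 1.2, 0.0]
        assert out["reassigned_p"].iloc[2] == 1.0
        again = expr.reassign_log2fc(out)
        pd.testing.assert_frame_equal(out, again)

    def test_every_gene_gets_one_label(self, calls_leg3):
        calls, _, expressed = calls_leg3
        assert set(calls["label"]).issubset(set(expr.LABELS))
        n_exp = (calls["label"] != "unexpressed").sum()
        assert n_exp == len(expressed[3])


class TestSummaries:
    def test_percentage_recomputes_from_counts(self):
        calls = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "leg": 1,
                "label": ["male"] * 2 + ["female"] * 3 + ["unbiased"] * 4 + ["unexpressed"],
            }
        )
        out = expr.summarize_bias({1: calls})
        row = out.iloc[0]
        assert row["n_expressed"] == 9
        assert row["pct_male_biased"] == expr.percentage(2, 9)
        assert row["pct_female_biased"] == expr.percentage(3, 9)

    def test_zero_biased_is_zero_pct(self):
        assert expr.percentage(0, 100) == 0.0

    def test_rounding_half_away_from_zero(self):
        assert expr.percentage(1, 16000) == 0.01  # 0.00625 -> 0.01
        assert expr.percentage(125, 10000) == 1.25
        assert expr.percentage(1125, 100000) == 1.13  # 1.125 rounds up, not to even

    def test_venn_cells_match_hand_enumeration(self):
        sets = {1: {"1", "2", "3"}, 2: {"2", "3"}, 3: {"3"}}
        cells = expr.bias_overlap(sets)
        assert cells["leg1"] == {"1"}
        assert cells["leg2"] == set()
        assert cells["leg3"] == set()
        assert cells["leg1&leg2"] == {"2"}
        assert cells["leg1&leg3"] == set()
        assert cells["leg2&leg3"] == set()
        assert cells["leg1&leg2&leg3"] == {"3"}

    def test_disjoint_sets(self):
        cells = expr.bias_overlap({1: {"a", "b"}, 3: {"c"}})
        assert cells["leg3_only"] == {"c"}


class TestMagnitude:
    @staticmethod
    def _calls(values, direction="male"):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(values))], "leg": 1,
             "label": direction, "log2FC": values, "padj": 0.01}
        )

    def test_identical_multisets_p_one(self):
        a = self._calls([1.0, 1.5, 2.0])
        _, p = expr.compare_bias_magnitude(a, a.copy(), "male")
        assert p == pytest.approx(1.0)

    def test_3v3_matches_enumeration(self):
        a = self._calls([0.9, 1.4, 2.2])
        b = self._calls([0.7, 1.1, 1.2])
        _, p = expr.compare_bias_magnitude(a, b, "male")
        assert p == pytest.approx(
            exact_mwu_two_sided(np.array([0.9, 1.4, 2.2]), np.array([0.7, 1.1, 1.2]))
        )

    def test_shifted_distribution_detected(self):
        rng = np.random.default_rng(2)
        a = self._calls(0.6 + rng.exponential(0.8, size=60))
        b = self._calls(0.6 + rng.exponential(0.4, size=60))
        _, p = expr.compare_bias_magnitude(a, b, "male")
        assert p < 0.05

    def test_empty_side_errors(self):
        a = self._calls([1.0])
        b = self._calls([1.0], direction="female")
        with pytest.raises(ValueError, match="biased"):
            expr.compare_bias_magnitude(a, b, "male")


class TestBH:
    def test_matches_naive_step_up(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = rng.uniform(size=40)
            adj = expr.benjamini_hochberg(p)
            # naive step-up
            order = np.argsort(p)
            m = len(p)
            naive = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                naive[i] = running
            assert np.allclose(adj, naive)


class TestWithinClassPca:
    def test_single_class_equals_plain_pca(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(10, 6)))
        plain = expr.within_class_pca(X)
        corrected = expr.within_class_pca(X, classes=pd.Series(["a"] * 10))
        assert np.allclose(plain.variance_fraction, corrected.variance_fraction)
        assert np.allclose(
            np.abs(plain.coordinates.to_numpy()), np.abs(corrected.coordinates.to_numpy())
        )

    def test_class_shift_removed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 8))
        classes = pd.Series(["a"] * 20 + ["b"] * 20)
        X[20:] += 5.0  # pure mean shift for class b
        res = expr.within_class_pca(pd.DataFrame(X), classes=classes)
        pc1 = res.coordinates["PC1"].to_numpy()
        # class label should not predict PC1 sign better than chance
        acc = max(
            np.mean((pc1 > 0) == (classes == "b")), np.mean((pc1 > 0) == (classes == "a"))
        )
        null_acc = []
        for _ in range(200):
            perm = rng.permutation(classes.to_numpy())
            null_acc.append(
                max(np.mean((pc1 > 0) == (perm == "b")), np.mean((pc1 > 0) == (perm == "a")))
            )
        assert acc <= np.quantile(null_acc, 0.95)

    def test_constant_matrix_zero_variance(self):
        X = pd.DataFrame(np.full((6, 4), 3.0))
        res = expr.within_class_pca(X)
        assert np.allclose(res.variance_fraction, 0)
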