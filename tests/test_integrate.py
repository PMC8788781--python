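"""Correlation, clustering, PCA, chord contributions and covariation."""

import numpy as np
import pandas as pd
import pytest

from tubulomics.integrate import (
    CovariationResult,
    chord_contributions,
    correlation_matrix,
    covariation_vs_regulation,
    filter_by_completeness,
    hclust_order,
    pca,
)


def _matrix(rows: dict, columns=None) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


class TestCorrelationMatrix:
    def test_self_correlation_is_one_and_symmetric(self):
        m = _matrix({"A": [1.0, 2.0, 3.0, 5.0], "B": [2.0, 1.0, 4.0, 3.0]})
        corr = correlation_matrix(m)
        assert corr.loc["A", "A"] == pytest.approx(1.0)
        assert corr.loc["A", "B"] == pytest.approx(corr.loc["B", "A"])

    def test_exact_linear_relations(self):
        m = _matrix({"X": [1.0, 2.0, 3.0], "Y": [2.0, 4.0, 6.0], "Z": [6.0, 4.0, 2.0]})
        corr = correlation_matrix(m)
        assert corr.loc["X", "Y"] == pytest.approx(1.0)
        assert corr.loc["X", "Z"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        m = _matrix({"X": [1.0, 2.0, 3.0, 4.0], "Y": [1.0, 3.0, 2.0, 4.0]})
        assert correlation_matrix(m).loc["X", "Y"] == pytest.approx(0.8)

    def test_affine_rescaling_invariance(self):
        m = _matrix({"X": [1.0, 2.0, 3.0, 4.0], "Y": [1.0, 3.0, 2.0, 4.0]})
        m2 = m.copy()
        m2.loc["Y"] = 100.0 - 7.0 * m2.loc["Y"]
        assert abs(correlation_matrix(m2).loc["X", "Y"]) == pytest.approx(0.8)

    def test_zero_variance_series_is_missing(self):
        m = _matrix({"X": [1.0, 2.0, 3.0], "C": [5.0, 5.0, 5.0]})
        assert np.isnan(correlation_matrix(m).loc["X", "C"])

    def test_observation_floor_enforced(self):
        m = _matrix({"X": [1.0, 2.0, np.nan, np.nan], "Y": [2.0, 1.0, 3.0, 4.0]})
        assert np.isnan(correlation_matrix(m).loc["X", "Y"])

    def test_rectangular_against_phenotypes(self):
        m = _matrix({"X": [1.0, 2.0, 3.0, 4.0]}, columns=list("abcd"))
        pheno = pd.DataFrame({"f": [1.0, 3.0, 2.0, 4.0]}, index=list("abcd"))
        corr = correlation_matrix(m, pheno)
        assert corr.loc["X", "f"] == pytest.approx(0.8)


class TestHclustOrder:
    def test_identical_rows_merge_first_at_zero_distance(self):
        corr = pd.DataFrame(
            [[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        order, link = hclust_order(corr)
        assert link[0, 2] == pytest.approx(0.0)
        pos = {label: i for i, label in enumerate(order)}
        assert abs(pos["A"] - pos["B"]) == 1

    def test_planted_blocks_are_contiguous(self):
        rng = np.random.default_rng(0)
        blocks = {"PC": 4, "IC": 5, "HK": 3}
        labels, rows = [], []
        for name, size in blocks.items():
            labels += [f"{name}{i}" for i in range(size)]
        n = len(labels)
        corr = np.full((n, n), 0.0)
        start = 0
        for size in blocks.values():
            corr[start : start + size, start : start + size] = 0.8
            start += size
        np.fill_diagonal(corr, 1.0)
        corr += rng.normal(0, 0.02, size=corr.shape)
        corr = (corr + corr.T) / 2
        df = pd.DataFrame(corr, index=labels, columns=labels)
        order, _ = hclust_order(df)
        classes = [lbl[:2] for lbl in order]
        n_runs = 1 + sum(classes[i] != classes[i - 1] for i in range(1, len(classes)))
        assert n_runs == len(blocks)

    def test_row_permutation_preserves_merge_heights(self):
        rng = np.random.default_rng(1)
        corr = pd.DataFrame(
            np.corrcoef(rng.normal(size=(6, 30))),
            index=list("ABCDEF"),
            columns=list("ABCDEF"),
        )
        _, link_a = hclust_order(corr)
        perm = list("FEDCBA")
        _, link_b = hclust_order(corr.loc[perm, perm])
        assert np.allclose(sorted(link_a[:, 2]), sorted(link_b[:, 2]))

    def test_single_item_rejected(self):
        corr = pd.DataFrame([[1.0]], index=["A"], columns=["A"])
        with pytest.raises(ValueError):
            hclust_order(corr)


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 8)))
        res = pca(m, axis="tubules")
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_rank_one_matrix_concentrates_variance(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([2.0, -1.0, 0.5])
        m = pd.DataFrame(np.outer(v, u) + 5.0)
        res = pca(m, axis="tubules")
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_invariant_to_observation_order_up_to_sign(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 9)), columns=[f"T{i}" for i in range(9)])
        res = pca(m, axis="tubules")
        perm = list(reversed(m.columns))
        res_p = pca(m[perm], axis="tubules")
        a = res.scores["PC1"].reindex(res_p.scores.index)
        b = res_p.scores["PC1"]
        assert np.allclose(a, b) or np.allclose(a, -b)

    def test_missing_values_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            pca(m)


class TestFilterByCompleteness:
    def test_undersampled_proteins_dropped(self):
        m = pd.DataFrame(
            {
                "S1": [1.0, np.nan, 1.0],
                "S2": [2.0, np.nan, 2.0],
                "S3": [3.0, 3.0, np.nan],
            },
            index=["full", "sparse", "edge"],
        )
        kept = filter_by_completeness(m, min_valid_fraction=0.7)
        assert list(kept.index) == ["full"]


CHORD_CORR = pd.DataFrame(
    {
        "f1": [0.5, 0.3, -0.6, 0.0],
        "f2": [-0.2, 0.4, 0.1, 0.2],
    },
    index=["A", "B", "C", "D"],
)
CHORD_MARKERS = pd.Series({"A": "PC", "B": "PC", "C": "IC", "D": "HK"})


class TestChordContributions:
    def test_hand_computed_masses_and_widths(self):
        pos = chord_contributions(CHORD_CORR, CHORD_MARKERS, "pos").set_index(
            ["cell_class", "phenotype"]
        )
        # positive masses: PC-f1 0.8, PC-f2 0.4, IC-f2 0.1, HK-f2 0.2 (total 1.5)
        assert pos.loc[("PC", "f1"), "mass"] == pytest.approx(0.8)
        assert pos.loc[("PC", "f2"), "mass"] == pytest.approx(0.4)
        assert pos.loc[("IC", "f1"), "mass"] == pytest.approx(0.0)
        assert pos.loc[("PC", "f1"), "width"] == pytest.approx(0.8 / 1.5)
        assert pos["width"].sum() == pytest.approx(1.0)
        neg = chord_contributions(CHORD_CORR, CHORD_MARKERS, "neg").set_index(
            ["cell_class", "phenotype"]
        )
        # negative masses: IC-f1 0.6, PC-f2 0.2 (total 0.8)
        assert neg.loc[("IC", "f1"), "width"] == pytest.approx(0.75)
        assert neg.loc[("PC", "f2"), "width"] == pytest.approx(0.25)

    def test_single_class_signed_masses(self):
        corr = pd.DataFrame({"f": [0.5, 0.3, -0.2]}, index=["A", "B", "C"])
        markers = pd.Series({"A": "PC", "B": "PC", "C": "PC"})
        pos = chord_contributions(corr, markers, "pos")
        neg = chord_contributions(corr, markers, "neg")
        assert pos["mass"].sum() == pytest.approx(0.8)
        assert neg["mass"].sum() == pytest.approx(0.2)

    def test_all_zero_correlations_give_zero_widths(self):
        corr = pd.DataFrame({"f": [0.0, 0.0]}, index=["A", "B"])
        markers = pd.Series({"A": "PC", "B": "IC"})
        out = chord_contributions(corr, markers, "pos")
        assert (out["width"] == 0.0).all()

    def test_widths_renormalize_under_duplicated_phenotype(self):
        dup = CHORD_CORR.copy()
        dup["f1_copy"] = dup["f1"]
        out = chord_contributions(dup, CHORD_MARKERS, "pos")
        assert out["width"].sum() == pytest.approx(1.0)

    def test_unmapped_protein_rejected(self):
        with pytest.raises(ValueError, match="marker map"):
            chord_contributions(CHORD_CORR, pd.Series({"A": "PC"}), "pos")


class TestCovariation:
    def _wt(self, rng, n_proteins=10, n_tubules=8):
        m = pd.DataFrame(
            rng.normal(size=(n_proteins, n_tubules)),
            index=[f"P{i}" for i in range(n_proteins)],
        )
        return m

    def test_perfect_anticorrelation(self, rng):
        wt = self._wt(rng)
        x = correlation_matrix(wt).loc[:, "P0"].drop("P0")
        ko = pd.DataFrame({"log2fc": -x})
        res = covariation_vs_regulation(wt, "P0", ko)
        assert res.r == pytest.approx(-1.0)

    def test_anchor_excluded_from_table(self, rng):
        wt = self._wt(rng)
        ko = pd.DataFrame(
            {"log2fc": rng.normal(size=10)}, index=[f"P{i}" for i in range(10)]
        )
        res = covariation_vs_regulation(wt, "P0", ko)
        assert "P0" not in res.table.index
        assert sum(res.quadrant_counts.values()) == len(res.table)

    def test_missing_anchor_rejected(self, rng):
        wt = self._wt(rng)
        with pytest.raises(ValueError, match="anchor"):
            covariation_vs_regulation(wt, "NOPE", pd.DataFrame({"log2fc": []}))

    def test_permutation_detects_planted_coregulation(self, rng):
        # 4 proteins co-expressed with the anchor and strongly decreased;
        # the rest independent and unchanged
        n_tub = 12
        f = rng.normal(size=n_tub)
        rows, fcs = {}, {}
        rows["ANCHOR"] = f + 0.3 * rng.normal(size=n_tub)
        for i in range(4):
            rows[f"M{i}"] = f + 0.3 * rng.normal(size=n_tub)
            fcs[f"M{i}"] = -1.5 + 0.1 * rng.normal()
        for i in range(20):
            rows[f"N{i}"] = rng.normal(size=n_tub)
            fcs[f"N{i}"] = 0.2 * rng.normal()
        wt = pd.DataFrame.from_dict(rows, orient="index")
        ko = pd.DataFrame({"log2fc": pd.Series(fcs)})
        res = covariation_vs_regulation(wt, "ANCHOR", ko, n_permutations=500, seed=1)
        assert res.r < 0
        assert res.p_quadrant_mass < 0.05
        assert res.p_r_negative < 0.05
        assert res.quadrant_counts["x>0,y<0"] >= 4
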