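"""Expression filtering, normalization and NB differential expression."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirnaome.quant import (
    cpm_normalize,
    differential_expression,
    estimate_size_factors,
    filter_expressed,
    log_cpm,
    pca_project,
    sample_distances,
    volcano_classify,
)


def _matrix(rows: dict, design) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=design.index)


class TestFilterExpressed:
    def test_one_qualifying_population_keeps_feature(self, design9):
        counts = _matrix({"f": [6, 7, 9, 0, 1, 2, 0, 0, 0]}, design9)
        for rule in ("strict", "mean_only"):
            assert list(filter_expressed(counts, design9, rule=rule).index) == ["f"]

    def test_rule_contrast_on_uneven_replicates(self, design9):
        counts = _matrix({"f": [4, 50, 1, 0, 0, 0, 0, 0, 0]}, design9)
        assert filter_expressed(counts, design9, rule="strict").empty
        assert not filter_expressed(counts, design9, rule="mean_only").empty

    def test_all_zero_dropped(self, design9):
        counts = _matrix({"f": [0] * 9}, design9)
        assert filter_expressed(counts, design9).empty

    def test_negative_threshold_rejected(self, design9):
        counts = _matrix({"f": [1] * 9}, design9)
        with pytest.raises(ValueError):
            filter_expressed(counts, design9, min_reads=-1)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_strict_subset_of_mean_only(self, seed):
        rng = np.random.default_rng(seed)
        design = pd.DataFrame(
            {"population": ["A"] * 3 + ["B"] * 3},
            index=[f"s{i}" for i in range(6)],
        )
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(30, 6)),
            index=[f"f{i}" for i in range(30)],
            columns=design.index,
        )
        strict = set(filter_expressed(counts, design, rule="strict").index)
        mean = set(filter_expressed(counts, design, rule="mean_only").index)
        assert strict <= mean


class TestCpm:
    def test_scaling(self, design9):
        counts = _matrix({"f": [200] + [0] * 8, "g": [2_000_000 - 200] + [1] * 8},
                         design9)
        cpm = cpm_normalize(counts)
        assert cpm.loc["f", counts.columns[0]] == pytest.approx(100.0)

    def test_columns_sum_to_million(self, design9):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 100, size=(50, 9)),
                              columns=design9.index)
        assert cpm_normalize(counts).sum(axis=0).to_numpy() == pytest.approx(
            np.full(9, 1e6)
        )

    def test_zero_column_warns(self):
        counts = pd.DataFrame({"a": [0, 0], "b": [1, 1]})
        with pytest.warns(UserWarning, match="all-zero"):
            cpm = cpm_normalize(counts)
        assert (cpm["a"] == 0).all()


class TestSizeFactors:
    def test_doubled_library(self):
        rng = np.random.default_rng(2)
        base = rng.integers(1, 200, size=40)
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        sf = estimate_size_factors(counts)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2), rel=1e-9)
        assert sf["b"] == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3]})
        assert estimate_size_factors(counts).to_numpy() == pytest.approx([1, 1])

    def test_single_sample(self):
        counts = pd.DataFrame({"a": [5, 10, 3]})
        assert estimate_size_factors(counts)["a"] == pytest.approx(1.0)

    def test_no_common_feature_is_error(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 3]})
        with pytest.raises(ValueError, match="pseudocount"):
            estimate_size_factors(counts)

    def test_scalar_multiples_recovered(self):
        rng = np.random.default_rng(3)
        base = rng.integers(1, 500, size=60).astype(float)
        scales = np.array([0.5, 1.0, 2.0])
        counts = pd.DataFrame(
            {f"s{i}": np.round(base * c) for i, c in enumerate(scales)}
        )
        sf = estimate_size_factors(counts).to_numpy()
        expected = scales / np.exp(np.log(scales).mean())
        assert sf == pytest.approx(expected, rel=0.05)


def _nb(rng, mean, alpha, size):
    n = 1 / alpha
    return rng.negative_binomial(n, n / (n + mean), size=size)


class TestDifferentialExpression:
    def test_identical_groups_null_result(self, design9):
        counts = _matrix({"f": [10] * 9, "g": [55] * 9}, design9)
        de = differential_expression(counts, design9, "PSC", "CM")
        assert de["log2FC"].to_numpy() == pytest.approx(0.0)
        assert de["pvalue"].to_numpy() == pytest.approx(1.0)

    def test_antisymmetry(self, design9):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            _nb(rng, 100, 0.05, (80, 9)), columns=design9.index
        )
        ab = differential_expression(counts, design9, "PSC", "CM")
        ba = differential_expression(counts, design9, "CM", "PSC")
        assert ba["log2FC"].to_numpy() == pytest.approx(-ab["log2FC"].to_numpy())
        assert ba["pvalue"].to_numpy() == pytest.approx(ab["pvalue"].to_numpy())

    def test_insufficient_replicates_rejected(self, design9):
        counts = _matrix({"f": [1] * 9}, design9).iloc[:, [0, 3, 4, 5]]
        with pytest.raises(ValueError, match="replicates"):
            differential_expression(counts, design9.iloc[[0, 3, 4, 5]], "PSC", "CM")

    def test_planted_fold_change_sign_recovery(self, design9):
        """Features planted at log2FC=4 and mean >= 50 get the right sign."""
        rng = np.random.default_rng(5)
        n, n_de = 400, 50
        meanA = rng.uniform(50, 500, size=n)
        meanB = meanA.copy()
        meanB[:n_de] *= 16  # log2FC = 4 on a minority of features
        A = np.column_stack([_nb(rng, meanA, 0.05, n) for _ in range(3)])
        B = np.column_stack([_nb(rng, meanB, 0.05, n) for _ in range(3)])
        counts = pd.DataFrame(np.hstack([A, B]), columns=design9.index[:6])
        design = design9.iloc[:6]
        de = differential_expression(counts, design, "PSC", "MPC")
        assert (de["log2FC"].iloc[:n_de] > 0).mean() >= 0.99

    def test_padj_monotone_in_p(self, design9):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            _nb(rng, 50, 0.1, (100, 9)), columns=design9.index
        )
        de = differential_expression(counts, design9, "MPC", "CM")
        order = de.sort_values("pvalue")
        assert order["padj"].is_monotonic_increasing
        assert (de["padj"] >= de["pvalue"] - 1e-12).all()


class TestVolcano:
    @pytest.mark.parametrize(
        "lfc,p,expected",
        [(4.2, 0.001, "up"), (-3.5, 0.005, "down"), (2.9, 1e-6, "ns"),
         (3.0, 0.01, "up"), (4.0, 0.02, "ns")],
    )
    def test_threshold_labels(self, lfc, p, expected):
        de = pd.DataFrame({"log2FC": [lfc], "pvalue": [p], "padj": [p]})
        assert volcano_classify(de).iloc[0] == expected


class TestDistancesAndPca:
    def test_identical_samples_distance_zero_and_symmetry(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.uniform(0, 10, size=(30, 4)),
                           columns=list("abcd"))
        mat["d"] = mat["a"]
        d = sample_distances(mat)
        assert d.loc["a", "d"] == pytest.approx(0.0)
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.allclose(np.diag(d.to_numpy()), 0.0)

    def test_unit_offset_distance_is_sqrt_k(self):
        k = 9
        mat = pd.DataFrame({"a": np.zeros(k), "b": np.ones(k)})
        assert sample_distances(mat).loc["a", "b"] == pytest.approx(np.sqrt(k))

    def test_rank_one_data_explained_by_pc1(self):
        t = np.linspace(0, 1, 5)
        mat = pd.DataFrame(np.outer(np.arange(1, 11), t))
        _, _, evr = pca_project(mat, n_components=2)
        assert evr["PC1"] == pytest.approx(1.0)
        assert evr.is_monotonic_decreasing

    def test_full_rank_scores_reproduce_sample_distances(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.normal(size=(20, 5)))
        scores, _, _ = pca_project(mat, n_components=4)
        got = sample_distances(scores.T)
        expected = sample_distances(mat)
        assert np.allclose(got.to_numpy(), expected.to_numpy())

    def test_too_many_components_rejected(self):
        mat = pd.DataFrame(np.random.default_rng(9).normal(size=(20, 4)))
        with pytest.raises(ValueError):
            pca_project(mat, n_components=4)

    def test_log_cpm_transform(self):
        counts = pd.DataFrame({"a": [0, 10], "b": [5, 5]})
        lc = log_cpm(counts)
        assert lc.loc[0, "a"] == pytest.approx(0.0)
        assert lc.loc[0, "b"] == pytest.approx(np.log2(5e5 + 1))
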