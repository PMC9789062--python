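"""Nearest-centroid classification, transitions and subgenome contributions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polycross import triad_bias
from polycross.io_formats import ExpressionMatrix, SampleMeta, ValidationError
from polycross.triad_bias import (
    CATEGORIES_3G,
    classify_all,
    classify_triad,
    default_centroids,
    subgenome_contribution,
    transition_table,
    triad_fractions,
)


def brute_force_classify(v, centroids):
    """Independent oracle: explicit loop over centroids, first strict minimum wins."""
    best, best_d = None, np.inf
    for cat, c in centroids.as_dict().items():
        d = sum((float(vi) - float(ci)) ** 2 for vi, ci in zip(v, c))
        if d < best_d:
            best, best_d = cat, d
    return best


def simplex_grid(step=0.05, dims=3):
    n = round(1 / step)
    for parts in itertools.product(range(n + 1), repeat=dims - 1):
        if sum(parts) <= n:
            yield tuple(p / n for p in parts) + ((n - sum(parts)) / n,)


class TestClassifyTriad:
    @pytest.mark.parametrize("mode", ["3g", "2g"])
    def test_centroid_fixed_points(self, mode):
        centroids = default_centroids(mode)
        for cat, c in centroids.as_dict().items():
            assert classify_triad(c, centroids) == cat

    @pytest.mark.parametrize(
        "fraction, expected",
        [
            ((1 / 3, 1 / 3, 1 / 3), "balanced"),
            ((0.5, 0.5, 0.0), "D_suppressed"),
            ((0.70, 0.15, 0.15), "A_dominant"),
            # exact tie between A_dominant and D_suppressed; canonical order wins
            ((0.75, 0.25, 0.0), "A_dominant"),
        ],
    )
    def test_worked_examples(self, fraction, expected):
        assert classify_triad(fraction) == expected

    def test_rejects_non_composition(self):
        with pytest.raises(ValidationError):
            classify_triad((0.5, 0.5, 0.5))
        with pytest.raises(ValidationError):
            classify_triad((0.5, 0.5))  # wrong length for 3-genome centroids

    def test_matches_brute_force_on_simplex_grid(self):
        centroids = default_centroids("3g")
        for v in simplex_grid(step=0.05):
            assert classify_triad(v, centroids) == brute_force_classify(v, centroids)

    @given(
        st.tuples(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)),
        st.permutations([0, 1, 2]),
    )
    def test_axis_permutation_equivariance(self, raw, perm):
        """Permuting A/B/D axes of input and centroids permutes the category."""
        v = np.asarray(raw) / np.sum(raw)
        centroids = default_centroids("3g")
        permuted = triad_bias.CentroidSet(
            centroids.categories, centroids.matrix[:, perm]
        )
        assert classify_triad(v[perm], permuted) == classify_triad(v, centroids)


def tiny_dataset():
    samples = [
        SampleMeta("AxC_E3_r1", "AxC", "A", "C", 6, 4, "embryo", "E3", 1),
        SampleMeta("AxC_E3_r2", "AxC", "A", "C", 6, 4, "embryo", "E3", 2),
    ]
    values = pd.DataFrame(
        {
            "AxC_E3_r1": [10.0, 30.0, 60.0, 0.0, 0.0, 0.0, 5.0, 5.0, 5.0],
            "AxC_E3_r2": [10.0, 30.0, 60.0, 0.0, 0.0, 0.0, 5.0, 5.0, 5.0],
        },
        index=["a1", "b1", "d1", "a2", "b2", "d2", "a3", "b3", "d3"],
    )
    expr = ExpressionMatrix(values, samples)
    triads = pd.DataFrame(
        {
            "triad_id": ["t1", "t2", "t3"],
            "gene_A": ["a1", "a2", "a3"],
            "gene_B": ["b1", "b2", "b3"],
            "gene_D": ["d1", "d2", "d3"],
        }
    )
    return expr, triads


class TestTriadFractions:
    def test_fraction_computation_and_floor(self):
        expr, triads = tiny_dataset()
        fr = triad_fractions(expr, triads, floor=0.5)
        r1 = fr[fr["sample_id"] == "AxC_E3_r1"].set_index("triad_id")
        assert r1.loc["t1", ["frac_A", "frac_B", "frac_D"]].tolist() == pytest.approx(
            [0.1, 0.3, 0.6]
        )
        assert not r1.loc["t2", "defined"]
        assert r1.loc["t3", ["frac_A", "frac_B", "frac_D"]].tolist() == pytest.approx(
            [1 / 3, 1 / 3, 1 / 3]
        )

    def test_missing_gene_named(self):
        expr, triads = tiny_dataset()
        triads.loc[0, "gene_A"] = "ghost"
        with pytest.raises(ValidationError, match="ghost"):
            triad_fractions(expr, triads)

    def test_replicate_average_matches_single_replicates(self):
        expr, triads = tiny_dataset()
        fr = triad_fractions(expr, triads, floor=0.5)
        avg = triad_bias.average_replicate_fractions(fr, expr)
        t1 = avg[avg["triad_id"] == "t1"].iloc[0]
        # identical replicates: average equals each replicate
        assert [t1["frac_A"], t1["frac_B"], t1["frac_D"]] == pytest.approx([0.1, 0.3, 0.6])
        assert t1["sample_id"] == "AxC_E3"


class TestClassifyAll:
    def test_exact_centroids_recover_planted_percentages(self):
        centroids = default_centroids("3g")
        rows = []
        for i, cat in enumerate(CATEGORIES_3G):
            c = centroids.as_dict()[cat]
            rows.append(
                {
                    "triad_id": f"t{i}",
                    "sample_id": "s",
                    "frac_A": c[0],
                    "frac_B": c[1],
                    "frac_D": c[2],
                    "total_tpm": 10.0,
                    "defined": True,
                }
            )
        calls = classify_all(pd.DataFrame(rows), centroids)
        assert list(calls["category"]) == list(CATEGORIES_3G)
        pct = triad_bias.category_percentages(calls, centroids)
        assert pct["percent"].sum() == pytest.approx(100.0)

    def test_empty_defined_set_warns(self):
        fr = pd.DataFrame(
            {
                "triad_id": ["t1"],
                "sample_id": ["s"],
                "frac_A": [np.nan],
                "frac_B": [np.nan],
                "frac_D": [np.nan],
                "total_tpm": [0.0],
                "defined": [False],
            }
        )
        with pytest.warns(UserWarning):
            calls = classify_all(fr)
        assert calls["category"].isna().all()


class TestTransitionTable:
    @staticmethod
    def calls(mapping):
        return pd.DataFrame(
            {"triad_id": list(mapping), "sample_id": "s", "category": list(mapping.values())}
        )

    def test_worked_example(self):
        a = self.calls({"t1": "balanced", "t2": "balanced", "t3": "D_suppressed"})
        b = self.calls({"t1": "balanced", "t2": "D_suppressed", "t3": "D_suppressed"})
        table = transition_table(a, b)
        assert table.loc["balanced", "balanced"] == 1
        assert table.loc["balanced", "D_suppressed"] == 1
        assert table.loc["D_suppressed", "D_suppressed"] == 1
        assert table.to_numpy().sum() == 3

    def test_identity_is_diagonal(self):
        a = self.calls({"t1": "balanced", "t2": "A_dominant", "t3": "D_suppressed"})
        table = transition_table(a, a)
        off_diag = table.to_numpy().sum() - np.trace(
            table.reindex(index=table.columns, columns=table.columns, fill_value=0).to_numpy()
        )
        assert off_diag == 0

    def test_undefined_tallied_separately(self):
        a = self.calls({"t1": "balanced", "t2": pd.NA})
        b = self.calls({"t1": "balanced", "t2": "balanced"})
        table = transition_table(a, b)
        assert table.loc["undefined", "balanced"] == 1

    def test_disjoint_triads_error(self):
        a = self.calls({"t1": "balanced"})
        b = self.calls({"t9": "balanced"})
        with pytest.raises(ValidationError):
            transition_table(a, b)

    def test_row_sums_match_source_counts(self, triad_dataset):
        from polycross.triad_bias import classify_all, triad_fractions

        expr, triads, _ = triad_dataset
        fr = triad_fractions(expr, triads, floor=0.5)
        sample_ids = expr.sample_ids
        calls_a = classify_all(fr[fr["sample_id"] == sample_ids[0]])
        calls_b = classify_all(fr[fr["sample_id"] == sample_ids[-1]])
        table = transition_table(calls_a, calls_b)
        counts_a = calls_a["category"].fillna("undefined").value_counts()
        for cat in table.index:
            assert table.loc[cat].sum() == counts_a.get(cat, 0)


class TestSubgenomeContribution:
    def test_all_balanced(self):
        fr = pd.DataFrame(
            {
                "triad_id": ["t1", "t2"],
                "sample_id": "s",
                "frac_A": [1 / 3, 1 / 3],
                "frac_B": [1 / 3, 1 / 3],
                "frac_D": [1 / 3, 1 / 3],
                "total_tpm": 10.0,
                "defined": True,
            }
        )
        contrib = subgenome_contribution(fr).set_index("sample_id")
        assert contrib.loc["s"].tolist() == pytest.approx([100 / 3] * 3)

    def test_pentaploid_like_pattern(self):
        fr = pd.DataFrame(
            {
                "triad_id": ["t1", "t2"],
                "sample_id": "s",
                "frac_A": [0.4, 0.4],
                "frac_B": [0.4, 0.4],
                "frac_D": [0.2, 0.2],
                "total_tpm": 10.0,
                "defined": True,
            }
        )
        contrib = subgenome_contribution(fr).set_index("sample_id")
        assert contrib.loc["s"].tolist() == pytest.approx([40.0, 40.0, 20.0])
        assert contrib.loc["s"].sum() == pytest.approx(100.0)

    def test_mixture_mean_matches_closed_form(self, triad_dataset):
        """Simulated mixture: mean contribution ~ proportion-weighted centroid mean."""
        expr, triads, truth = triad_dataset
        fr = triad_fractions(expr, triads, floor=0.5)
        contrib = subgenome_contribution(fr)
        centroids = default_centroids("3g").as_dict()
        cats = pd.Series(truth.triad_category)
        expected = sum(
            (cats == c).mean() * np.asarray(centroids[c]) * 100 for c in cats.unique()
        )
        sample_mean = contrib[["A", "B", "D"]].mean(axis=0).to_numpy()
        assert sample_mean == pytest.approx(expected, abs=1.5)
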