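"""Nearest-centroid classification of homoeolog triad expression bias.

In hexaploid wheat, each homoeologous triad contributes one gene from the A,
B and D subgenomes. Within a sample, the triad's expression composition (the
per-homoeolog fraction of total triad TPM) is assigned to the nearest of
seven reference compositions by Euclidean distance:

====================  ==================
category              centroid
====================  ==================
balanced              (1/3, 1/3, 1/3)
A_dominant            (1, 0, 0)
B_dominant            (0, 1, 0)
D_dominant            (0, 0, 1)
A_suppressed          (0, 1/2, 1/2)
B_suppressed          (1/2, 0, 1/2)
D_suppressed          (1/2, 1/2, 0)
====================  ==================

The balanced centroid uses exact thirds rather than the conventional rounded
0.33: the difference never changes an assignment by more than a distance of
~0.006 but exactness keeps the fixed-point property (every centroid
classifies as its own category) strict. In two-genome mode (tetraploid
crosses, A and B only) the centroids are balanced (1/2, 1/2), A_dominant
(1, 0) and B_dominant (0, 1). Ties are broken by the canonical category
order above (balanced first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ValidationError

__all__ = [
    "CATEGORIES_3G",
    "CATEGORIES_2G",
    "CentroidSet",
    "default_centroids",
    "classify_triad",
    "classify_compositions",
    "triad_fractions",
    "average_replicate_fractions",
    "classify_all",
    "category_percentages",
    "transition_table",
    "subgenome_contribution",
]

CATEGORIES_3G = (
    "balanced",
    "A_dominant",
    "B_dominant",
    "D_dominant",
    "A_suppressed",
    "B_suppressed",
    "D_suppressed",
)
CATEGORIES_2G = ("balanced", "A_dominant", "B_dominant")


@dataclass(frozen=True)
class CentroidSet:
    """Ordered mapping from bias category to reference composition.

    ``categories`` fixes the canonical order used for tie-breaking;
    ``matrix`` holds one centroid per row, each summing to 1.
    """

    categories: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != len(self.categories):
            raise ValidationError("one centroid per category required")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each centroid must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def n_genomes(self) -> int:
        return self.matrix.shape[1]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {c: self.matrix[i] for i, c in enumerate(self.categories)}


def default_centroids(mode: str = "3g") -> CentroidSet:
    """Default centroid set: ``"3g"`` (A/B/D) or ``"2g"`` (A/B, tetraploid)."""
    if mode == "3g":
        third = 1.0 / 3.0
        return CentroidSet(
            CATEGORIES_3G,
            np.array(
                [
                    [third, third, third],
                    [1.0, 0.0, 0.0],
                    [0.0, 1.0, 0.0],
                    [0.0, 0.0, 1.0],
                    [0.0, 0.5, 0.5],
                    [0.5, 0.0, 0.5],
                    [0.5, 0.5, 0.0],
                ]
            ),
        )
    if mode == "2g":
        return CentroidSet(
            CATEGORIES_2G,
            np.array([[0.5, 0.5], [1.0, 0.0], [0.0, 1.0]]),
        )
    raise ValidationError(f"unknown centroid mode {mode!r}; expected '3g' or '2g'")


def classify_triad(fraction, centroids: CentroidSet | None = None) -> str:
    """Assign one composition vector to the nearest centroid's category.

    The vector must sum to 1 within 1e-6. Exact distance ties go to the
    earliest category in canonical order.
    """
    if centroids is None:
        centroids = default_centroids()
    v = np.asarray(fraction, dtype=float)
    if v.shape != (centroids.n_genomes,):
        raise ValidationError(
            f"fraction vector has length {v.size}, expected {centroids.n_genomes}"
        )
    if abs(v.sum() - 1.0) > 1e-6:
        raise ValidationError(f"fraction vector sums to {v.sum():.8f}, not 1")
    d2 = np.sum((centroids.matrix - v) ** 2, axis=1)
    return centroids.categories[int(np.argmin(d2))]


def classify_compositions(fractions: np.ndarray, centroids: CentroidSet) -> np.ndarray:
    """Vectorized nearest-centroid assignment for an (n, k) array of compositions."""
    f = np.asarray(fractions, dtype=float)
    if not np.allclose(f.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("every composition must sum to 1 within 1e-6")
    # squared distances, (n, n_categories); argmin takes the first minimum,
    # which realizes canonical-order tie-breaking
    d2 = ((f[:, None, :] - centroids.matrix[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    return np.asarray(centroids.categories, dtype=object)[idx]


def triad_fractions(
    expr: ExpressionMatrix, triads: pd.DataFrame, floor: float = 0.5
) -> pd.DataFrame:
    """Per-replicate relative homoeolog expression within each triad.

    Returns a long DataFrame with columns triad_id, sample_id, frac_A,
    frac_B, frac_D (frac_D absent in two-genome mode), total_tpm, defined.
    A triad is ``defined`` in a sample when its total TPM reaches ``floor``;
    fractions are NaN otherwise.
    """
    two_genome = triads["gene_D"].isna().all()
    gene_cols = ["gene_A", "gene_B"] if two_genome else ["gene_A", "gene_B", "gene_D"]
    frac_cols = ["frac_A", "frac_B"] if two_genome else ["frac_A", "frac_B", "frac_D"]
    for col in gene_cols:
        missing = triads.loc[~triads[col].isin(expr.gene_ids), col]
        if len(missing):
            raise ValidationError(
                f"triad gene {missing.iloc[0]!r} absent from expression matrix"
            )
    records = []
    values = expr.values
    per_gene = [values.loc[triads[col].values].to_numpy() for col in gene_cols]
    stack = np.stack(per_gene, axis=2)  # (n_triads, n_samples, n_genomes)
    totals = stack.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = stack / totals[:, :, None]
    defined = totals >= floor
    fracs[~defined] = np.nan
    for j, sample_id in enumerate(expr.sample_ids):
        block = pd.DataFrame(fracs[:, j, :], columns=frac_cols)
        block.insert(0, "triad_id", triads["triad_id"].values)
        block.insert(1, "sample_id", sample_id)
        block["total_tpm"] = totals[:, j]
        block["defined"] = defined[:, j]
        records.append(block)
    return pd.concat(records, ignore_index=True)


def average_replicate_fractions(
    fractions: pd.DataFrame, expr: ExpressionMatrix
) -> pd.DataFrame:
    """Average per-replicate fractions over replicates of the same (cross, stage).

    The mean is taken over replicates in which the triad is defined, then
    renormalized to sum exactly to 1; a triad is defined for the group when
    it is defined in at least one replicate. ``sample_id`` becomes
    ``"<cross>_<stage>"``.
    """
    meta = expr.sample_table()[["sample_id", "cross", "stage"]]
    merged = fractions.merge(meta, on="sample_id")
    merged["group_id"] = merged["cross"] + "_" + merged["stage"]
    frac_cols = [c for c in fractions.columns if c.startswith("frac_")]
    grouped = merged.groupby(["triad_id", "group_id"], sort=False)
    agg = grouped.agg(
        {**{c: "mean" for c in frac_cols}, "total_tpm": "mean", "defined": "any"}
    ).reset_index()
    total = agg[frac_cols].sum(axis=1)
    with np.errstate(invalid="ignore"):
        agg[frac_cols] = agg[frac_cols].div(total, axis=0)
    agg = agg.rename(columns={"group_id": "sample_id"})
    return agg[["triad_id", "sample_id", *frac_cols, "total_tpm", "defined"]]


def classify_all(
    fractions: pd.DataFrame, centroids: CentroidSet | None = None
) -> pd.DataFrame:
    """Classify every defined triad composition.

    Input is a fractions table from :func:`triad_fractions` or
    :func:`average_replicate_fractions`. Returns columns triad_id,
    sample_id, category (NaN where undefined).
    """
    if centroids is None:
        frac_cols = [c for c in fractions.columns if c.startswith("frac_")]
        centroids = default_centroids("2g" if len(frac_cols) == 2 else "3g")
    frac_cols = [c for c in fractions.columns if c.startswith("frac_")]
    out = fractions[["triad_id", "sample_id"]].copy()
    out["category"] = pd.NA
    defined = fractions["defined"].to_numpy(dtype=bool)
    if not defined.any():
        warnings.warn("no defined triads to classify", stacklevel=2)
        return out
    comps = fractions.loc[defined, frac_cols].to_numpy()
    out.loc[defined, "category"] = classify_compositions(comps, centroids)
    return out


def category_percentages(calls: pd.DataFrame, centroids: CentroidSet | None = None) -> pd.DataFrame:
    """Per-sample category counts and percentages over defined triads."""
    if centroids is None:
        centroids = default_centroids()
    defined = calls.dropna(subset=["category"])
    rows = []
    for sample_id, grp in defined.groupby("sample_id", sort=False):
        counts = grp["category"].value_counts()
        n = len(grp)
        for cat in centroids.categories:
            c = int(counts.get(cat, 0))
            rows.append(
                {
                    "sample_id": sample_id,
                    "category": cat,
                    "count": c,
                    "percent": 100.0 * c / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def transition_table(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Count triad category switches between two call sets (e.g. reciprocal crosses).

    Only triads defined (classified) in both call sets enter the from→to
    counts; triads undefined in either are tallied separately under the
    pseudo-category ``"undefined"``. Raises on disjoint triad universes.
    """
    for name, calls in (("calls_a", calls_a), ("calls_b", calls_b)):
        if calls["triad_id"].duplicated().any():
            raise ValidationError(
                f"{name} contains several calls per triad; filter to one sample first"
            )
    a = calls_a.set_index("triad_id")["category"]
    b = calls_b.set_index("triad_id")["category"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValidationError("call sets share no triads")
    a, b = a.loc[shared], b.loc[shared]
    table = pd.crosstab(
        a.fillna("undefined"), b.fillna("undefined"), dropna=False
    )
    table.index.name = "from_category"
    table.columns.name = "to_category"
    return table


def subgenome_contribution(fractions: pd.DataFrame) -> pd.DataFrame:
    """Mean percentage contribution of each subgenome per sample.

    Arithmetic mean of the defined triad fractions × 100; rows sum to 100.
    In pentaploid embryos the D subgenome typically falls to ~20% while A
    and B rise to ~40% each.
    """
    frac_cols = [c for c in fractions.columns if c.startswith("frac_")]
    defined = fractions[fractions["defined"]]
    means = defined.groupby("sample_id", sort=False)[frac_cols].mean() * 100.0
    means.columns = [c.replace("frac_", "") for c in frac_cols]
    return means.reset_index()
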