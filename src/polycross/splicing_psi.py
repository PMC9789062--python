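"""Isoform-level PSI, ΔPSI and empirical differential-splicing significance.

PSI (percent spliced-in) of an isoform is its share of the gene's total
isoform-level TPM in one sample. ΔPSI between two sample groups is the
difference of group-mean PSIs. Significance uses an empirical null built
from between-replicate PSI fluctuations within groups, pooled across
isoforms within gene-abundance bins: biological replicates of the same
group differ only by noise, so their PSI differences characterize the
magnitude of ΔPSI expected in the absence of differential splicing at a
given expression level (low-expression genes have noisier PSI estimates).

A call is differential (DAS) when |ΔPSI| exceeds the effect threshold
(default 0.1, strict) and the BH-adjusted empirical p-value is below the
FDR level (default 0.05).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_stats import bh_adjust, ks_two_sample
from .io_formats import ValidationError

__all__ = [
    "psi_per_isoform",
    "alternative_flag",
    "delta_psi",
    "empirical_significance",
    "das_call",
    "differential_splicing",
    "psi_distribution_compare",
]


def psi_per_isoform(quant: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Per-isoform PSI for one sample's transcript quantifications.

    Parameters
    ----------
    quant
        One sample's table with columns transcript_id, gene_id, tpm,
        sample_id (as produced by
        :func:`polycross.io_formats.read_transcript_quant`).
    floor
        Genes with total isoform TPM below this are left undefined (NaN PSI)
        — PSI of an unexpressed gene is meaningless.

    Returns
    -------
    DataFrame with columns gene_id, isoform_id, sample_id, psi, gene_tpm.
    """
    if (quant["tpm"] < 0).any():
        raise ValidationError("negative TPM in quantification table")
    if quant["sample_id"].nunique() > 1:
        raise ValidationError("psi_per_isoform expects a single sample")
    gene_tpm = quant.groupby("gene_id")["tpm"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(gene_tpm >= floor, quant["tpm"] / gene_tpm, np.nan)
    return pd.DataFrame(
        {
            "gene_id": quant["gene_id"],
            "isoform_id": quant["transcript_id"],
            "sample_id": quant["sample_id"],
            "psi": psi,
            "gene_tpm": gene_tpm,
        }
    )


def alternative_flag(psi: float) -> bool | None:
    """True when an isoform is 'alternative': 0.05 <= PSI <= 0.95 (inclusive).

    Isoforms outside the band are essentially constitutive (always or never
    the gene's product). Undefined PSI yields an undefined flag (None).
    """
    if psi is None or (isinstance(psi, float) and np.isnan(psi)):
        return None
    return 0.05 <= psi <= 0.95


def _psi_wide(psi_records: pd.DataFrame) -> pd.DataFrame:
    """Pivot long PSI records to an isoform × sample matrix."""
    return psi_records.pivot_table(
        index="isoform_id", columns="sample_id", values="psi", dropna=False
    )


def delta_psi(group1: pd.DataFrame, group2: pd.DataFrame) -> pd.Series:
    """Mean PSI difference per isoform: mean(group2) − mean(group1).

    Each argument is a long PSI-record table covering that group's
    replicates. Undefined PSIs are excluded from means; the result is NaN
    where either group has no defined PSI for an isoform.
    """
    m1 = _psi_wide(group1).mean(axis=1, skipna=True)
    m2 = _psi_wide(group2).mean(axis=1, skipna=True)
    isoforms = m1.index.union(m2.index)
    return m2.reindex(isoforms) - m1.reindex(isoforms)


def _within_group_diffs(wide: pd.DataFrame) -> pd.Series:
    """All pairwise |PSI_i − PSI_j| between replicates, per isoform (long)."""
    cols = list(wide.columns)
    out = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            d = (wide[cols[i]] - wide[cols[j]]).abs().dropna()
            out.append(d)
    if not out:
        return pd.Series(dtype=float)
    return pd.concat(out)


def empirical_significance(
    delta: pd.Series,
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    n_null: int = 1000,
    n_bins: int = 3,
    seed: int = 0,
) -> pd.Series:
    """Empirical p-values for observed ΔPSI against a replicate-noise null.

    The null pool for each isoform is the set of within-group
    between-replicate |ΔPSI| values of all isoforms in the same gene
    abundance bin (``n_bins`` quantile bins of log10 mean gene TPM). Each
    isoform's p is the add-one-smoothed fraction of ``n_null`` resampled
    null values that reach its observed |ΔPSI|:
    ``p = (1 + #{null >= |Δ|}) / (n_null + 1)``.

    Requires at least two replicates per group. Deterministic given seed.
    """
    for grp, name in ((group1, "group1"), (group2, "group2")):
        if grp["sample_id"].nunique() < 2:
            raise ValidationError(
                f"{name} has fewer than 2 replicates; empirical significance "
                "needs within-group replicate differences (no permutation-free mode)"
            )
    rng = np.random.default_rng(seed)
    wide1, wide2 = _psi_wide(group1), _psi_wide(group2)
    null_values = pd.concat([_within_group_diffs(wide1), _within_group_diffs(wide2)])

    both = pd.concat([group1, group2], ignore_index=True)
    abundance = both.groupby("isoform_id")["gene_tpm"].mean()
    log_ab = np.log10(abundance.clip(lower=1e-6))
    # quantile bins; fall back to a single bin when abundances are too uniform
    try:
        bins = pd.qcut(log_ab, q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = pd.Series(0, index=log_ab.index)
    if bins.isna().all():
        bins = pd.Series(0, index=log_ab.index)
    bins = bins.fillna(0).astype(int)

    observed = delta.dropna()
    p = pd.Series(np.nan, index=delta.index, dtype=float)
    null_bins = bins.reindex(null_values.index)
    for b in sorted(bins.unique()):
        pool = null_values[null_bins == b].to_numpy()
        if pool.size == 0:  # degenerate bin: use the global pool
            pool = null_values.to_numpy()
        if pool.size == 0:
            raise ValidationError("no within-group replicate pairs with defined PSI")
        members = observed.index.intersection(bins.index[bins == b])
        if len(members) == 0:
            continue
        draws = rng.choice(pool, size=(len(members), n_null), replace=True)
        obs = np.abs(observed.loc[members].to_numpy())[:, None]
        exceed = (draws >= obs).sum(axis=1)
        p.loc[members] = (1.0 + exceed) / (n_null + 1.0)
    return p


def das_call(
    delta: pd.Series,
    p_empirical: pd.Series,
    dpsi_threshold: float = 0.1,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Differential-splicing calls from ΔPSI and empirical p-values.

    ``significant`` requires |ΔPSI| strictly greater than ``dpsi_threshold``
    AND BH-adjusted q below ``fdr``. ``direction`` reports the sign of ΔPSI
    (up = higher inclusion in group 2).
    """
    delta, p_empirical = delta.align(p_empirical)
    out = pd.DataFrame({"delta_psi": delta, "p_empirical": p_empirical})
    out["q"] = np.nan
    tested = out["p_empirical"].notna()
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p_empirical"].to_numpy())
    out["significant"] = (
        (out["delta_psi"].abs() > dpsi_threshold) & (out["q"] < fdr)
    ).fillna(False)
    out["direction"] = np.where(
        out["delta_psi"] > 0, "up", np.where(out["delta_psi"] < 0, "down", "none")
    )
    out.index.name = "isoform_id"
    return out.reset_index()


def differential_splicing(
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    n_null: int = 1000,
    n_bins: int = 3,
    seed: int = 0,
    dpsi_threshold: float = 0.1,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """End-to-end DAS analysis between two groups of PSI record tables."""
    delta = delta_psi(group1, group2)
    p = empirical_significance(delta, group1, group2, n_null=n_null, n_bins=n_bins, seed=seed)
    return das_call(delta, p, dpsi_threshold=dpsi_threshold, fdr=fdr)


def psi_distribution_compare(psis_a, psis_b) -> tuple[float, float]:
    """Kolmogorov–Smirnov comparison of two pooled PSI distributions.

    Accepts arrays or PSI-record tables; undefined PSIs are dropped.
    """
    def _vals(x):
        if isinstance(x, pd.DataFrame):
            x = x["psi"]
        v = np.asarray(x, dtype=float)
        return v[~np.isnan(v)]

    a, b = _vals(psis_a), _vals(psis_b)
    if a.size == 0 or b.size == 0:
        raise ValidationError("no defined PSI values to compare")
    return ks_two_sample(a, b)
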