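"""Dosage-aware MEG/PEG calling from allele-specific counts of a reciprocal cross pair.

A gene is called imprinted only when both directions of a reciprocal cross
agree. For each direction, replicate counts are pooled and the maternal
read fraction is tested by a Pearson chi-square goodness-of-fit against the
tissue's dosage expectation: 0.5 in the diploid embryo (one maternal + one
paternal genome copy) and 2/3 in the triploid endosperm (two maternal + one
paternal). p-values are Benjamini–Hochberg adjusted across all
(gene x direction) tests of the stage/tissue.

Call rules (defaults):

* minimum 10 pooled SNP-associated reads per cross direction, otherwise
  ``insufficient_data``;
* MEG — both directions FDR < 0.01 and maternal fraction >= 0.7 (embryo)
  or >= 0.85 (endosperm);
* PEG — both directions FDR < 0.01 and paternal fraction >= 0.7 (embryo)
  or >= 0.6 (endosperm).

The endosperm MEG bar is higher than the PEG bar because unimprinted
endosperm genes already sit at ~67% maternal reads. The chi-square
expectation uses 2/3 for every endosperm gene, including D-subgenome genes
of pentaploid endosperm whose true dosage differs — a deliberate
simplification mirroring a single 67% reference line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_stats import bh_adjust
from .io_formats import ValidationError, tissue_for_stage

__all__ = [
    "ImprintingThresholds",
    "maternal_fraction",
    "call_imprinted",
    "maternal_fraction_summary",
]


@dataclass(frozen=True)
class ImprintingThresholds:
    """Read-depth, ratio and FDR thresholds for MEG/PEG calling."""

    min_reads_per_cross: int = 10
    embryo_fraction: float = 0.7
    endosperm_meg_fraction: float = 0.85
    endosperm_peg_fraction: float = 0.6
    fdr: float = 0.01
    embryo_expected_maternal: float = 0.5
    endosperm_expected_maternal: float = 2.0 / 3.0

    def __post_init__(self):
        fracs = (
            self.embryo_fraction,
            self.endosperm_meg_fraction,
            self.endosperm_peg_fraction,
            self.fdr,
            self.embryo_expected_maternal,
            self.endosperm_expected_maternal,
        )
        if not all(0.0 < f < 1.0 for f in fracs):
            raise ValidationError("all threshold fractions must lie strictly in (0, 1)")
        if self.min_reads_per_cross < 1:
            raise ValidationError("min_reads_per_cross must be >= 1")

    def expected_maternal(self, tissue: str) -> float:
        if tissue == "embryo":
            return self.embryo_expected_maternal
        if tissue == "endosperm":
            return self.endosperm_expected_maternal
        raise ValidationError(f"unknown tissue {tissue!r}")

    def meg_fraction(self, tissue: str) -> float:
        return self.embryo_fraction if tissue == "embryo" else self.endosperm_meg_fraction

    def peg_fraction(self, tissue: str) -> float:
        # embryo thresholds are symmetric ("maternal or paternal reads > 0.7")
        return self.embryo_fraction if tissue == "embryo" else self.endosperm_peg_fraction


def _chi2_gof_pvalues(maternal: np.ndarray, paternal: np.ndarray, expected: float) -> np.ndarray:
    """Vectorized counterpart of :func:`polycross.core_stats.chi_square_gof`."""
    from scipy.stats import chi2

    total = maternal + paternal
    e_m = total * expected
    e_p = total * (1.0 - expected)
    stat = (maternal - e_m) ** 2 / e_m + (paternal - e_p) ** 2 / e_p
    return chi2.sf(stat, df=1)


def maternal_fraction(maternal: int, paternal: int) -> float:
    """Maternal reads over total reads; total must be >= 1."""
    total = maternal + paternal
    if total < 1:
        raise ValueError("total read count must be at least 1")
    return maternal / total


def call_imprinted(
    counts: pd.DataFrame,
    stage: str,
    tissue: str,
    cross_pair: tuple[str, str],
    thresholds: ImprintingThresholds | None = None,
    require_each_replicate: bool = False,
) -> pd.DataFrame:
    """Call MEGs and PEGs for one stage/tissue of a reciprocal cross pair.

    Parameters
    ----------
    counts
        Allele-count table (see :func:`polycross.io_formats.read_allele_counts`);
        maternal/paternal are relative to each cross's own maternal parent.
    stage, tissue
        Developmental stage (E1–E9) and matching tissue.
    cross_pair
        (forward, reverse) cross labels, e.g. ``("AxC", "CxA")``.
    thresholds
        Calling thresholds; defaults mirror the standard rules above.
    require_each_replicate
        If True, additionally require every individual replicate of both
        directions to pass the tissue's fraction threshold (stricter
        per-replicate consistency mode).

    Returns
    -------
    DataFrame with one row per gene: gene_id, stage, tissue,
    maternal_fraction_forward/reverse, p_forward/reverse,
    q_forward/reverse, q, status in
    {MEG, PEG, not_imprinted, insufficient_data}.
    """
    if thresholds is None:
        thresholds = ImprintingThresholds()
    if tissue_for_stage(stage) != tissue:
        raise ValidationError(f"stage {stage} inconsistent with tissue {tissue}")
    fwd, rev = cross_pair
    sub = counts[(counts["stage"] == stage) & (counts["tissue"] == tissue)]
    present = set(sub["cross"].unique())
    for direction in (fwd, rev):
        if direction not in present:
            raise ValidationError(
                f"cross direction {direction!r} missing for stage {stage}/{tissue}"
            )
    sub = sub[sub["cross"].isin([fwd, rev])]

    pooled = (
        sub.groupby(["gene_id", "cross"], sort=False)[["maternal_reads", "paternal_reads"]]
        .sum()
        .unstack("cross")
    )
    for direction in (fwd, rev):
        for col in ("maternal_reads", "paternal_reads"):
            if (col, direction) not in pooled.columns:
                pooled[(col, direction)] = np.nan
    m_f = pooled[("maternal_reads", fwd)]
    p_f = pooled[("paternal_reads", fwd)]
    m_r = pooled[("maternal_reads", rev)]
    p_r = pooled[("paternal_reads", rev)]
    tot_f = m_f + p_f
    tot_r = m_r + p_r

    min_reads = thresholds.min_reads_per_cross
    sufficient = (tot_f >= min_reads) & (tot_r >= min_reads)
    sufficient &= tot_f.notna() & tot_r.notna()

    expected = thresholds.expected_maternal(tissue)
    out = pd.DataFrame(index=pooled.index)
    out["stage"] = stage
    out["tissue"] = tissue
    with np.errstate(invalid="ignore"):
        out["maternal_fraction_forward"] = m_f / tot_f
        out["maternal_fraction_reverse"] = m_r / tot_r
    out["p_forward"] = np.nan
    out["p_reverse"] = np.nan

    tested = out.index[sufficient]
    if len(tested):
        out.loc[tested, "p_forward"] = _chi2_gof_pvalues(
            m_f[tested].to_numpy(), p_f[tested].to_numpy(), expected
        )
        out.loc[tested, "p_reverse"] = _chi2_gof_pvalues(
            m_r[tested].to_numpy(), p_r[tested].to_numpy(), expected
        )

    # BH over all (gene x direction) tests of this stage/tissue
    out["q_forward"] = np.nan
    out["q_reverse"] = np.nan
    if len(tested):
        p_all = np.concatenate(
            [out.loc[tested, "p_forward"].to_numpy(), out.loc[tested, "p_reverse"].to_numpy()]
        )
        q_all = bh_adjust(p_all)
        out.loc[tested, "q_forward"] = q_all[: len(tested)]
        out.loc[tested, "q_reverse"] = q_all[len(tested):]
    out["q"] = out[["q_forward", "q_reverse"]].max(axis=1)

    meg_thr = thresholds.meg_fraction(tissue)
    peg_thr = thresholds.peg_fraction(tissue)
    sig = (out["q_forward"] < thresholds.fdr) & (out["q_reverse"] < thresholds.fdr)
    frac_f = out["maternal_fraction_forward"]
    frac_r = out["maternal_fraction_reverse"]
    is_meg = sig & (frac_f >= meg_thr) & (frac_r >= meg_thr)
    is_peg = sig & ((1 - frac_f) >= peg_thr) & ((1 - frac_r) >= peg_thr)

    if require_each_replicate:
        rep_frac = sub.assign(
            frac=sub["maternal_reads"] / (sub["maternal_reads"] + sub["paternal_reads"])
        )
        meg_ok = rep_frac.groupby("gene_id")["frac"].agg(lambda f: (f >= meg_thr).all())
        peg_ok = rep_frac.groupby("gene_id")["frac"].agg(lambda f: ((1 - f) >= peg_thr).all())
        is_meg &= meg_ok.reindex(out.index, fill_value=False)
        is_peg &= peg_ok.reindex(out.index, fill_value=False)

    status = pd.Series("not_imprinted", index=out.index, dtype=object)
    status[is_meg] = "MEG"
    status[is_peg] = "PEG"
    status[~sufficient] = "insufficient_data"
    out["status"] = status
    out.loc[~sufficient, ["p_forward", "p_reverse", "q_forward", "q_reverse", "q"]] = np.nan
    return out.reset_index().rename(columns={"index": "gene_id"})


def maternal_fraction_summary(counts: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-gene maternal read fractions with grouping labels, for density plots.

    Replicates are pooled per (gene, cross, stage). Returns the long table
    (gene_id, cross, stage, tissue, total_reads, maternal_fraction) plus
    metadata giving the dosage reference lines: 50% for embryo, 67% for
    endosperm.
    """
    pooled = (
        counts.groupby(["gene_id", "cross", "stage", "tissue"], sort=False)[
            ["maternal_reads", "paternal_reads"]
        ]
        .sum()
        .reset_index()
    )
    total = pooled["maternal_reads"] + pooled["paternal_reads"]
    pooled["total_reads"] = total
    with np.errstate(invalid="ignore"):
        pooled["maternal_fraction"] = np.where(
            total > 0, pooled["maternal_reads"] / total, np.nan
        )
    reference = {"embryo": 0.5, "endosperm": 2.0 / 3.0}
    return (
        pooled[
            ["gene_id", "cross", "stage", "tissue", "total_reads", "maternal_fraction"]
        ],
        {"reference_maternal_fraction": reference},
    )
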