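"""Shared statistical primitives for the imprinting and splicing stages.

The three operations here are deliberately thin wrappers with strict input
validation around scipy/statsmodels routines:

* :func:`chi_square_gof` — one-degree-of-freedom Pearson goodness-of-fit test
  of observed maternal/paternal allele counts against an expected maternal
  fraction (0.5 for embryo, 2/3 for triploid endosperm dosage).
* :func:`bh_adjust` — Benjamini–Hochberg step-up false-discovery-rate
  adjustment.
* :func:`ks_two_sample` — two-sample Kolmogorov–Smirnov test (asymptotic
  p-value), used to compare PSI distributions between sample groups.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["chi_square_gof", "bh_adjust", "ks_two_sample"]


def chi_square_gof(
    maternal_count: int,
    paternal_count: int,
    expected_maternal_fraction: float,
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square goodness-of-fit test for a maternal/paternal count pair.

    Tests the two-cell observed vector ``(maternal, paternal)`` against the
    expected split ``(total * f, total * (1 - f))`` where ``f`` is the
    expected maternal fraction under parental genome dosage. One degree of
    freedom; p-value from the upper tail of chi2(1).

    Parameters
    ----------
    maternal_count, paternal_count
        Non-negative allele-specific read counts; their sum must be >= 1.
    expected_maternal_fraction
        Expected maternal read fraction, strictly inside (0, 1).
    continuity_correction
        Apply the Yates correction (|O - E| reduced by 0.5). Off by default.

    Returns
    -------
    (statistic, p_value)
    """
    if maternal_count < 0 or paternal_count < 0:
        raise ValueError("allele counts must be non-negative")
    total = maternal_count + paternal_count
    if total < 1:
        raise ValueError("total read count must be at least 1")
    f = float(expected_maternal_fraction)
    if not 0.0 < f < 1.0:
        raise ValueError("expected_maternal_fraction must lie strictly in (0, 1)")

    observed = np.array([maternal_count, paternal_count], dtype=float)
    expected = np.array([total * f, total * (1.0 - f)])
    if continuity_correction:
        dev = np.maximum(np.abs(observed - expected) - 0.5, 0.0)
        statistic = float(np.sum(dev**2 / expected))
        p_value = float(stats.chi2.sf(statistic, df=1))
    else:
        statistic, p_value = stats.chisquare(f_obs=observed, f_exp=expected)
        statistic, p_value = float(statistic), float(p_value)
    return statistic, p_value


def bh_adjust(p_values, test_ids=None) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Parameters
    ----------
    p_values
        Sequence of p-values in [0, 1]; must be non-empty.
    test_ids
        Optional identifiers aligned to ``p_values``; must be unique.

    Returns
    -------
    numpy array of q-values aligned to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p-value vector must be one-dimensional and non-empty")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if test_ids is not None:
        ids = list(test_ids)
        if len(ids) != p.size:
            raise ValueError("test_ids must align with p-values")
        if len(set(ids)) != len(ids):
            raise ValueError("test_ids must be unique")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test with asymptotic p-value.

    D = sup |ECDF_a - ECDF_b| over the pooled support. Intended for
    comparing PSI value distributions pooled over many isoforms, where the
    asymptotic p-value is appropriate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
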