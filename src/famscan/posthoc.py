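"""Post-scan statistics: genomic control, LD pruning, concordance tests.

Genomic control estimates the inflation factor lambda as the median of the
association chi-squares divided by the null chi-square(1) median (0.4549);
dividing every chi-square by lambda removes median inflation while
preserving the ranking of SNPs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.45494


def genomic_control_lambda(pvals, method: str = "median") -> float:
    """Inflation factor of a set of association p-values.

    lambda = median(chi2 quantiles of 1 - p) / median(chi2_1); 1 indicates
    no inflation.  ``method="mean"`` uses the mean instead of the median.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("no p-values")
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(pvals, df=1)
    if method == "median":
        return float(np.median(chisq) / _CHI2_1_MEDIAN)
    if method == "mean":
        return float(np.mean(chisq))
    raise ValueError(f"unknown method {method!r}")


def gc_correct(pvals, lam: float) -> np.ndarray:
    """Divide the implied chi-squares by lambda and recompute p-values.

    Lambda below 1 (deflation) applies no correction, with a log note.
    """
    pvals = np.asarray(pvals, dtype=float)
    if lam < 1.0:
        logger.info("lambda = %.4f < 1: no genomic-control correction applied", lam)
        return pvals.copy()
    chisq = stats.chi2.isf(pvals, df=1)
    return stats.chi2.sf(chisq / lam, df=1)


def prune_by_ld(sumstats: pd.DataFrame, ld_r2: np.ndarray, r2_max: float = 0.1) -> pd.DataFrame:
    """Greedy LD pruning of a summary-statistics table.

    Repeatedly keeps the remaining SNP with the smallest p-value and drops
    every SNP whose squared correlation with it exceeds ``r2_max``.
    ``ld_r2`` is the SNP x SNP squared-correlation matrix aligned with the
    table rows.
    """
    ld_r2 = np.asarray(ld_r2, dtype=float)
    m = len(sumstats)
    if ld_r2.shape != (m, m):
        raise ValueError("LD matrix not aligned with summary statistics")
    order = np.argsort(sumstats["p_value"].to_numpy(), kind="stable")
    alive = np.ones(m, dtype=bool)
    kept = []
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive &= ~(ld_r2[i] > r2_max)
        alive[i] = False
    kept = sorted(kept)
    return sumstats.iloc[kept].reset_index(drop=True)


def concordance_test(signs_a, signs_b, method: str = "point-probability"):
    """Exact binomial test of effect-sign concordance between two studies.

    Pairs with a zero effect in either study are excluded (count reported).
    Returns (n_concordant, n_total, two-sided p).  The default two-sided
    p sums outcome probabilities not exceeding that of the observed count;
    ``method="doubled-tail"`` doubles the smaller tail instead.
    """
    a = np.sign(np.asarray(signs_a, dtype=float))
    b = np.sign(np.asarray(signs_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("sign vectors must be aligned")
    valid = (a != 0) & (b != 0)
    n_zero = int((~valid).sum())
    if n_zero:
        logger.info("excluded %d pairs with a zero effect", n_zero)
    a, b = a[valid], b[valid]
    n = len(a)
    if n == 0:
        raise ValueError("no pairs with defined signs")
    k = int((a == b).sum())
    if method == "point-probability":
        p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
    elif method == "doubled-tail":
        lower = stats.binom.cdf(k, n, 0.5)
        upper = stats.binom.sf(k - 1, n, 0.5)
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise ValueError(f"unknown method {method!r}")
    return k, n, float(p)


def bonferroni_threshold(base_alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold base_alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return base_alpha / n_tests
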