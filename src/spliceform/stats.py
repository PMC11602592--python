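"""Shared statistical primitives.

Thin, contract-enforcing wrappers over scipy/statsmodels: count
normalization, Benjamini-Hochberg FDR, the exact/asymptotic rank-sum test,
chi-square independence without continuity correction, Spearman correlation,
and the exact two-sided binomial test used by the enrichment analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    statistic: float
    p_value: float
    q_value: Optional[float] = None
    n: int = 0


def normalize_counts(counts: pd.DataFrame, mode: str, lengths: Optional[pd.Series] = None) -> pd.DataFrame:
    """CPM or TPM normalization of an isoform x sample count matrix.

    TPM divides by isoform length (nt) before scaling each sample to 1e6;
    all-zero samples are returned as zeros with a warning.
    """
    if mode not in ("CPM", "TPM"):
        raise ValidationError(f"unknown normalization mode {mode!r}")
    mat = counts.astype(float)
    if mode == "TPM":
        if lengths is None:
            raise ValidationError("TPM requires isoform lengths")
        lengths = pd.Series(lengths, dtype=float).reindex(mat.index)
        if lengths.isna().any():
            raise ValidationError("lengths missing for some isoforms")
        mat = mat.div(lengths, axis=0)
    totals = mat.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("all-zero sample(s) in %s normalization: %s", mode, list(totals.index[zero]))
        totals = totals.replace(0, np.nan)
    out = mat.div(totals, axis=1) * 1e6
    return out.fillna(0.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1, order-preserving).

    NaN entries are ignored for the family size and propagated as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> StatResult:
    """Wilcoxon (Mann-Whitney) rank-sum test of ``x`` versus ``y``.

    ``alternative="greater"`` tests whether ``x`` tends larger than ``y``.
    Exact enumeration of rank assignments is used when the pooled size is
    <= 12 and there are no ties; otherwise the normal approximation with
    midrank tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("empty sample in rank-sum test")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return StatResult(float(res.statistic), float(res.pvalue), n=int(pooled.size))


def chi_square_independence(table) -> StatResult:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any():
        raise ValidationError("negative cell in contingency table")
    if obs.sum() == 0:
        raise ValidationError("empty contingency table")
    row_zero = np.where(obs.sum(axis=1) == 0)[0]
    col_zero = np.where(obs.sum(axis=0) == 0)[0]
    if row_zero.size or col_zero.size:
        raise ValidationError(
            f"zero margin in contingency table (rows {row_zero.tolist()}, "
            f"columns {col_zero.tolist()})"
        )
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return StatResult(float(stat), float(p), n=int(obs.sum()))


def spearman_correlation(x, y) -> float:
    """Spearman rho (Pearson correlation of midranks); NaN with a warning
    for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman requires two equal-length samples, n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("constant vector in Spearman correlation; returning NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, _ = sps.spearmanr(x, y)
    return float(rho)


def binomial_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial test p-value by tail summation."""
    if n == 0:
        raise ValidationError("binomial test with n = 0")
    return float(sps.binomtest(int(k), int(n), p, alternative="two-sided").pvalue)


def welch_t_test(x, y) -> StatResult:
    """Welch two-sample t-test (two-sided), with a deterministic convention
    for degenerate zero-variance inputs: p = 1 when the group means are
    equal, p = 0 otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("Welch t-test requires >= 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        same = np.isclose(x.mean(), y.mean())
        return StatResult(0.0 if same else np.inf, 1.0 if same else 0.0, n=int(x.size + y.size))
    res = sps.ttest_ind(x, y, equal_var=False)
    return StatResult(float(res.statistic), float(res.pvalue), n=int(x.size + y.size))


def logit(x, eps: float = 0.01) -> np.ndarray:
    """Stabilized logit ``ln((x + eps) / (1 - x + eps))`` for fractions."""
    x = np.asarray(x, dtype=float)
    return np.log((x + eps) / (1.0 - x + eps))
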