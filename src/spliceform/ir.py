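"""Gene-level aggregated intron-retention fractions, differential IR usage,
gene-set contrasts, and splicing-factor anti-correlation.

IR-labeled isoform counts are aggregated per gene and divided by the gene
total, giving a two-feature (IR vs non-IR) usage fraction per sample.  The
differential test is the same logit-Welch stand-in used for isoform
switching, applied to the aggregated fractions, after DRIMSeq-style
expression filters (gene count >= 10 in >= 3 samples; IR proportion > 0.01
in >= 1 sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import ValidationError
from .stats import (
    bh_fdr,
    logit,
    spearman_correlation,
    welch_t_test,
    wilcoxon_rank_sum,
    StatResult,
)

logger = logging.getLogger(__name__)


def aggregate_ir_fraction(
    counts: pd.DataFrame, gene_map: pd.Series, ir_labels: pd.Series
) -> pd.DataFrame:
    """Per (gene, sample) aggregated IR fraction.

    ``ir_labels`` is a boolean Series over all isoforms (from
    ``find_retained_introns``).  Genes with zero total in a sample get NaN;
    genes with no IR isoform get 0.0 wherever the total is positive.
    """
    gene_map = pd.Series(gene_map).reindex(counts.index)
    ir_labels = pd.Series(ir_labels).reindex(counts.index)
    if ir_labels.isna().any():
        missing = list(counts.index[ir_labels.isna()])[:5]
        raise ValidationError(f"isoforms without IR label: {missing} ...")
    totals = counts.groupby(gene_map).sum()
    ir_counts = counts[ir_labels.astype(bool)].groupby(
        gene_map[ir_labels.astype(bool)]
    ).sum().reindex(totals.index).fillna(0.0)
    return ir_counts / totals.where(totals > 0)


@dataclass
class IRFilterParams:
    """DRIMSeq-style inclusion filters translated to the two-feature
    (IR / non-IR) aggregate."""

    min_gene_expr: float = 10.0   # gene count threshold ...
    min_samps_gene_expr: int = 3  # ... required in this many samples
    min_feature_prop: float = 0.01  # IR fraction threshold ...
    min_samps_feature_prop: int = 1  # ... required in this many samples


def test_ir_usage(
    counts: pd.DataFrame,
    gene_map: pd.Series,
    ir_labels: pd.Series,
    design: pd.DataFrame,
    condition_pair: tuple[str, str],
    filters: Optional[IRFilterParams] = None,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Per-gene differential aggregated-IR-usage test between two conditions.

    Returns gene-indexed dIF (condition2 - condition1 mean aggregated IR
    fraction), p and BH q values for genes passing the filters.
    """
    filters = filters or IRFilterParams()
    gene_map = pd.Series(gene_map).reindex(counts.index)
    agg = aggregate_ir_fraction(counts, gene_map, ir_labels)
    totals = counts.groupby(gene_map).sum()
    expr_ok = (totals >= filters.min_gene_expr).sum(axis=1) >= filters.min_samps_gene_expr
    prop_ok = (agg > filters.min_feature_prop).sum(axis=1) >= filters.min_samps_feature_prop
    genes = agg.index[expr_ok & prop_ok]
    if len(genes) == 0:
        logger.warning("IR-usage filters eliminated all genes")
        return pd.DataFrame(columns=["dIF", "statistic", "p_value", "q_value"])
    c1, c2 = condition_pair
    s1 = list(design.loc[design["condition"] == c1, "sample_id"])
    s2 = list(design.loc[design["condition"] == c2, "sample_id"])
    rows = []
    for g in genes:
        f1 = agg.loc[g, s1].dropna().to_numpy(float)
        f2 = agg.loc[g, s2].dropna().to_numpy(float)
        if len(f1) < 2 or len(f2) < 2:
            continue
        res = welch_t_test(logit(f2, eps), logit(f1, eps))
        rows.append(dict(gene_id=g, dIF=float(f2.mean() - f1.mean()),
                         statistic=res.statistic, p_value=res.p_value))
    out = pd.DataFrame(rows).set_index("gene_id")
    out["q_value"] = bh_fdr(out["p_value"])
    return out


def compare_genesets(
    gene_dif: pd.Series, set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[StatResult, pd.DataFrame]:
    """One-sided rank-sum test that set A's aggregated dIFs exceed set B's,
    with a per-set median/IQR summary."""
    a = gene_dif.reindex([g for g in set_a]).dropna()
    b = gene_dif.reindex([g for g in set_b]).dropna()
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("both gene sets need >= 3 genes with defined dIF")
    res = wilcoxon_rank_sum(a.to_numpy(), b.to_numpy(), alternative="greater")
    summary = pd.DataFrame(
        {
            "n": [len(a), len(b)],
            "median": [a.median(), b.median()],
            "q25": [a.quantile(0.25), b.quantile(0.25)],
            "q75": [a.quantile(0.75), b.quantile(0.75)],
        },
        index=["set_a", "set_b"],
    )
    return res, summary


@dataclass(frozen=True)
class CorrelationResult:
    factor_gene: str
    ir_isoform: str
    rho: float
    flagged: bool


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) normalization used in place of a variance-stabilizing
    transform for correlation analysis."""
    from .stats import normalize_counts

    return np.log2(normalize_counts(counts, "CPM") + 1.0)


def correlate_factors(
    factor_expr: pd.DataFrame,
    ir_expr: pd.DataFrame,
    factors_with_own_ir: Iterable[str] = (),
    rho_threshold: float = 0.9,
) -> list[CorrelationResult]:
    """Spearman correlation of every (splicing factor, IR isoform) pair
    across samples; pairs with rho <= -rho_threshold are flagged.

    Factor genes that themselves carry IR-labeled isoforms are excluded.
    Both matrices are (rows x samples) on matching sample columns of
    normalized expression (e.g. log2(CPM+1)); constant rows are skipped
    with a warning.
    """
    if factor_expr.shape[1] < 4:
        raise ValidationError("correlation requires >= 4 samples")
    excluded = set(factors_with_own_ir)
    samples = [s for s in factor_expr.columns if s in ir_expr.columns]
    results = []
    for factor in factor_expr.index:
        if factor in excluded:
            continue
        fv = factor_expr.loc[factor, samples].to_numpy(float)
        for iso in ir_expr.index:
            iv = ir_expr.loc[iso, samples].to_numpy(float)
            rho = spearman_correlation(fv, iv)
            if np.isnan(rho):
                logger.warning("constant expression for pair (%s, %s); skipped", factor, iso)
                continue
            results.append(
                CorrelationResult(factor, iso, rho, rho <= -rho_threshold)
            )
    return results
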