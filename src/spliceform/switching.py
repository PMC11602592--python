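"""Isoform fractions, dIF, the switch test, and functional-consequence calls.

The isoform fraction (IF) of an isoform in a sample is its count divided by
its gene's total count; dIF is the difference of condition-mean IFs.  The
switch test is a deliberately simple, deterministic stand-in for
DEXSeq-style differential usage machinery: a Welch two-sample t-test on
logit-transformed per-replicate IFs (logit(x) = ln((x+eps)/(1-x+eps)),
eps = 0.01), BH-corrected across all tested isoforms.  An isoform switches
significantly when |dIF| > 0.05 and q < 0.05 (defaults).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .events import detect_events, DEFAULT_MIN_END_DIST
from .model import CountMatrix, TranscriptModel, ValidationError, transcript_sequence
from .stats import bh_fdr, binomial_two_sided, logit, normalize_counts, welch_t_test

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# isoform fractions
# ---------------------------------------------------------------------------

def isoform_fractions(counts: pd.DataFrame, gene_map: pd.Series) -> pd.DataFrame:
    """Per-sample isoform fractions within genes.

    ``gene_map`` maps isoform_id -> gene_id and must cover every isoform.
    Samples where a gene's total count is 0 get NaN fractions for that
    gene's isoforms (zero totals are meaningfully missing, not zero).
    """
    gene_map = pd.Series(gene_map).reindex(counts.index)
    if gene_map.isna().any():
        missing = list(counts.index[gene_map.isna()])[:5]
        raise ValidationError(f"isoforms without gene assignment: {missing} ...")
    totals = counts.groupby(gene_map).transform("sum")
    frac = counts / totals.where(totals > 0)
    return frac


def condition_mean_if(
    fractions: pd.DataFrame, design: pd.DataFrame, condition_col: str = "condition"
) -> pd.DataFrame:
    """Mean IF per condition (NaN-aware)."""
    groups = design.groupby(condition_col)["sample_id"]
    return pd.DataFrame(
        {cond: fractions[list(samples)].mean(axis=1) for cond, samples in groups}
    )


def delta_if(
    fractions: pd.DataFrame,
    design: pd.DataFrame,
    condition_pair: tuple[str, str],
    condition_col: str = "condition",
) -> pd.Series:
    """dIF = mean IF(condition2) - mean IF(condition1)."""
    means = condition_mean_if(fractions, design, condition_col)
    c1, c2 = condition_pair
    return means[c2] - means[c1]


# ---------------------------------------------------------------------------
# expression filters and the switch test
# ---------------------------------------------------------------------------

@dataclass
class SwitchParams:
    min_dif: float = 0.05
    alpha: float = 0.05
    eps: float = 0.01
    min_gene_tpm: float = 0.1
    isoform_tpm: float = 0.1           # isoform prefilter: TPM > 0.1 ...
    isoform_tpm_sample_frac: float = 0.1  # ... in at least this fraction of samples


def expression_filters(cm: CountMatrix, gene_map: pd.Series, params: SwitchParams):
    """Gene- and isoform-level expression inclusion.

    Genes pass when their summed TPM exceeds ``min_gene_tpm`` in at least
    one sample; isoforms additionally need TPM > ``isoform_tpm`` in at
    least ``isoform_tpm_sample_frac`` of samples.
    """
    tpm = normalize_counts(cm.counts, "TPM", cm.lengths)
    gene_map = pd.Series(gene_map).reindex(cm.counts.index)
    gene_tpm = tpm.groupby(gene_map).sum()
    genes_ok = gene_tpm.max(axis=1) > params.min_gene_tpm
    min_samples = max(1, int(np.ceil(params.isoform_tpm_sample_frac * tpm.shape[1])))
    iso_ok = (tpm > params.isoform_tpm).sum(axis=1) >= min_samples
    iso_ok &= gene_map.map(genes_ok).fillna(False)
    return genes_ok, iso_ok


def test_switch(
    cm: CountMatrix,
    design: pd.DataFrame,
    gene_map: pd.Series,
    condition_pair: tuple[str, str],
    params: Optional[SwitchParams] = None,
) -> pd.DataFrame:
    """Per-isoform switch test between two conditions.

    Returns a DataFrame indexed by isoform_id with gene_id, dIF, p_value,
    q_value and the significance flag (|dIF| > min_dif and q < alpha).
    Requires >= 2 replicates per condition.
    """
    params = params or SwitchParams()
    c1, c2 = condition_pair
    gene_map = pd.Series(gene_map).reindex(cm.counts.index)
    s1 = list(design.loc[design["condition"] == c1, "sample_id"])
    s2 = list(design.loc[design["condition"] == c2, "sample_id"])
    if len(s1) < 2 or len(s2) < 2:
        raise ValidationError(
            f"need >= 2 replicates per condition for the switch test "
            f"({c1}: {len(s1)}, {c2}: {len(s2)}); use descriptive dIF only"
        )
    _, iso_ok = expression_filters(cm, gene_map, params)
    frac = isoform_fractions(cm.counts, gene_map)
    rows = []
    for iso in cm.counts.index[iso_ok]:
        f1 = frac.loc[iso, s1].dropna().to_numpy(float)
        f2 = frac.loc[iso, s2].dropna().to_numpy(float)
        if len(f1) < 2 or len(f2) < 2:
            continue
        res = welch_t_test(logit(f2, params.eps), logit(f1, params.eps))
        rows.append(
            dict(isoform_id=iso, gene_id=gene_map[iso],
                 dIF=float(f2.mean() - f1.mean()),
                 statistic=res.statistic, p_value=res.p_value)
        )
    out = pd.DataFrame(rows).set_index("isoform_id") if rows else pd.DataFrame(
        columns=["gene_id", "dIF", "statistic", "p_value"]
    )
    if not out.empty:
        out["q_value"] = bh_fdr(out["p_value"])
        out["significant"] = (out["dIF"].abs() > params.min_dif) & (out["q_value"] < params.alpha)
    return out


def top_switch_pair(gene_id: str, switch_results: pd.DataFrame) -> Optional[tuple[str, str]]:
    """(most increased, most decreased) isoform of a gene, or None when the
    gene has no isoform moving in each direction.  Ties break by smaller
    q-value, then lexicographic id."""
    sub = switch_results[switch_results["gene_id"] == gene_id]
    if len(sub) < 2:
        return None
    q = sub["q_value"] if "q_value" in sub else pd.Series(1.0, index=sub.index)
    order_up = sorted(sub.index, key=lambda i: (-sub.at[i, "dIF"], q[i], i))
    order_dn = sorted(sub.index, key=lambda i: (sub.at[i, "dIF"], q[i], i))
    up, down = order_up[0], order_dn[0]
    if sub.at[up, "dIF"] <= 0 or sub.at[down, "dIF"] >= 0:
        return None
    ties = (sub["dIF"] == sub.at[up, "dIF"]).sum() > 1 or (sub["dIF"] == sub.at[down, "dIF"]).sum() > 1
    if ties:
        logger.info("top_switch_pair tie in gene %s resolved by q then id", gene_id)
    return (up, down)


# ---------------------------------------------------------------------------
# ORF, NMD, and switch consequences
# ---------------------------------------------------------------------------

@dataclass
class ORF:
    start: int      # transcript coordinate of the A of ATG
    end: int        # exclusive end (past the stop codon when complete)
    protein: str
    complete: bool  # ends at an in-frame stop within the transcript


STOPS = {"TAA", "TAG", "TGA"}


def predict_orf(seq: str, min_len: int = 30) -> Optional[ORF]:
    """Longest ATG-initiated open reading frame.

    Ties go to the most 5' start; ORFs running off the transcript end
    without a stop are returned flagged incomplete.  Returns None when the
    longest ORF is shorter than ``min_len`` nt (stop included).
    """
    seq = seq.upper()
    best: Optional[tuple[int, int, bool]] = None  # (length, -start) ordering
    i = seq.find("ATG")
    while i != -1:
        j = i
        complete = False
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if codon in STOPS:
                complete = True
                j += 3
                break
            j += 3
        length = j - i
        if best is None or length > best[1] - best[0]:
            best = (i, j, complete)
        i = seq.find("ATG", i + 1)
    if best is None:
        return None
    start, end, complete = best
    if end - start < min_len:
        return None
    coding = seq[start : end - 3] if complete else seq[start : start + (end - start) // 3 * 3]
    protein = str(Seq(coding).translate())
    return ORF(start, end, protein, complete)


def nmd_status(tx: TranscriptModel, orf_end_tx_coord: int) -> bool:
    """50-nt rule for nonsense-mediated decay sensitivity: True iff the stop
    codon lies more than 50 nt (transcript coordinates) upstream of the last
    exon-exon junction.  Mono-exonic transcripts are never NMD-sensitive."""
    junctions = tx.junction_tx_positions()
    if not junctions:
        return False
    return junctions[-1] - orf_end_tx_coord > 50


@dataclass(frozen=True)
class Consequence:
    gene_id: str
    up_isoform: str
    down_isoform: str
    consequence_type: str
    magnitude: float


@dataclass
class ConsequenceParams:
    utr_min_diff: int = 50
    orf_min_len: int = 30
    min_end_dist: int = DEFAULT_MIN_END_DIST


def switch_consequences(
    up: TranscriptModel,
    down: TranscriptModel,
    genome,
    domains: Optional[pd.DataFrame] = None,
    params: Optional[ConsequenceParams] = None,
) -> list[Consequence]:
    """Functional consequences of a switch pair: 3' UTR length change, NMD
    gain/loss, domain gain/loss (by name), and AS-event gains/losses.

    ``domains`` is the per-isoform domain table (isoform_id, domain_name,
    tx_start, tx_end).  When an ORF cannot be called on either isoform the
    ORF-dependent consequences are skipped (logged) and only AS events and
    domains are reported.
    """
    params = params or ConsequenceParams()
    out: list[Consequence] = []
    gene = up.gene_id

    orf_up = predict_orf(transcript_sequence(up, genome), params.orf_min_len)
    orf_dn = predict_orf(transcript_sequence(down, genome), params.orf_min_len)
    if orf_up is not None and orf_dn is not None:
        utr_up = up.length - orf_up.end
        utr_dn = down.length - orf_dn.end
        if abs(utr_up - utr_dn) >= params.utr_min_diff:
            ctype = "utr3_shorter" if utr_up < utr_dn else "utr3_longer"
            out.append(Consequence(gene, up.transcript_id, down.transcript_id,
                                   ctype, abs(utr_up - utr_dn)))
        nmd_up = nmd_status(up, orf_up.end)
        nmd_dn = nmd_status(down, orf_dn.end)
        if nmd_up and not nmd_dn:
            out.append(Consequence(gene, up.transcript_id, down.transcript_id, "nmd_gain", 1))
        elif nmd_dn and not nmd_up:
            out.append(Consequence(gene, up.transcript_id, down.transcript_id, "nmd_loss", 1))
    else:
        logger.info(
            "ORF missing for %s/%s: restricting consequences to AS events and domains",
            up.transcript_id, down.transcript_id,
        )

    if domains is not None and not domains.empty:
        def counts_for(tid):
            sub = domains[domains["isoform_id"] == tid]
            return sub["domain_name"].value_counts()
        c_up, c_dn = counts_for(up.transcript_id), counts_for(down.transcript_id)
        names = set(c_up.index) | set(c_dn.index)
        gained = sum(max(0, c_up.get(n, 0) - c_dn.get(n, 0)) for n in names)
        lost = sum(max(0, c_dn.get(n, 0) - c_up.get(n, 0)) for n in names)
        if gained:
            out.append(Consequence(gene, up.transcript_id, down.transcript_id, "domain_gain", gained))
        if lost:
            out.append(Consequence(gene, up.transcript_id, down.transcript_id, "domain_loss", lost))

    for ev in detect_events(up, down, min_end_dist=params.min_end_dist):
        direction = "as_gain" if ev.isoform_in == up.transcript_id else "as_loss"
        out.append(Consequence(gene, up.transcript_id, down.transcript_id,
                               f"{direction}:{ev.event_type}", len(ev.span)))
    return out


OPPOSING = [
    ("utr3_shorter", "utr3_longer"),
    ("nmd_gain", "nmd_loss"),
    ("domain_gain", "domain_loss"),
] + [(f"as_gain:{t}", f"as_loss:{t}") for t in ("ES", "A5", "A3", "IR", "aTSS", "aTTS")]


def consequence_enrichment(consequences: Iterable[Consequence]) -> pd.DataFrame:
    """Gene-level enrichment of each opposing consequence pair.

    Counts genes contributing each side, tests the proportion against 0.5
    with the exact two-sided binomial, BH across the tested pairs.
    """
    per_type_genes: dict[str, set] = {}
    for c in consequences:
        per_type_genes.setdefault(c.consequence_type, set()).add(c.gene_id)
    rows = []
    for a, b in OPPOSING:
        na, nb = len(per_type_genes.get(a, ())), len(per_type_genes.get(b, ()))
        n = na + nb
        if n == 0:
            continue
        rows.append(dict(type_a=a, type_b=b, n_a=na, n_b=nb,
                         proportion_a=na / n, p_value=binomial_two_sided(na, n)))
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_value"] = bh_fdr(df["p_value"])
    return df
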