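"""Within-gene protein-domain presence/absence, attribution of losses to
alternative-splicing events by genomic overlap, and the chi-square contrast
of IR- versus non-IR-attributed losses across dIF strata.

A domain "loss" is pairwise: for an ordered (bearer, loser) isoform pair and
a domain name, every bearer copy that cannot be matched to a loser copy
(greedy matching by genomic overlap, ties to the leftmost copy) is one loss
event carrying the bearer copy's genomic intervals.  Attribution overlaps
the AS-event span with the *hull* of those intervals (min start to max end):
a domain encoded across a splice junction abuts the intron on both sides in
split coordinates, so only its hull can overlap an IR event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .events import ASEvent, detect_events, DEFAULT_MIN_END_DIST
from .model import GenomicInterval, TranscriptModel, ValidationError, map_tx_to_genome
from .stats import StatResult, chi_square_independence

IR_TYPE = "IR"


@dataclass
class DomainAnnotation:
    isoform_id: str
    domain_name: str
    tx_start: int
    tx_end: int
    genomic_intervals: list[GenomicInterval]

    @property
    def hull(self) -> GenomicInterval:
        iv0 = self.genomic_intervals[0]
        return GenomicInterval(
            iv0.chrom,
            min(iv.start for iv in self.genomic_intervals),
            max(iv.end for iv in self.genomic_intervals),
            iv0.strand,
        )


@dataclass
class DomainLossEvent:
    gene_id: str
    bearer_isoform: str
    loser_isoform: str
    domain_name: str
    lost_genomic_intervals: list[GenomicInterval]
    attributed_event_types: frozenset = frozenset()
    loser_dIF: Optional[float] = None

    @property
    def lost_hull(self) -> GenomicInterval:
        iv0 = self.lost_genomic_intervals[0]
        return GenomicInterval(
            iv0.chrom,
            min(iv.start for iv in self.lost_genomic_intervals),
            max(iv.end for iv in self.lost_genomic_intervals),
            iv0.strand,
        )


def annotate_domains(
    domains: pd.DataFrame, transcripts: dict[str, TranscriptModel]
) -> list[DomainAnnotation]:
    """Lift transcript-coordinate domain rows to genomic intervals."""
    out = []
    for row in domains.itertuples(index=False):
        tx = transcripts.get(row.isoform_id)
        if tx is None:
            raise ValidationError(f"domain on unknown isoform {row.isoform_id!r}")
        ivs = map_tx_to_genome(tx, int(row.tx_start), int(row.tx_end))
        out.append(DomainAnnotation(row.isoform_id, row.domain_name,
                                    int(row.tx_start), int(row.tx_end), ivs))
    return out


def domain_presence(
    gene_id: str,
    isoforms: Iterable[TranscriptModel],
    domains: Iterable[DomainAnnotation],
) -> pd.DataFrame:
    """Copy-count matrix (isoform x domain_name) for one gene."""
    iso_ids = [tx.transcript_id for tx in isoforms]
    if not iso_ids:
        raise ValidationError(f"no isoforms for gene {gene_id}")
    names = sorted({d.domain_name for d in domains})
    mat = pd.DataFrame(0, index=iso_ids, columns=names, dtype=int)
    for d in domains:
        if d.isoform_id not in mat.index:
            raise ValidationError(
                f"domain {d.domain_name} on isoform {d.isoform_id} not in gene {gene_id}"
            )
        mat.at[d.isoform_id, d.domain_name] += 1
    return mat


def _greedy_match(bearer_copies: list[DomainAnnotation], loser_copies: list[DomainAnnotation]):
    """Match copies by maximal genomic overlap (of hulls), ties to the
    leftmost bearer copy; returns the unmatched bearer copies (= lost)."""
    bearer_left = sorted(bearer_copies, key=lambda d: d.hull.start)
    unmatched_losers = list(loser_copies)
    lost = []
    for b in bearer_left:
        best_i, best_ov = None, 0
        for i, l in enumerate(unmatched_losers):
            ov = b.hull.overlap(l.hull)
            if ov > best_ov:
                best_i, best_ov = i, ov
        if best_i is not None:
            unmatched_losers.pop(best_i)
        else:
            lost.append(b)
    # when zero-overlap bearers coexist with unmatched losers, only the copy
    # count difference is reported as lost (leftmost copies first)
    n_lost_expected = max(0, len(bearer_copies) - len(loser_copies))
    if len(lost) > n_lost_expected:
        lost = lost[:n_lost_expected]
    return lost


def detect_domain_loss(
    gene_id: str,
    isoforms: list[TranscriptModel],
    domains: list[DomainAnnotation],
) -> list[DomainLossEvent]:
    """Unattributed loss events over every ordered isoform pair of a gene."""
    if len(isoforms) < 2:
        return []
    by_iso: dict[str, dict[str, list[DomainAnnotation]]] = {
        tx.transcript_id: {} for tx in isoforms
    }
    for d in domains:
        by_iso.setdefault(d.isoform_id, {}).setdefault(d.domain_name, []).append(d)
    losses = []
    ids = sorted(by_iso)
    for bearer in ids:
        for loser in ids:
            if bearer == loser:
                continue
            for name, copies in by_iso[bearer].items():
                loser_copies = by_iso[loser].get(name, [])
                if len(copies) <= len(loser_copies):
                    continue
                for lost_copy in _greedy_match(copies, loser_copies):
                    losses.append(
                        DomainLossEvent(gene_id, bearer, loser, name,
                                        lost_copy.genomic_intervals)
                    )
    return losses


def attribute_loss_to_as(loss: DomainLossEvent, events: list[ASEvent]) -> DomainLossEvent:
    """Attach the AS event types whose span overlaps the lost domain's
    genomic hull by >= 1 bp; events must come from the (loser, bearer) pair."""
    pair = {loss.bearer_isoform, loss.loser_isoform}
    for ev in events:
        if {ev.isoform_in, ev.isoform_out} != pair:
            raise ValidationError(
                f"event {ev.event_type} from pair ({ev.isoform_in}, {ev.isoform_out}) "
                f"does not match loss pair {sorted(pair)}"
            )
    hull = loss.lost_hull
    types = frozenset(ev.event_type for ev in events if ev.span.overlap(hull) >= 1)
    return DomainLossEvent(
        loss.gene_id, loss.bearer_isoform, loss.loser_isoform, loss.domain_name,
        loss.lost_genomic_intervals, types, loss.loser_dIF,
    )


def attribute_gene_losses(
    losses: list[DomainLossEvent],
    transcripts: dict[str, TranscriptModel],
    min_end_dist: int = DEFAULT_MIN_END_DIST,
) -> list[DomainLossEvent]:
    """Attribute every loss using events detected on its own isoform pair."""
    out = []
    for loss in losses:
        evs = detect_events(
            transcripts[loss.loser_isoform], transcripts[loss.bearer_isoform],
            min_end_dist=min_end_dist,
        )
        out.append(attribute_loss_to_as(loss, evs))
    return out


def domain_loss_by_as_test(
    losses: list[DomainLossEvent],
    dif_threshold: float = 0.05,
) -> tuple[StatResult, pd.DataFrame]:
    """Chi-square of {IR-attributed, non-IR-attributed} x {loser dIF
    increased, decreased}.

    Losses attributed to both IR and a non-IR type count once in the IR
    row; unattributed losses and losers with |dIF| <= threshold are
    excluded.  Raises (with the table in the message) on a zero margin.
    """
    table = pd.DataFrame(
        0, index=["IR", "non-IR"], columns=["increased", "decreased"], dtype=int
    )
    for loss in losses:
        if not loss.attributed_event_types or loss.loser_dIF is None:
            continue
        row = "IR" if IR_TYPE in loss.attributed_event_types else "non-IR"
        if loss.loser_dIF > dif_threshold:
            col = "increased"
        elif loss.loser_dIF < -dif_threshold:
            col = "decreased"
        else:
            continue
        table.at[row, col] += 1
    try:
        res = chi_square_independence(table.values)
    except ValidationError as exc:
        raise ValidationError(f"{exc}\n{table}") from exc
    return res, table


def loss_type_counts(losses: list[DomainLossEvent]) -> pd.Series:
    """Per-type attributed loss counts with the IR-priority rule, plus an
    'unattributed' bucket; sums to the total number of losses."""
    counts: dict[str, int] = {}
    for loss in losses:
        if not loss.attributed_event_types:
            key = "unattributed"
        elif IR_TYPE in loss.attributed_event_types:
            key = IR_TYPE
        else:
            key = sorted(loss.attributed_event_types)[0]
        counts[key] = counts.get(key, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
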