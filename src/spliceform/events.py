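"""Pairwise typing of alternative-splicing differences between isoforms.

Event types between two isoforms of one gene:

* **IR** — one isoform's exon fully contains an intron of the other with at
  least 1 exonic bp on both sides; the span is the intron and ``isoform_in``
  the retainer.
* **ES** — one isoform's intron fully contains an internal exon of the
  other; one event per skipped exon; span is the exon, ``isoform_in`` the
  includer.
* **A5 / A3** — two junctions share the strand-resolved acceptor (A5) or
  donor (A3) but differ at the other site; the span is the interval between
  the differing coordinates and ``isoform_in`` the isoform with the longer
  exon (shorter intron).
* **aTSS / aTTS** — transcript 5'/3' ends differing by at least
  ``min_end_dist``; ``isoform_in`` extends further out.

Precedence: junctions consumed by IR or ES are not re-reported as A5/A3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .model import GenomicInterval, TranscriptModel, ValidationError
from .stats import bh_fdr, binomial_two_sided

EVENT_TYPES = ("ES", "A5", "A3", "IR", "aTSS", "aTTS")

DEFAULT_MIN_END_DIST = 50


@dataclass(frozen=True)
class ASEvent:
    event_type: str
    chrom: str
    start: int
    end: int
    strand: str
    isoform_in: str
    isoform_out: str

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def swapped(self) -> "ASEvent":
        return ASEvent(
            self.event_type, self.chrom, self.start, self.end, self.strand,
            self.isoform_out, self.isoform_in,
        )


def detect_events(
    isoA: TranscriptModel,
    isoB: TranscriptModel,
    min_end_dist: int = DEFAULT_MIN_END_DIST,
) -> list[ASEvent]:
    """Deterministic list of AS differences between two isoforms of one gene."""
    if (isoA.gene_id, isoA.chrom, isoA.strand) != (isoB.gene_id, isoB.chrom, isoB.strand):
        raise ValidationError(
            f"{isoA.transcript_id} vs {isoB.transcript_id}: different gene/chrom/strand"
        )
    chrom, strand = isoA.chrom, isoA.strand
    events: list[ASEvent] = []
    consumed = {isoA.transcript_id: set(), isoB.transcript_id: set()}

    pairs = [(isoA, isoB), (isoB, isoA)]

    # IR: exon of `holder` strictly contains intron of `other`
    for holder, other in pairs:
        for es, ee in holder.exons:
            for j in other.junctions():
                if es < j.donor_end and j.acceptor_start < ee:
                    events.append(
                        ASEvent("IR", chrom, j.donor_end, j.acceptor_start, strand,
                                holder.transcript_id, other.transcript_id)
                    )
                    consumed[other.transcript_id].add(j.coords())

    # ES: intron of `skipper` contains internal exon of `includer`
    for skipper, includer in pairs:
        internal = includer.exons[1:-1]
        jlist = includer.junctions()
        for j in skipper.junctions():
            for k, (es, ee) in enumerate(internal, start=1):
                if j.donor_end <= es and ee <= j.acceptor_start:
                    events.append(
                        ASEvent("ES", chrom, es, ee, strand,
                                includer.transcript_id, skipper.transcript_id)
                    )
                    consumed[skipper.transcript_id].add(j.coords())
                    # includer junctions flanking the skipped exon
                    consumed[includer.transcript_id].add(jlist[k - 1].coords())
                    consumed[includer.transcript_id].add(jlist[k].coords())

    # A5/A3 on junction pairs sharing exactly one boundary
    shared = {j.coords() for j in isoA.junctions()} & {j.coords() for j in isoB.junctions()}
    seen = set()
    for jA in isoA.junctions():
        if jA.coords() in consumed[isoA.transcript_id] or jA.coords() in shared:
            continue
        for jB in isoB.junctions():
            if jB.coords() in consumed[isoB.transcript_id] or jB.coords() in shared:
                continue
            if jA.donor_end != jB.donor_end and jA.acceptor_start == jB.acceptor_start:
                side = "left"
                lo, hi = sorted((jA.donor_end, jB.donor_end))
                inner = isoA if jA.donor_end > jB.donor_end else isoB
            elif jA.donor_end == jB.donor_end and jA.acceptor_start != jB.acceptor_start:
                side = "right"
                lo, hi = sorted((jA.acceptor_start, jB.acceptor_start))
                inner = isoA if jA.acceptor_start < jB.acceptor_start else isoB
            else:
                continue
            # genomic-left difference is the donor side on +, acceptor on -
            if side == "left":
                etype = "A5" if strand == "+" else "A3"
            else:
                etype = "A3" if strand == "+" else "A5"
            outer = isoB if inner is isoA else isoA
            key = (etype, lo, hi, inner.transcript_id)
            if key not in seen:
                seen.add(key)
                events.append(
                    ASEvent(etype, chrom, lo, hi, strand,
                            inner.transcript_id, outer.transcript_id)
                )

    # alternative ends
    for side in ("left", "right"):
        a = isoA.start if side == "left" else isoA.end
        b = isoB.start if side == "left" else isoB.end
        if abs(a - b) >= min_end_dist:
            lo, hi = sorted((a, b))
            if side == "left":
                etype = "aTSS" if strand == "+" else "aTTS"
                extender = isoA if a < b else isoB
            else:
                etype = "aTTS" if strand == "+" else "aTSS"
                extender = isoA if a > b else isoB
            other = isoB if extender is isoA else isoA
            events.append(
                ASEvent(etype, chrom, lo, hi, strand,
                        extender.transcript_id, other.transcript_id)
            )

    events.sort(key=lambda e: (e.start, e.end, e.event_type, e.isoform_in))
    return events


def find_retained_introns(
    iso: TranscriptModel, companions: Iterable[TranscriptModel],
    min_end_dist: int = DEFAULT_MIN_END_DIST,
) -> list[GenomicInterval]:
    """Deduplicated IR spans where ``iso`` is the retainer against any
    same-gene companion.  An isoform is "IR-labeled" iff this is non-empty."""
    spans = set()
    for comp in companions:
        if comp.transcript_id == iso.transcript_id:
            continue
        for ev in detect_events(iso, comp, min_end_dist=min_end_dist):
            if ev.event_type == "IR" and ev.isoform_in == iso.transcript_id:
                spans.add((ev.start, ev.end))
    return [GenomicInterval(iso.chrom, s, e, iso.strand) for s, e in sorted(spans)]


def splicing_gain_loss_enrichment(
    switch_pairs: list[tuple[TranscriptModel, TranscriptModel]],
    min_end_dist: int = DEFAULT_MIN_END_DIST,
) -> pd.DataFrame:
    """Gain/loss counts of AS event types across switching pairs.

    Each pair is (up isoform, down isoform) of one gene; an event is a gain
    when the up isoform possesses the feature, a loss when the down isoform
    does.  Per event type an exact two-sided binomial test of the gain
    proportion against 0.5, BH-corrected across event types.
    """
    if not switch_pairs:
        raise ValidationError("no switch pairs supplied")
    gains: dict[str, int] = {t: 0 for t in EVENT_TYPES}
    losses: dict[str, int] = {t: 0 for t in EVENT_TYPES}
    for up, down in switch_pairs:
        for ev in detect_events(up, down, min_end_dist=min_end_dist):
            if ev.isoform_in == up.transcript_id:
                gains[ev.event_type] += 1
            else:
                losses[ev.event_type] += 1
    rows = []
    for t in EVENT_TYPES:
        n = gains[t] + losses[t]
        if n == 0:
            continue
        rows.append(
            dict(event_type=t, gains=gains[t], losses=losses[t],
                 proportion_gain=gains[t] / n,
                 p_value=binomial_two_sided(gains[t], n))
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_value"] = bh_fdr(df["p_value"])
    return df
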