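"""Core domain types and coordinate arithmetic.

Conventions used throughout the package:

* All internal coordinates are 0-based, half-open ``[start, end)`` on the
  genomic (+) axis; the external GTF convention (1-based, closed) is converted
  at the I/O boundary.
* Strand is stored genomically; 5'/3' semantics (donor vs acceptor, TSS vs
  TTS) are resolved by accessors, never by re-ordering stored intervals.
* Transcript coordinates count along the mature mRNA 5'->3', i.e. they run
  against the genomic axis on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

VALID_STRANDS = ("+", "-")

#: Structural categories of a query isoform relative to a reference
#: annotation: full splice match, incomplete (consecutive sub-chain) splice
#: match, novel in catalog (known sites, new chain), novel not in catalog
#: (at least one unknown splice site).
CATEGORIES = ("FSM", "ISM", "NIC", "NNC", "other", "unclassified")


class SpliceformError(Exception):
    """Base class for validation and parse errors raised by this package."""


class ValidationError(SpliceformError):
    pass


class BoundsError(SpliceformError):
    pass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with another interval (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An intron: ``donor_end`` is where the intron begins on the genomic
    axis (= end of the upstream exon), ``acceptor_start`` where it ends
    (exclusive, = start of the downstream exon).  On the minus strand the
    biological donor (5' splice site) lies at ``acceptor_start``; use
    :meth:`donor_site` / :meth:`acceptor_site` for strand-resolved roles.
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValidationError(
                f"junction donor_end {self.donor_end} >= acceptor_start "
                f"{self.acceptor_start}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def intron(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.donor_end, self.acceptor_start, self.strand)

    def donor_site(self) -> int:
        """Genomic coordinate of the 5' (donor) splice site."""
        return self.donor_end if self.strand == "+" else self.acceptor_start

    def acceptor_site(self) -> int:
        """Genomic coordinate of the 3' (acceptor) splice site."""
        return self.acceptor_start if self.strand == "+" else self.donor_end

    def coords(self) -> tuple[int, int]:
        return (self.donor_end, self.acceptor_start)


@dataclass
class TranscriptModel:
    """An exon chain on one chromosome/strand with a gene assignment.

    ``exons`` are stored in genomic order (ascending start), regardless of
    strand; consecutive exons must be separated by at least 1 bp of intron.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    category: str = "unclassified"
    matched_reference_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValidationError(f"{self.transcript_id}: bad exon [{s}, {e})")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping or abutting exons at {s}"
                )
            prev_end = e
        if self.category not in CATEGORIES:
            raise ValidationError(f"{self.transcript_id}: bad category {self.category!r}")

    # -- basic geometry ----------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(self.chrom, s, e, self.strand) for s, e in self.exons]

    def junctions(self) -> list[SpliceJunction]:
        """Introns in genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append(SpliceJunction(self.chrom, e1, s2, self.strand))
        return out

    def junction_chain(self) -> tuple[tuple[int, int], ...]:
        """The junction chain as genomic ``(donor_end, acceptor_start)``
        pairs in genomic order — the identity used for structural
        classification."""
        return tuple(j.coords() for j in self.junctions())

    def introns(self) -> list[GenomicInterval]:
        return [j.intron for j in self.junctions()]

    # -- strand-resolved accessors ----------------------------------------

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start (5' end)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Genomic coordinate of the transcription termination (3' end)."""
        return self.end if self.strand == "+" else self.start

    def exons_5to3(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def junction_tx_positions(self) -> list[int]:
        """Transcript coordinates (5'->3') of the exon-exon junctions."""
        pos, out = 0, []
        for s, e in self.exons_5to3()[:-1]:
            pos += e - s
            out.append(pos)
        return out


def transcript_sequence(tx: TranscriptModel, genome) -> str:
    """Spliced transcript sequence, 5'->3'.

    ``genome`` is any mapping from chromosome name to a sliceable sequence
    (a :class:`pyfaidx.Fasta` opened with ``as_raw=True``, or a plain dict of
    strings).
    """
    try:
        contig = genome[tx.chrom]
    except KeyError as exc:
        raise SpliceformError(f"chromosome {tx.chrom!r} not in genome") from exc
    if tx.end > len(contig):
        raise BoundsError(
            f"{tx.transcript_id}: exon end {tx.end} beyond contig length {len(contig)}"
        )
    seq = "".join(str(contig[s:e]) for s, e in tx.exons).upper()
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def map_tx_to_genome(tx: TranscriptModel, tx_start: int, tx_end: int) -> list[GenomicInterval]:
    """Lift a transcript-coordinate span ``[tx_start, tx_end)`` to genomic
    intervals.  The result partitions the span: intervals are in genomic
    order, never cross introns, and their lengths sum to ``tx_end - tx_start``.
    """
    if not (0 <= tx_start < tx_end <= tx.length):
        raise BoundsError(
            f"{tx.transcript_id}: tx span [{tx_start}, {tx_end}) outside [0, {tx.length})"
        )
    pieces: list[GenomicInterval] = []
    offset = 0  # transcript coordinate at the 5' edge of the current exon
    for s, e in tx.exons_5to3():
        elen = e - s
        lo = max(tx_start, offset)
        hi = min(tx_end, offset + elen)
        if lo < hi:
            if tx.strand == "+":
                g_lo, g_hi = s + (lo - offset), s + (hi - offset)
            else:
                g_lo, g_hi = e - (hi - offset), e - (lo - offset)
            pieces.append(GenomicInterval(tx.chrom, g_lo, g_hi, tx.strand))
        offset += elen
    pieces.sort(key=lambda iv: iv.start)
    return pieces


def map_genome_to_tx(tx: TranscriptModel, g_start: int, g_end: int) -> tuple[int, int]:
    """Transcript coordinates of a genomic span fully contained in exons.

    Inverse of :func:`map_tx_to_genome` for spans that do not cross introns
    of ``tx``; raises if any base falls in an intron or outside the model.
    """
    if g_start >= g_end:
        raise BoundsError("empty genomic span")
    offset = 0
    hits = []
    for s, e in tx.exons_5to3():
        lo, hi = max(g_start, s), min(g_end, e)
        if lo < hi:
            if tx.strand == "+":
                hits.append((offset + (lo - s), offset + (hi - s)))
            else:
                hits.append((offset + (e - hi), offset + (e - lo)))
        offset += e - s
    if sum(b - a for a, b in hits) != g_end - g_start:
        raise BoundsError(
            f"genomic span [{g_start}, {g_end}) not fully exonic in {tx.transcript_id}"
        )
    return (min(a for a, _ in hits), max(b for _, b in hits))


@dataclass
class CountMatrix:
    """Isoform-level counts: a pandas DataFrame (isoforms x samples) plus
    isoform lengths in nt."""

    counts: "pandas.DataFrame"  # noqa: F821 - forward ref, avoids import cycle
    lengths: "pandas.Series"  # noqa: F821

    def __post_init__(self) -> None:
        import pandas as pd

        self.counts = self.counts.astype(float)
        self.lengths = pd.Series(self.lengths, dtype=float).reindex(self.counts.index)
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts")
        if self.lengths.isna().any():
            raise ValidationError("missing isoform lengths")
        if (self.lengths < 1).any():
            raise ValidationError("isoform lengths must be >= 1")

    @property
    def isoform_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)
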