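"""Structural classification of query isoforms against a reference
annotation, plus the long-read quality filters and junction-concordance
metrics.

Categories (applied within the assigned gene, in order):

* **FSM** — the query junction chain equals a reference transcript's chain.
* **ISM** — the chain is a *consecutive* sub-chain of some reference chain.
* **NNC** — at least one query donor or acceptor coordinate is unknown.
* **NIC** — all splice sites known, but the chain is neither a full match
  nor a consecutive sub-chain (a new combination of known sites/junctions).
* **other** — no gene could be assigned (or an unmatched mono-exonic query).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io import JunctionSupportTable
from .model import SpliceJunction, TranscriptModel, ValidationError

logger = logging.getLogger(__name__)

CANONICAL_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneIndex:
    gene_id: str
    chrom: str
    strand: str
    chains: set = field(default_factory=set)          # full junction chains (tuples)
    junctions: set = field(default_factory=set)       # (donor_end, acceptor_start)
    donors: set = field(default_factory=set)          # strand-resolved 5' sites
    acceptors: set = field(default_factory=set)       # strand-resolved 3' sites
    footprint: list = field(default_factory=list)     # merged exonic intervals
    mono_spans: list = field(default_factory=list)    # spans of mono-exonic refs


class ReferenceIndex:
    """Per-gene junction chains, known splice-site sets and exonic
    footprints of a reference annotation."""

    def __init__(self, genes: dict[str, GeneIndex]):
        self.genes = genes
        self._by_chrom: dict[tuple[str, str], list[GeneIndex]] = {}
        for g in genes.values():
            self._by_chrom.setdefault((g.chrom, g.strand), []).append(g)

    def __len__(self) -> int:
        return len(self.genes)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def build_reference_index(reference: Iterable[TranscriptModel]) -> ReferenceIndex:
    genes: dict[str, GeneIndex] = {}
    raw_exons: dict[str, list[tuple[int, int]]] = {}
    for tx in reference:
        g = genes.get(tx.gene_id)
        if g is None:
            g = genes[tx.gene_id] = GeneIndex(tx.gene_id, tx.chrom, tx.strand)
            raw_exons[tx.gene_id] = []
        elif (g.chrom, g.strand) != (tx.chrom, tx.strand):
            raise ValidationError(
                f"gene {tx.gene_id}: transcripts on different chrom/strand"
            )
        chain = tx.junction_chain()
        if chain:
            g.chains.add(chain)
            for j in tx.junctions():
                g.junctions.add(j.coords())
                g.donors.add(j.donor_site())
                g.acceptors.add(j.acceptor_site())
        else:
            g.mono_spans.append((tx.start, tx.end))
        raw_exons[tx.gene_id].extend(tx.exons)
    for gid, g in genes.items():
        g.footprint = _merge_intervals(raw_exons[gid])
    return ReferenceIndex(genes)


def _exonic_overlap(exons: list[tuple[int, int]], footprint: list[tuple[int, int]]) -> int:
    total = 0
    for s, e in exons:
        for fs, fe in footprint:
            total += max(0, min(e, fe) - max(s, fs))
    return total


def assign_gene(query: TranscriptModel, index: ReferenceIndex) -> Optional[str]:
    """Gene with maximal same-strand exonic overlap; None if no overlap.
    Ties break to the lexicographically smallest gene_id (logged)."""
    candidates = index._by_chrom.get((query.chrom, query.strand), [])
    best: list[tuple[int, str]] = []
    for g in candidates:
        ov = _exonic_overlap(query.exons, g.footprint)
        if ov > 0:
            best.append((ov, g.gene_id))
    if not best:
        return None
    best.sort(key=lambda t: (-t[0], t[1]))
    if len(best) > 1 and best[0][0] == best[1][0]:
        logger.info(
            "gene assignment tie for %s: %s vs %s; taking %s",
            query.transcript_id, best[0][1], best[1][1], best[0][1],
        )
    return best[0][1]


def _is_consecutive_subchain(chain, ref_chain) -> bool:
    k = len(chain)
    if k == 0 or k > len(ref_chain):
        return False
    return any(tuple(ref_chain[i : i + k]) == chain for i in range(len(ref_chain) - k + 1))


MONO_END_SLACK = 50


def classify_transcript(
    query: TranscriptModel, index: ReferenceIndex
) -> tuple[str, Optional[str]]:
    """Structural category and (for FSM) the matched reference chain's id
    surrogate.

    Returns ``(category, matched_reference_id)``; ``matched_reference_id``
    is the gene id for FSM matches (chains, not transcripts, are indexed).
    """
    if len(index) == 0:
        raise ValidationError("cannot classify against an empty reference index")
    gid = assign_gene(query, index)
    if gid is None:
        return ("other", None)
    g = index.genes[gid]
    chain = query.junction_chain()
    if not chain:  # mono-exonic: FSM against a mono-exonic reference with end slack
        for s, e in g.mono_spans:
            if s - MONO_END_SLACK <= query.start and query.end <= e + MONO_END_SLACK:
                return ("FSM", gid)
        return ("other", None)
    if chain in g.chains:
        return ("FSM", gid)
    if any(_is_consecutive_subchain(chain, ref) for ref in g.chains):
        return ("ISM", gid)
    donors = {j.donor_site() for j in query.junctions()}
    acceptors = {j.acceptor_site() for j in query.junctions()}
    if (donors - g.donors) or (acceptors - g.acceptors):
        return ("NNC", gid)
    return ("NIC", gid)


def canonical_status(junction: SpliceJunction, genome) -> bool:
    """True iff the strand-oriented intron boundary dinucleotides are one of
    GT..AG, GC..AG, AT..AC."""
    contig = genome[junction.chrom]
    if junction.acceptor_start > len(contig) or junction.donor_end < 0:
        raise ValidationError(f"junction {junction} out of contig range")
    if junction.acceptor_start - junction.donor_end < 4:
        raise ValidationError("intron shorter than 4 bp")
    left = str(contig[junction.donor_end : junction.donor_end + 2]).upper()
    right = str(contig[junction.acceptor_start - 2 : junction.acceptor_start]).upper()
    if junction.strand == "+":
        pair = (left, right)
    else:
        pair = (_revcomp(right), _revcomp(left))
    return pair in CANONICAL_PAIRS


@dataclass
class FilterDecision:
    transcript_id: str
    kept: bool
    removal_reasons: tuple[str, ...]
    rescue_applied: bool


@dataclass
class FilterParams:
    """Quality-filter knobs.

    intra-priming: remove when the fraction of genomic-sense adenine in the
    ``ip_window_nt`` bases immediately downstream of the transcript 3' end
    is >= ``ip_a_fraction``.  Junction support: remove when a non-canonical
    junction (optionally only reference-novel ones) has fewer than
    ``min_unique_reads`` uniquely mapped reads in every sample; FSM isoforms
    are rescued from this rule.
    """

    ip_window_nt: int = 20
    ip_a_fraction: float = 0.60
    min_unique_reads: int = 3
    novel_only: bool = False


def _intra_priming(tx: TranscriptModel, genome, params: FilterParams) -> bool:
    contig = genome[tx.chrom]
    w = params.ip_window_nt
    if tx.strand == "+":
        lo, hi = tx.end, min(tx.end + w, len(contig))
        base = "A"
    else:
        lo, hi = max(tx.start - w, 0), tx.start
        base = "T"  # genomic complement of sense-strand adenine
    window = str(contig[lo:hi]).upper()
    if len(window) < w:
        logger.warning(
            "%s: downstream window truncated to %d nt at contig edge",
            tx.transcript_id, len(window),
        )
    if not window:
        return False
    return window.count(base) / len(window) >= params.ip_a_fraction


def apply_quality_filters(
    queries: Iterable[TranscriptModel],
    support: JunctionSupportTable,
    genome,
    index: ReferenceIndex,
    params: Optional[FilterParams] = None,
) -> dict[str, FilterDecision]:
    """Intra-priming and junction-support filters with FSM rescue.

    Every triggered reason is reported even for rescued isoforms; an
    isoform is kept iff it has no reasons, or its only reason is
    ``nc_junction_support`` and it is FSM (``rescue_applied``).
    """
    params = params or FilterParams()
    report: dict[str, FilterDecision] = {}
    for tx in sorted(queries, key=lambda t: t.transcript_id):
        reasons = []
        if _intra_priming(tx, genome, params):
            reasons.append("intra_priming")
        known = index.genes[tx.gene_id].junctions if tx.gene_id in index.genes else set()
        flagged = False
        for j in tx.junctions():
            if params.novel_only and j.coords() in known:
                continue
            if not canonical_status(j, genome) and not support.supported(
                j, params.min_unique_reads
            ):
                flagged = True
                break
        if flagged:
            reasons.append("nc_junction_support")
        rescue = False
        if tx.category == "FSM" and "nc_junction_support" in reasons:
            rescue = True
        kept = not reasons or (set(reasons) == {"nc_junction_support"} and rescue)
        report[tx.transcript_id] = FilterDecision(
            tx.transcript_id, kept, tuple(reasons), rescue
        )
    return report


def junction_concordance(
    junctions: Iterable,
    support: JunctionSupportTable,
    min_unique: int,
    per_sample: bool = False,
):
    """Fraction of ``junctions`` supported by >= ``min_unique`` uniquely
    mapped reads, pooled over samples or per sample."""
    junctions = list(junctions)
    if not junctions:
        raise ValidationError("empty junction set")
    if per_sample:
        return {
            s: sum(support.supported(j, min_unique, sample=s) for j in junctions) / len(junctions)
            for s in support.samples
        }
    return sum(support.supported(j, min_unique) for j in junctions) / len(junctions)
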