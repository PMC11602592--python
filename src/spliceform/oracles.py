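"""Brute-force reference implementations used to validate the fast paths.

Everything here is deliberately naive — per-base maps, exhaustive
enumeration — and shares no code with the implementations it checks.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

from .model import TranscriptModel


# -- structural classification ---------------------------------------------

def classify_oracle(query: TranscriptModel, ref_chains: set, gene_found: bool = True) -> str:
    """Category of a multi-exonic query against one gene's reference chains
    by exhaustive enumeration of full chains, all consecutive sub-chains,
    and the splice-site sets."""
    if not gene_found:
        return "other"
    chain = query.junction_chain()
    if chain in ref_chains:
        return "FSM"
    sub_chains = set()
    for rc in ref_chains:
        for i in range(len(rc)):
            for j in range(i + 1, len(rc) + 1):
                sub_chains.add(tuple(rc[i:j]))
    if chain in sub_chains:
        return "ISM"
    donors, acceptors = set(), set()
    for rc in ref_chains:
        for d, a in rc:
            left, right = d, a
            if query.strand == "+":
                donors.add(left)
                acceptors.add(right)
            else:
                donors.add(right)
                acceptors.add(left)
    for j in query.junctions():
        if j.donor_site() not in donors or j.acceptor_site() not in acceptors:
            return "NNC"
    return "NIC"


# -- coordinate mapping -----------------------------------------------------

def map_tx_to_genome_oracle(tx: TranscriptModel, tx_start: int, tx_end: int) -> list[tuple[int, int]]:
    """Per-base transcript->genome map, merged into intervals."""
    bases = []
    for s, e in tx.exons:
        bases.extend(range(s, e))
    if tx.strand == "-":
        bases = bases[::-1]  # transcript 5'->3' order
    hit = sorted(bases[tx_start:tx_end])
    out: list[list[int]] = []
    for b in hit:
        if out and b == out[-1][1]:
            out[-1][1] = b + 1
        else:
            out.append([b, b + 1])
    return [(s, e) for s, e in out]


# -- AS events --------------------------------------------------------------

def exon_membership_diff(isoA: TranscriptModel, isoB: TranscriptModel) -> list[tuple[int, int, str]]:
    """Maximal genomic regions covered by exactly one isoform's exons,
    labeled with which isoform covers them ('A' or 'B').  Regions outside
    both transcripts' spans are ignored."""
    lo = min(isoA.start, isoB.start)
    hi = max(isoA.end, isoB.end)
    inA = np.zeros(hi - lo, dtype=bool)
    inB = np.zeros(hi - lo, dtype=bool)
    for s, e in isoA.exons:
        inA[s - lo : e - lo] = True
    for s, e in isoB.exons:
        inB[s - lo : e - lo] = True
    diff = inA ^ inB
    out = []
    i = 0
    n = hi - lo
    while i < n:
        if diff[i]:
            j = i
            while j < n and diff[j] and inA[j] == inA[i]:
                j += 1
            out.append((lo + i, lo + j, "A" if inA[i] else "B"))
            i = j
        else:
            i += 1
    return out


def reflect_transcript(tx: TranscriptModel, pivot: int) -> TranscriptModel:
    """Reflect all coordinates about ``pivot`` (x -> pivot - x) and flip the
    strand; used for strand-reflection invariance checks."""
    exons = sorted((pivot - e, pivot - s) for s, e in tx.exons)
    strand = "-" if tx.strand == "+" else "+"
    return TranscriptModel(tx.transcript_id, tx.gene_id, tx.chrom, strand, exons,
                           category=tx.category)


# -- rank-sum enumeration ---------------------------------------------------

def wilcoxon_exact_oracle(x: Sequence[float], y: Sequence[float], alternative: str) -> float:
    """Exact rank-sum p-value by full enumeration of the C(n+m, n) group
    assignments over the pooled midranks (ties allowed)."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = sorted(x + y)
    # midranks
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        mid = (i + j + 1) / 2  # average of ranks i+1..j
        ranks.setdefault(pooled[i], mid)
        i = j
    w_obs = sum(ranks[v] for v in x)
    n, m = len(x), len(y)
    idx = list(range(n + m))
    all_vals = x + y
    count_ge = count_le = total = 0
    pooled_vals = all_vals
    for grp in combinations(idx, n):
        w = sum(ranks[pooled_vals[i]] for i in grp)
        total += 1
        if w >= w_obs - 1e-12:
            count_ge += 1
        if w <= w_obs + 1e-12:
            count_le += 1
    if alternative == "greater":
        return count_ge / total
    if alternative == "less":
        return count_le / total
    return min(1.0, 2.0 * min(count_ge, count_le) / total)


# -- motif scanning ---------------------------------------------------------

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def scan_motif_oracle(seq: str, iupac: str) -> list[int]:
    """Sliding-window IUPAC match without regular expressions."""
    seq = seq.upper()
    iupac = iupac.upper()
    k = len(iupac)
    hits = []
    for i in range(len(seq) - k + 1):
        ok = True
        for c, p in zip(seq[i : i + k], iupac):
            if c not in _IUPAC_SETS[p]:
                ok = False
                break
        if ok:
            hits.append(i)
    return hits
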