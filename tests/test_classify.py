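"""Structural classification, quality filters, and junction concordance."""

import numpy as np
import pandas as pd
import pytest

from spliceform.classify import (
    FilterParams,
    apply_quality_filters,
    assign_gene,
    build_reference_index,
    canonical_status,
    classify_transcript,
    junction_concordance,
)
from spliceform.io import JunctionSupportTable
from spliceform.model import SpliceJunction, ValidationError
from spliceform.oracles import classify_oracle

from conftest import make_tx


def ref_two_junction():
    return [make_tx("R1", [(100, 200), (300, 400), (500, 600)])]


class TestReferenceIndex:
    def test_single_transcript_sets(self):
        idx = build_reference_index(ref_two_junction())
        g = idx.genes["G1"]
        assert g.donors == {200, 400}
        assert g.acceptors == {300, 500}
        assert g.chains == {((200, 300), (400, 500))}

    def test_shared_junction_deduplicated(self):
        # R2 shares junction (200, 300) with R1 and adds (400, 550)
        refs = ref_two_junction() + [make_tx("R2", [(100, 200), (300, 400), (550, 600)])]
        g = build_reference_index(refs).genes["G1"]
        assert g.junctions == {(200, 300), (400, 500), (400, 550)}

    def test_empty_reference(self):
        assert len(build_reference_index([])) == 0


class TestAssignGene:
    def test_containment_and_no_overlap(self):
        idx = build_reference_index(ref_two_junction())
        q = make_tx("Q", [(110, 190)])
        assert assign_gene(q, idx) == "G1"
        assert assign_gene(make_tx("Q2", [(5000, 5100)]), idx) is None

    def test_tie_breaks_lexicographically(self):
        refs = [make_tx("Ra", [(100, 200)], gene="Gb"),
                make_tx("Rb", [(100, 200)], gene="Ga")]
        idx = build_reference_index(refs)
        assert assign_gene(make_tx("Q", [(100, 200)]), idx) == "Ga"


class TestClassify:
    def setup_method(self):
        self.idx = build_reference_index(ref_two_junction())

    def test_full_splice_match(self):
        q = make_tx("Q", [(90, 200), (300, 400), (500, 610)])
        assert classify_transcript(q, self.idx)[0] == "FSM"

    def test_incomplete_splice_match_consecutive_subchain(self):
        q = make_tx("Q", [(320, 400), (500, 600)])
        assert classify_transcript(q, self.idx)[0] == "ISM"

    def test_nic_vs_nnc_on_multi_chain_gene(self):
        refs = [make_tx("R1", [(100, 200), (300, 400), (500, 600)]),
                make_tx("R2", [(100, 200), (350, 600)])]
        idx = build_reference_index(refs)
        nic = make_tx("Q1", [(100, 200), (350, 400), (500, 600)])
        nnc = make_tx("Q2", [(100, 200), (310, 400), (500, 600)])
        assert classify_transcript(nic, idx)[0] == "NIC"
        assert classify_transcript(nnc, idx)[0] == "NNC"

    def test_mono_exonic_rules(self):
        refs = ref_two_junction() + [make_tx("M", [(1000, 1500)], gene="G2")]
        idx = build_reference_index(refs)
        assert classify_transcript(make_tx("Q", [(980, 1520)]), idx)[0] == "FSM"
        assert classify_transcript(make_tx("Q", [(900, 1520)]), idx)[0] == "other"

    def test_empty_index_rejected(self):
        with pytest.raises(ValidationError):
            classify_transcript(make_tx("Q", [(0, 10)]), build_reference_index([]))

    def test_monotone_under_reference_growth(self, small_dataset):
        """Adding reference chains can only move queries toward more-known
        categories (NNC -> NIC -> ISM -> FSM)."""
        rank = {"other": 0, "NNC": 1, "NIC": 2, "ISM": 3, "FSM": 4}
        refs = small_dataset.reference
        small_idx = build_reference_index(refs[:1])
        # grow the first gene with an exon-skipping chain
        first = refs[0]
        grown = build_reference_index(
            [first, make_tx("extra", [e for i, e in enumerate(first.exons) if i != 2],
                            gene=first.gene_id, chrom=first.chrom, strand=first.strand)]
        )
        for tx in small_dataset.queries:
            if tx.gene_id != first.gene_id:
                continue
            before, _ = classify_transcript(tx, small_idx)
            after, _ = classify_transcript(tx, grown)
            assert rank[after] >= rank[before]

    def test_agrees_with_brute_force_oracle(self):
        from spliceform.validation import classification_oracle_agreement

        res = classification_oracle_agreement(seed=5, n_queries=2000)
        assert res["agreement"] == 1.0


class TestCanonical:
    def test_plus_strand_gt_ag(self, toy_genome):
        assert canonical_status(SpliceJunction("chr1", 3, 12, "+"), toy_genome)

    def test_minus_strand_ct_ac(self):
        genome = {"c": "AAACTTTTTTACGGG"}
        assert canonical_status(SpliceJunction("c", 3, 12, "-"), genome)
        assert not canonical_status(SpliceJunction("c", 3, 12, "+"), genome)

    def test_gg_ag_noncanonical(self):
        genome = {"c": "AAAGGTTTTTAGCCC"}
        assert not canonical_status(SpliceJunction("c", 3, 12, "+"), genome)


def _support(entries, samples=("s1",)):
    per_sample = {}
    for s in samples:
        rows = [dict(chrom=c, donor_end=d, acceptor_start=a,
                     unique_reads=entries.get((c, d, a), {}).get(s, 0),
                     multi_reads=0)
                for (c, d, a) in entries]
        per_sample[s] = pd.DataFrame(rows) if rows else pd.DataFrame(
            columns=["chrom", "donor_end", "acceptor_start", "unique_reads", "multi_reads"])
    return JunctionSupportTable(per_sample)


class TestFilters:
    def test_quality_filters_closed_loop(self, small_dataset):
        """Generated data: filters remove exactly the planted intra-priming
        and unsupported-non-canonical isoforms, rescuing planted FSMs."""
        ds = small_dataset
        idx = build_reference_index(ds.reference)
        for tx in ds.queries:
            tx.category = classify_transcript(tx, idx)[0]
        report = apply_quality_filters(ds.queries, ds.support, ds.genome, idx)
        truth = ds.truth.isoforms
        for tid, dec in report.items():
            row = truth.loc[tid]
            assert dec.kept == row["expected_kept"], tid
            assert ";".join(dec.removal_reasons) == row["expected_reasons"], tid
            assert dec.rescue_applied == row["expected_rescue"], tid

    def test_intra_priming_sixty_percent_adenine(self):
        # 13/20 = 65% adenine downstream of the 3' end -> removed
        genome = {"c": "G" * 100 + "A" * 13 + "C" * 7 + "G" * 20}
        tx = make_tx("T", [(10, 50), (60, 100)], chrom="c", category="NIC")
        sup = _support({("c", 50, 60): {"s1": 10}})
        idx = build_reference_index(
            [make_tx("R", [(10, 50), (60, 100)], chrom="c")])
        # make the junction canonical so only intra-priming fires
        genome["c"] = genome["c"][:50] + "GT" + genome["c"][52:58] + "AG" + genome["c"][60:]
        rep = apply_quality_filters([tx], sup, genome, idx)
        assert rep["T"].removal_reasons == ("intra_priming",)
        assert not rep["T"].kept

    def test_unsupported_noncanonical_removed_and_fsm_rescued(self):
        genome = {"c": "T" * 50 + "GG" + "T" * 8 + "AG" + "C" * 60}
        exons = [(10, 50), (62, 100)]
        nnc = make_tx("N", exons, chrom="c", category="NNC")
        fsm = make_tx("F", exons, chrom="c", category="FSM")
        sup = _support({("c", 50, 62): {"s1": 2}})
        idx = build_reference_index([make_tx("R", [(10, 100)], chrom="c")])
        rep = apply_quality_filters([nnc, fsm], sup, genome, idx)
        assert rep["N"].removal_reasons == ("nc_junction_support",) and not rep["N"].kept
        assert rep["F"].kept and rep["F"].rescue_applied

    def test_determinism_across_input_order(self, small_dataset):
        ds = small_dataset
        idx = build_reference_index(ds.reference)
        for tx in ds.queries:
            tx.category = classify_transcript(tx, idx)[0]
        a = apply_quality_filters(ds.queries, ds.support, ds.genome, idx)
        b = apply_quality_filters(list(reversed(ds.queries)), ds.support, ds.genome, idx)
        assert a == b


class TestConcordance:
    def test_fraction_supported(self):
        entries = {("c", i, i + 10): {"s1": (5 if i < 80 else 1)} for i in range(0, 100, 10)}
        sup = _support(entries)
        juncs = list(entries)
        assert junction_concordance(juncs, sup, 3) == pytest.approx(0.8)
        assert junction_concordance(juncs, sup, 0) == 1.0
        assert junction_concordance(juncs, sup, 1) == 1.0

    def test_per_sample_and_empty(self):
        sup = _support({("c", 0, 10): {"s1": 5}})
        assert junction_concordance([("c", 0, 10)], sup, 3, per_sample=True) == {"s1": 1.0}
        with pytest.raises(ValidationError):
            junction_concordance([], sup, 3)
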