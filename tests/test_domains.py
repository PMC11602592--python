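"""Domain presence, pairwise loss detection, AS attribution, and the
IR-vs-non-IR chi-square contrast."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from spliceform.domains import (
    DomainAnnotation,
    DomainLossEvent,
    annotate_domains,
    attribute_gene_losses,
    attribute_loss_to_as,
    detect_domain_loss,
    domain_loss_by_as_test,
    domain_presence,
    loss_type_counts,
)
from spliceform.events import ASEvent, detect_events
from spliceform.model import GenomicInterval, ValidationError

from conftest import make_tx


def ann(iso, name, s, e, chrom="chr1"):
    return DomainAnnotation(iso, name, 0, e - s, [GenomicInterval(chrom, s, e)])


class TestPresence:
    def test_counts_and_copies(self):
        isos = [make_tx("i1", [(0, 500)]), make_tx("i2", [(0, 500)])]
        mat = domain_presence("G1", isos, [ann("i1", "Pkinase", 10, 50),
                                           ann("i1", "Pkinase", 100, 140)])
        assert mat.at["i1", "Pkinase"] == 2 and mat.at["i2", "Pkinase"] == 0

    def test_empty_table_all_zero(self):
        isos = [make_tx("i1", [(0, 500)])]
        assert domain_presence("G1", isos, []).empty

    def test_unknown_isoform_rejected(self):
        with pytest.raises(ValidationError):
            domain_presence("G1", [make_tx("i1", [(0, 10)])], [ann("iX", "D", 0, 5)])


class TestLossDetection:
    def test_simple_loss_carries_intervals(self):
        isos = [make_tx("b", [(0, 500)]), make_tx("l", [(0, 500)])]
        losses = detect_domain_loss("G1", isos, [ann("b", "Pkinase", 300, 400)])
        assert len(losses) == 1
        l = losses[0]
        assert (l.bearer_isoform, l.loser_isoform) == ("b", "l")
        assert (l.lost_hull.start, l.lost_hull.end) == (300, 400)

    def test_equal_sets_no_loss_and_antisymmetry(self):
        isos = [make_tx("a", [(0, 500)]), make_tx("b", [(0, 500)])]
        doms = [ann("a", "D", 10, 50), ann("b", "D", 10, 50)]
        assert detect_domain_loss("G1", isos, doms) == []

    def test_two_copies_greedy_matching(self):
        isos = [make_tx("b", [(0, 900)]), make_tx("l", [(0, 900)])]
        doms = [ann("b", "D", 100, 200), ann("b", "D", 500, 600),
                ann("l", "D", 120, 210)]
        (loss,) = detect_domain_loss("G1", isos, doms)
        assert (loss.lost_hull.start, loss.lost_hull.end) == (500, 600)


class TestAttribution:
    def _loss(self, s, e):
        return DomainLossEvent("G1", "b", "l", "D", [GenomicInterval("chr1", s, e)])

    def _ev(self, t, s, e):
        return ASEvent(t, "chr1", s, e, "+", "b", "l")

    def test_adjacency_is_not_overlap(self):
        out = attribute_loss_to_as(self._loss(300, 400), [self._ev("IR", 200, 300)])
        assert out.attributed_event_types == frozenset()

    def test_exact_overlap(self):
        out = attribute_loss_to_as(self._loss(300, 400), [self._ev("ES", 300, 400)])
        assert out.attributed_event_types == {"ES"}

    def test_multiple_overlapping_events(self):
        out = attribute_loss_to_as(
            self._loss(300, 400),
            [self._ev("IR", 250, 320), self._ev("aTTS", 390, 600)])
        assert out.attributed_event_types == {"IR", "aTTS"}

    def test_event_from_wrong_pair_rejected(self):
        ev = ASEvent("IR", "chr1", 0, 10, "+", "x", "y")
        with pytest.raises(ValidationError):
            attribute_loss_to_as(self._loss(0, 10), [ev])

    def test_attribution_soundness_on_generated_data(self, small_dataset):
        """Every attributed type's event span overlaps the lost hull,
        re-checked with an independent interval routine."""
        ds = small_dataset
        txs = ds.transcripts()
        anns = annotate_domains(ds.domains, txs)
        by_iso, by_ann = {}, {}
        for tx in ds.queries:
            by_iso.setdefault(tx.gene_id, []).append(tx)
        for a in anns:
            by_ann.setdefault(txs[a.isoform_id].gene_id, []).append(a)
        n_checked = 0
        for g, isos in by_iso.items():
            losses = attribute_gene_losses(
                detect_domain_loss(g, isos, by_ann.get(g, [])), txs)
            for l in losses:
                evs = detect_events(txs[l.loser_isoform], txs[l.bearer_isoform])
                for t in l.attributed_event_types:
                    spans = [(e.start, e.end) for e in evs if e.event_type == t]
                    hull = (l.lost_hull.start, l.lost_hull.end)
                    assert any(max(s, hull[0]) < min(e, hull[1]) for s, e in spans)
                    n_checked += 1
        assert n_checked > 0

    def test_planted_losses_attributed_to_planted_types(self, small_dataset):
        ds = small_dataset
        txs = ds.transcripts()
        anns = annotate_domains(ds.domains, txs)
        by_iso, by_ann = {}, {}
        for tx in ds.queries:
            by_iso.setdefault(tx.gene_id, []).append(tx)
        for a in anns:
            by_ann.setdefault(txs[a.isoform_id].gene_id, []).append(a)
        losses = []
        for g, isos in by_iso.items():
            losses += attribute_gene_losses(
                detect_domain_loss(g, isos, by_ann.get(g, [])), txs)
        truth = {
            (r.gene_id, r.bearer, r.loser, r.domain_name): r.expected_type
            for r in ds.truth.domain_losses.itertuples(index=False)
        }
        assert len(losses) == len(truth)
        for l in losses:
            key = (l.gene_id, l.bearer_isoform, l.loser_isoform, l.domain_name)
            assert truth[key] in l.attributed_event_types

    def test_count_conservation_with_ir_priority(self):
        losses = [
            dataclasses.replace(self._loss(0, 10), attributed_event_types=frozenset({"IR", "ES"})),
            dataclasses.replace(self._loss(0, 10), attributed_event_types=frozenset({"ES"})),
            dataclasses.replace(self._loss(0, 10), attributed_event_types=frozenset()),
        ]
        counts = loss_type_counts(losses)
        assert counts.sum() == 3
        assert counts["IR"] == 1 and counts["ES"] == 1 and counts["unattributed"] == 1


class TestChiSquare:
    def _losses(self, table):
        out = []
        for (row, col), n in table.items():
            types = frozenset({"IR"}) if row == "IR" else frozenset({"ES"})
            dif = 0.2 if col == "inc" else -0.2
            for _ in range(n):
                out.append(DomainLossEvent("G", "b", "l", "D",
                                           [GenomicInterval("c", 0, 10)],
                                           types, dif))
        return out

    def test_worked_table(self):
        losses = self._losses({("IR", "inc"): 30, ("IR", "dec"): 10,
                               ("nonIR", "inc"): 15, ("nonIR", "dec"): 25})
        res, table = domain_loss_by_as_test(losses)
        assert res.statistic == pytest.approx(11.4286, abs=1e-3)
        assert table.values.tolist() == [[30, 10], [15, 25]]

    def test_proportional_rows_not_significant(self):
        losses = self._losses({("IR", "inc"): 10, ("IR", "dec"): 10,
                               ("nonIR", "inc"): 10, ("nonIR", "dec"): 10})
        res, _ = domain_loss_by_as_test(losses)
        assert res.statistic == 0 and res.p_value == pytest.approx(1.0)

    def test_zero_margin_reports_table(self):
        losses = self._losses({("IR", "inc"): 10, ("nonIR", "inc"): 10})
        with pytest.raises(ValidationError, match="IR"):
            domain_loss_by_as_test(losses)

    def test_dual_attribution_counts_in_ir_row(self):
        losses = [DomainLossEvent("G", "b", "l", "D", [GenomicInterval("c", 0, 1)],
                                  frozenset({"IR", "ES"}), 0.2),
                  DomainLossEvent("G", "b", "l", "D", [GenomicInterval("c", 0, 1)],
                                  frozenset({"ES"}), -0.2)]
        _, table = domain_loss_by_as_test(losses)
        assert table.at["IR", "increased"] == 1
        assert table.at["non-IR", "decreased"] == 1
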