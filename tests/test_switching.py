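"""Isoform fractions, the switch test, ORF/NMD calls, and consequences."""

import numpy as np
import pandas as pd
import pytest

from spliceform.model import ValidationError
from spliceform.simulate import GeneratorConfig, generate_annotation, simulate_counts
from spliceform.switching import (
    Consequence,
    ConsequenceParams,
    SwitchParams,
    consequence_enrichment,
    delta_if,
    isoform_fractions,
    nmd_status,
    predict_orf,
    switch_consequences,
    top_switch_pair,
)
from spliceform.switching import test_switch as switch_test  # avoid pytest collection

from conftest import make_tx


GENE_MAP = pd.Series({"i1": "G1", "i2": "G1", "i3": "G2"})


class TestFractions:
    def test_within_gene_fractions(self):
        counts = pd.DataFrame({"s1": [80.0, 20.0, 5.0]}, index=["i1", "i2", "i3"])
        frac = isoform_fractions(counts, GENE_MAP)
        assert frac.loc["i1", "s1"] == pytest.approx(0.8)
        assert frac.loc["i2", "s1"] == pytest.approx(0.2)
        assert frac.loc["i3", "s1"] == pytest.approx(1.0)

    def test_zero_gene_total_is_missing(self):
        counts = pd.DataFrame({"s1": [0.0, 0.0, 5.0]}, index=["i1", "i2", "i3"])
        frac = isoform_fractions(counts, GENE_MAP)
        assert frac.loc["i1", "s1"] != frac.loc["i1", "s1"]  # NaN

    def test_unmapped_isoform_rejected(self):
        counts = pd.DataFrame({"s1": [1.0]}, index=["iX"])
        with pytest.raises(ValidationError):
            isoform_fractions(counts, GENE_MAP)

    def test_dif_arithmetic_and_zero_sum(self):
        counts = pd.DataFrame(
            {"a1": [80.0, 20.0, 1], "a2": [78.0, 22.0, 1],
             "b1": [20.0, 80.0, 1], "b2": [22.0, 78.0, 1]},
            index=["i1", "i2", "i3"],
        )
        design = pd.DataFrame(dict(
            sample_id=["a1", "a2", "b1", "b2"],
            condition=["A", "A", "B", "B"], timepoint_h=0, replicate=[1, 2, 1, 2]))
        dif = delta_if(isoform_fractions(counts, GENE_MAP), design, ("A", "B"))
        assert dif["i1"] == pytest.approx(-0.58)
        assert dif.groupby(GENE_MAP).sum().abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_per_gene_dif_sums_to_zero_on_generated_data(self):
        cfg = GeneratorConfig(n_genes=30, seed=5)
        ds = generate_annotation(cfg)
        simulate_counts(ds)
        frac = isoform_fractions(ds.counts.counts, ds.gene_map)
        dif = delta_if(frac, ds.design, ("unstim", "stim"))
        assert dif.groupby(ds.gene_map).sum().abs().max() < 1e-9


class TestSwitchTest:
    def test_identical_fractions_not_significant(self):
        counts = pd.DataFrame(
            {s: [60.0, 40.0, 10.0] for s in ["a1", "a2", "b1", "b2"]},
            index=["i1", "i2", "i3"],
        )
        design = pd.DataFrame(dict(
            sample_id=["a1", "a2", "b1", "b2"],
            condition=["A", "A", "B", "B"], timepoint_h=0, replicate=[1, 2, 1, 2]))
        from spliceform.model import CountMatrix

        cm = CountMatrix(counts, pd.Series(1000.0, index=counts.index))
        res = switch_test(cm, design, GENE_MAP, ("A", "B"))
        assert (res["p_value"] == 1.0).all()
        assert (res["dIF"] == 0).all()
        assert not res["significant"].any()

    def test_requires_two_replicates(self):
        counts = pd.DataFrame({"a1": [1.0, 1, 1], "b1": [1.0, 1, 1]},
                              index=["i1", "i2", "i3"])
        design = pd.DataFrame(dict(sample_id=["a1", "b1"], condition=["A", "B"],
                                   timepoint_h=0, replicate=[1, 1]))
        from spliceform.model import CountMatrix

        cm = CountMatrix(counts, pd.Series(1000.0, index=counts.index))
        with pytest.raises(ValidationError, match="descriptive"):
            switch_test(cm, design, GENE_MAP, ("A", "B"))

    def test_planted_switches_recovered(self):
        cfg = GeneratorConfig(
            n_genes=40, fraction_ir_genes=0, fraction_switch_genes=0.5,
            fraction_nc_filter_genes=0, fraction_rescue_genes=0,
            fraction_intra_priming_genes=0, timepoints=(0, 24), n_replicates=10,
            seed=9,
        )
        ds = generate_annotation(cfg)
        simulate_counts(ds)
        res = switch_test(ds.counts, ds.design, ds.gene_map, ("unstim", "stim"))
        planted = set(ds.truth.switches["up_isoform"]) | set(ds.truth.switches["down_isoform"])
        sig = set(res.index[res["significant"]])
        assert len(sig & planted) / len(planted) >= 0.9
        est = res["dIF"].reindex(sorted(planted))
        planted_dif = pd.concat([
            ds.truth.switches.set_index("up_isoform")["dif"],
            -ds.truth.switches.set_index("down_isoform")["dif"],
        ]).reindex(est.index)
        assert (est - planted_dif).abs().mean() < 0.05


class TestTopPair:
    def _results(self, difs, qs=None):
        idx = [f"i{k}" for k in range(len(difs))]
        return pd.DataFrame(dict(
            gene_id="G1", dIF=difs,
            q_value=qs if qs is not None else [0.5] * len(difs)), index=idx)

    def test_max_and_min(self):
        pair = top_switch_pair("G1", self._results([0.4, -0.3, -0.1]))
        assert pair == ("i0", "i1")

    def test_all_zero_gives_none(self):
        assert top_switch_pair("G1", self._results([0.0, 0.0])) is None

    def test_tie_broken_by_q(self):
        pair = top_switch_pair("G1", self._results([0.4, 0.4, -0.2], [0.04, 0.01, 0.5]))
        assert pair == ("i1", "i2")


class TestOrf:
    def test_minimal_orf(self):
        orf = predict_orf("ATGAAATAG", min_len=0)
        assert (orf.start, orf.end, orf.protein, orf.complete) == (0, 9, "MK", True)
        assert predict_orf("ATGAAATAG", min_len=30) is None

    def test_no_start_codon(self):
        assert predict_orf("CCCCCCTAG", min_len=0) is None

    def test_tie_goes_most_five_prime(self):
        seq = "ATGAAATAGCATGCCCTAG"  # two 9-nt ORFs at 0 and 10
        orf = predict_orf(seq, min_len=0)
        assert orf.start == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(21)
        bases = np.array(list("ACGT"))
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(200):
            seq = "".join(rng.choice(bases, size=int(rng.integers(30, 200))))
            best = None
            for i in range(len(seq) - 2):
                if seq[i : i + 3] != "ATG":
                    continue
                j = i
                while j + 3 <= len(seq) and seq[j : j + 3] not in stops:
                    j += 3
                end = j + 3 if j + 3 <= len(seq) and seq[j : j + 3] in stops else j
                if best is None or end - i > best[1] - best[0]:
                    best = (i, end)
            got = predict_orf(seq, min_len=0)
            if best is None:
                assert got is None
            else:
                assert (got.start, got.end) == best


class TestNmd:
    def test_stop_far_upstream_of_last_junction(self):
        tx = make_tx("T", [(0, 300), (400, 700), (800, 900)])
        # last junction at tx position 600
        assert nmd_status(tx, 480)
        assert not nmd_status(tx, 650)  # stop in last exon

    def test_exact_fifty_is_not_nmd(self):
        tx = make_tx("T", [(0, 300), (400, 700), (800, 900)])
        assert not nmd_status(tx, 550)
        assert nmd_status(tx, 549)

    def test_mono_exonic_never_nmd(self):
        assert not nmd_status(make_tx("T", [(0, 900)]), 10)


def _coding_genome(length=2000):
    rng = np.random.default_rng(3)
    seq = list("".join(rng.choice(np.array(list("ACG")), size=length)))
    return {"chr1": "".join(seq)}


class TestConsequences:
    def _pair(self):
        up = make_tx("U", [(0, 120), (200, 320)], gene="G1")
        down = make_tx("D", [(0, 120), (200, 320), (400, 1100)], gene="G1")
        return up, down

    def test_utr3_shorter_with_magnitude(self):
        genome = _coding_genome()
        # plant identical ORFs: ATG at tx 0, stop early
        g = genome["chr1"]
        genome["chr1"] = "ATG" + "GCA" * 30 + "TAA" + g[96:]
        up, down = self._pair()
        cons = switch_consequences(up, down, genome)
        types = {c.consequence_type: c for c in cons}
        assert "utr3_shorter" in types
        assert types["utr3_shorter"].magnitude == down.length - up.length

    def test_identical_isoforms_no_consequences(self):
        genome = _coding_genome()
        up = make_tx("U", [(0, 120), (200, 320)], gene="G1")
        down = make_tx("D", [(0, 120), (200, 320)], gene="G1")
        assert switch_consequences(up, down, genome) == []

    def test_domain_loss_from_set_difference(self):
        genome = _coding_genome()
        up, down = self._pair()
        domains = pd.DataFrame(
            [dict(isoform_id="D", domain_name="Pkinase", tx_start=0, tx_end=30)]
        )
        cons = switch_consequences(up, down, genome, domains)
        loss = [c for c in cons if c.consequence_type == "domain_loss"]
        assert len(loss) == 1 and loss[0].magnitude == 1

    def test_direction_flips_when_pair_swapped(self):
        genome = _coding_genome()
        g = genome["chr1"]
        genome["chr1"] = "ATG" + "GCA" * 30 + "TAA" + g[96:]
        up, down = self._pair()
        fwd = {c.consequence_type for c in switch_consequences(up, down, genome)}
        rev = {c.consequence_type for c in switch_consequences(down, up, genome)}
        flip = {"utr3_shorter": "utr3_longer", "utr3_longer": "utr3_shorter"}
        for t in fwd:
            if t.startswith("utr3"):
                assert flip[t] in rev
            elif t.startswith("as_gain:"):
                assert t.replace("as_gain", "as_loss") in rev


class TestConsequenceEnrichment:
    def _cons(self, n_short, n_long):
        out = []
        for i in range(n_short):
            out.append(Consequence(f"gS{i}", "u", "d", "utr3_shorter", 100))
        for i in range(n_long):
            out.append(Consequence(f"gL{i}", "u", "d", "utr3_longer", 100))
        return out

    def test_binomial_on_gene_counts(self):
        from scipy.stats import binomtest

        df = consequence_enrichment(self._cons(60, 40))
        row = df[df.type_a == "utr3_shorter"].iloc[0]
        assert row["proportion_a"] == pytest.approx(0.6)
        assert row["p_value"] == pytest.approx(binomtest(60, 100, 0.5).pvalue)

    def test_balanced_and_single_gene(self):
        df = consequence_enrichment(self._cons(5, 5))
        assert df["p_value"].iloc[0] == pytest.approx(1.0)
        df1 = consequence_enrichment(self._cons(1, 0))
        assert df1["p_value"].iloc[0] == pytest.approx(1.0)
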