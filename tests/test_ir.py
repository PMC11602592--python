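"""Aggregated IR fractions, differential IR usage, gene-set contrasts, and
splicing-factor correlation."""

import numpy as np
import pandas as pd
import pytest

from spliceform.ir import (
    IRFilterParams,
    aggregate_ir_fraction,
    compare_genesets,
    correlate_factors,
    log2_cpm,
)
from spliceform.ir import test_ir_usage as ir_usage_test  # avoid pytest collection
from spliceform.model import ValidationError

GENE_MAP = pd.Series({"i1": "G1", "i2": "G1", "i3": "G2"})
IR = pd.Series({"i1": True, "i2": False, "i3": False})


class TestAggregate:
    def test_fraction_of_ir_counts(self):
        counts = pd.DataFrame({"s1": [30.0, 70.0, 5.0]}, index=["i1", "i2", "i3"])
        agg = aggregate_ir_fraction(counts, GENE_MAP, IR)
        assert agg.at["G1", "s1"] == pytest.approx(0.3)
        assert agg.at["G2", "s1"] == 0.0

    def test_zero_total_is_missing(self):
        counts = pd.DataFrame({"s1": [0.0, 0.0, 5.0]}, index=["i1", "i2", "i3"])
        agg = aggregate_ir_fraction(counts, GENE_MAP, IR)
        assert np.isnan(agg.at["G1", "s1"])

    def test_unlabeled_isoform_rejected(self):
        counts = pd.DataFrame({"s1": [1.0]}, index=["iX"])
        with pytest.raises(ValidationError):
            aggregate_ir_fraction(counts, pd.Series({"iX": "G"}), IR)

    def test_ir_plus_nonir_conserve_to_one(self, small_dataset):
        ds = small_dataset
        labels = ds.truth.isoforms["ir_label"]
        agg_ir = aggregate_ir_fraction(ds.counts.counts, ds.gene_map, labels)
        agg_non = aggregate_ir_fraction(ds.counts.counts, ds.gene_map, ~labels)
        assert (agg_ir + agg_non - 1.0).abs().max().max() < 1e-9

    def test_consistency_with_individual_fractions(self, small_dataset):
        from spliceform.switching import isoform_fractions

        ds = small_dataset
        labels = ds.truth.isoforms["ir_label"].reindex(ds.counts.counts.index).astype(bool)
        agg = aggregate_ir_fraction(ds.counts.counts, ds.gene_map, labels)
        frac = isoform_fractions(ds.counts.counts, ds.gene_map)
        per_iso = frac.loc[labels].groupby(ds.gene_map[labels]).sum()
        assert (agg.reindex(per_iso.index) - per_iso).abs().max().max() < 1e-9


def _design(samples, conds):
    return pd.DataFrame(dict(sample_id=samples, condition=conds,
                             timepoint_h=0, replicate=list(range(len(samples)))))


class TestUsageTest:
    def test_identical_fractions_p_one(self):
        counts = pd.DataFrame(
            {s: [30.0, 70.0, 20.0] for s in ["a1", "a2", "b1", "b2"]},
            index=["i1", "i2", "i3"])
        res = ir_usage_test(counts, GENE_MAP, IR, _design(
            ["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"]), ("A", "B"))
        assert (res["p_value"] == 1.0).all()

    def test_min_gene_expr_filter(self):
        # G2 never reaches 10 counts -> excluded
        counts = pd.DataFrame(
            {s: [30.0, 70.0, 9.0] for s in ["a1", "a2", "b1", "b2"]},
            index=["i1", "i2", "i3"])
        res = ir_usage_test(counts, GENE_MAP, IR, _design(
            ["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"]), ("A", "B"))
        assert "G2" not in res.index and "G1" in res.index

    def test_planted_timecourse_means_recovered(self, small_dataset):
        """Sample-mean aggregated IR fractions track the planted
        0.20/0.30/0.35 time course closely at n = 4 replicates."""
        ds = small_dataset
        labels = ds.truth.isoforms["ir_label"]
        agg = aggregate_ir_fraction(ds.counts.counts, ds.gene_map, labels)
        des = ds.design
        devs = []
        for r in ds.truth.ir_profile.itertuples(index=False):
            samples = des.loc[des.timepoint_h == r.timepoint_h, "sample_id"]
            devs.append(abs(agg.loc[r.gene_id, samples].mean() - r.fraction))
        assert np.mean(devs) < 0.03

    def test_planted_ir_shift_detected(self, small_dataset):
        ds = small_dataset
        labels = ds.truth.isoforms["ir_label"]
        res = ir_usage_test(ds.counts.counts, ds.gene_map, labels,
                            ds.design, ("unstim", "stim"))
        ir_genes = set(ds.truth.ir_profile["gene_id"])
        sig = set(res.index[res["q_value"] < 0.05])
        assert len(sig & ir_genes) / len(ir_genes) >= 0.8


class TestGenesets:
    def test_separated_sets_minimal_exact_p(self):
        dif = pd.Series({"a1": 0.2, "a2": 0.21, "a3": 0.19,
                         "b1": 0.0, "b2": 0.01, "b3": -0.01})
        res, summary = compare_genesets(dif, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert res.p_value == pytest.approx(1 / 20)  # 1 / C(6,3)
        assert summary.at["set_a", "median"] > summary.at["set_b", "median"]

    def test_identical_sets_symmetric(self):
        dif = pd.Series({"g1": 0.1, "g2": 0.2, "g3": 0.3})
        res, _ = compare_genesets(dif, ["g1", "g2", "g3"], ["g1", "g2", "g3"])
        assert 0.5 <= res.p_value <= 1.0

    def test_small_set_rejected(self):
        dif = pd.Series({"g1": 0.1})
        with pytest.raises(ValidationError):
            compare_genesets(dif, ["g1"], ["g1"])


class TestFactors:
    def test_perfect_anticorrelation_flagged(self):
        fx = pd.DataFrame([[4.0, 3, 2, 1]], index=["F1"], columns=list("abcd"))
        ir = pd.DataFrame([[1.0, 2, 3, 4]], index=["I1"], columns=list("abcd"))
        (res,) = correlate_factors(fx, ir)
        assert res.rho == pytest.approx(-1.0) and res.flagged

    def test_factor_with_own_ir_excluded(self):
        fx = pd.DataFrame([[4.0, 3, 2, 1]], index=["F1"], columns=list("abcd"))
        ir = pd.DataFrame([[1.0, 2, 3, 4]], index=["I1"], columns=list("abcd"))
        assert correlate_factors(fx, ir, factors_with_own_ir={"F1"}) == []

    def test_constant_vector_skipped(self):
        fx = pd.DataFrame([[1.0, 1, 1, 1]], index=["F1"], columns=list("abcd"))
        ir = pd.DataFrame([[1.0, 2, 3, 4]], index=["I1"], columns=list("abcd"))
        assert correlate_factors(fx, ir) == []

    def test_too_few_samples_rejected(self):
        fx = pd.DataFrame([[1.0, 2, 3]], index=["F1"], columns=list("abc"))
        with pytest.raises(ValidationError):
            correlate_factors(fx, fx)

    def test_planted_copula_pairs_recovered(self, small_dataset):
        ds = small_dataset
        truth = ds.truth
        ir_isos = sorted(truth.isoforms.index[truth.isoforms["ir_label"]])
        expr = log2_cpm(ds.counts.counts)
        own = set(truth.factors.loc[truth.factors["has_own_ir"], "factor_id"])
        results = correlate_factors(ds.factor_expr, expr.loc[ir_isos], own)
        planted = {(r.factor_id, r.target_isoform)
                   for r in truth.factors.itertuples(index=False) if r.target_isoform}
        flagged = {(r.factor_gene, r.ir_isoform) for r in results if r.flagged}
        assert len(flagged & planted) / len(planted) >= 0.8
        # exclusion rule: no flagged pair involves an own-IR factor
        assert not any(f in own for f, _ in flagged)
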