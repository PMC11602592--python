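"""Closed-loop validation suite.

Each function regenerates synthetic data under stated study conditions,
runs the corresponding analysis stage, and measures recovery of the planted
ground truth (or agreement with an independent brute-force oracle).  These
are the quantities the acceptance script reports and the acceptance tests
assert on.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import oracles
from .classify import apply_quality_filters, build_reference_index, classify_transcript
from .domains import (
    annotate_domains,
    attribute_gene_losses,
    detect_domain_loss,
    domain_loss_by_as_test,
)
from .events import detect_events, find_retained_introns
from .ir import aggregate_ir_fraction, compare_genesets, correlate_factors, log2_cpm, test_ir_usage
from .model import GenomicInterval, TranscriptModel
from .motifs import MotifDefinition, classify_regions, per_bin_enrichment, region_bin_densities
from .simulate import (
    GeneratorConfig,
    generate,
    generate_annotation,
    plant_domains_and_motifs,
    simulate_counts,
    simulate_junction_support,
)
from .stats import bh_fdr, chi_square_independence, spearman_correlation, wilcoxon_rank_sum
from .switching import delta_if, isoform_fractions, test_switch


# ---------------------------------------------------------------------------
# 1. structural classification vs brute-force oracle
# ---------------------------------------------------------------------------

def _random_reference_gene(rng: np.random.Generator, gene: str):
    """A gene with 1-3 reference chains over a random exon grid."""
    n_ex = int(rng.integers(4, 9))
    pos = 100
    exons = []
    for _ in range(n_ex):
        exons.append((pos, pos + int(rng.integers(80, 200))))
        pos = exons[-1][1] + int(rng.integers(100, 400))
    strand = "+" if rng.random() < 0.5 else "-"
    chrom = f"chr_{gene}"
    refs = [TranscriptModel(f"{gene}.r1", gene, chrom, strand, exons)]
    if rng.random() < 0.7 and n_ex >= 4:  # exon-skipping variant
        k = int(rng.integers(1, n_ex - 1))
        refs.append(TranscriptModel(
            f"{gene}.r2", gene, chrom, strand,
            [e for i, e in enumerate(exons) if i != k]))
    if rng.random() < 0.5:  # shifted-donor variant (adds a novel known site)
        k = int(rng.integers(0, n_ex - 1))
        var = list(exons)
        var[k] = (var[k][0], var[k][1] + int(rng.integers(3, 20)))
        refs.append(TranscriptModel(f"{gene}.r3", gene, chrom, strand, var))
    return refs, exons


def _random_query(rng: np.random.Generator, refs, exons, qid: str):
    """A random junction chain drawn from known, shifted and recombined
    sites, anchored inside the gene footprint."""
    junctions = sorted({j.coords() for tx in refs for j in tx.junctions()})
    pool = list(junctions)
    for d, a in junctions:
        if rng.random() < 0.5:
            pool.append((d + int(rng.integers(-8, 9)) or d + 1, a))
        if rng.random() < 0.5:
            pool.append((d, a + int(rng.integers(-8, 9)) or a + 1))
    for d1, _ in junctions:
        for _, a2 in junctions:
            if d1 + 10 < a2 and rng.random() < 0.3:
                pool.append((d1, a2))
    pool = sorted({(d, a) for d, a in pool if d < a})
    k = int(rng.integers(1, min(len(junctions) + 2, 6)))
    order = rng.permutation(len(pool))
    chain: list[tuple[int, int]] = []
    for idx in order:
        d, a = pool[idx]
        if all(a < d2 - 1 or d > a2 + 1 for d2, a2 in chain):
            chain.append((d, a))
            if len(chain) == k:
                break
    chain.sort()
    if not chain:
        return None
    start = exons[0][0] + int(rng.integers(0, 40))
    end = exons[-1][1] - int(rng.integers(0, 40))
    if start >= chain[0][0] or end <= chain[-1][1]:
        start = min(start, chain[0][0] - 10)
        end = max(end, chain[-1][1] + 10)
    bounds = [start] + [c for j in chain for c in j] + [end]
    q_exons = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)]
    if any(s >= e for s, e in q_exons):
        return None
    tx = refs[0]
    return TranscriptModel(qid, tx.gene_id, tx.chrom, tx.strand, q_exons)


def classification_oracle_agreement(seed: int, n_queries: int = 10_000) -> dict:
    """Agreement of classify_transcript with exhaustive chain/site-set
    enumeration over random queries on random multi-chain genes."""
    rng = np.random.default_rng(seed)
    agree = total = 0
    counts: dict[str, int] = {}
    while total < n_queries:
        gene = f"G{total:06d}"
        refs, exons = _random_reference_gene(rng, gene)
        index = build_reference_index(refs)
        chains = index.genes[gene].chains
        for qi in range(40):
            if total >= n_queries:
                break
            q = _random_query(rng, refs, exons, f"{gene}.q{qi}")
            if q is None:
                continue
            got, _ = classify_transcript(q, index)
            exp = oracles.classify_oracle(q, chains)
            total += 1
            agree += got == exp
            counts[exp] = counts.get(exp, 0) + 1
    return dict(agreement=agree / total, n=total, category_counts=counts)


# ---------------------------------------------------------------------------
# 2. planted-category recovery and quality filters
# ---------------------------------------------------------------------------

def planted_category_recovery(seed: int, n_genes: int = 200) -> dict:
    cfg = GeneratorConfig(n_genes=n_genes, seed=seed)
    ds = generate_annotation(cfg)
    simulate_junction_support(ds)
    index = build_reference_index(ds.reference)
    truth = ds.truth.isoforms
    correct = 0
    for tx in ds.queries:
        cat, _ = classify_transcript(tx, index)
        tx.category = cat
        correct += cat == truth.at[tx.transcript_id, "category"]
    report = apply_quality_filters(ds.queries, ds.support, ds.genome, index)
    filter_ok = 0
    for tid, dec in report.items():
        row = truth.loc[tid]
        filter_ok += (
            dec.kept == row["expected_kept"]
            and ";".join(dec.removal_reasons) == row["expected_reasons"]
            and dec.rescue_applied == row["expected_rescue"]
        )
    n = len(ds.queries)
    return dict(classification_accuracy=correct / n,
                filter_accuracy=filter_ok / n, n=n)


# ---------------------------------------------------------------------------
# 3-4. switch test calibration and recovery
# ---------------------------------------------------------------------------

def switch_null_calibration(seed: int) -> dict:
    """Type-I error of the switch test on a null simulation (no planted
    switches; 500 genes x 4 isoforms = 2,000 isoforms, n = 5/group)."""
    cfg = GeneratorConfig(
        n_genes=500, fraction_ir_genes=0, fraction_switch_genes=0,
        fraction_nc_filter_genes=0, fraction_rescue_genes=0,
        fraction_intra_priming_genes=0, timepoints=(0, 24), n_replicates=5,
        seed=seed,
    )
    ds = generate_annotation(cfg)
    simulate_counts(ds)
    res = test_switch(ds.counts, ds.design, ds.gene_map, ("unstim", "stim"))
    return dict(type_i_error=float((res["p_value"] < 0.05).mean()), n=len(res))


def switch_recovery(seed: int) -> dict:
    """Sensitivity / FDR / dIF accuracy on 200 genes with planted
    |dIF| in [0.2, 0.4] at n = 10/group."""
    cfg = GeneratorConfig(
        n_genes=200, fraction_ir_genes=0, fraction_switch_genes=1.0,
        fraction_nc_filter_genes=0, fraction_rescue_genes=0,
        fraction_intra_priming_genes=0, timepoints=(0, 24), n_replicates=10,
        seed=seed,
    )
    ds = generate_annotation(cfg)
    simulate_counts(ds)
    res = test_switch(ds.counts, ds.design, ds.gene_map, ("unstim", "stim"))
    tr = ds.truth.switches
    planted = set(tr["up_isoform"]) | set(tr["down_isoform"])
    sig = set(res.index[res["significant"]])
    sensitivity = len(sig & planted) / len(planted)
    fdr = len(sig - planted) / max(1, len(sig))
    planted_dif = pd.concat([
        tr.set_index("up_isoform")["dif"],
        -tr.set_index("down_isoform")["dif"],
    ])
    est = res["dIF"].reindex(planted_dif.index)
    err = (est - planted_dif).dropna()
    return dict(sensitivity=sensitivity, fdr=fdr,
                mean_dif_error=float(err.mean()),
                mean_abs_dif_error=float(err.abs().mean()),
                n=len(planted))


# ---------------------------------------------------------------------------
# 5. AS-event recovery and strand-reflection invariance
# ---------------------------------------------------------------------------

def event_recovery(seed: int, n_reflect_pairs: int = 1000) -> dict:
    cfg = GeneratorConfig(n_genes=200, seed=seed)
    ds = generate_annotation(cfg)
    txs = ds.transcripts()
    hit = 0
    for r in ds.truth.events.itertuples(index=False):
        evs = detect_events(txs[r.isoform], txs[r.partner])
        hit += any(
            e.event_type == r.event_type and e.start == r.start
            and e.end == r.end and e.isoform_in == r.isoform_in
            for e in evs
        )
    n_events = len(ds.truth.events)

    # strand reflection: x -> C - x with strand flip preserves every label
    rng = np.random.default_rng(seed + 7)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in ds.queries:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    genes = sorted(by_gene)
    ok = 0
    for i in range(n_reflect_pairs):
        g = genes[int(rng.integers(len(genes)))]
        isos = by_gene[g]
        a, b = rng.choice(len(isos), size=2, replace=False)
        isoA, isoB = isos[a], isos[b]
        pivot = max(isoA.end, isoB.end) + 100
        fwd = {(e.event_type, e.start, e.end, e.isoform_in)
               for e in detect_events(isoA, isoB)}
        rA = oracles.reflect_transcript(isoA, pivot)
        rB = oracles.reflect_transcript(isoB, pivot)
        rev = {(e.event_type, pivot - e.end, pivot - e.start, e.isoform_in)
               for e in detect_events(rA, rB)}
        ok += fwd == rev
    return dict(type_accuracy=hit / n_events, n_events=n_events,
                reflection_invariance=ok / n_reflect_pairs)


# ---------------------------------------------------------------------------
# 6. domain loss attribution and IR enrichment
# ---------------------------------------------------------------------------

def domain_loss_validation(seed: int, n_replicates: int = 100) -> dict:
    cfg = GeneratorConfig(
        n_genes=60, fraction_ir_genes=0.4, fraction_switch_genes=0.4,
        fraction_nc_filter_genes=0, fraction_rescue_genes=0,
        fraction_intra_priming_genes=0, seed=seed,
    )
    ds = generate_annotation(cfg)
    simulate_counts(ds)
    plant_domains_and_motifs(ds)
    txs = ds.transcripts()
    anns = annotate_domains(ds.domains, txs)
    by_iso: dict[str, list] = {}
    by_ann: dict[str, list] = {}
    for tx in ds.queries:
        by_iso.setdefault(tx.gene_id, []).append(tx)
    for a in anns:
        by_ann.setdefault(txs[a.isoform_id].gene_id, []).append(a)
    base_losses = []
    for g, isos in by_iso.items():
        base_losses += attribute_gene_losses(
            detect_domain_loss(g, isos, by_ann.get(g, [])), txs
        )
    truth = {
        (r.gene_id, r.bearer, r.loser, r.domain_name): r.expected_type
        for r in ds.truth.domain_losses.itertuples(index=False)
    }
    correct = sum(
        truth.get((l.gene_id, l.bearer_isoform, l.loser_isoform, l.domain_name))
        in l.attributed_event_types
        for l in base_losses
    )
    attribution_accuracy = correct / len(truth)

    hand_table = chi_square_independence([[30, 10], [15, 25]])

    n_sig = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + 100 + rep)
        simulate_counts(ds, rng)
        frac = isoform_fractions(ds.counts.counts, ds.gene_map)
        dif = delta_if(frac, ds.design, ("unstim", "stim"))
        losses = [dataclasses.replace(l, loser_dIF=float(dif.get(l.loser_isoform, np.nan)))
                  for l in base_losses]
        res, _ = domain_loss_by_as_test(losses)
        q = bh_fdr([res.p_value])[0]
        n_sig += q < 0.05
    return dict(attribution_accuracy=attribution_accuracy,
                n_losses=len(base_losses),
                chi2_worked_example=float(hand_table.statistic),
                ir_enrichment_detection_rate=n_sig / n_replicates,
                n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# 7. IR dynamics
# ---------------------------------------------------------------------------

def ir_dynamics_validation(seed: int) -> dict:
    cfg = GeneratorConfig(
        n_genes=400, fraction_ir_genes=0.4, fraction_switch_genes=0.05,
        fraction_nc_filter_genes=0, fraction_rescue_genes=0,
        fraction_intra_priming_genes=0, seed=seed,
    )
    ds = generate_annotation(cfg)
    simulate_counts(ds)
    truth = ds.truth
    ir_labels = truth.isoforms["ir_label"]
    agg_ir = aggregate_ir_fraction(ds.counts.counts, ds.gene_map, ir_labels)
    agg_non = aggregate_ir_fraction(ds.counts.counts, ds.gene_map, ~ir_labels)
    conservation = float((agg_ir + agg_non - 1.0).abs().max().max())

    frac = isoform_fractions(ds.counts.counts, ds.gene_map)
    lab = ir_labels.reindex(frac.index).astype(bool)
    ir_sum = frac.loc[lab].groupby(ds.gene_map[lab]).sum()
    consistency = float(
        (agg_ir.reindex(ir_sum.index) - ir_sum).abs().max().max()
    )

    des = ds.design
    ir_genes = sorted(truth.ir_profile["gene_id"].unique())
    tps = sorted(des["timepoint_h"].unique())
    monotone = 0
    for g in ir_genes:
        means = [
            float(agg_ir.loc[g, des.loc[des.timepoint_h == tp, "sample_id"]].mean())
            for tp in tps
        ]
        monotone += all(a < b for a, b in zip(means, means[1:]))
    dif = delta_if(agg_ir, des, ("unstim", "stim"))
    res, summary = compare_genesets(
        dif, truth.gene_sets["isg"], truth.gene_sets["housekeeping"]
    )
    return dict(conservation_max_dev=conservation,
                aggregation_consistency_max_dev=consistency,
                monotone_fraction=monotone / len(ir_genes),
                n_ir_genes=len(ir_genes),
                geneset_p=float(res.p_value),
                n_isg=int(summary.at["set_a", "n"]),
                n_housekeeping=int(summary.at["set_b", "n"]))


# ---------------------------------------------------------------------------
# 8. factor correlation and motif enrichment
# ---------------------------------------------------------------------------

def correlation_validation(seed: int) -> dict:
    cfg = GeneratorConfig(n_genes=200, seed=seed)
    ds = generate(cfg)
    truth = ds.truth
    ir_isos = sorted(truth.isoforms.index[truth.isoforms["ir_label"]])
    expr = log2_cpm(ds.counts.counts)
    own_ir = set(truth.factors.loc[truth.factors["has_own_ir"], "factor_id"])
    results = correlate_factors(ds.factor_expr, expr.loc[ir_isos], own_ir)
    planted = {
        (r.factor_id, r.target_isoform)
        for r in truth.factors.itertuples(index=False) if r.target_isoform
    }
    corr_factors = {f for f, _ in planted}
    flags = {(r.factor_gene, r.ir_isoform) for r in results if r.flagged}
    sensitivity = len(flags & planted) / len(planted)
    # independent pairs: both series generated without any planted or
    # confounded dependence, i.e. pairs of the pure-noise factors
    independent = [(r.factor_gene, r.ir_isoform) for r in results
                   if r.factor_gene not in corr_factors]
    false_flags = sum(1 for p in independent if p in flags)
    return dict(factor_sensitivity=sensitivity, n_planted=len(planted),
                false_flag_rate=false_flags / max(1, len(independent)),
                n_independent=len(independent))


def motif_enrichment_validation(seed: int) -> dict:
    cfg = GeneratorConfig(
        n_genes=250, fraction_ir_genes=0.8, fraction_switch_genes=0,
        fraction_nc_filter_genes=0, fraction_rescue_genes=0,
        fraction_intra_priming_genes=0, seed=seed,
    )
    ds = generate_annotation(cfg)
    plant_domains_and_motifs(ds)
    truth = ds.truth
    motif = MotifDefinition(ds.motifs.at[0, "name"], ds.motifs.at[0, "iupac"])
    spans: dict[str, list[GenomicInterval]] = {}
    for r in truth.ir_spans.itertuples(index=False):
        spans.setdefault(r.gene_id, []).append(
            GenomicInterval(r.chrom, r.start, r.end)
        )
    by_gene: dict[str, list] = {}
    for tx in ds.queries:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    dens = pd.concat(
        [
            region_bin_densities(
                classify_regions(isos, spans.get(g, [])), ds.genome, motif
            )
            for g, isos in sorted(by_gene.items())
        ],
        ignore_index=True,
    )
    res = per_bin_enrichment(dens, ("IR_intron", "nonIR_intron"), "greater")
    n_ir = dens.loc[dens.region_class == "IR_intron", "region_id"].nunique()
    return dict(bins_q_below_1e3=int((res["q_value"] < 0.001).sum()),
                n_ir_intron_regions=int(n_ir),
                median_density_ratio=float(
                    dens.loc[dens.region_class == "IR_intron", "sites_per_bp"].mean()
                    / dens.loc[dens.region_class == "nonIR_intron", "sites_per_bp"].mean()
                ))


# ---------------------------------------------------------------------------
# 9. statistical primitives vs independent oracles
# ---------------------------------------------------------------------------

def primitives_validation(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    n_checked = 0
    for nx in range(1, 6):
        for ny in range(1, 6):
            for _ in range(4):
                x = rng.permutation(np.arange(1, nx + ny + 1, dtype=float))[:nx]
                pool = set(range(1, nx + ny + 1)) - set(int(v) for v in x)
                y = np.array(sorted(pool), dtype=float)
                for alt in ("two-sided", "less", "greater"):
                    p_impl = wilcoxon_rank_sum(x, y, alt).p_value
                    p_orc = oracles.wilcoxon_exact_oracle(x, y, alt)
                    max_dev = max(max_dev, abs(p_impl - p_orc))
                    n_checked += 1
    bh = bh_fdr([0.01, 0.02, 0.03, 0.04])
    bh_ok = bool(np.allclose(bh, [0.04, 0.04, 0.04, 0.04]))
    rho = spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3])
    spearman_ok = bool(np.isclose(rho, 0.6))
    chi = chi_square_independence([[30, 10], [15, 25]]).statistic
    return dict(wilcoxon_max_abs_dev=max_dev, n_wilcoxon_checked=n_checked,
                bh_worked_example_ok=float(bh_ok),
                spearman_worked_example_ok=float(spearman_ok),
                chi2_worked_example=float(chi))
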