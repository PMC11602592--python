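"""Seeded synthetic-data generator with planted ground truth.

The generator emulates, at desk scale, the statistical structure the
analysis assumes: a multi-exon gene annotation whose query isoforms are
constructed *by rule* to fall into the structural categories (FSM copy, ISM
5'-truncation, NIC exon skip, NNC shifted donor, an intron-retaining NIC
isoform), Dirichlet-multinomial isoform counts with planted
condition-dependent switches and time-increasing IR fractions, planted
domain architectures whose losses are attributable to the planted AS
events, motif instances written into the genome at controlled densities,
and splicing-factor expression rank-correlated with IR-isoform expression
through a Gaussian copula.

Every construction is recorded in :class:`SyntheticTruth`; identical
config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import CountMatrix, TranscriptModel, ValidationError, map_genome_to_tx

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# deterministic sequence patterns written at transcript ends
_BALANCED_20 = "ACGT" * 5              # 25% A: never trips the intra-priming filter
_A_RICH_20 = "AACAA" * 4               # 80% A: always trips it
_T_RICH_20 = "TTGTT" * 4               # minus-strand genomic complement


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic experiment.

    Defaults describe an interferon-stimulation-like time course: three
    timepoints (0 h unstimulated, 24 h and 72 h stimulated), four
    replicates each, deep per-sample coverage, and tight biological
    replicate dispersion (Dirichlet concentration 300, i.e. a replicate
    isoform-fraction sd of ~0.026 at IF = 0.3).
    """

    n_genes: int = 200
    n_exons: int = 6
    exon_len: tuple[int, int] = (100, 300)
    intron_len: tuple[int, int] = (200, 600)
    n_replicates: int = 4
    timepoints: tuple[int, ...] = (0, 24, 72)
    library_size: int = 2_000_000
    concentration: float = 300.0
    # gene role fractions (disjoint; remainder are plain genes)
    fraction_ir_genes: float = 0.30
    fraction_switch_genes: float = 0.25
    fraction_nc_filter_genes: float = 0.15
    fraction_rescue_genes: float = 0.10
    fraction_intra_priming_genes: float = 0.10
    # planted effect sizes
    dif_range: tuple[float, float] = (0.2, 0.4)
    ir_base: float = 0.20
    ir_increments: tuple[float, ...] = (0.10, 0.05)
    nnc_shift: int = 6
    # motif planting
    motif_name: str = "SRSF_sim"
    motif_iupac: str = "GGAGGA"
    motif_density_per_kb: float = 10.0
    motif_density_ratio: float = 2.0
    motif_exon_scale: float = 0.5
    motif_ir_exon_scale: float = 0.5
    # splicing factors
    n_factors: int = 40
    fraction_correlated_factors: float = 0.75
    n_factors_with_own_ir: int = 2
    factor_rho: float = -0.95
    # junction support
    sj_mean_unique: float = 30.0
    sj_mean_multi: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_ir_genes + self.fraction_switch_genes
            + self.fraction_nc_filter_genes + self.fraction_rescue_genes
            + self.fraction_intra_priming_genes
        )
        if fracs > 1.0 + 1e-9:
            raise ValidationError("gene role fractions sum to more than 1")
        if self.n_exons < 6:
            raise ValidationError(
                "backbone needs >= 6 exons to plant ISM/NIC/NNC/IR in one gene"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth, one table per analysis stage."""

    isoforms: pd.DataFrame       # isoform_id, gene_id, role, category, ir_label,
                                 # expected_kept, expected_reasons, expected_rescue
    planted_if: pd.DataFrame     # isoform_id, gene_id, timepoint_h, IF
    switches: pd.DataFrame       # gene_id, up_isoform, down_isoform, dif
    events: pd.DataFrame         # gene_id, isoform, partner, event_type, start, end, isoform_in
    ir_profile: pd.DataFrame     # gene_id, timepoint_h, fraction
    domain_losses: pd.DataFrame  # gene_id, bearer, loser, domain_name, expected_type
    factors: pd.DataFrame        # factor_id, target_isoform, rho, has_own_ir
    unsupported_junctions: pd.DataFrame  # chrom, donor_end, acceptor_start
    ir_spans: pd.DataFrame       # gene_id, chrom, start, end (planted retained introns)
    gene_sets: dict = field(default_factory=dict)  # isg / housekeeping lists


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    reference: list
    queries: list
    genome: dict
    truth: SyntheticTruth
    design: Optional[pd.DataFrame] = None
    counts: Optional[CountMatrix] = None
    support: Optional["JunctionSupportTable"] = None  # noqa: F821
    domains: Optional[pd.DataFrame] = None
    motifs: Optional[pd.DataFrame] = None
    factor_expr: Optional[pd.DataFrame] = None

    @property
    def gene_map(self) -> pd.Series:
        return pd.Series(
            {tx.transcript_id: tx.gene_id for tx in self.queries}, name="gene_id"
        )

    def transcripts(self) -> dict[str, TranscriptModel]:
        return {tx.transcript_id: tx for tx in self.queries}


# ---------------------------------------------------------------------------
# annotation + genome
# ---------------------------------------------------------------------------

def _t2g(i: int, n: int, strand: str) -> int:
    """Transcript-order exon index -> genomic-order index."""
    return i if strand == "+" else n - 1 - i


def _write(seq: bytearray, pos: int, s: str) -> None:
    seq[pos : pos + len(s)] = s.encode()


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _write_junction_dinucs(seq: bytearray, donor_end: int, acceptor_start: int,
                           strand: str, canonical: bool = True) -> None:
    """Force the boundary dinucleotides of an intron to GT..AG on its own
    strand (or to a non-canonical pair)."""
    if strand == "+":
        left, right = ("GT", "AG") if canonical else ("GG", "AG")
    else:
        # on '-' the canonical GT..AG reads CT..AC on the genomic strand
        left, right = ("CT", "AC") if canonical else ("CT", "TT")
    _write(seq, donor_end, left)
    _write(seq, acceptor_start - 2, right)


def generate_annotation(config: GeneratorConfig) -> SyntheticDataset:
    """Reference + query transcript models, genome, and structural truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_ex = config.n_exons
    flank = 400

    # gene roles (disjoint partition in index order of a seeded shuffle)
    order = rng.permutation(n)
    roles = np.array(["plain"] * n, dtype=object)
    cursor = 0
    for role, frac in [
        ("ir", config.fraction_ir_genes),
        ("switch", config.fraction_switch_genes),
        ("nc_filter", config.fraction_nc_filter_genes),
        ("rescue", config.fraction_rescue_genes),
        ("intra_priming", config.fraction_intra_priming_genes),
    ]:
        k = int(round(frac * n))
        roles[order[cursor : cursor + k]] = role
        cursor += k

    reference: list[TranscriptModel] = []
    queries: list[TranscriptModel] = []
    genome: dict[str, str] = {}
    iso_rows, event_rows, ir_span_rows, unsupported = [], [], [], []

    for gi in range(n):
        gene = f"G{gi:04d}"
        chrom = f"chr_{gene}"
        strand = "+" if rng.random() < 0.5 else "-"
        role = roles[gi]

        elens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_ex)
        ilens = rng.integers(config.intron_len[0], config.intron_len[1] + 1, n_ex - 1)
        exons = []
        pos = flank
        for k in range(n_ex):
            exons.append((pos, pos + int(elens[k])))
            pos = exons[-1][1] + (int(ilens[k]) if k < n_ex - 1 else 0)
        contig_len = exons[-1][1] + flank
        seq = bytearray(rng.choice(_BASES, size=contig_len).tobytes())

        backbone = TranscriptModel(f"{gene}.ref", gene, chrom, strand, exons)
        reference.append(backbone)
        for j in backbone.junctions():
            _write_junction_dinucs(seq, j.donor_end, j.acceptor_start, strand)

        # transcript-order helpers
        g = lambda t: exons[_t2g(t, n_ex, strand)]

        def add(iso_suffix, tx_exons, category, ir_label=False,
                kept=True, reasons="", rescue=False):
            tid = f"{gene}.{iso_suffix}"
            queries.append(TranscriptModel(tid, gene, chrom, strand, tx_exons))
            iso_rows.append(dict(
                isoform_id=tid, gene_id=gene, role=role, category=category,
                ir_label=ir_label, expected_kept=kept,
                expected_reasons=reasons, expected_rescue=rescue,
            ))
            return tid

        # FSM: exact copy (rescued in rescue genes: junction j_t0 is
        # non-canonical and left without read support there)
        rescue_gene = role == "rescue"
        fsm = add("fsm", list(exons), "FSM",
                  kept=True, reasons="nc_junction_support" if rescue_gene else "",
                  rescue=rescue_gene)

        # ISM: drop the first 1 (2 in rescue genes) transcript-order exons
        ism_skip = 2 if rescue_gene else 1
        ism_exons = [g(t) for t in range(ism_skip, n_ex)]
        ism = add("ism", sorted(ism_exons), "ISM")
        # 5' end difference vs FSM -> alternative TSS
        if strand == "+":
            span = (backbone.start, min(s for s, _ in ism_exons))
        else:
            span = (max(e for _, e in ism_exons), backbone.end)
        event_rows.append(dict(gene_id=gene, isoform=ism, partner=fsm,
                               event_type="aTSS", start=span[0], end=span[1],
                               isoform_in=fsm))

        if rescue_gene:
            # the non-canonical unsupported junction is the 5'-most one
            j0 = backbone.junctions()[0 if strand == "+" else -1]
            _write_junction_dinucs(seq, j0.donor_end, j0.acceptor_start, strand,
                                   canonical=False)
            unsupported.append(dict(chrom=chrom, donor_end=j0.donor_end,
                                    acceptor_start=j0.acceptor_start))
        else:
            # NIC: skip internal transcript exon t2 (new combination of
            # known donor/acceptor sites)
            skip = g(2)
            nic = add("nic", [e for e in exons if e != skip], "NIC")
            event_rows.append(dict(gene_id=gene, isoform=nic, partner=fsm,
                                   event_type="ES", start=skip[0], end=skip[1],
                                   isoform_in=fsm))

            # NNC: extend transcript exon t4 by nnc_shift into the next
            # intron (novel donor site)
            shift = config.nnc_shift
            e4 = g(4)
            nnc_exons = list(exons)
            idx4 = exons.index(e4)
            if strand == "+":
                nnc_exons[idx4] = (e4[0], e4[1] + shift)
                new_j = (e4[1] + shift, exons[idx4 + 1][0])
                a5_span = (e4[1], e4[1] + shift)
            else:
                nnc_exons[idx4] = (e4[0] - shift, e4[1])
                new_j = (exons[idx4 - 1][1], e4[0] - shift)
                a5_span = (e4[0] - shift, e4[0])
            nc_gene = role == "nc_filter"
            _write_junction_dinucs(seq, new_j[0], new_j[1], strand,
                                   canonical=not nc_gene)
            nnc = add("nnc", nnc_exons, "NNC",
                      kept=not nc_gene,
                      reasons="nc_junction_support" if nc_gene else "")
            if nc_gene:
                unsupported.append(dict(chrom=chrom, donor_end=new_j[0],
                                        acceptor_start=new_j[1]))
            # the shifted site is the transcript-direction donor on either
            # strand, so the planted event is A5 regardless of strand
            event_rows.append(dict(gene_id=gene, isoform=nnc, partner=fsm,
                                   event_type="A5",
                                   start=a5_span[0], end=a5_span[1],
                                   isoform_in=nnc))

        if role == "ir":
            # IR: merge transcript exons t3 and t4 (retain intron t3);
            # all splice sites remain known -> structurally NIC
            ga, gb = sorted((_t2g(3, n_ex, strand), _t2g(4, n_ex, strand)))
            merged = (exons[ga][0], exons[gb][1])
            ir_exons = [e for k, e in enumerate(exons) if k not in (ga, gb)]
            ir_exons.append(merged)
            ir_iso = add("ir", sorted(ir_exons), "NIC", ir_label=True)
            intron = (exons[ga][1], exons[gb][0])
            event_rows.append(dict(gene_id=gene, isoform=ir_iso, partner=fsm,
                                   event_type="IR", start=intron[0], end=intron[1],
                                   isoform_in=ir_iso))
            ir_span_rows.append(dict(gene_id=gene, chrom=chrom,
                                     start=intron[0], end=intron[1]))

        if role == "intra_priming":
            # FSM-category isoform with a 100-nt 3' extension whose
            # downstream 20-mer is adenine-rich (genomic sense)
            ipr_exons = list(exons)
            if strand == "+":
                ipr_exons[-1] = (exons[-1][0], exons[-1][1] + 100)
                _write(seq, ipr_exons[-1][1], _A_RICH_20)
                span = (exons[-1][1], ipr_exons[-1][1])
            else:
                ipr_exons[0] = (exons[0][0] - 100, exons[0][1])
                _write(seq, ipr_exons[0][0] - 20, _T_RICH_20)
                span = (ipr_exons[0][0], exons[0][0])
            ipr = add("ipr", ipr_exons, "FSM", kept=False, reasons="intra_priming")
            event_rows.append(dict(gene_id=gene, isoform=ipr, partner=fsm,
                                   event_type="aTTS", start=span[0], end=span[1],
                                   isoform_in=ipr))

        # guard the shared 3'-end window so background sequence never trips
        # the intra-priming filter on non-planted isoforms
        if strand == "+":
            _write(seq, exons[-1][1], _BALANCED_20)
        else:
            _write(seq, exons[0][0] - 20, _BALANCED_20)

        genome[chrom] = seq.decode()

    isoforms = pd.DataFrame(iso_rows).set_index("isoform_id", drop=False)
    truth = SyntheticTruth(
        isoforms=isoforms,
        planted_if=pd.DataFrame(),
        switches=pd.DataFrame(columns=["gene_id", "up_isoform", "down_isoform", "dif"]),
        events=pd.DataFrame(event_rows),
        ir_profile=pd.DataFrame(columns=["gene_id", "timepoint_h", "fraction"]),
        domain_losses=pd.DataFrame(columns=["gene_id", "bearer", "loser",
                                            "domain_name", "expected_type"]),
        factors=pd.DataFrame(columns=["factor_id", "target_isoform", "rho", "has_own_ir"]),
        unsupported_junctions=pd.DataFrame(
            unsupported, columns=["chrom", "donor_end", "acceptor_start"]
        ),
        ir_spans=pd.DataFrame(ir_span_rows, columns=["gene_id", "chrom", "start", "end"]),
        gene_sets={},
    )
    ds = SyntheticDataset(config=config, reference=reference, queries=queries,
                          genome=genome, truth=truth)
    _plant_fractions(ds, rng)
    return ds


# ---------------------------------------------------------------------------
# planted isoform fractions
# ---------------------------------------------------------------------------

def _plant_fractions(ds: SyntheticDataset, rng: np.random.Generator) -> None:
    cfg = ds.config
    truth = ds.truth
    tps = list(cfg.timepoints)
    if_rows, switch_rows, profile_rows = [], [], []
    for gene, sub in truth.isoforms.groupby("gene_id", sort=True):
        ids = list(sub.index)
        role = sub["role"].iloc[0]
        k = len(ids)
        base = 0.6 * rng.dirichlet(np.full(k, 2.0)) + 0.4 / k
        per_tp = {tp: base.copy() for tp in tps}
        if role == "switch":
            up, down = ids.index(f"{gene}.fsm"), ids.index(f"{gene}.nic")
            dif = float(rng.uniform(*cfg.dif_range))
            need = dif + 0.05
            if base[down] < need:
                deficit = need - base[down]
                others = [i for i in range(k) if i != down]
                take = base[others] / base[others].sum() * deficit
                base[others] -= take
                base[down] = need
            stim = base.copy()
            stim[up] += dif
            stim[down] -= dif
            per_tp = {tp: (base.copy() if tp == tps[0] else stim.copy()) for tp in tps}
            switch_rows.append(dict(gene_id=gene, up_isoform=ids[up],
                                    down_isoform=ids[down], dif=dif))
        elif role == "ir":
            ir_idx = ids.index(f"{gene}.ir")
            fracs = np.concatenate([[cfg.ir_base],
                                    cfg.ir_base + np.cumsum(cfg.ir_increments)])
            others = np.array([i for i in range(k) if i != ir_idx])
            rel = base[others] / base[others].sum()
            for tp, f in zip(tps, fracs[: len(tps)]):
                p = np.empty(k)
                p[ir_idx] = f
                p[others] = (1.0 - f) * rel
                per_tp[tp] = p
                profile_rows.append(dict(gene_id=gene, timepoint_h=tp, fraction=float(f)))
        for tp in tps:
            p = np.clip(per_tp[tp], 0.005, None)
            p = p / p.sum()
            for iso, v in zip(ids, p):
                if_rows.append(dict(isoform_id=iso, gene_id=gene,
                                    timepoint_h=tp, IF=float(v)))
    truth.planted_if = pd.DataFrame(if_rows)
    truth.switches = pd.DataFrame(
        switch_rows, columns=["gene_id", "up_isoform", "down_isoform", "dif"]
    )
    truth.ir_profile = pd.DataFrame(
        profile_rows, columns=["gene_id", "timepoint_h", "fraction"]
    )
    ir_genes = sorted(truth.isoforms.loc[truth.isoforms["role"] == "ir", "gene_id"].unique())
    plain = sorted(truth.isoforms.loc[truth.isoforms["role"] == "plain", "gene_id"].unique())
    truth.gene_sets = {"isg": ir_genes, "housekeeping": plain}


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(ds: SyntheticDataset, rng: Optional[np.random.Generator] = None) -> None:
    """Dirichlet-multinomial isoform counts for every sample; fills
    ``ds.design`` and ``ds.counts``."""
    cfg = ds.config
    rng = rng or np.random.default_rng(cfg.seed + 1)
    truth = ds.truth
    tps = list(cfg.timepoints)
    design_rows = []
    for tp in tps:
        for rep in range(1, cfg.n_replicates + 1):
            design_rows.append(dict(
                sample_id=f"t{tp}_r{rep}",
                condition="unstim" if tp == tps[0] else "stim",
                timepoint_h=tp, replicate=rep,
            ))
    design = pd.DataFrame(design_rows)

    pif = truth.planted_if.pivot_table(index="isoform_id", columns="timepoint_h",
                                       values="IF")
    gene_of = truth.isoforms["gene_id"]
    genes = sorted(gene_of.unique())
    iso_by_gene = {g: sorted(gene_of.index[gene_of == g]) for g in genes}
    shares = rng.lognormal(0.0, 0.5, len(genes))
    shares /= shares.sum()

    counts = pd.DataFrame(0, index=sorted(gene_of.index), columns=design["sample_id"],
                          dtype=int)
    for row in design.itertuples(index=False):
        gene_totals = rng.multinomial(cfg.library_size, shares)
        for g, total in zip(genes, gene_totals):
            isos = iso_by_gene[g]
            p = pif.loc[isos, row.timepoint_h].to_numpy(float)
            theta = rng.dirichlet(cfg.concentration * p)
            counts.loc[isos, row.sample_id] = rng.multinomial(total, theta)

    lengths = pd.Series({tx.transcript_id: tx.length for tx in ds.queries})
    ds.design = design
    ds.counts = CountMatrix(counts.astype(float), lengths)


# ---------------------------------------------------------------------------
# junction support
# ---------------------------------------------------------------------------

def simulate_junction_support(ds: SyntheticDataset,
                              rng: Optional[np.random.Generator] = None) -> None:
    """Poisson unique/multi read support per junction and sample, with the
    planted unsupported set forced to zero in every sample."""
    from .io import JunctionSupportTable

    cfg = ds.config
    rng = rng or np.random.default_rng(cfg.seed + 2)
    if ds.design is None:
        samples = [f"t{tp}_r{r}" for tp in cfg.timepoints
                   for r in range(1, cfg.n_replicates + 1)]
    else:
        samples = list(ds.design["sample_id"])
    blocked = {
        (r.chrom, int(r.donor_end), int(r.acceptor_start))
        for r in ds.truth.unsupported_junctions.itertuples(index=False)
    }
    keys = sorted({
        (j.chrom, j.donor_end, j.acceptor_start)
        for tx in list(ds.reference) + list(ds.queries)
        for j in tx.junctions()
    })
    per_sample = {}
    for s in samples:
        uniq = rng.poisson(cfg.sj_mean_unique, len(keys))
        multi = rng.poisson(cfg.sj_mean_multi, len(keys))
        df = pd.DataFrame(
            dict(chrom=[k[0] for k in keys],
                 donor_end=[k[1] for k in keys],
                 acceptor_start=[k[2] for k in keys],
                 unique_reads=uniq, multi_reads=multi)
        )
        mask = [k in blocked for k in keys]
        df.loc[mask, "unique_reads"] = 0
        per_sample[s] = df
    ds.support = JunctionSupportTable(per_sample)


# ---------------------------------------------------------------------------
# domains, motifs, factors
# ---------------------------------------------------------------------------

def _junction_tx_pos(tx: TranscriptModel, donor_end: int, acceptor_start: int) -> int:
    for idx, j in enumerate(tx.junctions()):
        if j.coords() == (donor_end, acceptor_start):
            jpos = tx.junction_tx_positions()
            return jpos[idx if tx.strand == "+" else len(jpos) - 1 - idx]
    raise ValidationError(f"junction ({donor_end}, {acceptor_start}) not in {tx.transcript_id}")


def plant_domains_and_motifs(ds: SyntheticDataset,
                             rng: Optional[np.random.Generator] = None) -> None:
    """Domain table, motif instances written into the genome, and factor
    expression; fills ``ds.domains``, ``ds.motifs``, ``ds.factor_expr`` and
    the corresponding truth tables."""
    cfg = ds.config
    rng = rng or np.random.default_rng(cfg.seed + 3)
    truth = ds.truth
    txs = ds.transcripts()
    n_ex = cfg.n_exons

    domain_rows, loss_rows = [], []
    by_gene = truth.isoforms.groupby("gene_id", sort=True)
    ref_by_gene = {tx.gene_id: tx for tx in ds.reference}
    ir_span_by_gene = {r.gene_id: (r.start, r.end)
                       for r in truth.ir_spans.itertuples(index=False)}

    for gene, sub in by_gene:
        backbone = ref_by_gene[gene]
        exons = backbone.exons
        strand = backbone.strand
        ids = list(sub.index)

        # DOM_CORE inside the 3'-most transcript exon, on every isoform
        core_gex = exons[_t2g(n_ex - 1, n_ex, strand)]
        core_span = (core_gex[0] + 10, core_gex[0] + 40)
        for iso in ids:
            s, e = map_genome_to_tx(txs[iso], *core_span)
            domain_rows.append(dict(isoform_id=iso, domain_name="DOM_CORE",
                                    tx_start=s, tx_end=e))

        # DOM_ES inside transcript exon t2, on every isoform retaining that
        # exon (i.e. all but the exon-skipping NIC isoform)
        es_gex = exons[_t2g(2, n_ex, strand)]
        es_span = (es_gex[0] + 10, es_gex[1] - 10)
        nic_id = f"{gene}.nic"
        for iso in ids:
            if iso == nic_id:
                continue
            try:
                s, e = map_genome_to_tx(txs[iso], *es_span)
            except Exception:
                continue  # isoform does not retain the exon intact
            domain_rows.append(dict(isoform_id=iso, domain_name="DOM_ES",
                                    tx_start=s, tx_end=e))
            if nic_id in ids:
                loss_rows.append(dict(gene_id=gene, bearer=iso, loser=nic_id,
                                      domain_name="DOM_ES", expected_type="ES"))

        # DOM_IR straddling the retained intron's junction, on every
        # spliced isoform that still uses that junction
        if gene in ir_span_by_gene:
            i_start, i_end = ir_span_by_gene[gene]
            ir_id = f"{gene}.ir"
            for iso in ids:
                if iso == ir_id:
                    continue
                try:
                    jpos = _junction_tx_pos(txs[iso], i_start, i_end)
                except ValidationError:
                    continue
                domain_rows.append(dict(isoform_id=iso, domain_name="DOM_IR",
                                        tx_start=jpos - 30, tx_end=jpos + 30))
                loss_rows.append(dict(gene_id=gene, bearer=iso, loser=ir_id,
                                      domain_name="DOM_IR", expected_type="IR"))

    ds.domains = pd.DataFrame(domain_rows)
    truth.domain_losses = pd.DataFrame(
        loss_rows, columns=["gene_id", "bearer", "loser", "domain_name", "expected_type"]
    )

    # ---- motif planting -------------------------------------------------
    motif = cfg.motif_iupac  # concrete instances equal the consensus here
    klen = len(motif)
    margin = 4
    for gene, sub in by_gene:
        backbone = ref_by_gene[gene]
        strand = backbone.strand
        seq = bytearray(ds.genome[backbone.chrom].encode())
        ir_span = ir_span_by_gene.get(gene)
        regions = []
        for j in backbone.junctions():
            is_ir = ir_span == (j.donor_end, j.acceptor_start)
            dens = cfg.motif_density_per_kb * (cfg.motif_density_ratio if is_ir else 1.0)
            regions.append((j.donor_end, j.acceptor_start, dens))
        for s, e in backbone.exons:
            flanking = ir_span is not None and (e == ir_span[0] or s == ir_span[1])
            dens = cfg.motif_density_per_kb * cfg.motif_exon_scale
            if flanking:
                dens *= cfg.motif_ir_exon_scale
            regions.append((s, e, dens))
        for s, e, dens in regions:
            length = e - s
            n_inst = int(round(length * dens / 1000.0))
            if n_inst == 0:
                continue
            usable = length - 2 * margin - klen
            if usable <= 0:
                continue
            slot = usable / n_inst
            for i in range(n_inst):
                lo = margin + int(i * slot)
                hi = margin + int(min((i + 1) * slot, usable))
                if hi <= lo + 1:
                    off = lo
                else:
                    off = int(rng.integers(lo, hi))
                inst = motif if strand == "+" else _revcomp(motif)
                # place relative to the sense-strand 5' edge of the region
                gpos = s + off if strand == "+" else e - off - klen
                _write(seq, gpos, inst)
        ds.genome[backbone.chrom] = seq.decode()
    ds.motifs = pd.DataFrame([dict(name=cfg.motif_name, iupac=cfg.motif_iupac)])

    # ---- splicing factors ------------------------------------------------
    if ds.counts is None:
        simulate_counts(ds)
    from .ir import log2_cpm

    expr = log2_cpm(ds.counts.counts)
    samples = list(expr.columns)
    n_s = len(samples)
    ir_isoforms = sorted(truth.isoforms.index[truth.isoforms["ir_label"]])
    n_corr = int(round(cfg.fraction_correlated_factors * cfg.n_factors))
    factor_rows, expr_rows = [], []
    for fi in range(cfg.n_factors):
        fid = f"SF{fi:03d}"
        has_own_ir = fi >= cfg.n_factors - cfg.n_factors_with_own_ir
        correlated = fi < n_corr and fi < len(ir_isoforms) and not has_own_ir
        if correlated:
            from scipy.stats import norm

            target = ir_isoforms[fi]
            x = expr.loc[target, samples].to_numpy(float)
            ranks = pd.Series(x).rank(method="average").to_numpy()
            z = norm.ppf((ranks - 0.5) / n_s)
            eps = rng.standard_normal(n_s)
            rho = cfg.factor_rho
            # Fisher-consistent Gaussian-copula calibration: the latent
            # normal correlation giving population Spearman rho
            lat = float(np.sign(rho) * 2 * np.sin(np.pi * abs(rho) / 6))
            zf = lat * z + np.sqrt(max(0.0, 1 - lat ** 2)) * eps
            vals = 8.0 + zf
            factor_rows.append(dict(factor_id=fid, target_isoform=target,
                                    rho=rho, has_own_ir=False))
        else:
            vals = 8.0 + rng.standard_normal(n_s)
            factor_rows.append(dict(factor_id=fid, target_isoform=None,
                                    rho=0.0, has_own_ir=has_own_ir))
        expr_rows.append(pd.Series(vals, index=samples, name=fid))
    ds.factor_expr = pd.DataFrame(expr_rows)
    truth.factors = pd.DataFrame(
        factor_rows, columns=["factor_id", "target_isoform", "rho", "has_own_ir"]
    )


# ---------------------------------------------------------------------------
# one-call generation + file emission
# ---------------------------------------------------------------------------

def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Full dataset: annotation, counts, junction support, domains, motifs,
    factors, truth."""
    ds = generate_annotation(config)
    simulate_counts(ds)
    simulate_junction_support(ds)
    plant_domains_and_motifs(ds)
    return ds


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Emit the dataset as plain-text files (GTF/FASTA/TSV)."""
    from .io import write_counts_tsv, write_fasta, write_gtf

    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    write_gtf(ds.reference, out / "reference.gtf")
    write_gtf(ds.queries, out / "query.gtf")
    write_fasta(ds.genome, out / "genome.fa")
    if ds.counts is not None:
        write_counts_tsv(ds.counts, out / "counts.tsv")
        ds.design.to_csv(out / "design.tsv", sep="\t", index=False)
    if ds.support is not None:
        ds.support.to_long_frame().to_csv(out / "sj.tsv", sep="\t", index=False)
    if ds.domains is not None:
        ds.domains.to_csv(out / "domains.tsv", sep="\t", index=False)
        ds.motifs.to_csv(out / "motifs.tsv", sep="\t", index=False)
        ds.factor_expr.to_csv(out / "factors.tsv", sep="\t", index_label="factor_id")
    t = ds.truth
    t.isoforms.to_csv(out / "truth" / "isoforms.tsv", sep="\t", index=False)
    t.planted_if.to_csv(out / "truth" / "planted_if.tsv", sep="\t", index=False)
    t.switches.to_csv(out / "truth" / "switches.tsv", sep="\t", index=False)
    t.events.to_csv(out / "truth" / "events.tsv", sep="\t", index=False)
    t.ir_profile.to_csv(out / "truth" / "ir_profile.tsv", sep="\t", index=False)
    t.domain_losses.to_csv(out / "truth" / "domain_losses.tsv", sep="\t", index=False)
    t.factors.to_csv(out / "truth" / "factors.tsv", sep="\t", index=False)
    for name, genes in t.gene_sets.items():
        (out / f"{name}.txt").write_text("\n".join(genes) + "\n")
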