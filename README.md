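# spliceform

Isoform-level analysis of stimulus-induced transcriptomes, built for the
kind of question raised by interferon-stimulated B cells: when a cell is
stimulated, which transcript isoforms appear, how does their usage shift
over time, and how does alternative splicing — intron retention in
particular — strip functional domains from the proteins a gene makes?

The package provides, as composable library code under `src/spliceform/`:

* **Structural classification** of query isoforms against a reference
  annotation (FSM / ISM / NIC / NNC / other, by junction-chain and
  splice-site comparison), with long-read quality filters (intra-priming;
  unsupported non-canonical junctions with FSM rescue) and short-read
  junction concordance.
* **Isoform switching**: isoform fractions IF = count / gene total, the
  switch magnitude dIF = ΔIF between conditions, a calibrated
  differential-usage test (Welch t on logit IF, BH-corrected,
  significant at |dIF| > 0.05 and q < 0.05), top up/down pair selection,
  and functional consequences (longest-ORF, 3' UTR length, the 50-nt NMD
  rule, domain and AS-event gains/losses) with exact binomial enrichment.
* **AS-event typing** between isoform pairs (ES, A5, A3, IR, aTSS, aTTS,
  strand-resolved, with IR/ES precedence over A5/A3).
* **Domain-loss attribution**: pairwise within-gene domain comparison,
  genomic-overlap attribution of each lost copy to AS events, and the
  chi-square contrast of IR- vs non-IR-attributed losses across isoforms
  with increased vs decreased usage.
* **IR dynamics**: gene-level aggregated IR fractions, differential IR
  usage with DRIMSeq-style filters, gene-set contrasts (rank-sum), and
  Spearman screening for splicing factors anti-correlated with IR
  isoforms.
* **Motif enrichment**: exact IUPAC scanning, 10-bin 5'→3' density
  profiles per exon/intron, and per-bin one-sided rank-sum tests between
  IR and non-IR regions.
* **A synthetic-data generator** (`spliceform.simulate`) that plants
  ground truth for every stage — structural categories by construction
  rule, Dirichlet-multinomial counts with planted switches and rising IR
  time courses, attributable domain architectures, controlled motif
  densities, copula-correlated factor expression — so each stage is
  validated in a closed loop (`spliceform.validation`).

The scientific model and its parameters are documented in
[docs/methods.md](docs/methods.md).

## Worked example

The analysis is organised as numbered drivers under `analysis/`, each a
thin script over the library that writes its tables under `results/`:

```bash
python analysis/01_simulate.py          # fixtures + planted truth
python analysis/02_classify_filter.py   # categories + quality filters
python analysis/03_switch_analysis.py   # dIF, switch test, consequences
python analysis/04_domain_loss.py       # loss attribution + chi-square
python analysis/05_ir_dynamics.py       # aggregated IR, gene sets, factors
python analysis/06_motif_enrichment.py  # binned motif densities
```

On the default 200-gene dataset (seed 7) the drivers print, among other
things:

```
classified 840 isoforms -> results/classification.tsv
  category counts: {'NIC': 240, 'FSM': 220, 'ISM': 200, 'NNC': 180}
  agreement with planted categories: 1.000
  removed: 50 (intra-priming 20, unsupported non-canonical 30)
  rescued FSMs: 20
  junction concordance (>=3 unique reads, pooled): 0.963
...
tested 840 isoforms; 179 significant switches in 109 genes (|dIF| > 0.05, q < 0.05)
  planted switch isoforms recovered: 100/100
...
  IR vs non-IR x increased vs decreased (|dIF| > 0.05):
          increased  decreased
  IR            240          0
  non-IR          0        194
  chi-square = 434.000, p = 2.19e-96
...
ISG vs housekeeping aggregated dIF: one-sided rank-sum p = 9.49e-12
IR_intron vs nonIR_intron (greater): 9/10 bins with q < 0.001
```

Reading: every planted structural category is recovered; the filters
remove exactly the planted artifact isoforms while rescuing reference-
matching ones; the 100 planted switching isoforms are all called; domain
losses attributed to intron retention occur almost exclusively in
isoforms whose usage increases after stimulation (the chi-square contrast
above); aggregated IR rises over the time course in the stimulated gene
set but not in housekeeping genes; and the planted 2x motif-density excess
in retained introns is detected in essentially every bin.

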