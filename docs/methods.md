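# Methods

`spliceform` re-implements, as a tested library plus analysis pipeline, an
isoform-level view of a stimulus-induced transcriptome: how transcript
isoforms relate structurally to a reference annotation, how their usage
shifts between conditions, and how intron retention (IR) reshapes protein
output. Every stage is exercised end-to-end on synthetic data whose ground
truth is planted by construction, so the pipeline's recovery of that truth
is a measurable property, not an anecdote.

## Coordinate and strand conventions

All internal coordinates are 0-based half-open on the genomic (+) axis;
GTF (1-based closed) and STAR `SJ.out.tab` inputs are converted at the I/O
boundary. Strand is stored genomically and never re-orders stored exon
lists; donor/acceptor, TSS/TTS and transcript-coordinate semantics are
resolved by accessors. This confines strand bugs to a handful of small
functions that are covered by strand-reflection property tests (reflecting
every coordinate about a pivot and flipping strand must preserve every
event label and reverse every bin vector).

## Structural classification

A query isoform is compared with the junction chains of its assigned gene
(the gene with maximal same-strand exonic overlap; ties break to the
lexicographically smaller id and are logged):

* **FSM** — chain equal to a reference chain;
* **ISM** — a *consecutive* sub-chain of a reference chain (arbitrary
  subsets are not ISM; they fall through to NIC);
* **NNC** — any donor or acceptor coordinate absent from the gene's known
  strand-resolved site sets;
* **NIC** — all sites known but the chain is neither a full match nor a
  consecutive sub-chain;
* **other** — no gene overlap, or a mono-exonic query without a
  mono-exonic reference containing it within 50 nt end slack.

FSM matching is exact on coordinates: no fuzz is applied at internal
junctions. The implementation is validated against a brute-force oracle
that enumerates all chains, all consecutive sub-chains and the site sets
(10,000 random queries, 100% agreement required), and against planted
categories in generated annotations.

## Quality filters

Two long-read artifact filters operate on classified isoforms:

* **Intra-priming** — an isoform is removed when the 20 nt immediately
  downstream of its 3' end contain >= 60% genomic-sense adenine (window
  length configurable; the 60% threshold is the filter's defining
  parameter). This filter applies to all categories.
* **Junction support** — an isoform is removed when it contains a
  non-canonical junction (boundary dinucleotides outside GT..AG / GC..AG /
  AT..AC on its own strand) with fewer than 3 uniquely mapped supporting
  reads in every sample. FSM isoforms are *rescued* from this rule (kept,
  with the would-be removal recorded), which matters precisely when a
  reference junction is itself non-canonical and unsupported in the
  short-read data at hand. A `novel_only` switch restricts the rule to
  reference-novel junctions for users who want the narrower behavior;
  novel *canonical* junctions are never support-filtered.

## AS-event typing

Events between two isoforms of one gene are typed on genomic coordinates
with strand-resolved labels: IR (an exon of one isoform strictly contains
an intron of the other), ES (an intron fully contains an internal exon;
one event per skipped exon), A5/A3 (junction pairs sharing the
strand-resolved acceptor/donor and differing at the other site; the
isoform with the longer exon "possesses" the event), and aTSS/aTTS
(transcript ends differing by >= 50 nt; the threshold suppresses
end-position jitter from transcript collapsing while keeping genuine
alternative ends). Junction pairs consumed by IR or ES are not re-reported
as A5/A3. Mutually exclusive exons are not a separate type; they surface
as two ES events. An isoform is IR-labeled iff it retains at least one
intron of any same-gene companion.

## Isoform fractions and the switch test

IF (isoform fraction) is an isoform's count over its gene's total in a
sample; a zero gene total yields a missing value, never a zero. dIF is the
difference of condition-mean IFs, so per gene the dIFs of all isoforms sum
to zero. The differential-usage test is a deliberately simple,
deterministic stand-in for DEXSeq/DRIMSeq-style machinery: a Welch
two-sample t-test on logit-transformed per-replicate IFs,
logit(x) = ln((x + 0.01) / (1 − x + 0.01)), BH-corrected across isoforms,
with significance at |dIF| > 0.05 and q < 0.05. The same machinery tests
gene-level aggregated IR fractions, after DRIMSeq-style inclusion filters
(gene count >= 10 in >= 3 samples; IR fraction > 0.01 in >= 1 sample).
The stand-in is calibrated rather than assumed: on a null simulation
(2,000 isoforms, n = 5/group) its empirical type-I error at nominal 0.05
must fall in [0.03, 0.07], and planted |dIF| >= 0.2 effects at n = 10/group
must be recovered with sensitivity >= 0.9 at observed FDR <= 0.10. Groups
with zero variance are resolved deterministically (p = 1 for equal means,
p = 0 otherwise).

Coding consequences use a longest-ORF caller (ATG-initiated, ties to the
most 5' start, minimum 30 nt) instead of an external coding-potential
predictor, NMD sensitivity uses the canonical 50-nt rule (stop codon
strictly more than 50 nt upstream of the last exon-exon junction), and
3' UTR changes are reported when the lengths differ by >= 50 nt.
Enrichment of opposing consequence pairs (shorter vs longer 3' UTR, NMD
gain vs loss, domain gain vs loss, per-type AS gain vs loss) uses the
exact two-sided binomial test against 0.5 on gene-level counts with BH
across pairs.

## Domain loss and attribution

Domain presence is compared pairwise between all ordered isoform pairs of
a gene; for each domain name, bearer copies unmatched by a loser copy
(greedy matching by genomic overlap, ties to the leftmost copy) are loss
events carrying the bearer copy's genomic intervals. Attribution overlaps
the AS-event span with the genomic *hull* (min start to max end) of the
lost copy: a domain encoded across a splice junction abuts the retained
intron on both sides in split coordinates, so split-interval overlap would
structurally never attribute an IR-driven loss; the hull reproduces the
interval-overlap behavior of BED-style domain ranges. Adjacency (zero
overlap) never attributes. Losses attributed to both IR and a non-IR type
count once in the IR row of the 2x2 contrast {IR, non-IR} x {loser dIF
increased, decreased}, tested by Pearson chi-square without continuity
correction (the classical statistic; the hand-checkable table
[[30,10],[15,25]] gives 11.4286 on 1 df).

## IR dynamics, correlation, motifs

Aggregated IR fraction per gene/sample is the summed count of IR-labeled
isoforms over the gene total; IR and non-IR fractions conserve to 1 within
1e-9 wherever defined. Gene-set contrasts (e.g. interferon-stimulated vs
housekeeping genes; both are user-supplied lists) compare aggregated dIFs
with the one-sided exact/asymptotic rank-sum test. Splicing-factor screens
compute Spearman correlation between factor expression and IR-isoform
expression on log2(CPM+1) values — a simple, monotone variance-compressing
transform standing in for model-based variance stabilization — and flag
rho <= −0.9; factors carrying IR isoforms of their own are excluded before
testing. Motif analysis scans IUPAC consensus strings exactly on the sense
strand of each distinct exon/intron (overlapping matches counted, N in the
sequence never matches), bins match starts into 10 equal-width 5'->3' bins
(last bin absorbs the remainder), and compares per-bin densities between
IR and non-IR regions with one-sided rank-sum tests, BH over the 10 bins
within one motif and class pair. "IR exons" are the exons immediately
flanking a retained intron in the spliced isoforms.

Statistical primitives are scipy/statsmodels-backed with enforced
contracts: the rank-sum test uses exact enumeration when the pooled size
is <= 12 without ties (verified against full enumeration for all sizes
<= 5) and the midrank-corrected normal approximation otherwise; BH is
step-up, order-preserving and capped at 1.

## The synthetic-data generator

Each gene lives on its own contig with a 6-exon backbone (exons 100-300
bp, introns 200-600 bp, random sequence with GT..AG dinucleotides written
at every junction, strand-resolved). Query isoforms are constructed by
rule — an FSM copy, an ISM 5'-truncation, a NIC exon-skip, an NNC with one
donor shifted 6 nt, and in IR genes an intron-retaining isoform
(structurally NIC) — so planted categories, events and IR labels are
definitionally correct, and the analysis stages are tested against them in
a closed loop. Disjoint gene roles plant the filter fixtures: genes whose
NNC junction is written non-canonical and left without read support, genes
whose reference 5'-most junction is non-canonical and unsupported (the FSM
rescue case; their ISM truncates past it), and genes with an extra
FSM-category isoform whose extended 3' end sits before an adenine-rich
20-mer. All other 3'-end windows are overwritten with a balanced 20-mer so
background sequence can never trip the intra-priming filter — removals are
exactly the planted ones.

Counts are Dirichlet-multinomial: per sample, gene totals are a
multinomial split of a 2M-read library over lognormal gene weights; within
a gene, isoform proportions draw from Dirichlet(concentration x planted
IF) and counts from a multinomial of the gene total. The concentration
default (300) was fixed from the stated study conditions for the IR time
course — recovering sample-mean aggregated IR fractions of 0.20/0.30/0.35
at 0/24/72 h within a few hundredths at n = 4 replicates, and monotone
time courses in >= 95% of genes, requires a replicate-level IF sd of about
0.025 — and corresponds to deep-coverage bulk RNA-seq with tight
biological replicates. Switch genes move a planted dIF in [0.2, 0.4] from
the skipping isoform to the full-length isoform in stimulated samples; IR
genes follow the 0.20/0.30/0.35 profile (base 0.2, increments +0.10 and
+0.05). Junction support is Poisson (mean 30 unique reads) except the
planted unsupported set, which is zero in every sample.

Domains are planted so losses are attributable by construction: a
constitutive domain in the last exon (never lost), a domain inside the
skipped exon (lost by the NIC isoform, attributable to ES), and in IR
genes a domain straddling the retained intron's junction (lost by the IR
isoform; its hull overlaps the intron, attributable to IR). Motif
instances of a concrete consensus are written into region interiors at
10/kb in non-IR introns, 2x in IR introns, and lower in exons (0.5x, and
0.5x again in IR-flanking exons), at least 4 bp from splice boundaries;
random background matches add equal noise to both classes. Factor
expression uses a Gaussian copula against the realized rank scores of each
target IR isoform's log2(CPM+1) profile, with the latent correlation set
to 2·sin(pi·rho/6) so the *population Spearman* equals the planted rho
(−0.95); 40 factors, 30 correlated, 2 flagged as carrying their own IR
isoforms (they must be excluded by the analysis), and the remainder pure
noise. False-flag rates are measured on the noise factors' pairs — pairs
involving a correlated factor and a non-target IR isoform are confounded
through the shared IR time course and genuinely co-vary, so they are not
counted as independent.

### What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: category
construction rules, within-gene count coupling, condition- and
time-dependent usage shifts, attributable domain architectures, controlled
motif-density ratios, and rank-correlated factor expression. It does not
emulate read-level phenomena (alignment error, positional coverage bias,
3' bias), overlapping genes on shared contigs, un-annotatable isoform
diversity, or uncertainty in domain calls — so passing the closed loop
demonstrates correctness of the pipeline's logic and calibration of its
tests under the stated noise model, not robustness to every artifact of
real long-read data.

## Numerical and design choices

* Chi-square without Yates correction (classical statistic, matches the
  hand-computed oracle). Ties in rank tests: midranks plus variance
  correction in the approximate branch.
* Missing values (zero gene totals, constant correlation vectors)
  propagate as NaN with a logged warning, never silently as zeros.
* Deterministic tie-breaks throughout: lexicographic ids for gene
  assignment and top-pair selection (after q-value), leftmost copies in
  domain matching, most-5' starts for equal-length ORFs.
* All randomness flows from a single seeded `numpy` generator per stage;
  identical config and seed reproduce byte-identical files.
* Problem sizes in the validation suite (200-500 genes, 10-12 samples,
  100 chi-square replicates, 10,000 oracle queries) were chosen as the
  smallest scales at which the binomial noise on each measured rate is
  comfortably below the margin it is compared against.

## Known limitations

* The Welch-on-logit stand-in ignores the mean-variance coupling a
  beta-binomial likelihood would model; it is calibrated at the
  concentrations the generator produces, and the test interface isolates
  it so a likelihood-based test can be slotted in.
* Gene assignment is overlap-greedy and does not model fusion, antisense
  or intergenic queries beyond the catch-all `other` category.
* `extractSplicingEnrichment`-style gain/loss counting uses the top
  up/down pair per gene; genes with more complex multi-isoform shifts
  contribute only that pair.
* The hmmscan `--domtblout` reader assumes the ORF starts at transcript
  position 0 when converting amino-acid envelopes to transcript
  coordinates; callers with a known ORF offset must shift the result.
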