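"""Readers and writers for the standard formats the pipeline consumes.

GTF is 1-based closed externally and converted to 0-based half-open on read;
STAR ``SJ.out.tab`` intron coordinates likewise.  Attribute parsing of GTF
lines is delegated to :mod:`gffutils`; grouping exon features into transcript
models is done here.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Optional

import pandas as pd
from gffutils.feature import feature_from_line

from .model import (
    CountMatrix,
    SpliceformError,
    SpliceJunction,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)


class GtfParseError(SpliceformError):
    pass


def read_gtf(path) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into :class:`TranscriptModel`.

    Exon features must carry ``transcript_id`` and ``gene_id`` attributes.
    Coordinates are converted from the GTF 1-based closed convention to
    0-based half-open.  Exon line order is irrelevant.
    """
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GtfParseError(
                    f"{path}: malformed GTF at line {lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise GtfParseError(f"{path}: malformed GTF at line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon feature missing {exc} attribute"
                )
            exons[tid].append((feat.start - 1, feat.end))
            prev = meta.setdefault(tid, (gid, feat.seqid, feat.strand))
            if prev != (gid, feat.seqid, feat.strand):
                raise GtfParseError(
                    f"{path}: line {lineno}: inconsistent gene/chrom/strand for {tid}"
                )
    models = []
    for tid, ex in exons.items():
        gid, chrom, strand = meta[tid]
        try:
            models.append(TranscriptModel(tid, gid, chrom, strand, ex))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return models


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    """Write exon features; round-trips coordinates with :func:`read_gtf`."""
    with open(path, "w") as fh:
        for tx in models:
            for s, e in tx.exons:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                fh.write(
                    f"{tx.chrom}\tspliceform\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_counts_tsv(path, lengths: Optional[pd.Series] = None) -> CountMatrix:
    """Counts TSV with isoform_id as the first column and one column per
    sample; an optional ``length`` column is used for isoform lengths."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" in df.columns:
        lengths = df.pop("length")
    if lengths is None:
        raise ValidationError("isoform lengths required (length column or argument)")
    return CountMatrix(df, lengths)


def write_counts_tsv(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.lengths.astype(int))
    out.to_csv(path, sep="\t", index_label="isoform_id")


def read_counts_mtx(mtx_path, isoform_path, sample_path, lengths: pd.Series) -> CountMatrix:
    """MatrixMarket counts with sidecar one-per-line id files (rows =
    isoforms, columns = samples)."""
    from scipy.io import mmread

    mat = mmread(mtx_path).toarray()
    isoforms = [l.strip() for l in open(isoform_path) if l.strip()]
    samples = [l.strip() for l in open(sample_path) if l.strip()]
    df = pd.DataFrame(mat, index=isoforms, columns=samples)
    return CountMatrix(df, lengths)


DESIGN_COLUMNS = ["sample_id", "condition", "timepoint_h", "replicate"]


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValidationError(f"design table missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in design table")
    return design


def read_star_sj(path) -> pd.DataFrame:
    """One STAR ``SJ.out.tab`` file -> DataFrame with 0-based half-open
    intron coordinates.

    STAR columns: chrom, intron start (1-based), intron end (1-based,
    inclusive), strand code (0 undefined / 1 + / 2 -), motif code, annotated
    flag, unique reads, multi reads, max overhang.
    """
    cols = [
        "chrom", "intron_first", "intron_last", "strand_code", "motif",
        "annotated", "unique_reads", "multi_reads", "overhang",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    df["donor_end"] = df["intron_first"] - 1
    df["acceptor_start"] = df["intron_last"]
    df["strand"] = df["strand_code"].map({0: ".", 1: "+", 2: "-"})
    if (df["unique_reads"] < 0).any() or (df["multi_reads"] < 0).any():
        raise ValidationError("negative read counts in SJ table")
    return df[["chrom", "donor_end", "acceptor_start", "strand",
               "motif", "annotated", "unique_reads", "multi_reads", "overhang"]]


class JunctionSupportTable:
    """Per-(junction, sample) unique/multi read support.

    Built from one STAR-style table per sample; lookup keys are genomic
    ``(chrom, donor_end, acceptor_start)`` triples (strand-agnostic, as the
    support evidence is).
    """

    def __init__(self, per_sample: dict[str, pd.DataFrame]):
        self.samples = list(per_sample)
        self._unique: dict[tuple, dict[str, int]] = defaultdict(dict)
        self._multi: dict[tuple, dict[str, int]] = defaultdict(dict)
        for sample, df in per_sample.items():
            for row in df.itertuples(index=False):
                key = (row.chrom, int(row.donor_end), int(row.acceptor_start))
                self._unique[key][sample] = int(row.unique_reads)
                self._multi[key][sample] = int(row.multi_reads)

    @classmethod
    def from_star_files(cls, paths: dict[str, str]) -> "JunctionSupportTable":
        return cls({sample: read_star_sj(p) for sample, p in paths.items()})

    @classmethod
    def from_long_table(cls, df: pd.DataFrame) -> "JunctionSupportTable":
        """Long table: chrom, donor_end, acceptor_start, sample_id,
        unique_reads, multi_reads (already 0-based half-open)."""
        return cls({str(s): sub for s, sub in df.groupby("sample_id")})

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self._unique):
            for sample in self.samples:
                rows.append(dict(
                    chrom=key[0], donor_end=key[1], acceptor_start=key[2],
                    sample_id=sample,
                    unique_reads=self._unique[key].get(sample, 0),
                    multi_reads=self._multi[key].get(sample, 0),
                ))
        return pd.DataFrame(rows)

    def _key(self, junction) -> tuple:
        if isinstance(junction, SpliceJunction):
            return (junction.chrom, junction.donor_end, junction.acceptor_start)
        return tuple(junction)

    def unique_count(self, junction, sample: str) -> int:
        return self._unique.get(self._key(junction), {}).get(sample, 0)

    def max_unique(self, junction) -> int:
        vals = self._unique.get(self._key(junction), {})
        return max(vals.values()) if vals else 0

    def supported(self, junction, min_unique: int, sample: Optional[str] = None) -> bool:
        """Support in one sample, or in at least one sample when pooled."""
        if min_unique <= 0:
            return True
        if sample is not None:
            return self.unique_count(junction, sample) >= min_unique
        return self.max_unique(junction) >= min_unique


def read_domains_tsv(path) -> pd.DataFrame:
    """Per-isoform protein-domain table: isoform_id, domain_name, tx_start,
    tx_end (0-based half-open transcript coordinates)."""
    df = pd.read_csv(path, sep="\t")
    required = {"isoform_id", "domain_name", "tx_start", "tx_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"domain table missing columns: {sorted(missing)}")
    if (df["tx_start"] >= df["tx_end"]).any():
        raise ValidationError("domain with tx_start >= tx_end")
    return df


def read_domtblout(path) -> pd.DataFrame:
    """hmmscan --domtblout reader extracting envelope coordinates.

    Target coordinates are amino-acid 1-based inclusive; they are converted
    to 0-based half-open *nucleotide* transcript coordinates assuming the
    query name is the isoform id and the ORF starts at transcript position 0
    (callers with a known ORF offset should shift tx_start/tx_end).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 23:
                raise ValidationError(f"short domtblout line: {line[:60]}...")
            domain_name, isoform_id = parts[0], parts[3]
            env_from, env_to = int(parts[19]), int(parts[20])
            rows.append(
                dict(
                    isoform_id=isoform_id,
                    domain_name=domain_name,
                    tx_start=(env_from - 1) * 3,
                    tx_end=env_to * 3,
                )
            )
    return pd.DataFrame(rows, columns=["isoform_id", "domain_name", "tx_start", "tx_end"])


def read_motifs_tsv(path) -> pd.DataFrame:
    """Motif definitions: name, iupac."""
    df = pd.read_csv(path, sep="\t")
    if not {"name", "iupac"} <= set(df.columns):
        raise ValidationError("motif table needs columns: name, iupac")
    return df


def read_gene_list(path) -> list[str]:
    """Plain text gene set, one gene per line."""
    with open(path) as fh:
        return [l.strip() for l in fh if l.strip()]
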