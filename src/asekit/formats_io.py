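"""Readers/writers for the file formats an ASE study touches, plus the domain types.

Coordinate convention: every genomic coordinate held in memory is 1-based
inclusive, the native convention of GTF and VCF. BED's 0-based half-open
coordinates appear only at the file boundary (``write_snp_coverage`` /
``read_snp_coverage``).

Spliced-transcript coordinates are 1-based positions along the mature
transcript in its own 5'->3' orientation (i.e. counted from the transcript
start after reverse-complementing minus-strand transcripts).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from gffutils.feature import feature_from_line


class FormatError(ValueError):
    """Raised for malformed or contract-violating input files."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named sequence (nucleotide or protein)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TranscriptModel:
    """One isoform: exons and (optionally) CDS intervals on the genome.

    ``exons`` and ``cds`` are lists of 1-based inclusive ``(start, end)``
    genomic intervals sorted by genomic coordinate; every CDS interval is
    contained in an exon.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"transcript {self.transcript_id}: strand must be '+' or '-'")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        prev_end = 0
        for s, e in self.exons:
            if s > e or s < 1:
                raise FormatError(
                    f"transcript {self.transcript_id}: bad exon ({s},{e})")
            if s <= prev_end:
                raise FormatError(
                    f"transcript {self.transcript_id}: overlapping exons")
            prev_end = e
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise FormatError(
                    f"transcript {self.transcript_id}: CDS ({s},{e}) "
                    "not contained in an exon")

    # ---- coordinate helpers -------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains(self, pos: int) -> bool:
        """True iff ``pos`` falls inside an exon."""
        return any(s <= pos <= e for s, e in self.exons)

    def exon_of(self, pos: int) -> Optional[tuple[int, int]]:
        for s, e in self.exons:
            if s <= pos <= e:
                return (s, e)
        return None

    def _plus_index(self, pos: int) -> int:
        """1-based index along the spliced transcript read left-to-right."""
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                return offset + (pos - s) + 1
            offset += e - s + 1
        raise ValueError(
            f"position {pos} is not exonic in transcript {self.transcript_id}")

    def genomic_to_spliced(self, pos: int) -> int:
        """Map an exonic genomic position to a 1-based spliced position."""
        i = self._plus_index(pos)
        return i if self.strand == "+" else self.spliced_length - i + 1

    def spliced_to_genomic(self, spos: int) -> int:
        """Inverse of :meth:`genomic_to_spliced`."""
        if not 1 <= spos <= self.spliced_length:
            raise ValueError(f"spliced position {spos} out of range")
        i = spos if self.strand == "+" else self.spliced_length - spos + 1
        offset = 0
        for s, e in self.exons:
            n = e - s + 1
            if i <= offset + n:
                return s + (i - offset) - 1
            offset += n
        raise AssertionError("unreachable")

    def cds_spliced_interval(self) -> Optional[tuple[int, int]]:
        """The CDS as a single 1-based inclusive interval in spliced coords."""
        if not self.cds:
            return None
        idx = []
        for s, e in self.cds:
            idx.append(self.genomic_to_spliced(s))
            idx.append(self.genomic_to_spliced(e))
        return min(idx), max(idx)


@dataclass
class GeneModel:
    """A gene: one or more isoforms sharing chromosome and strand.

    The gene span runs from the leftmost transcript start to the rightmost
    transcript end.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise FormatError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} "
                    "disagrees on chrom/strand")

    @property
    def span(self) -> tuple[int, int]:
        return (min(t.span[0] for t in self.transcripts),
                max(t.span[1] for t in self.transcripts))


@dataclass
class Variant:
    """A SNP or indel; ``pos`` is the 1-based position of the first ref base."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: Optional[str] = None
    effects: list = field(default_factory=list)
    damaging: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant at non-positive position {self.pos}")
        if self.ref == self.alt:
            raise FormatError(
                f"variant {self.chrom}:{self.pos} has ref == alt ({self.ref})")

    @property
    def vtype(self) -> str:
        return "snp" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def is_snp(self) -> bool:
        return self.vtype == "snp"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


# Parental-allele suffixes appended to transcript ids in the parental
# transcript/protein FASTAs and the xprs count tables. "_R" carries the
# reference alleles, "_A" the alternative alleles.
REF_SUFFIX = "_R"
ALT_SUFFIX = "_A"


@dataclass
class XprsCount:
    """One estimated-count row from an eXpress-style '.xprs' table."""

    target_id: str
    est_counts: float

    def __post_init__(self) -> None:
        if self.est_counts < 0:
            raise FormatError(
                f"negative est_counts for {self.target_id}")

    @property
    def transcript_id(self) -> str:
        """Target id with any parental-allele suffix stripped."""
        for suf in (REF_SUFFIX, ALT_SUFFIX):
            if self.target_id.endswith(suf):
                return self.target_id[: -len(suf)]
        return self.target_id

    @property
    def allele(self) -> Optional[str]:
        """'R', 'A', or None when the target carries no parental suffix."""
        if self.target_id.endswith(REF_SUFFIX):
            return "R"
        if self.target_id.endswith(ALT_SUFFIX):
            return "A"
        return None


@dataclass
class SnpCoverageRow:
    """Per-replicate allele counts at one SNP, as serialized to BED."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    replicate: str
    ref_count: int
    alt_count: int


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, SequenceRecord]:
    """Read a FASTA file into an ordered ``{id: SequenceRecord}`` map."""
    records: dict[str, SequenceRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id: {rec.id}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records[rec.id] = SequenceRecord(rec.id, str(rec.seq), desc)
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# --------------------------------------------------------------------------
# GTF
# --------------------------------------------------------------------------

def read_gtf(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Parse gene models from a GTF file (exon and CDS features).

    Features on chromosomes absent from any genome are retained; chromosome
    validation happens downstream where a genome is available.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
            if feat.featuretype not in {"exon", "CDS"}:
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs or not attrs["transcript_id"]:
                raise FormatError(
                    f"{path} line {lineno}: {feat.featuretype} feature "
                    "missing transcript_id")
            if "gene_id" not in attrs or not attrs["gene_id"]:
                raise FormatError(
                    f"{path} line {lineno}: {feat.featuretype} feature "
                    "missing gene_id")
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0]
            if tid in meta:
                g0, c0, s0 = meta[tid]
                if feat.strand != s0:
                    raise FormatError(
                        f"{path} line {lineno}: transcript {tid} has "
                        f"features on both strands")
                if feat.seqid != c0:
                    raise FormatError(
                        f"{path} line {lineno}: transcript {tid} spans "
                        "multiple chromosomes")
            else:
                meta[tid] = (gid, feat.seqid, feat.strand)
                order.append(tid)
            store = exons if feat.featuretype == "exon" else cds
            store.setdefault(tid, []).append((feat.start, feat.end))

    genes: dict[str, GeneModel] = {}
    per_gene: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in order:
        gid, chrom, strand = meta[tid]
        t = TranscriptModel(tid, chrom, strand,
                            exons.get(tid, []), cds.get(tid, []))
        if gid not in per_gene:
            gene_order.append(gid)
        per_gene.setdefault(gid, []).append(t)
    for gid in gene_order:
        ts = per_gene[gid]
        genes[gid] = GeneModel(gid, ts[0].chrom, ts[0].strand, ts)
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | os.PathLike,
              source: str = "asekit") -> None:
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                for s, e in t.exons:
                    fh.write("\t".join([g.chrom, source, "exon", str(s),
                                        str(e), ".", g.strand, ".",
                                        attrs]) + "\n")
                for s, e in t.cds:
                    fh.write("\t".join([g.chrom, source, "CDS", str(s),
                                        str(e), ".", g.strand, "0",
                                        attrs]) + "\n")


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> list[Variant]:
    """Read VCF records as Variants, splitting multi-allelic sites per alt.

    The genotype of the first sample is captured when present (e.g. "1/1").
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    out: list[Variant] = []
    try:
        for rec in vcf:
            gt = None
            if len(vcf.samples) > 0 and rec.genotypes:
                alleles = rec.genotypes[0]
                phased = bool(alleles[-1])
                sep = "|" if phased else "/"
                gt = sep.join(
                    "." if a == -1 else str(a) for a in alleles[:-1])
            for alt in rec.ALT:
                out.append(Variant(rec.CHROM, rec.POS, rec.REF, alt,
                                   genotype=gt))
    except Exception as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"malformed VCF record in {path}: {exc}") from exc
    return out


def write_vcf(variants: Sequence[Variant], path: str | os.PathLike,
              contigs: Optional[dict[str, int]] = None,
              sample: str = "sample") -> None:
    """Write a minimal single-sample VCF 4.2 file."""
    has_gt = any(v.genotype is not None for v in variants)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        if has_gt:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if has_gt:
            cols += ["FORMAT", sample]
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            row = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", ".", "."]
            if has_gt:
                row += ["GT", v.genotype if v.genotype is not None else "./."]
            fh.write("\t".join(row) + "\n")


# --------------------------------------------------------------------------
# samtools mpileup base column
# --------------------------------------------------------------------------

def parse_pileup_column(bases: str, ref: str, alt: str) -> tuple[int, int]:
    """Count reference and alternative allele observations in an mpileup
    base column.

    '.' and ',' count as reference; the alt letter (either case) counts as
    alternative. '^X' read-start markers consume their mapping-quality
    character, '$' read-end markers are skipped, '+n<seq>'/'-n<seq>' indel
    suffixes are consumed without counting, and '*' deletion placeholders
    and other substitution letters are ignored.
    """
    ref_count = 0
    alt_count = 0
    altU = alt.upper()
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise FormatError("dangling '^' at end of pileup string")
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise FormatError(
                    f"malformed indel suffix at offset {i} in pileup string")
            length = int(bases[i + 1:j])
            if j + length > n:
                raise FormatError(
                    f"indel suffix at offset {i} runs past end of string")
            i = j + length
            continue
        if c in ".,":
            ref_count += 1
        elif c.upper() == altU:
            alt_count += 1
        # '*', 'N', other substitutions: covered but counted for neither
        i += 1
    return ref_count, alt_count


# --------------------------------------------------------------------------
# xprs count tables
# --------------------------------------------------------------------------

def read_xprs(path: str | os.PathLike) -> list[XprsCount]:
    """Read an eXpress-style TSV with ``target_id`` and ``est_counts``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("target_id", "est_counts"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return [XprsCount(str(t), float(c))
            for t, c in zip(df["target_id"], df["est_counts"])]


def write_xprs(rows: Iterable[XprsCount], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\test_counts\n")
        for r in rows:
            fh.write(f"{r.target_id}\t{r.est_counts:.6g}\n")


# --------------------------------------------------------------------------
# SNP coverage BED
# --------------------------------------------------------------------------

def write_snp_coverage(rows: Iterable[SnpCoverageRow],
                       path: str | os.PathLike) -> None:
    """Write per-replicate SNP allele counts in a BED dialect.

    Columns: chrom, start (0-based), end (half-open), ref, alt, replicate,
    ref_count, alt_count. Sorted by (chrom, start, replicate); no header.
    """
    ordered = sorted(rows, key=lambda r: (r.chrom, r.pos - 1, r.replicate))
    with open(path, "w") as fh:
        for r in ordered:
            fh.write("\t".join([r.chrom, str(r.pos - 1), str(r.pos),
                                r.ref, r.alt, r.replicate,
                                str(r.ref_count), str(r.alt_count)]) + "\n")


def read_snp_coverage(path: str | os.PathLike) -> list[SnpCoverageRow]:
    rows: list[SnpCoverageRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise FormatError(
                    f"{path} line {lineno}: expected 8 columns, "
                    f"got {len(parts)}")
            chrom, start, end, ref, alt, rep, rc, ac = parts
            start_i, end_i = int(start), int(end)
            if end_i - start_i != 1:
                raise FormatError(
                    f"{path} line {lineno}: SNP interval must have length 1")
            rows.append(SnpCoverageRow(chrom, start_i + 1, ref, alt, rep,
                                       int(rc), int(ac)))
    return rows
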