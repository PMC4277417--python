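"""Deterministic generator of a miniature F1-hybrid ASE study.

The generator emulates the design of a hybrid of two inbred parents where
one parent is the reference strain: every variant is homozygous-alternative
in the non-reference parent (genotype 1/1), hence heterozygous with known
parental origin in the hybrid. It produces a random genome, multi-exon
multi-isoform gene models (isoforms share internal exons and differ in
terminal UTR exons, plus occasional non-coding isoforms), exonic and
intronic SNPs and indels with constructed ground-truth effect labels,
and per-replicate allele counts drawn from the binomial model the AI test
assumes:

    total ~ Poisson(mean_coverage),  ref ~ Binomial(total, theta + delta)

where theta is the transcript's true allelic ratio and delta a global
reference-bias offset (the count-level signature of residual mapping bias
after genome masking). Transcript-level estimated counts ('.xprs') carry
the heterozygous read masses of the parental pair; the no-variant mass
goes into separate total-count tables used for isoform ranking.

Truth files (theta map, effect labels, configuration) are first-class
outputs so downstream checks never re-derive ground truth.

All randomness flows from a single seed through per-stage child generators,
so outputs are bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from . import formats_io as fio
from .formats_io import (GeneModel, SequenceRecord, TranscriptModel, Variant,
                         XprsCount)

_BASES = "ACGT"
_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"
_NONSTOP_CODONS = sorted(standard_dna_table.forward_table)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate a four-tissue,
    four-replicate hybrid design with masked-genome residual bias."""

    seed: int = 0
    n_chroms: int = 2
    n_genes: int = 20
    isoforms_per_gene: tuple[int, int] = (1, 3)
    n_exons: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (60, 200)
    intergenic_length: tuple[int, int] = (200, 500)
    variants_per_kb: float = 2.0
    indel_fraction: float = 0.1
    paired_snp_fraction: float = 0.25
    libraries: tuple[str, ...] = ("brain", "kidney", "liver", "muscle")
    n_replicates: int = 4
    mean_coverage: float = 50.0
    default_theta: float = 0.5
    ai_fraction: float = 0.25
    ai_theta: float = 0.8
    ref_bias_delta: float = 0.014
    mean_transcript_reads: float = 300.0
    #: optional per-gene allelic-ratio overrides
    theta_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for theta in (self.default_theta, self.ai_theta,
                      1.0 - self.ai_theta, *self.theta_overrides.values()):
            if not 0.0 < theta < 1.0:
                raise ValueError("allelic ratio theta must lie in (0,1)")
            if not 0.0 < theta + self.ref_bias_delta < 1.0:
                raise ValueError("theta + delta outside (0,1)")
        if self.mean_coverage <= 0:
            raise ValueError("mean coverage must be positive")
        if self.n_exons[0] < 3:
            raise ValueError("genes need at least 3 exons "
                             "(pure-UTR terminal exons)")
        if self.exon_length[0] < 100:
            raise ValueError("exon length minimum too small for CDS layout")

    @property
    def stems(self) -> list[str]:
        return [f"{lib}_R{i + 1}" for lib in self.libraries
                for i in range(self.n_replicates)]

    def design(self) -> dict[str, tuple[str, str]]:
        return {f"{lib}_R{i + 1}": (lib, f"R{i + 1}")
                for lib in self.libraries for i in range(self.n_replicates)}


@dataclass
class _ExonMap:
    """One exon in transcript order: spliced and genomic intervals."""

    spliced: tuple[int, int]
    genomic: tuple[int, int]


@dataclass
class GeneLayout:
    """The generator's own bookkeeping for one gene (ground truth)."""

    gene_id: str
    chrom: str
    strand: str
    exon_maps: list[_ExonMap]  # transcript order
    spliced_seq: str
    cds_start: int  # spliced, 1-based
    cds_end: int
    master_id: str
    theta: float
    weights: dict[str, float] = field(default_factory=dict)

    def genomic_to_spliced(self, pos: int) -> Optional[int]:
        for em in self.exon_maps:
            gs, ge = em.genomic
            if gs <= pos <= ge:
                ss = em.spliced[0]
                return ss + (pos - gs if self.strand == "+" else ge - pos)
        return None

    def spliced_to_genomic(self, spos: int) -> int:
        for em in self.exon_maps:
            ss, se = em.spliced
            if ss <= spos <= se:
                gs, ge = em.genomic
                return (gs + (spos - ss) if self.strand == "+"
                        else ge - (spos - ss))
        raise ValueError(f"spliced position {spos} outside exons")


@dataclass
class TruthEffect:
    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str
    transcript_id: str
    term: str


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: dict[str, SequenceRecord]
    genes: dict[str, GeneModel]
    layouts: dict[str, GeneLayout]
    variants: list[Variant]
    variant_gene: dict[tuple, str]  # variant key -> gene_id
    truth_effects: list[TruthEffect]
    counts: dict[str, list[tuple]]  # stem -> (chrom,pos,ref,alt,rc,ac)
    xprs: dict[str, list[XprsCount]]
    totals: dict[str, dict[str, int]]  # stem -> transcript -> total reads

    @property
    def theta_by_transcript(self) -> dict[str, float]:
        out = {}
        for gid, layout in self.layouts.items():
            for t in self.genes[gid].transcripts:
                out[t.transcript_id] = layout.theta
        return out


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


# --------------------------------------------------------------------------
# reference (genome + annotation)
# --------------------------------------------------------------------------

def _build_gene(cfg: SimulationConfig, rng: np.random.Generator,
                gene_id: str, chrom: str, offset: int, strand: str,
                ) -> tuple[GeneModel, GeneLayout, str]:
    """Construct one gene starting at genomic ``offset + 1``.

    Returns the gene model, its layout and the genomic region sequence.
    """
    k = int(rng.integers(cfg.n_exons[0], cfg.n_exons[1] + 1))
    exon_lens = [int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
                 for _ in range(k)]
    intron_lens = [int(rng.integers(cfg.intron_length[0],
                                    cfg.intron_length[1] + 1))
                   for _ in range(k - 1)]
    L = sum(exon_lens)

    # CDS starts inside exon 2 and ends inside exon k-1 (transcript order),
    # leaving the terminal exons as pure UTR so isoforms may drop them.
    a = int(rng.integers(6, min(46, exon_lens[1] - 50)))
    b = int(rng.integers(6, min(46, exon_lens[-2] - 50)))
    cds_start = exon_lens[0] + a + 1
    cds_end_raw = L - exon_lens[-1] - b
    cds_len = cds_end_raw - cds_start + 1
    cds_len -= cds_len % 3
    cds_end = cds_start + cds_len - 1

    n_codons = cds_len // 3 - 2
    body = "".join(_NONSTOP_CODONS[i]
                   for i in rng.integers(0, len(_NONSTOP_CODONS),
                                         size=n_codons))
    stop = standard_dna_table.stop_codons[
        int(rng.integers(0, len(standard_dna_table.stop_codons)))]
    cds_seq = "ATG" + body + stop
    spliced = (_rand_seq(rng, cds_start - 1) + cds_seq
               + _rand_seq(rng, L - cds_end))
    assert len(spliced) == L

    # local (transcript-orientation) coordinates for exons
    local_exons: list[tuple[int, int]] = []
    spliced_exons: list[tuple[int, int]] = []
    lpos = spos = 0
    parts: list[str] = []
    for i, elen in enumerate(exon_lens):
        local_exons.append((lpos + 1, lpos + elen))
        spliced_exons.append((spos + 1, spos + elen))
        parts.append(spliced[spos:spos + elen])
        lpos += elen
        spos += elen
        if i < k - 1:
            parts.append(_rand_seq(rng, intron_lens[i]))
            lpos += intron_lens[i]
    G = lpos
    local_seq = "".join(parts)

    def to_genomic(local: tuple[int, int]) -> tuple[int, int]:
        s, e = local
        if strand == "+":
            return offset + s, offset + e
        return offset + (G - e + 1), offset + (G - s + 1)

    region_seq = local_seq if strand == "+" else _revcomp(local_seq)

    exon_maps = [_ExonMap(spliced=spliced_exons[i],
                          genomic=to_genomic(local_exons[i]))
                 for i in range(k)]

    # CDS genomic intervals: intersect spliced CDS with each exon
    cds_genomic: list[tuple[int, int]] = []
    for em, (ls, le) in zip(exon_maps, local_exons):
        ss, se = em.spliced
        lo, hi = max(ss, cds_start), min(se, cds_end)
        if lo > hi:
            continue
        # local coords of the CDS slice within this exon
        cds_genomic.append(to_genomic((ls + (lo - ss), ls + (hi - ss))))

    genomic_exons = [em.genomic for em in exon_maps]
    master_id = f"{gene_id}.1"
    transcripts = [TranscriptModel(master_id, chrom, strand,
                                   genomic_exons, cds_genomic)]

    lo_iso, hi_iso = cfg.isoforms_per_gene
    n_iso = int(rng.integers(lo_iso, hi_iso + 1))
    if n_iso >= 2 and k >= 3:
        transcripts.append(TranscriptModel(
            f"{gene_id}.2", chrom, strand, genomic_exons[1:], cds_genomic))
    if n_iso >= 3 and k >= 3:
        transcripts.append(TranscriptModel(
            f"{gene_id}.3", chrom, strand, genomic_exons[:-1], cds_genomic))
    if n_iso >= 4:
        transcripts.append(TranscriptModel(  # non-coding isoform
            f"{gene_id}.4", chrom, strand, genomic_exons[:2], []))

    gene = GeneModel(gene_id, chrom, strand, transcripts)
    weights = {master_id: 1.0}
    for t in transcripts[1:]:
        weights[t.transcript_id] = float(rng.uniform(0.2, 0.7))
    layout = GeneLayout(gene_id, chrom, strand, exon_maps, spliced,
                        cds_start, cds_end, master_id, theta=0.5,
                        weights=weights)
    return gene, layout, region_seq


def generate_reference(cfg: SimulationConfig,
                       rng: Optional[np.random.Generator] = None,
                       ) -> tuple[dict[str, SequenceRecord],
                                  dict[str, GeneModel],
                                  dict[str, GeneLayout]]:
    """Generate the genome and gene annotation."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    chrom_parts: dict[str, list[str]] = {}
    chrom_len: dict[str, int] = {}
    genome: dict[str, SequenceRecord] = {}
    genes: dict[str, GeneModel] = {}
    layouts: dict[str, GeneLayout] = {}
    for c in range(cfg.n_chroms):
        name = f"chr{c + 1}"
        chrom_parts[name] = []
        chrom_len[name] = 0
    names = sorted(chrom_parts)
    for i in range(cfg.n_genes):
        chrom = names[i % len(names)]
        gap = int(rng.integers(cfg.intergenic_length[0],
                               cfg.intergenic_length[1] + 1))
        chrom_parts[chrom].append(_rand_seq(rng, gap))
        chrom_len[chrom] += gap
        gene_id = f"g{i + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene, layout, region = _build_gene(cfg, rng, gene_id, chrom,
                                           chrom_len[chrom], strand)
        chrom_parts[chrom].append(region)
        chrom_len[chrom] += len(region)
        genes[gene_id] = gene
        layouts[gene_id] = layout
    for name in names:
        tail = int(rng.integers(cfg.intergenic_length[0],
                                cfg.intergenic_length[1] + 1))
        chrom_parts[name].append(_rand_seq(rng, tail))
        genome[name] = SequenceRecord(name, "".join(chrom_parts[name]))
    return genome, genes, layouts


# --------------------------------------------------------------------------
# variants
# --------------------------------------------------------------------------

def _codon_effect(layout: GeneLayout, spos: int, alt_base: str) -> str:
    """Ground-truth effect of substituting ``alt_base`` (transcript strand)
    at spliced position ``spos``, from the generator's own layout."""
    cs, ce = layout.cds_start, layout.cds_end
    if spos < cs:
        return "5_prime_UTR_variant"
    if spos > ce:
        return "3_prime_UTR_variant"
    ci = (spos - cs) // 3
    codon_start = cs + 3 * ci
    codon = layout.spliced_seq[codon_start - 1:codon_start + 2]
    off = spos - codon_start
    alt_codon = codon[:off] + alt_base + codon[off + 1:]
    ref_aa, alt_aa = _CODON_AA[codon], _CODON_AA[alt_codon]
    if ref_aa == alt_aa:
        return "synonymous_variant"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "missense_variant"


def generate_variants(cfg: SimulationConfig,
                      genome: dict[str, SequenceRecord],
                      genes: dict[str, GeneModel],
                      layouts: dict[str, GeneLayout],
                      rng: Optional[np.random.Generator] = None,
                      ) -> tuple[list[Variant], dict[tuple, str],
                                 list[TruthEffect]]:
    """Place SNPs/indels in genes; all genotypes 1/1 (inbred alt parent).

    Returns the variants, a variant-key -> gene_id map, and truth effect
    labels for the master isoform of each gene.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed + 1))
    variants: list[Variant] = []
    variant_gene: dict[tuple, str] = {}
    truth: list[TruthEffect] = []

    for gid, gene in genes.items():
        layout = layouts[gid]
        chrom_seq = genome[gene.chrom].seq
        lo, hi = gene.span
        n_target = max(1, round(cfg.variants_per_kb * (hi - lo + 1) / 1000))
        used: set[int] = set()

        def reserve(start: int, end: int) -> bool:
            span = range(start - 4, end + 5)
            if any(p in used for p in span):
                return False
            used.update(range(start, end + 1))
            return True

        def add_snp_at_spliced(spos: int) -> bool:
            gpos = layout.spliced_to_genomic(spos)
            if not reserve(gpos, gpos):
                return False
            ref_t = layout.spliced_seq[spos - 1]
            alt_t = _BASES[int(rng.integers(0, 4))]
            while alt_t == ref_t:
                alt_t = _BASES[int(rng.integers(0, 4))]
            term = _codon_effect(layout, spos, alt_t)
            if gene.strand == "+":
                ref_g, alt_g = ref_t, alt_t
            else:
                ref_g, alt_g = _revcomp(ref_t), _revcomp(alt_t)
            assert chrom_seq[gpos - 1] == ref_g
            v = Variant(gene.chrom, gpos, ref_g, alt_g, genotype="1/1")
            variants.append(v)
            variant_gene[v.key] = gid
            truth.append(TruthEffect(gene.chrom, gpos, ref_g, alt_g, "snp",
                                     layout.master_id, term))
            return True

        L = len(layout.spliced_seq)
        cds_bounds = {layout.cds_start, layout.cds_end}
        placed = 0
        attempts = 0
        while placed < n_target and attempts < 50 * n_target:
            attempts += 1
            make_indel = rng.random() < cfg.indel_fraction
            exonic = rng.random() < 0.85
            if make_indel:
                if not exonic:
                    continue  # keep indels exonic: the interesting case
                dl = int(rng.integers(1, 4))
                em = layout.exon_maps[int(rng.integers(0,
                                                       len(layout.exon_maps)))]
                gs, ge = em.genomic
                if ge - gs < dl + 8:
                    continue
                gpos = int(rng.integers(gs + 2, ge - dl - 2))
                span_s = [layout.genomic_to_spliced(p)
                          for p in range(gpos, gpos + dl + 1)]
                if any(abs(s - b) < 7 for s in span_s for b in cds_bounds):
                    continue
                if rng.random() < 0.5:  # deletion
                    ref_g = chrom_seq[gpos - 1:gpos + dl]
                    alt_g = ref_g[0]
                else:  # insertion
                    ref_g = chrom_seq[gpos - 1]
                    alt_g = ref_g + _rand_seq(rng, dl)
                if not reserve(gpos, gpos + len(ref_g) - 1):
                    continue
                v = Variant(gene.chrom, gpos, ref_g, alt_g, genotype="1/1")
                variants.append(v)
                variant_gene[v.key] = gid
                smin = min(span_s)
                if smin < layout.cds_start:
                    term = "5_prime_UTR_variant"
                elif smin > layout.cds_end:
                    term = "3_prime_UTR_variant"
                else:
                    term = "coding_sequence_variant"
                truth.append(TruthEffect(gene.chrom, gpos, ref_g, alt_g,
                                         "indel", layout.master_id, term))
                placed += 1
                continue
            if exonic:
                spos = int(rng.integers(1, L + 1))
                if not add_snp_at_spliced(spos):
                    continue
                placed += 1
                if rng.random() < cfg.paired_snp_fraction:
                    partner = spos + int(rng.integers(5, 31))
                    if partner <= L and add_snp_at_spliced(partner):
                        placed += 1
            else:
                # intronic: a genomic position inside the master span but
                # outside every exon
                gpos = int(rng.integers(lo, hi + 1))
                if layout.genomic_to_spliced(gpos) is not None:
                    continue
                if not reserve(gpos, gpos):
                    continue
                ref_g = chrom_seq[gpos - 1]
                alt_g = _BASES[int(rng.integers(0, 4))]
                while alt_g == ref_g:
                    alt_g = _BASES[int(rng.integers(0, 4))]
                v = Variant(gene.chrom, gpos, ref_g, alt_g, genotype="1/1")
                variants.append(v)
                variant_gene[v.key] = gid
                truth.append(TruthEffect(gene.chrom, gpos, ref_g, alt_g,
                                         "snp", layout.master_id,
                                         "intron_variant"))
                placed += 1
    variants_sorted = sorted(variants, key=lambda v: v.key)
    return variants_sorted, variant_gene, truth


# --------------------------------------------------------------------------
# counts
# --------------------------------------------------------------------------

def assign_thetas(cfg: SimulationConfig, layouts: dict[str, GeneLayout],
                  rng: Optional[np.random.Generator] = None) -> None:
    """Assign each gene its allelic ratio: most genes balanced, a planted
    fraction skewed toward either parent (split evenly so the overall
    reference fraction stays 1/2 + delta)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed + 2))
    for gid, layout in sorted(layouts.items()):
        if gid in cfg.theta_overrides:
            layout.theta = cfg.theta_overrides[gid]
        elif rng.random() < cfg.ai_fraction:
            layout.theta = (cfg.ai_theta if rng.random() < 0.5
                            else 1.0 - cfg.ai_theta)
        else:
            layout.theta = cfg.default_theta


def simulate_counts(cfg: SimulationConfig,
                    genes: dict[str, GeneModel],
                    layouts: dict[str, GeneLayout],
                    variants: list[Variant],
                    variant_gene: dict[tuple, str],
                    rng: Optional[np.random.Generator] = None,
                    ) -> tuple[dict[str, list[tuple]],
                               dict[str, list[XprsCount]],
                               dict[str, dict[str, int]]]:
    """Draw per-replicate SNP counts, parental transcript counts, and
    total transcript counts for every replicate stem."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed + 3))
    snps = [v for v in variants if v.is_snp]
    counts: dict[str, list[tuple]] = {}
    xprs: dict[str, list[XprsCount]] = {}
    totals: dict[str, dict[str, int]] = {}
    # transcripts with at least one exonic SNP carry heterozygous reads
    has_het: dict[str, bool] = {}
    for gid, gene in genes.items():
        gene_snps = [v for v in snps if variant_gene[v.key] == gid]
        for t in gene.transcripts:
            has_het[t.transcript_id] = any(t.contains(v.pos)
                                           for v in gene_snps)
    for stem in cfg.stems:
        rows: list[tuple] = []
        for v in snps:
            theta = layouts[variant_gene[v.key]].theta
            p_ref = theta + cfg.ref_bias_delta
            total = int(rng.poisson(cfg.mean_coverage))
            ref = int(rng.binomial(total, p_ref)) if total else 0
            rows.append((v.chrom, v.pos, v.ref, v.alt, ref, total - ref))
        counts[stem] = rows
        xrows: list[XprsCount] = []
        trow: dict[str, int] = {}
        for gid, gene in genes.items():
            theta = layouts[gid].theta
            p_ref = theta + cfg.ref_bias_delta
            for t in gene.transcripts:
                tid = t.transcript_id
                if has_het[tid]:
                    het = int(rng.poisson(cfg.mean_coverage))
                    ref_h = int(rng.binomial(het, p_ref)) if het else 0
                else:
                    het = ref_h = 0
                xrows.append(XprsCount(tid + fio.REF_SUFFIX, float(ref_h)))
                xrows.append(XprsCount(tid + fio.ALT_SUFFIX,
                                       float(het - ref_h)))
                w = layouts[gid].weights.get(tid, 0.3)
                trow[tid] = het + int(rng.poisson(
                    w * cfg.mean_transcript_reads))
        xprs[stem] = xrows
        totals[stem] = trow
    return counts, xprs, totals


# --------------------------------------------------------------------------
# whole-study driver
# --------------------------------------------------------------------------

def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate a complete in-memory study from one seed."""
    ss = np.random.SeedSequence(cfg.seed)
    r_ref, r_var, r_theta, r_counts = (np.random.default_rng(c)
                                       for c in ss.spawn(4))
    genome, genes, layouts = generate_reference(cfg, r_ref)
    assign_thetas(cfg, layouts, r_theta)
    variants, variant_gene, truth = generate_variants(
        cfg, genome, genes, layouts, r_var)
    counts, xprs, totals = simulate_counts(cfg, genes, layouts, variants,
                                           variant_gene, r_counts)
    return SimulatedStudy(cfg, genome, genes, layouts, variants,
                          variant_gene, truth, counts, xprs, totals)


def write_study(study: SimulatedStudy, outdir: str | os.PathLike) -> None:
    """Write the study to disk in the standard formats."""
    outdir = str(outdir)
    for sub in ("counts", "xprs", "totals", "truth"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    fio.write_fasta(study.genome.values(),
                    os.path.join(outdir, "genome.fa"))
    fio.write_gtf(study.genes.values(), os.path.join(outdir, "genes.gtf"))
    contigs = {name: len(rec.seq) for name, rec in study.genome.items()}
    fio.write_vcf(study.variants, os.path.join(outdir, "variants.vcf"),
                  contigs=contigs)
    with open(os.path.join(outdir, "design.tsv"), "w") as fh:
        fh.write("stem\tlibrary\treplicate\n")
        for stem, (lib, rep) in study.config.design().items():
            fh.write(f"{stem}\t{lib}\t{rep}\n")
    for stem, rows in study.counts.items():
        with open(os.path.join(outdir, "counts", f"{stem}.tsv"), "w") as fh:
            fh.write("chrom\tpos\tref\talt\tref_count\talt_count\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
    for stem, xrows in study.xprs.items():
        fio.write_xprs(xrows, os.path.join(outdir, "xprs", f"{stem}.xprs"))
    for stem, trow in study.totals.items():
        with open(os.path.join(outdir, "totals", f"{stem}.tsv"), "w") as fh:
            fh.write("target_id\ttot_counts\n")
            for tid, n in trow.items():
                fh.write(f"{tid}\t{n}\n")
    with open(os.path.join(outdir, "truth", "theta.tsv"), "w") as fh:
        fh.write("gene_id\ttranscript_id\ttheta\n")
        for gid, layout in study.layouts.items():
            for t in study.genes[gid].transcripts:
                fh.write(f"{gid}\t{t.transcript_id}\t{layout.theta}\n")
    with open(os.path.join(outdir, "truth", "effects.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\tvtype\ttranscript_id\tterm\n")
        for e in study.truth_effects:
            fh.write(f"{e.chrom}\t{e.pos}\t{e.ref}\t{e.alt}\t{e.vtype}"
                     f"\t{e.transcript_id}\t{e.term}\n")
    with open(os.path.join(outdir, "truth", "config.json"), "w") as fh:
        json.dump(dataclasses.asdict(study.config), fh, indent=1,
                  default=list)
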