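"""Parental transcript/protein construction and variant-effect classification.

In an F1 hybrid of two inbred parents where one parent is the reference
strain, every alternative allele belongs to the non-reference parent, so
the two parental haplotypes of a transcript are simply the reference
spliced sequence and the same sequence with all known variants substituted
in. No phasing is needed.

Effect terms follow Sequence Ontology naming (5_prime_UTR_variant,
missense_variant, ...). Internally computed effects are never marked
damaging; the damaging flag comes only from external VEP (SIFT
"deleterious") or snpEff (impact HIGH) imports.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .formats_io import (FormatError, SequenceRecord, TranscriptModel,
                         Variant)

EFFECT_TERMS = {
    "5_prime_UTR_variant", "3_prime_UTR_variant", "missense_variant",
    "synonymous_variant", "stop_gained", "stop_lost", "intron_variant",
    "non_coding_variant", "coding_sequence_variant",
}


@dataclass
class ParentalTranscriptPair:
    """Reference-parent and alternative-parent sequences of one isoform."""

    transcript_id: str
    ref_seq: str
    alt_seq: str
    ref_protein: str = ""
    alt_protein: str = ""


@dataclass
class EffectAnnotation:
    """The effect of one variant on one transcript."""

    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    term: str
    damaging: bool = False
    source: str = "internal"

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def splice_transcript(genome: Mapping[str, SequenceRecord],
                      t: TranscriptModel) -> str:
    """Concatenate exon sequences 5'->3' (minus strand reverse-complemented)."""
    if t.chrom not in genome:
        raise ValueError(f"transcript {t.transcript_id}: unknown chromosome "
                         f"{t.chrom}")
    chrom_seq = genome[t.chrom].seq
    parts = []
    for s, e in t.exons:
        if e > len(chrom_seq):
            raise ValueError(
                f"transcript {t.transcript_id}: exon ({s},{e}) beyond end "
                f"of {t.chrom} (length {len(chrom_seq)})")
        parts.append(chrom_seq[s - 1:e])
    seq = "".join(parts)
    return _revcomp(seq) if t.strand == "-" else seq


def _oriented_edit(t: TranscriptModel, v: Variant) -> Optional[tuple[int, str, str]]:
    """Map a variant onto spliced coordinates as (start, ref, alt) in
    transcript orientation, or None when the ref span crosses an
    exon-intron boundary (such variants are excluded with a warning)."""
    first, last = v.pos, v.pos + len(v.ref) - 1
    exon = t.exon_of(first)
    if exon is None or last > exon[1]:
        warnings.warn(
            f"variant {v.id} spans an exon boundary of "
            f"{t.transcript_id}; excluded", stacklevel=3)
        return None
    if t.strand == "+":
        return t.genomic_to_spliced(first), v.ref, v.alt
    return t.genomic_to_spliced(last), _revcomp(v.ref), _revcomp(v.alt)


def apply_variants(t: TranscriptModel, ref_seq: str,
                   variants: Sequence[Variant]) -> ParentalTranscriptPair:
    """Substitute variants into the reference spliced sequence.

    Edits are applied in descending spliced coordinate so indel length
    changes never shift positions still to be edited. Overlapping variants
    or a ref-allele mismatch raise; boundary-spanning variants are excluded
    with a warning.
    """
    edits: list[tuple[int, str, str]] = []
    for v in variants:
        mapped = _oriented_edit(t, v)
        if mapped is None:
            continue
        s, oref, oalt = mapped
        found = ref_seq[s - 1:s - 1 + len(oref)]
        if found != oref:
            raise ValueError(
                f"ref-allele mismatch for {v.id} on {t.transcript_id}: "
                f"transcript has '{found}', expected '{oref}'")
        edits.append((s, oref, oalt))
    edits.sort(key=lambda e: e[0])
    for (s1, r1, _), (s2, _, _) in zip(edits, edits[1:]):
        if s1 + len(r1) - 1 >= s2:
            raise ValueError(
                f"overlapping variants on {t.transcript_id} at spliced "
                f"positions {s1} and {s2}")
    alt_seq = ref_seq
    for s, oref, oalt in reversed(edits):
        alt_seq = alt_seq[:s - 1] + oalt + alt_seq[s - 1 + len(oref):]

    ref_protein = alt_protein = ""
    interval = t.cds_spliced_interval()
    if interval is not None:
        cs, ce = interval
        ref_protein = translate_cds(ref_seq, cs, ce)
        # CDS start in the alt sequence shifts by upstream indel lengths
        shift = sum(len(oalt) - len(oref)
                    for s, oref, oalt in edits if s + len(oref) - 1 < cs)
        alt_protein = translate_cds(alt_seq, cs + shift)
    return ParentalTranscriptPair(t.transcript_id, ref_seq, alt_seq,
                                  ref_protein, alt_protein)


def translate_cds(seq: str, cds_start: int,
                  cds_end: Optional[int] = None) -> str:
    """Standard-code translation of ``seq[cds_start..cds_end]`` (1-based,
    inclusive), stopping at the first stop codon (not emitted); a trailing
    partial codon is ignored."""
    if cds_end is None:
        cds_end = len(seq)
    if cds_start < 1 or cds_start > len(seq):
        raise ValueError(f"CDS start {cds_start} outside sequence")
    sub = seq[cds_start - 1:cds_end]
    if len(sub) < 3:
        raise ValueError(f"CDS shorter than one codon (length {len(sub)})")
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate(to_stop=True))


def classify_effect(v: Variant, t: TranscriptModel,
                    ref_seq: str) -> EffectAnnotation:
    """Classify a variant's effect on one transcript from its anatomy.

    Exonic positions upstream of the CDS (in transcript orientation) are
    5' UTR, downstream 3' UTR; in-CDS SNPs are classified by comparing the
    reference and alternative codon translations; intronic positions within
    the transcript span are intron_variant; exonic positions of a
    transcript without CDS are non_coding_variant. In-CDS indels get the
    positional term coding_sequence_variant (codon comparison is undefined
    for length changes).
    """
    if v.chrom != t.chrom:
        raise ValueError(f"variant {v.id} not on transcript chromosome")
    lo, hi = t.span
    if not lo <= v.pos <= hi:
        raise ValueError(f"variant {v.id} outside span of {t.transcript_id}")

    def ann(term: str) -> EffectAnnotation:
        return EffectAnnotation(v.chrom, v.pos, v.ref, v.alt,
                                t.transcript_id, term)

    if not t.contains(v.pos):
        return ann("intron_variant")
    if not t.cds:
        return ann("non_coding_variant")

    cs, ce = t.cds_spliced_interval()
    if t.strand == "+":
        s = t.genomic_to_spliced(v.pos)
    else:
        # use the 5'-most transcript base of the ref span when it fits in
        # the exon, else the anchor base
        last = v.pos + len(v.ref) - 1
        s = (t.genomic_to_spliced(last) if t.contains(last)
             else t.genomic_to_spliced(v.pos))
    if s < cs:
        return ann("5_prime_UTR_variant")
    if s > ce:
        return ann("3_prime_UTR_variant")
    if not v.is_snp:
        return ann("coding_sequence_variant")

    codon_start = cs + 3 * ((s - cs) // 3)
    ref_codon = ref_seq[codon_start - 1:codon_start + 2]
    if len(ref_codon) < 3 or codon_start + 2 > ce:
        return ann("coding_sequence_variant")
    offset = s - codon_start
    alt_base = v.alt if t.strand == "+" else _revcomp(v.alt)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return ann("synonymous_variant")
    if alt_aa == "*":
        return ann("stop_gained")
    if ref_aa == "*":
        return ann("stop_lost")
    return ann("missense_variant")


# --------------------------------------------------------------------------
# external effect imports (VEP / snpEff)
# --------------------------------------------------------------------------

# legacy effect names mapped onto the internal (Sequence Ontology style)
# vocabulary; unknown terms pass through verbatim
_TERM_MAP = {
    "NON_SYNONYMOUS_CODING": "missense_variant",
    "SYNONYMOUS_CODING": "synonymous_variant",
    "UTR_5_PRIME": "5_prime_UTR_variant",
    "UTR_3_PRIME": "3_prime_UTR_variant",
    "INTRON": "intron_variant",
    "STOP_GAINED": "stop_gained",
    "STOP_LOST": "stop_lost",
}


def _map_term(term: str) -> str:
    return _TERM_MAP.get(term, term)


def _parse_vep(path: str) -> list[EffectAnnotation]:
    out: list[EffectAnnotation] = []
    header: Optional[list[str]] = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            if header is None:
                raise FormatError(f"{path}: no VEP header line found")
            row = dict(zip(header, line.split("\t")))
            uploaded = row.get("Uploaded_variation", "")
            m = re.match(r"(.+)_(\d+)_([A-Za-z]+)/([A-Za-z]+)$", uploaded)
            if not m:
                raise FormatError(
                    f"{path}: cannot parse variant id '{uploaded}' "
                    "(expected chrom_pos_ref/alt)")
            chrom, pos, ref, alt = (m.group(1), int(m.group(2)),
                                    m.group(3), m.group(4))
            term = _map_term(row.get("Consequence", "").split(",")[0])
            extra = row.get("Extra", "")
            damaging = bool(re.search(r"SIFT=deleterious\b|"
                                      r"SIFT=deleterious\(", extra))
            out.append(EffectAnnotation(chrom, pos, ref, alt,
                                        row.get("Feature", ""), term,
                                        damaging=damaging, source="vep"))
    if header is None:
        raise FormatError(f"{path}: unrecognized VEP file (no header)")
    return out


def _parse_snpeff(path: str) -> list[EffectAnnotation]:
    def find(cols: list[str], *patterns: str) -> Optional[int]:
        for i, c in enumerate(cols):
            cu = c.upper()
            if any(p in cu for p in patterns):
                return i
        return None

    out: list[EffectAnnotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        ix = {
            "chrom": find(header, "CHROM"),
            "pos": find(header, "POS"),
            "ref": find(header, "REF"),
            "alt": find(header, "ALT"),
            "feature": find(header, "FEATUREID", "TRANSCRIPT", "FEATURE"),
            "effect": find(header, "EFFECT", "ANNOTATION"),
            "impact": find(header, "IMPACT"),
        }
        missing = [k for k, v in ix.items() if v is None]
        if missing:
            raise FormatError(
                f"{path}: unrecognized snpEff header; missing "
                + ", ".join(missing))
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            impact = parts[ix["impact"]].upper()
            out.append(EffectAnnotation(
                parts[ix["chrom"]], int(parts[ix["pos"]]),
                parts[ix["ref"]], parts[ix["alt"]],
                parts[ix["feature"]],
                _map_term(parts[ix["effect"]]),
                damaging=(impact == "HIGH"), source="snpeff"))
    return out


def import_external_effects(path: str, dialect: str) -> list[EffectAnnotation]:
    """Import a VEP default-output TSV or a snpEff effect table.

    Damaging = VEP SIFT prediction "deleterious" or snpEff impact HIGH.
    """
    if dialect == "vep":
        return _parse_vep(str(path))
    if dialect == "snpeff":
        return _parse_snpeff(str(path))
    raise ValueError(f"unknown effect dialect: {dialect!r}")


def merge_effects(internal: Iterable[EffectAnnotation],
                  external: Iterable[EffectAnnotation],
                  ) -> dict[tuple, EffectAnnotation]:
    """Overlay external annotations on internal ones.

    Keyed by (chrom, pos, ref, alt, transcript_id); an imported annotation
    replaces the internally computed one for the same pair.
    """
    merged: dict[tuple, EffectAnnotation] = {}
    for a in internal:
        merged[a.variant_key + (a.transcript_id,)] = a
    for a in external:
        merged[a.variant_key + (a.transcript_id,)] = a
    return merged
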