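"""Consensus merging of variant call sets, genome masking, SNP clustering.

Masking replaces every SNP base with 'N' so that an ambiguity-aware aligner
penalizes neither allele; indels are deliberately left untouched (masking a
point base cannot represent a length change, so indel bias is only partially
addressable and is not attempted here).

Clustering exists because a sequencing read spanning several nearby SNPs
contributes to each of their counts; summing those counts over a transcript
would count the read more than once. One representative SNP per cluster of
closely spaced SNPs stands in for the cluster when transcript- and
gene-level coverage is summed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .formats_io import SequenceRecord, TranscriptModel, Variant


@dataclass
class ConsensusPolicy:
    """How per-sample call sets merge into a consensus set.

    ``min_samples``: a variant must be called identically (chrom, pos, ref,
    alt) in at least this many samples. ``expected_genotype``: when set
    (e.g. "1/1" for inbred alternative-strain reads, "0/1" for hybrid
    reads), the genotype must also match in at least ``min_samples`` of the
    occurrences.
    """

    min_samples: int = 5
    expected_genotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


def _norm_gt(gt: Optional[str]) -> Optional[str]:
    if gt is None:
        return None
    alleles = gt.replace("|", "/").split("/")
    return "/".join(sorted(alleles))


def merge_variant_sets(per_sample: Sequence[Sequence[Variant]],
                       policy: ConsensusPolicy) -> list[Variant]:
    """Merge per-sample variant lists into a consensus list.

    The result is invariant under permutation of the sample list and sorted
    by (chrom, pos, ref, alt).
    """
    if not per_sample:
        raise ValueError("merge_variant_sets: empty sample list")
    want_gt = _norm_gt(policy.expected_genotype)
    occurrences: dict[tuple, int] = {}
    gt_matches: dict[tuple, int] = {}
    exemplar: dict[tuple, Variant] = {}
    for sample in per_sample:
        seen: set[tuple] = set()
        for v in sample:
            if v.key in seen:  # defensive within-sample dedup
                continue
            seen.add(v.key)
            occurrences[v.key] = occurrences.get(v.key, 0) + 1
            if want_gt is not None and _norm_gt(v.genotype) == want_gt:
                gt_matches[v.key] = gt_matches.get(v.key, 0) + 1
            if v.key not in exemplar:
                exemplar[v.key] = v
    kept = []
    for key, n in occurrences.items():
        if n < policy.min_samples:
            continue
        if want_gt is not None and gt_matches.get(key, 0) < policy.min_samples:
            continue
        kept.append(exemplar[key])
    return sorted(kept, key=lambda v: v.key)


def mask_genome(genome: Mapping[str, SequenceRecord],
                variants: Sequence[Variant],
                ) -> tuple[dict[str, SequenceRecord], int]:
    """Replace every SNP base with 'N'; indels leave the genome unchanged.

    Returns the masked genome and the number of masked positions (distinct
    SNP (chrom, pos) pairs). The ref allele of each SNP is validated
    against the genome.
    """
    per_chrom: dict[str, set[int]] = {}
    mismatches: list[str] = []
    for v in variants:
        if not v.is_snp:
            continue
        if v.chrom not in genome:
            raise ValueError(f"SNP on unknown chromosome: {v.chrom}:{v.pos}")
        seq = genome[v.chrom].seq
        if v.pos > len(seq):
            raise ValueError(
                f"SNP beyond chromosome end: {v.chrom}:{v.pos}")
        if seq[v.pos - 1] != v.ref.upper():
            mismatches.append(
                f"{v.chrom}:{v.pos} (genome {seq[v.pos - 1]}, VCF {v.ref})")
        per_chrom.setdefault(v.chrom, set()).add(v.pos)
    if mismatches:
        raise ValueError(
            "reference-allele mismatches at: " + ", ".join(mismatches))
    masked: dict[str, SequenceRecord] = {}
    n_masked = 0
    for name, rec in genome.items():
        positions = per_chrom.get(name)
        if not positions:
            masked[name] = SequenceRecord(rec.id, rec.seq, rec.description)
            continue
        chars = list(rec.seq)
        for pos in positions:
            chars[pos - 1] = "N"
        n_masked += len(positions)
        masked[name] = SequenceRecord(rec.id, "".join(chars), rec.description)
    return masked, n_masked


@dataclass
class SnpCluster:
    """A run of closely spaced SNPs on one transcript.

    ``member_positions`` are genomic positions sorted by genomic coordinate;
    ``representative`` is the member whose counts stand in for the cluster.
    """

    member_positions: list[int]
    representative: int

    def __post_init__(self) -> None:
        if self.representative not in self.member_positions:
            raise ValueError("representative must be a cluster member")


def cluster_snps(transcript: TranscriptModel,
                 snps: Sequence[Variant],
                 coverage: Optional[Mapping[tuple, int]] = None,
                 window: int = 100) -> list[SnpCluster]:
    """Greedy left-to-right clustering of a transcript's SNPs in
    spliced-transcript coordinates.

    A SNP joins the current cluster iff its spliced distance to the
    cluster's previous member is <= ``window``. The representative is the
    member with the highest summed heterozygous coverage across libraries
    (``coverage`` maps variant key -> total count; missing keys count 0);
    ties break to the 5'-most (leftmost spliced) member. With ``window=0``
    every SNP is its own cluster.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    cov = coverage or {}
    placed = []
    for v in snps:
        if not transcript.contains(v.pos):
            raise ValueError(
                f"SNP {v.chrom}:{v.pos} outside exons of "
                f"{transcript.transcript_id}")
        placed.append((transcript.genomic_to_spliced(v.pos), v))
    placed.sort(key=lambda x: x[0])

    clusters: list[list[tuple[int, Variant]]] = []
    for spos, v in placed:
        if clusters and spos - clusters[-1][-1][0] <= window:
            clusters[-1].append((spos, v))
        else:
            clusters.append([(spos, v)])

    out = []
    for members in clusters:
        # max coverage, tie -> smallest spliced position (5'-most)
        rep = min(members,
                  key=lambda m: (-cov.get(m[1].key, 0), m[0]))[1]
        out.append(SnpCluster(sorted(m[1].pos for m in members), rep.pos))
    return out
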