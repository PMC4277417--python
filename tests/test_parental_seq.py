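"""Parental sequence construction, translation and effect classification."""

import warnings

import pytest
from Bio.Seq import Seq

from asekit import parental_seq as ps
from asekit.formats_io import SequenceRecord, TranscriptModel, Variant
from .conftest import revcomp, transcript_walk


class TestSplice:
    def test_plus_strand(self):
        genome = {"c1": SequenceRecord("c1", "ATGCCCGGG")}
        t = TranscriptModel("t", "c1", "+", exons=[(1, 3), (7, 9)])
        assert ps.splice_transcript(genome, t) == "ATGGGG"

    def test_minus_strand_reverse_complements(self):
        genome = {"c1": SequenceRecord("c1", "ATGCCCGGG")}
        t = TranscriptModel("t", "c1", "-", exons=[(1, 3), (7, 9)])
        assert ps.splice_transcript(genome, t) == "CCCCAT"

    def test_exon_beyond_end_error(self):
        genome = {"c1": SequenceRecord("c1", "ATGCCCGGG")}
        t = TranscriptModel("t", "c1", "+", exons=[(8, 12)])
        with pytest.raises(ValueError):
            ps.splice_transcript(genome, t)


class TestApplyVariants:
    def _t(self, n=6):
        return TranscriptModel("t", "c1", "+", exons=[(1, n)])

    def test_snp_substitution(self):
        pair = ps.apply_variants(self._t(), "ATGCCC",
                                 [Variant("c1", 4, "C", "T")])
        assert pair.alt_seq == "ATGTCC"

    def test_deletion_span_replacement(self):
        pair = ps.apply_variants(self._t(), "ATGCCC",
                                 [Variant("c1", 3, "GCC", "G")])
        assert pair.alt_seq == "ATGC"

    def test_zero_variants_identity(self):
        pair = ps.apply_variants(self._t(), "ATGCCC", [])
        assert pair.alt_seq == pair.ref_seq == "ATGCCC"

    def test_ref_mismatch_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            ps.apply_variants(self._t(), "ATGCCC",
                              [Variant("c1", 4, "G", "T")])

    def test_overlapping_variants_error(self):
        with pytest.raises(ValueError, match="overlap"):
            ps.apply_variants(self._t(), "ATGCCC",
                              [Variant("c1", 3, "GCC", "G"),
                               Variant("c1", 4, "C", "A")])

    def test_boundary_spanning_excluded_with_warning(self):
        t = TranscriptModel("t", "c1", "+", exons=[(1, 4), (8, 11)])
        with pytest.warns(UserWarning, match="boundary"):
            pair = ps.apply_variants(t, "ATGCCCCC",
                                     [Variant("c1", 4, "CAT", "C")])
        assert pair.alt_seq == pair.ref_seq

    def test_minus_strand_alleles_reverse_complemented(self):
        # genome AAACGTTT, exon 1-8 on '-': transcript = AAACGTTT
        t = TranscriptModel("t", "c1", "-", exons=[(1, 8)])
        ref_seq = revcomp("AAACGTTT")
        pair = ps.apply_variants(t, ref_seq, [Variant("c1", 4, "C", "T")])
        # genomic C at pos 4 is transcript G at spliced pos 5
        assert pair.alt_seq == ref_seq[:4] + "A" + ref_seq[5:]

    def test_length_bookkeeping(self):
        pair = ps.apply_variants(self._t(), "ATGCCC",
                                 [Variant("c1", 2, "T", "TAAA"),
                                  Variant("c1", 5, "CC", "C")])
        assert len(pair.alt_seq) == 6 + 3 - 1

    def test_matches_naive_sequential_oracle_on_study(self, sim_study):
        """Composed edits equal one-at-a-time edits on fresh copies."""
        checked = 0
        for gid, g in sim_study.genes.items():
            gvars = [v for v in sim_study.variants
                     if sim_study.variant_gene[v.key] == gid]
            for t in g.transcripts:
                applicable = [v for v in gvars
                              if t.contains(v.pos)
                              and t.contains(v.pos + len(v.ref) - 1)]
                walk = transcript_walk(sim_study.genome, t)
                ref_seq = "".join(b for _, b in walk)
                positions = [p for p, _ in walk]
                edits = []
                for v in applicable:
                    if t.strand == "+":
                        i = positions.index(v.pos)
                        r, a = v.ref, v.alt
                    else:
                        i = positions.index(v.pos + len(v.ref) - 1)
                        r, a = revcomp(v.ref), revcomp(v.alt)
                    edits.append((i, r, a))
                expected = ref_seq
                for i, r, a in sorted(edits, reverse=True):
                    assert expected[i:i + len(r)] == r
                    expected = expected[:i] + a + expected[i + len(r):]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pair = ps.apply_variants(t, ref_seq, applicable)
                assert pair.alt_seq == expected
                checked += 1
        assert checked >= 10


class TestTranslate:
    def test_standard_code(self):
        assert ps.translate_cds("ATGGCATAA", 1) == "MA"

    def test_immediate_stop(self):
        assert ps.translate_cds("ATGTAACCC", 1) == "M"

    def test_trailing_partial_codon_ignored(self):
        assert ps.translate_cds("ATGGCATAACC", 1) == "MA"

    def test_too_short_error(self):
        with pytest.raises(ValueError):
            ps.translate_cds("AT", 1)

    def test_start_beyond_sequence_error(self):
        with pytest.raises(ValueError):
            ps.translate_cds("ATG", 9)


class TestClassifyEffect:
    def _coding_transcript(self):
        # genome 1..40, exon 1-20, CDS 6-14: 5'UTR 1-5, CDS ATG GCA TAA
        genome = {"c1": SequenceRecord("c1",
                                       "CCCCC" + "ATGGCATAA" + "CCCCCC"
                                       + "AAAAAAAAAA")}
        t = TranscriptModel("t", "c1", "+", exons=[(1, 20)],
                            cds=[(6, 14)])
        return genome, t

    def test_missense(self):
        genome, t = self._coding_transcript()
        seq = ps.splice_transcript(genome, t)
        # GCA (Ala) -> GAA (Glu): position 10
        ann = ps.classify_effect(Variant("c1", 10, "C", "A"), t, seq)
        assert ann.term == "missense_variant"
        assert not ann.damaging and ann.source == "internal"

    def test_synonymous(self):
        genome, t = self._coding_transcript()
        seq = ps.splice_transcript(genome, t)
        # GCA -> GCG, both Ala: third codon base at position 11
        ann = ps.classify_effect(Variant("c1", 11, "A", "G"), t, seq)
        assert ann.term == "synonymous_variant"

    def test_stop_gained_and_lost(self):
        genome, t = self._coding_transcript()
        seq = ps.splice_transcript(genome, t)
        # GCA -> TCA stays Ser (missense); make TAA from GCA: pos 9 G->T
        # gives TGA? codon 2 spans 9-11 (GCA): G->T at 9 -> TCA (Ser).
        # Use the stop codon TAA at 12-14: T->C at 12 -> CAA (Gln) stop_lost
        ann = ps.classify_effect(Variant("c1", 12, "T", "C"), t, seq)
        assert ann.term == "stop_lost"
        # ATG -> TAG? pos 6 A->T gives TTG (Leu). Make stop_gained in codon
        # 2: GCA -> TGA needs two changes; instead pos 10 C->A gave Glu.
        # TAA from CAA impossible in one base of codon 2; use codon 2
        # GCA -> TCA (not stop). stop_gained: change codon 2 entirely:
        # simplest is GCA -> TGA via middle base C->G? That's GGA (Gly).
        # Build a dedicated sequence: CDS ATG TAC TAA, TAC->TAA at 3rd base
        genome2 = {"c1": SequenceRecord("c1", "ATGTACTAAGGG")}
        t2 = TranscriptModel("t2", "c1", "+", exons=[(1, 12)],
                             cds=[(1, 9)])
        seq2 = ps.splice_transcript(genome2, t2)
        ann2 = ps.classify_effect(Variant("c1", 6, "C", "A"), t2, seq2)
        assert ann2.term == "stop_gained"

    def test_utrs_and_intron_and_noncoding(self):
        genome = {"c1": SequenceRecord("c1",
                                       "CCCCC" + "ATGGCATAA" + "CCCCCC"
                                       + "AAAAAAAAAA")}
        t = TranscriptModel("t", "c1", "+", exons=[(1, 14), (18, 22)],
                            cds=[(6, 14)])
        seq = ps.splice_transcript(genome, t)
        assert ps.classify_effect(Variant("c1", 2, "C", "T"), t,
                                  seq).term == "5_prime_UTR_variant"
        assert ps.classify_effect(Variant("c1", 19, "A", "T"), t,
                                  seq).term == "3_prime_UTR_variant"
        assert ps.classify_effect(Variant("c1", 16, "A", "T"), t,
                                  seq).term == "intron_variant"
        tnc = TranscriptModel("tnc", "c1", "+", exons=[(1, 14)])
        snc = ps.splice_transcript(genome, tnc)
        assert ps.classify_effect(Variant("c1", 7, "T", "A"), tnc,
                                  snc).term == "non_coding_variant"

    def test_outside_span_error(self):
        genome, t = self._coding_transcript()
        seq = ps.splice_transcript(genome, t)
        with pytest.raises(ValueError):
            ps.classify_effect(Variant("c1", 35, "A", "T"), t, seq)

    def test_agrees_with_translate_and_diff_oracle(self, sim_study):
        """Brute-force oracle: edit the full transcript, translate both
        CDSs, classify from the protein diff and anatomy."""
        n = 0
        for v in sim_study.variants:
            if not v.is_snp:
                continue
            gid = sim_study.variant_gene[v.key]
            for t in sim_study.genes[gid].transcripts:
                lo, hi = t.span
                if not lo <= v.pos <= hi:
                    continue
                seq = ps.splice_transcript(sim_study.genome, t)
                got = ps.classify_effect(v, t, seq).term
                assert got == oracle_effect(sim_study.genome, t, v)
                n += 1
        assert n >= 30

    def test_missense_implies_protein_diff(self, sim_study):
        """A missense SNP alone changes the protein; a synonymous one
        alone does not."""
        checked = 0
        for v in sim_study.variants:
            if not v.is_snp:
                continue
            gid = sim_study.variant_gene[v.key]
            for t in sim_study.genes[gid].transcripts:
                if not (t.contains(v.pos) and t.cds):
                    continue
                seq = ps.splice_transcript(sim_study.genome, t)
                term = ps.classify_effect(v, t, seq).term
                if term not in {"missense_variant", "synonymous_variant"}:
                    continue
                pair = ps.apply_variants(t, seq, [v])
                if term == "missense_variant":
                    assert pair.ref_protein != pair.alt_protein
                else:
                    assert pair.ref_protein == pair.alt_protein
                checked += 1
        assert checked >= 5


def oracle_effect(genome, t, v):
    """Independent classification by whole-CDS substitution and diff."""
    walk = transcript_walk(genome, t)
    positions = [p for p, _ in walk]
    seq = "".join(b for _, b in walk)
    if v.pos not in positions:
        return "intron_variant"
    if not t.cds:
        return "non_coding_variant"
    cds_pos = set()
    for s, e in t.cds:
        cds_pos.update(range(s, e + 1))
    cds_idx = [j for j, p in enumerate(positions) if p in cds_pos]
    cs, ce = min(cds_idx), max(cds_idx)
    i = positions.index(v.pos)
    if i < cs:
        return "5_prime_UTR_variant"
    if i > ce:
        return "3_prime_UTR_variant"
    altb = v.alt if t.strand == "+" else revcomp(v.alt)
    alt_seq = seq[:i] + altb + seq[i + 1:]
    rp = str(Seq(seq[cs:ce + 1]).translate())
    ap = str(Seq(alt_seq[cs:ce + 1]).translate())
    if rp == ap:
        return "synonymous_variant"
    ci = (i - cs) // 3
    if ap[ci] == "*":
        return "stop_gained"
    if rp[ci] == "*":
        return "stop_lost"
    return "missense_variant"


class TestExternalEffects:
    VEP = ("## ENSEMBL VARIANT EFFECT PREDICTOR\n"
           "#Uploaded_variation\tLocation\tAllele\tGene\tFeature\t"
           "Feature_type\tConsequence\tExtra\n"
           "c1_10_C/T\tc1:10\tT\tg1\tt1\tTranscript\tmissense_variant\t"
           "SIFT=deleterious(0.01)\n"
           "c1_20_G/A\tc1:20\tA\tg1\tt1\tTranscript\tmissense_variant\t"
           "SIFT=tolerated(0.4)\n")
    SNPEFF = ("CHROM\tPOS\tREF\tALT\tANN[*].FEATUREID\tANN[*].EFFECT\t"
              "ANN[*].IMPACT\n"
              "c1\t30\tAT\tA\tt1\tframeshift_variant\tHIGH\n"
              "c1\t40\tC\tG\tt1\tmissense_variant\tMODERATE\n")

    def test_vep_sift_deleterious_marks_damaging(self, tmp_path):
        p = tmp_path / "vep.txt"
        p.write_text(self.VEP)
        anns = ps.import_external_effects(p, "vep")
        assert [a.damaging for a in anns] == [True, False]
        assert anns[0].source == "vep"
        assert anns[0].variant_key == ("c1", 10, "C", "T")

    def test_snpeff_high_impact_marks_damaging(self, tmp_path):
        p = tmp_path / "se.tsv"
        p.write_text(self.SNPEFF)
        anns = ps.import_external_effects(p, "snpeff")
        assert [a.damaging for a in anns] == [True, False]
        assert anns[0].term == "frameshift_variant"  # passthrough

    def test_unknown_dialect_error(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("foo\tbar\n")
        with pytest.raises(ValueError):
            ps.import_external_effects(p, "weird")
        with pytest.raises(Exception):
            ps.import_external_effects(p, "snpeff")

    def test_import_replaces_internal(self, tmp_path):
        internal = [ps.EffectAnnotation("c1", 10, "C", "T", "t1",
                                        "synonymous_variant")]
        p = tmp_path / "vep.txt"
        p.write_text(self.VEP)
        merged = ps.merge_effects(internal,
                                  ps.import_external_effects(p, "vep"))
        ann = merged[("c1", 10, "C", "T", "t1")]
        assert ann.source == "vep" and ann.term == "missense_variant"
        assert ann.damaging
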