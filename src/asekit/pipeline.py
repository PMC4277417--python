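"""End-to-end assembly of an ASE study from files on disk.

``run_study`` reads the genome, annotation, variants, per-replicate SNP
counts and (optionally) parental transcript counts, then computes every
derived result: per-SNP/transcript/gene allele-imbalance tests, isoform
ranks, discordance flags, variant effects, parental sequences and the
overview summary. The result object carries both the raw per-entity
results and flat pandas tables ready for the query layer.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import ase_stats, formats_io as fio, parental_seq, variant_prep
from .ase_stats import AiResult, AlleleCounts, LibraryDesign
from .formats_io import GeneModel, SequenceRecord, Variant
from .parental_seq import EffectAnnotation, ParentalTranscriptPair


@dataclass
class StudyResults:
    """Everything computed for one study."""

    design: LibraryDesign
    genome: dict[str, SequenceRecord]
    genes: dict[str, GeneModel]
    variants: list[Variant]
    variant_gene: dict[tuple, str]
    snp_counts: dict[tuple, AlleleCounts]
    snp_results: dict[tuple, AiResult]
    snp_rep_flags: dict[tuple, dict[str, bool]]
    tx_clusters: dict[str, list]
    tx_cov_results: dict[str, AiResult]
    tx_read_results: dict[str, AiResult]
    tx_rep_flags: dict[str, dict[str, bool]]
    opposite_flags: dict[str, bool]
    gene_cov_results: dict[str, AiResult]
    gene_read_results: dict[str, AiResult]
    ranks: dict[str, int]
    effects: dict[tuple, EffectAnnotation]
    pairs: dict[str, ParentalTranscriptPair]
    window: int
    snp_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    transcript_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    overview: dict = field(default_factory=dict)

    @property
    def libraries(self) -> list[str]:
        return self.design.libraries


def _read_counts_dir(counts_dir: str, design: LibraryDesign,
                     ) -> tuple[dict[tuple, AlleleCounts],
                                dict[tuple, dict]]:
    """Read per-replicate SNP count tables into AlleleCounts per variant."""
    snp_counts: dict[tuple, AlleleCounts] = {}
    for stem, (lib, rep) in design.stems.items():
        path = os.path.join(counts_dir, f"{stem}.tsv")
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing count table {path}")
        df = pd.read_csv(path, sep="\t")
        for col in ("chrom", "pos", "ref", "alt", "ref_count", "alt_count"):
            if col not in df.columns:
                raise fio.FormatError(f"{path}: missing column '{col}'")
        for row in df.itertuples():
            key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
            snp_counts.setdefault(key, AlleleCounts()).add(
                lib, rep, int(row.ref_count), int(row.alt_count))
    return snp_counts, {}


def _read_xprs_dir(xprs_dir: str, design: LibraryDesign,
                   ) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-transcript, per-library replicate-summed (ref, alt) estimates."""
    sums: dict[str, dict[str, list[float]]] = {}
    for stem, (lib, _) in design.stems.items():
        path = os.path.join(xprs_dir, f"{stem}.xprs")
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing xprs table {path}")
        for x in fio.read_xprs(path):
            if x.allele is None:
                continue
            entry = sums.setdefault(x.transcript_id, {}).setdefault(
                lib, [0.0, 0.0])
            entry[0 if x.allele == "R" else 1] += x.est_counts
    return {tid: {lib: (v[0], v[1]) for lib, v in libs.items()}
            for tid, libs in sums.items()}


def _read_totals_dir(totals_dir: str, design: LibraryDesign,
                     ) -> dict[str, float]:
    """Total reads per transcript summed over every replicate and library."""
    totals: dict[str, float] = {}
    for stem in design.stems:
        path = os.path.join(totals_dir, f"{stem}.tsv")
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing totals table {path}")
        df = pd.read_csv(path, sep="\t")
        count_col = "tot_counts" if "tot_counts" in df.columns else \
            df.columns[1]
        for tid, n in zip(df[df.columns[0]], df[count_col]):
            totals[str(tid)] = totals.get(str(tid), 0.0) + float(n)
    return totals


def run_study(genome_fa, gtf, vcf, design_tsv, counts_dir,
              xprs_dir: Optional[str] = None,
              totals_dir: Optional[str] = None,
              window: int = 100,
              vep: Optional[str] = None,
              snpeff: Optional[str] = None) -> StudyResults:
    """Assemble and analyse a complete study from its input files."""
    genome = fio.read_fasta(genome_fa)
    genes = fio.read_gtf(gtf)
    variants = fio.read_vcf(vcf)
    design = LibraryDesign.from_tsv(design_tsv)
    libraries = design.libraries
    snp_counts, _ = _read_counts_dir(counts_dir, design)

    # assign variants to genes by span
    variant_gene: dict[tuple, str] = {}
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    gene_variants: dict[str, list[Variant]] = {g: [] for g in genes}
    for gid, g in genes.items():
        lo, hi = g.span
        for v in by_chrom.get(g.chrom, []):
            if lo <= v.pos <= hi:
                gene_variants[gid].append(v)
                variant_gene.setdefault(v.key, gid)

    # per-SNP results and replicate flags
    snp_results: dict[tuple, AiResult] = {}
    snp_rep_flags: dict[tuple, dict[str, bool]] = {}
    for key, ac in snp_counts.items():
        snp_results[key] = ase_stats.snp_ai(
            f"{key[0]}:{key[1]}:{key[2]}>{key[3]}", ac, libraries)
        snp_rep_flags[key] = ase_stats.flag_replicate_discordance(ac)

    totals_cov = {key: sum(ac.total()) for key, ac in snp_counts.items()}

    xprs_sums = _read_xprs_dir(xprs_dir, design) if xprs_dir else {}
    read_totals = (_read_totals_dir(totals_dir, design) if totals_dir
                   else {tid: sum(sum(v) for v in libs.values())
                         for tid, libs in xprs_sums.items()})

    tx_clusters: dict[str, list] = {}
    tx_cov_results: dict[str, AiResult] = {}
    tx_read_results: dict[str, AiResult] = {}
    tx_rep_flags: dict[str, dict[str, bool]] = {}
    opposite_flags: dict[str, bool] = {}
    gene_cov_results: dict[str, AiResult] = {}
    gene_read_results: dict[str, AiResult] = {}
    ranks: dict[str, int] = {}
    effects: dict[tuple, EffectAnnotation] = {}
    pairs: dict[str, ParentalTranscriptPair] = {}

    for gid, g in genes.items():
        gvars = gene_variants[gid]
        per_tx_clusters: dict[str, list] = {}
        tx_results_for_gene: list[AiResult] = []
        for t in g.transcripts:
            tid = t.transcript_id
            exonic = [v for v in gvars if v.is_snp and t.contains(v.pos)
                      and v.key in snp_counts]
            clusters = variant_prep.cluster_snps(t, exonic, totals_cov,
                                                 window)
            tx_clusters[tid] = clusters
            per_tx_clusters[tid] = clusters
            member_counts = {v.key: snp_counts[v.key] for v in exonic}
            tx_cov_results[tid] = ase_stats.transcript_snp_coverage_ai(
                t, clusters, member_counts, libraries)
            # transcript-level per-replicate counts over representatives
            rep_pos = {c.representative for c in clusters}
            tx_ac = AlleleCounts()
            for v in exonic:
                if v.pos in rep_pos:
                    for (lib, rep), (r, a) in \
                            snp_counts[v.key].replicates.items():
                        tx_ac.add(lib, rep, r, a)
            tx_rep_flags[tid] = (ase_stats.flag_replicate_discordance(tx_ac)
                                 if tx_ac.replicates else
                                 {lib: False for lib in libraries})
            opposite_flags[tid] = ase_stats.flag_opposite_snps(
                [snp_results[v.key] for v in exonic])
            if tid in xprs_sums:
                res = ase_stats.transcript_read_count_ai(tid,
                                                         xprs_sums[tid])
                tx_read_results[tid] = res
                tx_results_for_gene.append(res)
            # effects + parental sequences
            ref_seq = parental_seq.splice_transcript(genome, t)
            lo_t, hi_t = t.span
            for v in gvars:
                if lo_t <= v.pos <= hi_t:
                    ann = parental_seq.classify_effect(v, t, ref_seq)
                    effects[ann.variant_key + (tid,)] = ann
            applicable = [v for v in gvars
                          if t.contains(v.pos)
                          and t.contains(v.pos + len(v.ref) - 1)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pairs[tid] = parental_seq.apply_variants(t, ref_seq,
                                                         applicable)
        gene_cov_results[gid] = ase_stats.gene_snp_coverage_ai(
            g, per_tx_clusters,
            {v.key: snp_counts[v.key] for v in gvars
             if v.is_snp and v.key in snp_counts
             and any(t.contains(v.pos) for t in g.transcripts)},
            libraries)
        if tx_results_for_gene:
            gene_read_results[gid] = ase_stats.gene_read_count_ai(
                g, tx_results_for_gene)
        ranks.update(ase_stats.rank_transcripts(g, read_totals))

    external: list[EffectAnnotation] = []
    if vep:
        external += parental_seq.import_external_effects(vep, "vep")
    if snpeff:
        external += parental_seq.import_external_effects(snpeff, "snpeff")
    if external:
        effects = parental_seq.merge_effects(effects.values(), external)

    res = StudyResults(design, genome, genes, variants, variant_gene,
                       snp_counts, snp_results, snp_rep_flags, tx_clusters,
                       tx_cov_results, tx_read_results, tx_rep_flags,
                       opposite_flags, gene_cov_results, gene_read_results,
                       ranks, effects, pairs, window)
    res.snp_table = _snp_table(res)
    res.transcript_table = _transcript_table(res)
    res.gene_table = _gene_table(res)
    res.overview = ase_stats.overview_summary(res)
    return res


# --------------------------------------------------------------------------
# flat tables
# --------------------------------------------------------------------------

def _p_cols(res: AiResult | None, libraries, measure) -> dict:
    cols = {}
    for lib in libraries:
        p = res.p_values.get(lib) if res else None
        d = res.directions.get(lib, "") if res else ""
        c = res.counts.get(lib, (0, 0)) if res else (0, 0)
        cols[f"p_{measure}:{lib}"] = np.nan if p is None else p
        cols[f"dir_{measure}:{lib}"] = d
        cols[f"counts_{measure}:{lib}"] = f"{c[0]}:{c[1]}"
    return cols


def _snp_table(st: StudyResults) -> pd.DataFrame:
    libs = st.libraries
    rows = []
    for v in st.variants:
        if not v.is_snp or v.key not in st.snp_results:
            continue
        res = st.snp_results[v.key]
        terms = sorted({a.term for k, a in st.effects.items()
                        if k[:4] == v.key})
        row = {
            "id": v.id, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt,
            "gene_id": st.variant_gene.get(v.key, ""),
            "effects": ",".join(terms),
            "damaging": any(a.damaging for k, a in st.effects.items()
                            if k[:4] == v.key),
            "flag_replicate_discordant": any(
                st.snp_rep_flags.get(v.key, {}).values()),
        }
        row.update(_p_cols(res, libs, "snp_coverage"))
        rows.append(row)
    return pd.DataFrame(rows)


def _transcript_table(st: StudyResults) -> pd.DataFrame:
    libs = st.libraries
    rows = []
    for gid, g in st.genes.items():
        for t in g.transcripts:
            tid = t.transcript_id
            exonic = [v for v in st.variants
                      if v.is_snp and v.chrom == t.chrom
                      and t.contains(v.pos)]
            n_cov = sum(
                1 for v in exonic if v.key in st.snp_counts and any(
                    sum(st.snp_counts[v.key].library_sum(lib)) >=
                    ase_stats.MIN_HET_COUNT for lib in libs))
            n_ai = sum(1 for v in exonic
                       if v.key in st.snp_results
                       and st.snp_results[v.key].any_ai())
            n_mis = sum(1 for v in exonic
                        if st.effects.get(v.key + (tid,)) is not None
                        and st.effects[v.key + (tid,)].term ==
                        "missense_variant")
            n_dam = sum(1 for v in exonic
                        if st.effects.get(v.key + (tid,)) is not None
                        and st.effects[v.key + (tid,)].damaging)
            row = {
                "id": tid, "gene_id": gid,
                "rank": st.ranks.get(tid, 0),
                "n_snps": len(exonic),
                "n_snps_covered": n_cov,
                "n_snps_ai": n_ai,
                "n_missense": n_mis,
                "n_damaging": n_dam,
                "flag_opposite_snps": st.opposite_flags.get(tid, False),
                "flag_replicate_discordant": any(
                    st.tx_rep_flags.get(tid, {}).values()),
            }
            row.update(_p_cols(st.tx_cov_results.get(tid), libs,
                               "snp_coverage"))
            row.update(_p_cols(st.tx_read_results.get(tid), libs,
                               "read_count"))
            rows.append(row)
    return pd.DataFrame(rows)


def _gene_table(st: StudyResults) -> pd.DataFrame:
    libs = st.libraries
    rows = []
    for gid, g in st.genes.items():
        lo, hi = g.span
        n_snps = sum(1 for v in st.variants
                     if v.is_snp and v.chrom == g.chrom and lo <= v.pos <= hi)
        row = {
            "id": gid,
            "chrom": g.chrom,
            "start": lo,
            "end": hi,
            "n_transcripts": len(g.transcripts),
            "n_snps": n_snps,
        }
        row.update(_p_cols(st.gene_cov_results.get(gid), libs,
                           "snp_coverage"))
        row.update(_p_cols(st.gene_read_results.get(gid), libs,
                           "read_count"))
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(st: StudyResults, outdir: str) -> None:
    """Write the study tables and overview to ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    st.snp_table.to_csv(os.path.join(outdir, "snp_ai.tsv"), sep="\t",
                        index=False, na_rep="NA")
    st.transcript_table.to_csv(os.path.join(outdir, "transcript_ai.tsv"),
                               sep="\t", index=False, na_rep="NA")
    st.gene_table.to_csv(os.path.join(outdir, "gene_ai.tsv"), sep="\t",
                         index=False, na_rep="NA")
    with open(os.path.join(outdir, "overview.txt"), "w") as fh:
        fh.write(ase_stats.render_overview(st.overview))
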