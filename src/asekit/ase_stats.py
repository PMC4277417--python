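"""Allelic-imbalance statistics at SNP, transcript and gene level.

The allele-imbalance (AI) test is a two-sided exact binomial test of the
reference-allele count against a 1:1 null. With a symmetric null the
two-sided p-value equals the doubled upper tail,

    p = min(1, 2 * P(X >= max(ref, alt))),   X ~ Binomial(ref + alt, 1/2).

Counts are accumulated per replicate and summed per library; tests run on
the library sums. Entities below the coverage floor (20 heterozygous
counts; for transcripts/genes, at least one member SNP with >= 20 in that
library for the SNP-coverage measure, or summed read counts >= 20 for the
read-count measure) get an undefined p-value rather than an unreliable one.

Two quality flags guard the summed tests: a replicate that individually
points the opposite way from its library sum (2x2 chi-square, p < 0.05)
flags the entity as replicate-discordant, and a transcript with two
significantly imbalanced SNPs pointing in opposite directions within one
library is flagged as internally inconsistent (a signature of isoform
mixtures or genotyping error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .formats_io import GeneModel, TranscriptModel, Variant
from .variant_prep import SnpCluster

#: minimum heterozygous count for a defined p-value
MIN_HET_COUNT = 20
#: significance threshold used for AI calls and flags
AI_ALPHA = 0.05

REF_GT = "ref>alt"
ALT_GT = "alt>ref"
TIE = "tie"


@dataclass
class LibraryDesign:
    """Maps replicate file stems to (library, replicate) labels.

    Mirrors the file-naming convention of a multi-condition, multi-replicate
    design (library = condition, e.g. tissue).
    """

    stems: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.stems:
            raise ValueError("design with no replicates")
        seen = set()
        for stem, (lib, rep) in self.stems.items():
            if (lib, rep) in seen:
                raise ValueError(f"duplicate replicate label {lib}/{rep}")
            seen.add((lib, rep))

    @property
    def libraries(self) -> list[str]:
        out: list[str] = []
        for lib, _ in self.stems.values():
            if lib not in out:
                out.append(lib)
        return out

    def replicates(self, library: str) -> list[str]:
        return [rep for lib, rep in self.stems.values() if lib == library]

    @classmethod
    def from_tsv(cls, path) -> "LibraryDesign":
        df = pd.read_csv(path, sep="\t")
        for col in ("stem", "library", "replicate"):
            if col not in df.columns:
                raise ValueError(f"design file missing column '{col}'")
        return cls({str(r.stem): (str(r.library), str(r.replicate))
                    for r in df.itertuples()})


@dataclass
class AlleleCounts:
    """Per-replicate (ref, alt) counts for one entity."""

    replicates: dict[tuple[str, str], tuple[int, int]] = field(
        default_factory=dict)

    def add(self, library: str, replicate: str, ref: int, alt: int) -> None:
        if ref < 0 or alt < 0:
            raise ValueError("negative allele count")
        prev = self.replicates.get((library, replicate), (0, 0))
        self.replicates[(library, replicate)] = (prev[0] + ref, prev[1] + alt)

    def library_sum(self, library: str) -> tuple[int, int]:
        ref = alt = 0
        for (lib, _), (r, a) in self.replicates.items():
            if lib == library:
                ref += r
                alt += a
        return ref, alt

    def library_replicates(self, library: str) -> dict[str, tuple[int, int]]:
        return {rep: ra for (lib, rep), ra in self.replicates.items()
                if lib == library}

    @property
    def libraries(self) -> list[str]:
        out: list[str] = []
        for lib, _ in self.replicates:
            if lib not in out:
                out.append(lib)
        return out

    def total(self) -> tuple[int, int]:
        ref = sum(r for r, _ in self.replicates.values())
        alt = sum(a for _, a in self.replicates.values())
        return ref, alt


@dataclass
class AiResult:
    """Per-library allele-imbalance result for one entity."""

    entity_id: str
    level: str  # snp | transcript | gene
    measure: str  # snp_coverage | read_count
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    p_values: dict[str, Optional[float]] = field(default_factory=dict)
    directions: dict[str, str] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)

    def is_ai(self, library: str, alpha: float = AI_ALPHA) -> bool:
        p = self.p_values.get(library)
        return p is not None and p < alpha

    def any_ai(self, alpha: float = AI_ALPHA) -> bool:
        return any(self.is_ai(lib, alpha) for lib in self.p_values)


def direction_of(ref: int, alt: int) -> str:
    if ref > alt:
        return REF_GT
    if alt > ref:
        return ALT_GT
    return TIE


def binomial_ai(ref: int, alt: int) -> float:
    """Two-sided exact binomial p-value against a 1:1 allele ratio."""
    if ref < 0 or alt < 0:
        raise ValueError("negative allele count")
    n = ref + alt
    if n == 0:
        raise ValueError("binomial_ai requires ref + alt > 0")
    m = max(ref, alt)
    return min(1.0, 2.0 * float(stats.binom.sf(m - 1, n, 0.5)))


def snp_ai(entity_id: str, counts: AlleleCounts,
           libraries: Optional[Sequence[str]] = None) -> AiResult:
    """Per-library AI test on a SNP's summed heterozygous counts.

    Libraries whose summed coverage is below ``MIN_HET_COUNT`` get an
    undefined p-value. Only SNPs carry heterozygous counts (indel counts
    are never computed).
    """
    libs = list(libraries) if libraries is not None else counts.libraries
    res = AiResult(entity_id, "snp", "snp_coverage")
    for lib in libs:
        ref, alt = counts.library_sum(lib)
        res.counts[lib] = (ref, alt)
        res.directions[lib] = direction_of(ref, alt)
        if ref + alt >= MIN_HET_COUNT:
            res.p_values[lib] = binomial_ai(ref, alt)
        else:
            res.p_values[lib] = None
    return res


def transcript_snp_coverage_ai(
        t: TranscriptModel,
        clusters: Sequence[SnpCluster],
        snp_counts: Mapping[tuple, AlleleCounts],
        libraries: Sequence[str]) -> AiResult:
    """Transcript-level AI from summed SNP coverage.

    Counts are summed over cluster representatives only, so a read spanning
    several nearby SNPs is not counted once per SNP. The p-value for a
    library is defined only when at least one member SNP (any member, not
    just representatives) reaches ``MIN_HET_COUNT`` there.
    """
    res = AiResult(t.transcript_id, "transcript", "snp_coverage")
    rep_positions = {c.representative for c in clusters}
    reps = [(key, ac) for key, ac in snp_counts.items()
            if key[1] in rep_positions]
    for lib in libraries:
        ref = alt = 0
        for _, ac in reps:
            r, a = ac.library_sum(lib)
            ref += r
            alt += a
        covered = any(sum(ac.library_sum(lib)) >= MIN_HET_COUNT
                      for ac in snp_counts.values())
        res.counts[lib] = (ref, alt)
        res.directions[lib] = direction_of(ref, alt)
        res.p_values[lib] = (binomial_ai(ref, alt)
                             if covered and ref + alt > 0 else None)
    return res


def round_half_up(x: float) -> int:
    if x < 0:
        raise ValueError("negative count")
    return int(math.floor(x + 0.5))


def transcript_read_count_ai(entity_id: str,
                             lib_counts: Mapping[str, tuple[float, float]],
                             ) -> AiResult:
    """Transcript-level AI from estimated parental read counts.

    ``lib_counts`` maps library -> (ref_est, alt_est), replicate-summed
    estimated counts of the reference/alternative parental transcript pair.
    Estimates are rounded half-up to integers before testing; libraries
    with rounded ref + alt < ``MIN_HET_COUNT`` are undefined.
    """
    res = AiResult(entity_id, "transcript", "read_count")
    for lib, (ref_est, alt_est) in lib_counts.items():
        if ref_est < 0 or alt_est < 0:
            raise ValueError("negative estimated count")
        ref, alt = round_half_up(ref_est), round_half_up(alt_est)
        res.counts[lib] = (ref, alt)
        res.directions[lib] = direction_of(ref, alt)
        res.p_values[lib] = (binomial_ai(ref, alt)
                             if ref + alt >= MIN_HET_COUNT else None)
    return res


def gene_snp_coverage_ai(g: GeneModel,
                         transcript_clusters: Mapping[str, Sequence[SnpCluster]],
                         snp_counts: Mapping[tuple, AlleleCounts],
                         libraries: Sequence[str]) -> AiResult:
    """Gene-level AI from cluster-deduplicated exonic SNP coverage.

    Representatives from all isoforms are pooled and deduplicated by
    genomic position, so a SNP shared between isoforms is counted once.
    """
    rep_positions: set[int] = set()
    for clusters in transcript_clusters.values():
        rep_positions.update(c.representative for c in clusters)
    res = AiResult(g.gene_id, "gene", "snp_coverage")
    reps = [(key, ac) for key, ac in snp_counts.items()
            if key[1] in rep_positions]
    for lib in libraries:
        ref = alt = 0
        for _, ac in reps:
            r, a = ac.library_sum(lib)
            ref += r
            alt += a
        covered = any(sum(ac.library_sum(lib)) >= MIN_HET_COUNT
                      for ac in snp_counts.values())
        res.counts[lib] = (ref, alt)
        res.directions[lib] = direction_of(ref, alt)
        res.p_values[lib] = (binomial_ai(ref, alt)
                             if covered and ref + alt > 0 else None)
    return res


def gene_read_count_ai(g: GeneModel,
                       transcript_results: Sequence[AiResult]) -> AiResult:
    """Gene-level read-count AI: sum the (rounded) transcript counts."""
    res = AiResult(g.gene_id, "gene", "read_count")
    libs: list[str] = []
    for tr in transcript_results:
        for lib in tr.counts:
            if lib not in libs:
                libs.append(lib)
    for lib in libs:
        ref = sum(tr.counts.get(lib, (0, 0))[0] for tr in transcript_results)
        alt = sum(tr.counts.get(lib, (0, 0))[1] for tr in transcript_results)
        res.counts[lib] = (ref, alt)
        res.directions[lib] = direction_of(ref, alt)
        res.p_values[lib] = (binomial_ai(ref, alt)
                             if ref + alt >= MIN_HET_COUNT else None)
    return res


def rank_transcripts(g: GeneModel,
                     read_totals: Mapping[str, float]) -> dict[str, int]:
    """Rank a gene's isoforms by total reads; rank 1 = most likely
    transcribed isoform. Ties break by transcript_id lexical order."""
    tids = [t.transcript_id for t in g.transcripts]
    ordered = sorted(tids, key=lambda tid: (-read_totals.get(tid, 0.0), tid))
    return {tid: i + 1 for i, tid in enumerate(ordered)}


def flag_replicate_discordance(counts: AlleleCounts,
                               alpha: float = AI_ALPHA) -> dict[str, bool]:
    """Per-library flag: does any replicate point significantly the other
    way from the library sum?

    Each replicate whose direction strictly opposes the library-sum
    direction is tested replicate-vs-rest with a 2x2 chi-square (no
    continuity correction); the flag is set iff any such test has
    p < ``alpha``. A library with a single replicate is vacuously false;
    tables with a zero expected cell short-circuit to false.
    """
    out: dict[str, bool] = {}
    for lib in counts.libraries:
        reps = counts.library_replicates(lib)
        sum_ref, sum_alt = counts.library_sum(lib)
        lib_dir = direction_of(sum_ref, sum_alt)
        flag = False
        if len(reps) >= 2 and lib_dir != TIE:
            opposite = REF_GT if lib_dir == ALT_GT else ALT_GT
            for r_ref, r_alt in reps.values():
                if direction_of(r_ref, r_alt) != opposite:
                    continue
                rest = (sum_ref - r_ref, sum_alt - r_alt)
                table = [[r_ref, r_alt], [rest[0], rest[1]]]
                if min(sum(row) for row in table) == 0 or \
                        min(table[0][j] + table[1][j] for j in (0, 1)) == 0:
                    continue  # degenerate margin -> expected cell of 0
                chi2, p, _, _ = stats.chi2_contingency(table,
                                                       correction=False)
                if p < alpha:
                    flag = True
                    break
        out[lib] = flag
    return out


def flag_opposite_snps(snp_results: Sequence[AiResult],
                       alpha: float = AI_ALPHA) -> bool:
    """True iff some library has significantly imbalanced SNPs in both
    directions."""
    libs: set[str] = set()
    for r in snp_results:
        libs.update(r.p_values)
    for lib in libs:
        has_ref = has_alt = False
        for r in snp_results:
            if not r.is_ai(lib, alpha):
                continue
            if r.directions.get(lib) == REF_GT:
                has_ref = True
            elif r.directions.get(lib) == ALT_GT:
                has_alt = True
        if has_ref and has_alt:
            return True
    return False


def compute_bias(counts: Iterable[AlleleCounts]) -> float:
    """Overall reference fraction, as a percentage, over all SNPs,
    replicates and libraries."""
    ref = alt = 0
    for ac in counts:
        r, a = ac.total()
        ref += r
        alt += a
    if ref + alt == 0:
        raise ValueError("compute_bias: zero total count")
    return 100.0 * ref / (ref + alt)


def substitution_class(ref: str, alt: str) -> str:
    """Complement-grouped substitution label, e.g. C>T and G>A -> 'CT/GA'."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    a = ref.upper() + alt.upper()
    b = comp[ref.upper()] + comp[alt.upper()]
    first, second = sorted([a, b])
    return f"{first}/{second}"


def overview_summary(study) -> dict:
    """Database-overview style summary of an assembled study.

    ``study`` is any object exposing the assembled results (see
    :class:`asekit.pipeline.StudyResults`). Returns a nested dict with
    entity counts, SNP coverage/AI tallies, complement-grouped
    substitution-type percentages, the per-effect Count/Covered/AI table
    (Covered and AI are library-weighted: one unit per library reaching
    the coverage floor / the AI call), discordance-flag counts and the
    overall reference bias.
    """
    libraries = study.libraries
    genes = study.genes
    variants = study.variants

    def in_span(v: Variant, span, chrom) -> bool:
        return v.chrom == chrom and span[0] <= v.pos <= span[1]

    genes_with_snp = genes_with_indel = 0
    tx_with_snp = tx_with_indel = 0
    n_tx = 0
    for g in genes.values():
        gvars = [v for v in variants if in_span(v, g.span, g.chrom)]
        if any(v.is_snp for v in gvars):
            genes_with_snp += 1
        if any(not v.is_snp for v in gvars):
            genes_with_indel += 1
        for t in g.transcripts:
            n_tx += 1
            tvars = [v for v in gvars if in_span(v, t.span, t.chrom)]
            if any(v.is_snp for v in tvars):
                tx_with_snp += 1
            if any(not v.is_snp for v in tvars):
                tx_with_indel += 1

    covered = ai = 0
    for key, res in study.snp_results.items():
        ac = study.snp_counts[key]
        if any(sum(ac.library_sum(lib)) >= MIN_HET_COUNT
               for lib in libraries):
            covered += 1
        if res.any_ai():
            ai += 1

    sub_counts: dict[str, int] = {}
    n_sub = 0
    for v in variants:
        if v.is_snp:
            cls = substitution_class(v.ref, v.alt)
            sub_counts[cls] = sub_counts.get(cls, 0) + 1
            n_sub += 1
    sub_percent = {cls: 100.0 * n / n_sub for cls, n in sub_counts.items()} \
        if n_sub else {}

    effect_table: dict[str, dict[str, float]] = {}
    term_variants: dict[str, set] = {}
    for ann in study.effects.values():
        term_variants.setdefault(ann.term, set()).add(ann.variant_key)
    for term, keys in sorted(term_variants.items()):
        cov_w = ai_w = 0
        for key in keys:
            res = study.snp_results.get(key)
            ac = study.snp_counts.get(key)
            if res is None or ac is None:
                continue
            for lib in libraries:
                if sum(ac.library_sum(lib)) >= MIN_HET_COUNT:
                    cov_w += 1
                if res.is_ai(lib):
                    ai_w += 1
        effect_table[term] = {
            "count": len(keys),
            "covered": cov_w,
            "ai": ai_w,
            "ai_percent": (100.0 * ai_w / cov_w) if cov_w else 0.0,
        }

    n_disc_snps = sum(1 for flags in study.snp_rep_flags.values()
                      if any(flags.values()))
    n_disc_tx = sum(1 for flags in study.tx_rep_flags.values()
                    if any(flags.values()))
    n_opposite = sum(1 for f in study.opposite_flags.values() if f)

    return {
        "n_genes": len(genes),
        "n_transcripts": n_tx,
        "genes_with_snp": genes_with_snp,
        "genes_with_indel": genes_with_indel,
        "transcripts_with_snp": tx_with_snp,
        "transcripts_with_indel": tx_with_indel,
        "n_snps": sum(1 for v in variants if v.is_snp),
        "n_indels": sum(1 for v in variants if not v.is_snp),
        "snps_covered": covered,
        "snps_ai": ai,
        "substitution_percent": sub_percent,
        "effect_table": effect_table,
        "replicate_discordant_snps": n_disc_snps,
        "replicate_discordant_transcripts": n_disc_tx,
        "opposite_snp_transcripts": n_opposite,
        "bias_percent": (compute_bias(study.snp_counts.values())
                         if study.snp_counts else float("nan")),
    }


def render_overview(summary: dict) -> str:
    """Human-readable text rendering of :func:`overview_summary`."""
    lines = [
        "ASE study overview",
        "==================",
        f"genes: {summary['n_genes']} "
        f"(with >=1 SNP: {summary['genes_with_snp']}, "
        f"with >=1 indel: {summary['genes_with_indel']})",
        f"transcripts: {summary['n_transcripts']} "
        f"(with >=1 SNP: {summary['transcripts_with_snp']}, "
        f"with >=1 indel: {summary['transcripts_with_indel']})",
        f"SNPs: {summary['n_snps']}  indels: {summary['n_indels']}",
        f"SNPs covered (>= {MIN_HET_COUNT} in >=1 library): "
        f"{summary['snps_covered']}",
        f"SNPs with AI (p < {AI_ALPHA} in >=1 library): "
        f"{summary['snps_ai']}",
        "",
        "substitution types (complements grouped):",
    ]
    for cls, pct in sorted(summary["substitution_percent"].items(),
                           key=lambda kv: -kv[1]):
        lines.append(f"  {cls}: {pct:.1f}%")
    lines += ["", "variant effects (Count / Covered / AI):"]
    for term, row in summary["effect_table"].items():
        lines.append(f"  {term}: {row['count']} / {row['covered']} / "
                     f"{row['ai']} ({row['ai_percent']:.0f}%)")
    lines += [
        "",
        f"replicate-discordant SNPs: "
        f"{summary['replicate_discordant_snps']}",
        f"replicate-discordant transcripts: "
        f"{summary['replicate_discordant_transcripts']}",
        f"opposite-SNP transcripts: "
        f"{summary['opposite_snp_transcripts']}",
        f"reference bias: {summary['bias_percent']:.1f}% / "
        f"{100 - summary['bias_percent']:.1f}%",
    ]
    return "\n".join(lines) + "\n"
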