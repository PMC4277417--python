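"""Shared fixtures: small hand-built gene models and a simulated study."""

from __future__ import annotations

import pytest

from asekit import pipeline
from asekit.formats_io import GeneModel, SequenceRecord, TranscriptModel
from asekit.simulate import SimulationConfig, simulate_study, write_study

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def transcript_walk(genome, t):
    """Oracle helper: (genomic position, base) of every transcript base in
    transcript order, built by explicit exon walking (independent of the
    package's coordinate arithmetic)."""
    chrom = genome[t.chrom].seq
    out = [(p, chrom[p - 1]) for s, e in t.exons for p in range(s, e + 1)]
    if t.strand == "-":
        out = [(p, COMP[b]) for p, b in reversed(out)]
    return out


@pytest.fixture
def plus_transcript():
    # chr: 1..40; exons 3-10 and 16-25; CDS 6-10 + 16-22
    return TranscriptModel("tx_plus", "c1", "+",
                           exons=[(3, 10), (16, 25)],
                           cds=[(6, 10), (16, 22)])


@pytest.fixture
def small_genome():
    #        123456789012345678901234567890
    seq = "TTATGGCATAACGGTACCGTTGACCTTTGG" + "ACGT" * 3
    return {"c1": SequenceRecord("c1", seq)}


@pytest.fixture(scope="session")
def sim_study():
    """A small deterministic study used across test modules."""
    cfg = SimulationConfig(seed=101, n_genes=12, n_replicates=3,
                           variants_per_kb=3.0, indel_fraction=0.15,
                           isoforms_per_gene=(1, 3))
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def study_dir(sim_study, tmp_path_factory):
    d = tmp_path_factory.mktemp("study")
    write_study(sim_study, d)
    return d


@pytest.fixture(scope="session")
def study_results(study_dir):
    return pipeline.run_study(
        study_dir / "genome.fa", study_dir / "genes.gtf",
        study_dir / "variants.vcf", study_dir / "design.tsv",
        study_dir / "counts", xprs_dir=str(study_dir / "xprs"),
        totals_dir=str(study_dir / "totals"))
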