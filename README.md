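# asekit

Allele-specific expression (ASE) analysis for F1 hybrids of inbred
parents, where one parent is the reference strain. In that design every
variant site distinguishing the parents is heterozygous in the hybrid and
the alternative allele belongs to the non-reference parent, so allelic
expression can be read directly off allele counts at heterozygous SNPs —
no phasing needed.

`asekit` is aimed at people running count-based ASE studies (multiple
conditions × biological replicates) who need the computational core of
such a pipeline as a scriptable library and CLI:

* **Reference-bias mitigation** — merge per-sample variant call sets into
  a consensus (called in ≥ *k* samples, optional genotype filter) and
  write an N-masked genome so an ambiguity-aware aligner penalizes
  neither allele.
* **Allelic-imbalance statistics** — exact binomial tests of ref:alt
  counts against 1:1 at SNP, transcript and gene level, for both summed
  SNP coverage and isoform-resolved read counts, with a ≥20-count
  coverage floor (below it the p-value is reported undefined, `NA`),
  one-representative-per-cluster counting of closely spaced SNPs,
  replicate-discordance flags (2×2 chi-square, p < 0.05) and flags for
  transcripts with significantly opposite-direction SNPs.
* **Parental sequences & variant effects** — reference/alternative
  transcript and protein FASTAs (`_R`/`_A` suffixes) built by
  substituting variants into spliced isoforms; Sequence Ontology style
  effect classification (UTR / missense / synonymous / stop / intron /
  non-coding) with optional VEP/snpEff import, which also marks SIFT-
  deleterious or HIGH-impact variants as damaging.
* **GO-set trimming** — reduce a redundant set of enriched GO terms to
  the terms primarily responsible for enrichment in their own sub-DAG.
* **Query layer** — filter result tables (rank, missense/damaging
  counts, per-library p-value ceilings, directions, flags), combine them
  with union/intersection/difference, export TSV or parental FASTA.
* **Synthetic studies** — a deterministic generator producing a complete
  miniature study (genome, GTF, VCF, per-replicate counts, truth files)
  from one seed, so everything above is testable offline.

## The statistic

For a library with summed counts (ref, alt) the allele-imbalance p-value
is the two-sided exact binomial test against a balanced null, computed as
the doubled symmetric tail:

    p = min(1, 2 · P(X ≥ max(ref, alt))),  X ~ Binomial(ref + alt, 1/2)

Counts are per replicate, summed per library; transcripts additionally
count only one representative SNP per cluster of closely spaced SNPs
(default window 100 spliced bp) so a read spanning several SNPs is not
counted repeatedly. See `docs/methods.md` for the full model, thresholds
and design rationale.

## Worked example

Generate a small synthetic study and run the full analysis:

```
$ asekit simulate --seed 4 --out demo --genes 8 --libraries 2 --replicates 3
wrote study (8 genes, 22 variants) to demo

$ asekit ase --genome demo/genome.fa --gtf demo/genes.gtf \
    --vcf demo/variants.vcf --design demo/design.tsv \
    --counts demo/counts --xprs demo/xprs --totals demo/totals -o demo/out
ASE study overview
==================
genes: 8 (with >=1 SNP: 8, with >=1 indel: 0)
transcripts: 17 (with >=1 SNP: 16, with >=1 indel: 0)
SNPs: 22  indels: 0
SNPs covered (>= 20 in >=1 library): 22
SNPs with AI (p < 0.05 in >=1 library): 5
...
```

Reading the output: 22 heterozygous SNPs all clear the 20-read coverage
floor in at least one library, and 5 show significant allele imbalance
(binomial p < 0.05) somewhere. `demo/out/` contains `snp_ai.tsv`,
`transcript_ai.tsv`, `gene_ai.tsv` (per-library p-values, directions,
counts, flags; undefined p-values as `NA`) and `overview.txt`.

Query the transcript table — rank-1 isoforms with SNP-coverage AI in
brain — and export their parental sequences for e.g. protein-folding
analysis:

```
$ asekit query --table demo/out/transcript_ai.tsv --rank 1 \
    --p snp_coverage:brain:0.05 -o demo/hits.tsv
2 of 17 rows -> demo/hits.tsv

$ asekit export-fasta --ids demo/hits.tsv --genome demo/genome.fa \
    --gtf demo/genes.gtf --vcf demo/variants.vcf -o demo/seqs
exported 2 transcript pairs to demo/seqs
```

Trim an enriched GO set (chain A→B→C with p-values 1e-5, 1e-3, 2e-6:
the child C beats its ancestors, A's signal is diluted through B):

```
$ asekit go-trim --edges edges.tsv --scores scores.tsv --threshold 0.01
C	2e-06
# kept 1 of 3 enriched terms
```

The same operations are available as library calls
(`asekit.pipeline.run_study`, `asekit.ase_stats.binomial_ai`,
`asekit.go_trim.trim_go_terms`, ...).

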