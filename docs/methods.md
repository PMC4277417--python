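# Methods

## Setting and model

`asekit` analyses allele-specific expression (ASE) in an F1 hybrid of two
inbred parents where one parent is the reference strain. Under that
design every variant site distinguishing the parents is heterozygous in
the hybrid, and the alternative allele of each site belongs unambiguously
to the non-reference parent — no phasing is required. The unit
observation is a pair of allele counts (ref, alt) at a heterozygous SNP,
obtained either from read pileups at SNP positions ("SNP coverage") or
from estimated counts of the two parental transcript haplotypes ("read
counts").

The allele-imbalance (AI) statistic is a two-sided exact binomial test of
the reference count against the balanced null,

    p = min(1, 2 · P(X ≥ max(ref, alt))),   X ~ Binomial(ref + alt, 1/2).

Because the null is symmetric, the doubled symmetric tail is exactly the
canonical two-sided exact p-value (verified against
`scipy.stats.binomtest` to < 1e-9 over all count pairs up to n = 200 per
side); we state it in this closed form because it is cheap and numerically
transparent. Counts are accumulated per replicate, summed per library
(condition, e.g. a tissue), and tested on the library sums.

### Coverage floor and undefined p-values

Roughly 20 informative reads are needed for the exact test to have usable
power, so entities below that floor get an *undefined* p-value rather
than a meaningless one: a SNP needs summed heterozygous counts ≥ 20 in a
library; a transcript or gene needs at least one member SNP at ≥ 20 for
the SNP-coverage measure, and rounded ref+alt ≥ 20 for the read-count
measure. Undefined p-values serialize as `NA` and fail every p-value
filter in the query layer.

### SNP clustering and representative counting

A sequencing read that spans several nearby SNPs contributes to each of
their counts, so summing per-SNP counts over a transcript would count
such reads more than once and overstate significance. SNPs are therefore
clustered greedily left-to-right in *spliced-transcript* coordinates: a
SNP joins the current cluster when its spliced distance to the cluster's
previous member is at most the window (default 100 bp, the typical read
length; configurable). Only the cluster representative — the member with
the highest total heterozygous coverage across libraries, ties to the
5'-most member — enters transcript- and gene-level sums. Spliced rather
than genomic distance is used because reads are spliced; with window 0
the procedure degenerates to naive per-SNP summation. The representative
is chosen once per transcript (not per library) so that library sums stay
comparable.

### Gene level

A gene spans from its leftmost transcript start to its rightmost
transcript end. Gene SNP-coverage counts pool the cluster representatives
of all isoforms deduplicated by genomic position (a SNP shared by
isoforms counts once); gene read counts are the sums of its transcripts'
rounded read counts. In-span intronic variants are classified and
reported but never contribute counts — pileup counts at RNA-derived
alignments are exonic in expectation, and including intronic sites would
mix a different error process into the sums.

### Flags

Two per-entity quality flags guard the summed tests:

* **replicate-discordant** — within a library, a replicate whose
  direction strictly opposes the library sum is tested replicate-vs-rest
  with a 2×2 chi-square without continuity correction; the flag is set if
  any such replicate has p < 0.05. Replicate-vs-rest (not vs-total) is
  used because the total contains the replicate itself. Degenerate tables
  (a zero margin, i.e. an expected cell of 0) short-circuit to unflagged,
  and single-replicate libraries are vacuously unflagged.
* **opposite-SNPs** — a transcript is flagged when any single library has
  two significantly imbalanced SNPs (p < 0.05) pointing in opposite
  directions: a signature of isoform mixtures, genotype error or
  position-specific mapping bias. Ties in direction never trigger the
  flag.

### Transcript ranking

Within a gene, isoforms are ranked 1..k by total read count (ref + alt +
reads covering no variant), summed over all libraries and replicates;
rank 1 is the most plausibly expressed isoform. Ties break by transcript
id so rank 1 is always unique. Library-summed rather than per-library
totals are used so that each transcript has one rank.

## Reference-bias masking

Aligning hybrid reads to a single reference genome over-maps reads
carrying reference alleles. The toolkit writes a masked genome in which
every SNP base is replaced by `N`, so an ambiguity-aware aligner
penalizes neither allele. Indels are left untouched: replacing a point
base cannot represent a length difference, so indel bias is only
partially addressable by masking and is not attempted. Ref alleles are
validated against the genome before masking and mismatches are reported
as errors rather than silently skipped.

Upstream of masking, per-sample variant call sets are merged into a
consensus: a variant is retained when the identical (chrom, pos, ref,
alt) call appears in at least `min_samples` samples (default 5), and,
when a genotype filter is set (e.g. `1/1` for inbred alternative-strain
reads), the genotype must also match in at least `min_samples` of those
occurrences. We apply the genotype condition with the same ≥ threshold
rather than to all occurrences, which tolerates occasional miscalls in
otherwise concordant samples.

## Parental sequences and variant effects

Parental transcript pairs are built by splicing the reference exons
(minus-strand transcripts reverse-complemented) and substituting every
exonic variant — alleles reverse-complemented on the minus strand —
applied in descending spliced coordinate so indel length changes cannot
shift pending edit positions. Variants whose ref span crosses an
exon–intron boundary are excluded with a warning; partial application is
not well defined. Proteins are translated with the standard genetic code
from the annotated CDS start, stopping at the first stop codon; in the
alternative haplotype the CDS start is shifted by upstream indel length
changes and translation runs to the first stop, so frameshifts naturally
truncate (or extend) the alternative protein.

Internally computed effect terms follow Sequence Ontology naming:
`5_prime_UTR_variant`, `3_prime_UTR_variant`, `synonymous_variant`,
`missense_variant`, `stop_gained`, `stop_lost`, `intron_variant`,
`non_coding_variant`. In-CDS SNPs are classified by comparing the
reference and substituted codon translations. The vocabulary has no
basic term for an in-CDS indel, so those receive the positional term
`coding_sequence_variant`; splice-site effects are not computed
internally. External annotations (Ensembl VEP default tab output, or a
snpEff effect table) can be imported and replace the internal term for
the same (variant, transcript); a variant is marked *damaging* only from
external evidence — VEP SIFT "deleterious" or snpEff impact HIGH.
Internal classification never sets the damaging flag.

## GO-set trimming

Enrichment signal is highly redundant along the GO hierarchy. Given a
DAG of terms (`is_a`/`part_of` edges) with enrichment p-values, the trim
restricts to terms below a threshold (default 0.001) and keeps a term
when no enriched proper ancestor scores at least as well (p ≤) and no
enriched proper descendant scores strictly better (p <), over the
transitive closure of the edge relation. The asymmetric tie rule keeps
the most ancestral term of an equally scored chain, on the view that an
equal child score is inherited from the parent. Diamond-shaped ancestries
with interleaved scores are not fully determined by the two informal
displacement rules; the closure-based conditions above are the consistent
completion implemented here, checked against a brute-force closure oracle
on random DAGs. Multiple terms per subtree survive when siblings
independently satisfy the conditions, so the output is a set, not one
term per root.

## Synthetic study generator

The generator (`asekit.simulate`) emulates the study conditions end to
end with no external data:

* **Genome/annotation** — random chromosomes carrying multi-exon genes on
  both strands. Each gene has 3–5 exons (120–300 bp, introns 60–200 bp);
  the CDS starts inside the second exon and ends inside the second-to-last
  so the terminal exons are pure UTR, which lets isoforms share all
  internal (coding) exons while differing in terminal exons; a fourth
  isoform, when drawn, is non-coding. CDSs are built as ATG + non-stop
  codons + stop, so every coding isoform translates cleanly.
* **Variants** — SNPs (and indels at a configurable fraction, default
  0.10) placed in exons and introns at ~2 per kb of gene span, all
  genotype `1/1` (homozygous alternative parent). A quarter of exonic
  SNPs receive a partner 5–30 spliced bp away to exercise clustering.
  Ground-truth effect labels are derived from the generator's own layout
  bookkeeping plus a codon-table lookup — an independent path from the
  classifier being tested.
* **Counts** — per replicate, each SNP draws total ~ Poisson(coverage)
  and ref ~ Binomial(total, θ + δ), where θ is the gene's allelic ratio
  and δ a global reference-bias offset. Defaults: 4 libraries × 4
  replicates (the multi-tissue replicate design the toolkit targets),
  mean coverage 50 (a realistic heterozygous-site depth for a deeply
  sequenced bulk RNA-seq library), δ = 0.014 — the count-level signature
  of the residual reference bias that survives genome masking, yielding a
  51.4/48.6 overall split. A quarter of genes are planted with θ = 0.8,
  split evenly between ref- and alt-skew so the overall reference
  fraction stays 1/2 + δ. Parental `.xprs` counts carry the heterozygous
  read masses only; reads covering no variant are allele-uninformative,
  so they are emitted separately in total-count tables used for isoform
  ranking. Truth files (θ map, effect labels, config) are first-class
  outputs.

The generator works at count level, not read level: it does not simulate
alignment, mapping ambiguity between isoforms, overdispersion beyond
Poisson–binomial, or correlated errors across nearby SNPs. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under its own model assumptions, not robustness to alignment
artefacts in real data.

## Numerical choices and degenerate inputs

* Estimated (fractional) read counts are rounded half-up before the
  binomial test, which needs integers.
* `binomial_ai` requires ref + alt > 0; both-zero is an error, not p = 1.
* Direction is `tie` when ref = alt; ties never satisfy direction
  filters nor opposite-direction flags.
* Multi-allelic VCF records split into one variant per alt allele.
* Cluster tie-breaks, rank tie-breaks and table sort orders are all
  deterministic (documented above) so repeated runs are bit-identical.
* All simulation randomness derives from one seed through spawned
  per-stage generators; identical seeds give byte-identical output files.

## Verification problem sizes

The test-suite and the acceptance script run at desk scale, chosen to
keep exact-oracle comparisons exhaustive where cheap and statistical
checks well-powered: the binomial oracle is checked over all count pairs
up to 200 per side; calibration uses 10,000 simulated SNPs (type-I error
at coverage 100 within the conservative band [0.03, 0.055]; power at
coverage 20, θ = 0.8 within ±0.02 of the enumerated 0.804); effect
classification is cross-checked against a translate-and-diff oracle on
>1,000 variant-transcript pairs; GO trimming against a brute-force
closure oracle on 100 random DAGs of up to 50 nodes; and the end-to-end
run uses a 50-gene, 4-library × 3-replicate study, recovering the
planted θ ≠ 0.5 transcripts at the analytic power and the planted δ
within 3 standard errors.

## Known limitations

* The binomial model ignores overdispersion between replicates; the
  replicate-discordance flag is the guard, not a mixed model.
* Gene-level pooling of representatives deduplicated by position can
  still correlate across isoforms sharing clusters; p-values at gene
  level are approximations, as at transcript level.
* No multiple-testing correction is applied; thresholds are raw
  p-values by design, and downstream consumers can correct over the
  exported tables.
* Indel consequences beyond positional classification (e.g. predicted
  frameshift severity) are out of scope; import snpEff/VEP annotations
  for that.
* The VEP/snpEff importers target the default tab dialects; exotic
  column layouts need pre-massaging.
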