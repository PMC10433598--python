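# Methods

## Coordinate model

A `GeneModel` is a single transcript on one chromosome: ordered, fully
closed, 1-based exon intervals, a strand, the cDNA offset of the first
coding base (`cds_start_cdna`), and optionally the plus-strand reference
sequence of the gene span. `cds_end_cdna` (the last coding base) is an
addition to the minimal field set: region labeling needs a stop boundary to
distinguish 3' UTR from coding sequence; it defaults to the transcript end
(no 3' UTR) when not given.

c. coordinates follow HGVS: coding `c.1..n`, UTRs `c.-k`/`c.*k`, intronic
offsets anchored at exon boundaries (`+k` after a donor, `-k` before an
acceptor). Mapping to genomic coordinates is exact and strand-aware; the
inverse reports intronic positions from the *nearer* boundary, breaking the
exact-midpoint tie toward the upstream (+k) form so that consolidation has
one canonical spelling. Published far-anchor forms (offsets up to the full
intron length, e.g. an IVS offset counted from the distant boundary) are
accepted on input; only the canonical nearest form is ever emitted.

Single-transcript scope is deliberate: the analysis concerns one gene, and
alternate protein numbering (a transcript whose CDS starts a fixed number
of codons later) is modeled as a second `GeneModel` sharing the same exons
and sequence.

## Notation parsing and normalization

`parse_notation` is total: anything unrecognized returns
`system="unparseable"` rather than raising, so a corpus pass never dies on
one bad string. Each tolerated non-standard form maps to a named rule
recorded on the result (`whitespace-tolerant`, `legacy-ivs`,
`sloppy-offset-range-end` for `c.1016+41_45dupTGCCC`,
`sloppy-anchor-offset-pair` for `c.1016_41dupTGCCC`,
`one-letter-amino-acid`, `digit-group-commas`,
`free-text-large-deletion`), keeping dialect handling auditable.

Normalization maps a parsed notation to a genomic key. Duplications,
deletions and insertions are shifted to their most-3' equivalent position
*in transcript orientation* over the unspliced genomic sequence whenever
sequence is available (insertions roll with base rotation; an insertion that
duplicates adjacent sequence is re-expressed as a duplication). Without
sequence the stated position is kept and the variant carries a
`not-shifted` flag. A stated reference base that contradicts the model
sequence sets `ref-mismatch` but the variant stays at its stated
coordinates — automatic relocation of a mis-annotated variant is never
guessed, because the same printed coordinate confusion can hide a genuinely
different variant.

Protein-only mentions resolve by enumerating the single-nucleotide changes
of the *actual* codon (read from the model sequence) that produce the
stated residue change, across all supplied transcript models; a companion
cDNA notation in the same mention short-circuits the enumeration. More than
one surviving key flags ambiguity and the mention is reported unresolved
rather than guessed. A residue that matches only a non-primary model is
flagged `transcript-mismatch` (the alternate-numbering case). Large
deletions are keyed by exon set, not base coordinates, and are deduplicated
by exact exon-set equality; database matching uses ≥ 50% reciprocal
exon-set overlap.

Consolidation attaches every resolvable mention to exactly one normalized
variant, retains all evidence bundles and alias strings, lists unresolved
mentions with reasons, and satisfies
`n_unique + n_duplicates + n_unresolved = n_raw`. Output is sorted by key,
so it is invariant to input order.

## Evidence cascade

Evidence per mention: clinical CTD composite (phenotype flag plus the MRS
and urinary Cr:Crn items), creatine uptake as % of wild type, segregation,
observations in unaffected males, control-population allele counts, de novo
status, and an explicit conflicting-reports flag. Merging across mentions
of one variant: flags union, uptake values average. Conflict demotes to VUS
*before* the cascade: an explicit flag, uptake measurements more than 15
percentage points apart, or bundles that individually land on opposite
sides. The per-bundle cascade, in order:

1. uptake < 70% with clinical phenotype → Pathogenic;
   uptake in [60, 70) alone → Likely Pathogenic (the 10-point "likely"
   band reproduces the worked 65%-uptake example without inventing a second
   threshold); uptake < 60% alone → Pathogenic;
2. uptake ≥ 75% (within 25% of wild type) → Benign;
3. any unaffected hemizygous male, or control allele frequency ≥ 0.001
   (the 21/166 worked example is well above it) → Benign;
4. non-segregation → Likely Benign;
5. clinical phenotype without functional data → Pathogenic with the full
   composite (phenotype + MRS + Cr:Crn), else Likely Pathogenic — the
   composite requirement is this package's explicit choice where partial
   clinical pictures were not specified, and the fired rule is recorded in
   the call's rationale;
6. nothing fired → Unassigned.

The gray zone 70–75% deliberately falls through to non-functional evidence.
De novo status is recorded and reported but never enters the cascade. The
cascade is total, deterministic, order-invariant over bundles, and
monotone: lowering uptake with everything else fixed never moves a call
toward Benign (property-tested).

Chaperone rescue (4-PBA): rescued iff uptake after − before ≥ 5 percentage
points; missing after-measurement → not measured. The published 17-row
assay table ships as packaged data and yields 8 rescued / 9 not rescued.
Protein feature overlap is an exact residue-index lookup against a
(residue, feature) table; the packaged table carries the literature-derived
SLC6A8 sites (helix-stabilizing, creatine-binding, phosphorylation,
glycosylation, leucine-zipper, disulfide).

## Database matching and the inclusion test

Database exports load through the same key machinery (VCF via pysam with
shared-prefix/suffix trimming then 3'-shifting; HGVS-column TSVs through the
parser), so matching is representation-independent by construction.
Classification concordance collapses Likely tiers and is recorded only
where both sides are classified. Tier strata (`pathogenic*`, `benign`,
`vus`) exclude large deletions by reporting convention; region and SNV/MNV
strata cover all variants.

The SNV-vs-MNV inclusion contrast uses the per-variant count of containing
databases (ClinVar, dbSNP, gnomAD, 1000 Genomes; 0–4). Because the named
test in the source analysis is ambiguous ("unpaired t test with
Mann-Whitney"), the Mann-Whitney U is primary and a Welch t-test is
reported alongside. Inclusion counts are heavily tied, so the exact null
(used when combined n ≤ 25) is computed by dynamic programming over tied
rank groups — the full permutation distribution of the rank sum, in
polynomial time — rather than scipy's tie-free exact method; the two-sided
p is `min(1, 2·min(P(R≤r), P(R≥r)))`, which gives exactly 1.0 on identical
groups. Larger samples use the tie-corrected normal approximation.

## Predictor benchmarking

Binarization: SIFT deleterious, PolyPhen2 probably/possibly damaging
(possibly-damaging counts as a pathogenic call by default — the
conservative, conventional grouping; configurable), MutationTaster2
disease-causing, MutationAssessor high/medium, PROVEAN ≤ −2.5, CADD ≥
cutoff (default 20; a score exactly at the cutoff counts as pathogenic,
since the source analysis states only strict inequalities on both sides).
Coverage denominators include every curated variant; accuracy denominators
exclude VUS/Unassigned (no truth to match). The CADD-accuracy denominator
is ambiguous in the source, so the aggregate report emits all three
readings (all variants, scored variants, scored-and-classified).
Percentages destined for integer-style tables use round-half-up.

## What the synthetic generator emulates

Defaults are the study conditions: 210 mentions, 12% alias mentions
(rewritten in a different dialect: IVS form, opposite intron anchor, raw
genomic, sloppy duplication, or alternate-transcript protein numbering
offset by 115 codons), class mix 116 exonic / 63 intronic / 2 UTR / 4 large
deletions with 147 SNVs, tier mix 92 pathogenic* / 68 benign / 21 uncertain
realized exactly by largest-remainder allocation, tier-consistent evidence
(pathogenic: uptake U(0,60) plus the full clinical composite; likely
pathogenic: U(60,70) alone; benign: U(75,110) or control observations;
likely benign: non-segregation; VUS: a conflicting-reports bundle, with the
contradictory benign-side bundle riding on the alias mention when one
exists), per-database per-stratum presence (LOVD 72/88%, ClinVar 21/45%,
dbSNP 27/85%, gnomAD 3/60%, 1000G 1/30% for pathogenic/benign; the
population-database benign and VUS rates are this package's choices, since
only the pathogenic rates are printed, constrained so ClinVar's overall
rate is 29%), 6% clinical-archive misclassification, and per-algorithm
coverage/accuracy at the published rates. CADD numeric scores come from
truth- and correctness-conditional piecewise-uniform bands; the default
CADD accuracy (0.75 pathogenic / 0.72 benign) makes scored-set accuracy at
cutoff 20 ≈ 65%.

Presence is independent per database (and per algorithm), with one planted
correlation: MNV presence in the population databases is halved, making the
inclusion contrast real. Real curation data is more correlated than this —
a variant missing from one database is disproportionately missing from all,
and one algorithm's failure predicts another's — so emergent co-absence
quantities (the uncaptured-anywhere fractions, the any-algorithm-accurate
fraction, the high-CADD evidence bands) come out respectively lower and
higher here than in correlated real data. Passing tests therefore
demonstrate that the machinery recovers what was planted, not that real
corpora obey independence. The generator also does not emulate realistic
mutation spectra, position hotspots, or allele-frequency distributions.

All randomness flows from integer seeds through `numpy.random.Generator`;
nothing depends on hash ordering, and regeneration is byte-identical.

## Numerical and degenerate-input choices

Tolerances are exact where counting is exact (consolidation, tier counts);
rate-recovery tests pool ten seeded corpora and check the pooled estimate
against the planted rate within a 95% binomial interval. Degenerate inputs:
empty evidence → Unassigned (not an error); empty database export → empty
catalog with a logged warning; malformed export rows are skipped, counted
and logged, never fatal; a single-exon model simply rejects IVS forms and
intronic mixes. Problem sizes throughout (corpus 210, ten seeds, exhaustive
round-trips over ~10 kb spans) keep the full suite under ten seconds while
leaving binomial standard errors around a percentage point.

## Known limitations

* One transcript per gene model; no alternative splicing beyond the
  fixed-offset alternate-numbering twin.
* The HGVS subset covers the dialects that occur in this curation setting;
  inversions, mosaicism and RNA-level notation are out of scope.
* 3'-shifting operates on the unspliced genomic sequence; exon-boundary-
  crossing repeats (not observed in this setting) could in principle shift
  across a splice site.
* The cascade implements the operationalized evidence rules of this
  analysis, not the full 28-criterion ACMG framework.
* Large-deletion matching is exon-set based; breakpoint-level comparison is
  not attempted.
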