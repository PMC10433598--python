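# curagap

Harmonization, pathogenicity classification and database gap analysis for
literature-curated gene variants, built around X-linked Creatine Transporter
Deficiency (CTD) and its gene *SLC6A8*.

## The problem

Variants that cause rare diseases are scattered across decades of
publications under inconsistent names: coding-DNA HGVS (`c.1540C>T`), legacy
intron notation (`IVS12+32 C>A`), protein notation in one- or three-letter
code (`p.R514X`, `p.Arg514Ter`), raw genomic coordinates, sloppy duplication
spellings (`c.1016+41dupTGCCC` vs `c.1016+41_45dupTGCCC`), and free-text
multi-exon deletions. Before anyone can ask "is this published variant in
ClinVar?" every mention has to be mapped to the same genomic alteration.
This package implements that analysis end to end, for anyone curating
variants of a monogenic disease from the literature:

1. **Harmonizer** — parses every dialect, maps it through a single-transcript
   gene model (cDNA ↔ genomic with intronic offsets), 3'-shifts
   duplications/deletions/insertions per the HGVS normalization rule, and
   consolidates duplicate names onto one canonical genomic key
   `(chrom, pos, ref, alt, build)`.
2. **Evidence classifier** — an ACMG-style rule cascade over structured
   evidence: the clinical CTD composite (developmental phenotype, absent MRS
   cerebral creatine peak, elevated urinary Cr:Crn), in-vitro creatine
   uptake as % of wild type (pathogenic below 70%, benign at ≥ 75%, a
   "likely" band just under the cutoff), family segregation, and
   control-population observations; conflicting sources demote to VUS. Also:
   SNV/MNV and region classes, 4-phenylbutyrate rescue calls
   (rescued iff uptake gains ≥ 5 percentage points), and protein
   feature-site overlap.
3. **Gap analysis** — presence of each curated variant in database exports
   (LOVD/ClinVar-style TSV, dbSNP/gnomAD/1000G-style VCF), classification
   concordance, the fraction of each tier captured nowhere, and an exact
   tie-aware two-sided Mann-Whitney U test of whether multi-nucleotide
   variants are less likely than SNVs to be included in the databases
   (per-variant inclusion counts 0–4; full permutation null computed by
   dynamic programming over tied rank groups).
4. **Predictor benchmark** — SIFT / PolyPhen2 / MutationTaster2 /
   MutationAssessor / PROVEAN / CADD calls binarized against curated tiers:
   coverage, accuracy by super-class, CADD cutoff bands (10/20/30, score ≥
   cutoff ⇒ pathogenic), and cross-algorithm aggregation (any-accurate,
   solely-CADD).
5. **Synthetic data** — a generator with planted ground truth (alias
   mentions in alternate dialects, tier-consistent evidence, per-database
   per-stratum presence, per-algorithm coverage/accuracy) whose defaults are
   the study conditions: 210 mentions with 12% duplicate names → 185 unique
   variants, 92 pathogenic*/68 benign/21 uncertain, 147 SNVs, 63 intronic.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
inputs (no downloads). `python analysis/01_simulate.py --seed 1` writes the
inputs, then each later driver prints its findings:

```
$ python analysis/02_harmonize.py
210 raw mentions -> 185 unique variants; 25 mentions (12%) were duplicate names
of an already-seen alteration
every mention resolved to a genomic key
45 variants were published under more than one notation; examples:
  c.32T>C  <-  ['c.32T>C', 'chrX:g.100121T>C', 'p.I11T']

$ python analysis/04_gap_analysis.py
LOVD: 75% of the curated list present (138/185); classification concordance 92% ...
ClinVar: 31% of the curated list present (58/185); classification concordance 84% ...
captured nowhere: 12% of pathogenic* vs 0% of benign variants
MNVs vs SNVs inclusion over ClinVar/dbSNP/gnomAD/1000G: U=3648,
two-sided p=0.00233 (asymptotic); Welch t-test p=0.00161
```

The consolidation line is the harmonizer recovering the planted 12% alias
rate exactly; the LOVD/ClinVar lines estimate the planted per-stratum
presence rates (72–88% and 15–45%); the small Mann-Whitney p reflects the
planted halving of MNV presence in the population databases. Library use:

```python
from curagap import demo
bundle = demo("out/", seed=1)          # generate inputs + run all stages
print(bundle.consolidation)            # {'n_raw': 210, 'n_unique': 185, ...}
```

or stage by stage via `parse_notation` / `normalize_variant` /
`consolidate_mentions` / `assign_pathogenicity` / `mark_presence` /
`prediction_accuracy` on your own files (formats in `docs/methods.md`).

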