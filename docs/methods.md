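# Methods

## Cohort model

The unit of analysis is a `FamilyCohort`: a variants × samples matrix of
allele-dosage genotype codes (0 hom-ref, 1 het, 2 hom-alt, −1 missing) plus a
map from sample names to the six pedigree roles `mother`, `father`,
`child_f`, `child_m`, `tumor_f`, `tumor_m`. Each role binds at most one
sample; the quad filters need the four germline roles, the tumor filters
additionally the two tumor roles. All positions are 1-based, chromosome
names are normalized to the `chr`-prefixed dialect, and gene symbols are
compared case-sensitively after whitespace stripping, with no alias
resolution.

VCF ingestion splits multi-allelic sites into one biallelic record per
alternate allele and recodes each genotype as the dosage of that record's
own alternate; alleles pointing at a different alternate count as reference
for the split record. Phasing is ignored (`0|1` ≡ `1/0` ≡ het) and any
half-called genotype (`./1`) is treated as missing — the conservative
reading, since a partially observed call cannot certify a segregation
pattern. `pass_only` defaults to off because the intended input has already
passed upstream variant-level filtering; the flag lets users enforce PASS.

## Segregation and tumor filters

Each filter is a per-variant predicate on the joint genotype vector
(documented in the README table). Two conventions matter:

* **Missing disqualifies.** A missing call in any required role fails the
  variant. The alternative (treating missing as compatible) inflates false
  positives in exactly the configurations the filters exist to exclude.
* **"Homozygous" means hom-alt.** In the recessive filter the children must
  carry two alternate alleles while each parent is a heterozygous carrier —
  the only pattern consistent with an autosomal-recessive model in which
  unaffected parents transmit the variant to both affected children. Both
  parents must be heterozygous at the same biallelic record as the children.

A variant annotated to *k* overlapping genes contributes once to the variant
total and once to each of the *k* per-gene counts. The tumor filters require
the pattern in **both** siblings' tumors jointly; per-sibling somatic
analysis is out of scope, as are compound-heterozygote phasing, de-novo
germline detection, and somatic allele-fraction modeling.

## Cumulative gene scores and the cascade

score(G, s) = Σ over the positions of G of the dosage weight (0/1/2).
Missing genotypes contribute 0 and are tallied per gene in `n_missing`, so
users can discard high-missingness genes; no normalization by gene length or
position count is applied (raw sums are the point: the score measures
accumulated burden, and the cascade compares the same gene across family
members, so gene length cancels). Scores are computed over all annotated
variants by default, with a `nonsyn_only` switch.

Cascade semantics, where the prose definition left room:

* Step 1 ("score below 5 in children excluded") is read as **both** children
  ≥ `min_child_score` (default 5) — the stricter interpretation —
  configurable to `either` or `mean`.
* Step 2 compares means: children's mean ≥ `child_parent_ratio` (default
  1.5) × parents' mean. A parents' mean of 0 passes iff the children's mean
  is positive, preserving the filter's intent without dividing by zero; the
  reported ratio is then infinite.
* Step 3 is strictly greater-than on the combined sums.
* Output is sorted by descending combined children's score, ties broken
  alphabetically, so reruns are bit-identical.
* Tumor samples may be scored (for display next to germline bars) but never
  enter the cascade, which is defined on the four germline roles.

Raising `min_child_score` or `child_parent_ratio` can only shrink the
passing set (each step is monotone in its threshold); the property suite
asserts this, along with additivity over position partitions and the
full-transmission identity (child score = mother + father on disjoint
parental het sets, e.g. 12 + 13 → 25).

## Over-representation analysis

The test is the one-sided upper-tail hypergeometric probability
P(X ≥ k), inclusive, computed with `scipy.stats.hypergeom.sf(k−1, N, K, n)`
— the standard ORA direction; under-representation is not tested. BH
adjustment uses `statsmodels` (`fdr_bh`); inputs outside (0, 1] are
rejected. FDR is applied within each category family separately
(chromosomes, bands, pathways, matching per-category reporting), and
`hypergeom_ora` can be called on a pooled collection when a single family is
preferred. The background defaults to the supplied annotation/GMT universe;
because reference ORA backgrounds are tool- and version-specific, absolute
p-values from other tools are not comparison surfaces — only the mechanics
(tail, adjustment) are asserted, against exhaustive enumeration on small
backgrounds and hand-computed step-up vectors. Pathway results are reported
at a minimum overlap of 3 query genes (configurable). Query genes outside
the background are dropped with a warning. Positional sets are emitted at
two levels (per chromosome, per chromosome.band); genes with malformed band
strings stay in the chromosome-level set only.

## Synthetic cohorts and the packaged fixtures

`simulate_cohort` plants three qualifying classes — recessive (85 by
default), tumor newly-homozygous (1), tumor-acquired heterozygous (15),
mirroring the planted class sizes of the motivating study design — plus
`n_decoys_per_class` copies of each of 14 **enumerated** decoy
configurations: a hom-ref or hom-alt parent, a het or hom-ref child, a
missing parent/child/tumor call, a synonymous variant with the qualifying
recessive genotypes, tumor changes confined to one sibling, tumors matching
leukocytes, all-reference and all-het records. Enumerating rather than
sampling decoys guarantees negative coverage of every way each predicate can
fail. Germline decoys are Mendelian-consistent (checked in the suite) except
classes explicitly modeling tumor-acquired alleles; tumors default to the
matching leukocyte genotype. Positions sit in disjoint per-gene blocks ≥ 2 bp
apart; alleles are single-base substitutions except a small configurable
indel fraction; identical plan + seed reproduce byte-identical files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level error, coverage-dependent genotype
quality, linkage/haplotype structure, population allele frequencies,
multi-gene annotations, and somatic subclonality. Tests on simulated cohorts
certify the filtering/scoring logic, not robustness to noisy calls.

The packaged fixtures transcribe the study's two printed variant tables
(85 recessive-pattern rows in 73 gene symbols; 15 tumor-acquired rows),
checksum-verified against a manifest at load time. Editorial choices:
the table's `ANKRD53` is kept where the surrounding text once prints
"ANKRD5" (the table is the more structured source); the one deletion among
the 85 rows is kept as printed and classed frameshift; all other rows are
classed missense, since the tables print no per-row class and any
non-synonymous class behaves identically in the filters. The single tumor
newly-homozygous hit is not printed with coordinates, so the package plants
a clearly labeled synthetic stand-in (`SYNTHETIC_TUMOR_HOM_PLANT`, invented
chr17 coordinates, RAI1 symbol, frameshift class, qualifying genotypes).

Reported chromosome-level gene counts in the source text (15/7/10 on
chr1/chr22/chr11, and once "75 genes") differ slightly from counts derived
from the printed table (14/6/9 distinct symbols, 73 genes) — an
annotation-version effect; the package documents and follows the table.

## Pipeline

`run_pipeline` executes load → recessive filter (+multi-hit summary) →
gene scores → cascade → both sibling contrasts → tumor filters → enrichment,
writing one TSV per stage plus `run_manifest.json` (version, parameters,
counts, runtime). Every manifest count is recomputable from the stage file
it summarizes. Stages write into a temporary directory renamed into place on
success, so a failure (surfaced as `StageError` naming the stage) leaves no
partial output. Problem sizes throughout the suite are desk-scale — the
fixture bundle is ~240 records and simulated cohorts a few hundred — chosen
because the filters are per-record predicates whose correctness is fully
exercised at that scale.
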