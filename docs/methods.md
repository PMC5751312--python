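# Methods

## Estimation model

The estimator treats an exome/genome aggregation repository as a random
sample of chromosomes per population.  For each gene and population the
*collective frequency* q is the summed alternate-allele count of all
eligible variants divided by an allele-number denominator.  Because
sequencing success varies slightly by site, allele numbers differ across
sites; the denominator is the **maximum allele number among the eligible
variants** of that gene and population — the number of chromosomes the
best-covered site saw.  Sites with `an = 0` in a population were not called
there and are skipped.  The panel-wide (ALL) group is derived, never read
from input: a variant's ALL allele number is the sum of its eight
per-population allele numbers, and the ALL denominator maximises that total
(hence ALL's denominator is ≤ the sum of the per-population denominators).

Under Hardy–Weinberg equilibrium and the rare-variant regime:

* carrier (heterozygote) frequency = 2q.  The exact form 2q(1−q) differs
  only in the third significant digit at these frequencies; 2q is the
  module default and matches the published tables, with `hw_exact=True`
  available throughout.
* recessive prevalence = q² per gene, summed over the three genes.  Using
  the per-gene *collective* q² counts homozygotes and compound
  heterozygotes of the same gene, which is the correct genetic model for a
  biallelic (in-trans) disease mechanism; it assumes no linkage between the
  rare alleles and random mating.
* dominant prevalence pools all deleterious variants of the three genes
  into a single collective frequency (one hit in any gene suffices) and
  reports 2q per 10³.

Allele counts are allele copies, not carriers: a homozygote contributes 2.
At these frequencies virtually every observed carrier is heterozygous, so
"heterozygous individuals" and "allele copies" coincide numerically.

## Classification rules and their parameters

Inclusion (first match wins): frameshift/nonsense → `null_mutation`;
core splice site (intronic ±1, ±2) → `splice_core`; near splice site
(−3, +3…+6) with 3/3 disrupting splice-predictor verdicts →
`splice_near_consensus`; database-reported missense/in-frame indel →
`db_reported_missense`; 7/7-damaging missense/in-frame →
`missense_consensus`.  Synonymous and other consequences are never
deleterious regardless of predictions.

A splice predictor's verdict is *disrupting* when it reports the wild-type
site abolished, or a mutant score strictly below half the wild-type score
(a tie at exactly half is not disrupting).  A missing predictor output
never counts as damaging/disrupting, keeping the 7/7 and 3/3 consensus
rules literal; with one tool missing a variant cannot reach consensus.

Exclusions are applied before any inclusion rule, in order: low-confidence
filter status (this also wins over a database report, and the conflict is
logged); location in an excluded exon (defaults: *FGA* exon 6, *FGG* exon
10 — both encode low-abundance chain isoforms and have never been clearly
associated with disease); intronic location annotated only on alternative
transcripts of unknown significance.

Eligibility: every deleterious variant is dominant-eligible.  Variants
whose database phenotype set intersects {dysfibrinogenemia,
hypo-dysfibrinogenemia, amyloidosis} are excluded from the recessive
calculation — those conditions are dominantly inherited and their alleles
do not produce afibrinogenemia in trans.  For multi-label phenotypes
(e.g. "d/h") the exclusion applies if *any* excluded label is present, the
conservative reading.

## Residue numbering

Legacy fibrinogen nomenclature numbers the mature chains (after
signal-peptide cleavage); databases use HGVS numbering on the native
protein.  The schemes differ by the signal-peptide length: 19 residues for
the Aα chain (FGA), 30 for Bβ (FGB), 26 for γ (FGG).  The FGA and FGG
offsets are confirmed by every published legacy/native pair (e.g.
Aα(16)Arg>Cys ↔ p.Arg35Cys, γ(275)Arg>His ↔ p.Arg301His, γAla82Gly ↔
p.Ala108Gly); no FGB pair is printed anywhere we know of, so the FGB
offset of 30 is taken from the chain's signal-peptide length and is
config-overridable like the others.

## Fisher exact r×c test

The mutation-type spectrum comparison uses a two-tailed Fisher exact test
for 2×k tables under the standard probability-ordering convention: with
both margins fixed, p is the total multivariate-hypergeometric probability
of all tables whose probability does not exceed the observed table's
(comparison done in log space with a 1e-9 absolute slack against
floating-point noise).  Tables with total ≤ 500 are enumerated exactly by
column-wise recursion with feasibility pruning; larger tables use seeded
Monte Carlo sampling (numpy's multivariate hypergeometric generator,
200,000 draws by default) with a reported standard error.  Zero-margin
columns are dropped with a warning; an all-zero table is an error; a table
with one empty row admits a single configuration and p = 1.  Reference
class counts (e.g. from a curated mutation database snapshot) are supplied
by the user; none ship with the package.

## The reference dataset

The allele-level repository data cannot be redistributed, but every
aggregate of the published analysis is printed: per-(gene, population)
summed allele counts and denominators for both eligibility modes, the
allele counts of the named recurrent/founder/hotspot variants, the
unique-mutation spectrum with database-reported subtotals, and the
database-reported allele totals implied by the reported-variants-only
reanalysis.  `fibropanel.fixture.paper_fixture()` reconstructs a synthetic
variant table that reproduces all of those aggregates exactly:

* named variants carry their printed per-population allele counts, fixed
  from the printed *shares* (exact to 3 s.f. in every case; two printed
  allele frequencies — p.Asp172Asn in Admixed Americans and p.Thr47Ile in
  non-Finnish Europeans — are inconsistent with their own shares at the
  last digit, and the shares win);
* the remaining allele mass is filled with anonymous variants (mostly
  singletons and doubletons) whose per-gene class mix matches the printed
  spectrum, so spectrum outputs are shaped like the published distribution
  without claiming per-class exactness beyond printed totals;
* per-variant allele numbers: each variant of a gene carries the gene's
  per-population allele numbers with the (sum − ALL) deficit subtracted on
  the NFE group; one designated variant per gene carries the full NFE
  number with the deficit moved to OTH.  This makes the per-population
  maxima and the ALL maximum equal the printed denominators
  simultaneously.  One dominant-only variant carries the slightly larger
  AFR allele number printed for the pooled dominant table;
* amyloidosis-labelled missense variants carry 0/7 damaging verdicts
  (consistent with the observation that no amyloidosis variant reaches
  predictor consensus — they sit in the unstructured Aα C-terminal tail)
  and are included via the database-report rule instead;
* a handful of non-eligible showcase rows (synonymous, 5/7 missense,
  excluded-exon, low-confidence, alternative-transcript) exercise the
  exclusion paths without entering any aggregate.

The builder re-derives every aggregate from the finished rows and raises
if reconciliation fails, so the fixture cannot drift silently.

## Synthetic-data generator

`simulate_dataset` emulates the input structure: eight populations with
the release-2.0 sample sizes; per-site call rates drawn uniformly from
(0.995, 1.0), matching the observed per-mille variation in allele numbers;
`an = 2·Binomial(N, call rate)` and `ac = Binomial(an, f)` per site and
population; background sites at the singleton scale `1/(2N_total)`;
founder alleles restricted to population subsets (default: one
hypofibrinogenemia founder at f = 3×10⁻³, the scale of the known FGG
founder allele, absent from East Asians); predictor consensus reached with
probability 0.8 for truly-deleterious missense sites and 0.001 for benign
ones; database labels drawn per-site at rates chosen so that roughly 30%
of deleterious sites are reported, as in the real spectrum.  Default
per-gene site counts follow the published class mix at reduced scale.
True frequencies above 0.5 are rejected — the model is for rare variants.

What the generator does **not** emulate: linkage/haplotype structure,
genotype-level data (allele counts only), sequencing-depth heterogeneity
beyond the per-site call rate, relatedness, and population substructure
within groups.  Passing recovery tests therefore demonstrate correctness
of the counting and estimation pipeline under binomial sampling, not
robustness to cohort artefacts.

The estimator-recovery test and the acceptance script's recovery run use a
single-site configuration (q* = 10⁻³ at an allele number of 2×10⁵, perfect
predictor concordance) so that the property isolates binomial sampling
error: the pipeline estimate then equals the binomial MLE and must fall in
the central 99% interval of Binomial(2×10⁵, 10⁻³) in ≥ 99% of 1000 seeded
replicates.  With predictor noise enabled the estimate is deliberately
conservative (classification misses dilute q̂ downward), which is a
property of the published rule set, not of the estimator.

## Numerical and presentation choices

All internal arithmetic is unrounded; rounding happens only at
presentation: frequencies to 3 significant figures, per-10⁶ prevalence to
2 decimals (2 significant figures below 0.095, e.g. 0.024), per-10³
prevalence to the nearest integer, empty strata printed "-" but carried as
numeric zero.  The panel-wide recessive table sums the per-gene values
*after* rounding them to table precision (the convention of the published
summary table, whose world-wide 10.54 equals 0.31+0.69+9.54; the unrounded
sum is 10.547); `sum_rounded=False` gives the unrounded sum.

Known irreproducibilities in the source aggregates, all documented rather
than matched:

* the per-gene prevalence column mixes rounding conventions: the FGG
  non-Finnish European entry (23.05) reproduces only from unrounded q,
  while the FGG Finnish (2.40) and East Asian (0.47) entries reproduce
  only from the 3-s.f.-rounded q.  Consequently the summary-table entries
  for East Asians (1.05) and Finns (2.42) cannot be reproduced under any
  single convention (we obtain 1.06 and 2.43);
* the global recessive rate quoted after removing the founder variant
  (3.2 per million) does not follow from the printed data by any
  aggregation we tried; our ALL-group recomputation gives 2.3 per million.
  The per-population figure for Africans/African Americans (4 per million)
  does reproduce and is asserted;
* the global reported-variants-only rate (6.8 per million) is not the sum
  of its own printed per-gene components (0.033 + 0.16 + 6.68 = 6.87); the
  per-gene values reproduce exactly and are the ones asserted.

## Limitations

Exome-based burden misses promoter/deep-intronic variants, poorly called
indels and gross deletions (including the recurrent 11-kb FGA deletion
that accounts for a substantial fraction of afibrinogenemia alleles), so
recessive estimates are lower bounds in that respect; conversely,
predictor-consensus false positives and incompletely penetrant alleles
push estimates upward.  No confidence intervals are attached to the point
estimates, penetrance is not modelled, and the deleteriousness rules take
predictor outputs as given — the package never runs the prediction tools
themselves.
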