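# Methods

## Scope and data model

`sliprio` operates downstream of alignment, variant calling and annotation:
its input is a per-cohort table of annotated variant calls (gene, functional
class, two reference-panel allele frequencies, SIFT/PolyPhen-2/PhyloP/
PhastCons scores, segmental-duplication flag, carrier read depth, carrier
proband identifiers), together with extended PED pedigrees, per-sample
genotypes (minimal VCF) and user-supplied gene-set collections (GMT).
Coordinates are 1-based inclusive, as in VCF. Frequencies are held
internally as fractions in [0, 1]; the TSV dialect carries percent columns
(suffix `_pct`) because cohort reports conventionally print percentages.
`NA` is the only missing-value token in the dialect — an empty cell is an
error, which guards against silent column drift; the dbSNP column also
accepts `.`. A variant carried by several probands occupies one row with a
comma-separated carrier cell and is counted once wherever counting is by
distinct variant.

## Filtering and classification

**QC filter.** Retained classes are the protein-affecting ones
(nonsynonymous, stop-gain/loss, splice, frameshift and non-frameshift
indels); variants in segmental duplications and variants whose carrier depth
is below 10 are excluded. Exclusions are attributed to the first failing
rule in a fixed order (class, segdup, depth) so the per-rule tallies are
deterministic. The depth rule is stated against carriers; published wording
of this style of filter ("below 10 in all probands") is ambiguous between
any-carrier and every-carrier semantics, so both are implemented
(`depth_mode`), defaulting to the permissive any-carrier reading: the stored
`min_depth` is interpreted as the best carrier's depth.

**Frequency tiers.** Novel means absent from both panels; a bare dbSNP
identifier without frequency information does not preclude novelty (such
records exist in practice). Otherwise the tier is set by the maximum over
available panel frequencies — conservative, since a variant common in either
panel is not rare; `tier_panel="kg"` restricts to the 1000 Genomes panel.
Rare is strictly `f < 0.01`: published usage mixes "<1%" and "≤1%", no
worked-example record sits exactly at 1%, and the bound is a one-line config
override (`rare_threshold`). The low-frequency tier is closed at 5%
(`f ≤ 0.05`); above is common.

**Deleteriousness.** SIFT ≤ 0.05 or PolyPhen-2 ≥ 0.85. Loss-of-function
classes (stop-gain/loss, splice, frameshift) are exempt from the score
predicate by default: substitution predictors routinely emit uninformative
scores (e.g. SIFT 1.0) for truncating alleles, and truncation is damaging
on mechanism. With both scores absent a substitution is conservatively
called benign.

**Truncation.** The percent of protein lost to a premature stop at residue
`p` of an `L`-residue isoform is `100·(L − p + 1)/L`, rounded to 1 decimal —
the stop codon's own residue counts as missing. The packaged isoform lengths
for the stop-gain fixture were back-derived from the printed percentages
under this formula; one record (OR52B2 p.C243X) admits no integer length
reproducing its printed 25.0% exactly and is stored as 323 aa (25.1%).

## Screens

**Candidate screen** restricts to a user-replaceable gene list (the packaged
default is the 19 literature candidates), tallies variants per frequency
tier, and shortlists the novel/rare records. Matching is exact and
case-insensitive; no alias resolution is attempted. Tier shares are
percentages of the total to 1 decimal. The common and low-frequency tallies
of a full cohort cannot be reconstructed from a rare/novel shortlist, so the
share computation accepts externally supplied counts for those tiers.

**Stop-gain screen** keeps truncating variants that are novel/rare and
predicted deleterious; stop-loss and frameshift classes are screened
alongside stop-gains.

**Compound-het search** groups qualifying variants (coding SNV/splice/
frameshift classes, novel/rare, deleterious, outside segmental duplications)
by (proband, gene) and keeps groups of size ≥ 2 after proximity pruning:
*both* members of any same-chromosome pair ≤ 10 bp apart are removed, since
such clusters are characteristic alignment artefacts and either member is
suspect. Homozygous rare deleterious genotypes would also put two variant
alleles in one gene; they are reported as a separate category
(`hom_alt_rare_deleterious`), not as compound hets.

**Multiple-hit pooling** collects candidate-shortlist, stop-gain and
compound-het hits per proband and reports probands with ≥ 2 distinct
variants. A compound-het gene counts as one hit whose variants all enter the
distinct-variant tally, so a lone trans pair already qualifies. Phase is
attached afterwards by the segregation stage, so both pre- and
post-segregation readings of the report are available to the consumer.

## Segregation

Affection in children is derived from CELF-R expressive/receptive scores
standardized to mean 100, SD 15: affected iff either score is strictly below
77.5 (1.5 SD below the mean). Parents are never classified from scores —
the instruments are child-normed — and children with other diagnoses but no
scores stay `unknown` and drop out of co-segregation tallies.

Parental origin: both parents hom-ref with a het child is `de_novo`; one
carrying parent resolves the origin; one missing parental genotype with the
other hom-ref yields `inferred_*` from the missing side. A het child of two
hom-ref parents is exactly the de novo signature and is not a Mendelian
error; a hom-alt child of a hom-ref parent (or hom-ref child of a hom-alt
parent) is flagged by the audit. Compound-het groups larger than two are
phased pairwise and called trans if any pair resolves to opposite parents.
Co-segregation over genotyped, phenotyped children: `co_segregates` when
every informative child's carrier status matches its affection;
`contradicts` when none does; `partial` otherwise; `uninformative` with
fewer than two informative children.

## Pathway sharing and its permutation tail probability

Each proband's gene set holds the genes of its qualifying variants
(disruptive classes, novel/rare, deleterious), deduplicated; probands with
empty sets stay in the cohort denominator by default (`include_empty`) —
they can never share a pathway, so including them is conservative. The
sharing statistic per pathway is the number of probands whose set intersects
it. The null redraws each proband's list uniformly without replacement from
the universe of *all* genes with variants (not only qualifying ones),
independently across probands and permutations, keeping list sizes fixed;
with `n_perm` permutations the reported `fdr` is
`#(permuted count ≥ observed) / n_perm` — a per-pathway empirical
permutation tail probability, *not* a cross-pathway corrected rate; the
field is named `fdr` for continuity with how such values are reported in
this literature. An optional max-statistic family-wise correction is
available (`fwer=True`). Reports carry a majority flag
(observed > cohort/2). The generator is seeded explicitly and the seed is
recorded in every result row.

Because the sharing statistic is a small integer, the null distribution of
`fdr` is a staircase; uniformity holds exactly only for the tie-randomized
permutation rank `(#{perm > obs} + U·(#{perm = obs} + 1))/(n_perm + 1)`
(`randomized_null_rank`), which the calibration tests use. The acceptance
suite checks it over 200 independent null cohorts at `n_perm = 200`
(20 probands, universe of 400 genes, pathway sizes 20–40, list sizes 3–8 —
sizes chosen to keep the statistic away from saturation) with a
Kolmogorov–Smirnov test at α = 0.01.

## Gene-set enrichment

The pooled gene list (union of proband gene sets) is tested set-by-set with
the hypergeometric upper tail `P(X ≥ k)`, accumulated in log space from
exact log-binomial terms so deep tails do not underflow; exhaustive
enumeration (universes ≤ 12) and an independent library implementation
cross-check it in the tests. Expected counts are `set·list/universe`.
Benjamini–Hochberg correction runs over all tested sets; reports keep rows
with p < 0.01, FDR < 0.01 and set size > 10 by default. The flat
(graph-unaware) test is intentional; GO-DAG conditional testing is out of
scope. Frequency-stratified lists apply a relaxed filter — nonsynonymous and
stop-gain/loss at ≤ 5% 1000 Genomes frequency, regardless of predictions —
and assign each variant's gene to exactly one stratum by that variant's
frequency (novel requires absence from both panels; the 1%/5% cuts use the
1000 Genomes panel; variants reported only in EVS fall outside the
frequency-cut strata). Genes may appear in several strata via different
variants.

## Synthetic cohorts

The generator emulates the study design, not any particular dataset: 43
nuclear families (1–3 genotyped siblings), ~600 background variants over 300
genes plus the 19 candidate genes, and planted signals. Distributional
choices are the package's own:

* tier mixture 55/20/15/10% (common/low/rare/novel), allele frequencies
  log-uniform within tier bounds (common 5–50%, low 1–5%, rare 0.01–1%);
* benign substitutions draw SIFT above 0.05 and PolyPhen below 0.85
  (beta-shaped); planted deleterious variants draw beyond the cuts — the
  separation is deliberately clean so that planted-signal recovery measures
  the screens, not score overlap;
* background variants in candidate genes are forced to common/low tiers, so
  rare/novel candidate-gene signal exists only where planted;
* founder genotypes are drawn per haplotype from the variant's frequency;
  children inherit one haplotype per parent per gene, giving within-gene
  phase consistency; planted trans pairs sit on opposite parental
  haplotypes > 10 bp apart; planted de novos are absent from all founders;
  planted variants are private to their family, as validated ultra-rare
  variants effectively are (their printed panel frequency still reflects the
  tier label);
* children's ELS/RLS scores are drawn truncated on the side implied by their
  assigned affection (probands affected by ascertainment; carrier siblings
  affected with probability `penetrance`, default 1; non-carriers at a 5%
  background rate), so `affection_status` round-trips exactly;
* the pathway signal plants one qualifying rare variant in a target-set gene
  in 70% of probands, cycling the set's genes.

Emitted genotypes are unphased; phase exists only inside the generator. All
outputs are byte-identical for a fixed seed. What passing recovery tests
shows is that the screens implement their definitions exactly on clean,
Mendelian-consistent data; it does not show robustness to genotyping error,
score miscalibration, population structure or linkage disequilibrium, none
of which the generator models.

## Worked-example fixtures

Three dialect-conformant tables transcribed from the published study ship
with the package: the 11 validated novel/rare candidate-gene variants (one
shared by three probands), the 7 validated rare stop-gains with a companion
protein-annotation table, and the 25 records over 11 genes with more than
one rare variant in the same proband. They drive the acceptance checks:
5 novel + 6 rare candidate variants (13.5% and 16.2% of the 37 validated
candidate-gene calls, using the published common/low tallies of 18 and 8 as
inputs), 7 retained stop-gains with maximum panel frequency 0.22%, and 11
compound-het genes.

## Numerical and problem-size choices

Percent/fraction conversion normalizes to 10 significant digits so the same
logical frequency is bit-identical whether it arrives via a percent column
or a VCF INFO fraction (float32); writing restores percent strings exactly
for values with ≤ 4 decimal digits of percent. Scores are serialized by
Python float repr (exact round-trip). Report rows sort by (chromosome,
position); pathway results by (fdr, −observed, set id). Test problem sizes —
200-replicate calibration at `n_perm = 200`, 100 random cohorts of ≤ 20
probands × ≤ 200 variants for oracle equivalence, a 12 500-variant cohort
for the spectrum goodness-of-fit — were chosen as the smallest scales at
which the statistical assertions are stable.

## Known limitations

* Indels are representable (anchored ref/alt) but indel-specific annotation
  is minimal; the VCF subset excludes phased genotypes and breakends.
* No liftover, no aliasing of gene symbols, no recomputation of prediction
  scores.
* The enrichment FDR is plain Benjamini–Hochberg; published tables of this
  kind sometimes print non-monotone FDR columns whose construction is not
  described, and no attempt is made to reverse-engineer them.
* X-linked inheritance is not special-cased: hemizygous male genotypes must
  be encoded as diploid calls.
* The pathway permutation preserves list sizes but not gene-level covariates
  (length, mutability), which a real exome analysis might want to match.
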