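# sliprio

Exome variant prioritization for cohorts of children with specific language
impairment (SLI) — a developmental disorder of spoken language despite normal
nonverbal intelligence and opportunity. Given an annotated exome variant
table for ~40 unrelated probands from nuclear families, `sliprio` runs the
post-annotation prioritization used in family-based rare-variant studies:

* **QC filtering** — drop non-protein-affecting classes, segmental-duplication
  regions and low-depth calls;
* **frequency tiering** — novel (absent from 1000 Genomes *and* EVS), rare
  (< 1%), low-frequency (1–5%), common (> 5%);
* **candidate-gene screen** — all coding variants in 19 literature candidates
  for speech/language/reading disorders (*CMIP, ATP2C2, CNTNAP2, NFXL1,
  FOXP1, FOXP2, DYX1C1, KIAA0319, DCDC2, ROBO1, SRPX2, GRIN2A, GRIN2B, ERC1,
  SETBP1, CNTNAP5, DOCK4, SEMA6D, AUTS2*), with a rare/novel shortlist;
* **stop-gain screen** — rare/novel truncating variants predicted deleterious,
  annotated with the percent of protein lost;
* **compound-heterozygote search** — probands with ≥ 2 rare/novel deleterious
  coding variants in one gene (SIFT ≤ 0.05 or PolyPhen-2 ≥ 0.85; variants
  within 10 bp of each other excluded), phased against parental genotypes;
* **multiple-hit detection** — probands with ≥ 2 distinct variants across the
  screens above;
* **segregation analysis** — parental origin (including de novo flagging),
  trans/cis phase, and co-segregation with affection status derived from
  CELF-R expressive/receptive language scores (affected iff ELS or RLS
  > 1.5 SD below the mean of 100, i.e. < 77.5);
* **pathway sharing** — for each pathway, the number of probands whose
  qualifying-gene set intersects it, with an empirical permutation tail
  probability: probands' gene lists are redrawn uniformly from all genes with
  variants, and `fdr = #(permutation count ≥ observed) / n_perm`;
* **gene-set enrichment** — pooled hypergeometric upper tail
  `P(X ≥ k), X ~ Hypergeom(N, K, n)` against the all-genes-with-variants
  background, Benjamini–Hochberg corrected, plus frequency-stratified gene
  lists (novel / < 1% / 1–5%).

Because real cohorts of this kind are access-restricted, the package ships a
seeded synthetic-cohort generator (`sliprio.simulate`) that emulates the
study design — nuclear families, Mendelian transmission from simulated
parental haplotypes, a realistic frequency spectrum, and planted candidate /
stop-gain / trans-compound-het / de novo / pathway signals recorded in a
truth manifest — and packaged worked-example fixtures transcribed from the
published tables of a 43-proband SLI exome study.

## Worked example

```python
from sliprio.fixtures import load_candidate_shortlist, load_stopgain_table
from sliprio.candidates import screen_candidates
from sliprio.highrisk import stopgain_screen
from sliprio.models import FrequencyTier

variants, carriers = load_candidate_shortlist()
summary, shortlist = screen_candidates(variants, carriers)
print(summary.overall_counts[FrequencyTier.novel],
      summary.overall_counts[FrequencyTier.rare], len(shortlist))

sg, sgc = load_stopgain_table()
records = stopgain_screen(sg, sgc)
print(len(records), max(r.variant.freq_evs or r.variant.freq_kg for r in records))
```

prints

```
5 6 11
7 0.0022
```

— of the 11 validated candidate-gene variants, 5 are novel and 6 rare (the
*ATP2C2* substitution shared by three probands counts once), and all 7
validated stop-gains pass the rare/novel screen, the most frequent at 0.22%
in the reference panels.

The same analyses run from the shell:

```sh
sliprio simulate --outdir cohort --seed 1
sliprio run --variants cohort/variants.tsv --ped cohort/cohort.ped \
            --gmt cohort/pathways.gmt --vcf cohort/genotypes.vcf \
            --outdir reports --n-perm 1000 --seed 1
```

which writes per-stage TSV reports and a `run_log.json` that records every
threshold and seed needed to reproduce the run.

## Layout

- `src/sliprio/models.py`, `io.py` — domain types; the 17-column annotated
  variant TSV dialect, extended PED, GMT and minimal-VCF readers/writers
- `filters.py` — QC filter, frequency tiers, deleteriousness, truncation
- `candidates.py`, `highrisk.py` — the screens
- `segregation.py` — affection, transmission, phasing, co-segregation
- `pathways.py`, `enrichment.py` — permutation sharing test, hypergeometric
  enrichment, frequency strata
- `simulate.py` — synthetic cohorts with truth manifests
- `pipeline.py`, `cli.py` — orchestration and the `sliprio` command

See `docs/methods.md` for the modelling choices, parameters and limitations.
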