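# famprior

Family-based whole-exome variant prioritization.

When a disease clusters in a family but the established risk genes come
back clean, the discovery route is whole-exome sequencing of affected and
unaffected relatives followed by a filtering cascade: keep only
well-supported genotypes, demand co-segregation with disease under an
explicit inheritance model, discard anything common in control
populations, and rank what is left by predicted pathogenicity. `famprior`
implements that cascade as a reusable, fully tested pipeline, motivated
by the setting in which it is typically applied — pulmonary arterial
hypertension (PAH) families screened first against a known-gene panel
(BMPR2, CAV1, TBX4, SOX17, KDR, …) and then exome-wide.

The package is aimed at statistical-genetics and clinical-genomics
developers who need the *logic* of family-based prioritization —
segregation under incomplete penetrance, trio de novo detection,
novelty against population databases, predictor aggregation — as
importable, property-tested functions rather than as a point-and-click
suite.

## The cascade

For each normalized biallelic variant with per-sample genotype calls
and an annotation bundle:

1. **Genotype QC** — a call passes if depth ≥ 10, GQ ≥ 20, and its
   allele balance fits the genotype (het within [0.25, 0.75], hom-alt
   ≥ 0.85). Failing calls are *masked to missing*, never used to discard
   the variant outright.
2. **Panel pre-screen** — variants in the known-gene panel are triaged
   separately (a pathogenic hit there ends the exome-wide search).
3. **Segregation** — compatibility with per-family inheritance models:
   * `dominant_complete`: every affected carries, every unaffected is hom-ref;
   * `dominant_incomplete`: every affected carries, unaffected
     unconstrained (healthy obligate carriers allowed);
   * `de_novo`: proband carries, both parents confidently hom-ref
     (hom-ref **and** above the depth/GQ thresholds, guarding against
     parental allele dropout);
   * `recessive_hom`: affected hom-alt, genotyped parents of affected
     het, no unaffected hom-alt.
   A missing genotype required by the model makes the variant
   *uninformative*, never compatible. The engine is verified against an
   independent brute-force predicate over all 3ⁿ genotype assignments.
4. **Frequency / novelty** — removed if any control database (gnomAD
   exomes/genomes, Kaviar, Beacon, Bravo, ESP, 1000G phase III) reports
   an allele frequency strictly above 1%; *novel* means every database
   reports the variant absent or at exactly 0.
5. **Pathogenicity tiers** — in-silico predictor calls are tallied as
   *m* damaging of *n* informative tools (unknown calls leave the
   denominator); tier 1 = protein-truncating, tier 2 = missense with
   damaging fraction ≥ 0.5 and CADD ≥ 20, tier 3 = the rest (dropped
   from the report by default).
6. **Ranking** — tier, then CADD descending, then damaging fraction,
   then genomic coordinate: deterministic, byte-reproducible output.
7. **Network context** — shortest-path distance from each candidate gene
   to the nearest known disease gene on a user-supplied interaction edge
   list (annotation only, never a filter).

A built-in simulator generates pedigrees, Mendelian-consistent
genotypes, spiked causal variants, and decoys that each violate exactly
one filter, so the whole cascade is verifiable offline.

## Worked example

Simulate the two-family study design — a six-member family segregating a
dominant missense variant with an unaffected carrier, and a trio with a
de novo stop-gain — then run the cascade:

```bash
famprior simulate --scenario two_family --seed 5 --out demo/
famprior run --vcf demo/cohort.vcf --ped demo/cohort.ped \
             --config demo/config.yaml --out demo/report.tsv
# INFO famprior.run: 2 candidate(s), 1 panel hit(s) -> demo/report.tsv
```

The report (columns abridged):

| rank | tier | gene | hgvs_p | consequence | m/n | cadd | model | aff. carriers | unaff. carriers | net. dist |
|---|---|---|---|---|---|---|---|---|---|---|
| 1 | 1 | TRAF2 | p.Cys139Ter | stop_gain | 5/9 | 35.0 | de_novo | 1 | 0 | 1 |
| 2 | 2 | TNIP2 | p.Ser233Gly | missense | 12/19 | 25.8 | dominant_incomplete | 2 | 1 | 4 |

Reading it: the stop-gain ranks first (tier 1, truncating, CADD 35,
arising de novo in the trio proband); the missense ranks second (12 of
19 predictors damaging, CADD 25.8, carried by both affected members plus
one unaffected relative — the pattern a dominant model with incomplete
penetrance accepts and a fully penetrant one rejects). Both are novel
(AF 0 in every control database). One decoy lands in the BMPR2 panel
pre-screen; the other decoys (low-quality genotypes, 5% population
frequency, non-segregating, predicted benign) are rejected each by the
single filter built to catch it, visible in the `filter_trace` column.

The same analysis from Python:

```python
from famprior import make_two_family_fixture, run_prioritization

paths = make_two_family_fixture("demo/")
report = run_prioritization(paths.vcf, paths.ped, paths.config)
for c in report.candidates:
    print(c.rank, c.variant.annotation.gene, c.tier, round(c.assessment.cadd, 1))
# 1 TRAF2 1 35.0
# 2 TNIP2 2 25.8
```

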