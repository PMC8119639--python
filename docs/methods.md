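# Methods

## Scope and model

`famprior` prioritizes single-nucleotide variants from family-based
whole-exome sequencing. The unit of analysis is a normalized biallelic
site; multiallelic VCF records are decomposed per ALT allele, with
copies of other alternate alleles counted as reference for the
decomposed record. Structural variants, CNVs, phased genotypes and gVCF
blocks are out of scope, as are recomputation of any in-silico score
(CADD and per-tool predictor calls are consumed as annotations) and
compound-heterozygous recessive logic (which would require phasing).

Coordinates are 1-based throughout (VCF convention); cDNA positions are
1-based within the coding sequence, so the codon of position *p* is
⌈*p*/3⌉ (HGVS convention). Sex chromosomes are treated autosomally;
X-linked models are not offered.

## Genotype quality control

Per-genotype thresholds default to field-standard short-read exome
values: depth ≥ 10 reads, genotype quality ≥ 20 (phred), heterozygous
allele balance within [0.25, 0.75], homozygous-alternate alternate-read
fraction ≥ 0.85. Hom-ref calls carry no balance constraint at this
stage; reference-call confidence is enforced where it is load-bearing,
in the de novo parental check. A failing genotype is masked to missing
rather than removing the variant, because one bad sample should not
delete a true segregating variant — the segregation stage decides
whether the surviving genotypes still support a model. All thresholds
are config-overridable.

## Segregation semantics

Carrier means het or hom-alt (dominant logic concerns allele presence).
Individuals with unknown affection status are excluded from model
constraints but still counted for transmission checks. Informativeness
is model-specific: a variant is *uninformative* (and therefore not
compatible) when a genotype the model's rule needs is missing —
affected members for the dominant models, additionally the unaffected
members for complete penetrance and the recessive model, the proband
and both parents for de novo. The de novo proband defaults to the first
affected individual with both parents in the pedigree; a config
override is available. De novo parents must be hom-ref *and* exceed the
depth/GQ thresholds, so lowering `min_depth` can only grow the de novo
set — plain absence of the alternate allele is not accepted, since
parental allele dropout is the dominant failure mode of naive de novo
calling.

The engine is validated against `brute_force_segregation`, a separate
declarative restatement of each model predicate sharing no code with
the engine, by exhaustive enumeration of all 3ⁿ genotype assignments on
trio, quartet and six-member pedigrees (n ≤ 6, 729 assignments ×
4 models).

## Frequency, novelty, panel

The frequency rule removes a variant when any configured control
database reports an allele frequency strictly above `max_pop_af`
(default 0.01); a variant at exactly the cutoff survives. The maximum
across databases is used rather than a per-database rule — with a
shared cutoff the two are equivalent, and the maximum is the
conservative reading. Novelty requires every database to report the
variant absent or at exactly zero; a database with no entry supports
novelty (absence of evidence is how novel variants appear in practice).
The known-gene panel is a plain-text config input; panel-gene variants
are reported in a separate partition rather than silently dropped,
because a pathogenic panel hit changes the clinical conclusion, not
just the ranking.

## Pathogenicity tiers and ranking

Predictor calls are normalized per tool to damaging / tolerated /
unknown via a configurable translation table; unknown calls leave the
denominator, so tallies such as 12/19 and 5/9 can coexist under one
tool roster, and the damaging fraction is undefined (not zero) when no
tool is informative. Tier 1 is protein-truncating (stop-gain as
annotated; frameshift/splice would qualify if a schema maps them). Tier
2 is missense with damaging fraction ≥ 0.5 and CADD ≥ 20 — thresholds
at the conventional "majority of tools" and "top 1% deleteriousness"
marks; a missense variant with no informative predictors is gated on
CADD alone, since truncating and thinly annotated sites are sparsely
covered by missense predictors. Everything else is tier 3 and excluded
from the default report (`max_report_tier = 2`): the cascade's output
is a short candidate list, and survivors that every tool calls benign
are triage-outs, not candidates. Setting `max_report_tier = 3` restores
them.

No numeric priority score is invented: ranking is lexicographic (tier,
CADD descending with missing last, damaging fraction descending,
genomic coordinate), which reproduces the qualitative truncating-first
ordering without arbitrary weights and is fully deterministic.

Every variant's filter trace records all five stage verdicts (not just
the first failure), so a rejected variant shows exactly which rules it
broke.

## Network proximity

The interaction graph is undirected and unweighted — interaction
databases are used here qualitatively, and edge-confidence modelling
would suggest a precision the input does not have. Proximity is
breadth-first shortest-path distance to the nearest seed gene; a seed
gene scores 0, a gene absent from the graph is unreachable. Proximity
annotates the report and is never a filter: network context is
supporting evidence, not a selection criterion. The bundled edge list
is a small illustrative synthetic stand-in (candidate genes, the seed
panel, and the NF-κB axis connecting them), not a database export.

## Synthetic data generator

The generator emulates the two study designs the pipeline targets: a
six-member extended family (index case, spouse, index's sibling, two
children, sibling's child) segregating a dominant variant with
incomplete penetrance, and a trio with a de novo variant. Two built-in
spike cards encode the worked-example causal variants: a missense
change at coding position 697 (codon 233, Ser→Gly; 12 of 19 predictors
damaging; CADD 25.8) and a stop-gain at coding position 417 (codon 139,
Cys→Ter; 5 of 9; CADD 35), both with explicit zero frequency in all
seven control databases. Spike genomic coordinates live on a small
synthetic contig set; no genome build is referenced.

Simulated genotypes follow Mendelian gene-drop from founder carriers
(dominant: one het founder; recessive: all founders het; de novo:
proband het, all others hom-ref). Affection is drawn per qualifying
carrier with probability `penetrance` (default 0.8 in the dominant
scenario — high enough that multi-case families arise, low enough that
unaffected carriers do); a draw with no affected member is resampled on
an incremented sub-seed. The fixed worked-example family instead
hard-codes its carrier and affection states (two affected het carriers,
one unaffected het carrier, three hom-ref relatives): the real family's
penetrance is unknown, only its realization, so no penetrance value is
asserted.

Read depths are negative-binomial with mean 60× and dispersion 10
(typical clinical exome coverage; overridable), GQ uniform on [60, 99],
and allelic depths binomial given the genotype. Generated calls are
QC-clean by construction (depth and het allele balance are resampled
into the accepted bands): the generator's contract is that signal
enters clean and noise enters only through the explicit
`genotype_error_rate`, which flips a genotype to a uniformly chosen
other genotype. The corruption decision for each genotype uses a random
stream keyed by (seed, variant, sample) but not by the rate, so the
corrupted set at a lower rate is nested inside the set at a higher rate
— this makes recovery-versus-error-rate comparisons monotone by
construction rather than only in expectation.

Randomness is split per variant and per sample from the master seed
(seed-sequence keys, not a shared stream), so adding background
variants cannot perturb spiked genotypes, and identical seeds give
byte-identical VCFs.

Decoys each violate exactly one filter while mirroring the causal
genotype pattern otherwise: carrier depth forced to 4 (QC), gnomAD
frequency 0.05 (frequency), allele moved from the affected to an
unaffected founder (segregation), 1/19 damaging with CADD 3.2
(pathogenicity), and a BMPR2 location (panel). Background variants are
either common polymorphisms (AF drawn in [0.02, 0.30]) or novel but
predictor-benign sites, gene-dropped through each pedigree so all
generated data are transmission-consistent.

What passing on synthetic data does *not* show: the generator makes no
attempt at realistic exome-wide variant counts (tests use tens, not
tens of thousands, of sites), linkage disequilibrium, sequencing-error
structure beyond the flat genotype-error model, annotation
disagreement between transcripts, or population stratification in the
frequency fields. Results on it validate the cascade's logic and
bookkeeping, not variant-calling accuracy upstream.

## Problem sizes and reproducibility

Exhaustive oracle checks run over 3⁶ = 729 assignments per model;
recovery/rejection studies use 100 seeded replicates (50 dominant, 50
de novo) with 4 background variants and all 5 decoys each, chosen to
exercise every filter on every replicate while keeping the suite quick
to iterate on. `scripts/acceptance.py` re-derives all reported numbers
from a fresh simulation at run time; nothing is cached or hard-coded,
and every random stream descends from the `--seed` argument.

## Known limitations

* Segregation treats each family independently; cross-family evidence
  aggregation (e.g., gene-level burden across families) is not modelled.
* The recessive model requires observed parental hets only for
  genotyped parents, so an undetected consanguineous founder effect is
  not distinguishable from genotyping gaps.
* Incomplete-penetrance dominance accepts any unaffected-carrier count;
  with small pedigrees this is permissive by design and relies on the
  frequency and pathogenicity gates for specificity.
* HGVS parsing covers substitutions (including Ter); indel/frameshift
  protein notation is passed through unparsed with consequence
  `unknown`.
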