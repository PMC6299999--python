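# Methods

This note documents the models, numerical choices and limitations behind
`replong`. Coordinates are 0-based half-open internally; tables emit both
conventions (1-based inclusive spans divide exactly into unit length ×
copies for pure loci). `N` bases count as mismatches and as non-GC
everywhere.

## Repeat detection and purity

A candidate repeat is seeded at every position whose unit has an exact
adjacent copy. The region is extended left and right against the perfect
tiling of the anchored unit with score +1 per match and −k per mismatch
(default k = 3), keeping the score-maximal endpoints (ties extend
further); an X-drop bound of 30 stops extensions whose running score falls
too far below the best. Surviving candidates must meet the length, copy
and purity floors (default purity ≥85%), and overlapping calls are
resolved deterministically: highest score, then smallest unit, then
leftmost — the smallest-unit rule also collapses non-primitive units
(`ACAC` vs `AC`). The detector is validated against an exhaustive
prefix-sum window-scan oracle on sequences up to 2 kb.

Purity is the percentage of positions matching the best of the unit's
cyclic tiling phases, so a repeat whose detected boundary starts mid-unit
is not penalised.

## Variability score

The published variability predictor for tandem repeats is a regression on
unit length, reference copy number and intralocus homology whose exact
coefficients are not part of this package's inputs. The score here is an
explicit, overridable linear form:

    score = intercept + a·ln(copies) + b·(purity/100) + c·unit_len

with defaults (−2.0, 1.0, 1.0, −0.05). These place pure dinucleotide
repeats of ≥15 copies above 1 (the classic "usable for genotyping" band)
and short or impure loci near 0, so the selection thresholds 0.4 / 0.8 / 1
retain their intended meaning. The score is monotone non-decreasing in
copies and purity whenever a, b ≥ 0. Any coefficient set can be supplied
per call.

## Target selection

Six tiers are applied in order, each locus taking the first matching
label: (1) coding with span ≤500 bp; (2) regulatory with score ≥1 and span
≤500 bp; (3) regulatory with 0.4 < score < 1, any span; (4) remaining
regulatory loci within 1000 bp of a listed disease gene; (5) intronic
with score >0.8, ≥15 copies, unit ≥2 bp, span ≤500 bp, GC 30–70% and ≥3
available probes, thinned to a quota spread evenly along the chromosome
(quota-many equal bins, best-scoring locus per bin, round-robin
back-fill); (6) intergenic with score >1 and the same structural bounds.
Annotation precedence is coding > regulatory > intronic > intergenic, with
strand-aware up-/downstream windows (default 1000 bp) derived from gene
and miRNA features.

## Probe design

Each target gets up to four probes (default 120 bp): flanks abutting the
repeat, a spanning probe centred on the repeat midpoint, and a double
probe joining 60 bp of each flank. The genomic uniqueness screen
re-expresses a seeded-aligner criterion without an external aligner: a hit
is any genomic window, either strand, with ≤3 mismatches in the first
15 bases and ≤6 mismatches overall (both configurable); a probe is
*unique* with exactly one hit, *cluster-specific* when all secondary hits
fall inside declared duplication-cluster intervals, *ambiguous* otherwise.
Double probes are screened per segment and take the worse verdict.
Failed flanking/double probes shift outward up to 500 bp — coarse 10 bp
steps, then 1 bp refinement — and the smallest passing shift wins. Probes
with GC <40% or >70% are replicated 4×; boundaries are strict (GC exactly
0.40 or 0.70 keeps the base replication).

## Read preparation

Adaptors are removed positionally (32 nt each side; reads ≤64 nt are
dropped and counted). Alignment is restricted to ±1000 bp windows around
catalogued targets. Shared 13-mers (capped at 4 genomic placements to
exclude repeat-interior k-mers) vote for diagonals; a single clean
diagonal is placed by a maximal-scoring-subsegment scan, two clean
diagonals — the geometry of a whole-unit repeat-length polymorphism — are
stitched with one affine gap, and anything else falls back to affine-gap
local dynamic programming (match +1, mismatch −3, gap open −5, extend −2)
over a k-mer-banded stretch of the window. Reads scoring below 30 are
unmapped. Duplicates collapse identical (chrom, start, end, strand)
placements, keeping the best score then the lexicographically smallest
read id; the operation is idempotent.

Yield categories are nested by construction: useful ⊆ spanning ⊆
intersecting ⊆ within-1000 ⊆ mapped ⊆ total. "Useful" means the alignment
covers the repeat plus 20 nt of both flanks; a soft-clipped read whose
clipped tail re-matches the missing flank (≤10% mismatches over ≥20
bases, either orientation) is rescued into spanning/useful, since the
clip demonstrates the read physically crosses the repeat.

## Genotyping

Per target a locus library holds the 20 reference bases on each side of
the repeat (shorter flanks near contig edges, minimum 12). Flank matching
tolerates ⌈0.1·flank_len⌉ substitutions and no indels (indel-containing
flanks are handled upstream by soft-clip logic); both read orientations
are tried and ambiguous multiple placements take the outermost pair,
flagged. Both flanks found ⇒ a spanning call with the exact inter-flank
distance; one flank ⇒ a partial call measured to the read end, reported
as a lower bound; the per-read copy number is length/unit, two decimals.

Genotypes take the modal spanning length, pooling calls within one unit
of the mode as stutter; ties break toward the longer allele and are
flagged (the choice is arbitrary but documented). A call requires modal
support ≥5 — matching the ≥5× coverage floor used when tabulating
sequenced loci — and hemizygous males get exactly one allele; the diploid
model adds a second mode needing the same support and ≥20% of informative
reads. A locus is *expanded* when it yields no spanning call and at least
one partial call exceeding the reference copy number; the reported bound
is the maximum partial call in copies and bp. Compound repeats are
decomposed by a greedy left-to-right parse (maximal first-motif run,
separator, maximal second-motif run); a missing separator falls back to
the motifs parsed so far with a warning. For sequenced samples the modal
allele's per-position majority consensus across its supporting reads is
decomposed, which removes scattered substitution errors the way a
Sanger-validation step would.

## Segregation cascade

The candidate filter is a fixed stage order with a per-locus audit trail:
outside_interval → concordant → non_segregating → shared_across_families
→ found_in_controls → candidate. Segregation under the X-linked recessive
model requires every affected male to carry the proband allele, no
unaffected male to carry it, and carrier females to carry it in exactly
one of two alleles; missing genotypes (including a carrier with one
called allele) make a locus unevaluable rather than failed. Allele
equality is exact in copies for sequence-derived genotypes and ±1 bp for
fragment-analysis-scale inputs (instrument rounding); in `sub_repeat`
mode alleles carrying a compound decomposition compare by per-motif copy
numbers, emulating the follow-up sequencing of total-length-ambiguous
alleles, and fall back to total length otherwise. The cascade is monotone:
more controls can only shrink the candidate set, more family members can
only break segregation.

## Expression statistics

R = |P − C| / (Cmax − Cmin) with C the control value closest to P (exact
ties take the larger control; R is unaffected). R is affine-invariant and
zero exactly when the patient matches a control. Upstream differential
expression is consumed as a boolean flag column, not recomputed. Target
enrichment uses the exact one-sided binomial test ("greater") against a
caller-supplied expected background rate — the test choice is this
package's; only the observed and expected proportions are inherited from
the study design. The ddCt utility normalises Ct values against the
arithmetic mean of the endogenous-control Cts (the geometric mean of
control quantities), subtracts the calibrator's mean ΔCt and reports
2^(−ΔΔCt) with the SD across replicates.

## Synthetic study generator

All generators are pure functions of (config, seed) — identical seeds
give byte-identical outputs; per-sample read streams derive their seed
from the config seed and a CRC of the sample name.

* **Reference**: planted loci spaced 2.6 kb apart on a ~12 kb chromosome
  (margins 1.5 kb), background GC 0.45. The default study plants a simple
  AC repeat inside the linkage interval, the causal compound
  (CT)ₙTTT(GT)ₙ repeat with a miRNA feature ending 65 bp upstream, and
  two loci outside the interval. Sub-unit pools follow the observed
  normal ranges: CT uniform on [11,20], GT on [24,37]; the causal allele
  is (21,33) — one CT copy beyond anything in the normal pool.
* **Pedigree**: the causal family has a proband, two further affected
  males, two unaffected males and two carrier females (the configuration
  of the index family); two further families contribute an affected and
  an unaffected male each. Affected males of the causal family carry the
  causal allele, carriers are heterozygous, everyone else draws from the
  normal pools; the control pool holds 100 hemizygous males (tests use
  the first 50 where stated).
* **Reads**: fragments uniform on [800,1000] bp always carry ≥20 bp of at
  least one flank (spanning whenever the fragment is long enough —
  expansions beyond fragment size yield only partials); capture dropout
  follows a logistic GC curve (midpoint 0.70, floor 0.30, slope 25,
  matching ~30% recovery above 70% GC and near-complete recovery at
  moderate GC); substitutions are i.i.d. at 1% (CCS-like residual error —
  no homopolymer-specific model, a documented simplification); stutter
  shifts the allele by ±1 unit with probability 0.05 per read (p/2 each
  direction); reads get fixed 32-base adaptors, random strand, and a
  Poisson(15) subread-pass draw with a minimum of 6 passes.
* **Expression**: controls scatter around lognormal gene means with CV
  0.15; the designated miRNA-like gene drops 6-fold below the control
  minimum (comfortably beyond the 5-fold criterion), eight target genes
  rise 2.5-fold above the control maximum.

End-to-end replicates sequence only the proband and one unaffected male
of the causal family — the pair such a capture study sequences — at
coverage 10; other members and controls enter at fragment-analysis
resolution from the truth table. Problem sizes (4 loci, ~12 kb reference,
coverage 10, 100 replicates) were chosen as the smallest configuration
that exercises every cascade stage while keeping the whole suite quick to
run; the recovery statements are properties of this configuration.

## What passing tests do and do not show

The generator reproduces the statistical structure the method relies on
(fragment-length-limited spanning, stutter, GC dropout, hemizygous
X-linked transmission) but not real capture chemistry, chimeric reads,
mapping ambiguity on a full genome, homopolymer error structure, or
population haplotype sharing between families. Recovery rates on
synthetic data are therefore upper bounds on real-data performance; the
published real-data yields (per-sample read counts, 88–93% target
recovery) depend on patient material and are deliberately not modelled.

## Known limitations

* The uniqueness screen is exhaustive and suited to desk-scale references
  (≤ a few hundred kb), not whole genomes.
* Flank matching allows substitutions only; a flank containing an indel
  loses the read (partially mitigated by soft-clip rescue in yield
  accounting).
* The diploid genotype model is a simple two-mode rule with a fixed
  minor-allele floor; phased or mixture models are out of scope.
* Linkage LOD computation is not implemented; intervals are inputs.
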