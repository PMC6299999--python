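# replong

Targeted tandem-repeat capture design and flank-anchored long-read
genotyping for X-linked pedigree studies.

## The problem

Tandem repeats — head-to-tail repetitions of a 1–50 bp unit — largely
escape short-read sequencing: reads cannot span the tract and often fail to
map. Repeat expansions are therefore a plausible hidden cause of X-linked
disorders that remain unexplained after array and exome screens. `replong`
implements the desk-scale analysis workflow for a capture + long-read
consensus (CCS) assay over such repeats:

1. **repeat_catalog** — detect tandem repeats in a reference
   (ETANDEM-style best-phase tiling score), compute purity, score predicted
   variability with a pluggable SERV-style linear form in
   {unit length, log copies, purity}, annotate against gene models and
   apply six tiered target-selection criteria.
2. **probe_design** — four capture-probe types per target (left flank,
   right flank, spanning, double), a mismatch-bounded genomic uniqueness
   screen, outward-shift rescue of failed flanking probes (≤500 bp, most
   proximal passing shift), and 4× replication of probes with <40% or >70%
   GC.
3. **read_prep** — 32 nt adaptor trimming, local alignment to ±1000 bp
   target windows (k-mer-anchored diagonal placement with affine-gap DP
   fallback), duplicate removal, and nested yield categories:
   total ≥ mapped ≥ within-1000 ≥ intersecting ≥ spanning ≥ useful
   (spanning with 20 nt flanks, soft-clip-rescue aware).
4. **genotyper** — flank-anchored per-read allele calling (both flanks
   found ⇒ exact spanning length; one flank ⇒ partial read, a *lower
   bound* on the allele), modal genotyping with ±1-unit stutter pooling
   and ≥5× support, expansion flagging when a locus yields exclusively
   over-reference partial reads, and greedy decomposition of compound
   repeats such as (CT)ₐTTT(GT)_b.
5. **segregation_filter** — the candidate cascade for an X-linked
   recessive pedigree: linkage-interval restriction → affected/unaffected
   discordance → family segregation → cross-family uniqueness → control
   screening (fragment-analysis total length, or sub-repeat resolution).
6. **expression_stats** — the deregulation ratio
   `R = |P − C| / (Cmax − Cmin)` (patient value P, closest control C),
   ranking, exact one-sided binomial target enrichment, and a ddCt
   relative-expression utility with endogenous controls.
7. **synthetic_data** — a fully seeded generator for every input:
   reference with planted repeats, X-linked pedigree truth genotypes,
   capture + CCS-like reads (800–1000 bp fragments, substitution errors,
   stutter, GC-dependent dropout, 32 nt adaptors, subread-pass minimum),
   control allele pools and expression matrices.

The expansion logic exploits a simple but powerful signature: an allele
longer than the captured fragment can never be spanned, so the locus
yields only partial reads, and the longest partial read still bounds the
expansion from below. A 26 bp unit seen at ≥35 copies in partial reads
demonstrates ≥910 bp of repeat — detectable even though no read contains
the full allele.

## Worked example

Simulate a three-family study (one family segregating a planted CT-sub-repeat
expansion 65 bp downstream of a miRNA gene), genotype the sequenced
affected/unaffected pair from reads, and run the filter cascade with 50
controls:

```python
from replong import SimulationConfig, run_replicate

result = run_replicate(SimulationConfig(seed=7), n_controls=50)
print(result.report.to_string(index=False))
```

```
locus            stage            detail
 TR_A  non_segregating      inconsistent
 TR_B outside_interval
 TR_C outside_interval
XLIDC        candidate control_matches=0
```

`TR_B`/`TR_C` fall outside the linkage interval; `TR_A` is discordant
between the sequenced pair but does not segregate with the phenotype in
the wider family; the planted compound repeat `XLIDC` survives every stage
— discordant, segregating, unique across families and absent from all 50
controls at sub-repeat resolution — and is reported as the sole candidate.
The proband's sequencing-derived genotypes behind that call:

```
TR_A  [(34, 17.0, 10)]   # (allele bp, copies, supporting reads)
XLIDC [(111, 55.5, 10)]  # 111 bp = (CT)21 + TTT + (GT)33
TR_B  [(38, 19.0, 10)]
TR_C  [(27, 9.0, 10)]
```

The same workflow is scriptable from the shell (`replong simulate`,
`replong catalog`, `replong design`, `replong prep`, `replong genotype`,
`replong filter`, `replong express`).

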