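# catifunnel

Candidate-gene prioritization for hereditary cataract rodent models.

The package implements, as a tested and reusable pipeline, the analysis
design used to hunt the causative mutation of the ICR rat — a recessive
model that develops cortical lens opacity from about 7 weeks of age —
by combining three arms of evidence:

1. **Expression screen.** Normalized microarray signals from lenses
   before opacity onset (4 weeks) and after (8, 10 weeks), in the case
   strain and a wild-type control (SD).  After dropping genes with
   signal < 5 in every sample, a gene is *increased* in a contrast when
   the ratio of group means exceeds 1.5 (x̄_test / x̄_ref > 1.5) and
   *decreased* when x̄_ref / x̄_test > 2.25, both strictly.  Per-strain
   sets from the 4→8 and 4→10 contrasts are unioned, and genes shared
   with the control strain are removed by Venn exclusion, leaving
   case-only changes.
2. **qPCR validation.** Relative expression by the 2^−ΔCt model against
   a reference gene (Gapdh).  Group differences are tested two-tailed at
   α = 0.05 with Student's *t* (pooled variance) when a two-tailed
   F-test accepts homoscedasticity, otherwise Welch's *t* with
   Satterthwaite degrees of freedom.  Genes significantly increased in
   the case strain only are the cataract candidates; genes increased in
   both strains are read as lens maturation.
3. **Variant funnel.** Whole-genome variant calls against two reference
   assemblies (mRatBN7.2 and Rnor_6.0) flow through a monotone cascade:
   homozygosity (the model is recessive), annotation-impact selection
   (MODERATE and HIGH sequence-ontology classes, tracked separately),
   dual-assembly concordance, exclusion of variants carried by a panel
   of non-affected strains, and restriction to the linked loci *Cati1*
   (chr8) and *Cati2* (chr15).  A colinear-offset estimator places
   markers on an assembly where their position is unreleased:
   pos_target(m) = pos_target(anchor) − (pos_source(anchor) − pos_source(m)).

A synthetic-data module generates study-shaped inputs for every arm with
planted ground truth (case-only and shared expression changes; a causal
variant plus decoys each designed to die at exactly one funnel stage),
so the whole pipeline is exercisable and testable without any download.

Intended users: groups mapping recessive traits in inbred rodent strains
with a two-strain expression screen and a strain-panel variant filter.

## Worked example

The published chromosome-15 candidate selection, at desk scale — the
five reported variants, the *Cati2* interval, and the non-affected
strain panel:

```python
from catifunnel import datasets, run_variant_funnel, estimate_marker_position

est = estimate_marker_position(
    datasets.D15RAT52_RNOR6_SYNTHETIC,   # marker, source assembly
    datasets.D15RAT20_RNOR6_SYNTHETIC,   # anchor, source assembly
    datasets.D15RAT20_MAIN,              # anchor, target assembly
)
print(est.pos)

report = run_variant_funnel(
    datasets.CHR15_CANDIDATE_VARIANTS,
    datasets.CHR15_CANDIDATE_VARIANTS,
    panel=datasets.reported_panel(),
    loci=[datasets.CATI2],
)
print(sorted(v.gene for v in report.candidates))
```

prints

```
32677550
['Nkx2-6', 'Phf11b', 'Ppk', 'Sucla2']
```

The marker D15Rat52 lands at chr15:32,677,550 on mRatBN7.2 — the start
of the *Cati2* window — and four candidate genes survive: the funnel
keeps the stop-lost, splice-donor, missense and inframe-insertion
variants inside the window and removes *Fdft1*, whose identical missense
change is carried by a non-affected strain.

The same stages are available from the shell:

```bash
catifunnel simulate variants --defaults --seed 3 --out sim/
catifunnel variant-funnel --case-a sim/case_a.vcf --case-b sim/case_b.vcf \
    --panel sim/panel_manifest.tsv --loci sim/loci.tsv --defaults --out out/
```

Other subcommands: `expression-screen`, `qpcr-validate`,
`estimate-marker`, `simulate expression|variants|qpcr`, and `run` (all
arms plus a cross-referenced study summary).  Every subcommand requires
`--config <yaml>` or an explicit `--defaults`.

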