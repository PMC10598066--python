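# Methods

## The screening model

The pipeline targets a recessive hereditary cataract in an inbred rat
strain.  Because F1 hybrids with wild-type animals are unaffected, the
causative mutation is assumed homozygous; because cortical opacity
appears between 4 and 8 weeks of age, genes whose lens expression
changes across that window are candidate effectors.  The three arms —
fold-change screen, qPCR validation, variant funnel — are treated as
parallel, independent evidence: no arm gates another, and the study
summary only cross-references their gene lists at the end.

## Expression screen

Input is a post-normalization, linear-scale signal matrix (the pipeline
performs no normalization; if signals arrive log2-scale a config flag
de-logs them — there is no auto-detection).  Stages, in order:

* **Low-signal floor** (default 5 signal units): a gene is excluded only
  when *every* sample is strictly below the floor.  The floor is applied
  per strain dataset, before group means; both choices are conventions
  where the design leaves the order open, and both are config-visible.
* **Group means**: arithmetic means over replicates within each
  (strain, timepoint) group.  Fold changes are ratios of group means,
  not means of per-replicate ratios — the only reading that treats the
  single-replicate control groups (n = 1) identically to the replicated
  case groups (n = 3).
* **Contrast sets** (4→8 and 4→10 weeks): up when test/ref > 1.5, down
  when ref/test > 2.25, both strict ("more than").  The asymmetry of the
  two thresholds is preserved from the study design; both are
  `RunConfig` fields.  A zero denominator excludes the gene from that
  side with a logged warning rather than producing an infinite ratio.
* **Union** of the two contrasts per strain and direction, then **Venn
  exclusion** of the control strain's sets from the case strain's.

Consequences worth noting: the screen is invariant under rescaling all
signals (and the floor) by a positive constant, raising a threshold can
only shrink a set, and up/down sets within a contrast are disjoint for
any thresholds above 1.

## qPCR validation

Relative expression uses the 2^−ΔCt model with amplification efficiency
fixed at exactly 2; per-figure rescaling to a baseline group is
presentation-only and is kept out of the statistics.  The two-sample
test is gated by a classical two-tailed F-test on the variance ratio at
α = 0.05: accept → Student's pooled-variance *t*; reject → Welch's *t*
with Satterthwaite degrees of freedom.  The gate itself is a convention
(the design it mirrors cites only "homoscedasticity approval"); the
F-test is the standard pre-test paired with this switch.  Degenerate
inputs are handled explicitly: two zero-variance samples with equal
means give p = 1, with different means p = 0, and a single
zero-variance sample fails the gate (variance ratio 0 or ∞) and falls
through to Welch.

**No multiple-testing correction is applied.**  Each gene is judged at
the per-test α = 0.05, matching the validation design this reproduces;
users screening many genes should interpret the per-gene labels
accordingly.

Classification keys on significant *increase* only: a gene is
`case_only_increased` when at least one case contrast is significantly
up and no control contrast is; a significant *decrease* in the control
does not block the label.  Contrasts combine by OR (4→8 or 4→10).

## Variant funnel

All stages operate on decomposed (chrom, pos, ref, alt) atoms —
multi-allelic sites are split at VCF read time, one record per ALT
allele — and every stage is a pointwise predicate, so per-track counts
are non-increasing by construction.

* **Homozygosity**: genotype hom-alt only; missing genotypes are
  removed (absence of evidence is not homozygosity).
* **Impact selection**: sequence-ontology consequence terms map to
  HIGH/MODERATE/LOW/MODIFIER through a shipped table following the
  convention of SO-based annotators; a multi-term allele takes its most
  severe class; unknown terms classify as UNCLASSIFIED and are never
  silently dropped.  The table is overridable.  MODERATE and HIGH are
  tracked as separate funnel tracks (matching the "moderate"/"severe"
  candidate classes) and pooled only for locus restriction.
* **Dual-assembly concordance**: the default matching key is
  (gene symbol, ref, alt, most-severe consequence term) — coordinate
  free, because two assemblies place the same variant differently, and
  candidates are reported per gene.  A pure coordinate mode exists for
  same-assembly comparisons; with a zero inter-assembly shift the two
  modes agree.  Records lacking a gene name are excluded from
  concordance with a warning.
* **Panel exclusion**: a case variant is removed when any non-affected
  panel strain carries the identical atom at any zygosity.  The
  any-zygosity default is the stricter reading (the design text draws no
  zygosity distinction); `panel_hom_only` restricts to homozygous
  carriers.  Exclusion against a pooled panel equals sequential
  exclusion against its parts, so panel order is irrelevant.
* **Locus restriction**: 1-based, inclusive at both ends, matching the
  "from marker A to marker B" phrasing of linkage intervals.  An
  optional autosome allow-list is applied at VCF read time.

### Marker placement across assemblies

Where a marker's position is unreleased on the target assembly, it is
estimated from an anchor marker placed on both assemblies by preserving
the source-assembly base distance (colinear offset).  This is
deliberately the naive estimator — no chain-file liftover — and is exact
only when the two assemblies are colinear between marker and anchor;
assembly-specific indels bias the estimate by their net length.  The
worked example reproduces the published interval start at
chr15:32,677,550 from the anchor's target position and a
20,135,471-base source distance.  The shipped source-assembly anchor
coordinates are synthetic placeholders that preserve only that distance
(the estimator is invariant to the origin); they are labelled as such.

## Synthetic data

The generators emulate the *shape* of the study inputs, with planted
truth:

* **Expression**: log-normal baselines (meanlog 4, sdlog 1 — median
  ≈ 55 signal units, comfortably above the floor of 5), multiplicative
  log-normal noise (sd 0.05 on the natural-log scale, i.e. ≈ 5 %
  multiplicative), three timepoints with 3 case / 1 control replicates.
  Planted classes: case-only up (fold 3), shared "maturation" up
  (fold 3, both strains), case-only down (fold 4), null.  Effect folds
  sit well beyond the 1.5×/2.25× thresholds relative to the noise so
  that planted fate, not sampling luck, decides set membership;
  planted-gene baselines are floored at 50 units so the signal filter
  cannot remove them.  Defaults: 500 genes, 20 per planted class.
* **Variants**: one hom-alt missense causal variant inside the target
  locus, plus decoy classes each violating exactly one stage (het,
  synonymous, absent from the second assembly, shared with a random
  panel strain, outside the locus; 3 of each by default) and 100
  intergenic MODIFIER background calls that die at impact selection.
  The second assembly is the first shifted by a uniform per-chromosome
  offset — deliberately the exact regime in which the marker-offset
  estimator is error-free, so estimator exactness is testable.  Panel:
  10 strains.
* **qPCR**: target Ct = reference Ct − log2(planted quantity) +
  Gaussian cycle noise (sd 0.2 cycles by default), 4 case / 3 control
  replicates per timepoint — the validation design sizes.

What the generators do **not** emulate: probe-level microarray
artifacts and normalization residue, linkage disequilibrium or a
coalescent model for the panel strains, realistic assembly
rearrangements, and amplification-efficiency variation in qPCR.
Passing tests therefore demonstrate correctness of the set logic,
statistics and funnel plumbing under the stated noise models — not
robustness to those real-data effects.

## Problem sizes and numerical choices

The default synthetic specs (500 genes, ≈ 116 variant records, 10 panel
strains) and the calibration runs (10,000 null simulations for the
adaptive test, 1,000 random sets for funnel monotonicity) are sized so
the full suite and the acceptance script each complete in well under a
minute on one core while keeping Monte-Carlo error small (binomial sd
≈ 0.002 at 10,000 draws).  Ties and boundaries: fold-change thresholds
are strict (a ratio of exactly 2.25 is not "more than 2.25-fold");
interval endpoints are inclusive; the most-severe-term choice breaks
severity ties alphabetically for determinism; report serialization sorts
all keys and sets so reruns are byte-identical.

## Known limitations

* The genome-wide funnel counts of the original study (millions of
  calls down to tens of candidates) require the deposited sequencing
  runs and a variant-calling pipeline; this package starts from called,
  annotated VCFs and reproduces the desk-scale published endpoints.
* Gene-keyed concordance can conflate two distinct variants with the
  same gene, alleles and consequence term; coordinate mode avoids this
  on a shared assembly.
* The 2^−ΔCt model assumes perfect doubling per cycle; efficiencies
  below 2 bias relative quantities multiplicatively.
* The variance pre-test is known to distort the downstream test's size
  slightly; the calibration check bounds the realized type-I error at
  the design sizes (n = 4 vs 3) to 0.05 ± 0.01.
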