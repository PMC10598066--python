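"""Synthetic data with planted ground truth for every pipeline arm.

The generators emulate the shape of the study's inputs — normalized
two-strain signal matrices over 4/8/10-week lenses, qPCR Ct tables, and
paired-assembly variant call sets with a non-affected strain panel — and
return the planted labels so recovery can be checked exactly.

Signals get multiplicative log-normal noise (microarray-like); Ct values
get additive Gaussian noise on the cycle scale (qPCR-like).  The two
assemblies of a variant simulation differ by a uniform per-chromosome
coordinate shift, deliberately matching the colinearity assumption of
the marker-offset position estimator so its exactness is testable.
Every generator is a pure function of its spec (the seed lives in the
spec or argument list).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    Genotype,
    Impact,
    LocusInterval,
    SampleMeta,
    Strain,
    VariantRecord,
)
from .io import CT_COLUMNS
from .variants import PanelManifest, classify_impact

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionSimSpec",
    "VariantSimSpec",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_variant_callsets",
    "simulate_qpcr",
]


@dataclass
class SyntheticTruth:
    """Planted labels: what each generated item was designed to be."""

    gene_classes: dict[str, str] = field(default_factory=dict)
    variant_classes: dict[tuple[str, int, str, str], str] = field(
        default_factory=dict)
    causal_variant: VariantRecord | None = None


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimSpec:
    """Study-shaped two-strain expression experiment.

    Defaults mirror the screened design: three timepoints (4, 8, 10
    weeks), three case replicates and a single control replicate per
    timepoint, log-normal baseline signals, and planted effects applied
    at both post-onset timepoints with folds comfortably beyond the
    screen's 1.5x / 2.25x thresholds.
    """

    n_genes: int = 500
    timepoints: tuple[int, ...] = (4, 8, 10)
    case_replicates: int = 3
    control_replicates: int = 1
    #: natural-log mean/sd of the baseline signal distribution
    baseline_meanlog: float = 4.0
    baseline_sdlog: float = 1.0
    #: sd of the multiplicative noise on the natural-log scale
    noise_sd: float = 0.05
    n_case_only_up: int = 20
    n_shared_up: int = 20
    n_case_only_down: int = 20
    case_only_up_fold: float = 3.0
    shared_up_fold: float = 3.0
    case_only_down_fold: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_case_only_up + self.n_shared_up + self.n_case_only_down
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene classes ({planted}) exceed n_genes "
                f"({self.n_genes})"
            )
        for name in ("case_only_up_fold", "shared_up_fold",
                     "case_only_down_fold"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must be > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def simulate_expression(
    spec: ExpressionSimSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Generate (case matrix, control matrix, truth labels).

    Planted effects multiply (or divide) the baseline at every
    post-baseline timepoint: *case_only_up* genes rise in the case strain
    only, *shared_up* genes rise in both strains (maturation-like), and
    *case_only_down* genes fall in the case strain only; the rest are
    null.  Baselines of planted genes are kept well above the default
    signal floor so the planted fate is decided by fold change, not by
    the floor filter.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"gene{i:04d}" for i in range(spec.n_genes)]
    classes = (["case_only_up"] * spec.n_case_only_up
               + ["shared_up"] * spec.n_shared_up
               + ["case_only_down"] * spec.n_case_only_down)
    classes += ["null"] * (spec.n_genes - len(classes))
    baseline = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog,
                             size=spec.n_genes)
    planted = np.array([c != "null" for c in classes])
    baseline[planted] = np.maximum(baseline[planted], 50.0)

    ref_tp = spec.timepoints[0]
    later = spec.timepoints[1:]

    def effect(cls: str, strain: Strain, tp: int) -> float:
        if tp == ref_tp:
            return 1.0
        if cls == "case_only_up" and strain is Strain.CASE:
            return spec.case_only_up_fold
        if cls == "shared_up":
            return spec.shared_up_fold
        if cls == "case_only_down" and strain is Strain.CASE:
            return 1.0 / spec.case_only_down_fold
        return 1.0

    def build(strain: Strain, n_reps: int) -> ExpressionMatrix:
        samples: list[SampleMeta] = []
        cols: dict[str, np.ndarray] = {}
        for tp in spec.timepoints:
            for rep in range(1, n_reps + 1):
                sid = f"{strain.value}_{tp}w_r{rep}"
                samples.append(SampleMeta(sid, strain, tp, rep))
                eff = np.array([effect(c, strain, tp) for c in classes])
                noise = np.exp(rng.normal(0.0, spec.noise_sd,
                                          size=spec.n_genes)) \
                    if spec.noise_sd > 0 else 1.0
                cols[sid] = baseline * eff * noise
        return ExpressionMatrix(pd.DataFrame(cols, index=gene_ids), samples)

    case = build(Strain.CASE, spec.case_replicates)
    control = build(Strain.CONTROL, spec.control_replicates)
    truth = SyntheticTruth(gene_classes=dict(zip(gene_ids, classes)))
    logger.info("simulated expression: %d genes (%d case-only up, %d "
                "shared up, %d case-only down), timepoints %s",
                spec.n_genes, spec.n_case_only_up, spec.n_shared_up,
                spec.n_case_only_down, list(spec.timepoints))
    return case, control, truth


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")

#: decoy class -> the funnel stage it is designed to die at
DECOY_STAGES = {
    "het": "homozygosity",
    "low_impact": "impact_selection",
    "single_assembly_only": "cross_assembly_concordance",
    "panel_shared": "panel_exclusion",
    "off_locus": "locus_restriction",
}


@dataclass
class VariantSimSpec:
    """Paired-assembly call sets with one planted causal variant.

    One hom-alt MODERATE variant is planted inside the causal locus and
    constructed to pass every funnel stage; each decoy class violates
    exactly one stage (heterozygous, low impact, absent from the second
    assembly, shared with a panel strain, or outside the locus).
    Background variants are intergenic MODIFIER calls that drop out at
    impact selection, mimicking the genome-wide bulk.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000})
    n_background: int = 100
    causal_locus: LocusInterval = field(
        default_factory=lambda: LocusInterval("locusA", "chr1",
                                              10_000_000, 20_000_000))
    decoy_counts: dict[str, int] = field(
        default_factory=lambda: {"het": 3, "panel_shared": 3,
                                 "single_assembly_only": 3, "off_locus": 3,
                                 "low_impact": 3})
    #: per-chromosome uniform shift from assembly A to assembly B
    assembly_offset: dict[str, int] = field(
        default_factory=lambda: {"chr1": 150_000, "chr2": -75_000})
    n_panel_strains: int = 10
    assembly_a: str = "asmA"
    assembly_b: str = "asmB"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.decoy_counts) - set(DECOY_STAGES)
        if unknown:
            raise ValueError(f"unknown decoy classes: {sorted(unknown)}")
        loc = self.causal_locus
        if loc.chrom not in self.chrom_lengths:
            raise ValueError(
                f"causal locus chromosome {loc.chrom!r} not in "
                f"chrom_lengths"
            )
        if loc.end > self.chrom_lengths[loc.chrom]:
            raise ValueError("causal locus extends past its chromosome end")
        if self.n_panel_strains < 1 and self.decoy_counts.get(
                "panel_shared", 0) > 0:
            raise ValueError("panel_shared decoys need at least one "
                             "panel strain")


def _shift(v: VariantRecord, offset: int, assembly: str) -> VariantRecord:
    return VariantRecord(
        chrom=v.chrom, pos=v.pos + offset, ref=v.ref, alt=v.alt,
        genotype=v.genotype, gene=v.gene, so_terms=v.so_terms,
        impact=v.impact, assembly=assembly,
    )


def simulate_variant_callsets(
    spec: VariantSimSpec,
) -> tuple[list[VariantRecord], list[VariantRecord], PanelManifest,
           SyntheticTruth]:
    """Generate (case set on A, case set on B, panel, truth labels)."""
    rng = np.random.default_rng(spec.seed)
    truth = SyntheticTruth()
    used: set[tuple[str, int]] = set()

    def draw_site(chrom: str, lo: int, hi: int) -> int:
        while True:
            pos = int(rng.integers(lo, hi + 1))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return pos

    def snv(chrom: str, pos: int, gene: str, terms: set[str],
            genotype: Genotype) -> VariantRecord:
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        return VariantRecord(
            chrom=chrom, pos=pos, ref=_BASES[ref], alt=_BASES[alt],
            genotype=genotype, gene=gene, so_terms=frozenset(terms),
            impact=classify_impact(terms), assembly=spec.assembly_a,
        )

    loc = spec.causal_locus
    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"simgene{gene_counter:04d}"

    # the planted causal variant: hom-alt missense inside the locus
    causal = snv(loc.chrom, draw_site(loc.chrom, loc.start, loc.end),
                 next_gene(), {"missense_variant"}, Genotype.HOM_ALT)
    truth.causal_variant = causal
    truth.variant_classes[causal.site_key] = "causal"
    case_a = [causal]

    off_chroms = [c for c in spec.chrom_lengths if c != loc.chrom] \
        or [loc.chrom]

    def off_locus_site() -> tuple[str, int]:
        chrom = off_chroms[int(rng.integers(len(off_chroms)))]
        if chrom == loc.chrom:
            # single-chromosome genome: place the decoy after the locus
            return chrom, draw_site(chrom, loc.end + 1,
                                    spec.chrom_lengths[chrom])
        return chrom, draw_site(chrom, 1, spec.chrom_lengths[chrom])

    single_assembly_keys: set[tuple[str, int, str, str]] = set()
    panel_shared: list[VariantRecord] = []
    for cls, n in sorted(spec.decoy_counts.items()):
        for _ in range(n):
            if cls == "het":
                v = snv(loc.chrom, draw_site(loc.chrom, loc.start, loc.end),
                        next_gene(), {"missense_variant"}, Genotype.HET)
            elif cls == "low_impact":
                v = snv(loc.chrom, draw_site(loc.chrom, loc.start, loc.end),
                        next_gene(), {"synonymous_variant"},
                        Genotype.HOM_ALT)
            elif cls == "single_assembly_only":
                v = snv(loc.chrom, draw_site(loc.chrom, loc.start, loc.end),
                        next_gene(), {"missense_variant"}, Genotype.HOM_ALT)
                single_assembly_keys.add(v.site_key)
            elif cls == "panel_shared":
                v = snv(loc.chrom, draw_site(loc.chrom, loc.start, loc.end),
                        next_gene(), {"missense_variant"}, Genotype.HOM_ALT)
                panel_shared.append(v)
            else:  # off_locus
                chrom, pos = off_locus_site()
                v = snv(chrom, pos, next_gene(), {"missense_variant"},
                        Genotype.HOM_ALT)
            truth.variant_classes[v.site_key] = cls
            case_a.append(v)

    for _ in range(spec.n_background):
        chrom = list(spec.chrom_lengths)[int(rng.integers(
            len(spec.chrom_lengths)))]
        pos = draw_site(chrom, 1, spec.chrom_lengths[chrom])
        v = snv(chrom, pos, "", {"intergenic_region"}, Genotype.HOM_ALT)
        truth.variant_classes[v.site_key] = "background"
        case_a.append(v)

    case_b = [
        _shift(v, spec.assembly_offset.get(v.chrom, 0), spec.assembly_b)
        for v in case_a if v.site_key not in single_assembly_keys
    ]

    panel = PanelManifest()
    strain_labels = [f"panel_strain_{i:02d}"
                     for i in range(1, spec.n_panel_strains + 1)]
    panel_calls: dict[str, list[VariantRecord]] = {s: [] for s in strain_labels}
    for v in panel_shared:
        carrier = strain_labels[int(rng.integers(len(strain_labels)))]
        gt = Genotype.HET if rng.random() < 0.5 else Genotype.HOM_ALT
        panel_calls[carrier].append(VariantRecord(
            chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, genotype=gt,
            gene=v.gene, so_terms=v.so_terms, impact=v.impact,
            assembly=spec.assembly_a,
        ))
    # panel strains also carry private variants that never touch the case set
    for label in strain_labels:
        chrom = list(spec.chrom_lengths)[int(rng.integers(
            len(spec.chrom_lengths)))]
        pos = draw_site(chrom, 1, spec.chrom_lengths[chrom])
        panel_calls[label].append(snv(chrom, pos, "", {"intergenic_region"},
                                      Genotype.HOM_ALT))
    for label in strain_labels:
        panel.add(label, panel_calls[label])

    case_a.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    case_b.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    logger.info("simulated variant call sets: %d case records, %d decoys, "
                "%d panel strains", len(case_a),
                sum(spec.decoy_counts.values()), spec.n_panel_strains)
    return case_a, case_b, panel, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    genes: list[str],
    effects: dict[str, dict[tuple[str, int], float]],
    noise_sd: float = 0.2,
    seed: int = 0,
    timepoints: tuple[int, ...] = (4, 8, 10),
    case_replicates: int = 4,
    control_replicates: int = 3,
    baseline_quantity: float = 0.05,
    reference_ct: float = 18.0,
) -> pd.DataFrame:
    """Generate a Ct table with planted per-group fold effects.

    ``effects[gene][(strain, timepoint)]`` is the fold change of the
    relative quantity over baseline (missing entries default to 1).
    Target Ct = reference Ct - log2(planted quantity) + Gaussian noise,
    so ``relative_expression`` recovers the planted quantity in
    expectation on the Ct scale.  Replicate counts default to the
    validation design (4 case, 3 control).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        per_gene = effects.get(gene, {})
        for strain in (Strain.CASE, Strain.CONTROL):
            n_reps = (case_replicates if strain is Strain.CASE
                      else control_replicates)
            for tp in timepoints:
                fold = per_gene.get((strain.value, tp), 1.0)
                quantity = baseline_quantity * fold
                for rep in range(1, n_reps + 1):
                    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    rows.append({
                        "gene": gene,
                        "sample_id": f"{strain.value}_{tp}w_r{rep}",
                        "strain": strain,
                        "timepoint": tp,
                        "ct_target": reference_ct - np.log2(quantity) + noise,
                        "ct_reference": reference_ct,
                    })
    return pd.DataFrame(rows, columns=CT_COLUMNS)
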