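"""Variant prioritization: the multi-stage candidate-mutation funnel.

Under a recessive model (F1 hybrids of the cataractous strain with
wild-type do not develop cataract) the causal mutation must be carried on
both chromosomes, so the funnel runs:

1. homozygosity — keep hom-alt genotypes only;
2. annotation-impact selection — keep consequences predicted to change
   the protein (MODERATE: e.g. missense, one-amino-acid indels) or to
   severely disrupt it (HIGH: e.g. frameshift, stop gain/loss, splice
   donor/acceptor), tracked as two separate severity tracks;
3. dual-assembly concordance — keep variants also called against a
   second reference assembly, matching by gene/allele/effect because the
   two assemblies do not share coordinates;
4. strain-panel exclusion — drop variants also carried by any strain of
   a non-affected panel;
5. locus restriction — optionally keep only variants inside
   marker-delimited linkage intervals.

Every stage is a pointwise predicate on (chrom, pos, ref, alt) atoms, so
counts are non-increasing along each track.  The module also provides the
colinear-offset estimator used to place a marker on an assembly where its
position is not released, from its distance to an anchor marker on an
assembly where both are placed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .config import RunConfig
from .core import (
    IMPACT_SEVERITY,
    Genotype,
    Impact,
    LocusInterval,
    Marker,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SO_IMPACT_TABLE",
    "classify_impact",
    "most_severe_term",
    "filter_homozygous",
    "select_impact",
    "cross_assembly_concordance",
    "PanelManifest",
    "panel_exclusion",
    "estimate_marker_position",
    "restrict_to_locus",
    "FunnelStage",
    "FunnelReport",
    "run_variant_funnel",
]


# ---------------------------------------------------------------------------
# Impact classification
# ---------------------------------------------------------------------------

#: Sequence-ontology consequence term -> impact class.  This is the
#: conventional table of SO-based annotators (SnpEff dialect); it can be
#: overridden per run.  Unknown terms map to UNCLASSIFIED, never dropped.
SO_IMPACT_TABLE: dict[str, Impact] = {
    # HIGH: predicted to severely alter gene function
    "chromosome_number_variation": Impact.HIGH,
    "exon_loss_variant": Impact.HIGH,
    "frameshift_variant": Impact.HIGH,
    "rare_amino_acid_variant": Impact.HIGH,
    "splice_acceptor_variant": Impact.HIGH,
    "splice_donor_variant": Impact.HIGH,
    "start_lost": Impact.HIGH,
    "stop_gained": Impact.HIGH,
    "stop_lost": Impact.HIGH,
    "transcript_ablation": Impact.HIGH,
    "gene_fusion": Impact.HIGH,
    "bidirectional_gene_fusion": Impact.HIGH,
    # MODERATE: amino-acid-level changes, e.g. missense and in-frame indels
    "coding_sequence_variant": Impact.MODERATE,
    "conservative_inframe_deletion": Impact.MODERATE,
    "conservative_inframe_insertion": Impact.MODERATE,
    "disruptive_inframe_deletion": Impact.MODERATE,
    "disruptive_inframe_insertion": Impact.MODERATE,
    "inframe_deletion": Impact.MODERATE,
    "inframe_insertion": Impact.MODERATE,
    "missense_variant": Impact.MODERATE,
    "protein_altering_variant": Impact.MODERATE,
    "regulatory_region_ablation": Impact.MODERATE,
    "3_prime_UTR_truncation": Impact.MODERATE,
    "5_prime_UTR_truncation": Impact.MODERATE,
    # LOW
    "splice_region_variant": Impact.LOW,
    "initiator_codon_variant": Impact.LOW,
    "start_retained_variant": Impact.LOW,
    "stop_retained_variant": Impact.LOW,
    "synonymous_variant": Impact.LOW,
    "5_prime_UTR_premature_start_codon_gain_variant": Impact.LOW,
    # MODIFIER
    "3_prime_UTR_variant": Impact.MODIFIER,
    "5_prime_UTR_variant": Impact.MODIFIER,
    "downstream_gene_variant": Impact.MODIFIER,
    "upstream_gene_variant": Impact.MODIFIER,
    "intergenic_region": Impact.MODIFIER,
    "intergenic_variant": Impact.MODIFIER,
    "intragenic_variant": Impact.MODIFIER,
    "intron_variant": Impact.MODIFIER,
    "non_coding_transcript_exon_variant": Impact.MODIFIER,
    "non_coding_transcript_variant": Impact.MODIFIER,
    "gene_variant": Impact.MODIFIER,
    "transcript_variant": Impact.MODIFIER,
}


def classify_impact(
    so_terms: Iterable[str], table: dict[str, Impact] | None = None
) -> Impact:
    """Impact class of a term set: the most severe class among its terms.

    Terms absent from the table contribute UNCLASSIFIED; a set with no
    known term therefore classifies as UNCLASSIFIED rather than being
    silently dropped.
    """
    table = SO_IMPACT_TABLE if table is None else table
    terms = list(so_terms)
    if not terms:
        raise ValueError("cannot classify an empty consequence-term set")
    best = Impact.UNCLASSIFIED
    for t in terms:
        cls = table.get(t, Impact.UNCLASSIFIED)
        if IMPACT_SEVERITY[cls] > IMPACT_SEVERITY[best]:
            best = cls
    return best


def most_severe_term(
    so_terms: Iterable[str], table: dict[str, Impact] | None = None
) -> str:
    """The consequence term carrying the highest-severity class.

    Ties are broken alphabetically so the choice is deterministic.
    """
    table = SO_IMPACT_TABLE if table is None else table
    terms = sorted(so_terms)
    if not terms:
        raise ValueError("empty consequence-term set")
    best = terms[0]
    best_sev = IMPACT_SEVERITY[table.get(best, Impact.UNCLASSIFIED)]
    for t in terms[1:]:
        sev = IMPACT_SEVERITY[table.get(t, Impact.UNCLASSIFIED)]
        if sev > best_sev:
            best, best_sev = t, sev
    return best


# ---------------------------------------------------------------------------
# Funnel stages
# ---------------------------------------------------------------------------

def filter_homozygous(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep hom-alt calls only.

    Heterozygous, hom-ref and missing genotypes are removed; a missing
    genotype is not evidence of homozygosity.
    """
    out = [v for v in variants if v.genotype is Genotype.HOM_ALT]
    logger.info("homozygosity filter: %d -> %d", len(variants), len(out))
    return out


def select_impact(
    variants: Sequence[VariantRecord], classes: set[Impact]
) -> list[VariantRecord]:
    """Keep variants whose impact class is in ``classes``."""
    out = [v for v in variants if v.impact in classes]
    logger.info(
        "impact selection %s: %d -> %d",
        sorted(c.value for c in classes), len(variants), len(out),
    )
    return out


def _gene_key(v: VariantRecord) -> tuple[str, str, str, str] | None:
    if not v.gene or not v.so_terms:
        return None
    return (v.gene, v.ref, v.alt, most_severe_term(v.so_terms))


def cross_assembly_concordance(
    set_a: Sequence[VariantRecord],
    set_b: Sequence[VariantRecord],
    key: Literal["gene", "coordinate"] = "gene",
) -> list[VariantRecord]:
    """Keep variants of ``set_a`` also called in ``set_b`` (another assembly).

    The default matching key is (gene, ref, alt, most-severe consequence
    term): coordinate-free, because two assemblies place the same variant
    at different positions.  ``key="coordinate"`` matches on
    (chrom, pos, ref, alt) instead, for same-assembly comparisons.
    Records missing a key field are excluded with a logged warning.
    Surviving records keep set_a (assembly-A) coordinates.
    """
    if key == "coordinate":
        b_keys = {v.site_key for v in set_b}
        out = [v for v in set_a if v.site_key in b_keys]
    elif key == "gene":
        b_keys = set()
        for v in set_b:
            k = _gene_key(v)
            if k is not None:
                b_keys.add(k)
        out = []
        for v in set_a:
            k = _gene_key(v)
            if k is None:
                logger.warning(
                    "concordance: %s lacks gene/consequence annotation; "
                    "excluded", v,
                )
                continue
            if k in b_keys:
                out.append(v)
    else:  # pragma: no cover
        raise ValueError(f"unknown concordance key {key!r}")
    logger.info("cross-assembly concordance (%s key): %d -> %d",
                key, len(set_a), len(out))
    return out


@dataclass
class PanelManifest:
    """Variant call sets of non-affected strains, keyed by strain label."""

    strains: dict[str, list[VariantRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # dict keys are unique by construction; validate non-empty labels
        for label in self.strains:
            if not label:
                raise ValueError("empty strain label in panel manifest")

    def add(self, label: str, variants: list[VariantRecord]) -> None:
        if label in self.strains:
            raise ValueError(f"duplicate panel strain label {label!r}")
        self.strains[label] = variants

    def site_keys(self, hom_only: bool = False) -> set[tuple[str, int, str, str]]:
        keys: set[tuple[str, int, str, str]] = set()
        for variants in self.strains.values():
            for v in variants:
                if hom_only and v.genotype is not Genotype.HOM_ALT:
                    continue
                keys.add(v.site_key)
        return keys


def panel_exclusion(
    case_variants: Sequence[VariantRecord],
    panel: PanelManifest,
    hom_only: bool = False,
) -> list[VariantRecord]:
    """Drop case variants carried by ANY strain of the non-affected panel.

    Matching is exact on (chrom, pos, ref, alt).  By default a panel
    carrier at any zygosity disqualifies the variant; ``hom_only=True``
    counts only homozygous panel carriers.
    """
    shared = panel.site_keys(hom_only=hom_only)
    out = [v for v in case_variants if v.site_key not in shared]
    logger.info("panel exclusion (%d strains%s): %d -> %d",
                len(panel.strains), ", hom-only" if hom_only else "",
                len(case_variants), len(out))
    return out


def restrict_to_locus(
    variants: Sequence[VariantRecord], interval: LocusInterval
) -> list[VariantRecord]:
    """Keep variants inside the interval (1-based, inclusive both ends)."""
    out = [v for v in variants if interval.contains(v.chrom, v.pos)]
    logger.info("locus restriction %s (%s:%d-%d): %d -> %d",
                interval.name, interval.chrom, interval.start, interval.end,
                len(variants), len(out))
    return out


# ---------------------------------------------------------------------------
# Marker position estimation across assemblies
# ---------------------------------------------------------------------------

def estimate_marker_position(
    marker: Marker, anchor_source: Marker, anchor_target: Marker
) -> Marker:
    """Place a marker on a target assembly by colinear offset from an anchor.

    ``marker`` and ``anchor_source`` are on the source assembly;
    ``anchor_target`` is the same anchor marker on the target assembly.
    Assuming the two assemblies are colinear over the interval, the
    marker's estimated target position preserves the source-assembly
    base distance to the anchor::

        pos_target(marker) = pos_target(anchor) - (pos_source(anchor)
                                                   - pos_source(marker))

    The sign of the offset handles markers on either side of the anchor.
    The estimate ignores assembly-specific insertions, deletions and
    rearrangements between the two points.
    """
    if anchor_source.name != anchor_target.name:
        raise ValueError(
            f"anchor mismatch: {anchor_source.name!r} vs {anchor_target.name!r}"
        )
    if marker.assembly != anchor_source.assembly:
        raise ValueError(
            f"marker {marker.name!r} is on {marker.assembly!r} but the "
            f"source anchor is on {anchor_source.assembly!r}"
        )
    if marker.chrom != anchor_source.chrom:
        raise ValueError(
            f"chromosome mismatch: marker {marker.name!r} on {marker.chrom}, "
            f"anchor {anchor_source.name!r} on {anchor_source.chrom}"
        )
    offset = anchor_source.pos - marker.pos
    est = anchor_target.pos - offset
    if est < 1:
        raise ValueError(
            f"estimated position {est} for {marker.name!r} is off the "
            f"target chromosome start"
        )
    logger.info(
        "estimated %s on %s at %s:%d (colinear offset %+d from anchor %s)",
        marker.name, anchor_target.assembly, anchor_target.chrom, est,
        -offset, anchor_source.name,
    )
    return Marker(
        name=marker.name,
        assembly=anchor_target.assembly,
        chrom=anchor_target.chrom,
        pos=est,
    )


# ---------------------------------------------------------------------------
# The funnel
# ---------------------------------------------------------------------------

@dataclass
class FunnelStage:
    name: str
    track: str  # "moderate" | "high" | "all"
    n_in: int
    n_out: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError(
                f"stage {self.name!r}: output {self.n_out} exceeds input "
                f"{self.n_in}"
            )


@dataclass
class FunnelReport:
    """Ordered per-stage counts plus the final candidate list."""

    stages: list[FunnelStage] = field(default_factory=list)
    candidates: list[VariantRecord] = field(default_factory=list)
    per_locus: dict[str, list[VariantRecord]] = field(default_factory=dict)

    def counts(self, track: str | None = None) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_out) for s in self.stages
                if track is None or s.track == track]

    def to_json_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "track": s.track, "n_in": s.n_in,
                 "n_out": s.n_out, "params": s.params}
                for s in self.stages
            ],
            "n_candidates": len(self.candidates),
            "candidates": [_variant_row(v) for v in self.candidates],
            "per_locus": {
                name: [_variant_row(v) for v in vs]
                for name, vs in sorted(self.per_locus.items())
            },
        }


def _variant_row(v: VariantRecord) -> dict:
    return {
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "genotype": v.genotype.value,
        "gene": v.gene,
        "so_terms": "&".join(sorted(v.so_terms)),
        "impact": v.impact.value,
        "assembly": v.assembly,
    }


def _sorted_variants(vs: Iterable[VariantRecord]) -> list[VariantRecord]:
    return sorted(vs, key=lambda v: (v.chrom, v.pos, v.ref, v.alt, v.gene))


def run_variant_funnel(
    case_a: Sequence[VariantRecord],
    case_b: Sequence[VariantRecord],
    panel: PanelManifest | None = None,
    loci: Sequence[LocusInterval] | None = None,
    config: RunConfig | None = None,
    concordance_key: Literal["gene", "coordinate"] = "gene",
) -> FunnelReport:
    """Run the full prioritization funnel and record every stage count.

    ``case_a`` is the call set on the reporting assembly; ``case_b`` the
    call set of the same genome against the second assembly (used only
    for concordance).  MODERATE and HIGH impact variants are tracked as
    separate severity tracks through concordance and panel exclusion,
    then pooled for the optional locus restriction.
    """
    config = config or RunConfig()
    report = FunnelReport()

    def stage(name: str, track: str, before: Sequence[VariantRecord],
              after: Sequence[VariantRecord], **params) -> None:
        report.stages.append(
            FunnelStage(name=name, track=track, n_in=len(before),
                        n_out=len(after), params=params)
        )

    hom_a = filter_homozygous(case_a)
    stage("homozygosity", "all", case_a, hom_a)
    hom_b = filter_homozygous(case_b)

    tracks: dict[str, list[VariantRecord]] = {}
    for track, cls in (("moderate", Impact.MODERATE), ("high", Impact.HIGH)):
        sel = select_impact(hom_a, {cls})
        stage("impact_selection", track, hom_a, sel, impact=cls.value)
        tracks[track] = sel

    b_sel = select_impact(hom_b, {Impact.MODERATE, Impact.HIGH})
    for track in ("moderate", "high"):
        conc = cross_assembly_concordance(tracks[track], b_sel,
                                          key=concordance_key)
        stage("cross_assembly_concordance", track, tracks[track], conc,
              key=concordance_key)
        tracks[track] = conc

    if panel is not None:
        for track in ("moderate", "high"):
            kept = panel_exclusion(tracks[track], panel,
                                   hom_only=config.panel_hom_only)
            stage("panel_exclusion", track, tracks[track], kept,
                  n_strains=len(panel.strains),
                  hom_only=config.panel_hom_only)
            tracks[track] = kept

    pooled = _sorted_variants(tracks["moderate"] + tracks["high"])
    if loci:
        in_any: list[VariantRecord] = []
        for locus in loci:
            hit = restrict_to_locus(pooled, locus)
            report.per_locus[locus.name] = _sorted_variants(hit)
            in_any.extend(hit)
        final = _sorted_variants(set(in_any))
        stage("locus_restriction", "all", pooled, final,
              loci=[f"{l.name}:{l.chrom}:{l.start}-{l.end}" for l in loci])
    else:
        final = pooled

    report.candidates = final
    logger.info("funnel complete: %d final candidates", len(final))
    return report
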