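"""Published ICR-study worked-example data: variants, markers and loci.

These tables transcribe the candidate variants, SSLP markers and locus
intervals reported for the ICR cortical-cataract model, at desk scale.
They exist so the funnel's interval restriction, panel exclusion, impact
classification and marker-offset estimation can be exercised and checked
against the published outcome without any sequence download.

Genotypes are hom-alt throughout: every reported candidate passed the
homozygosity stage (the model is recessive).  The mRatBN7.2 coordinates
are as published.  The Rnor_6.0 marker coordinates are SYNTHETIC
placeholders: only the inter-marker base distance on Rnor_6.0 is
published (implied by the two reported mRatBN7.2 endpoint positions of
the Cati2 interval), and the colinear-offset estimator depends only on
that distance, so the placeholders anchor the distance at an arbitrary
origin and must not be read as real Rnor_6.0 positions.
"""

from __future__ import annotations

from .core import Genotype, LocusInterval, Marker, VariantRecord
from .variants import PanelManifest, classify_impact

__all__ = [
    "ASSEMBLY_MAIN",
    "ASSEMBLY_ALT",
    "CATI1",
    "THY1_CYP1A1_WINDOW",
    "CATI2",
    "MARKERS",
    "D15RAT52_RNOR6_SYNTHETIC",
    "D15RAT20_RNOR6_SYNTHETIC",
    "D15RAT20_MAIN",
    "CHR15_CANDIDATE_VARIANTS",
    "CHR8_SELECTED_VARIANTS",
    "OTHER_REPORTED_VARIANTS",
    "PANEL_STRAIN_LABELS",
    "reported_panel",
]

ASSEMBLY_MAIN = "mRatBN7.2"
ASSEMBLY_ALT = "Rnor_6.0"


def _variant(chrom: str, pos: int, ref: str, alt: str, gene: str,
             *terms: str) -> VariantRecord:
    so = frozenset(terms)
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=Genotype.HOM_ALT,
        gene=gene, so_terms=so, impact=classify_impact(so),
        assembly=ASSEMBLY_MAIN,
    )


#: Chromosome-8 locus linked to cataract formation, delimited by SSLP
#: markers D8Rat68 and D8N136.
CATI1 = LocusInterval("Cati1", "chr8", 18_984_168, 84_531_276)

#: The narrower chromosome-8 focus window between the Thy1 and Cyp1a1
#: SSLP sites, inside Cati1.
THY1_CYP1A1_WINDOW = LocusInterval("Thy1-Cyp1a1", "chr8",
                                   44_393_886, 58_098_974)

#: Chromosome-15 locus linked to cataract timing, D15Rat52 to D15Rat20;
#: the start coordinate is the colinear-offset estimate (see MARKERS).
CATI2 = LocusInterval("Cati2", "chr15", 32_677_550, 52_813_021)

D15RAT20_MAIN = Marker("D15Rat20", ASSEMBLY_MAIN, "chr15", 52_813_021)

#: SYNTHETIC Rnor_6.0 anchor placements (arbitrary origin).  Only the
#: 20,135,471-base distance between the two markers is published; the
#: offset estimator is invariant to the origin choice.
_RNOR6_ANCHOR_ORIGIN = 58_000_000
D15RAT20_RNOR6_SYNTHETIC = Marker("D15Rat20", ASSEMBLY_ALT, "chr15",
                                  _RNOR6_ANCHOR_ORIGIN)
D15RAT52_RNOR6_SYNTHETIC = Marker("D15Rat52", ASSEMBLY_ALT, "chr15",
                                  _RNOR6_ANCHOR_ORIGIN - 20_135_471)

MARKERS: list[Marker] = [
    Marker("D8Rat68", ASSEMBLY_MAIN, "chr8", 18_984_168),
    Marker("D8N136", ASSEMBLY_MAIN, "chr8", 84_531_276),
    Marker("D8Rat80", ASSEMBLY_MAIN, "chr8", 47_353_202),
    Marker("D8Rat43", ASSEMBLY_MAIN, "chr8", 48_630_131),
    Marker("Thy1", ASSEMBLY_MAIN, "chr8", 44_393_886),
    Marker("Cyp1a1", ASSEMBLY_MAIN, "chr8", 58_098_974),
    D15RAT20_MAIN,
    D15RAT20_RNOR6_SYNTHETIC,
    D15RAT52_RNOR6_SYNTHETIC,
]

#: The five chromosome-15 candidate variants reported inside or near the
#: Cati2 interval.  Fdft1 is the panel-shared one: the same missense
#: change occurs in non-affected strains, so the panel rule removes it.
CHR15_CANDIDATE_VARIANTS: list[VariantRecord] = [
    _variant("chr15", 33_378_050, "T", "G", "Phf11b", "stop_lost"),
    _variant("chr15", 37_423_413, "A", "T", "Fdft1", "missense_variant"),
    _variant("chr15", 40_027_471, "GGTGAGTGAGTGA", "G", "Ppk",
             "splice_donor_variant", "splice_region_variant",
             "intron_variant"),
    _variant("chr15", 44_446_376, "G", "C", "Nkx2-6", "missense_variant"),
    _variant("chr15", 48_760_331, "T", "TGCA", "Sucla2",
             "conservative_inframe_insertion"),
]

#: The two chromosome-8 variants selected inside the Thy1-Cyp1a1 window
#: of the Cati1 locus.
CHR8_SELECTED_VARIANTS: list[VariantRecord] = [
    _variant("chr8", 46_532_966, "C", "T", "Apoc3", "missense_variant"),
    _variant("chr8", 57_650_592, "GCAGGGA", "G", "RGD1305464",
             "disruptive_inframe_deletion"),
]

#: Reported candidates outside the two loci (minor-gene candidates).
OTHER_REPORTED_VARIANTS: list[VariantRecord] = [
    _variant("chr2", 184_491_323, "C", "A", "Gja8", "missense_variant"),
    _variant("chr7", 113_719_718, "TTTTTG", "T", "Srebf2",
             "splice_donor_variant", "3_prime_UTR_variant",
             "intron_variant"),
]

#: The ten non-affected strains whose sequence-archive runs formed the
#: exclusion panel.
PANEL_STRAIN_LABELS: list[str] = [
    "F344/stm", "ACI/N", "BN/SsN", "BUF/N", "F344/N",
    "M520/N", "MR/N", "WKY/N", "WN/N", "LE/Stm",
]


def reported_panel() -> PanelManifest:
    """Desk-scale panel manifest for the worked example.

    Carries the one published panel-shared fact: the Fdft1 missense
    variant (chr15-37,423,413-A>T) is present in a non-affected strain,
    which is why it was not selected as model-specific.  Which panel
    strain carries it was not reported; it is attached to the first
    label, which is immaterial under the ANY-strain exclusion rule.
    """
    panel = PanelManifest()
    fdft1 = CHR15_CANDIDATE_VARIANTS[1]
    for i, label in enumerate(PANEL_STRAIN_LABELS):
        panel.add(label, [fdft1] if i == 0 else [])
    return panel
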