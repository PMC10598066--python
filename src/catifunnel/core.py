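"""Core domain types shared by every analysis arm.

The pipeline studies a recessive hereditary cataract model (the ICR rat,
which develops cortical opacity from about 7 weeks of age) against a
non-cataractous control strain.  Three kinds of evidence flow through it:
normalized microarray signal matrices, qPCR quantification-cycle tables,
and annotated variant call sets against two reference assemblies.  The
types here are the common vocabulary: samples, variants, SSLP markers and
the marker-delimited locus intervals used to restrict candidates.

Coordinates are 1-based inclusive throughout (the VCF convention); BED
interchange is converted at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Strain",
    "Genotype",
    "Impact",
    "SampleMeta",
    "ExpressionMatrix",
    "VariantRecord",
    "Marker",
    "LocusInterval",
]


class Strain(str, enum.Enum):
    """Which arm of the two-strain comparison a sample belongs to."""

    CASE = "case"
    CONTROL = "control"


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Impact(str, enum.Enum):
    """Predicted severity of a variant's effect on a transcript.

    The four-level vocabulary (HIGH/MODERATE/LOW/MODIFIER) follows the
    convention of sequence-ontology based annotators; UNCLASSIFIED marks
    records whose consequence terms are all outside the shipped table.
    """

    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"
    UNCLASSIFIED = "UNCLASSIFIED"


#: Severity rank used when combining several consequence terms for one
#: allele: the variant takes the most severe class among its terms.
IMPACT_SEVERITY: dict[Impact, int] = {
    Impact.HIGH: 4,
    Impact.MODERATE: 3,
    Impact.LOW: 2,
    Impact.MODIFIER: 1,
    Impact.UNCLASSIFIED: 0,
}


@dataclass(frozen=True)
class SampleMeta:
    """One lens sample: (strain, age in weeks, replicate) triple."""

    sample_id: str
    strain: Strain
    timepoint: int
    replicate: int

    def __post_init__(self) -> None:
        if self.timepoint <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: timepoint must be a positive "
                f"number of weeks, got {self.timepoint}"
            )
        if self.replicate <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate must be positive, "
                f"got {self.replicate}"
            )


class ExpressionMatrix:
    """Normalized linear-scale signal matrix (genes x samples).

    Holds post-normalization values; no normalization is performed here.
    Signals must be nonnegative and gene ids unique.
    """

    def __init__(self, signals: pd.DataFrame, samples: list[SampleMeta]):
        if signals.index.has_duplicates:
            dups = sorted(signals.index[signals.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dups}")
        by_id = {s.sample_id: s for s in samples}
        if len(by_id) != len(samples):
            raise ValueError("duplicate sample ids in metadata")
        missing = [c for c in signals.columns if c not in by_id]
        if missing:
            raise ValueError(f"sample columns without metadata: {missing}")
        signals = signals.astype(float)
        if (signals.to_numpy() < 0).any():
            raise ValueError("negative signal values in matrix")
        if not np.isfinite(signals.to_numpy()).all():
            raise ValueError("non-finite signal values in matrix")
        self.signals = signals
        self.samples = [by_id[c] for c in signals.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.signals.index)

    @property
    def n_genes(self) -> int:
        return len(self.signals.index)

    def sample_ids(
        self, strain: Strain | None = None, timepoint: int | None = None
    ) -> list[str]:
        """Sample ids, optionally restricted to one (strain, timepoint) group."""
        out = []
        for s in self.samples:
            if strain is not None and s.strain != strain:
                continue
            if timepoint is not None and s.timepoint != timepoint:
                continue
            out.append(s.sample_id)
        return out

    def timepoints(self, strain: Strain | None = None) -> list[int]:
        return sorted({s.timepoint for s in self.samples
                       if strain is None or s.strain == strain})

    def strains(self) -> list[Strain]:
        seen: list[Strain] = []
        for s in self.samples:
            if s.strain not in seen:
                seen.append(s.strain)
        return seen

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.signals.loc[genes], self.samples)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ExpressionMatrix({self.n_genes} genes x "
                f"{len(self.samples)} samples)")


@dataclass(frozen=True)
class VariantRecord:
    """One called variant (one ALT allele at one site).

    ``pos`` is the 1-based position of the first aligned base, VCF style,
    so a record prints in the field's usual notation, e.g.
    ``chr8-46,532,966-C>T``.  ``so_terms`` carries every sequence-ontology
    consequence term annotated for this allele; ``impact`` is the
    severity-maximum class over those terms.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: Genotype = Genotype.MISSING
    gene: str = ""
    so_terms: frozenset[str] = field(default_factory=frozenset)
    impact: Impact = Impact.UNCLASSIFIED
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be nonempty")
        if self.ref == self.alt:
            raise ValueError(
                f"ref and alt are identical at {self.chrom}:{self.pos}"
            )
        object.__setattr__(self, "so_terms", frozenset(self.so_terms))

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) -- the atom every funnel stage operates on."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}-{self.pos:,}-{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Marker:
    """A named genomic position (e.g. an SSLP site) on one assembly."""

    name: str
    assembly: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker {self.name!r}: pos must be >= 1")


@dataclass(frozen=True)
class LocusInterval:
    """A marker-delimited genomic window, 1-based and inclusive at both ends."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval {self.name!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"interval {self.name!r}: start must be >= 1")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1
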