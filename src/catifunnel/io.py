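"""Readers and writers for every external format the pipeline touches.

Formats: TSV (expression matrices, Ct tables, marker tables, loci,
reports), VCF 4.2 subset (CHROM, POS, ID, REF, ALT, FILTER, INFO/ANN,
FORMAT/GT) via pysam, JSON reports, and optional BED interchange for
intervals.  Internal coordinates are 1-based inclusive; BED conversion
happens only at this boundary.

Expression sample metadata can come from a sidecar TSV (columns
sample_id, strain, timepoint, replicate) or be encoded in the column
names themselves as ``<strain>_<weeks>w_r<replicate>``, e.g.
``case_8w_r2``.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .core import (
    ExpressionMatrix,
    Genotype,
    Impact,
    LocusInterval,
    Marker,
    SampleMeta,
    Strain,
    VariantRecord,
)
from .variants import PanelManifest, classify_impact

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_vcf",
    "write_vcf",
    "read_marker_table",
    "write_marker_table",
    "read_loci_table",
    "write_loci_table",
    "read_panel_manifest",
    "read_ct_table",
    "write_ct_table",
    "write_report",
    "locus_to_bed_line",
    "locus_from_bed_line",
]

_SAMPLE_NAME_RE = re.compile(r"^(case|control)_(\d+)w_r(\d+)$")


class ParseError(ValueError):
    """A malformed input file; message names the offending row/column."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _meta_from_column_name(name: str) -> SampleMeta:
    m = _SAMPLE_NAME_RE.match(name)
    if m is None:
        raise ParseError(
            f"sample column {name!r} has no sidecar metadata and does not "
            f"match the '<strain>_<weeks>w_r<replicate>' naming scheme"
        )
    return SampleMeta(
        sample_id=name,
        strain=Strain(m.group(1)),
        timepoint=int(m.group(2)),
        replicate=int(m.group(3)),
    )


def _read_sample_sidecar(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "strain", "timepoint", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(
            f"sample metadata {path}: missing columns {sorted(missing)}"
        )
    metas: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in metas:
            raise ParseError(f"sample metadata {path}: duplicate id {sid!r}")
        metas[sid] = SampleMeta(
            sample_id=sid,
            strain=Strain(row["strain"]),
            timepoint=int(row["timepoint"]),
            replicate=int(row["replicate"]),
        )
    return metas


def read_expression_matrix(
    path: str | Path,
    samples_path: str | Path | None = None,
    log2_input: bool = False,
    annotation_map: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples signal TSV.

    The first column holds gene ids; every other column is one sample.
    Signals are linear-scale unless ``log2_input`` is set, in which case
    values are de-logged (2**x) before use; there is no auto-detection.
    ``annotation_map`` optionally maps probe ids to gene symbols; probes
    absent from the map (no gene correspondence) are dropped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ParseError(f"{path}: duplicate gene ids: {dups}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nonnum = df.index[bad.isna() & df[col].notna()]
        if len(nonnum):
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row {nonnum[0]!r}"
            )
        df[col] = bad
    if df.isna().to_numpy().any():
        r, c = next(zip(*df.isna().to_numpy().nonzero()))
        raise ParseError(
            f"{path}: missing value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if annotation_map is not None:
        keep = [g for g in df.index if g in annotation_map]
        df = df.loc[keep]
        df.index = [annotation_map[g] for g in keep]
        if pd.Index(df.index).has_duplicates:
            raise ParseError(
                f"{path}: annotation map collapses several probes onto one "
                f"gene symbol; resolve before screening"
            )
    if log2_input:
        df = 2.0 ** df
    if samples_path is not None:
        metas = _read_sample_sidecar(samples_path)
        missing = [c for c in df.columns if c not in metas]
        if missing:
            raise ParseError(
                f"{path}: sample columns without metadata: {missing}"
            )
        samples = [metas[c] for c in df.columns]
    else:
        samples = [_meta_from_column_name(c) for c in df.columns]
    matrix = ExpressionMatrix(df, samples)
    logger.info("read expression matrix %s: %d genes, %d samples",
                path, matrix.n_genes, len(matrix.samples))
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.signals.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _genotype_for_alt(gt: tuple, alt_index: int) -> Genotype:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if len(alleles) >= 2 and n_alt == len(alleles):
        return Genotype.HOM_ALT
    if n_alt >= 1:
        return Genotype.HET
    return Genotype.HOM_REF


def _parse_ann_entries(ann_field: Iterable[str]) -> dict[str, tuple[set[str], str]]:
    """ANN entries -> per-allele (SO terms, gene).

    Expected pipe-delimited layout (SnpEff ANN dialect):
    ``Allele|Annotation|Impact|Gene_Name|...``; several consequence terms
    may be joined by '&'.  Gene is taken from the first entry naming one.
    Unparseable entries raise ParseError for the caller to downgrade.
    """
    per_allele: dict[str, tuple[set[str], str]] = {}
    for entry in ann_field:
        parts = entry.split("|")
        if len(parts) < 4:
            raise ParseError(f"unparseable ANN entry {entry!r}")
        allele, annotation, _impact_word, gene = parts[0], parts[1], parts[2], parts[3]
        if not allele or not annotation:
            raise ParseError(f"unparseable ANN entry {entry!r}")
        terms = {t for t in annotation.split("&") if t}
        old_terms, old_gene = per_allele.get(allele, (set(), ""))
        per_allele[allele] = (old_terms | terms, old_gene or gene)
    return per_allele


def read_vcf(
    path: str | Path,
    assembly_label: str,
    contigs: Iterable[str] | None = None,
) -> list[VariantRecord]:
    """Read a single-sample annotated VCF into one record per ALT allele.

    Genotypes are mapped per ALT allele (1/1 -> hom_alt, 0/1 -> het,
    0/0 -> hom_ref, ./. -> missing; a 1/2 site yields two het records).
    Consequence terms and gene come from the INFO ANN field; a record
    whose ANN cannot be parsed is kept with impact UNCLASSIFIED and a
    logged warning.  ``contigs`` optionally restricts to an allow-list
    of chromosomes (e.g. the autosomes) at read time.
    """
    allow = set(contigs) if contigs is not None else None
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        if len(sample_names) != 1:
            raise ParseError(
                f"{path}: expected a single-sample VCF, found "
                f"{len(sample_names)} samples"
            )
        for rec in vf:
            if allow is not None and rec.chrom not in allow:
                continue
            sample = rec.samples[sample_names[0]]
            if "GT" not in sample:
                raise ParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks a GT field"
                )
            gt = sample["GT"]
            ann_ok = True
            per_allele: dict[str, tuple[set[str], str]] = {}
            ann = rec.info.get("ANN")
            if ann is not None:
                if isinstance(ann, str):
                    ann = (ann,)
                try:
                    per_allele = _parse_ann_entries(ann)
                except ParseError as exc:
                    ann_ok = False
                    logger.warning("%s: %s at %s:%d; record kept with "
                                   "impact UNCLASSIFIED",
                                   path, exc, rec.chrom, rec.pos)
            for i, alt in enumerate(rec.alts or (), start=1):
                terms, gene = per_allele.get(alt, (set(), ""))
                impact = (classify_impact(terms)
                          if ann_ok and terms else Impact.UNCLASSIFIED)
                records.append(VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    genotype=_genotype_for_alt(gt, i),
                    gene=gene,
                    so_terms=frozenset(terms),
                    impact=impact,
                    assembly=assembly_label,
                ))
    logger.info("read %d variant records from %s (%s)",
                len(records), path, assembly_label)
    return records


_GT_TUPLE = {
    Genotype.HOM_ALT: (1, 1),
    Genotype.HET: (0, 1),
    Genotype.HOM_REF: (0, 0),
    Genotype.MISSING: (None, None),
}


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_name: str = "sample",
) -> None:
    """Write records as an uncompressed single-sample VCF.

    One VCF line per record (multi-allelic sites are kept decomposed,
    matching the one-atom-per-record model of the funnel).  The ANN INFO
    field is emitted in the pipe-delimited dialect ``read_vcf`` accepts,
    so a write/read round trip preserves chrom/pos/ref/alt/genotype/gene
    and consequence terms.
    """
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    chrom_max: dict[str, int] = {}
    for v in records:
        chrom_max[v.chrom] = max(chrom_max.get(v.chrom, 0), v.pos)
    for chrom in sorted(chrom_max):
        header.contigs.add(chrom, length=chrom_max[chrom] + 1000)
    header.add_line(
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional '
        'annotations: Allele|Annotation|Annotation_Impact|Gene_Name">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(sample_name)
    ordered = sorted(records, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.so_terms or v.gene:
                terms = "&".join(sorted(v.so_terms)) or "."
                rec.info["ANN"] = f"{v.alt}|{terms}|{v.impact.value}|{v.gene}"
            rec.samples[sample_name]["GT"] = _GT_TUPLE[v.genotype]
            out.write(rec)
    logger.info("wrote %d variant records to %s", len(records), path)


# ---------------------------------------------------------------------------
# Markers, loci, panel manifests
# ---------------------------------------------------------------------------

def read_marker_table(path: str | Path) -> list[Marker]:
    """Read a marker TSV with columns name, assembly, chrom, pos."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "assembly": str,
                                            "chrom": str})
    required = {"name", "assembly", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    markers: list[Marker] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        key = (row["name"], row["assembly"])
        if key in seen:
            raise ParseError(f"{path}: duplicate marker {key}")
        seen.add(key)
        markers.append(Marker(name=row["name"], assembly=row["assembly"],
                              chrom=row["chrom"], pos=int(row["pos"])))
    return markers


def write_marker_table(markers: Sequence[Marker], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": m.name, "assembly": m.assembly, "chrom": m.chrom,
          "pos": m.pos} for m in markers]
    ).to_csv(path, sep="\t", index=False)


def read_loci_table(path: str | Path) -> list[LocusInterval]:
    """Read a loci TSV with columns name, chrom, start, end (1-based incl.)."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str})
    required = {"name", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        LocusInterval(name=row["name"], chrom=row["chrom"],
                      start=int(row["start"]), end=int(row["end"]))
        for _, row in df.iterrows()
    ]


def write_loci_table(loci: Sequence[LocusInterval], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": l.name, "chrom": l.chrom, "start": l.start, "end": l.end}
         for l in loci]
    ).to_csv(path, sep="\t", index=False)


def read_panel_manifest(path: str | Path, assembly_label: str) -> PanelManifest:
    """Read a panel manifest TSV with columns strain, vcf (path per strain).

    Relative VCF paths are resolved against the manifest's directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"strain", "vcf"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    base = Path(path).parent
    panel = PanelManifest()
    for _, row in df.iterrows():
        vcf_path = Path(row["vcf"])
        if not vcf_path.is_absolute():
            vcf_path = base / vcf_path
        panel.add(row["strain"], read_vcf(vcf_path, assembly_label))
    return panel


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

CT_COLUMNS = ["gene", "sample_id", "strain", "timepoint",
              "ct_target", "ct_reference"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR quantification-cycle table.

    Columns: gene, sample_id, strain, timepoint, ct_target, ct_reference.
    Ct values must be finite and positive; (gene, sample_id) unique.
    """
    df = pd.read_csv(path, sep="\t",
                     dtype={"gene": str, "sample_id": str, "strain": str})
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["timepoint"] = df["timepoint"].astype(int)
    for col in ("ct_target", "ct_reference"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        bad = df.index[~(df[col] > 0) | ~df[col].apply(pd.notna)]
        if len(bad):
            raise ParseError(
                f"{path}: non-positive or missing {col} at row {bad[0]}"
            )
    dup = df.duplicated(subset=["gene", "sample_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate (gene, sample) entry "
            f"({row['gene']!r}, {row['sample_id']!r})"
        )
    df["strain"] = df["strain"].map(Strain)
    return df[CT_COLUMNS]


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["strain"] = out["strain"].map(
        lambda s: s.value if isinstance(s, Strain) else s
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report, out_dir: str | Path, prefix: str = "report") -> Path:
    """Serialize a report (any object with ``to_json_dict``) to a directory.

    Writes ``<prefix>.json`` with per-stage counts, plus one TSV per
    serialized item table so surviving sets can be re-read; JSON counts
    equal TSV row counts by construction.  Returns the JSON path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = report.to_json_dict()
    json_path = out_dir / f"{prefix}.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for key, value in payload.items():
        if isinstance(value, list) and value and isinstance(value[0], dict):
            pd.DataFrame(value).to_csv(out_dir / f"{prefix}.{key}.tsv",
                                       sep="\t", index=False)
        elif isinstance(value, list) and not value and key == "candidates":
            pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "genotype",
                                  "gene", "so_terms", "impact", "assembly"]
                         ).to_csv(out_dir / f"{prefix}.{key}.tsv",
                                  sep="\t", index=False)
    logger.info("wrote report to %s", json_path)
    return json_path


# ---------------------------------------------------------------------------
# BED interchange
# ---------------------------------------------------------------------------

def locus_to_bed_line(locus: LocusInterval) -> str:
    """1-based inclusive interval -> 0-based half-open BED line."""
    return f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t{locus.name}"


def locus_from_bed_line(line: str) -> LocusInterval:
    """0-based half-open BED line -> 1-based inclusive interval."""
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        raise ParseError(f"malformed BED line: {line!r}")
    name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
    return LocusInterval(name=name, chrom=parts[0],
                         start=int(parts[1]) + 1, end=int(parts[2]))
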