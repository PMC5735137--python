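"""Readers and writers for variant tables, reference panels, transcript models
and domain maps.

Variant tables are TSV with a header; column names are declared in a
:class:`TableDialect` so external cohorts with different headers can be
ingested without code changes. The transcript model is a single BED12 line
(0-based half-open block coordinates on disk, converted to the package's
1-based inclusive convention on read). Domain maps and reference panels are
small JSON documents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .model import (
    CohortTable,
    DomainMap,
    HgvsParseError,
    PopulationReference,
    PredictionSet,
    TranscriptModel,
    VariantRecord,
    parse_hgvs_c,
    parse_hgvs_p,
)

__all__ = [
    "TableDialect",
    "VariantTableError",
    "read_variant_table",
    "write_variant_table",
    "read_reference_panels",
    "write_reference_panels",
    "read_domain_map",
    "write_domain_map",
    "read_transcript_model",
]


class VariantTableError(ValueError):
    """A variant table failed validation; the message carries the line number."""


@dataclass(frozen=True)
class TableDialect:
    """Column-name schema of a variant TSV.

    ``maf_columns`` maps panel name -> column header. Missing optional
    columns (band, predictor calls, zygosity, ddg) simply leave the
    corresponding record fields at their defaults.
    """

    subject: str = "subject_id"
    gene: str = "gene"
    chrom: str = "chrom"
    g_pos: str = "g_pos"
    exon: str = "exon"
    hgvs_c: str = "hgvs_c"
    hgvs_p: str = "hgvs_p"
    band: str = "band"
    maf_columns: Mapping[str, str] = field(
        default_factory=lambda: {"1000g": "maf_1000g", "esp": "maf_esp", "exac": "maf_exac"}
    )
    sift: str = "sift"
    mutation_taster: str = "mutation_taster"
    polyphen_hvar: str = "polyphen_hvar"
    polyphen_hdiv: str = "polyphen_hdiv"
    zygosity: str = "zygosity"
    ddg: str = "ddg"

    @property
    def required(self) -> tuple[str, ...]:
        return (self.subject, self.gene, self.g_pos, self.hgvs_c) + tuple(
            self.maf_columns.values()
        )


DEFAULT_DIALECT = TableDialect()


def _cell(row: pd.Series, column: str):
    if column not in row.index:
        return None
    value = row[column]
    if pd.isna(value) or (isinstance(value, str) and not value.strip()):
        return None
    return value


def read_variant_table(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    *,
    name: str | None = None,
    n_probands: int | None = None,
) -> CohortTable:
    """Read a TSV of proband-variants into a :class:`CohortTable`.

    ``n_probands`` defaults to the number of distinct subjects in the file,
    which is only correct for a fully-penetrant table; cohorts with
    variant-free probands must pass the true cohort size.

    Raises :class:`VariantTableError` naming the offending line for malformed
    HGVS strings, missing required columns, or duplicated (subject, g_pos)
    rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in dialect.required if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path.name}: missing required columns {missing}")

    records: list[VariantRecord] = []
    seen: set[tuple[str, int]] = set()
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            record = _row_to_record(row, dialect)
        except (HgvsParseError, ValueError) as exc:
            raise VariantTableError(f"{path.name} line {line_no}: {exc}") from exc
        key = (record.subject_id, record.g_pos)
        if key in seen:
            raise VariantTableError(
                f"{path.name} line {line_no}: duplicate row for subject "
                f"{record.subject_id!r} at g.{record.g_pos}"
            )
        seen.add(key)
        records.append(record)

    cohort_name = name if name is not None else path.stem
    if n_probands is None:
        n_probands = max(1, len({r.subject_id for r in records}))
    return CohortTable(cohort_name, n_probands, records)


def _row_to_record(row: pd.Series, dialect: TableDialect) -> VariantRecord:
    c_pos, ref, alt = parse_hgvs_c(str(row[dialect.hgvs_c]))
    p_residue = aa_ref = aa_alt = None
    hgvs_p = _cell(row, dialect.hgvs_p)
    if hgvs_p is not None:
        aa_ref, p_residue, aa_alt = parse_hgvs_p(str(hgvs_p))

    maf: dict[str, float] = {}
    for panel, column in dialect.maf_columns.items():
        value = _cell(row, column)
        maf[panel] = float(value) if value is not None else 0.0

    calls = {}
    for field_name in ("sift", "mutation_taster", "polyphen_hvar", "polyphen_hdiv"):
        value = _cell(row, getattr(dialect, field_name))
        calls[field_name] = str(value) if value is not None else "missing"

    exon = _cell(row, dialect.exon)
    band = _cell(row, dialect.band)
    zygosity = _cell(row, dialect.zygosity)
    ddg = _cell(row, dialect.ddg)
    chrom = _cell(row, dialect.chrom)

    return VariantRecord(
        subject_id=str(row[dialect.subject]),
        gene=str(row[dialect.gene]),
        chrom=str(chrom) if chrom is not None else "",
        g_pos=int(row[dialect.g_pos]),
        c_pos=c_pos,
        ref_allele=ref,
        alt_allele=alt,
        exon=int(exon) if exon is not None else None,
        p_residue=p_residue,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        band=str(band) if band is not None else None,
        maf=maf,
        predictions=PredictionSet(**calls),
        zygosity=str(zygosity) if zygosity is not None else "het",
        ddg=float(ddg) if ddg is not None else None,
    )


def write_variant_table(
    cohort: CohortTable, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    """Serialize a cohort back to the TSV dialect; inverse of the reader."""
    rows = []
    for r in cohort:
        row = {
            dialect.subject: r.subject_id,
            dialect.gene: r.gene,
            dialect.chrom: r.chrom,
            dialect.g_pos: r.g_pos,
            dialect.exon: r.exon if r.exon is not None else "",
            dialect.hgvs_c: r.hgvs_c,
            dialect.hgvs_p: r.hgvs_p or "",
            dialect.band: r.band or "",
            dialect.sift: r.predictions.sift,
            dialect.mutation_taster: r.predictions.mutation_taster,
            dialect.polyphen_hvar: r.predictions.polyphen_hvar,
            dialect.polyphen_hdiv: r.predictions.polyphen_hdiv,
            dialect.zygosity: r.zygosity,
            dialect.ddg: r.ddg if r.ddg is not None else "",
        }
        for panel, column in dialect.maf_columns.items():
            freq = r.maf.get(panel, 0.0)
            row[column] = repr(freq) if freq else "0"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reference_panels(path: str | Path) -> list[PopulationReference]:
    """Read a JSON list of population panels with per-stratum allele counts.

    Expected shape::

        [{"name": "ESP6500", "total_alleles": 13006,
          "variant_alleles": {"0.0005": 1895, "0.0001": 820}}, ...]
    """
    with open(path) as handle:
        payload = json.load(handle)
    panels = []
    for entry in payload:
        panels.append(
            PopulationReference(
                name=entry["name"],
                total_alleles=int(entry["total_alleles"]),
                variant_alleles_by_stratum={
                    float(cutoff): int(count)
                    for cutoff, count in entry["variant_alleles"].items()
                },
            )
        )
    return panels


def write_reference_panels(panels: Sequence[PopulationReference], path: str | Path) -> None:
    payload = [
        {
            "name": p.name,
            "total_alleles": p.total_alleles,
            "variant_alleles": {
                repr(cutoff): count for cutoff, count in p.variant_alleles_by_stratum.items()
            },
        }
        for p in panels
    ]
    Path(path).write_text(json.dumps(payload, indent=1, ensure_ascii=False) + "\n")


def read_domain_map(path: str | Path) -> DomainMap:
    """Read a JSON domain map: ``{"bands": [[label, start, end], ...], "tk": [s, e]}``.

    Validation (non-overlap, ordering, TK containment in the M-band) happens
    in the :class:`DomainMap` constructor.
    """
    with open(path) as handle:
        payload = json.load(handle)
    bands = tuple((str(label), int(start), int(end)) for label, start, end in payload["bands"])
    tk = tuple(int(v) for v in payload["tk"])
    return DomainMap(bands=bands, tk_interval=(tk[0], tk[1]))


def write_domain_map(dm: DomainMap, path: str | Path) -> None:
    payload = {"bands": [list(b) for b in dm.bands], "tk": list(dm.tk_interval)}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_transcript_model(path: str | Path, cds_offset: int = 1) -> TranscriptModel:
    """Read a transcript model from a one-line BED12 file.

    BED12 columns: chrom, chromStart, chromEnd, name, score, strand,
    thickStart, thickEnd, itemRgb, blockCount, blockSizes, blockStarts.
    Block coordinates are 0-based half-open and listed in ascending genomic
    order regardless of strand; they are converted to 1-based inclusive exon
    intervals ordered in transcript (5'->3') direction.
    """
    path = Path(path)
    lines = [
        line for line in path.read_text().splitlines() if line.strip() and not line.startswith("#")
    ]
    if len(lines) != 1:
        raise ValueError(f"{path.name}: expected exactly one BED12 record, found {len(lines)}")
    fields = lines[0].split("\t")
    if len(fields) < 12:
        raise ValueError(f"{path.name}: BED12 needs 12 columns, found {len(fields)}")
    chrom, chrom_start, _, tx_id, _, strand = fields[0], int(fields[1]), fields[2], fields[3], fields[4], fields[5]
    block_count = int(fields[9])
    sizes = [int(v) for v in fields[10].rstrip(",").split(",")]
    starts = [int(v) for v in fields[11].rstrip(",").split(",")]
    if len(sizes) != block_count or len(starts) != block_count:
        raise ValueError(f"{path.name}: block count {block_count} disagrees with block lists")
    exons = [
        (chrom_start + rel + 1, chrom_start + rel + size)
        for rel, size in zip(starts, sizes)
    ]
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel(
        transcript_id=tx_id, chrom=chrom, strand=strand, exons=tuple(exons), cds_offset=cds_offset
    )
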