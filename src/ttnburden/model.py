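"""Domain types for case-control rare-variant enrichment analysis.

The central objects are :class:`VariantRecord` (one proband-variant with
coordinates in genomic, cDNA and protein space plus per-panel allele
frequencies and in-silico predictor calls), :class:`CohortTable` (an ordered
case series), :class:`PopulationReference` (aggregate allele counts from a
population panel such as 1000 Genomes, NHLBI-ESP6500 or ExAC, stratified by
MAF cut-off), :class:`TranscriptModel` (strand-aware exon intervals driving
genomic<->cDNA mapping), :class:`DomainMap` (sarcomere-band residue
intervals) and :class:`ContingencyTable2x2` (the substrate of all exact
inference).

Coordinates are 1-based inclusive throughout, matching HGVS usage.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

__all__ = [
    "PredictionSet",
    "VariantRecord",
    "CohortTable",
    "PopulationReference",
    "TranscriptModel",
    "DomainMap",
    "ContingencyTable2x2",
    "EnrichmentResult",
    "HgvsParseError",
    "parse_hgvs_c",
    "parse_hgvs_p",
    "format_hgvs_c",
    "format_hgvs_p",
]

_CALL_VALUES = {
    "sift": {"damaging", "tolerated", "missing"},
    "mutation_taster": {"damaging", "benign", "missing"},
    "polyphen_hvar": {"damaging", "benign", "missing"},
    "polyphen_hdiv": {"damaging", "benign", "missing"},
}


class HgvsParseError(ValueError):
    """A cDNA or protein change string does not follow the expected grammar."""


_HGVS_C = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_HGVS_P = re.compile(r"^p\.([A-Z])(\d+)([A-Z*])$")


def parse_hgvs_c(text: str) -> tuple[int, str, str]:
    """Parse a substitution like ``c.15286T>C`` into (position, ref, alt)."""
    m = _HGVS_C.match(text.strip())
    if not m:
        raise HgvsParseError(f"malformed cDNA change {text!r}; expected e.g. 'c.15286T>C'")
    return int(m.group(1)), m.group(2), m.group(3)


def parse_hgvs_p(text: str) -> tuple[str, int, str]:
    """Parse a substitution like ``p.C5096R`` into (ref_aa, residue, alt_aa)."""
    m = _HGVS_P.match(text.strip())
    if not m:
        raise HgvsParseError(f"malformed protein change {text!r}; expected e.g. 'p.C5096R'")
    return m.group(1), int(m.group(2)), m.group(3)


def format_hgvs_c(c_pos: int, ref: str, alt: str) -> str:
    return f"c.{c_pos}{ref}>{alt}"


def format_hgvs_p(aa_ref: str, residue: int, aa_alt: str) -> str:
    return f"p.{aa_ref}{residue}{aa_alt}"


@dataclass(frozen=True)
class PredictionSet:
    """In-silico pathogenicity calls, consumed as annotations (never computed).

    ``missing`` means the tool reported nothing for the variant and is treated
    as not-damaging by the consensus rule.
    """

    sift: str = "missing"
    mutation_taster: str = "missing"
    polyphen_hvar: str = "missing"
    polyphen_hdiv: str = "missing"

    def __post_init__(self) -> None:
        for name, allowed in _CALL_VALUES.items():
            value = getattr(self, name)
            if value not in allowed:
                raise ValueError(f"{name} call {value!r} not in {sorted(allowed)}")

    @classmethod
    def all_damaging(cls) -> "PredictionSet":
        return cls("damaging", "damaging", "damaging", "damaging")


@dataclass(frozen=True)
class VariantRecord:
    """One proband-variant observation.

    ``maf`` maps panel name -> allele frequency; an absent panel is read as
    frequency 0 (a variant unreported in a panel is treated as novel there).
    ``ddg`` is a pass-through protein-stability annotation (kcal/mol) and is
    never interpreted by the pipeline.
    """

    subject_id: str
    gene: str
    chrom: str
    g_pos: int
    c_pos: int
    ref_allele: str
    alt_allele: str
    exon: int | None = None
    p_residue: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    band: str | None = None
    maf: Mapping[str, float] = field(default_factory=dict)
    predictions: PredictionSet = field(default_factory=PredictionSet)
    zygosity: str = "het"
    ddg: float | None = None

    def __post_init__(self) -> None:
        if self.g_pos < 1:
            raise ValueError(f"g_pos must be >= 1, got {self.g_pos}")
        if self.c_pos < 1:
            raise ValueError(f"c_pos must be >= 1, got {self.c_pos}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be 'het' or 'hom', got {self.zygosity!r}")
        if self.p_residue is not None:
            expected = (self.c_pos - 1) // 3 + 1
            if self.p_residue != expected:
                raise ValueError(
                    f"p_residue {self.p_residue} inconsistent with c_pos {self.c_pos} "
                    f"(codon arithmetic gives residue {expected})"
                )
        for panel, f in self.maf.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"MAF for panel {panel!r} out of [0,1]: {f}")

    @property
    def hgvs_c(self) -> str:
        return format_hgvs_c(self.c_pos, self.ref_allele, self.alt_allele)

    @property
    def hgvs_p(self) -> str | None:
        if self.p_residue is None or self.aa_ref is None or self.aa_alt is None:
            return None
        return format_hgvs_p(self.aa_ref, self.p_residue, self.aa_alt)

    def with_band(self, band: str) -> "VariantRecord":
        return replace(self, band=band)


@dataclass(frozen=True)
class CohortTable:
    """An ordered case series of proband-variant records.

    ``n_probands`` is the full cohort size including variant-free probands;
    the allele denominator of case-side 2x2 cells is ``2 * n_probands``.
    """

    name: str
    n_probands: int
    records: tuple[VariantRecord, ...]

    def __init__(self, name: str, n_probands: int, records: Sequence[VariantRecord]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "n_probands", int(n_probands))
        object.__setattr__(self, "records", tuple(records))
        if self.n_probands < 1:
            raise ValueError("n_probands must be positive")
        if self.n_probands < len(self.subjects()):
            raise ValueError(
                f"cohort of {self.n_probands} probands cannot contain "
                f"{len(self.subjects())} distinct subjects with records"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def subjects(self) -> tuple[str, ...]:
        """Distinct subject ids with at least one record, in first-seen order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return tuple(seen)

    @property
    def allele_denominator(self) -> int:
        return 2 * self.n_probands

    def subset(self, records: Sequence[VariantRecord], name: str | None = None) -> "CohortTable":
        return CohortTable(name or self.name, self.n_probands, records)


@dataclass(frozen=True)
class PopulationReference:
    """Aggregate allele counts of qualifying variants in a population panel.

    ``variant_alleles_by_stratum`` maps a MAF cut-off to the number of
    variant alleles qualifying at that cut-off; counts must not increase as
    the cut-off tightens.
    """

    name: str
    total_alleles: int
    variant_alleles_by_stratum: Mapping[float, int]

    def __post_init__(self) -> None:
        if self.total_alleles <= 0:
            raise ValueError("total_alleles must be positive")
        for cutoff, k in self.variant_alleles_by_stratum.items():
            if not 0 <= k <= self.total_alleles:
                raise ValueError(f"variant alleles {k} at cutoff {cutoff} out of range")
        strata = sorted(self.variant_alleles_by_stratum, reverse=True)
        counts = [self.variant_alleles_by_stratum[s] for s in strata]
        if any(lo > hi for hi, lo in zip(counts, counts[1:])):
            raise ValueError("variant allele counts must be non-increasing as the cutoff decreases")

    def variant_alleles(self, cutoff: float) -> int:
        try:
            return self.variant_alleles_by_stratum[cutoff]
        except KeyError:
            raise KeyError(
                f"panel {self.name!r} has no stratum at cutoff {cutoff}; "
                f"available: {sorted(self.variant_alleles_by_stratum)}"
            ) from None

    def frequency_percent(self, cutoff: float) -> float:
        return 100.0 * self.variant_alleles(cutoff) / self.total_alleles


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exon intervals of one transcript, in transcript (5'->3') order.

    Exon tuples are 1-based inclusive genomic (start, end) with start <= end;
    for a minus-strand transcript the genomic coordinates strictly decrease
    along transcript order. ``cds_offset`` is the transcript coordinate of the
    first coding base; the default 1 means the model covers the CDS only, so
    transcript coordinates coincide with HGVS c. positions.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_offset: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript model needs at least one exon")
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValueError(f"bad exon interval ({start}, {end})")
        by_pos = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_pos, by_pos[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons ({s1},{e1}) and ({s2},{e2})")
        ordered = self.exons if self.strand == "+" else self.exons[::-1]
        if list(ordered) != by_pos:
            raise ValueError("exons are not ordered in transcript direction for the declared strand")

    @property
    def total_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    def exon_offsets(self) -> tuple[int, ...]:
        """Cumulative transcript coordinate of the first base of each exon."""
        offsets = []
        pos = 1
        for start, end in self.exons:
            offsets.append(pos)
            pos += end - start + 1
        return tuple(offsets)


@dataclass(frozen=True)
class DomainMap:
    """Ordered, non-overlapping residue intervals for protein bands.

    Bands follow the sarcomere layout of TITIN (Z-disk, I-band, A-band,
    M-band from the N- to the C-terminus); ``tk_interval`` is the titin
    kinase sub-domain and must lie inside the band labelled ``M-band``.
    """

    bands: tuple[tuple[str, int, int], ...]
    tk_interval: tuple[int, int]

    def __post_init__(self) -> None:
        prev_end = 0
        for label, start, end in self.bands:
            if start < 1 or end < start:
                raise ValueError(f"bad residue interval for band {label!r}: ({start}, {end})")
            if start <= prev_end:
                raise ValueError(
                    f"band {label!r} starting at {start} overlaps or precedes the previous band"
                )
            prev_end = end
        tk_s, tk_e = self.tk_interval
        m_bands = [(s, e) for label, s, e in self.bands if label == "M-band"]
        if not m_bands:
            raise ValueError("domain map has no band labelled 'M-band'")
        m_s, m_e = m_bands[0]
        if not (m_s <= tk_s <= tk_e <= m_e):
            raise ValueError(
                f"TK interval ({tk_s}, {tk_e}) not contained in M-band ({m_s}, {m_e})"
            )

    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.bands)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Integer 2x2 table (a, b | c, d); rows are the compared groups.

    ``a`` counts exposed (carrier / variant-allele) units in group 1, ``b``
    the unexposed remainder; ``c`` and ``d`` likewise for group 2. Exact
    inference conditions on all margins.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both row margins must be positive")

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d

    @property
    def m(self) -> int:
        """First-column margin (total exposed units)."""
        return self.a + self.c

    @property
    def support(self) -> tuple[int, int]:
        """Feasible range of cell ``a`` given fixed margins, inclusive."""
        return max(0, self.m - self.n2), min(self.n1, self.m)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EnrichmentResult:
    """Bundled exact-inference output for one 2x2 comparison."""

    table: ContingencyTable2x2
    or_cross_product: float
    or_cmle: float
    ci: tuple[float, float]
    ci_method: str
    level: float
    p_midp: float
    p_fisher: float
    stratum: str = "patient-level"
    psi_grid_note: str | None = None

    def __post_init__(self) -> None:
        for p in (self.p_midp, self.p_fisher):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value out of [0,1]: {p}")
        lo, hi = self.ci
        if math.isfinite(self.or_cross_product) and self.or_cross_product > 0:
            if not (lo <= self.or_cross_product <= hi or lo <= self.or_cmle <= hi):
                raise ValueError(
                    f"CI ({lo}, {hi}) does not bracket point estimates "
                    f"{self.or_cross_product}, {self.or_cmle}"
                )

    @property
    def or_display(self) -> str:
        """Cross-product OR rendered for reports; infinite estimates print as '∞'."""
        if math.isinf(self.or_cross_product):
            return "∞"
        return f"{self.or_cross_product:.3f}"
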