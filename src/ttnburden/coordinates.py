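"""Strand-aware genomic<->cDNA mapping, codon arithmetic and band assignment.

The transcript model fixes a bijection between genomic positions covered by
its exons and 1-based cDNA positions. On the minus strand the mapping is
order-reversing: larger genomic coordinates correspond to smaller cDNA
coordinates, and cDNA-sense alleles are the reverse complement of the
genomic (plus-strand reference) alleles.
"""

from __future__ import annotations

from .model import CohortTable, DomainMap, TranscriptModel, VariantRecord

__all__ = [
    "NotExonicError",
    "genomic_to_cdna",
    "cdna_to_genomic",
    "cdna_to_protein",
    "assign_domain",
    "in_titin_kinase",
    "reverse_complement",
    "genomic_alleles_to_cdna",
    "annotate_bands",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class NotExonicError(ValueError):
    """A genomic position fell outside every exon of the transcript model."""

    def __init__(self, g: int, nearest_boundary: int):
        self.g = g
        self.nearest_boundary = nearest_boundary
        super().__init__(
            f"position {g} is not exonic; nearest exon boundary at {nearest_boundary}"
        )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def genomic_to_cdna(tm: TranscriptModel, g: int) -> int:
    """Map a genomic position inside an exon to its 1-based cDNA coordinate."""
    offset = 0
    nearest = None
    for start, end in tm.exons:
        if start <= g <= end:
            within = (g - start) if tm.strand == "+" else (end - g)
            return offset + within + 1 - (tm.cds_offset - 1)
        for boundary in (start, end):
            if nearest is None or abs(boundary - g) < abs(nearest - g):
                nearest = boundary
        offset += end - start + 1
    raise NotExonicError(g, nearest if nearest is not None else -1)


def cdna_to_genomic(tm: TranscriptModel, c: int) -> int:
    """Inverse of :func:`genomic_to_cdna`; raises on out-of-range coordinates."""
    t = c + (tm.cds_offset - 1)  # transcript coordinate
    if t < 1 or t > tm.total_length:
        raise ValueError(
            f"cDNA position {c} outside transcript {tm.transcript_id} "
            f"(length {tm.total_length}, cds_offset {tm.cds_offset})"
        )
    remaining = t - 1
    for start, end in tm.exons:
        length = end - start + 1
        if remaining < length:
            return start + remaining if tm.strand == "+" else end - remaining
        remaining -= length
    raise AssertionError("unreachable: transcript length already checked")


def cdna_to_protein(c: int) -> tuple[int, int]:
    """Codon arithmetic: cDNA position -> (residue index, position in codon).

    HGVS c. numbering counts from the A of the initiator ATG, so residue
    ``(c - 1) // 3 + 1`` and codon position ``(c - 1) % 3 + 1``.
    """
    if c < 1:
        raise ValueError(f"cDNA position must be >= 1, got {c}")
    return (c - 1) // 3 + 1, (c - 1) % 3 + 1


def genomic_alleles_to_cdna(tm: TranscriptModel, ref: str, alt: str) -> tuple[str, str]:
    """Convert plus-strand genomic alleles to cDNA-sense alleles."""
    if tm.strand == "+":
        return ref, alt
    return reverse_complement(ref), reverse_complement(alt)


def assign_domain(dm: DomainMap, residue: int) -> str:
    """Label of the band containing ``residue``; ``'unassigned'`` if none does."""
    if residue < 1:
        raise ValueError(f"residue must be >= 1, got {residue}")
    for label, start, end in dm.bands:
        if start <= residue <= end:
            return label
    return "unassigned"


def in_titin_kinase(dm: DomainMap, residue: int) -> bool:
    """Whether a residue lies in the titin kinase (TK) sub-domain, bounds inclusive."""
    start, end = dm.tk_interval
    return start <= residue <= end


def annotate_bands(cohort: CohortTable, dm: DomainMap) -> CohortTable:
    """Return a cohort whose records carry band labels derived from the map.

    Records without a protein residue keep their existing band annotation.
    """
    annotated = []
    for record in cohort:
        if record.p_residue is None:
            annotated.append(record)
        else:
            annotated.append(record.with_band(assign_domain(dm, record.p_residue)))
    return cohort.subset(annotated)
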