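"""Variant prioritization: MAF filtering, predictor consensus, gene recurrence,
carrier summaries and trio segregation.

Rarity filtering compares an aggregate per-record allele frequency against a
cut-off with ``<=`` (a variant at exactly the cut-off qualifies). How the
per-panel frequencies collapse to one number is a :class:`MafPolicy`: the
discovery stage uses the maximum over all panels, while the rare-variant
stratum of the packaged study is only reproducible with a single-panel
(ExAC) rule carrying an auxiliary threshold — both ship as named policies
and the reconstruction is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import CohortTable, PredictionSet, VariantRecord

__all__ = [
    "MafPolicy",
    "DISCOVERY_POLICY",
    "RARE_SET_POLICY",
    "aggregate_maf",
    "apply_maf_filter",
    "consensus_damaging",
    "prioritize_recurrent_genes",
    "carrier_summary",
    "check_trio_segregation",
]


@dataclass(frozen=True)
class MafPolicy:
    """How per-panel frequencies collapse into one filterable number.

    ``max_over_panels`` takes the largest reported frequency (0 if the
    variant is unreported everywhere). ``single_panel`` reads one panel only.
    ``aux_cutoff``, when set, additionally requires the aggregate to be at or
    below it regardless of the stratum cut-off, i.e. the effective threshold
    is ``min(cutoff, aux_cutoff)``.
    """

    mode: str = "max_over_panels"
    panel: str | None = None
    aux_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("max_over_panels", "single_panel"):
            raise ValueError(f"unknown MAF policy mode {self.mode!r}")
        if self.mode == "single_panel" and not self.panel:
            raise ValueError("single_panel policy requires a panel name")
        if self.aux_cutoff is not None and not 0 < self.aux_cutoff < 1:
            raise ValueError("aux_cutoff must lie in (0,1)")


DISCOVERY_POLICY = MafPolicy(mode="max_over_panels")
#: Reconstructed rare-stratum rule: ExAC frequency with an auxiliary 5e-5
#: threshold. See the methods note for the derivation of this policy.
RARE_SET_POLICY = MafPolicy(mode="single_panel", panel="exac", aux_cutoff=5e-5)


def aggregate_maf(record: VariantRecord, policy: MafPolicy = DISCOVERY_POLICY) -> float:
    """Collapse a record's per-panel frequencies under the policy; absent panels read 0."""
    if policy.mode == "single_panel":
        return float(record.maf.get(policy.panel, 0.0))
    return float(max(record.maf.values(), default=0.0))


def apply_maf_filter(
    cohort: CohortTable, cutoff: float, policy: MafPolicy = DISCOVERY_POLICY
) -> CohortTable:
    """Retain records with aggregate MAF <= the effective cut-off.

    Order-preserving and idempotent; the cohort size (and hence the allele
    denominator) is unchanged, only the record list shrinks.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in (0,1], got {cutoff}")
    effective = cutoff if policy.aux_cutoff is None else min(cutoff, policy.aux_cutoff)
    kept = [r for r in cohort if aggregate_maf(r, policy) <= effective]
    return cohort.subset(kept, name=f"{cohort.name}|maf<={cutoff:g}")


def consensus_damaging(p: PredictionSet) -> bool:
    """Predictor-consensus rule for retaining a variant.

    Damaging by SIFT AND MutationTaster AND at least one of the two
    PolyPhen-2 models (HVAR and/or HDIV); a missing call counts as
    not-damaging.
    """
    return (
        p.sift == "damaging"
        and p.mutation_taster == "damaging"
        and (p.polyphen_hvar == "damaging" or p.polyphen_hdiv == "damaging")
    )


def prioritize_recurrent_genes(
    cohort: CohortTable, min_count: int = 2, unit: str = "patients"
) -> list[tuple[str, int]]:
    """Genes recurrently hit in the cohort, ranked by descending count.

    ``unit='patients'`` counts distinct subjects per gene; ``unit='variants'``
    counts records. Ties break lexicographically by gene symbol.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if unit not in ("patients", "variants"):
        raise ValueError(f"unit must be 'patients' or 'variants', got {unit!r}")
    if unit == "patients":
        subjects: dict[str, set[str]] = {}
        for r in cohort:
            subjects.setdefault(r.gene, set()).add(r.subject_id)
        counts = {gene: len(subs) for gene, subs in subjects.items()}
    else:
        counts = {}
        for r in cohort:
            counts[r.gene] = counts.get(r.gene, 0) + 1
    ranked = [(gene, n) for gene, n in counts.items() if n >= min_count]
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked


def carrier_summary(cohort: CohortTable, gene: str) -> tuple[int, int, int]:
    """(distinct carriers, variant records, carrier percent) for one gene.

    A subject counts once however many records they contribute; the percent
    is over the full cohort size, rounded to the nearest whole percent.
    """
    gene_records = [r for r in cohort if r.gene == gene]
    carriers = {r.subject_id for r in gene_records}
    if not carriers:
        return 0, 0, 0
    percent = round(100.0 * len(carriers) / cohort.n_probands)
    return len(carriers), len(gene_records), int(percent)


_GENOTYPES = ("wildtype", "het", "hom")


def check_trio_segregation(
    proband: str,
    father: tuple[str, bool | None],
    mother: tuple[str, bool | None],
) -> str:
    """Classify a trio under a dominant single-variant segregation model.

    Parents are (genotype, affected) pairs with ``affected`` in
    {True, False, None} (None = status unknown). Returns ``'consistent'``,
    ``'inconsistent'`` or ``'uninformative'``:

    - a carrier proband with both parents wildtype is a Mendelian violation
      (or de novo), hence inconsistent;
    - transmission from exactly one carrier parent is consistent when that
      parent is affected, inconsistent when the carrier parent is unaffected
      or the allele-free parent is the affected one, and uninformative when
      statuses are unknown;
    - both parents carrying (or a variant-free proband) leaves the trio
      uninformative.
    """
    f_gt, f_aff = father
    m_gt, m_aff = mother
    for gt in (proband, f_gt, m_gt):
        if gt not in _GENOTYPES:
            raise ValueError(f"genotype must be one of {_GENOTYPES}, got {gt!r}")

    if proband == "wildtype":
        return "uninformative"

    parent_carries = (f_gt != "wildtype", m_gt != "wildtype")
    if proband == "hom":
        if not all(parent_carries):
            return "inconsistent"
        if f_aff is None or m_aff is None:
            return "uninformative"
        return "consistent" if (f_aff and m_aff) else "inconsistent"

    # heterozygous proband
    if not any(parent_carries):
        return "inconsistent"
    if all(parent_carries):
        return "uninformative"
    carrier_aff, other_aff = (f_aff, m_aff) if parent_carries[0] else (m_aff, f_aff)
    if carrier_aff is None:
        return "uninformative"
    if not carrier_aff:
        return "inconsistent"
    if other_aff:  # affected parent without the allele breaks segregation
        return "inconsistent"
    return "consistent"
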