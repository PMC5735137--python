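"""Case-control enrichment at MAF strata and protein-band spectrum analysis.

The allele-level comparison puts the cohort's qualifying variant alleles
(one per heterozygous record, two per homozygous record) over the cohort's
``2 * n_probands`` allele denominator against a population panel's variant
allele counts in the same MAF stratum; the patient-level comparison puts
carrier counts of two cohorts side by side. Both feed the exact 2x2
machinery of :mod:`ttnburden.exact`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .coordinates import assign_domain
from .exact import DEFAULT_CONFIG, ExactConfig, enrichment_test
from .filtration import DISCOVERY_POLICY, MafPolicy, apply_maf_filter
from .model import (
    CohortTable,
    ContingencyTable2x2,
    DomainMap,
    EnrichmentResult,
    PopulationReference,
    VariantRecord,
)

__all__ = [
    "SpectrumTable",
    "qualifying_allele_count",
    "build_case_allele_table",
    "run_enrichment",
    "patient_level_enrichment",
    "mean_control_frequency",
    "band_distribution",
    "band_enrichment",
    "mband_carrier_summary",
]


@dataclass(frozen=True)
class SpectrumTable:
    """Per-band variant counts and percents for one cohort and stratum."""

    cohort: str
    stratum: str
    counts: Mapping[str, int]
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator != sum(self.counts.values()):
            raise ValueError(
                f"band counts {dict(self.counts)} do not sum to denominator {self.denominator}"
            )

    def percent(self, band: str, digits: int = 1) -> float:
        """Share of one band in percent, rounded to ``digits`` decimals."""
        if self.denominator == 0:
            return 0.0
        return round(100.0 * self.counts.get(band, 0) / self.denominator, digits)

    def percents(self, digits: int = 1) -> dict[str, float]:
        return {band: self.percent(band, digits) for band in self.counts}


def qualifying_allele_count(cohort: CohortTable) -> int:
    """Variant alleles contributed by the cohort's records: 1 per het, 2 per hom."""
    return sum(2 if r.zygosity == "hom" else 1 for r in cohort)


def build_case_allele_table(
    n_qualifying: int,
    n_probands: int,
    ref: PopulationReference,
    cutoff: float,
) -> ContingencyTable2x2:
    """Allele-level 2x2: case qualifying alleles vs a panel's stratum counts."""
    if n_qualifying > 2 * n_probands:
        raise ValueError(
            f"{n_qualifying} qualifying alleles exceed the {2 * n_probands}-allele denominator"
        )
    c = ref.variant_alleles(cutoff)
    return ContingencyTable2x2(
        a=n_qualifying,
        b=2 * n_probands - n_qualifying,
        c=c,
        d=ref.total_alleles - c,
    )


def run_enrichment(
    cohort: CohortTable,
    refs: Sequence[PopulationReference],
    cutoffs: Sequence[float],
    policy: MafPolicy | Mapping[float, MafPolicy] = DISCOVERY_POLICY,
    cfg: ExactConfig = DEFAULT_CONFIG,
) -> list[EnrichmentResult]:
    """One exact enrichment result per (cutoff, panel), in that nesting order.

    ``policy`` may be a single :class:`MafPolicy` or a mapping cutoff ->
    policy when strata use different aggregation rules (as the packaged
    study's two strata do).
    """
    if not refs or not cutoffs:
        raise ValueError("need at least one reference panel and one cutoff")
    results = []
    for cutoff in cutoffs:
        stratum_policy = policy[cutoff] if isinstance(policy, Mapping) else policy
        qualifying = apply_maf_filter(cohort, cutoff, stratum_policy)
        n_alleles = qualifying_allele_count(qualifying)
        for ref in refs:
            table = build_case_allele_table(n_alleles, cohort.n_probands, ref, cutoff)
            results.append(
                enrichment_test(table, cfg, stratum=f"{ref.name}@{cutoff:g}")
            )
    return results


def patient_level_enrichment(
    k1: int, n1: int, k2: int, n2: int, cfg: ExactConfig = DEFAULT_CONFIG
) -> EnrichmentResult:
    """Carrier-count comparison of two cohorts: table (k1, n1-k1, k2, n2-k2)."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("carrier counts cannot exceed cohort sizes")
    table = ContingencyTable2x2(a=k1, b=n1 - k1, c=k2, d=n2 - k2)
    return enrichment_test(table, cfg, stratum="patient-level")


def mean_control_frequency(refs: Sequence[PopulationReference], cutoff: float) -> int:
    """Unweighted mean of the panels' stratum frequencies, in whole percent."""
    if not refs:
        raise ValueError("need at least one reference panel")
    mean = sum(ref.frequency_percent(cutoff) for ref in refs) / len(refs)
    return int(round(mean))


def band_distribution(
    records: Sequence[VariantRecord],
    dm: DomainMap,
    *,
    cohort: str = "cohort",
    stratum: str = "all",
) -> SpectrumTable:
    """Count variant records per protein band.

    Residue-bearing records are assigned through the domain map; records
    without a residue fall back to their stored band label, else
    ``'unassigned'``. Every band of the map appears in the output, zero or
    not, so spectra over the same map are always comparable.
    """
    counts: dict[str, int] = {label: 0 for label in dm.labels()}
    for r in records:
        if r.p_residue is not None:
            label = assign_domain(dm, r.p_residue)
        else:
            label = r.band or "unassigned"
        counts[label] = counts.get(label, 0) + 1
    return SpectrumTable(cohort=cohort, stratum=stratum, counts=counts, denominator=len(records))


def band_enrichment(
    spec_case: SpectrumTable,
    spec_ctrl: SpectrumTable,
    band: str,
    cfg: ExactConfig = DEFAULT_CONFIG,
) -> EnrichmentResult:
    """Exact band-vs-rest comparison of two spectra (e.g. the M-band excess)."""
    for spec in (spec_case, spec_ctrl):
        if band not in spec.counts:
            raise KeyError(f"band {band!r} absent from spectrum of {spec.cohort!r}")
    a = spec_case.counts[band]
    c = spec_ctrl.counts[band]
    table = ContingencyTable2x2(
        a=a, b=spec_case.denominator - a, c=c, d=spec_ctrl.denominator - c
    )
    return enrichment_test(table, cfg, stratum=f"band:{band}")


def mband_carrier_summary(cohort: CohortTable) -> tuple[int, int, int]:
    """Carriers with at least one M-band variant among all carriers.

    Returns (M-band carriers, carriers total, whole percent). Band
    annotations must already be present on the records.
    """
    carriers = set(cohort.subjects())
    if not carriers:
        return 0, 0, 0
    m_carriers = {r.subject_id for r in cohort if r.band == "M-band"}
    percent = round(100.0 * len(m_carriers) / len(carriers))
    return len(m_carriers), len(carriers), int(percent)
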