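"""Seeded generators for synthetic cohorts, reference panels and trios.

The defaults emulate the structure of the packaged case series: a 35-proband
cohort with carrier fraction 0.34, heterozygous singleton missense variants
(a small fraction of carriers get a second variant), per-panel frequencies
that are exactly 0 for about half the variants and otherwise uniform across
the rare range straddling the 0.0005/0.0001 cut-offs, consensus-damaging
predictor calls, band placement mildly A/I-balanced with an M-band excess,
and panel variant-allele rates of ~10% / ~4% at the loose / strict stratum.

Each generator draws from its own pseudo-random stream derived from the
master seed by a fixed label, so adding a generator never perturbs the
outputs of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .fixtures import ttn_domain_map
from .model import (
    CohortTable,
    DomainMap,
    PopulationReference,
    PredictionSet,
    VariantRecord,
)

__all__ = ["SimulationParams", "simulate_cohort", "simulate_reference", "simulate_trio"]

_BASES = ("A", "C", "G", "T")
# stream labels: fixed, never reordered
_COHORT_STREAM = 101
_REFERENCE_STREAM = 211
_TRIO_STREAM = 307

# arbitrary anchor for synthetic genomic coordinates (minus-strand layout,
# mirroring a gene whose cDNA runs against the genomic axis)
_GENOMIC_ANCHOR = 179_700_000


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic generators; defaults mirror the packaged study."""

    n_probands: int = 35
    carrier_fraction: float = 0.34
    gene_panel: tuple[str, ...] = ("TTN",)
    second_variant_fraction: float = 1 / 12
    maf_spike_at_zero: float = 7 / 13
    rare_maf_range: tuple[float, float] = (1e-5, 5e-4)
    predictor_damaging_rate: float = 1.0
    band_weights: Mapping[str, float] = field(
        default_factory=lambda: {"Z-disk": 1.0, "I-band": 5.0, "A-band": 5.0, "M-band": 2.0}
    )
    reference_total_alleles: int = 13006
    reference_variant_rate_by_stratum: Mapping[float, float] = field(
        default_factory=lambda: {0.0005: 0.10, 0.0001: 0.04}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probands < 1:
            raise ValueError("n_probands must be positive")
        if not self.gene_panel:
            raise ValueError("gene_panel must not be empty")
        for name in ("carrier_fraction", "second_variant_fraction", "maf_spike_at_zero",
                     "predictor_damaging_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        lo, hi = self.rare_maf_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError(f"rare_maf_range must be ordered within [0,1], got {self.rare_maf_range}")
        weights = list(self.band_weights.values())
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ValueError("band_weights must be non-negative with positive sum")
        for cutoff, rate in self.reference_variant_rate_by_stratum.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"reference rate at cutoff {cutoff} out of [0,1]: {rate}")


def _stream(p: SimulationParams, label: int) -> np.random.Generator:
    return np.random.default_rng([label, p.seed])


def _draw_predictions(rng: np.random.Generator, damaging_rate: float) -> PredictionSet:
    # consensus structure: either the full damaging consensus holds, or one
    # randomly chosen leg of the rule fails
    if rng.random() < damaging_rate:
        return PredictionSet.all_damaging()
    broken = rng.integers(0, 3)
    calls = {"sift": "damaging", "mutation_taster": "damaging",
             "polyphen_hvar": "damaging", "polyphen_hdiv": "damaging"}
    if broken == 0:
        calls["sift"] = "tolerated"
    elif broken == 1:
        calls["mutation_taster"] = "benign"
    else:
        calls["polyphen_hvar"] = calls["polyphen_hdiv"] = "benign"
    return PredictionSet(**calls)


def simulate_cohort(p: SimulationParams, dm: DomainMap | None = None) -> CohortTable:
    """Draw a synthetic case series, fully reproducible from ``p.seed``.

    Carriers are independent coin flips at ``carrier_fraction``; each carrier
    receives one heterozygous variant (two with probability
    ``second_variant_fraction``) placed in a band drawn by ``band_weights``
    and uniformly within the band's residue interval.
    """
    if dm is None:
        dm = ttn_domain_map()
    rng = _stream(p, _COHORT_STREAM)
    bands = [b for b in dm.bands if b[0] in p.band_weights]
    if not bands:
        raise ValueError("band_weights name no band of the domain map")
    weights = np.array([p.band_weights[label] for label, _, _ in bands], dtype=float)
    weights /= weights.sum()

    records: list[VariantRecord] = []
    for i in range(p.n_probands):
        if rng.random() >= p.carrier_fraction:
            continue
        subject = f"SIM{i:04d}"
        n_variants = 2 if rng.random() < p.second_variant_fraction else 1
        used_g: set[int] = set()
        for _ in range(n_variants):
            while True:
                band_idx = rng.choice(len(bands), p=weights)
                label, start, end = bands[band_idx]
                residue = int(rng.integers(start, end + 1))
                codon_pos = int(rng.integers(1, 4))
                c_pos = 3 * (residue - 1) + codon_pos
                g_pos = _GENOMIC_ANCHOR - (c_pos - 1)
                if g_pos not in used_g:
                    used_g.add(g_pos)
                    break
            ref, alt = rng.choice(len(_BASES), size=2, replace=False)
            freq = 0.0 if rng.random() < p.maf_spike_at_zero else float(
                rng.uniform(*p.rare_maf_range)
            )
            records.append(
                VariantRecord(
                    subject_id=subject,
                    gene=str(rng.choice(p.gene_panel)),
                    chrom="chrS",
                    g_pos=g_pos,
                    c_pos=c_pos,
                    ref_allele=_BASES[ref],
                    alt_allele=_BASES[alt],
                    p_residue=residue,
                    band=label,
                    maf={"exac": freq},
                    predictions=_draw_predictions(rng, p.predictor_damaging_rate),
                    zygosity="het",
                )
            )
    return CohortTable(f"sim-cohort-seed{p.seed}", p.n_probands, records)


def simulate_reference(p: SimulationParams) -> PopulationReference:
    """Draw a synthetic panel: binomial stratum counts, monotone by construction.

    The loosest stratum is drawn as Binomial(total, rate); each stricter
    stratum resamples from the looser stratum's count with the conditional
    rate ratio, so counts can never increase as the cut-off tightens.
    """
    rng = _stream(p, _REFERENCE_STREAM)
    cutoffs = sorted(p.reference_variant_rate_by_stratum, reverse=True)
    counts: dict[float, int] = {}
    prev_count = None
    prev_rate = None
    for cutoff in cutoffs:
        rate = p.reference_variant_rate_by_stratum[cutoff]
        if prev_count is None:
            counts[cutoff] = int(rng.binomial(p.reference_total_alleles, rate))
        else:
            ratio = 0.0 if prev_rate == 0 else min(1.0, rate / prev_rate)
            counts[cutoff] = int(rng.binomial(prev_count, ratio))
        prev_count, prev_rate = counts[cutoff], rate
    return PopulationReference(
        name=f"sim-ref-seed{p.seed}",
        total_alleles=p.reference_total_alleles,
        variant_alleles_by_stratum=counts,
    )


def simulate_trio(
    p: SimulationParams,
    proband_genotype: str = "het",
    transmission: str = "paternal_affected",
) -> tuple[str, tuple[str, bool], tuple[str, bool]]:
    """Parental genotypes/statuses consistent with a declared transmission mode.

    Returns ``(proband, (father_gt, father_affected), (mother_gt,
    mother_affected))`` suitable for
    :func:`ttnburden.filtration.check_trio_segregation`.
    """
    if proband_genotype not in ("wildtype", "het", "hom"):
        raise ValueError(f"bad proband genotype {proband_genotype!r}")
    modes = {
        "paternal_affected": (("het", True), ("wildtype", False)),
        "maternal": (("wildtype", False), ("het", True)),
        "de_novo": (("wildtype", False), ("wildtype", False)),
    }
    try:
        father, mother = modes[transmission]
    except KeyError:
        raise ValueError(f"unknown transmission mode {transmission!r}") from None
    return proband_genotype, father, mother
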