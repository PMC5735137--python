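"""Packaged study fixtures: the published BRRS *TTN* variant table, the
population-panel allele counts, a reconstructed TITIN domain map and a toy
transcript model.

The variant table transcribes the 13 germline *TTN* missense variants
reported in 12 of 35 unrelated *PTEN*-wildtype classic-BRRS probands
(heterozygous singletons; one proband carries two variants). The panel
counts are the qualifying *TTN* variant alleles in 1000 Genomes,
NHLBI-ESP6500 and ExAC at the two MAF strata, with total-allele denominators
5008 / 13006 / 106210 back-computed from the published counts and percents.

The domain map's Z/I/A boundaries are a synthetic reconstruction (they are
not published); they are chosen to be consistent with every published band
label and with the titin-kinase span, residues 33819-34073 of the IC
isoform, which is exact.
"""

from __future__ import annotations

from importlib.resources import as_file, files

from .filtration import DISCOVERY_POLICY, RARE_SET_POLICY, MafPolicy
from .io import (
    read_domain_map,
    read_reference_panels,
    read_transcript_model,
    read_variant_table,
)
from .model import CohortTable, DomainMap, PopulationReference, TranscriptModel

__all__ = [
    "GENE",
    "STRATA",
    "STUDY_POLICIES",
    "CLASSIC_BRRS_SIZE",
    "BRRS_LIKE_CARRIERS",
    "INTERNAL_CONTROL_CARRIERS",
    "brrs_cohort",
    "reference_panels",
    "ttn_domain_map",
    "toy_transcript",
]

GENE = "TTN"

#: The two MAF strata of the allele-level analysis.
STRATA: tuple[float, float] = (0.0005, 0.0001)

#: Per-stratum aggregation rules that reproduce the published qualifying
#: counts (12 variants at 0.0005, 9 at 0.0001). See the methods note.
STUDY_POLICIES: dict[float, MafPolicy] = {
    0.0005: DISCOVERY_POLICY,
    0.0001: RARE_SET_POLICY,
}

#: Cohort sizes and carrier counts of the patient-level comparisons:
#: classic BRRS (12/35), BRRS-like/CS/CS-like (37/231), and the non-BRRS
#: internal-control exome series (6/45).
CLASSIC_BRRS_SIZE = 35
BRRS_LIKE_CARRIERS = (37, 231)
INTERNAL_CONTROL_CARRIERS = (6, 45)

_DATA = files("ttnburden.data")


def brrs_cohort() -> CohortTable:
    """The classic-BRRS case series: 13 records from 12 of 35 probands."""
    with as_file(_DATA / "brrs_ttn_variants.tsv") as path:
        return read_variant_table(path, name="classic-BRRS", n_probands=CLASSIC_BRRS_SIZE)


def reference_panels() -> list[PopulationReference]:
    """1000G, ESP6500 and ExAC qualifying-allele counts at both strata."""
    with as_file(_DATA / "reference_panels.json") as path:
        return read_reference_panels(path)


def ttn_domain_map() -> DomainMap:
    """TITIN band map (Z/I/A boundaries reconstructed; TK span exact)."""
    with as_file(_DATA / "ttn_domain_map.json") as path:
        return read_domain_map(path)


def toy_transcript() -> TranscriptModel:
    """Small synthetic minus-strand 3-exon model for mapping examples."""
    with as_file(_DATA / "toy_transcript.bed") as path:
        return read_transcript_model(path)
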