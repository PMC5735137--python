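# Methods

## Statistical model

All enrichment questions are reduced to 2×2 tables. For a table
(a, b / c, d) with rows "cases / comparison group" and columns
"exposed / unexposed" (exposure = carrying a qualifying variant, or one
variant allele), inference conditions on all margins: the count `a` then
follows Fisher's noncentral hypergeometric distribution with odds
parameter ψ,

P<sub>ψ</sub>(X = k) ∝ C(n₁, k) · C(n₂, m − k) · ψᵏ over the support
max(0, m − n₂) ≤ k ≤ min(n₁, m), with n₁ = a + b, n₂ = c + d, m = a + c.

The package reports, per table:

- **Cross-product OR** ad/bc, with boundary conventions: 0 when ad = 0,
  +∞ (rendered "∞") when bc = 0, and an `UndefinedOddsRatioError` for 0/0.
- **Conditional-MLE OR**: the ψ solving E<sub>ψ</sub>[X] = a. The
  conditional mean is strictly increasing in ψ, so the root is found by
  bisection on log ψ; a count at a support boundary maps to 0 or +∞.
- **Mid-p exact test**: one-sided tails P(X > a) + ½·P(X = a) and
  P(X < a) + ½·P(X = a) under ψ = 1; the two-sided value doubles the
  smaller tail and caps at 1. This is the convention of the common
  epidemiological exact calculators and reproduces every published p-value
  of the packaged study; a minimum-likelihood two-sided rule is available
  behind `ExactConfig(sidedness="two_sided_minlike")` but is not the
  default. Fisher's exact test (observed mass counted fully in each tail)
  is reported alongside; mid-p ≤ Fisher p always.
- **Mid-p exact CI**: the lower bound solves
  P<sub>ψ</sub>(X > a) + ½·P<sub>ψ</sub>(X = a) = (1 − level)/2, the upper
  bound the mirror equation on the lower tail. Both tails are monotone in
  ψ. Counts at a support boundary leave the corresponding bound open
  (0 or +∞), as in the empty rare 1000-Genomes stratum. Woolf's
  exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d)) interval is provided for tables
  with no zero cell as an asymptotic cross-check.

### Numerical choices

- The pmf is computed in log space with log-gamma factorials and
  normalised over the support with log-sum-exp, so panel-scale cells
  (~10⁶) neither overflow nor lose the tails. Normalisation is exact to
  ≈1e-12 for small margins and to a few times that at ExAC-scale margins
  (log-gamma rounding).
- Root finding uses plain bisection on log ψ within the bracket
  (1e-8, 1e8) to a log-width tolerance of 1e-8; bisection is slower than
  Brent but guaranteed on these monotone tails, and each CI costs ~60
  pmf evaluations.
- "More extreme" is defined on the count `a` with margins fixed; ties in
  the minimum-likelihood rule use a 1 + 1e-12 relative slack.

## Qualifying-variant selection

A record's per-panel frequencies collapse to a single number under a
`MafPolicy` and pass the filter when ≤ the cut-off (boundary inclusive).
Two strata are analysed: 0.0005 (the discovery cut-off) and 0.0001
(private, singleton-like variants).

- At 0.0005 the **discovery policy** (maximum over all panels) retains 12
  of the 13 packaged case variants — p.E11286K is excluded by its ExAC
  frequency 0.0005749; this reproduces the published 12-allele case cell.
- At 0.0001 no simple published rule yields the 9-variant rare set that
  the published odds ratios and the 11.1% Z-disk share imply: max-over-
  panels gives 8 (the two ESP-frequency variants p.V30830I and p.A9773T
  both fall), single-panel ExAC at 1e-4 gives 10. The packaged
  **rare-set policy** is single-panel ExAC with an auxiliary threshold of
  5e-5 (effective cut-off min(1e-4, 5e-5)), which drops exactly p.A9773T
  (ExAC 5.797e-5) and keeps p.V30830I (ExAC 2.49e-5), yielding the
  9-record set including the Z-disk variant p.R713Q. This is a documented
  reconstruction, shipped as the named `RARE_SET_POLICY` and fully
  overridable; nothing in the pipeline hard-codes it.

The predictor consensus (SIFT damaging AND MutationTaster damaging AND
PolyPhen-2 HVAR and/or HDIV damaging, missing = not damaging) is applied
to annotations carried on the records; the predictors themselves are never
re-implemented, and the ΔΔG stability annotation is pass-through only.

Case exposure at the allele level counts one allele per heterozygous
record and two per homozygous record over the 2·n_probands denominator;
all packaged study variants are heterozygous singletons, so there the two
conventions coincide.

## Coordinates and bands

The transcript model is an ordered list of 1-based inclusive exon
intervals; cumulative exon lengths define a bijection between covered
genomic positions and cDNA positions, order-reversing on the minus strand.
`cds_offset` (default 1, CDS-only models) aligns transcript coordinates
with HGVS c. numbering, so residue = ⌊(c−1)/3⌋+1 and codon position =
(c−1) mod 3 + 1. cDNA-sense alleles on minus-strand transcripts are the
reverse complement of the genomic alleles.

The packaged TITIN band map places Z-disk at residues 1–2200, I-band
2201–14200, A-band 14201–33818 and M-band 33819–35991 (IC-isoform
numbering). Only the titin-kinase span (33819–34073, inside the M-band) is
an exactly published boundary; the Z/I and I/A and A/M boundaries are a
**reconstruction** chosen to be consistent with all 13 published
(residue, band) pairs, and are configuration, not code. Exon numbers of a
real transcript cannot be verified without the full 363-exon model, which
is deliberately not bundled; a user-supplied BED12 model slots in.

## Trio segregation

A dominant single-variant model: a heterozygous proband with exactly one
carrier parent segregates consistently when that parent is affected and
the other (non-carrier) parent is not; an unaffected carrier parent, an
affected non-carrier parent, or two wildtype parents (de novo /
Mendelian violation) are inconsistent; unknown statuses or two carrier
parents are uninformative. Homozygous probands require both parents to
carry.

## Synthetic data

`SimulationParams` defaults encode the study conditions: 35 probands,
carrier fraction 0.34, one heterozygous variant per carrier with a 1/12
chance of a second (mirroring the one double-carrier proband), panel
frequency exactly 0 with probability 7/13 (the fraction of case variants
absent from all panels) and otherwise uniform on (1e-5, 5e-4) straddling
both cut-offs, all-damaging predictor consensus, band weights 1/5/5/2
(Z/I/A/M, the observed case spectrum), and a 13006-allele reference panel
with stratum rates 0.10/0.04 (the published mean control frequencies).
Each generator owns a pseudo-random stream derived from the master seed by
a fixed label, so outputs are byte-reproducible and adding a generator
never perturbs existing ones. Reference strata are monotone by
construction (the stricter stratum resamples binomially from the looser
count).

The generator emulates the *statistical* structure only: no linkage or
haplotype structure, no sequencing error, no relatedness or ancestry
stratification, no realistic per-gene mutability. Passing recovery tests
on synthetic cohorts therefore demonstrates correctness of the inference
machinery under the stated sampling model, not robustness to the
confounders of real cohort data (batch effects, coverage differences
between case and panel sequencing, population structure — none of which
the underlying study design corrects either).

## Calibration checks and problem sizes

The test suite verifies, against scipy's central/noncentral hypergeometric
distributions as independent oracles: exact agreement of Fisher/mid-p
tails with enumeration for all row margins ≤ 30 (public functions
exhaustively for margins ≤ 12), mid-p ≤ Fisher dominance, CI inversion
consistency to 10× the root tolerance, a null (ψ = 1) two-sided mid-p
rejection rate of 3–7% at α = 0.05 over 2,000 seeded tables on the
carrier-table margins (n₁ = 35, n₂ = 231, m = 49), and 93–97% coverage of
ψ = 3 by the 95% mid-p CI over 2,000 seeded replicates on the same
margins. Signal-recovery tests use 300 replicates per odds-ratio level and
500 for median-OR recovery; these sizes keep the full suite in the
low minutes on one CPU while leaving Monte-Carlo error well inside the
asserted bands.

## Known limitations

- The pooled "all panels collectively" odds ratio of the underlying study
  (2.2) is not reproduced: no single pooled 2×2 of the published counts
  yields it, and its construction is ambiguous, so it is excluded.
- Band-spectrum enrichment against population controls requires
  user-supplied control spectra; the published control band counts are not
  available, so only the case-side spectrum quantities are reproduced.
- Only single-nucleotide substitutions are handled (no indels,
  multi-allelics, splice-isoform inference or liftover). VCF ingestion is
  not implemented; the TSV dialect is the ingestion path.
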