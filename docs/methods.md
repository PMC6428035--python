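# Methods

## Scope and model

`pgxtriage` consumes *annotated* variants: effect and impact classes
(snpEff-style), reference-population allele frequency (gnomAD), four
precomputed in-silico predictor calls (SIFT, PolyPhen-2, MutationTaster,
MetaSVM), CADD Phred and GERP++ RS scores, ClinVar significance codes, and
per-site depth/quality. Alignment, variant calling and annotation itself are
out of scope — the pipeline starts where an exome annotation pipeline ends.
The unit of analysis is one alternate allele at one site; multi-allelic VCF
lines are split per alt, with het/hom carrier counts recomputed per allele
(a 1/2 genotype is heterozygous for both alts) and alleles normalized by
trimming shared suffix then prefix before keying.

## Filtering and classification rules

**Site QC.** A record is kept iff depth ≥ `min_depth` (default 20) *and*
quality ≥ `min_quality` (default 300). The conjunctive reading is the
conservative QC convention; both thresholds are configurable. Depth is the
site-level INFO/DP value, not a per-sample mean.

**Panel restriction.** Case-insensitive exact match of the gene symbol
against a plain-text symbol list. A ~40-gene fixture panel is bundled;
production panels (hundreds of pharmacogenes) are user-supplied.

**Rarity.** `gnomad_af ≤ 0.01` (absence from gnomAD counts as rare — missing
annotations never become zeros) AND `het ≤ 19` AND `hom ≤ 15` cohort
carriers. The carrier bounds are the 1%-of-cohort convention at N = 1904;
they are parameters (`RarityThresholds`), not constants. Note the boundary
semantics: *more than* 19/15 carriers excludes, so 19 het/15 hom is still
rare. Global, not population-specific, reference frequency is used.

**Consensus pathogenic missense.** Missense effect AND all four predictors
damaging AND CADD Phred strictly > 20. Predictor output tokens are
harmonized (D/deleterious/probably\_damaging/disease\_causing/A → damaging;
T/benign/polymorphism/N → tolerated; anything else → unknown); an unknown
call breaks the consensus, and CADD = 20.0 fails the strict cutoff.

**Protein truncation.** Effect ∈ {frameshift, stop gain, stop lost, start
lost, splice acceptor, splice donor} — equivalently HIGH impact.
`splice_region` deliberately does not qualify: it is tabulated as its own
category, consistent with the HIGH-impact count decomposing into
frameshift + stop + essential-splice classes.

**Novelty.** Exclusive categories with fixed precedence gnomAD → dbSNP →
ClinVar → novel, so they partition any variant set. The cascade matrix also
reports the *non-exclusive* membership columns (a variant can be in all
three databases), because published cascade tables overlap; the `novel`
column is always the exclusive remainder.

**Gene superfamilies.** Symbol-prefix match: CYP, ABC, SLC (which also
captures SLCO solute-carrier organic-anion transporters), UGT, else other.

## Frequencies

Cohort alt-allele frequency is `(het + 2·hom) / (2N)` with N the fixed
cohort size: missing genotypes count as homozygous reference and hemizygous
calls as homozygous alternate, so every sample contributes two alleles. This
fixed-denominator convention makes published 3-significant-figure
frequencies exactly recoverable from integer carrier counts. Frequencies are
*not* folded to ≤ 0.5 — for several pharmacogenetic alleles the alternate is
the major allele (cohort frequencies up to ~88% occur) and folding would
destroy the reported quantity. Arithmetic is exact-rational
(`fractions.Fraction`) until the reporting boundary: 3 significant figures
for frequencies, integer percent (half-up) for carrier fractions in
narrative output. Cohort-vs-reference comparison reports the absolute
difference and ratio and flags |Δ| > 0.03 by default, the scale at which
national cohorts visibly diverge from worldwide aggregates; the flag
threshold is configurable and the check is symmetric under swapping the two
frequencies. Intronic variants from exome capture carry unreliable cohort
frequencies (poor coverage); no correction is applied — they are simply
subject to the same QC depth filter.

Per-gene CADD summaries take the median Phred score over scored variants
only, separately for rare and common strata; an even-length stratum takes
the midpoint mean, and an unscored stratum has an absent (not zero) median.

## Knowledge base

A minimal two-table TSV schema (clinical annotations: rsid, gene, level,
semicolon-separated drugs, association type; star alleles: gene, allele
name, semicolon-separated defining rsIDs, function class) is used instead of
the live PharmGKB export format, which changes between releases; a converter
maps the export's columns onto the schema. Evidence levels are the PharmGKB
tokens {1A, 1B, 2A, 2B, 3, 4}; anything else is a format error. Star alleles
defined by multiple variants (TPMT \*3A = \*3B + \*3C) keep all defining
rsIDs; because cohort data are unphased, a variant belonging to such an
allele is reported as "potentially encoding" it, never as a diplotype call.
Unknown (gene, allele) lookups raise rather than returning an empty list, so
an unresolvable allele cannot be mistaken for one defined by no variants.

## Synthetic data

`generate_cohort` draws genotypes i.i.d. per sample and per site under
Hardy–Weinberg proportions at each variant's true allele frequency — no
linkage disequilibrium, relatedness or population structure, which is
adequate because every triage decision is single-site. The default cohort
spec emulates an exome pharmacogene screen: 90% of variants with true
frequency below 1% (log-uniform 10⁻⁴–10⁻²), a non-coding-dominated effect
spectrum, and damaging annotations enriched in the rare missense tail.
`generate_rare_spectrum` instead fixes the triage class per variant by
construction (consensus missense / truncating / neutral, novel or known)
for exact truth-recovery tests; its carrier counts are Hardy–Weinberg draws
conditioned on staying below the rarity thresholds so the "rare" label is
deterministic, and CADD is drawn on (20, 50] for deleterious vs [0, 15] for
neutral classes — the gap keeps labels away from the decision boundary.
What passing these tests shows is that the *classification logic* is exact
and the *frequency estimator* is unbiased under HWE sampling; it does not
validate annotation quality, capture-platform coverage differences, or any
real-data artefact upstream of annotation.

The bundled fixture is packaged data, not simulation: 24 actionable
level-1A/1B variants with published integer carrier counts over N = 1904,
plus matching clinical-annotation and star-allele tables. Its genomic
coordinates are synthetic placeholders (true chromosome per gene, dummy
positions) because the source table is keyed by rsID; all downstream joins
use rsIDs. One fixture row (CFTR Asp1152His, rs75541969) carries a published
frequency of 0.000526 that is arithmetically inconsistent with its own
carrier counts under the fixed-denominator convention (2/3808 = 0.000525);
it is consistent with a per-site called-allele denominator a few samples
short of 2N, which cannot be reconstructed from printed counts. The fixture
stores the published value verbatim and the corresponding acceptance check
documents the one-digit discrepancy rather than adjusting either side.

All randomness flows through a single explicitly passed
`numpy.random.Generator`; fixed seeds give byte-identical output files.

## Determinism and numerics

Report tables carry no timestamps and are written with fixed column orders
and stable sort keys (actionable tiers before moderate tiers, then
descending cohort frequency, then gene, then rsID), so identical inputs
produce byte-identical TSVs. Significant-figure rounding uses the platform's
correctly-rounded `%g` formatting of IEEE doubles. VCF float fields
round-trip at float32 precision (an htslib property), which is why
equality checks on frequencies read back from VCF use a 10⁻⁵ relative
tolerance rather than exact comparison.

## Problem sizes in the validation suite

The statistical acceptance checks run at deliberately moderate sizes chosen
to give tight binomial error bars while keeping the suite quick: frequency
recovery uses 200 replicate variants at each of five true frequencies
(0.001–0.5) over 1904 samples, with a three-standard-error bound on the mean
of each cell; truth-label recovery uses 200-variant spectra across ten
seeds; cascade tabulation is checked against an independent brute-force
tally on 100 random lists of up to 1000 variants.

## Known limitations

No diplotype or phase calling, no compound-heterozygote detection, no CNV
or structural variation, no dosing-guideline logic, no per-patient
reporting: the pipeline is cohort-level and de-identified by design.
Highly homologous loci (several CYP genes) are only as reliable as the
upstream alignment and caller. The rarity rule depends on the reference
database snapshot used for annotation; counts are reproducible only against
the same annotation inputs.
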