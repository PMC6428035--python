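"""Compare cohort allele frequencies against the reference population.

For each bundled actionable variant, computes the cohort alt-allele frequency
(het + 2*hom)/(2*1904) and flags variants whose frequency differs from the
gnomAD reference by more than 0.03 — the scale at which population-specific
databases visibly diverge from worldwide aggregates.
"""

from pgxtriage import FrequencyRecord, compare_to_reference, actionable_fixture
from pgxtriage.popfreq import het_hom_fractions, percent, round_sig

fixture = actionable_fixture()
print(f"{'rsid':<12} {'gene':<9} {'MAF_cohort':>10} {'MAF_ref':>8} {'diff':>7}  flagged")
for variant, summary in fixture.records:
    record = FrequencyRecord.from_summary(summary, maf_reference=variant.gnomad_af)
    disc = compare_to_reference(record)
    if disc is None:
        continue  # not in the reference database
    if disc.flagged:
        print(
            f"{variant.rsid:<12} {variant.gene:<9} {round_sig(record.maf_cohort):>10g} "
            f"{variant.gnomad_af:>8g} {disc.abs_difference:>7.3f}  yes"
        )

s = next(s for v, s in fixture.records if v.rsid == "rs4149056")
het_frac, hom_frac = het_hom_fractions(s)
print(
    f"\nrs4149056 carriers: {s.het_count}/1904 ({percent(het_frac)}%) heterozygous, "
    f"{s.hom_count}/1904 ({percent(hom_frac)}%) homozygous"
)
# flagged rows mark cohort-specific frequency departures; the carrier line
# shows the narrative integer-percent rendering used in clinical summaries
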