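"""Build the actionable-variant report from the bundled cohort fixture.

Loads the 24 level-1A/1B pharmacogenetic variants with their published carrier
counts over 1904 samples, triages them against the bundled knowledge base,
and prints the report: one row per variant per evidence block, sorted by
descending cohort allele frequency.
"""

from pgxtriage import (
    FrequencyRecord,
    build_actionable_report,
    count_actionable_rsids,
    actionable_fixture,
    triage_variant,
)

fixture = actionable_fixture()
triaged = [(triage_variant(v, s, kb=fixture.kb), v) for v, s in fixture.records]
frequencies = {
    v.key: FrequencyRecord.from_summary(s, maf_reference=v.gnomad_af)
    for v, s in fixture.records
}
report = build_actionable_report(triaged, frequencies, fixture.kb)

print(f"{'gene':<9} {'star':<6} {'rsid':<12} {'MAF_ref':>8} {'MAF_cohort':>10}  level  drugs")
for row in report[:8]:
    ref = "." if row.maf_reference is None else f"{row.maf_reference:g}"
    print(
        f"{row.gene:<9} {row.star_allele or '.':<6} {row.rsid:<12} "
        f"{ref:>8} {row.maf_cohort:>10g}  {row.level:<5}  {', '.join(row.drugs)}"
    )
print(f"... {len(report)} rows total")
print(f"distinct actionable (1A/1B) variants: {count_actionable_rsids(report)}")
print(f"rare under the 1% thresholds:          {sum(r.is_rare for r, _ in triaged)}")
# MAF_cohort is the alt-allele frequency (het + 2*hom)/(2*1904); a variant
# appears twice when it carries separate 1A and 1B drug blocks.
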