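"""Render the analysis products as fixed-layout TSV tables.

Outputs are deliberately plain tidy tables (no graphics, no timestamps in
data files) so that runs on identical input are byte-identical:

* ``actionable_report.tsv`` — one row per actionable variant per evidence
  block (gene, star allele, variant type, HGVS, rsID, reference and cohort
  frequencies, carrier counts, level, drugs);
* ``cascade.tsv`` — the category-by-membership count matrix;
* ``gene_groups.tsv`` — rare-variant counts per gene superfamily and gene;
* ``gene_cadd.tsv`` — per-gene median CADD for rare vs common variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .knowledgebase import ACTIONABLE_LEVELS, KnowledgeBase
from .popfreq import FrequencyRecord, round_sig
from .triage import CASCADE_CATEGORIES, CASCADE_COLUMNS, CascadeCounts, TriageResult

REPORT_COLUMNS = [
    "gene",
    "star_allele",
    "variant_type",
    "hgvs_c",
    "protein_effect",
    "rsid",
    "maf_reference",
    "het_count",
    "maf_cohort",
    "hom_count",
    "level",
    "drugs",
]


@dataclass(frozen=True)
class ActionableReportRow:
    gene: str
    star_allele: Optional[str]
    variant_type: str
    hgvs_c: Optional[str]
    protein_effect: Optional[str]
    rsid: Optional[str]
    maf_reference: Optional[float]
    het_count: int
    maf_cohort: float
    hom_count: int
    level: str
    drugs: tuple


def build_actionable_report(
    triaged: list, frequencies: dict, kb: KnowledgeBase
) -> list:
    """Assemble the actionable-variant report.

    ``triaged`` is a list of ``(TriageResult, AnnotatedVariant)`` pairs;
    ``frequencies`` maps variant key -> :class:`FrequencyRecord`. A variant
    appears once per (level, drugs) evidence block, the layout used when one
    allele carries, say, a 1A block and a separate 1B drug. Variants with
    neither a PharmGKB tier nor the ClinVar drug-response code are omitted.
    Rows sort actionable tiers (1A/1B) before 2A/2B, then by descending
    cohort frequency, then gene, then rsID.
    """
    rows = []
    for result, variant in triaged:
        if not result.actionability and not result.clinvar_drug_response:
            continue
        freq = frequencies.get(result.variant_key)
        if freq is None:
            raise ValueError(f"no frequency record for actionable variant {result.variant_key}")
        blocks = sorted(result.actionability)
        if not blocks:  # ClinVar drug-response only: no PharmGKB tier to cite
            blocks = [("ClinVar:drug_response", ())]
        star = kb.star_allele_of(variant.gene, variant.rsid) if variant.rsid else None
        for level, drugs in blocks:
            rows.append(
                ActionableReportRow(
                    gene=variant.gene,
                    star_allele=star,
                    variant_type=variant.effect.value,
                    hgvs_c=variant.hgvs_c,
                    protein_effect=variant.hgvs_p,
                    rsid=variant.rsid,
                    maf_reference=variant.gnomad_af,
                    het_count=freq.het_count,
                    maf_cohort=round_sig(freq.maf_cohort, 3),
                    hom_count=freq.hom_count,
                    level=level,
                    drugs=drugs,
                )
            )

    def sort_key(row: ActionableReportRow):
        tier = 0 if row.level in ACTIONABLE_LEVELS else 1
        return (tier, -row.maf_cohort, row.gene, row.rsid or "", row.level)

    return sorted(rows, key=sort_key)


def count_actionable_rsids(report: list) -> int:
    """Distinct rsIDs carrying a level-1A or -1B block in the report."""
    return len({r.rsid for r in report if r.level in ACTIONABLE_LEVELS})


def _report_frame(report: list) -> pd.DataFrame:
    rows = []
    for r in report:
        rows.append(
            {
                "gene": r.gene,
                "star_allele": r.star_allele or ".",
                "variant_type": r.variant_type,
                "hgvs_c": r.hgvs_c or ".",
                "protein_effect": r.protein_effect or ".",
                "rsid": r.rsid or ".",
                "maf_reference": "." if r.maf_reference is None else f"{r.maf_reference:g}",
                "het_count": r.het_count,
                "maf_cohort": f"{r.maf_cohort:g}",
                "hom_count": r.hom_count,
                "level": r.level,
                "drugs": "; ".join(r.drugs) if r.drugs else ".",
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def gene_group_table(triaged: list) -> pd.DataFrame:
    """Rare-variant counts by gene superfamily and gene (tidy table)."""
    tally: dict[tuple, int] = {}
    for result, variant in triaged:
        if not result.is_rare:
            continue
        key = (result.gene_group.value, variant.gene)
        tally[key] = tally.get(key, 0) + 1
    rows = [
        {"gene_group": group, "gene": gene, "n_rare": n}
        for (group, gene), n in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["gene_group", "gene", "n_rare"])


def cascade_frame(cascade: CascadeCounts) -> pd.DataFrame:
    rows = []
    for key, label in CASCADE_CATEGORIES:
        row = {"category": label}
        row.update({col: cascade[(key, col)] for col in CASCADE_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows, columns=["category", *CASCADE_COLUMNS])


def gene_cadd_frame(summaries: list) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene,
            "median_cadd_rare": "." if s.median_cadd_rare is None else f"{s.median_cadd_rare:g}",
            "median_cadd_common": "." if s.median_cadd_common is None else f"{s.median_cadd_common:g}",
            "n_rare": s.n_rare,
            "n_common": s.n_common,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows, columns=["gene", "median_cadd_rare", "median_cadd_common", "n_rare", "n_common"]
    )


def write_tables(
    report: list,
    cascade: Optional[CascadeCounts],
    gene_summaries: Optional[list],
    out_dir,
    triaged: Optional[list] = None,
) -> dict:
    """Write the report tables under ``out_dir``; returns name -> path.

    Output is deterministic: identical inputs give byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}") from exc
    paths = {}
    frame_by_name = {"actionable_report.tsv": _report_frame(report)}
    if cascade is not None:
        frame_by_name["cascade.tsv"] = cascade_frame(cascade)
    if gene_summaries is not None:
        frame_by_name["gene_cadd.tsv"] = gene_cadd_frame(gene_summaries)
    if triaged is not None:
        frame_by_name["gene_groups.tsv"] = gene_group_table(triaged)
    for name, frame in frame_by_name.items():
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
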