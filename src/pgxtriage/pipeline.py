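"""End-to-end convenience driver: ingest -> QC -> panel -> triage -> report.

Deterministic: the same input files always produce byte-identical output
TSVs (run metadata goes to the logger, never into data files).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

from . import popfreq, report, variant_io
from .knowledgebase import KnowledgeBase
from .triage import RarityThresholds, cascade_counts, triage_variant


def run_pipeline(
    variants_path,
    kb: KnowledgeBase,
    out_dir,
    panel: Optional[Iterable[str]] = None,
    min_depth: int = 20,
    min_quality: float = 300.0,
    thresholds: RarityThresholds = RarityThresholds(),
    format: Optional[str] = None,
) -> dict:
    """Run the full triage pipeline on a VCF/TSV and write the report tables.

    Returns a dict with the triage results, cascade matrix, frequency
    records and written file paths.
    """
    records = variant_io.read_annotated_variants(variants_path, format=format)
    records = variant_io.apply_quality_filter(records, min_depth, min_quality)
    if panel is not None:
        records = variant_io.restrict_to_panel(records, panel)
    if not records:
        raise ValueError(f"no variants left after filtering {variants_path}")

    triaged = [(triage_variant(v, s, thresholds, kb), v) for v, s in records]
    frequencies = {
        v.key: popfreq.FrequencyRecord.from_summary(s, maf_reference=v.gnomad_af)
        for v, s in records
    }
    cascade = cascade_counts(triaged)
    gene_cadd = popfreq.median_cadd_by_gene([(v, r.is_rare) for r, v in triaged])
    actionable = report.build_actionable_report(triaged, frequencies, kb)
    paths = report.write_tables(actionable, cascade, gene_cadd, Path(out_dir), triaged=triaged)
    return {
        "records": records,
        "triaged": triaged,
        "frequencies": frequencies,
        "cascade": cascade,
        "gene_cadd": gene_cadd,
        "actionable_report": actionable,
        "paths": paths,
    }
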