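"""Clinical-annotation knowledge base: PharmGKB evidence tiers, star alleles,
and the ClinVar drug-response code.

The on-disk format is a minimal TSV schema bundled with the package (not the
live PharmGKB export, whose column layout changes between releases);
:func:`convert_pharmgkb_export` maps a PharmGKB ``clinical_annotations.tsv``
onto it. Evidence levels follow the PharmGKB tiers: 1A (CPIC guideline or
clinically implemented) and 1B (replicated association) are *actionable*;
2A/2B are moderate replicated evidence; 3 and 4 are weaker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import FormatError, NotFoundError

log = logging.getLogger(__name__)

EVIDENCE_LEVELS = ("1A", "1B", "2A", "2B", "3", "4")
ACTIONABLE_LEVELS = frozenset({"1A", "1B"})

#: ClinVar clinical-significance code for "drug response".
CLINVAR_DRUG_RESPONSE_CODE = 6


@dataclass(frozen=True)
class ClinicalAnnotation:
    """One variant-drug evidence annotation (one PharmGKB level block)."""

    rsid: str
    gene: str
    level: str
    drugs: tuple
    association_type: str = ""

    def __post_init__(self):
        if self.level not in EVIDENCE_LEVELS:
            raise FormatError(f"unknown evidence level {self.level!r} for {self.rsid}")
        if not self.drugs:
            raise FormatError(f"annotation for {self.rsid} has no drugs")
        object.__setattr__(self, "drugs", tuple(d.strip().lower() for d in self.drugs))


@dataclass(frozen=True)
class StarAllele:
    """A named pharmacogene haplotype and its defining variants.

    Alleles defined by more than one variant (e.g. TPMT *3A = *3B + *3C)
    carry several defining rsIDs; without phase information their joint
    presence is only "potentially encoding" the combined allele.
    """

    gene: str
    allele_name: str
    defining_rsids: tuple
    function_class: Optional[str] = None

    def __post_init__(self):
        if not self.defining_rsids:
            raise FormatError(f"star allele {self.gene}{self.allele_name} has no defining rsids")
        if self.function_class is not None and self.function_class not in {
            "normal",
            "decreased",
            "none",
            "unknown",
        }:
            raise FormatError(f"bad function class {self.function_class!r}")


@dataclass
class KnowledgeBase:
    annotations: list = field(default_factory=list)
    star_alleles: dict = field(default_factory=dict)  # (GENE, allele) -> StarAllele

    # -- clinical annotations -------------------------------------------------

    def lookup_actionability(self, rsid: Optional[str]) -> set:
        """All (level, drugs) pairs annotated to an rsID; empty set if none.

        A variant may legitimately carry annotations in several tiers (e.g.
        a 1A block and a distinct 1B drug block).
        """
        if rsid is None:
            return set()
        return {(a.level, a.drugs) for a in self.annotations if a.rsid == rsid}

    def annotated_rsids(self, levels: Iterable[str]) -> set:
        wanted = set(levels)
        return {a.rsid for a in self.annotations if a.level in wanted}

    # -- star alleles ---------------------------------------------------------

    def resolve_star_allele(self, gene: str, allele_name: str) -> list:
        """Defining rsIDs for a (gene, star allele) pair; gene match is
        case-insensitive. Unknown pairs raise, so a caller cannot mistake an
        unresolvable allele for one defined by no variants."""
        record = self.star_alleles.get((gene.upper(), _norm_star(allele_name)))
        if record is None:
            raise NotFoundError(f"no star allele {allele_name} for gene {gene}")
        return list(record.defining_rsids)

    def star_allele_of(self, gene: str, rsid: str) -> Optional[str]:
        """Inverse lookup: the star-allele name a variant defines, if any.

        Single-variant alleles match directly; for multi-variant alleles the
        name is reported as 'potentially encoding'."""
        gene = gene.upper()
        single = [
            a for (g, _), a in self.star_alleles.items()
            if g == gene and len(a.defining_rsids) == 1 and a.defining_rsids[0] == rsid
        ]
        if single:
            return single[0].allele_name
        multi = [
            a for (g, _), a in self.star_alleles.items()
            if g == gene and len(a.defining_rsids) > 1 and rsid in a.defining_rsids
        ]
        if multi:
            return f"potentially encoding {multi[0].allele_name}"
        return None


def _norm_star(name: str) -> str:
    return name.strip().replace("∗", "*").lstrip("*").upper()


def has_drug_response_code(codes) -> bool:
    """True iff the ClinVar significance code set contains 6 ("drug response")."""
    return codes is not None and CLINVAR_DRUG_RESPONSE_CODE in codes


def load_clinical_annotations(path) -> list:
    """Load the clinical-annotation TSV (rsid, gene, level, drugs,
    association_type; drugs semicolon-separated). Duplicate
    (rsid, level, drug) triples are collapsed with a warning."""
    df = _read_tsv(path, ["rsid", "gene", "level", "drugs", "association_type"])
    annotations, seen = [], set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        drugs = tuple(d.strip().lower() for d in str(row.drugs).split(";") if d.strip())
        try:
            ann = ClinicalAnnotation(
                rsid=str(row.rsid),
                gene=str(row.gene),
                level=str(row.level),
                drugs=drugs,
                association_type=str(row.association_type),
            )
        except FormatError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        key = (ann.rsid, ann.level, ann.drugs)
        if key in seen:
            log.warning("%s: line %d: duplicate annotation %s collapsed", path, i, key)
            continue
        seen.add(key)
        annotations.append(ann)
    return annotations


def load_star_alleles(path) -> dict:
    """Load the star-allele TSV (gene, allele_name, defining_rsids
    semicolon-separated, function_class)."""
    df = _read_tsv(path, ["gene", "allele_name", "defining_rsids", "function_class"])
    table = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rsids = tuple(r.strip() for r in str(row.defining_rsids).split(";") if r.strip())
        fc = str(row.function_class).strip()
        allele = StarAllele(
            gene=str(row.gene),
            allele_name="*" + _norm_star(str(row.allele_name)),
            defining_rsids=rsids,
            function_class=fc if fc not in ("", ".") else None,
        )
        key = (allele.gene.upper(), _norm_star(allele.allele_name))
        if key in table:
            raise FormatError(f"{path}: line {i}: duplicate star allele {key}")
        table[key] = allele
    return table


def load_knowledge_base(directory) -> KnowledgeBase:
    """Load ``clinical_annotations.tsv`` and ``star_alleles.tsv`` from a directory."""
    directory = Path(directory)
    return KnowledgeBase(
        annotations=load_clinical_annotations(directory / "clinical_annotations.tsv"),
        star_alleles=load_star_alleles(directory / "star_alleles.tsv"),
    )


def _read_tsv(path, required: list) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: empty knowledge-base file")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def convert_pharmgkb_export(path, out_path) -> None:
    """Converter stub: map a PharmGKB ``clinical_annotations.tsv`` export onto
    the bundled schema.

    Expects the export columns ``Variant/Haplotypes``, ``Gene``,
    ``Level of Evidence``, ``Drug(s)``, ``Phenotype Category``; haplotype rows
    without an rsID are dropped (resolve them through the star-allele table).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {
        "Variant/Haplotypes": "rsid",
        "Gene": "gene",
        "Level of Evidence": "level",
        "Drug(s)": "drugs",
        "Phenotype Category": "association_type",
    }
    missing = [c for c in colmap if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: not a PharmGKB export (missing {missing})")
    out = df.rename(columns=colmap)[list(colmap.values())]
    out = out[out["rsid"].str.startswith("rs")]
    out["drugs"] = out["drugs"].str.replace('"', "").str.strip()
    out.to_csv(out_path, sep="\t", index=False)
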