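"""Read annotated variants from VCF or TSV, with QC filtering and panel restriction.

Two input dialects are supported:

* **VCF** (``VCFv4.x``, plain or bgzipped) with annotations in INFO and
  per-sample ``GT`` fields. INFO key names are configurable via
  :data:`DEFAULT_INFO_KEYS`; the rsID is taken from the ID column, site
  quality from QUAL and site depth from ``INFO/DP``. Multi-allelic lines are
  split into one record per alternate allele, with het/hom carrier counts
  recomputed per allele (a 1/2 genotype is heterozygous for *both* alts).

* **TSV**, the canonical annotation table this module also writes
  (columns in :data:`TSV_COLUMNS`, ``.`` marks an absent value).

Missing annotations always map to "absent"/"unknown", never to zero: a
variant without a gnomAD entry is *not* a variant with frequency 0.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .errors import FormatError
from .model import (
    PREDICTORS,
    AnnotatedVariant,
    CohortGenotypeSummary,
    Effect,
    Impact,
    harmonize_predictor_call,
)

#: Default INFO-key mapping for annotated VCF input.
DEFAULT_INFO_KEYS = {
    "gene": "GENE",
    "effect": "EFFECT",
    "impact": "IMPACT",
    "hgvs_c": "HGVS_C",
    "hgvs_p": "HGVS_P",
    "gnomad_af": "GNOMAD_AF",
    "cadd_phred": "CADD_PHRED",
    "gerp_rs": "GERP_RS",
    "SIFT": "SIFT",
    "PolyPhen2": "PP2",
    "MutationTaster": "MT",
    "MetaSVM": "METASVM",
    "clinvar": "CLNSIG",
    "depth": "DP",
}

#: Canonical annotation-TSV column order.
TSV_COLUMNS = [
    "contig",
    "position",
    "ref",
    "alt",
    "gene",
    "effect",
    "impact",
    "hgvs_c",
    "hgvs_p",
    "rsid",
    "gnomad_af",
    "sift",
    "polyphen2",
    "mutation_taster",
    "metasvm",
    "cadd_phred",
    "gerp_rs",
    "clinvar_codes",
    "site_depth",
    "site_quality",
    "het_count",
    "hom_count",
    "n_samples",
]

MISSING = "."

# snpEff / ANNOVAR effect vocabulary -> canonical effect classes
_EFFECT_ALIASES = {
    "missense_variant": Effect.missense,
    "missense": Effect.missense,
    "synonymous_variant": Effect.synonymous,
    "synonymous": Effect.synonymous,
    "frameshift_variant": Effect.frameshift,
    "frameshift": Effect.frameshift,
    "stop_gained": Effect.stop_gain,
    "stop_gain": Effect.stop_gain,
    "stop_lost": Effect.stop_lost,
    "start_lost": Effect.start_lost,
    "splice_acceptor_variant": Effect.splice_acceptor,
    "splice_acceptor": Effect.splice_acceptor,
    "splice_donor_variant": Effect.splice_donor,
    "splice_donor": Effect.splice_donor,
    "splice_region_variant": Effect.splice_region,
    "splice_region": Effect.splice_region,
    "inframe_deletion": Effect.inframe_deletion,
    "disruptive_inframe_deletion": Effect.inframe_deletion,
    "intron_variant": Effect.intronic,
    "intronic": Effect.intronic,
    "5_prime_utr_variant": Effect.utr5,
    "utr5": Effect.utr5,
    "3_prime_utr_variant": Effect.utr3,
    "utr3": Effect.utr3,
    "upstream_gene_variant": Effect.upstream,
    "upstream": Effect.upstream,
    "downstream_gene_variant": Effect.downstream,
    "downstream": Effect.downstream,
}


def parse_effect(token: str) -> Effect:
    return _EFFECT_ALIASES.get(str(token).strip().lower(), Effect.other)


def normalize_alleles(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align an allele pair by trimming shared suffix, then shared prefix.

    Keying convention only; at least one base is always retained on each side.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


def _info_get(info, key):
    """INFO access tolerant of keys absent from the header (pysam raises)."""
    if key is None:
        return None
    try:
        return info.get(key)
    except (KeyError, ValueError):
        return None


def _per_alt(value, alt_index: int):
    """Pick the entry for one alt allele out of a possibly per-alt INFO value."""
    if isinstance(value, (tuple, list)):
        if len(value) == 0:
            return None
        return value[alt_index] if alt_index < len(value) else value[0]
    return value


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def count_alt_genotypes(genotypes: Sequence[tuple], alt_index: int) -> tuple[int, int]:
    """Het/hom-alt carrier counts for allele ``alt_index`` (1-based).

    Missing calls count as homozygous reference (fixed-denominator
    convention); hemizygous calls carrying the allele count as hom.
    """
    het = hom = 0
    for gt in genotypes:
        alleles = [a for a in gt if a is not None]
        copies = sum(1 for a in alleles if a == alt_index)
        if len(alleles) == 1:
            if copies == 1:
                hom += 1
        elif copies == 1:
            het += 1
        elif copies >= 2:
            hom += 1
    return het, hom


def read_annotated_variants(
    path, format: str = None, info_keys: dict = None
) -> list[tuple[AnnotatedVariant, CohortGenotypeSummary]]:
    """Read a multi-sample annotated VCF or a canonical annotation TSV.

    Returns one ``(AnnotatedVariant, CohortGenotypeSummary)`` pair per
    (site, alt allele). ``format`` defaults from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".txt"} else "vcf"
    if format == "vcf":
        return _read_vcf(path, info_keys or DEFAULT_INFO_KEYS)
    if format == "tsv":
        return read_annotation_tsv(path)
    raise ValueError(f"unknown format: {format!r}")


def _read_vcf(path: Path, keys: dict) -> list[tuple[AnnotatedVariant, CohortGenotypeSummary]]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        n_samples = len(vcf.header.samples)
        if n_samples == 0:
            raise FormatError(f"{path}: VCF has no sample columns")
        for rec in vcf:
            try:
                genotypes = [rec.samples[s].get("GT", (None, None)) for s in rec.samples]
            except Exception as exc:  # malformed GT field
                raise FormatError(f"{path}: bad GT at {rec.chrom}:{rec.pos}") from exc
            info = rec.info
            clnsig = _info_get(info, keys["clinvar"])
            codes = None
            if clnsig is not None:
                toks = clnsig if isinstance(clnsig, (tuple, list)) else str(clnsig).split(",")
                parsed = [int(t) for t in toks if str(t).strip() not in ("", MISSING)]
                codes = frozenset(parsed) if parsed else None
            depth = _info_get(info, keys["depth"])
            for k, alt in enumerate(rec.alts or (), start=1):
                pos, ref, alt_n = normalize_alleles(rec.pos, rec.ref, alt)
                calls = {
                    p: harmonize_predictor_call(_per_alt(_info_get(info, keys[p]), k - 1)) for p in PREDICTORS
                }
                variant = AnnotatedVariant(
                    contig=rec.chrom,
                    position=pos,
                    ref_allele=ref,
                    alt_allele=alt_n,
                    gene=str(_per_alt(_info_get(info, keys["gene"]), k - 1) or ""),
                    effect=parse_effect(_per_alt(_info_get(info, keys["effect"]), k - 1) or "other"),
                    impact=Impact(str(_per_alt(_info_get(info, keys["impact"]), k - 1) or "MODIFIER")),
                    hgvs_c=_per_alt(_info_get(info, keys["hgvs_c"]), k - 1),
                    hgvs_p=_per_alt(_info_get(info, keys["hgvs_p"]), k - 1),
                    rsid=rec.id if rec.id not in (None, MISSING) else None,
                    gnomad_af=_opt_float(_per_alt(_info_get(info, keys["gnomad_af"]), k - 1)),
                    predictor_calls=calls,
                    cadd_phred=_opt_float(_per_alt(_info_get(info, keys["cadd_phred"]), k - 1)),
                    gerp_rs=_opt_float(_per_alt(_info_get(info, keys["gerp_rs"]), k - 1)),
                    clinvar_codes=codes,
                    site_depth=int(depth) if depth is not None else 0,
                    site_quality=float(rec.qual) if rec.qual is not None else 0.0,
                )
                het, hom = count_alt_genotypes(genotypes, k)
                out.append(
                    (variant, CohortGenotypeSummary(variant.key, het, hom, n_samples))
                )
    return out


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_annotation_tsv(
    records: Iterable[tuple[AnnotatedVariant, CohortGenotypeSummary]], path
) -> None:
    """Write the canonical annotation TSV (round-trips through the reader)."""
    rows = []
    for v, s in records:
        rows.append(
            {
                "contig": v.contig,
                "position": v.position,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "gene": v.gene,
                "effect": v.effect.value,
                "impact": v.impact.value,
                "hgvs_c": _fmt(v.hgvs_c),
                "hgvs_p": _fmt(v.hgvs_p),
                "rsid": _fmt(v.rsid),
                "gnomad_af": _fmt(v.gnomad_af),
                "sift": v.predictor_calls["SIFT"].value,
                "polyphen2": v.predictor_calls["PolyPhen2"].value,
                "mutation_taster": v.predictor_calls["MutationTaster"].value,
                "metasvm": v.predictor_calls["MetaSVM"].value,
                "cadd_phred": _fmt(v.cadd_phred),
                "gerp_rs": _fmt(v.gerp_rs),
                "clinvar_codes": MISSING
                if v.clinvar_codes is None
                else ",".join(str(c) for c in sorted(v.clinvar_codes)),
                "site_depth": v.site_depth,
                "site_quality": _fmt(v.site_quality),
                "het_count": s.het_count,
                "hom_count": s.hom_count,
                "n_samples": s.n_samples,
            }
        )
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> list[tuple[AnnotatedVariant, CohortGenotypeSummary]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):

        def opt(col):
            val = getattr(row, col)
            return None if val == MISSING or val == "" else val

        try:
            codes = opt("clinvar_codes")
            variant = AnnotatedVariant(
                contig=row.contig,
                position=int(row.position),
                ref_allele=row.ref,
                alt_allele=row.alt,
                gene=row.gene,
                effect=Effect(row.effect),
                impact=Impact(row.impact),
                hgvs_c=opt("hgvs_c"),
                hgvs_p=opt("hgvs_p"),
                rsid=opt("rsid"),
                gnomad_af=_opt_float(opt("gnomad_af")),
                predictor_calls={
                    "SIFT": harmonize_predictor_call(opt("sift")),
                    "PolyPhen2": harmonize_predictor_call(opt("polyphen2")),
                    "MutationTaster": harmonize_predictor_call(opt("mutation_taster")),
                    "MetaSVM": harmonize_predictor_call(opt("metasvm")),
                },
                cadd_phred=_opt_float(opt("cadd_phred")),
                gerp_rs=_opt_float(opt("gerp_rs")),
                clinvar_codes=frozenset(int(c) for c in codes.split(",")) if codes else None,
                site_depth=int(row.site_depth),
                site_quality=float(row.site_quality),
            )
            summary = CohortGenotypeSummary(
                variant.key, int(row.het_count), int(row.hom_count), int(row.n_samples)
            )
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        out.append((variant, summary))
    return out


def apply_quality_filter(
    variants: Sequence, min_depth: int = 20, min_quality: float = 300.0
) -> list:
    """Drop records with site depth below ``min_depth`` or quality below
    ``min_quality`` (both criteria must pass — the conservative QC reading).

    Works on ``AnnotatedVariant`` items or ``(variant, summary)`` pairs;
    order is preserved and the input is not mutated.
    """
    if min_depth < 0 or min_quality < 0:
        raise ValueError("thresholds must be nonnegative")

    def _variant(item):
        return item[0] if isinstance(item, tuple) else item

    return [
        item
        for item in variants
        if _variant(item).site_depth >= min_depth and _variant(item).site_quality >= min_quality
    ]


def restrict_to_panel(variants: Sequence, panel: Iterable[str]) -> list:
    """Keep records whose gene symbol is in the panel (case-insensitive)."""
    panel_uc = {g.strip().upper() for g in panel if g and g.strip()}
    if not panel_uc:
        raise ValueError("panel must be nonempty")

    def _variant(item):
        return item[0] if isinstance(item, tuple) else item

    return [item for item in variants if _variant(item).gene.upper() in panel_uc]


def load_panel(path) -> set[str]:
    """Read a plain gene-symbol list (one symbol per line, '#' comments)."""
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.add(line.upper())
    if not symbols:
        raise FormatError(f"{path}: empty gene panel")
    return symbols
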