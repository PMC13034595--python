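"""Readers and writers: annotated VCF, PED, gene panels, configs, outputs.

VCF input is read with cyvcf2 and decomposed so that every
:class:`~ranktriage.core.VariantRecord` carries exactly one alternate
allele; multi-allelic sites yield one record per alt, in input order.
Annotation values live in INFO under configurable keys
(:class:`InfoFieldMap`); unknown keys are ignored.  Because htslib stores
Float INFO values in 32-bit precision, all floating annotation values are
normalised to six significant digits on both read and write, which makes
read -> write -> read lossless for every field the tool owns.

Output is (a) a ranked TSV, one row per variant with per-category scores
and provenance, and (b) an annotated VCF adding ``RankScore``
(``family_id:score``, the decision-support interoperability convention),
``GeneticModels`` and ``Compounds`` INFO keys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from cyvcf2 import VCF

from .core import (
    AffectedStatus,
    AnnotationBundle,
    ClinvarSig,
    GenePanel,
    Genotype,
    Individual,
    PanelMode,
    Pedigree,
    Sex,
    StrLocusConfig,
    VariantRecord,
    VarType,
    impact_for_consequence,
    variant_key,
)
from .ranking import RankedVariant

__all__ = [
    "InfoFieldMap",
    "read_annotated_vcf",
    "read_pedigree",
    "read_panel",
    "read_str_loci",
    "default_str_loci",
    "write_vcf",
    "write_pedigree",
    "write_ranked_output",
    "read_rank_scores",
]


def _round6(x: float) -> float:
    """Normalise to 6 significant digits (float32-safe round-trip)."""
    return float(f"{x:.6g}")


@dataclass(frozen=True)
class InfoFieldMap:
    """Mapping from annotation fields to VCF INFO keys.

    Defaults follow a documented convention; production pipelines with
    different annotation keys supply their own map.
    """

    gene: str = "GENE"
    consequence: str = "CSQ"
    gnomad_af: str = "GNOMAD_AF"
    gnomad_ac: str = "GNOMAD_AC"
    gnomad_nhomalt: str = "GNOMAD_NHOMALT"
    local_sv_freq: str = "LOCAL_SV_FREQ"
    clinvar_sig: str = "CLNSIG"
    clinvar_stars: str = "CLNREVSTAT"
    cadd_phred: str = "CADD_PHRED"
    revel: str = "REVEL"
    spliceai_max: str = "SPLICEAI_MAX"
    distance_to_exon: str = "DIST_EXON"
    var_type: str = "VARTYPE"
    sv_end: str = "END"
    str_repeat_count: str = "REPCN"


DEFAULT_INFO_MAP = InfoFieldMap()

_FLOAT_FIELDS = ("gnomad_af", "local_sv_freq", "cadd_phred", "revel", "spliceai_max")
_INT_FIELDS = ("gnomad_ac", "gnomad_nhomalt", "distance_to_exon")


def _info_scalar(value, alt_index: int):
    """Pick the per-alt element from Number=A INFO values."""
    if isinstance(value, (tuple, list)):
        return value[alt_index] if alt_index < len(value) else None
    return value


def _parse_genotype(gt_row: list, alt_number: int) -> Genotype:
    """Decompose a cyvcf2 genotype row against one alt allele.

    Alleles equal to this alt become 1; reference and *other* alt alleles
    become 0 (per-allele view of a multi-allelic site); -1 is missing.
    Haploid calls become hemizygous genotypes.
    """
    *alleles, phased = gt_row
    mapped = []
    for a in alleles:
        if a == -2:  # cyvcf2 padding for mixed-ploidy rows
            continue
        mapped.append(None if a == -1 else (1 if a == alt_number else 0))
    if len(mapped) == 1:
        return Genotype(alleles=(mapped[0], None), phased=bool(phased), hemizygous=True)
    return Genotype(alleles=(mapped[0], mapped[1]), phased=bool(phased))


def read_annotated_vcf(
    path: str | Path, info_map: InfoFieldMap = DEFAULT_INFO_MAP
) -> list[VariantRecord]:
    """Read an annotated VCF into per-alt variant records, preserving order."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for site in vcf:
        for alt_i, alt in enumerate(site.ALT):
            ann = AnnotationBundle()
            for name in _FLOAT_FIELDS:
                raw = site.INFO.get(getattr(info_map, name))
                val = _info_scalar(raw, alt_i)
                if val is not None:
                    setattr(ann, name, _round6(float(val)))
            for name in _INT_FIELDS:
                raw = site.INFO.get(getattr(info_map, name))
                val = _info_scalar(raw, alt_i)
                if val is not None:
                    setattr(ann, name, int(val))
            csq = site.INFO.get(info_map.consequence)
            if csq:
                term = str(_info_scalar(csq, alt_i))
                ann.consequence = term
                ann.impact = impact_for_consequence(term)
            sig = site.INFO.get(info_map.clinvar_sig)
            if sig:
                ann.clinvar_sig = ClinvarSig(str(_info_scalar(sig, alt_i)))
            stars = site.INFO.get(info_map.clinvar_stars)
            if stars is not None:
                ann.clinvar_stars = int(_info_scalar(stars, alt_i))
            genes_raw = site.INFO.get(info_map.gene)
            gene_ids = (
                {g for g in str(genes_raw).split(",") if g} if genes_raw else set()
            )
            vt_raw = site.INFO.get(info_map.var_type)
            if vt_raw:
                var_type = VarType(str(vt_raw))
            elif len(site.REF) == 1 and len(alt) == 1:
                var_type = VarType.SNV
            else:
                var_type = VarType.INDEL
            end_raw = site.INFO.get(info_map.sv_end)
            rep_raw = site.INFO.get(info_map.str_repeat_count)
            genotypes = {
                sample: _parse_genotype(site.genotypes[i], alt_i + 1)
                for i, sample in enumerate(samples)
            }
            records.append(
                VariantRecord(
                    chrom=site.CHROM,
                    pos=site.POS,
                    ref=site.REF,
                    alt=alt,
                    var_type=var_type,
                    gene_ids=gene_ids,
                    annotations=ann,
                    genotypes=genotypes,
                    sv_end=int(end_raw) if end_raw is not None else None,
                    str_repeat_count=int(rep_raw) if rep_raw is not None else None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# PED


_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_PED_STATUS = {
    "2": AffectedStatus.AFFECTED,
    "1": AffectedStatus.UNAFFECTED,
    "0": AffectedStatus.UNKNOWN,
}
_SEX_PED = {v: k for k, v in _PED_SEX.items()}
_STATUS_PED = {v: k for k, v in _PED_STATUS.items()}


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (one family per file)."""
    members: list[Individual] = []
    family_id: Optional[str] = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: PED line has {len(parts)} columns, need 6")
        fam, iid, father, mother, sex, status = parts[:6]
        if family_id is None:
            family_id = fam
        elif fam != family_id:
            raise ValueError(f"{path}:{lineno}: multiple families in one PED file")
        members.append(
            Individual(
                id=iid,
                father_id=None if father in ("0", ".") else father,
                mother_id=None if mother in ("0", ".") else mother,
                sex=_PED_SEX.get(sex, Sex.UNKNOWN),
                status=_PED_STATUS.get(status, AffectedStatus.UNKNOWN),
            )
        )
    if family_id is None:
        raise ValueError(f"{path}: empty PED file")
    return Pedigree(family_id=family_id, members=members)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    lines = []
    for m in pedigree.members:
        lines.append(
            "\t".join(
                [
                    pedigree.family_id,
                    m.id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    _SEX_PED[m.sex],
                    _STATUS_PED[m.status],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Panels


def read_panel(path: str | Path) -> GenePanel:
    """Read a gene panel from TSV (gene, optional inheritance tag) or JSON.

    TSV files may carry ``#name=``, ``#version=`` and ``#mode=`` header
    comments; otherwise the name falls back to the file stem.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return GenePanel(
            name=data["name"],
            version=str(data.get("version", "unversioned")),
            genes=set(data["genes"]),
            mode=PanelMode(data.get("mode", "mixed")),
        )
    name, version, mode = path.stem, "unversioned", PanelMode.MIXED
    genes: set[str] = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("name="):
                name = body[5:]
            elif body.startswith("version="):
                version = body[8:]
            elif body.startswith("mode="):
                mode = PanelMode(body[5:])
            continue
        genes.add(line.split("\t")[0])
    return GenePanel(name=name, version=version, genes=genes, mode=mode)


# ---------------------------------------------------------------------------
# STR locus configs


def read_str_loci(path: str | Path) -> dict[str, StrLocusConfig]:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    loci = {}
    for raw in data.get("locus", []):
        cfg = StrLocusConfig(
            locus_id=raw["locus_id"],
            gene=raw["gene"],
            repeat_unit=raw["repeat_unit"],
            normal_max=int(raw["normal_max"]),
            intermediate_max=int(raw["intermediate_max"]),
            premutation_max=int(raw["premutation_max"]),
        )
        loci[cfg.locus_id] = cfg
    return loci


def default_str_loci() -> dict[str, StrLocusConfig]:
    """Shipped illustrative locus thresholds (site policy must override)."""
    from importlib import resources

    with resources.as_file(
        resources.files("ranktriage.data").joinpath("str_loci_default.toml")
    ) as p:
        return read_str_loci(p)


# ---------------------------------------------------------------------------
# VCF writing


_INFO_DEFS = [
    ("GENE", ".", "String", "Overlapping gene symbols"),
    ("CSQ", "A", "String", "Most severe consequence"),
    ("GNOMAD_AF", "A", "Float", "gnomAD allele frequency"),
    ("GNOMAD_AC", "A", "Integer", "gnomAD allele count"),
    ("GNOMAD_NHOMALT", "A", "Integer", "gnomAD homozygote count"),
    ("LOCAL_SV_FREQ", "A", "Float", "Local SV frequency"),
    ("CLNSIG", "A", "String", "ClinVar significance"),
    ("CLNREVSTAT", "A", "Integer", "ClinVar review stars"),
    ("CADD_PHRED", "A", "Float", "CADD PHRED score"),
    ("REVEL", "A", "Float", "REVEL score"),
    ("SPLICEAI_MAX", "A", "Float", "Max SpliceAI delta score"),
    ("DIST_EXON", "A", "Integer", "Signed distance to nearest exon boundary"),
    ("VARTYPE", "1", "String", "Variant type"),
    ("END", "1", "Integer", "End position of SV/STR"),
    ("REPCN", "1", "Integer", "Estimated repeat count"),
    ("RankScore", ".", "String", "family_id:rank score"),
    ("GeneticModels", ".", "String", "Compatible inheritance models"),
    ("Compounds", ".", "String", "Compound partner variant keys"),
]


def _fmt_float(x: float) -> str:
    return f"{_round6(x):.6g}"


def _info_string(
    v: VariantRecord,
    info_map: InfoFieldMap,
    extra: Optional[dict[str, str]] = None,
) -> str:
    ann = v.annotations
    parts: list[str] = []
    if v.gene_ids:
        parts.append(f"{info_map.gene}={','.join(sorted(v.gene_ids))}")
    if ann.consequence is not None:
        parts.append(f"{info_map.consequence}={ann.consequence}")
    for name in _FLOAT_FIELDS:
        val = getattr(ann, name)
        if val is not None:
            parts.append(f"{getattr(info_map, name)}={_fmt_float(val)}")
    for name in _INT_FIELDS:
        val = getattr(ann, name)
        if val is not None:
            parts.append(f"{getattr(info_map, name)}={val}")
    if ann.clinvar_sig is not ClinvarSig.NONE:
        parts.append(f"{info_map.clinvar_sig}={ann.clinvar_sig.value}")
        parts.append(f"{info_map.clinvar_stars}={ann.clinvar_stars}")
    parts.append(f"{info_map.var_type}={v.var_type.value}")
    if v.sv_end is not None:
        parts.append(f"{info_map.sv_end}={v.sv_end}")
    if v.str_repeat_count is not None:
        parts.append(f"{info_map.str_repeat_count}={v.str_repeat_count}")
    if extra:
        parts.extend(f"{k}={val}" for k, val in extra.items())
    return ";".join(parts) if parts else "."


def write_vcf(
    records: list[VariantRecord],
    samples: list[str],
    path: str | Path,
    info_map: InfoFieldMap = DEFAULT_INFO_MAP,
    extra_info: Optional[dict[str, dict[str, str]]] = None,
    header_comments: Optional[list[str]] = None,
) -> None:
    """Write records as VCF 4.2 text (one line per single-alt record).

    ``extra_info`` maps variant key -> {INFO key: value} for stage outputs
    such as RankScore.  Genotypes are written for ``samples`` in order;
    individuals without a genotype on a record get ``./.``.
    """
    lines = ["##fileformat=VCFv4.2"]
    for comment in header_comments or []:
        lines.append(f"##{comment}")
    contigs = []
    for v in records:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    for key, number, typ, desc in _INFO_DEFS:
        lines.append(
            f'##INFO=<ID={key},Number={number},Type={typ},Description="{desc}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header_cols += ["FORMAT"] + samples
    lines.append("\t".join(header_cols))
    for v in records:
        extra = (extra_info or {}).get(variant_key(v))
        row = [
            v.chrom,
            str(v.pos),
            ".",
            v.ref,
            v.alt,
            ".",
            "PASS",
            _info_string(v, info_map, extra),
        ]
        if samples:
            row.append("GT")
            for s in samples:
                gt = v.genotypes.get(s)
                row.append("./." if gt is None else str(gt))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ranked output


TSV_COLUMNS = [
    "rank_position",
    "variant_key",
    "chrom",
    "pos",
    "ref",
    "alt",
    "var_type",
    "genes",
    "total_score",
    "genetic_models",
    "compound_partners",
    "acmg_class",
]


def write_ranked_output(
    ranked: list[RankedVariant],
    tsv_path: str | Path,
    vcf_path: Optional[str | Path] = None,
    family_id: str = "FAM",
    samples: Optional[list[str]] = None,
    info_map: InfoFieldMap = DEFAULT_INFO_MAP,
    header_comments: Optional[list[str]] = None,
    decisions: Optional[dict[str, list[str]]] = None,
) -> None:
    """Write the ranked table (TSV) and optionally an annotated VCF.

    The TSV has one row per variant ordered by rank position, with
    per-category scores as extra columns and filter provenance flags when
    ``decisions`` (variant key -> rule ids) is given.  The VCF adds
    ``RankScore=family_id:total``, ``GeneticModels`` and ``Compounds``.
    """
    categories = list(ranked[0].category_scores) if ranked else []
    cols = TSV_COLUMNS + [f"score_{c}" for c in categories] + ["filter_flags"]
    lines = [f"#{comment}" for comment in header_comments or []]
    lines.append("\t".join(cols))
    for rv in sorted(ranked, key=lambda r: (r.rank_position is None, r.rank_position)):
        v = rv.variant
        row = [
            "" if rv.rank_position is None else str(rv.rank_position),
            rv.key,
            v.chrom,
            str(v.pos),
            v.ref,
            v.alt,
            v.var_type.value,
            ",".join(sorted(v.gene_ids)),
            str(rv.total_score),
            ",".join(sorted(m.value for m in rv.genetic_models)),
            ",".join(sorted(rv.compound_partners)),
            "" if rv.acmg_class is None else str(rv.acmg_class),
        ]
        row += [str(rv.category_scores[c]) for c in categories]
        row.append(",".join((decisions or {}).get(rv.key, [])))
        lines.append("\t".join(row))
    Path(tsv_path).write_text("\n".join(lines) + "\n")

    if vcf_path is not None:
        extra_info: dict[str, dict[str, str]] = {}
        for rv in ranked:
            extra = {"RankScore": f"{family_id}:{rv.total_score}"}
            if rv.genetic_models:
                extra["GeneticModels"] = ",".join(
                    sorted(m.value for m in rv.genetic_models)
                )
            if rv.compound_partners:
                extra["Compounds"] = ",".join(sorted(rv.compound_partners)).replace(
                    ";", "_"
                )
            extra_info[rv.key] = extra
        ordered = sorted(
            ranked, key=lambda r: (r.rank_position is None, r.rank_position)
        )
        write_vcf(
            [rv.variant for rv in ordered],
            samples or [],
            vcf_path,
            info_map=info_map,
            extra_info=extra_info,
            header_comments=header_comments,
        )


def read_rank_scores(path: str | Path) -> dict[str, int]:
    """Recover ``variant key -> total rank score`` from an annotated VCF."""
    scores: dict[str, int] = {}
    for site in VCF(str(path)):
        raw = site.INFO.get("RankScore")
        if raw is None:
            continue
        for alt in site.ALT:
            key = f"{site.CHROM}:{site.POS}:{site.REF}:{alt}"
            scores[key] = int(str(raw).rsplit(":", 1)[1])
    return scores
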