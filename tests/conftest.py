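"""Shared builders for triage tests: genotypes, trios, annotated variants."""

from __future__ import annotations

import pytest

from ranktriage.core import (
    AffectedStatus,
    AnnotationBundle,
    ClinvarSig,
    Genotype,
    Impact,
    Individual,
    Pedigree,
    Sex,
    VariantRecord,
    VarType,
)
from ranktriage.rankmodel import default_rank_model


def gt(spec: str) -> Genotype:
    """Shorthand genotype builder: '0/1', '1/1', './.', '1' (hemizygous),
    '0/.', etc."""
    if "/" not in spec and "|" not in spec:
        a = None if spec == "." else int(spec)
        return Genotype(alleles=(a, None), hemizygous=True)
    sep = "|" if "|" in spec else "/"
    a, b = spec.split(sep)
    conv = lambda s: None if s == "." else int(s)
    return Genotype(alleles=(conv(a), conv(b)), phased=sep == "|")


def trio(
    child_status: str = "affected",
    father_status: str = "unaffected",
    mother_status: str = "unaffected",
    child_sex: Sex = Sex.FEMALE,
    family_id: str = "FAM1",
) -> Pedigree:
    return Pedigree(
        family_id=family_id,
        members=[
            Individual(
                id="child",
                father_id="father",
                mother_id="mother",
                sex=child_sex,
                status=AffectedStatus(child_status),
            ),
            Individual(id="father", sex=Sex.MALE, status=AffectedStatus(father_status)),
            Individual(id="mother", sex=Sex.FEMALE, status=AffectedStatus(mother_status)),
        ],
    )


def mkvar(
    chrom: str = "1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "T",
    genotypes: dict[str, str] | None = None,
    genes: set[str] | None = None,
    var_type: VarType = VarType.SNV,
    **ann,
) -> VariantRecord:
    """Variant builder; genotype values given as strings ('0/1')."""
    if "impact" in ann and isinstance(ann["impact"], str):
        ann["impact"] = Impact(ann["impact"])
    if "clinvar_sig" in ann and isinstance(ann["clinvar_sig"], str):
        ann["clinvar_sig"] = ClinvarSig(ann["clinvar_sig"])
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        var_type=var_type,
        gene_ids=genes if genes is not None else {"GENE1"},
        annotations=AnnotationBundle(**ann),
        genotypes={k: gt(v) for k, v in (genotypes or {}).items()},
    )


@pytest.fixture(scope="session")
def model():
    return default_rank_model()
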