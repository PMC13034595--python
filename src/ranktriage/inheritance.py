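"""Genotype-driven inheritance-model annotation and compound-het pairing.

Each variant is annotated with every monogenic inheritance model that the
observed family genotypes do **not** exclude: autosomal dominant (AD, with
a de novo refinement), autosomal recessive homozygous (AR_hom, with a de
novo refinement), and their X-linked counterparts (XD/XR) under male
hemizygosity.  Compound-heterozygous recessive (AR_comp) is never produced
by the per-variant predicates; it is assigned by :func:`find_compound_pairs`
which pairs heterozygous variants in the same gene and, when parental
genotypes allow, requires the two alleles to be in trans.

Missing genotypes are permissive: they can never exclude a model (clinical
caution — an ungenotyped relative must not hide a candidate).  The single
exception is the de novo refinements, which positively require both
parents of an affected carrier to be genotyped homozygous-reference; an
unproven de novo is not annotated as one.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Optional

from .core import (
    Individual,
    Pedigree,
    Sex,
    VariantRecord,
    is_x_chromosome,
    variant_key,
)

__all__ = [
    "GeneticModel",
    "ParRegions",
    "ParentalOrigin",
    "annotate_genetic_models",
    "phase_by_pedigree",
    "CompoundPair",
    "find_compound_pairs",
]


class GeneticModel(str, enum.Enum):
    AD = "AD"
    AD_DENOVO = "AD_dn"
    AR_HOM = "AR_hom"
    AR_HOM_DENOVO = "AR_hom_dn"
    AR_COMP = "AR_comp"
    XD = "XD"
    XD_DENOVO = "XD_dn"
    XR = "XR"
    XR_DENOVO = "XR_dn"


@dataclass(frozen=True)
class ParRegions:
    """Pseudoautosomal intervals on X, treated as autosomal (GRCh38 defaults)."""

    intervals: tuple[tuple[int, int], ...] = ((10001, 2781479), (155701383, 156030895))

    def contains(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.intervals)


DEFAULT_PAR = ParRegions()


def _gt(variant: VariantRecord, individual: Individual):
    return variant.genotypes.get(individual.id)


def _hom_alt_equivalent(variant: VariantRecord, ind: Individual, x_linked: bool) -> Optional[bool]:
    """Is this individual homozygous alt (or hemizygous alt on X, for males)?

    Returns None when the genotype cannot decide either way (missing data).
    """
    gt = _gt(variant, ind)
    if gt is None or gt.fully_missing:
        return None
    if x_linked and (ind.sex is Sex.MALE or gt.hemizygous):
        # a single alt allele is the "biallelic" state for a hemizygous male
        if gt.carries_alt:
            return True
        return False if gt.definitely_no_alt or 0 in gt.known_alleles else None
    if gt.is_hom_alt:
        return True
    if 0 in gt.known_alleles:
        return False
    return None  # e.g. 1/. — could be 1/1 or 0/1


def _carries(variant: VariantRecord, ind: Individual) -> Optional[bool]:
    """Does the individual carry >=1 alt? None when undecidable."""
    gt = _gt(variant, ind)
    if gt is None or gt.fully_missing:
        return None
    if gt.carries_alt:
        return True
    return False if gt.definitely_no_alt else None


def _denovo_confirmed(
    variant: VariantRecord, child: Individual, pedigree: Pedigree, x_linked: bool
) -> bool:
    """Both transmitting parents genotyped and definitely alt-free.

    On X a son receives his only X from his mother, so the father's X
    genotype is not required; both parents must still be present.
    """
    father, mother = pedigree.parents_of(child)
    if father is None or mother is None:
        return False
    if x_linked and child.sex is Sex.MALE:
        mg = _gt(variant, mother)
        return mg is not None and mg.definitely_no_alt
    for parent in (father, mother):
        pg = _gt(variant, parent)
        if pg is None or not pg.definitely_no_alt:
            return False
    return True


def _one_allele_untransmittable(
    variant: VariantRecord, child: Individual, pedigree: Pedigree, x_linked: bool
) -> bool:
    """For a biallelic-alt affected: could at least one allele only be de novo?

    True when both parents are genotyped and at least one of them carries
    no alt allele at all (so full biparental transmission is impossible).
    """
    father, mother = pedigree.parents_of(child)
    if father is None or mother is None:
        return False
    if x_linked and child.sex is Sex.MALE:
        mg = _gt(variant, mother)
        return mg is not None and mg.definitely_no_alt
    fg, mg = _gt(variant, father), _gt(variant, mother)
    if fg is None or mg is None or fg.fully_missing or mg.fully_missing:
        return False
    return fg.definitely_no_alt or mg.definitely_no_alt


def _dominant_holds(
    variant: VariantRecord, pedigree: Pedigree, x_linked: bool, relaxed: bool
) -> bool:
    """Every affected carries alt; no unaffected carries alt (unless relaxed)."""
    for ind in pedigree.affected:
        if _carries(variant, ind) is False:
            return False
    if not relaxed:
        for ind in pedigree.unaffected:
            if _carries(variant, ind) is True:
                return False
    return True


def _recessive_holds(variant: VariantRecord, pedigree: Pedigree, x_linked: bool) -> bool:
    """Every affected hom-alt (hemizygous alt on X); no unaffected hom-alt."""
    for ind in pedigree.affected:
        if _hom_alt_equivalent(variant, ind, x_linked) is False:
            return False
    for ind in pedigree.unaffected:
        if _hom_alt_equivalent(variant, ind, x_linked) is True:
            return False
    return True


def _denovo_refinement(
    variant: VariantRecord,
    pedigree: Pedigree,
    x_linked: bool,
    recessive: bool,
) -> bool:
    """De novo variant of the base model holds for every affected carrier."""
    confirmed_any = False
    for ind in pedigree.affected:
        if recessive:
            state = _hom_alt_equivalent(variant, ind, x_linked)
            if state is not True:
                continue  # not a confirmed biallelic carrier
            if not _one_allele_untransmittable(variant, ind, pedigree, x_linked):
                return False
        else:
            if _carries(variant, ind) is not True:
                continue
            if not _denovo_confirmed(variant, ind, pedigree, x_linked):
                return False
        confirmed_any = True
    return confirmed_any


def annotate_genetic_models(
    variant: VariantRecord,
    pedigree: Pedigree,
    relaxed: bool = False,
    par_regions: ParRegions = DEFAULT_PAR,
) -> set[GeneticModel]:
    """Return every inheritance model not excluded by the observed genotypes.

    Autosomal models apply off the X chromosome (and inside pseudoautosomal
    intervals, where diploid inheritance holds); X-linked models apply on X
    outside those intervals.  ``relaxed`` permits unaffected carriers for
    the dominant models (reduced-penetrance escape hatch).  AR_comp is not
    produced here; see :func:`find_compound_pairs`.
    """
    x_linked = is_x_chromosome(variant.chrom) and not par_regions.contains(variant.pos)
    models: set[GeneticModel] = set()
    if x_linked:
        if _dominant_holds(variant, pedigree, True, relaxed):
            models.add(GeneticModel.XD)
            if _denovo_refinement(variant, pedigree, True, recessive=False):
                models.add(GeneticModel.XD_DENOVO)
        if _recessive_holds(variant, pedigree, True):
            models.add(GeneticModel.XR)
            if _denovo_refinement(variant, pedigree, True, recessive=True):
                models.add(GeneticModel.XR_DENOVO)
    else:
        if _dominant_holds(variant, pedigree, False, relaxed):
            models.add(GeneticModel.AD)
            if _denovo_refinement(variant, pedigree, False, recessive=False):
                models.add(GeneticModel.AD_DENOVO)
        if _recessive_holds(variant, pedigree, False):
            models.add(GeneticModel.AR_HOM)
            if _denovo_refinement(variant, pedigree, False, recessive=True):
                models.add(GeneticModel.AR_HOM_DENOVO)
    return models


# ---------------------------------------------------------------------------
# Parental-origin phasing


class ParentalOrigin(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    DENOVO = "denovo"
    AMBIGUOUS = "ambiguous"


def phase_by_pedigree(
    variant: VariantRecord, child: Individual, pedigree: Pedigree
) -> ParentalOrigin:
    """Infer which parent transmitted a heterozygous child allele.

    paternal iff only the father carries the alt; maternal iff only the
    mother; denovo iff both parents are genotyped homozygous-reference;
    ambiguous when both parents carry it or either genotype is missing.
    """
    father, mother = pedigree.parents_of(child)
    f_carries = _carries(variant, father) if father is not None else None
    m_carries = _carries(variant, mother) if mother is not None else None
    if f_carries is None or m_carries is None:
        return ParentalOrigin.AMBIGUOUS
    if f_carries and m_carries:
        return ParentalOrigin.AMBIGUOUS
    if f_carries:
        return ParentalOrigin.PATERNAL
    if m_carries:
        return ParentalOrigin.MATERNAL
    fg, mg = _gt(variant, father), _gt(variant, mother)
    if fg.definitely_no_alt and mg.definitely_no_alt:
        return ParentalOrigin.DENOVO
    return ParentalOrigin.AMBIGUOUS


# ---------------------------------------------------------------------------
# Compound heterozygotes


@dataclass(frozen=True)
class CompoundPair:
    """An unordered candidate compound-het pair of variant keys.

    ``phased`` is True when parental genotypes demonstrate a trans
    configuration; False flags an unphased (het/het only) candidate.
    """

    keys: frozenset[str]
    phased: bool = False


_TRANS = {
    frozenset({ParentalOrigin.MATERNAL, ParentalOrigin.PATERNAL}),
    frozenset({ParentalOrigin.MATERNAL, ParentalOrigin.DENOVO}),
    frozenset({ParentalOrigin.PATERNAL, ParentalOrigin.DENOVO}),
}


def _pair_state(
    a: VariantRecord, b: VariantRecord, ind: Individual, pedigree: Pedigree
) -> str:
    """Classify the pair for one individual: 'trans', 'cis', or 'unphased'."""
    oa = phase_by_pedigree(a, ind, pedigree)
    ob = phase_by_pedigree(b, ind, pedigree)
    if ParentalOrigin.AMBIGUOUS in (oa, ob):
        return "unphased"
    if frozenset({oa, ob}) in _TRANS:
        return "trans"
    return "cis"  # same parental origin (incl. both de novo: cannot be shown trans)


def find_compound_pairs(
    gene_variants: list[VariantRecord], pedigree: Pedigree
) -> dict[frozenset[str], CompoundPair]:
    """Candidate compound-het pairs among variants sharing a gene.

    A pair qualifies iff every affected member is heterozygous for both
    variants (missing genotypes are permissive), parental data — where it
    phases both variants — shows a trans configuration in every affected,
    and no unaffected member demonstrably carries both in trans.  Pairs
    whose phase could not be established in any affected are flagged
    ``phased=False`` ("unphased" candidates).
    """
    result: dict[frozenset[str], CompoundPair] = {}
    for a, b in itertools.combinations(gene_variants, 2):
        ka, kb = variant_key(a), variant_key(b)
        if ka == kb:
            continue
        ok = True
        phased_any = False
        for ind in pedigree.affected:
            for v in (a, b):
                gt = v.genotypes.get(ind.id)
                if gt is not None and not gt.fully_missing and not gt.is_het:
                    ok = False
                    break
            if not ok:
                break
            state = _pair_state(a, b, ind, pedigree)
            if state == "cis":
                ok = False
                break
            if state == "trans":
                phased_any = True
        if not ok:
            continue
        for ind in pedigree.unaffected:
            if _carries(a, ind) is True and _carries(b, ind) is True:
                if _pair_state(a, b, ind, pedigree) == "trans":
                    ok = False
                    break
        if ok:
            keys = frozenset({ka, kb})
            result[keys] = CompoundPair(keys=keys, phased=phased_any)
    return result
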