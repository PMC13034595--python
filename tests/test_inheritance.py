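"""Inheritance-model annotation, phasing and compound pairing.

The heavyweight checks live here: an exhaustive trio enumeration against
independent per-model predicate functions, and a brute-force all-pairs
oracle for compound heterozygotes.  The oracle code below restates the
model definitions directly (per-individual truth tables), independent of
the package's predicate engine.
"""

from __future__ import annotations

import itertools
import random

import pytest

from ranktriage.core import Individual, Pedigree, Sex, AffectedStatus
from ranktriage.inheritance import (
    GeneticModel as GM,
    ParentalOrigin,
    annotate_genetic_models,
    find_compound_pairs,
    phase_by_pedigree,
)

from conftest import gt, mkvar, trio


# ---------------------------------------------------------------------------
# Independent oracle: direct per-model truth tables for a trio


def _carries(g):  # definite alt carrier / definite non-carrier / unknown
    if 1 in g.known_alleles:
        return True
    n = 1 if g.hemizygous else 2
    return False if len(g.known_alleles) == n and set(g.known_alleles) == {0} else None


def _homalt(g, male, x):
    if x and (male or g.hemizygous):
        c = _carries(g)
        if c:
            return True
        return False if 0 in g.known_alleles or c is False else None
    n = 1 if g.hemizygous else 2
    if len(g.known_alleles) == n and set(g.known_alleles) == {1}:
        return True
    return False if 0 in g.known_alleles else None


def _refhom(g):
    n = 1 if g.hemizygous else 2
    return len(g.known_alleles) == n and set(g.known_alleles) == {0}


def oracle_trio_models(cg, fg, mg, f_aff, m_aff, child_male=False, x=False):
    """Expected model set for a trio with an affected child, stated as
    direct truth tables (independent of the package predicates)."""
    people = [
        ("child", cg, True, child_male, True),
        ("father", fg, f_aff, True, False),
        ("mother", mg, m_aff, False, False),
    ]
    affected = [p for p in people if p[2]]
    unaffected = [p for p in people if not p[2]]

    def dominant():
        if any(_carries(g) is False for _, g, _, _, _ in affected):
            return False
        if any(_carries(g) is True for _, g, _, _, _ in unaffected):
            return False
        return True

    def recessive():
        if any(_homalt(g, male, x) is False for _, g, _, male, _ in affected):
            return False
        if any(_homalt(g, male, x) is True for _, g, _, male, _ in unaffected):
            return False
        return True

    def dn_dominant():
        confirmed = False
        for name, g, _, male, is_child in affected:
            if _carries(g) is not True:
                continue
            if not is_child:
                return False  # parents have no genotyped parents here
            if x and male:
                ok = _refhom(mg)
            else:
                ok = _refhom(fg) and _refhom(mg)
            if not ok:
                return False
            confirmed = True
        return confirmed

    def dn_recessive():
        confirmed = False
        for name, g, _, male, is_child in affected:
            if _homalt(g, male, x) is not True:
                continue
            if not is_child:
                return False
            if x and male:
                ok = _refhom(mg)
            else:
                if len(fg.known_alleles) < (1 if fg.hemizygous else 2):
                    return False
                if len(mg.known_alleles) < 2:
                    return False
                ok = _refhom(fg) or _refhom(mg)
            if not ok:
                return False
            confirmed = True
        return confirmed

    models = set()
    if x:
        if dominant():
            models.add(GM.XD)
            if dn_dominant():
                models.add(GM.XD_DENOVO)
        if recessive():
            models.add(GM.XR)
            if dn_recessive():
                models.add(GM.XR_DENOVO)
    else:
        if dominant():
            models.add(GM.AD)
            if dn_dominant():
                models.add(GM.AD_DENOVO)
        if recessive():
            models.add(GM.AR_HOM)
            if dn_recessive():
                models.add(GM.AR_HOM_DENOVO)
    return models


def _run(cg, fg, mg, f_aff, m_aff, child_sex=Sex.FEMALE, chrom="1"):
    ped = trio(
        father_status="affected" if f_aff else "unaffected",
        mother_status="affected" if m_aff else "unaffected",
        child_sex=child_sex,
    )
    v = mkvar(chrom=chrom, pos=5_000_000,
              genotypes=None)
    v.genotypes = {"child": cg, "father": fg, "mother": mg}
    return annotate_genetic_models(v, ped)


AUTOSOMAL_GTS = ["0/0", "0/1", "1/1"]


class TestModelAnnotation:
    def test_denovo_dominant_trio(self):
        """Affected child 0/1 with hom-ref parents: dominant, de novo."""
        models = _run(gt("0/1"), gt("0/0"), gt("0/0"), False, False)
        assert models == {GM.AD, GM.AD_DENOVO}

    def test_recessive_hom_trio(self):
        """Affected child 1/1 with carrier parents: recessive only."""
        models = _run(gt("1/1"), gt("0/1"), gt("0/1"), False, False)
        assert models == {GM.AR_HOM}

    @pytest.mark.parametrize("f_aff,m_aff", [(False, False), (True, False),
                                             (False, True), (True, True)])
    def test_exhaustive_autosomal_trio_matches_oracle(self, f_aff, m_aff):
        """All 27 genotype combinations, for every parental status pattern."""
        for c, f, m in itertools.product(AUTOSOMAL_GTS, repeat=3):
            cg, fg, mg = gt(c), gt(f), gt(m)
            got = _run(cg, fg, mg, f_aff, m_aff)
            want = oracle_trio_models(cg, fg, mg, f_aff, m_aff)
            assert got == want, f"child={c} father={f} mother={m} aff=({f_aff},{m_aff})"

    @pytest.mark.parametrize("f_aff,m_aff", [(False, False), (True, False)])
    def test_exhaustive_x_trio_matches_oracle(self, f_aff, m_aff):
        """X-linked enumeration with hemizygous males (son and daughter)."""
        for child_male in (True, False):
            child_gts = ["0", "1"] if child_male else AUTOSOMAL_GTS
            for c, f, m in itertools.product(child_gts, ["0", "1"], AUTOSOMAL_GTS):
                cg, fg, mg = gt(c), gt(f), gt(m)
                got = _run(cg, fg, mg, f_aff, m_aff,
                           child_sex=Sex.MALE if child_male else Sex.FEMALE,
                           chrom="X")
                want = oracle_trio_models(cg, fg, mg, f_aff, m_aff,
                                          child_male=child_male, x=True)
                assert got == want, (c, f, m, f_aff, m_aff, child_male)

    def test_missing_genotypes_are_permissive(self):
        """An ungenotyped parent cannot exclude AD, but blocks the de novo
        confirmation."""
        models = _run(gt("0/1"), gt("./."), gt("0/0"), False, False)
        assert GM.AD in models and GM.AD_DENOVO not in models

    def test_pseudoautosomal_region_is_autosomal(self):
        v = mkvar(chrom="X", pos=1_000_000,  # inside PAR1
                  genotypes={"child": "0/1", "father": "0/0", "mother": "0/0"})
        assert annotate_genetic_models(v, trio()) == {GM.AD, GM.AD_DENOVO}
        v2 = mkvar(chrom="X", pos=50_000_000,
                   genotypes={"child": "0/1", "father": "0", "mother": "0/0"})
        assert annotate_genetic_models(v2, trio()) == {GM.XD, GM.XD_DENOVO}

    def test_relaxed_mode_tolerates_unaffected_carriers(self):
        v = mkvar(genotypes={"child": "0/1", "father": "0/1", "mother": "0/0"})
        assert GM.AD not in annotate_genetic_models(v, trio())
        assert GM.AD in annotate_genetic_models(v, trio(), relaxed=True)

    def test_adding_unaffected_carrier_never_adds_models(self):
        """Monotone exclusion over random small families."""
        rng = random.Random(7)
        for _ in range(200):
            ped = trio()
            v = mkvar(genotypes={
                "child": rng.choice(AUTOSOMAL_GTS),
                "father": rng.choice(AUTOSOMAL_GTS),
                "mother": rng.choice(AUTOSOMAL_GTS),
            })
            before = annotate_genetic_models(v, ped)
            bigger = Pedigree(family_id="FAM1", members=ped.members + [
                Individual(id="sib", father_id="father", mother_id="mother",
                           status=AffectedStatus.UNAFFECTED)])
            v.genotypes["sib"] = gt("0/1")  # unaffected carrier
            after = annotate_genetic_models(v, bigger)
            assert after <= before


class TestPhasing:
    @pytest.mark.parametrize("father,mother,expected", [
        ("0/1", "0/0", ParentalOrigin.PATERNAL),
        ("0/0", "0/1", ParentalOrigin.MATERNAL),
        ("0/1", "0/1", ParentalOrigin.AMBIGUOUS),
        ("0/0", "0/0", ParentalOrigin.DENOVO),
        ("0/0", "./.", ParentalOrigin.AMBIGUOUS),
        ("0/0", "0/.", ParentalOrigin.AMBIGUOUS),
    ])
    def test_parental_origin(self, father, mother, expected):
        ped = trio()
        v = mkvar(genotypes={"child": "0/1", "father": father, "mother": mother})
        assert phase_by_pedigree(v, ped.get("child"), ped) is expected


# ---------------------------------------------------------------------------
# Compound heterozygotes


def oracle_pairs(variants, ped):
    """Brute-force all-pairs evaluation of the compound-het predicate."""

    def origin(v, ind):
        father, mother = ped.parents_of(ind)
        if father is None or mother is None:
            return ParentalOrigin.AMBIGUOUS
        fc = _carries(v.genotypes.get(father.id, gt("./.")))
        mc = _carries(v.genotypes.get(mother.id, gt("./.")))
        if fc is None or mc is None or (fc and mc):
            return ParentalOrigin.AMBIGUOUS
        if fc:
            return ParentalOrigin.PATERNAL
        if mc:
            return ParentalOrigin.MATERNAL
        if _refhom(v.genotypes[father.id]) and _refhom(v.genotypes[mother.id]):
            return ParentalOrigin.DENOVO
        return ParentalOrigin.AMBIGUOUS

    out = set()
    for a, b in itertools.combinations(variants, 2):
        ok = True
        for ind in ped.affected:
            for v in (a, b):
                g = v.genotypes.get(ind.id)
                if g is not None and not g.fully_missing and not g.is_het:
                    ok = False
            if not ok:
                break
            oa, ob = origin(a, ind), origin(b, ind)
            if ParentalOrigin.AMBIGUOUS not in (oa, ob) and oa == ob:
                ok = False  # same demonstrated origin: in cis (or both de novo)
                break
        if not ok:
            continue
        for ind in ped.unaffected:
            ga, gb = a.genotypes.get(ind.id), b.genotypes.get(ind.id)
            if ga is not None and gb is not None and _carries(ga) and _carries(gb):
                oa, ob = origin(a, ind), origin(b, ind)
                if ParentalOrigin.AMBIGUOUS not in (oa, ob) and oa != ob:
                    ok = False
                    break
        if ok:
            out.add(frozenset({a.key, b.key}))
    return out


class TestCompoundPairs:
    def test_canonical_trans_pair(self):
        ped = trio()
        v1 = mkvar(pos=100, genotypes={"child": "0/1", "father": "0/1", "mother": "0/0"})
        v2 = mkvar(pos=200, genotypes={"child": "0/1", "father": "0/0", "mother": "0/1"})
        pairs = find_compound_pairs([v1, v2], ped)
        assert set(pairs) == {frozenset({v1.key, v2.key})}
        assert pairs[frozenset({v1.key, v2.key})].phased

    def test_cis_pair_excluded(self):
        ped = trio()
        v1 = mkvar(pos=100, genotypes={"child": "0/1", "father": "0/1", "mother": "0/0"})
        v2 = mkvar(pos=200, genotypes={"child": "0/1", "father": "0/1", "mother": "0/0"})
        assert find_compound_pairs([v1, v2], ped) == {}

    def test_unphased_candidate_without_parents(self):
        ped = Pedigree(family_id="F", members=[
            Individual(id="child", status=AffectedStatus.AFFECTED)])
        v1 = mkvar(pos=100, genotypes={"child": "0/1"})
        v2 = mkvar(pos=200, genotypes={"child": "0/1"})
        pairs = find_compound_pairs([v1, v2], ped)
        (pair,) = pairs.values()
        assert not pair.phased

    def test_symmetry_under_input_order(self):
        rng = random.Random(3)
        ped = trio()
        vs = [mkvar(pos=100 + i, genotypes={
            "child": rng.choice(AUTOSOMAL_GTS),
            "father": rng.choice(AUTOSOMAL_GTS),
            "mother": rng.choice(AUTOSOMAL_GTS)}) for i in range(6)]
        forward = set(find_compound_pairs(vs, ped))
        backward = set(find_compound_pairs(list(reversed(vs)), ped))
        assert forward == backward

    def test_random_genes_match_bruteforce_oracle(self):
        rng = random.Random(42)
        ped = trio()
        gts = AUTOSOMAL_GTS + ["./."]
        for _ in range(300):
            n = rng.randint(2, 10)
            vs = [mkvar(pos=1000 + i, genotypes={
                "child": rng.choice(gts),
                "father": rng.choice(gts),
                "mother": rng.choice(gts)}) for i in range(n)]
            got = set(find_compound_pairs(vs, ped))
            assert got == oracle_pairs(vs, ped)
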