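"""Shared domain types for rank-based variant triage.

The unit of work throughout the package is a :class:`VariantRecord`: one
called variant, already decomposed to a single alternate allele, carrying
the external annotations (population frequency, predicted consequence,
ClinVar assertion, in-silico scores) that the filtering and scoring rules
consume.  Family structure is a :class:`Pedigree` of :class:`Individual`
members; inheritance-model annotation and compound-heterozygote phasing
are driven entirely by the genotypes stored on the record.

Annotations that are not present in the input are represented as ``None``
("absent"), never imputed to zero here; every consumer documents its own
absent-handling rule (for example the clinical filter treats an absent
population frequency as a novel, hence rare, variant).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

__all__ = [
    "VarType",
    "Impact",
    "ClinvarSig",
    "PanelMode",
    "Sex",
    "AffectedStatus",
    "Genotype",
    "AnnotationBundle",
    "VariantRecord",
    "Individual",
    "Pedigree",
    "GenePanel",
    "StrLocusConfig",
    "Case",
    "CaseValidationError",
    "consequence_severity_table",
    "impact_for_consequence",
    "variant_key",
    "chrom_sort_key",
    "validate_case",
]


class VarType(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    SV = "SV"
    STR = "STR"
    MEI = "MEI"


class Impact(str, enum.Enum):
    """VEP-style predicted impact, ordered from most to least severe."""

    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"

    @property
    def severity(self) -> int:
        """Numeric severity; higher is more damaging."""
        return {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}[self.value]


class ClinvarSig(str, enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    CONFLICTING = "conflicting"
    NONE = "none"


class PanelMode(str, enum.Enum):
    DOMINANT_PEDIATRIC = "dominant_pediatric"
    RECESSIVE = "recessive"
    MIXED = "mixed"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class AffectedStatus(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


# ---------------------------------------------------------------------------
# Genotypes


@dataclass(frozen=True)
class Genotype:
    """A per-individual genotype for a single alternate allele.

    ``alleles`` holds 0 (reference), 1 (this alt) or ``None`` (missing).
    A hemizygous call (male X/Y) carries one meaningful allele; the second
    slot is ``None`` and ``hemizygous`` is set.  Missing alleles propagate
    as "unknown" and are never read as reference.
    """

    alleles: tuple[Optional[int], Optional[int]]
    phased: bool = False
    hemizygous: bool = False

    def __post_init__(self) -> None:
        for a in self.alleles:
            if a not in (0, 1, None):
                raise ValueError(f"allele must be 0, 1 or missing, got {a!r}")
        if self.hemizygous and self.alleles[1] is not None:
            raise ValueError("hemizygous genotype carries a single allele")

    @property
    def known_alleles(self) -> tuple[int, ...]:
        return tuple(a for a in self.alleles if a is not None)

    @property
    def fully_missing(self) -> bool:
        return len(self.known_alleles) == 0

    @property
    def carries_alt(self) -> bool:
        """True iff the individual definitely carries >=1 alt allele."""
        return 1 in self.known_alleles

    @property
    def definitely_no_alt(self) -> bool:
        """True iff every expected allele is observed and reference."""
        n_expected = 1 if self.hemizygous else 2
        known = self.known_alleles
        return len(known) == n_expected and all(a == 0 for a in known)

    @property
    def is_hom_alt(self) -> bool:
        """Homozygous alt (or hemizygous alt), with no missing allele."""
        n_expected = 1 if self.hemizygous else 2
        known = self.known_alleles
        return len(known) == n_expected and all(a == 1 for a in known)

    @property
    def is_het(self) -> bool:
        return not self.hemizygous and sorted(self.known_alleles) == [0, 1]

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        if self.hemizygous:
            a = self.alleles[0]
            return "." if a is None else str(a)
        return sep.join("." if a is None else str(a) for a in self.alleles)


# ---------------------------------------------------------------------------
# Consequence severity table (shipped as package data)

_SEVERITY_CACHE: Optional[dict[str, tuple[int, Impact]]] = None


def consequence_severity_table() -> dict[str, tuple[int, Impact]]:
    """Ordered consequence severity table: term -> (rank, impact).

    Rank 0 is the most severe term.  The table ships as package data
    (``data/consequence_severity.tsv``) and follows the VEP convention.
    """
    global _SEVERITY_CACHE
    if _SEVERITY_CACHE is None:
        table: dict[str, tuple[int, Impact]] = {}
        text = (
            resources.files("ranktriage.data")
            .joinpath("consequence_severity.tsv")
            .read_text()
        )
        reader = csv.DictReader(
            (ln for ln in text.splitlines() if ln and not ln.startswith("#")),
            delimiter="\t",
        )
        for row in reader:
            table[row["consequence"]] = (int(row["rank"]), Impact(row["impact"]))
        _SEVERITY_CACHE = table
    return _SEVERITY_CACHE


def impact_for_consequence(consequence: str) -> Impact:
    """Impact class a consequence term maps to; MODIFIER for unknown terms."""
    entry = consequence_severity_table().get(consequence)
    return entry[1] if entry is not None else Impact.MODIFIER


# ---------------------------------------------------------------------------
# Annotations


@dataclass
class AnnotationBundle:
    """External annotations attached to one variant allele.

    Absent fields are ``None``.  ``distance_to_exon`` is a signed base-pair
    distance to the nearest exon boundary; 0 means exonic, a nonzero value
    means intronic (sign may encode up/downstream but only the magnitude is
    used by the splice rules).
    """

    consequence: Optional[str] = None
    impact: Optional[Impact] = None
    gnomad_af: Optional[float] = None
    gnomad_ac: Optional[int] = None
    gnomad_nhomalt: Optional[int] = None
    local_sv_freq: Optional[float] = None
    clinvar_sig: ClinvarSig = ClinvarSig.NONE
    clinvar_stars: int = 0
    cadd_phred: Optional[float] = None
    revel: Optional[float] = None
    spliceai_max: Optional[float] = None
    distance_to_exon: Optional[int] = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty == valid)."""
        problems: list[str] = []
        if self.gnomad_af is not None and not 0.0 <= self.gnomad_af <= 1.0:
            problems.append(f"gnomad_af out of [0,1]: {self.gnomad_af}")
        if self.local_sv_freq is not None and not 0.0 <= self.local_sv_freq <= 1.0:
            problems.append(f"local_sv_freq out of [0,1]: {self.local_sv_freq}")
        if self.gnomad_ac is not None and self.gnomad_ac < 0:
            problems.append(f"gnomad_ac negative: {self.gnomad_ac}")
        if self.gnomad_nhomalt is not None and self.gnomad_nhomalt < 0:
            problems.append(f"gnomad_nhomalt negative: {self.gnomad_nhomalt}")
        if (
            self.gnomad_ac is not None
            and self.gnomad_nhomalt is not None
            and self.gnomad_ac < self.gnomad_nhomalt
        ):
            problems.append("gnomad_ac < gnomad_nhomalt")
        if not 0 <= self.clinvar_stars <= 4:
            problems.append(f"clinvar_stars out of 0..4: {self.clinvar_stars}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            problems.append(f"cadd_phred negative: {self.cadd_phred}")
        for name in ("revel", "spliceai_max"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                problems.append(f"{name} out of [0,1]: {v}")
        if self.consequence is not None and self.impact is not None:
            expected = impact_for_consequence(self.consequence)
            if expected is not self.impact:
                problems.append(
                    f"impact {self.impact.value} inconsistent with consequence "
                    f"{self.consequence} (severity table says {expected.value})"
                )
        return problems

    @property
    def is_clinvar_pathogenic_starred(self) -> bool:
        """P/LP with at least one review star — the unconditional-retention class."""
        return self.clinvar_sig in (ClinvarSig.P, ClinvarSig.LP) and self.clinvar_stars >= 1


# ---------------------------------------------------------------------------
# Variants


@dataclass
class VariantRecord:
    """One called variant (single alt allele) with annotations and genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    var_type: VarType
    gene_ids: set[str] = field(default_factory=set)
    annotations: AnnotationBundle = field(default_factory=AnnotationBundle)
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    sv_end: Optional[int] = None
    str_repeat_count: Optional[int] = None

    @property
    def key(self) -> str:
        return variant_key(self)

    def validate(self) -> list[str]:
        problems: list[str] = []
        if self.pos < 1:
            problems.append(f"pos must be >= 1, got {self.pos}")
        if self.var_type is VarType.SNV and not (
            len(self.ref) == 1 and len(self.alt) == 1
        ):
            problems.append(f"SNV alleles must be single bases: {self.ref}>{self.alt}")
        if self.var_type is VarType.INDEL:
            if len(self.ref) == len(self.alt) or not self.ref or not self.alt:
                problems.append(
                    f"INDEL alleles must differ in length and be nonempty: "
                    f"{self.ref}>{self.alt}"
                )
        if self.sv_end is not None and self.sv_end < self.pos:
            problems.append(f"sv_end {self.sv_end} < pos {self.pos}")
        if self.var_type is VarType.STR and (
            self.str_repeat_count is not None and self.str_repeat_count < 0
        ):
            problems.append(f"str_repeat_count negative: {self.str_repeat_count}")
        problems.extend(self.annotations.validate())
        return problems


def variant_key(v: VariantRecord) -> str:
    """Stable identifier ``chrom:pos:ref:alt`` used for pairing and truth sets."""
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "MT": 25, "M": 25})


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Deterministic contig ordering: 1..22, X, Y, MT, then lexicographic."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    idx = _CHROM_ORDER.get(name.upper())
    return (idx, "") if idx is not None else (100, name)


def is_x_chromosome(chrom: str) -> bool:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name.upper() == "X"


# ---------------------------------------------------------------------------
# Pedigree


@dataclass
class Individual:
    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    status: AffectedStatus = AffectedStatus.UNKNOWN


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        self._by_id = {m.id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            raise ValueError("duplicate individual ids in pedigree")

    def get(self, individual_id: str) -> Optional[Individual]:
        return self._by_id.get(individual_id)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    @property
    def affected(self) -> list[Individual]:
        return [m for m in self.members if m.status is AffectedStatus.AFFECTED]

    @property
    def unaffected(self) -> list[Individual]:
        return [m for m in self.members if m.status is AffectedStatus.UNAFFECTED]

    def parents_of(self, individual: Individual) -> tuple[Optional[Individual], Optional[Individual]]:
        father = self.get(individual.father_id) if individual.father_id else None
        mother = self.get(individual.mother_id) if individual.mother_id else None
        return father, mother

    def validate(self) -> list[str]:
        problems: list[str] = []
        for m in self.members:
            for pid, role in ((m.father_id, "father"), (m.mother_id, "mother")):
                if pid is not None and pid not in self:
                    problems.append(f"{m.id}: {role} {pid!r} not in pedigree")
        problems.extend(self._cycle_check())
        if not self.affected:
            problems.append("pedigree has no affected member")
        return problems

    def _cycle_check(self) -> list[str]:
        # DFS over parent edges; an individual reachable from itself is a cycle
        problems = []
        for start in self.members:
            seen: set[str] = set()
            stack = [p.id for p in self.parents_of(start) if p is not None]
            while stack:
                cur = stack.pop()
                if cur == start.id:
                    problems.append(f"{start.id} is its own ancestor")
                    break
                if cur in seen:
                    continue
                seen.add(cur)
                ind = self.get(cur)
                if ind is not None:
                    stack.extend(p.id for p in self.parents_of(ind) if p is not None)
        return problems


# ---------------------------------------------------------------------------
# Panels and STR locus configuration


@dataclass
class GenePanel:
    """A named in-silico gene panel restricting interpretation by phenotype."""

    name: str
    version: str
    genes: set[str]
    mode: PanelMode = PanelMode.MIXED

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} has no genes")
        self.genes = {g.upper() for g in self.genes}

    @property
    def small_panel(self) -> bool:
        """Gene-specific phenotype panel (1-2 genes) triggering the
        rare-intronic rescue rule."""
        return len(self.genes) <= 2

    def contains(self, gene_ids: Iterable[str]) -> bool:
        return any(g.upper() in self.genes for g in gene_ids)


@dataclass
class StrLocusConfig:
    """Locus-specific repeat-count thresholds for STR classification.

    Boundaries are inclusive at each ``*_max``: a count equal to
    ``normal_max`` is still normal.
    """

    locus_id: str
    gene: str
    repeat_unit: str
    normal_max: int
    intermediate_max: int
    premutation_max: int

    def __post_init__(self) -> None:
        if not self.normal_max <= self.intermediate_max <= self.premutation_max:
            raise ValueError(
                f"locus {self.locus_id}: thresholds must satisfy "
                f"normal_max <= intermediate_max <= premutation_max, got "
                f"{self.normal_max}/{self.intermediate_max}/{self.premutation_max}"
            )


# ---------------------------------------------------------------------------
# Case container and validation


class CaseValidationError(ValueError):
    """Raised when a case fails cross-validation; carries every violation."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


@dataclass
class Case:
    """A validated (variants, pedigree) pair ready for analysis."""

    variants: list[VariantRecord]
    pedigree: Pedigree

    @property
    def case_id(self) -> str:
        return self.pedigree.family_id


def validate_case(variants: list[VariantRecord], pedigree: Pedigree) -> Case:
    """Cross-check variants against the pedigree and each record's invariants.

    Collects every violation (unresolved sample ids, pedigree cycles,
    malformed records) and raises :class:`CaseValidationError` listing all
    of them, rather than stopping at the first.
    """
    problems: list[str] = []
    problems.extend(pedigree.validate())
    for v in variants:
        for p in v.validate():
            problems.append(f"{variant_key(v)}: {p}")
        for sample_id in v.genotypes:
            if sample_id not in pedigree:
                problems.append(
                    f"{variant_key(v)}: genotyped sample {sample_id!r} "
                    f"absent from pedigree {pedigree.family_id!r}"
                )
    if problems:
        # de-duplicate while keeping order (sample-id errors repeat per record)
        seen: set[str] = set()
        unique = [p for p in problems if not (p in seen or seen.add(p))]
        raise CaseValidationError(unique)
    return Case(variants=variants, pedigree=pedigree)
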