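"""Declarative rank-model configuration.

The rank model is data, not code: a versioned TOML file declares an
ordered list of scoring categories, each a first-match-wins list of rules
mapping annotation (or inheritance-model) predicates to integer scores,
plus a mandatory fallback so every variant receives a score in every
category.  The engine in :mod:`ranktriage.ranking` evaluates the model; it
never hard-codes weights, so sites can version and evolve their model the
way a clinical lab versions its production scoring over time.

Rule conditions
---------------
Each rule carries a list of conditions (all must hold).  A condition is
``{field, op, value}`` where ``field`` is an annotation field
(``gnomad_af``, ``impact``, ``cadd_phred``, ``clinvar_sig``,
``clinvar_stars``, ``revel``, ``spliceai_max``, ``distance_to_exon``,
``consequence``) or the pseudo-field ``models`` (the set of inheritance
models), and ``op`` is one of ``lt le gt ge eq in absent present
contains_any``.  Absent annotation values fail every comparison operator
(only ``absent`` matches them), so a rule can never fire on imputed data.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

from .core import ClinvarSig, Impact
from .inheritance import GeneticModel

__all__ = [
    "RuleCondition",
    "ScoreRule",
    "CategoryConfig",
    "CompoundBonusRule",
    "RankModelConfig",
    "RankModelError",
    "load_rank_model",
    "default_rank_model",
]

_OPS = {"lt", "le", "gt", "ge", "eq", "in", "absent", "present", "contains_any"}

_FIELDS = {
    "gnomad_af",
    "gnomad_ac",
    "gnomad_nhomalt",
    "local_sv_freq",
    "impact",
    "consequence",
    "clinvar_sig",
    "clinvar_stars",
    "cadd_phred",
    "revel",
    "spliceai_max",
    "distance_to_exon",
    "models",
}


class RankModelError(ValueError):
    """Invalid rank-model configuration."""


@dataclass(frozen=True)
class RuleCondition:
    field: str
    op: str
    value: Any = None

    def __post_init__(self) -> None:
        if self.field not in _FIELDS:
            raise RankModelError(f"unknown rule field {self.field!r}")
        if self.op not in _OPS:
            raise RankModelError(f"unknown operator {self.op!r}")

    def evaluate(self, annotations, models: set[GeneticModel]) -> bool:
        if self.field == "models":
            names = {m.value for m in models}
            if self.op == "contains_any":
                return bool(names & set(self.value))
            if self.op == "absent":
                return not names
            raise RankModelError(f"op {self.op!r} not valid for field 'models'")
        actual = getattr(annotations, self.field)
        if isinstance(actual, Impact) or isinstance(actual, ClinvarSig):
            actual = actual.value
        if self.op == "absent":
            return actual is None or actual == ClinvarSig.NONE.value
        if self.op == "present":
            return actual is not None and actual != ClinvarSig.NONE.value
        if actual is None:
            return False  # absent values never satisfy a comparison
        if self.op == "lt":
            return actual < self.value
        if self.op == "le":
            return actual <= self.value
        if self.op == "gt":
            return actual > self.value
        if self.op == "ge":
            return actual >= self.value
        if self.op == "eq":
            return actual == self.value
        if self.op == "in":
            return actual in self.value
        raise AssertionError(self.op)


@dataclass(frozen=True)
class ScoreRule:
    id: str
    score: int
    conditions: tuple[RuleCondition, ...]

    def matches(self, annotations, models: set[GeneticModel]) -> bool:
        return all(c.evaluate(annotations, models) for c in self.conditions)


@dataclass(frozen=True)
class CategoryConfig:
    """One scoring category: ordered rules, mandatory fallback, score bounds.

    ``clinvar_rescue`` marks a category (typically frequency) whose negative
    scores are lifted to zero for ClinVar P/LP variants with >=1 review
    star, mirroring the filter-level unconditional-retention guarantee so
    that post-filter ordering cannot bury a known pathogenic variant.
    """

    name: str
    rules: tuple[ScoreRule, ...]
    fallback: int
    min_score: int
    max_score: int
    clinvar_rescue: bool = False

    def __post_init__(self) -> None:
        for r in (*self.rules,):
            if not self.min_score <= r.score <= self.max_score:
                raise RankModelError(
                    f"category {self.name!r}: rule {r.id!r} score {r.score} "
                    f"outside [{self.min_score}, {self.max_score}]"
                )
        if not self.min_score <= self.fallback <= self.max_score:
            raise RankModelError(
                f"category {self.name!r}: fallback {self.fallback} outside "
                f"[{self.min_score}, {self.max_score}]"
            )

    def score_for(self, annotations, models: set[GeneticModel]) -> tuple[int, str]:
        """(score, rule_id) of the first matching rule, else the fallback."""
        for rule in self.rules:
            if rule.matches(annotations, models):
                return rule.score, rule.id
        return self.fallback, "fallback"


@dataclass(frozen=True)
class CompoundBonusRule:
    """Compound-pair scoring: a step function of the weakest partner's
    pre-compound total.

    A paired variant receives ``full_bonus`` when the minimum of its
    partners' pre-compound totals reaches ``partner_threshold``, otherwise
    ``partial_bonus``; unpaired variants keep the compound category at its
    fallback.
    """

    partner_threshold: int
    full_bonus: int
    partial_bonus: int

    def __call__(self, min_partner_total: int) -> int:
        if min_partner_total >= self.partner_threshold:
            return self.full_bonus
        return self.partial_bonus


@dataclass(frozen=True)
class RankModelConfig:
    version: str
    categories: tuple[CategoryConfig, ...]
    compound_category: str
    compound_bonus: CompoundBonusRule

    def __post_init__(self) -> None:
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise RankModelError(f"duplicate category names: {names}")
        if self.compound_category not in names:
            raise RankModelError(
                f"compound category {self.compound_category!r} not configured"
            )
        comp = self.category(self.compound_category)
        for bonus in (self.compound_bonus.full_bonus, self.compound_bonus.partial_bonus):
            if not comp.min_score <= bonus <= comp.max_score:
                raise RankModelError(
                    f"compound bonus {bonus} outside category bounds "
                    f"[{comp.min_score}, {comp.max_score}]"
                )

    def category(self, name: str) -> CategoryConfig:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def category_names(self) -> list[str]:
        return [c.name for c in self.categories]


# ---------------------------------------------------------------------------
# TOML loading


def _parse_condition(raw: dict) -> RuleCondition:
    return RuleCondition(field=raw["field"], op=raw["op"], value=raw.get("value"))


def _parse_category(raw: dict) -> CategoryConfig:
    name = raw.get("name")
    if not name:
        raise RankModelError("category without a name")
    if "fallback" not in raw:
        raise RankModelError(f"category {name!r} lacks a fallback score")
    rules = []
    for r in raw.get("rule", []):
        conds = tuple(_parse_condition(c) for c in r.get("when", []))
        rules.append(ScoreRule(id=r["id"], score=int(r["score"]), conditions=conds))
    return CategoryConfig(
        name=name,
        rules=tuple(rules),
        fallback=int(raw["fallback"]),
        min_score=int(raw["min"]),
        max_score=int(raw["max"]),
        clinvar_rescue=bool(raw.get("clinvar_rescue", False)),
    )


def parse_rank_model(data: dict) -> RankModelConfig:
    if "version" not in data:
        raise RankModelError("rank model config missing mandatory 'version'")
    categories = tuple(_parse_category(c) for c in data.get("category", []))
    if not categories:
        raise RankModelError("rank model declares no categories")
    comp_raw = data.get("compound")
    if comp_raw is None:
        raise RankModelError("rank model missing [compound] section")
    bonus = CompoundBonusRule(
        partner_threshold=int(comp_raw["partner_threshold"]),
        full_bonus=int(comp_raw["full_bonus"]),
        partial_bonus=int(comp_raw["partial_bonus"]),
    )
    return RankModelConfig(
        version=str(data["version"]),
        categories=categories,
        compound_category=str(comp_raw.get("category", "compound")),
        compound_bonus=bonus,
    )


def load_rank_model(path: str | Path) -> RankModelConfig:
    """Read and validate a rank-model TOML file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return parse_rank_model(data)


_DEFAULT_CACHE: Optional[RankModelConfig] = None


def default_rank_model() -> RankModelConfig:
    """The shipped default model (version ``default-1``), loaded from
    package data."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        from importlib import resources

        raw = (
            resources.files("ranktriage.data")
            .joinpath("rank_model_default.toml")
            .read_bytes()
        )
        _DEFAULT_CACHE = parse_rank_model(tomllib.loads(raw.decode()))
    return _DEFAULT_CACHE
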