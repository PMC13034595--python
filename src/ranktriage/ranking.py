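"""Additive rank scoring, compound-pair adjustment and rank positions.

Every variant receives one integer score per configured category (the
first matching rule, or the category fallback); the total rank score is
their sum.  Compound-heterozygote candidates then have their ``compound``
category replaced by a bonus computed from the weakest partner's
pre-compound total, and totals are recomputed.  Finally variants are
ordered by descending total with a deterministic genomic-coordinate tie
break, and assigned dense 1-based rank positions (distinct positions even
for equal totals, so "rank 1" is always a single variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .core import VariantRecord, chrom_sort_key, variant_key
from .inheritance import GeneticModel
from .rankmodel import RankModelConfig

__all__ = ["RankedVariant", "score_variant", "score_compound_pairs", "rank_case"]


@dataclass
class RankedVariant:
    """A variant with per-category scores, total, models and rank position."""

    variant: VariantRecord
    category_scores: dict[str, int]
    rule_ids: dict[str, str]
    total_score: int
    genetic_models: set[GeneticModel] = field(default_factory=set)
    compound_partners: set[str] = field(default_factory=set)
    acmg_class: Optional[int] = None  # pass-through annotation, 1..5
    rank_position: Optional[int] = None

    @property
    def key(self) -> str:
        return variant_key(self.variant)


def score_variant(
    variant: VariantRecord,
    models: set[GeneticModel],
    config: RankModelConfig,
) -> RankedVariant:
    """Score one variant against every category of the rank model.

    Deterministic for fixed inputs.  The compound category is left at its
    fallback here; :func:`score_compound_pairs` fills it for paired
    variants.  Categories flagged ``clinvar_rescue`` never contribute a
    negative score for a ClinVar P/LP variant with >=1 review star.
    """
    scores: dict[str, int] = {}
    rule_ids: dict[str, str] = {}
    ann = variant.annotations
    for category in config.categories:
        score, rule_id = category.score_for(ann, models)
        if (
            category.clinvar_rescue
            and score < 0
            and ann.is_clinvar_pathogenic_starred
        ):
            score, rule_id = 0, "clinvar_rescue"
        scores[category.name] = score
        rule_ids[category.name] = rule_id
    return RankedVariant(
        variant=variant,
        category_scores=scores,
        rule_ids=rule_ids,
        total_score=sum(scores.values()),
        genetic_models=set(models),
    )


def score_compound_pairs(
    ranked: list[RankedVariant],
    pairs: set[frozenset[str]],
    config: RankModelConfig,
) -> list[RankedVariant]:
    """Apply compound-pair scoring and recompute totals.

    For each paired variant the compound category becomes
    ``compound_bonus(min over partners' pre-compound totals)``; unpaired
    variants keep the category fallback.  Paired variants also gain the
    AR_comp inheritance model (re-evaluating the inheritance category so a
    variant with no other compatible model is no longer penalised).
    Returns a new list; input order is preserved.
    """
    by_key = {rv.key: rv for rv in ranked}
    partners: dict[str, set[str]] = {k: set() for k in by_key}
    for pair in pairs:
        ka, kb = sorted(pair)
        if ka not in by_key or kb not in by_key:
            raise KeyError(f"compound pair references unknown variant: {pair}")
        partners[ka].add(kb)
        partners[kb].add(ka)

    comp_cat = config.compound_category
    # pre-compound totals exclude the compound category entirely
    pre_totals = {
        k: rv.total_score - rv.category_scores[comp_cat] for k, rv in by_key.items()
    }

    out: list[RankedVariant] = []
    for rv in ranked:
        my_partners = partners[rv.key]
        scores = dict(rv.category_scores)
        rule_ids = dict(rv.rule_ids)
        models = set(rv.genetic_models)
        if my_partners:
            models.add(GeneticModel.AR_COMP)
            inh = next(
                (c for c in config.categories if c.name == "inheritance"), None
            )
            if inh is not None:
                score, rule_id = inh.score_for(rv.variant.annotations, models)
                scores[inh.name] = score
                rule_ids[inh.name] = rule_id
            min_partner = min(pre_totals[p] for p in my_partners)
            scores[comp_cat] = config.compound_bonus(min_partner)
            rule_ids[comp_cat] = "compound_pair"
        out.append(
            replace(
                rv,
                category_scores=scores,
                rule_ids=rule_ids,
                genetic_models=models,
                compound_partners=set(my_partners),
                total_score=sum(scores.values()),
            )
        )
    return out


def _order_key(rv: RankedVariant):
    v = rv.variant
    return (-rv.total_score, chrom_sort_key(v.chrom), v.pos, v.ref, v.alt)


def rank_case(ranked: list[RankedVariant]) -> list[RankedVariant]:
    """Order by descending total score and assign rank positions 1..n.

    Ties are broken by genomic coordinate (contig order, position, ref,
    alt) so output is reproducible; positions are dense and unique.
    """
    ordered = sorted(ranked, key=_order_key)
    return [replace(rv, rank_position=i + 1) for i, rv in enumerate(ordered)]
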