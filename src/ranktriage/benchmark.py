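"""Rank-sensitivity benchmark: where does the known causative variant land?

For each truth case the harness applies the panel filter, the clinical
filter (with intronic splice assessment), inheritance-model annotation,
rank scoring with compound-pair adjustment, and ranking — then records
the rank position of the known causative variant among the survivors.  A
truth variant removed by a filter (or absent from the case VCF) is
reported as ``not_found`` with the removing rule id, never silently
dropped or imputed as a worst rank.

The summary statistics mirror the clinical evaluation convention: the
fraction ranked first, the median, the mean with a 95% confidence
half-width of 1.96 * SD / sqrt(n) (SD with the n-1 denominator), the
fraction ranked below a cutoff (the approximate limit of routine manual
assessment, default 50, read as rank position strictly greater than the
cutoff), and the maximum observed rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import Case, GenePanel, variant_key
from .filtering import (
    FilterSettings,
    DEFAULT_SETTINGS,
    clinical_filter,
    intronic_splice_assessment,
    panel_filter,
)
from .inheritance import annotate_genetic_models, find_compound_pairs
from .rankmodel import RankModelConfig
from .ranking import rank_case, score_compound_pairs, score_variant

__all__ = [
    "TruthEntry",
    "BenchmarkResult",
    "CaseRankOutcome",
    "benchmark_case",
    "summarize_ranks",
    "ci95_halfwidth",
]


@dataclass(frozen=True)
class TruthEntry:
    """One previously solved case: its causative variant key(s) and panel."""

    case_id: str
    variant_keys: tuple[str, ...]
    panel_name: str
    mode: str = "mixed"


@dataclass(frozen=True)
class CaseRankOutcome:
    case_id: str
    rank: Optional[int]  # None == not_found
    reason: str  # "ranked", "absent", or the removing rule id
    n_survivors: int = 0


@dataclass(frozen=True)
class BenchmarkResult:
    n_cases: int
    frac_rank1: float
    median_rank: float
    mean_rank: float
    sd_rank: float
    ci95_halfwidth: float
    frac_below_cutoff: float
    cutoff: int
    max_rank: int
    n_not_found: int = 0


def _removal_reason(decisions, truth_keys: set[str]) -> str:
    for d in decisions:
        if d.key in truth_keys and not d.passed:
            return ",".join(d.reasons)
    return "filtered"


def benchmark_case(
    case: Case,
    truth: TruthEntry,
    rank_model: RankModelConfig,
    panel: GenePanel,
    settings: FilterSettings = DEFAULT_SETTINGS,
) -> CaseRankOutcome:
    """Run the triage pipeline on one case and locate the truth variant.

    Pipeline order: panel filter -> clinical filter (with splice
    assessment) -> model annotation -> scoring (incl. compound pairs) ->
    ranking.  The reported rank is the best (smallest) rank position over
    the truth keys, computed within the survivor list.
    """
    truth_keys = set(truth.variant_keys)
    present = {variant_key(v) for v in case.variants}
    if not truth_keys & present:
        return CaseRankOutcome(truth.case_id, None, "absent")

    survivors, panel_decisions = panel_filter(case.variants, panel)
    if not truth_keys & {variant_key(v) for v in survivors}:
        return CaseRankOutcome(
            truth.case_id, None, _removal_reason(panel_decisions, truth_keys)
        )
    rescues, _ = intronic_splice_assessment(survivors, panel, settings)
    survivors, clin_decisions = clinical_filter(survivors, settings, rescues)
    if not truth_keys & {variant_key(v) for v in survivors}:
        return CaseRankOutcome(
            truth.case_id, None, _removal_reason(clin_decisions, truth_keys)
        )

    scored = [
        score_variant(v, annotate_genetic_models(v, case.pedigree), rank_model)
        for v in survivors
    ]
    by_gene: dict[str, list] = {}
    for v in survivors:
        for g in v.gene_ids:
            by_gene.setdefault(g, []).append(v)
    pairs: set[frozenset[str]] = set()
    for gene_variants in by_gene.values():
        if len(gene_variants) > 1:
            pairs.update(find_compound_pairs(gene_variants, case.pedigree))
    scored = score_compound_pairs(scored, pairs, rank_model)
    ranked = rank_case(scored)
    best = min(rv.rank_position for rv in ranked if rv.key in truth_keys)
    return CaseRankOutcome(truth.case_id, best, "ranked", n_survivors=len(ranked))


def ci95_halfwidth(sd: float, n: int) -> float:
    """95% confidence half-width for a mean: 1.96 * SD / sqrt(n)."""
    return 1.96 * sd / math.sqrt(n)


def summarize_ranks(ranks: Sequence[int], cutoff: int = 50) -> BenchmarkResult:
    """Summary statistics of truth-variant rank positions.

    ``frac_below_cutoff`` counts ranks numerically greater than the
    cutoff (i.e. listed below the manual-assessment line).  SD uses the
    n-1 denominator (0.0 for a single case).
    """
    if len(ranks) == 0:
        raise ValueError("no ranks to summarize")
    arr = np.asarray(ranks, dtype=float)
    n = arr.size
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return BenchmarkResult(
        n_cases=n,
        frac_rank1=float(np.count_nonzero(arr == 1) / n),
        median_rank=float(np.median(arr)),
        mean_rank=float(arr.mean()),
        sd_rank=sd,
        ci95_halfwidth=ci95_halfwidth(sd, n),
        frac_below_cutoff=float(np.count_nonzero(arr > cutoff) / n),
        cutoff=cutoff,
        max_rank=int(arr.max()),
    )
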