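"""Clinical, panel, frequency and intronic-splice filtering with provenance.

The clinical filter is the pre-review triage step: it retains variants of
moderate-to-high predicted impact, located in exonic or splice-proximal
regions, and below a strict population allele-frequency threshold (< 1%
in gnomAD for SNVs/INDELs; < 1% in the local count database for SVs, STRs
and MEIs).  Variants asserted Likely Pathogenic or Pathogenic in ClinVar
with at least one review star are retained unconditionally by every rule
here — no combination of filters can remove them.

Mode-specific frequency discard rules then apply the stricter clinical
thresholds: for dominant pediatric phenotypes (early onset, high
penetrance) a variant seen more than five times in gnomAD is discarded;
for recessive phenotypes, more than five gnomAD homozygotes.  "More than
five" is strict: a count of exactly 5 is retained, 6 is discarded.

The intronic splice assessment widens the clinical filter for potential
splice-altering variants: intronic variants within +/-20 bp of an exon
boundary with a SpliceAI score over threshold are rescued from the impact
requirement, and for small gene-specific panels (1-2 genes) every rare
(gnomAD AF < 0.001, absent counts as rare) intronic variant is rescued
regardless of distance.

Every decision carries rule ids so any ordering of the stages can be
audited; absent annotation values never cause a discard (a variant with
no frequency record is treated as novel, favouring sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    GenePanel,
    Impact,
    PanelMode,
    VariantRecord,
    VarType,
    variant_key,
)

__all__ = [
    "FilterDecision",
    "FilterSettings",
    "clinical_filter",
    "panel_filter",
    "frequency_discard",
    "intronic_splice_assessment",
]


@dataclass
class FilterDecision:
    """Outcome of one filter stage for one variant, with rule provenance."""

    key: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FilterSettings:
    """Tunable filter thresholds with their clinical defaults.

    ``af_cutoff`` is strict ("< 1%"): a variant at exactly the cutoff is
    removed.  ``splice_window`` is the +/- bp window around exon
    boundaries counted as splice-proximal.  ``rare_intronic_af`` bounds
    the small-panel rare-intronic rescue.
    """

    af_cutoff: float = 0.01
    splice_window: int = 20
    spliceai_threshold: float = 0.5
    rare_intronic_af: float = 0.001
    max_gnomad_ac: int = 5
    max_gnomad_nhomalt: int = 5


DEFAULT_SETTINGS = FilterSettings()


def _override(v: VariantRecord) -> bool:
    return v.annotations.is_clinvar_pathogenic_starred


def clinical_filter(
    variants: list[VariantRecord],
    settings: FilterSettings = DEFAULT_SETTINGS,
    splice_rescues: set[str] | None = None,
) -> tuple[list[VariantRecord], list[FilterDecision]]:
    """Apply the pre-review clinical filter.

    SNVs/INDELs survive iff impact is MODERATE or HIGH (or the variant was
    rescued by the splice assessment), the site is exonic or within the
    splice window, and gnomAD AF (absent = 0, novel) is below the cutoff.
    SVs/STRs/MEIs survive iff the local frequency is below the cutoff.
    Starred ClinVar P/LP variants survive unconditionally.
    """
    rescues = splice_rescues or set()
    survivors: list[VariantRecord] = []
    decisions: list[FilterDecision] = []
    for v in variants:
        key = variant_key(v)
        reasons: list[str] = []
        ann = v.annotations
        if _override(v):
            decisions.append(FilterDecision(key, True, ["clinvar_override"]))
            survivors.append(v)
            continue
        if v.var_type in (VarType.SV, VarType.STR, VarType.MEI):
            freq = ann.local_sv_freq if ann.local_sv_freq is not None else 0.0
            if freq >= settings.af_cutoff:
                reasons.append("sv_freq_fail")
        else:
            if ann.impact not in (Impact.MODERATE, Impact.HIGH):
                if key in rescues:
                    reasons.append("splice_rescue")
                else:
                    reasons.append("impact_fail")
            dist = ann.distance_to_exon
            if dist is not None and abs(dist) > settings.splice_window:
                if key in rescues:
                    if "splice_rescue" not in reasons:
                        reasons.append("splice_rescue")
                else:
                    reasons.append("region_fail")
            af = ann.gnomad_af if ann.gnomad_af is not None else 0.0
            if af >= settings.af_cutoff:
                reasons.append("af_fail")
        passed = not any(r.endswith("_fail") for r in reasons)
        decisions.append(FilterDecision(key, passed, reasons or ["clinical_pass"]))
        if passed:
            survivors.append(v)
    return survivors, decisions


def panel_filter(
    variants: list[VariantRecord], panel: GenePanel
) -> tuple[list[VariantRecord], list[FilterDecision]]:
    """Restrict to variants hitting at least one panel gene.

    Gene symbols are matched case-insensitively (both sides uppercased);
    a variant spanning several genes survives if any is on the panel.
    """
    if not panel.genes:
        raise ValueError(f"panel {panel.name!r} is empty")
    survivors: list[VariantRecord] = []
    decisions: list[FilterDecision] = []
    for v in variants:
        hit = panel.contains(v.gene_ids)
        decisions.append(
            FilterDecision(variant_key(v), hit, ["panel_hit" if hit else "panel_miss"])
        )
        if hit:
            survivors.append(v)
    return survivors, decisions


def frequency_discard(
    variants: list[VariantRecord],
    mode: PanelMode,
    settings: FilterSettings = DEFAULT_SETTINGS,
) -> tuple[list[VariantRecord], list[FilterDecision]]:
    """Mode-specific population-count discard rules.

    dominant_pediatric: discard iff gnomAD allele count > 5.
    recessive: discard iff gnomAD homozygote count > 5.
    mixed: the laxer (recessive) rule.  Absent counts never discard, and
    the starred ClinVar P/LP override applies here too.
    """
    survivors: list[VariantRecord] = []
    decisions: list[FilterDecision] = []
    for v in variants:
        key = variant_key(v)
        ann = v.annotations
        if _override(v):
            decisions.append(FilterDecision(key, True, ["clinvar_override"]))
            survivors.append(v)
            continue
        reasons: list[str] = []
        if mode is PanelMode.DOMINANT_PEDIATRIC:
            if ann.gnomad_ac is not None and ann.gnomad_ac > settings.max_gnomad_ac:
                reasons.append("freq_discard_dominant")
        else:  # recessive and mixed share the homozygote-count rule
            if (
                ann.gnomad_nhomalt is not None
                and ann.gnomad_nhomalt > settings.max_gnomad_nhomalt
            ):
                reasons.append("freq_discard_recessive")
        passed = not reasons
        decisions.append(FilterDecision(key, passed, reasons or ["freq_pass"]))
        if passed:
            survivors.append(v)
    return survivors, decisions


def intronic_splice_assessment(
    variants: list[VariantRecord],
    panel: GenePanel,
    settings: FilterSettings = DEFAULT_SETTINGS,
) -> tuple[set[str], list[FilterDecision]]:
    """Mark intronic variants that the clinical filter must not drop.

    Rescued: intronic variants within the splice window whose SpliceAI
    score reaches the threshold; on small (1-2 gene) panels additionally
    every rare intronic variant (gnomAD AF below ``rare_intronic_af``,
    absent = rare) at any distance.  Deep intronic ClinVar-starred P/LP
    variants are already covered by the unconditional override.
    """
    rescued: set[str] = set()
    decisions: list[FilterDecision] = []
    for v in variants:
        key = variant_key(v)
        ann = v.annotations
        dist = ann.distance_to_exon
        if dist is None or dist == 0:
            continue  # exonic or unannotated: not this assessment's business
        reasons: list[str] = []
        if (
            abs(dist) <= settings.splice_window
            and ann.spliceai_max is not None
            and ann.spliceai_max >= settings.spliceai_threshold
        ):
            reasons.append("splice_rescue")
        if panel.small_panel:
            af = ann.gnomad_af if ann.gnomad_af is not None else 0.0
            if af < settings.rare_intronic_af:
                reasons.append("small_panel_rare_intronic")
        if reasons:
            rescued.add(key)
            decisions.append(FilterDecision(key, True, reasons))
    return rescued, decisions
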