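"""End-to-end triage orchestration with provenance.

``run_triage`` wires the stages in their clinical order — validation,
panel filter, clinical filter (with intronic splice assessment),
mode-specific frequency discard, inheritance-model annotation, rank
scoring with compound pairs, ranking, output — and records a run
manifest: tool and rank-model versions, input checksums, and the
survivor count after every stage (a snapshot of what was available when
the case was triaged).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import __version__
from .core import Case, GenePanel, validate_case
from .filtering import (
    DEFAULT_SETTINGS,
    FilterSettings,
    clinical_filter,
    frequency_discard,
    intronic_splice_assessment,
    panel_filter,
)
from .inheritance import annotate_genetic_models, find_compound_pairs
from .io import (
    DEFAULT_INFO_MAP,
    InfoFieldMap,
    read_annotated_vcf,
    read_panel,
    read_pedigree,
    write_ranked_output,
)
from .rankmodel import RankModelConfig, default_rank_model, load_rank_model
from .ranking import RankedVariant, rank_case, score_compound_pairs, score_variant

__all__ = ["RunManifest", "run_triage", "triage_case"]

logger = logging.getLogger("ranktriage")

# documented exit-code classes for the CLI
EXIT_INPUT_ERROR = 2
EXIT_CONFIG_ERROR = 3
EXIT_INTERNAL_ERROR = 4


@dataclass
class RunManifest:
    tool_version: str
    rank_model_version: str
    panel_name: str
    panel_version: str
    family_id: str
    input_checksums: dict[str, str]
    stage_counts: dict[str, int]
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def triage_case(
    case: Case,
    panel: GenePanel,
    rank_model: RankModelConfig,
    settings: FilterSettings = DEFAULT_SETTINGS,
    apply_frequency_discard: bool = True,
) -> tuple[list[RankedVariant], dict[str, int], dict[str, list[str]]]:
    """Run the in-memory pipeline; returns (ranked survivors, stage
    counts, per-variant decision flags)."""
    counts: dict[str, int] = {"input": len(case.variants)}
    flags: dict[str, list[str]] = {}

    survivors, decisions = panel_filter(case.variants, panel)
    for d in decisions:
        flags.setdefault(d.key, []).extend(d.reasons)
    counts["panel_filter"] = len(survivors)

    rescues, rescue_decisions = intronic_splice_assessment(survivors, panel, settings)
    for d in rescue_decisions:
        flags.setdefault(d.key, []).extend(d.reasons)
    survivors, decisions = clinical_filter(survivors, settings, rescues)
    for d in decisions:
        flags.setdefault(d.key, []).extend(d.reasons)
    counts["clinical_filter"] = len(survivors)

    if apply_frequency_discard:
        survivors, decisions = frequency_discard(survivors, panel.mode, settings)
        for d in decisions:
            flags.setdefault(d.key, []).extend(d.reasons)
        counts["frequency_discard"] = len(survivors)

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
    counts["ranked"] = len(ranked)
    return ranked, counts, flags


def run_triage(
    vcf: str | Path,
    ped: str | Path,
    panel: str | Path,
    rank_model: Optional[str | Path] = None,
    out_prefix: str | Path = "triage",
    settings: FilterSettings = DEFAULT_SETTINGS,
    info_map: InfoFieldMap = DEFAULT_INFO_MAP,
) -> RunManifest:
    """File-level pipeline: read inputs, triage, write TSV + VCF + manifest."""
    model = load_rank_model(rank_model) if rank_model else default_rank_model()
    panel_obj = read_panel(panel)
    pedigree = read_pedigree(ped)
    variants = read_annotated_vcf(vcf, info_map)
    case = validate_case(variants, pedigree)
    logger.info(
        "triage %s: %d variants, panel %s (%d genes), rank model %s",
        pedigree.family_id,
        len(variants),
        panel_obj.name,
        len(panel_obj.genes),
        model.version,
    )

    ranked, counts, flags = triage_case(case, panel_obj, model, settings)
    if not ranked:
        logger.warning("no variants survived filtering; writing empty output")

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        tool_version=__version__,
        rank_model_version=model.version,
        panel_name=panel_obj.name,
        panel_version=panel_obj.version,
        family_id=pedigree.family_id,
        input_checksums={
            Path(p).name: _sha256(p) for p in (vcf, ped, panel)
        },
        stage_counts=counts,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(
            timespec="seconds"
        ),
    )
    header_comments = [
        f"tool_version={__version__}",
        f"rank_model_version={model.version}",
        f"panel={panel_obj.name}:{panel_obj.version}",
    ]
    write_ranked_output(
        ranked,
        tsv_path=out_prefix.with_suffix(".ranked.tsv"),
        vcf_path=out_prefix.with_suffix(".ranked.vcf"),
        family_id=pedigree.family_id,
        samples=[m.id for m in pedigree.members],
        info_map=info_map,
        header_comments=header_comments,
        decisions=flags,
    )
    out_prefix.with_suffix(".manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
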