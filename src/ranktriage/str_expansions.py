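"""STR allele classification against locus-specific repeat-count thresholds.

Short-read WGS repeat-count estimates (ExpansionHunter-style) are binned
per locus into normal / intermediate / premutation / full expansion.
Boundaries are inclusive at each threshold: a count equal to
``normal_max`` is still normal, one above ``premutation_max`` is a full
expansion.  The WGS estimate is not precise enough for clinical sizing,
so any premutation or full-expansion allele is flagged as requiring
orthogonal confirmation (PCR fragment analysis or Southern blot) and the
size is reported as estimate-only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from .core import StrLocusConfig

__all__ = ["StrClass", "StrCall", "classify_str", "flag_confirmation"]


class StrClass(str, enum.Enum):
    NORMAL = "normal"
    INTERMEDIATE = "intermediate"
    PREMUTATION = "premutation"
    FULL = "full"


_ORDER = [StrClass.NORMAL, StrClass.INTERMEDIATE, StrClass.PREMUTATION, StrClass.FULL]


@dataclass(frozen=True)
class StrCall:
    """Classified repeat-count estimates for the two alleles at one locus."""

    locus_id: str
    allele_repeat_counts: tuple[int, int]
    classifications: tuple[StrClass, StrClass]
    requires_confirmation: bool = False
    estimate_only: bool = True  # WGS sizing is never reported as exact


def classify_str(count: int, locus: StrLocusConfig) -> StrClass:
    """Classify one repeat-count estimate against locus thresholds.

    Partitions the nonnegative integers: normal iff count <= normal_max;
    intermediate iff normal_max < count <= intermediate_max; premutation
    iff intermediate_max < count <= premutation_max; full otherwise.
    Collapsed zones (equal consecutive thresholds) make the corresponding
    class unreachable.
    """
    if count < 0:
        raise ValueError(f"repeat count must be >= 0, got {count}")
    if count <= locus.normal_max:
        return StrClass.NORMAL
    if count <= locus.intermediate_max:
        return StrClass.INTERMEDIATE
    if count <= locus.premutation_max:
        return StrClass.PREMUTATION
    return StrClass.FULL


def classify_call(
    locus: StrLocusConfig, allele_counts: tuple[int, int]
) -> StrCall:
    """Classify both alleles and set the confirmation flag."""
    classes = tuple(classify_str(c, locus) for c in allele_counts)
    call = StrCall(
        locus_id=locus.locus_id,
        allele_repeat_counts=tuple(allele_counts),
        classifications=classes,  # type: ignore[arg-type]
    )
    return flag_confirmation(call)


def flag_confirmation(call: StrCall) -> StrCall:
    """Flag clinically relevant expansions for orthogonal confirmation.

    Premutation and full-expansion alleles must be confirmed and sized by
    an orthogonal method before reporting; normal and intermediate
    alleles need no confirmation.
    """
    needs = any(
        c in (StrClass.PREMUTATION, StrClass.FULL) for c in call.classifications
    )
    return replace(call, requires_confirmation=needs, estimate_only=True)
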