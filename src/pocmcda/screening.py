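"""Satisfice ("deal-breaker") screening.

Two distinct mechanisms share this module:

* **Pre-scoring exclusion** — options struck from the candidate list by an
  explicit decision (e.g. a stakeholder workshop agreeing that a use case
  meets a deal-breaker).  These arrive as a list of option ids; the basis
  for the decision is not recomputed.

* **Per-cell satisfice flags** — during scoring, each option x criterion
  mean rating is compared against the criterion's satisfice threshold.  A
  flagged option is still scored and totalled, but marked ineligible.

Satisfice is evaluated on the *mean* rating with a threshold comparison at
full precision, not on the rounded category: a low-tail rule with
threshold 2 is met by a mean of 1.69 but not by 2.15, even though both
round to category 2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import Option, RatingScale, SatisficeRule, SatisficeTail, classify_satisfice

__all__ = ["ExclusionReason", "ExclusionRecord", "apply_exclusions", "satisfice_met"]


class ExclusionReason(str, enum.Enum):
    NAMED_DECISION = "named_decision"
    SATISFICE_MEAN = "satisfice_mean"


@dataclass(frozen=True)
class ExclusionRecord:
    option_id: str
    reason: ExclusionReason
    criterion_id: Optional[str] = None
    detail: str = ""


def apply_exclusions(
    options: Sequence[Option], excluded_ids: Iterable[str]
) -> tuple[tuple[Option, ...], tuple[ExclusionRecord, ...]]:
    """Remove the named options, preserving order; record each exclusion.

    Raises ``KeyError`` naming any id not present among the options.
    """
    known = {o.id for o in options}
    excluded = list(excluded_ids)
    unknown = [oid for oid in excluded if oid not in known]
    if unknown:
        raise KeyError(f"unknown option id(s) in exclusion list: {unknown}")
    excluded_set = set(excluded)
    survivors = tuple(o for o in options if o.id not in excluded_set)
    records = tuple(
        ExclusionRecord(
            option_id=oid,
            reason=ExclusionReason.NAMED_DECISION,
            detail="excluded before scoring by named decision",
        )
        for oid in dict.fromkeys(excluded)  # de-duplicate, keep order
    )
    return survivors, records


def satisfice_met(mean_rating: float, rule: SatisficeRule, scale: RatingScale) -> bool:
    """Does a mean rating fall in the rule's excluded tail of the scale?

    Low tail: met iff mean <= threshold.  High tail: met iff mean >=
    threshold.  No rule: never met.  Comparison at full precision.

    Raises ``ValueError`` if the mean lies outside the scale bounds.
    """
    if not (scale.min_code <= mean_rating <= scale.max_code):
        raise ValueError(
            f"mean rating {mean_rating} outside scale bounds "
            f"[{scale.min_code}, {scale.max_code}]"
        )
    tail, threshold = classify_satisfice(rule, scale)
    if tail is SatisficeTail.NONE:
        return False
    if tail is SatisficeTail.LOW:
        return mean_rating <= threshold
    return mean_rating >= threshold
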