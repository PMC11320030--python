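"""Domain types for a weighted-sum multiple-criteria decision analysis.

The decision problem is described by a :class:`DecisionConfig`: an ordered
set of criteria (each with an ordinal rating scale, a non-negative weight
and an optional satisfice rule) and an ordered set of options to be scored
against them.

A *satisfice* rule marks a "deal-breaker" region of a criterion's rating
scale: an option whose panel-mean rating falls in that region is flagged as
ineligible for further consideration regardless of its total score.  Rules
are stored as the set of excluded scale codes and interpreted as a
contiguous *tail* of the scale (either the low end or the high end),
reduced to a single threshold for comparison against real-valued means.

Invariant checking is split in two: construction through pydantic enforces
only structural typing, while :func:`validate_config` returns a list of
human-readable diagnostics for every violated domain invariant, so that a
configuration file can be fully linted in one pass instead of failing on
the first error.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict

__all__ = [
    "RatingScale",
    "SatisficeRule",
    "SatisficeTail",
    "SatisficeTailError",
    "ImportanceSummary",
    "Criterion",
    "Option",
    "DecisionConfig",
    "validate_config",
    "classify_satisfice",
]


class SatisficeTail(str, enum.Enum):
    """Which end of the rating scale a satisfice rule excludes."""

    LOW = "low"
    HIGH = "high"
    NONE = "none"


class SatisficeTailError(ValueError):
    """Raised when an excluded-code set is not a contiguous tail of its scale."""


class RatingScale(BaseModel):
    """An ordered ordinal scale: (integer code, text label) pairs.

    Codes need not be consecutive — e.g. a call-volume scale printed with
    levels 0, 1, 3, 4 is stored verbatim — but must be strictly increasing.
    """

    model_config = ConfigDict(frozen=True)

    levels: tuple[tuple[int, str], ...]

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(code for code, _ in self.levels)

    @property
    def min_code(self) -> int:
        return self.levels[0][0]

    @property
    def max_code(self) -> int:
        return self.levels[-1][0]

    def label(self, code: int) -> str:
        for c, lab in self.levels:
            if c == code:
                return lab
        raise KeyError(f"code {code} not on scale")


class SatisficeRule(BaseModel):
    """Deal-breaker rule: the set of scale codes that exclude an option."""

    model_config = ConfigDict(frozen=True)

    excluded_codes: frozenset[int] = frozenset()

    @property
    def is_empty(self) -> bool:
        return not self.excluded_codes


class ImportanceSummary(BaseModel):
    """Summary statistics of a criterion's importance-survey scores."""

    model_config = ConfigDict(frozen=True)

    mean: float
    median: float
    minimum: int
    maximum: int
    n_respondents: int


class Criterion(BaseModel):
    """A scoring dimension: rating scale, weight and optional satisfice rule.

    ``weight`` is the multiplier applied to the panel-mean rating; in the
    survey-driven workflow it equals the mean importance score (0-10 scale)
    elicited from stakeholders, used raw (not normalised to sum to one).
    """

    model_config = ConfigDict(frozen=True)

    id: str
    description: str = ""
    scale: RatingScale
    weight: float = 0.0
    weight_summary: Optional[ImportanceSummary] = None
    satisfice: SatisficeRule = SatisficeRule()


class Option(BaseModel):
    """A candidate to be scored, e.g. a clinical use case for a POC test."""

    model_config = ConfigDict(frozen=True)

    id: str
    label: str = ""
    pre_excluded: bool = False


class DecisionConfig(BaseModel):
    """A complete decision problem: criteria, options and display settings."""

    criteria: tuple[Criterion, ...]
    options: tuple[Option, ...]
    rounding_dp: int = 2
    top_k: int = 3
    excluded_option_ids: tuple[str, ...] = ()

    def criterion(self, cid: str) -> Criterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise KeyError(f"unknown criterion {cid!r}")

    def option(self, oid: str) -> Option:
        for o in self.options:
            if o.id == oid:
                return o
        raise KeyError(f"unknown option {oid!r}")

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    @property
    def option_ids(self) -> tuple[str, ...]:
        return tuple(o.id for o in self.options)


def classify_satisfice(
    rule: SatisficeRule, scale: RatingScale
) -> tuple[SatisficeTail, Optional[int]]:
    """Reduce an excluded-code set to a (tail, threshold) pair.

    A set containing the scale minimum (but not the maximum) is a *low*
    tail with threshold ``max(set)``: means at or below the threshold meet
    the rule.  A set containing the maximum (but not the minimum) is a
    *high* tail with threshold ``min(set)``.  The empty set is ``NONE``.

    Raises
    ------
    SatisficeTailError
        If the set is not a contiguous run of scale levels, touches both
        ends of the scale, or touches neither — such rules cannot be
        expressed as a single threshold and the configuration must state
        the intended tail explicitly.
    ValueError
        If the set contains codes not on the scale.
    """
    if rule.is_empty:
        return SatisficeTail.NONE, None
    codes = scale.codes
    stray = rule.excluded_codes - set(codes)
    if stray:
        raise ValueError(
            f"satisfice codes {sorted(stray)} are not levels of the scale {list(codes)}"
        )
    idx = sorted(codes.index(c) for c in rule.excluded_codes)
    contiguous = idx[-1] - idx[0] + 1 == len(idx)
    has_min = codes[0] in rule.excluded_codes
    has_max = codes[-1] in rule.excluded_codes
    if not contiguous or (has_min and has_max) or not (has_min or has_max):
        raise SatisficeTailError(
            "ambiguous satisfice tail: excluded codes "
            f"{sorted(rule.excluded_codes)} are not a contiguous tail of the scale"
        )
    if has_min:
        return SatisficeTail.LOW, max(rule.excluded_codes)
    return SatisficeTail.HIGH, min(rule.excluded_codes)


def _check_scale(prefix: str, scale: RatingScale, out: list[str]) -> None:
    codes = scale.codes
    if len(codes) < 2:
        out.append(f"{prefix}: rating scale must have at least 2 levels, has {len(codes)}")
    if any(a >= b for a, b in zip(codes, codes[1:])):
        out.append(f"{prefix}: rating scale codes {list(codes)} are not strictly increasing")


def _check_summary(prefix: str, s: ImportanceSummary, out: list[str]) -> None:
    if s.n_respondents < 1:
        out.append(f"{prefix}: importance summary has n_respondents={s.n_respondents} < 1")
    if not (s.minimum <= s.median <= s.maximum):
        out.append(
            f"{prefix}: importance median {s.median} outside [{s.minimum}, {s.maximum}]"
        )
    if not (s.minimum <= s.mean <= s.maximum):
        out.append(f"{prefix}: importance mean {s.mean} outside [{s.minimum}, {s.maximum}]")


def validate_config(cfg: DecisionConfig) -> list[str]:
    """Check every domain invariant; return one diagnostic per violation.

    An empty list means the configuration is valid.  Diagnostics name the
    offending criterion/option so a configuration file can be fixed in one
    round trip.
    """
    diags: list[str] = []
    if not cfg.criteria:
        diags.append("config: at least one criterion is required")
    if not cfg.options:
        diags.append("config: at least one option is required")

    seen: set[str] = set()
    for c in cfg.criteria:
        if c.id in seen:
            diags.append(f"criterion {c.id!r}: duplicate id")
        seen.add(c.id)
        _check_scale(f"criterion {c.id!r}", c.scale, diags)
        if not math.isfinite(c.weight):
            diags.append(f"criterion {c.id!r}: weight {c.weight} is not finite")
        elif c.weight < 0:
            diags.append(f"criterion {c.id!r}: weight {c.weight} is negative")
        if c.weight_summary is not None:
            _check_summary(f"criterion {c.id!r}", c.weight_summary, diags)
        stray = c.satisfice.excluded_codes - set(c.scale.codes)
        if stray:
            diags.append(
                f"criterion {c.id!r}: satisfice codes {sorted(stray)} not on its scale"
            )
        elif not c.satisfice.is_empty:
            try:
                classify_satisfice(c.satisfice, c.scale)
            except SatisficeTailError as e:
                diags.append(f"criterion {c.id!r}: {e}")

    seen = set()
    for o in cfg.options:
        if o.id in seen:
            diags.append(f"option {o.id!r}: duplicate id")
        seen.add(o.id)

    unknown = set(cfg.excluded_option_ids) - set(cfg.option_ids)
    for oid in sorted(unknown):
        diags.append(f"excluded option {oid!r}: not among the configured options")

    if cfg.rounding_dp < 0:
        diags.append(f"config: rounding_dp {cfg.rounding_dp} is negative")
    if cfg.top_k < 1:
        diags.append(f"config: top_k {cfg.top_k} must be >= 1")
    return diags
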