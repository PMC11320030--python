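"""Criterion weight elicitation from importance-survey responses.

Stakeholders score each criterion's importance on an 11-point (0-10)
scale.  The per-criterion arithmetic mean of those scores becomes the
criterion weight used by the scoring engine; median, minimum, maximum and
respondent count are reported alongside for transparency but play no role
downstream.  Respondents may skip questions, so per-criterion counts can
differ; summaries are computed over the responses actually present.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .model import Criterion, ImportanceSummary

__all__ = [
    "IMPORTANCE_COLUMNS",
    "validate_importance",
    "summarize_importance",
    "summarize_all",
    "assign_weights",
]

IMPORTANCE_COLUMNS = ("stakeholder", "criterion", "score")

#: Bounds of the importance scale (11 points, 0..10).
IMPORTANCE_MIN, IMPORTANCE_MAX = 0, 10


def validate_importance(responses: pd.DataFrame) -> list[str]:
    """Lint an importance-response table; return one diagnostic per violation."""
    diags: list[str] = []
    missing = [c for c in IMPORTANCE_COLUMNS if c not in responses.columns]
    if missing:
        return [f"importance table: missing column(s) {missing}"]
    bad = responses[
        (responses["score"] < IMPORTANCE_MIN) | (responses["score"] > IMPORTANCE_MAX)
    ]
    for row in bad.itertuples():
        diags.append(
            f"importance row {row.Index}: score {row.score} outside "
            f"[{IMPORTANCE_MIN}, {IMPORTANCE_MAX}]"
        )
    dup = responses.duplicated(subset=["stakeholder", "criterion"], keep=False)
    for idx in responses.index[dup]:
        row = responses.loc[idx]
        diags.append(
            f"importance row {idx}: duplicate response by {row['stakeholder']!r} "
            f"for criterion {row['criterion']!r}"
        )
    return diags


def summarize_importance(responses: pd.DataFrame, criterion: str) -> ImportanceSummary:
    """Mean/median/min/max/n of one criterion's importance scores.

    The median for an even number of responses is the midpoint of the two
    central values.  Raises ``ValueError`` if the criterion has no
    responses.
    """
    scores = responses.loc[responses["criterion"] == criterion, "score"]
    if scores.empty:
        raise ValueError(f"no responses for criterion {criterion!r}")
    return ImportanceSummary(
        mean=float(scores.mean()),
        median=float(scores.median()),
        minimum=int(scores.min()),
        maximum=int(scores.max()),
        n_respondents=int(scores.shape[0]),
    )


def summarize_all(responses: pd.DataFrame) -> dict[str, ImportanceSummary]:
    """Summaries for every criterion that appears in the response table."""
    return {
        cid: summarize_importance(responses, cid)
        for cid in pd.unique(responses["criterion"])
    }


def assign_weights(
    criteria: Iterable[Criterion], summaries: Mapping[str, ImportanceSummary]
) -> tuple[Criterion, ...]:
    """Set each criterion's weight to its mean importance, at full precision.

    Raises ``KeyError`` naming the first criterion without a summary.
    """
    out: list[Criterion] = []
    for c in criteria:
        if c.id not in summaries:
            raise KeyError(f"no importance summary for criterion {c.id!r}")
        s = summaries[c.id]
        out.append(c.model_copy(update={"weight": s.mean, "weight_summary": s}))
    return tuple(out)
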