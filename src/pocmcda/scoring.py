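"""Weighted-sum scoring engine.

Votes are ordinal scores cast by stakeholders for each option x criterion
cell.  The cell statistic is the arithmetic mean of the votes present
(participation may vary per cell), the weighted score is

    f_{o,c} = w_c * s_{o,c}

and an option's total is T_o = sum_c f_{o,c}.  Options are ranked by
descending total; ties keep input order and are annotated.  All arithmetic
is at full floating-point precision — rounding is display-only.

The engine never drops an option for meeting a satisfice rule: the flag is
carried on the cell and the option is marked ineligible, so the full
matrix remains inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import DecisionConfig
from .screening import satisfice_met

__all__ = [
    "VOTE_COLUMNS",
    "validate_votes",
    "mean_rating",
    "weighted_score",
    "total_score",
    "rank_options",
    "build_matrix",
    "matrix_from_means",
    "ScoringMatrix",
]

VOTE_COLUMNS = ("stakeholder", "option", "criterion", "score")


def validate_votes(votes: pd.DataFrame, cfg: DecisionConfig) -> list[str]:
    """Lint a long-format vote table against a configuration.

    Checks column presence, option/criterion ids, that every score is a
    valid code of its criterion's scale, and uniqueness of
    (stakeholder, option, criterion).  Returns one diagnostic per
    violation, citing the row index.
    """
    diags: list[str] = []
    missing = [c for c in VOTE_COLUMNS if c not in votes.columns]
    if missing:
        return [f"vote table: missing column(s) {missing}"]

    known_opts = set(cfg.option_ids)
    codes_by_crit = {c.id: set(c.scale.codes) for c in cfg.criteria}
    for row in votes.itertuples():
        if row.option not in known_opts:
            diags.append(f"vote row {row.Index}: unknown option {row.option!r}")
        if row.criterion not in codes_by_crit:
            diags.append(f"vote row {row.Index}: unknown criterion {row.criterion!r}")
        elif row.score not in codes_by_crit[row.criterion]:
            diags.append(
                f"vote row {row.Index}: score {row.score} is not a level of "
                f"criterion {row.criterion!r}"
            )
    dup = votes.duplicated(subset=["stakeholder", "option", "criterion"], keep=False)
    for idx in votes.index[dup]:
        r = votes.loc[idx]
        diags.append(
            f"vote row {idx}: duplicate vote by {r['stakeholder']!r} on "
            f"({r['option']!r}, {r['criterion']!r})"
        )
    return diags


def mean_rating(votes: pd.DataFrame, option: str, criterion: str) -> float:
    """Arithmetic mean of the votes present for one option x criterion cell.

    Raises ``ValueError`` if the cell has no votes.
    """
    cell = votes.loc[
        (votes["option"] == option) & (votes["criterion"] == criterion), "score"
    ]
    if cell.empty:
        raise ValueError(f"no votes for option {option!r} x criterion {criterion!r}")
    return float(cell.mean())


def weighted_score(weight: float, mean: float) -> float:
    """Product of criterion weight and mean rating, at full precision."""
    if weight < 0:
        raise ValueError(f"negative weight {weight}")
    return weight * mean


def total_score(weighted: Sequence[float], n_criteria: Optional[int] = None) -> float:
    """Sum of per-criterion weighted scores for one option.

    If ``n_criteria`` is given, the length of ``weighted`` must match it.
    """
    if n_criteria is not None and len(weighted) != n_criteria:
        raise ValueError(
            f"expected {n_criteria} weighted scores, got {len(weighted)}"
        )
    return float(sum(weighted))


def rank_options(totals: Mapping[str, float], k: int = 3) -> pd.DataFrame:
    """Rank options by descending total; stable tie-break by input order.

    Returns a DataFrame indexed 0..n-1 in rank order with columns
    ``option``, ``total``, ``rank`` (1-based), ``tied`` (shares its total
    with another option) and ``top_k``.
    """
    items = list(totals.items())
    order = sorted(range(len(items)), key=lambda i: -items[i][1])
    counts: dict[float, int] = {}
    for _, t in items:
        counts[t] = counts.get(t, 0) + 1
    rows = []
    for rank0, i in enumerate(order):
        oid, t = items[i]
        rows.append(
            {
                "option": oid,
                "total": t,
                "rank": rank0 + 1,
                "tied": counts[t] > 1,
                "top_k": rank0 < k,
            }
        )
    return pd.DataFrame(rows, columns=["option", "total", "rank", "tied", "top_k"])


@dataclass
class ScoringMatrix:
    """The full option x criterion scoring result.

    ``cells`` is long-format with one row per (option, criterion):
    mean rating, number of votes, satisfice flag, weighted score.
    ``options`` has one row per option in rank order: total, rank, tie
    flag, eligibility (no satisfice rule met) and top-k membership.
    """

    cells: pd.DataFrame
    options: pd.DataFrame
    config: DecisionConfig = field(repr=False)

    @property
    def top_k_ids(self) -> tuple[str, ...]:
        sel = self.options.loc[self.options["top_k"], "option"]
        return tuple(sel.tolist())

    def total(self, option: str) -> float:
        row = self.options.loc[self.options["option"] == option, "total"]
        if row.empty:
            raise KeyError(f"unknown option {option!r}")
        return float(row.iloc[0])


def _assemble(
    cfg: DecisionConfig,
    cell_rows: list[dict],
) -> ScoringMatrix:
    cells = pd.DataFrame(
        cell_rows,
        columns=["option", "criterion", "mean", "n_votes", "satisfice_met", "weighted"],
    )
    totals: dict[str, float] = {}
    for oid in cfg.option_ids:
        w = cells.loc[cells["option"] == oid, "weighted"]
        totals[oid] = total_score(w.tolist(), n_criteria=len(cfg.criteria))
    ranked = rank_options(totals, k=cfg.top_k)
    met_by_opt = cells.groupby("option")["satisfice_met"].any()
    ranked["eligible"] = [not met_by_opt[oid] for oid in ranked["option"]]
    return ScoringMatrix(cells=cells, options=ranked, config=cfg)


def build_matrix(cfg: DecisionConfig, votes: pd.DataFrame) -> ScoringMatrix:
    """Aggregate a vote table into the weighted scoring matrix.

    Every (option, criterion) cell must have at least one vote; a missing
    cell raises ``ValueError`` naming it (via :func:`mean_rating`).
    """
    problems = validate_votes(votes, cfg)
    if problems:
        raise ValueError("invalid vote table:\n" + "\n".join(problems))
    rows = []
    for o in cfg.options:
        for c in cfg.criteria:
            m = mean_rating(votes, o.id, c.id)
            n = int(
                (
                    (votes["option"] == o.id) & (votes["criterion"] == c.id)
                ).sum()
            )
            rows.append(
                {
                    "option": o.id,
                    "criterion": c.id,
                    "mean": m,
                    "n_votes": n,
                    "satisfice_met": satisfice_met(m, c.satisfice, c.scale),
                    "weighted": weighted_score(c.weight, m),
                }
            )
    return _assemble(cfg, rows)


def matrix_from_means(cfg: DecisionConfig, means: pd.DataFrame) -> ScoringMatrix:
    """Build a scoring matrix from pre-aggregated cell means.

    ``means`` is long-format with columns ``option``, ``criterion``,
    ``mean`` and optionally ``n_votes``.  Used to re-score published
    matrices for which only the cell means survive.
    """
    means = means.set_index(["option", "criterion"])
    rows = []
    for o in cfg.options:
        for c in cfg.criteria:
            try:
                rec = means.loc[(o.id, c.id)]
            except KeyError:
                raise ValueError(
                    f"no mean supplied for option {o.id!r} x criterion {c.id!r}"
                ) from None
            m = float(rec["mean"])
            n = int(rec["n_votes"]) if "n_votes" in rec.index and pd.notna(rec.get("n_votes")) else 0
            rows.append(
                {
                    "option": o.id,
                    "criterion": c.id,
                    "mean": m,
                    "n_votes": n,
                    "satisfice_met": satisfice_met(m, c.satisfice, c.scale),
                    "weighted": weighted_score(c.weight, m),
                }
            )
    return _assemble(cfg, rows)
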