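"""Consistency checking of published (printed) scoring matrices.

A printed matrix shows rounded weights, rounded cell means, rounded
weighted scores and rounded totals.  Because the underlying arithmetic was
done at full precision, a printed weighted score can differ from
``printed_weight x printed_mean`` by up to the rounding slack — but no
more.  This module checks each cell and each total against that slack and
reports every violation, including the *implied multiplier*
(printed score / printed mean) for a suspect cell, which often reveals
that a different weight was actually applied than the one printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .model import DecisionConfig

__all__ = ["Discrepancy", "verify_printed_matrix"]


@dataclass(frozen=True)
class Discrepancy:
    """One internal inconsistency found in a printed matrix."""

    kind: str  # "cell" or "total"
    option_id: str
    criterion_id: Optional[str]
    printed: float
    expected: float
    tolerance: float
    implied_multiplier: Optional[float] = None

    def __str__(self) -> str:  # human-readable, used in reports
        where = (
            f"{self.option_id} x {self.criterion_id}"
            if self.criterion_id
            else self.option_id
        )
        msg = (
            f"{self.kind} {where}: printed {self.printed} vs expected "
            f"{self.expected:.4f} (tolerance {self.tolerance:.4f})"
        )
        if self.implied_multiplier is not None:
            msg += f"; implied multiplier {self.implied_multiplier:.2f}"
        return msg


def verify_printed_matrix(
    cfg: DecisionConfig,
    printed_cells: pd.DataFrame,
    printed_totals: Mapping[str, float],
) -> list[Discrepancy]:
    """Flag printed weighted scores and totals inconsistent with w x mean.

    ``printed_cells`` is long-format with columns ``option``,
    ``criterion``, ``mean`` and ``final`` (the printed weighted score),
    all at the display precision ``cfg.rounding_dp``.  ``printed_totals``
    maps option id to the printed total.

    Cell tolerance: the printed mean may be off its true value by half an
    ulp of the display precision, and the printed score by another half,
    so |printed_final - w * printed_mean| may legitimately reach
    ``(w + 1) * 0.5 * 10^-dp``.  Total tolerance: each of the n summed
    printed scores contributes half an ulp, so
    ``(n + 1) * 0.5 * 10^-dp``.
    """
    ulp = 0.5 * 10 ** (-cfg.rounding_dp)
    weights = {c.id: c.weight for c in cfg.criteria}
    out: list[Discrepancy] = []

    for row in printed_cells.itertuples():
        w = weights[row.criterion]
        expected = w * row.mean
        tol = (w + 1.0) * ulp
        if abs(row.final - expected) > tol:
            implied = row.final / row.mean if row.mean else None
            out.append(
                Discrepancy(
                    kind="cell",
                    option_id=row.option,
                    criterion_id=row.criterion,
                    printed=float(row.final),
                    expected=expected,
                    tolerance=tol,
                    implied_multiplier=implied,
                )
            )

    n_crit = len(cfg.criteria)
    tol_total = (n_crit + 1) * ulp
    for oid, printed_total in printed_totals.items():
        s = float(printed_cells.loc[printed_cells["option"] == oid, "final"].sum())
        if abs(printed_total - s) > tol_total:
            out.append(
                Discrepancy(
                    kind="total",
                    option_id=oid,
                    criterion_id=None,
                    printed=float(printed_total),
                    expected=s,
                    tolerance=tol_total,
                )
            )
    return out
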