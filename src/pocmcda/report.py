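"""Human-readable rendering of a scoring matrix.

Mirrors the layout in which these matrices are conventionally published:
one block per criterion (weight, panel-mean rating, satisfice flag, final
weighted score across the option columns), then the total row and the
ranked list.  Every printed number is the full-precision matrix value
rounded half-up to the configured display precision — the renderer never
recomputes anything.
"""

from __future__ import annotations

from ._rounding import round_half_up
from .scoring import ScoringMatrix

__all__ = ["render_matrix"]


def _fmt(value: float, dp: int) -> str:
    return f"{round_half_up(value, dp):.{dp}f}"


def render_matrix(matrix: ScoringMatrix) -> str:
    cfg = matrix.config
    dp = cfg.rounding_dp
    opt_ids = list(cfg.option_ids)
    labels = {o.id: (o.label or o.id) for o in cfg.options}
    cells = matrix.cells.set_index(["option", "criterion"])

    col_w = max(12, *(len(oid) for oid in opt_ids)) + 2
    head_w = 34

    def row(label: str, values: list[str]) -> str:
        return label.ljust(head_w) + "".join(v.rjust(col_w) for v in values)

    lines = [row("Criterion", opt_ids), "-" * (head_w + col_w * len(opt_ids))]
    for c in cfg.criteria:
        lines.append(f"{c.description or c.id}")
        lines.append(row("  weighting", [_fmt(c.weight, dp)] * len(opt_ids)))
        lines.append(
            row(
                "  mean stakeholder score",
                [_fmt(cells.loc[(o, c.id), "mean"], dp) for o in opt_ids],
            )
        )
        lines.append(
            row(
                "  satisfice criteria met?",
                [
                    "Yes" if cells.loc[(o, c.id), "satisfice_met"] else "No"
                    for o in opt_ids
                ],
            )
        )
        lines.append(
            row(
                "  final score",
                [_fmt(cells.loc[(o, c.id), "weighted"], dp) for o in opt_ids],
            )
        )
    lines.append("-" * (head_w + col_w * len(opt_ids)))
    totals = {r.option: r.total for r in matrix.options.itertuples()}
    lines.append(row("Total", [_fmt(totals[o], dp) for o in opt_ids]))
    lines.append("")
    lines.append(f"Ranking (top-{cfg.top_k} flagged):")
    for r in matrix.options.itertuples():
        marks = []
        if r.top_k:
            marks.append("top-%d" % cfg.top_k)
        if r.tied:
            marks.append("tied")
        if not r.eligible:
            marks.append("satisfice met - ineligible")
        suffix = f"  [{', '.join(marks)}]" if marks else ""
        lines.append(
            f"  {r.rank}. {labels[r.option]} ({_fmt(r.total, dp)}){suffix}"
        )
    return "\n".join(lines) + "\n"
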