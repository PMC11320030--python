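"""Shared fixtures and the independent brute-force scoring oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pocmcda.model import (
    Criterion,
    DecisionConfig,
    Option,
    RatingScale,
    SatisficeRule,
)

SCALE_0_4 = RatingScale(
    levels=((0, "absent"), (1, "very low"), (2, "low"), (3, "moderate"), (4, "high"))
)
SCALE_0_3 = RatingScale(
    levels=((0, "none"), (1, "low"), (2, "moderate"), (3, "high"))
)


@pytest.fixture
def tiny_cfg() -> DecisionConfig:
    """Two options x two criteria, one low-tail satisfice rule."""
    return DecisionConfig(
        criteria=(
            Criterion(
                id="c1",
                scale=SCALE_0_4,
                weight=2.0,
                satisfice=SatisficeRule(excluded_codes=frozenset({0, 1})),
            ),
            Criterion(id="c2", scale=SCALE_0_3, weight=1.5),
        ),
        options=(Option(id="a", label="A"), Option(id="b", label="B")),
    )


def make_config(n_options: int, n_criteria: int, weights=None) -> DecisionConfig:
    """A plain configuration with 0-4 scales and no satisfice rules."""
    if weights is None:
        weights = [1.0] * n_criteria
    return DecisionConfig(
        criteria=tuple(
            Criterion(id=f"c{j}", scale=SCALE_0_4, weight=float(weights[j]))
            for j in range(n_criteria)
        ),
        options=tuple(Option(id=f"o{i}") for i in range(n_options)),
    )


def random_panel(
    rng: np.random.Generator,
    n_stakeholders: int,
    n_options: int,
    n_criteria: int,
    full_participation: bool = False,
) -> tuple[DecisionConfig, pd.DataFrame]:
    """Random config + vote table; every cell is guaranteed >= 1 vote."""
    weights = rng.uniform(0.5, 10.0, size=n_criteria)
    cfg = make_config(n_options, n_criteria, weights)
    rows = []
    for o in cfg.option_ids:
        for c in cfg.criterion_ids:
            if full_participation:
                voters = range(n_stakeholders)
            else:
                n_cell = int(rng.integers(1, n_stakeholders + 1))
                voters = rng.choice(n_stakeholders, size=n_cell, replace=False)
            for s in voters:
                rows.append(
                    {
                        "stakeholder": f"s{s}",
                        "option": o,
                        "criterion": c,
                        "score": int(rng.integers(0, 5)),
                    }
                )
    return cfg, pd.DataFrame(rows)


def brute_force_matrix(cfg: DecisionConfig, votes: pd.DataFrame):
    """Nested-loop recomputation of means, weighted scores, totals, ranks.

    Deliberately naive (pure-Python loops over the raw records) so it
    shares no code path with the engine under test.
    """
    records = list(votes.itertuples())
    means: dict[tuple[str, str], float] = {}
    for o in cfg.option_ids:
        for crit in cfg.criteria:
            cell = [r.score for r in records if r.option == o and r.criterion == crit.id]
            means[(o, crit.id)] = sum(cell) / len(cell)
    totals = {
        o: sum(crit.weight * means[(o, crit.id)] for crit in cfg.criteria)
        for o in cfg.option_ids
    }
    order = sorted(cfg.option_ids, key=lambda o: -totals[o])
    # stable: equal totals keep config order, which sorted() guarantees
    ranks = {o: i + 1 for i, o in enumerate(order)}
    return means, totals, ranks
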