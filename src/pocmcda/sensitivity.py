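"""Rank-robustness analysis.

Two complementary procedures quantify how fragile a weighted-sum ranking
is:

* **Stakeholder jackknife** — re-score the panel with each stakeholder
  removed in turn (leave-one-out) and report every rank change relative to
  the full panel.  A ranking that flips when one voter leaves is driven by
  that voter, not by consensus.

* **Weight perturbation** — resample the criterion weights many times,
  multiplying each weight by an independent log-normal factor with unit
  median and a chosen log-scale, and recompute the ranking.  Reported per
  option: the distribution of ranks across replicates and the frequency
  with which the baseline top-k set is retained.

Both are deterministic under a fixed seed and independent of the order of
the stakeholder records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DecisionConfig
from .scoring import ScoringMatrix, build_matrix

__all__ = [
    "JackknifeReport",
    "SensitivityReport",
    "jackknife_ranks",
    "perturb_weights",
]


@dataclass
class JackknifeReport:
    """Leave-one-out rankings, one replicate per removed stakeholder.

    ``ranks`` is long-format: (stakeholder removed, option, rank,
    baseline_rank, changed).  ``incomplete`` lists stakeholders whose
    removal left some cell without any vote; those replicates are flagged,
    not silently dropped.
    """

    ranks: pd.DataFrame
    incomplete: tuple[str, ...]
    baseline: pd.DataFrame = field(repr=False)

    @property
    def n_rank_changes(self) -> int:
        return int(self.ranks["changed"].sum())


def jackknife_ranks(cfg: DecisionConfig, votes: pd.DataFrame) -> JackknifeReport:
    """Re-score with each stakeholder left out; report rank changes."""
    baseline = build_matrix(cfg, votes).options
    base_rank = dict(zip(baseline["option"], baseline["rank"]))

    stakeholders = sorted(pd.unique(votes["stakeholder"]))
    rows = []
    incomplete: list[str] = []
    for s in stakeholders:
        reduced = votes[votes["stakeholder"] != s]
        # a replicate is incomplete if removal empties any cell
        present = reduced.groupby(["option", "criterion"]).size()
        n_cells = len(cfg.option_ids) * len(cfg.criterion_ids)
        if len(present) < n_cells:
            incomplete.append(s)
            continue
        ranked = build_matrix(cfg, reduced).options
        for r in ranked.itertuples():
            rows.append(
                {
                    "stakeholder": s,
                    "option": r.option,
                    "rank": r.rank,
                    "baseline_rank": base_rank[r.option],
                    "changed": r.rank != base_rank[r.option],
                }
            )
    ranks = pd.DataFrame(
        rows, columns=["stakeholder", "option", "rank", "baseline_rank", "changed"]
    )
    return JackknifeReport(ranks=ranks, incomplete=tuple(incomplete), baseline=baseline)


@dataclass
class SensitivityReport:
    """Monte-Carlo weight-perturbation summary.

    ``rank_freq`` is long-format (option, rank, frequency); frequencies
    for each option sum to 1.  ``top_k_retention`` is the fraction of
    replicates whose top-k *set* equals the baseline top-k set.
    ``first_place_freq`` maps option id to the fraction of replicates in
    which it ranked first.
    """

    rank_freq: pd.DataFrame
    top_k_retention: float
    first_place_freq: dict[str, float]
    n_reps: int
    noise_scale: float
    seed: int
    baseline: pd.DataFrame = field(repr=False)


def perturb_weights(
    cfg: DecisionConfig,
    matrix: ScoringMatrix,
    n_reps: int = 10_000,
    noise_scale: float = 0.1,
    seed: int = 0,
) -> SensitivityReport:
    """Recompute the ranking under multiplicative log-normal weight noise.

    Each replicate multiplies every criterion weight by an independent
    ``exp(Normal(0, noise_scale))`` factor — positive by construction,
    median 1, so the central tendency of every weight is preserved while
    their ratios wobble.  Rankings use the same descending-total,
    stable-tie rule as the scoring engine.

    ``matrix`` supplies the (fixed) cell means; only weights are
    perturbed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")

    opt_ids = list(cfg.option_ids)
    crit_ids = list(cfg.criterion_ids)
    means = (
        matrix.cells.pivot(index="option", columns="criterion", values="mean")
        .reindex(index=opt_ids, columns=crit_ids)
        .to_numpy()
    )  # (n_options, n_criteria)
    w = np.array([c.weight for c in cfg.criteria])

    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(0.0, noise_scale, size=(n_reps, len(crit_ids))))
    totals = (factors * w) @ means.T  # (n_reps, n_options)

    # stable argsort on negated totals reproduces the engine's tie rule
    order = np.argsort(-totals, axis=1, kind="stable")
    ranks = np.empty_like(order)
    n_opt = len(opt_ids)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(1, n_opt + 1), order.shape), axis=1)

    baseline = matrix.options
    base_top = set(baseline.loc[baseline["top_k"], "option"])
    k = cfg.top_k
    top_sets_match = np.fromiter(
        (
            {opt_ids[j] for j in order[i, :k]} == base_top
            for i in range(n_reps)
        ),
        dtype=bool,
        count=n_reps,
    )

    rows = []
    for j, oid in enumerate(opt_ids):
        counts = np.bincount(ranks[:, j], minlength=n_opt + 1)[1:]
        for r, c in enumerate(counts, start=1):
            if c:
                rows.append({"option": oid, "rank": r, "frequency": c / n_reps})
    rank_freq = pd.DataFrame(rows, columns=["option", "rank", "frequency"])
    first = {
        oid: float((ranks[:, j] == 1).mean()) for j, oid in enumerate(opt_ids)
    }
    return SensitivityReport(
        rank_freq=rank_freq,
        top_k_retention=float(top_sets_match.mean()),
        first_place_freq=first,
        n_reps=n_reps,
        noise_scale=noise_scale,
        seed=seed,
        baseline=baseline,
    )
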