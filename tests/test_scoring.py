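"""Scoring engine: cell means, weighted scores, totals, ranks, matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pocmcda.scoring import (
    build_matrix,
    matrix_from_means,
    mean_rating,
    rank_options,
    total_score,
    validate_votes,
    weighted_score,
)

from conftest import brute_force_matrix, make_config, random_panel


def _votes(cells: dict[tuple[str, str], list[int]]) -> pd.DataFrame:
    rows = [
        {"stakeholder": f"s{i}", "option": o, "criterion": c, "score": s}
        for (o, c), scores in cells.items()
        for i, s in enumerate(scores)
    ]
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "scores,expected",
    [
        ([3] * 13, 3.0),
        ([3, 3, 3, 4], 3.25),
        ([0, 0, 1, 1], 0.5),
    ],
)
def test_mean_rating(scores, expected):
    votes = _votes({("o0", "c0"): scores})
    assert mean_rating(votes, "o0", "c0") == expected


def test_mean_rating_empty_cell_raises():
    votes = _votes({("o0", "c0"): [1]})
    with pytest.raises(ValueError, match="no votes for option 'o0' x criterion 'c1'"):
        mean_rating(votes, "o0", "c1")


@pytest.mark.parametrize(
    "w,m,expected", [(5.90, 1.0, 5.90), (5.90, 0.0, 0.0), (2.5, 2.0, 5.0)]
)
def test_weighted_score(w, m, expected):
    assert weighted_score(w, m) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "scores,expected",
    [
        ([27.32, 29.33, 22.17, 0.00], 78.82),
        ([24.36, 27.08, 15.08, 5.90], 72.42),
        ([0, 0, 0, 0], 0.0),
    ],
)
def test_total_score(scores, expected):
    assert total_score(scores) == pytest.approx(expected, abs=1e-12)


def test_total_score_length_mismatch():
    with pytest.raises(ValueError, match="expected 4"):
        total_score([1.0, 2.0], n_criteria=4)


class TestRankOptions:
    def test_descending_with_top_k(self):
        totals = {
            "troponin_ami": 78.82,
            "ntprobnp_ahf": 45.06,
            "lactate_sepsis": 72.42,
            "lactate_trauma": 60.89,
            "ketones_dka": 51.64,
        }
        ranked = rank_options(totals, k=3)
        assert ranked["option"].tolist() == [
            "troponin_ami",
            "lactate_sepsis",
            "lactate_trauma",
            "ketones_dka",
            "ntprobnp_ahf",
        ]
        assert ranked["rank"].tolist() == [1, 2, 3, 4, 5]
        assert set(ranked.loc[ranked["top_k"], "option"]) == {
            "troponin_ami",
            "lactate_sepsis",
            "lactate_trauma",
        }
        assert not ranked["tied"].any()

    def test_singleton(self):
        ranked = rank_options({"only": 1.0}, k=1)
        assert ranked["rank"].tolist() == [1]
        assert ranked["top_k"].all()

    def test_ties_keep_input_order_and_are_annotated(self):
        ranked = rank_options({"first": 2.0, "second": 2.0, "third": 1.0}, k=1)
        assert ranked["option"].tolist() == ["first", "second", "third"]
        assert ranked["tied"].tolist() == [True, True, False]
        assert ranked.loc[0, "top_k"] and not ranked.loc[1, "top_k"]


class TestBuildMatrix:
    def test_identity_case(self):
        """One option, one criterion, weight 1: total equals the cell mean."""
        cfg = make_config(1, 1, weights=[1.0])
        m = build_matrix(cfg, _votes({("o0", "c0"): [1, 2, 3, 4]}))
        assert m.total("o0") == pytest.approx(2.5)

    def test_all_votes_at_scale_minimum_gives_zero_totals(self):
        cfg = make_config(2, 2)
        votes = _votes(
            {(o, c): [0, 0] for o in ("o0", "o1") for c in ("c0", "c1")}
        )
        m = build_matrix(cfg, votes)
        assert (m.options["total"] == 0).all()
        assert m.options["tied"].all()

    def test_missing_cell_aborts_naming_it(self):
        cfg = make_config(2, 1)
        with pytest.raises(ValueError, match="o1"):
            build_matrix(cfg, _votes({("o0", "c0"): [2]}))

    def test_conservation_weight_dot_means(self):
        """Totals equal weight-vector dot mean-vector at full precision."""
        rng = np.random.default_rng(7)
        cfg, votes = random_panel(rng, 5, 3, 4)
        m = build_matrix(cfg, votes)
        w = np.array([c.weight for c in cfg.criteria])
        for oid in cfg.option_ids:
            means = (
                m.cells.set_index(["option", "criterion"])
                .loc[oid]
                .reindex(list(cfg.criterion_ids))["mean"]
                .to_numpy()
            )
            assert m.total(oid) == pytest.approx(float(w @ means), abs=1e-12)

    def test_oracle_equivalence_random_panels(self):
        """Engine agrees with naive nested-loop recomputation to 1e-12."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_s, n_o, n_c = rng.integers(1, 5), rng.integers(1, 4), rng.integers(1, 4)
            cfg, votes = random_panel(rng, int(n_s), int(n_o), int(n_c))
            m = build_matrix(cfg, votes)
            means, totals, ranks = brute_force_matrix(cfg, votes)
            for row in m.cells.itertuples():
                assert row.mean == pytest.approx(means[(row.option, row.criterion)], abs=1e-12)
            for row in m.options.itertuples():
                assert row.total == pytest.approx(totals[row.option], abs=1e-12)
                assert row.rank == ranks[row.option]

    def test_permutation_invariance_of_vote_order(self):
        rng = np.random.default_rng(3)
        cfg, votes = random_panel(rng, 4, 3, 3)
        m1 = build_matrix(cfg, votes)
        shuffled = votes.sample(frac=1.0, random_state=5).reset_index(drop=True)
        m2 = build_matrix(cfg, shuffled)
        pd.testing.assert_frame_equal(m1.cells, m2.cells)
        pd.testing.assert_frame_equal(m1.options, m2.options)

    def test_monotonicity_raising_one_vote(self):
        """With positive weights, raising a single vote weakly increases
        that option's total and never lets another option overtake it."""
        rng = np.random.default_rng(19)
        for _ in range(10):
            cfg, votes = random_panel(rng, 4, 3, 2)
            before = build_matrix(cfg, votes)
            raisable = votes.index[votes["score"] < 4]
            if raisable.empty:
                continue
            i = rng.choice(raisable)
            target = votes.loc[i, "option"]
            bumped = votes.copy()
            bumped.loc[i, "score"] += 1
            after = build_matrix(cfg, bumped)
            assert after.total(target) >= before.total(target)
            rank_b = dict(zip(before.options["option"], before.options["rank"]))
            rank_a = dict(zip(after.options["option"], after.options["rank"]))
            for other in cfg.option_ids:
                if other != target and rank_b[other] > rank_b[target]:
                    assert rank_a[other] > rank_a[target]

    def test_satisfice_flag_does_not_drop_option(self, tiny_cfg):
        votes = _votes(
            {
                ("a", "c1"): [0, 1],   # mean 0.5 <= threshold 1: flagged
                ("a", "c2"): [3, 3],
                ("b", "c1"): [4, 4],
                ("b", "c2"): [0, 0],
            }
        )
        m = build_matrix(tiny_cfg, votes)
        flagged = m.cells[m.cells["satisfice_met"]]
        assert len(flagged) == 1
        assert flagged.iloc[0]["option"] == "a"
        opts = m.options.set_index("option")
        assert not opts.loc["a", "eligible"]
        assert opts.loc["b", "eligible"]
        assert m.total("a") == pytest.approx(2 * 0.5 + 1.5 * 3)


def test_validate_votes_reports_row_numbers(tiny_cfg):
    votes = pd.DataFrame(
        [
            {"stakeholder": "s1", "option": "a", "criterion": "c1", "score": 7},
            {"stakeholder": "s1", "option": "zz", "criterion": "c1", "score": 1},
            {"stakeholder": "s2", "option": "a", "criterion": "c2", "score": 2},
            {"stakeholder": "s2", "option": "a", "criterion": "c2", "score": 3},
        ]
    )
    diags = validate_votes(votes, tiny_cfg)
    assert any("row 0" in d and "score 7" in d for d in diags)
    assert any("row 1" in d and "zz" in d for d in diags)
    assert sum("duplicate" in d for d in diags) == 2


def test_matrix_from_means_requires_every_cell(tiny_cfg):
    means = pd.DataFrame(
        [{"option": "a", "criterion": "c1", "mean": 2.0}]
    )
    with pytest.raises(ValueError, match="no mean supplied"):
        matrix_from_means(tiny_cfg, means)
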