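"""Synthetic panel generator: determinism, validity, parameter recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pocmcda.scoring import validate_votes
from pocmcda.synthetic import (
    PanelModel,
    generate_importance,
    generate_votes,
    panel_from_dict,
    recovery_experiment,
    validate_panel,
)
from pocmcda.weights import summarize_importance, validate_importance

from conftest import make_config


def _model(cfg, n=10, participation=1.0, mu=2.0, sigma=0.5, seed=0,
           mu_w=None, sigma_w=1.0):
    consensus = pd.DataFrame(
        [
            {"option": o, "criterion": c, "mu": mu, "sigma": sigma}
            for o in cfg.option_ids
            for c in cfg.criterion_ids
        ]
    )
    if mu_w is None:
        mu_w = [5.0] * len(cfg.criterion_ids)
    importance = pd.DataFrame(
        {
            "criterion": list(cfg.criterion_ids),
            "mu_w": mu_w,
            "sigma_w": sigma_w,
        }
    )
    return PanelModel(
        n_stakeholders=n,
        participation=participation,
        consensus=consensus,
        importance=importance,
        seed=seed,
    )


class TestGenerateVotes:
    def test_degenerate_dispersion_reproduces_mu_exactly(self):
        cfg = make_config(2, 2)
        votes = generate_votes(_model(cfg, n=5, sigma=0.0, mu=2.0), cfg)
        assert (votes["score"] == 2).all()
        assert len(votes) == 5 * 2 * 2

    def test_zero_participation_yields_empty_table(self):
        cfg = make_config(2, 2)
        votes = generate_votes(_model(cfg, participation=0.0), cfg)
        assert votes.empty
        assert list(votes.columns) == ["stakeholder", "option", "criterion", "score"]

    def test_fixed_seed_is_bit_identical(self):
        cfg = make_config(3, 2)
        m = _model(cfg, n=20, sigma=1.0, participation=0.7, seed=123)
        pd.testing.assert_frame_equal(generate_votes(m, cfg), generate_votes(m, cfg))

    def test_generated_tables_always_validate(self):
        cfg = make_config(3, 3)
        for seed in range(5):
            m = _model(cfg, n=15, sigma=1.5, participation=0.8, seed=seed, mu=3.5)
            assert validate_votes(generate_votes(m, cfg), cfg) == []
            assert validate_importance(generate_importance(m)) == []

    def test_large_panel_mean_close_to_mu(self):
        """Monte-Carlo check: with 2000 voters and sigma 0.5 the cell mean
        lands within 3 standard errors of the interior consensus."""
        cfg = make_config(1, 1)
        m = _model(cfg, n=2000, mu=2.0, sigma=0.5, seed=99)
        votes = generate_votes(m, cfg)
        se = votes["score"].std(ddof=1) / np.sqrt(len(votes))
        assert votes["score"].mean() == pytest.approx(2.0, abs=3 * se)


class TestGenerateImportance:
    def test_degenerate_importance_recovers_exact_summary(self):
        cfg = make_config(1, 2)
        m = _model(cfg, n=6, sigma_w=0.0, mu_w=[9.0, 4.0])
        resp = generate_importance(m)
        s = summarize_importance(resp, cfg.criterion_ids[0])
        assert (s.mean, s.minimum, s.maximum) == (9.0, 9, 9)

    def test_partial_participation_hits_expected_count(self):
        """28 invitees at 54% participation: expected ~15 respondents."""
        cfg = make_config(1, 1)
        counts = [
            len(generate_importance(_model(cfg, n=28, participation=0.54, seed=s)))
            for s in range(40)
        ]
        # Binomial(28, .54): mean 15.1, sd 2.6; mean of 40 reps within 3 se
        assert np.mean(counts) == pytest.approx(15.12, abs=3 * 2.64 / np.sqrt(40))

    @staticmethod
    def _expected_mean(mu: float, sigma: float) -> float:
        """Closed-form expectation of a clamp-and-round normal response on
        the integer 0-10 scale — an oracle independent of the generator."""
        from scipy.stats import norm

        upper = np.concatenate([np.arange(0.5, 10.0, 1.0), [np.inf]])
        lower = np.concatenate([[-np.inf], np.arange(0.5, 10.0, 1.0)])
        probs = norm.cdf(upper, mu, sigma) - norm.cdf(lower, mu, sigma)
        return float(np.arange(11) @ probs)

    def test_weight_recovery_from_survey_consensus(self):
        """Latent importances like the published ones (7.2, 8.8, 7.0, 5.9)
        are recovered within 3 SE of the response model's expectation by a
        large synthetic survey.  For interior values the expectation is
        essentially the latent mean; near the top of the scale (8.8 with
        sigma 1.5) clamping shifts it down, which the oracle captures."""
        cfg = make_config(1, 4)
        mu_w = [7.2, 8.8, 7.0, 5.9]
        sigma_w = 1.5
        m = _model(cfg, n=2000, mu_w=mu_w, sigma_w=sigma_w, seed=17)
        resp = generate_importance(m)
        for cid, mu in zip(cfg.criterion_ids, mu_w):
            scores = resp.loc[resp["criterion"] == cid, "score"]
            se = scores.std(ddof=1) / np.sqrt(len(scores))
            target = self._expected_mean(mu, sigma_w)
            assert scores.mean() == pytest.approx(target, abs=3 * se)
            if mu <= 7.2:  # interior: clamping bias is negligible
                assert abs(target - mu) < 0.05


class TestRecoveryExperiment:
    def test_zero_sigma_gives_zero_bias_and_rmse(self):
        cfg = make_config(2, 2)
        rep = recovery_experiment(_model(cfg, n=5, sigma=0.0, mu=3.0), cfg, n_reps=3)
        assert (rep.cell_stats["bias"] == 0).all()
        assert (rep.cell_stats["rmse"] == 0).all()
        assert (rep.option_stats["rmse"] == 0).all()

    def test_rmse_shrinks_with_panel_size(self):
        cfg = make_config(1, 1)
        small = recovery_experiment(_model(cfg, n=10, seed=4), cfg, n_reps=30)
        large = recovery_experiment(_model(cfg, n=1000, seed=4), cfg, n_reps=30)
        assert (
            large.cell_stats["rmse"].iloc[0] < small.cell_stats["rmse"].iloc[0]
        )

    def test_mu_at_scale_edge_shows_negative_clamping_bias(self):
        """Consensus at the scale maximum with nonzero dispersion: clamping
        and rounding can only pull votes downward, so bias is negative."""
        cfg = make_config(1, 1)
        rep = recovery_experiment(
            _model(cfg, n=200, mu=4.0, sigma=0.8, seed=6), cfg, n_reps=20
        )
        assert rep.cell_stats["bias"].iloc[0] < 0


def test_panel_validation_catches_bad_parameters():
    cfg = make_config(1, 1)
    m = PanelModel(
        n_stakeholders=0,
        participation=1.5,
        consensus=pd.DataFrame(
            [{"option": "o0", "criterion": "c0", "mu": 9.0, "sigma": -1.0}]
        ),
        importance=pd.DataFrame(
            [{"criterion": "c0", "mu_w": 12.0, "sigma_w": 1.0}]
        ),
        seed=0,
    )
    diags = validate_panel(m, cfg)
    assert len(diags) == 5
    assert validate_panel(_model(cfg), cfg) == []


def test_panel_round_trip_from_dict():
    cfg = make_config(2, 1)
    data = {
        "n_stakeholders": 8,
        "participation": 0.9,
        "seed": 5,
        "consensus": [
            {"option": o, "criterion": "c0", "mu": 2.0, "sigma": 0.3}
            for o in cfg.option_ids
        ],
        "importance": [{"criterion": "c0", "mu_w": 7.0, "sigma_w": 1.0}],
    }
    m = panel_from_dict(data)
    assert m.n_stakeholders == 8
    assert validate_panel(m, cfg) == []
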