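"""Bundled example: prioritising prehospital point-of-care (POC) tests.

A published UK exercise used this kind of MCDA to choose which ambulance
POC-testing use cases should enter a platform trial.  The numbers below
are that exercise's published artefacts, reproduced here as a worked
example and regression fixture:

* twelve candidate use cases, of which seven were struck before scoring by
  a named stakeholder decision (they met deal-breaker criteria);
* four use-case criteria whose weights are the mean 0-10 importance
  scores from a 15-respondent expert survey;
* the workshop scoring record for five scored use cases: per-cell mean
  ratings (14-participant panel), the printed weighted scores and totals,
  rounded to two decimals as published.

A second criteria set for evaluating POC *devices* (power supply, size,
weight, turnaround time, risk, sustainability, systems integration,
precision) is included to show that device-level prioritisation is plain
configuration, not special-cased code.  The published record gives those
criteria weights and low-tail satisfice levels but no rating-scale text,
so a generic five-level suitability scale is supplied.

The scored set of five differs from the post-exclusion survivor set in one
slot (natriuretic peptides in heart failure was scored although listed
among the exclusions; SARS-CoV-2 testing survived but was not scored) —
the exercise's own records disagree, so both sets are exposed as data and
neither is "corrected".
"""

from __future__ import annotations

import pandas as pd

from .model import Criterion, DecisionConfig, Option, RatingScale, SatisficeRule

__all__ = [
    "usecase_criteria",
    "device_criteria",
    "candidate_options",
    "named_exclusions",
    "scored_options",
    "usecase_config",
    "scoring_config",
    "device_config",
    "workshop_cells",
    "workshop_totals",
]

_POTENTIAL_SCALE = RatingScale(
    levels=(
        (0, "No/Very low potential"),
        (1, "Low potential"),
        (2, "Moderate potential"),
        (3, "High potential"),
    )
)

_CERTAINTY_SCALE = RatingScale(
    levels=((0, "Absent"), (1, "Very low"), (2, "Low"), (3, "Moderate"), (4, "High"))
)

# Published verbatim with no level 2 and ambiguous interval boundaries;
# stored as printed, boundaries are not interpreted.
_CALL_VOLUME_SCALE = RatingScale(
    levels=((0, "<1%"), (1, "2.9%"), (3, "4.9%"), (4, ">=5%"))
)

_SUITABILITY_SCALE = RatingScale(
    levels=(
        (0, "Unsuitable"),
        (1, "Poor"),
        (2, "Acceptable"),
        (3, "Good"),
        (4, "Excellent"),
    )
)


def usecase_criteria() -> tuple[Criterion, ...]:
    """The four use-case criteria with survey-derived weights.

    Weights are the survey mean importance scores; the summaries
    (median/min/max over 15 respondents) are attached for reporting.
    """
    from .model import ImportanceSummary

    def crit(cid, desc, scale, mean, median, mn, mx, satisfice):
        return Criterion(
            id=cid,
            description=desc,
            scale=scale,
            weight=mean,
            weight_summary=ImportanceSummary(
                mean=mean, median=median, minimum=mn, maximum=mx, n_respondents=15
            ),
            satisfice=SatisficeRule(excluded_codes=frozenset(satisfice)),
        )

    return (
        crit(
            "pathway",
            "Potential to improve the care pathway",
            _POTENTIAL_SCALE,
            7.2, 7, 3, 10, (),
        ),
        crit(
            "diag_accuracy",
            "Certainty of evidence for diagnostic accuracy",
            _CERTAINTY_SCALE,
            8.8, 9, 6, 10, (0, 1, 2),
        ),
        crit(
            "clin_effectiveness",
            "Certainty of evidence for clinical effectiveness",
            _CERTAINTY_SCALE,
            7.0, 8, 2, 10, (4,),
        ),
        crit(
            "population",
            "Size of population affected (call volume)",
            _CALL_VOLUME_SCALE,
            5.9, 6, 2, 9, (),
        ),
    )


def device_criteria() -> tuple[Criterion, ...]:
    """The eight POC-device criteria (second configurable criteria set).

    All have a satisfice level of 0 (a device rated entirely unsuitable on
    any dimension is a deal-breaker) except precision, whose rule was left
    to be developed and is stored with no satisfice tail.
    """
    from .model import ImportanceSummary

    spec = [
        ("power_supply", "Suitability of the power supply for prehospital use", 8, 8, 5, 10, (0,)),
        ("size", "Suitability of the device size for prehospital use", 7, 8, 5, 10, (0,)),
        ("weight", "Suitability of the device weight for prehospital use", 6, 7, 0, 8, (0,)),
        ("turnaround", "Suitability of the test turnaround time", 8, 8, 5, 9, (0,)),
        ("risk", "Risk of the POC test", 8, 8, 5, 9, (0,)),
        ("sustainability", "Sustainability of the manufacturing process", 5, 5, 1, 8, (0,)),
        ("integration", "Integration with ambulance systems", 7, 6, 1, 10, (0,)),
        ("precision", "Precision (reproducibility and reliability)", 9, 9, 7, 10, ()),
    ]
    return tuple(
        Criterion(
            id=cid,
            description=desc,
            scale=_SUITABILITY_SCALE,
            weight=float(mean),
            weight_summary=ImportanceSummary(
                mean=mean, median=median, minimum=mn, maximum=mx, n_respondents=15
            ),
            satisfice=SatisficeRule(excluded_codes=frozenset(sat)),
        )
        for cid, desc, mean, median, mn, mx, sat in spec
    )


def candidate_options() -> tuple[Option, ...]:
    """The twelve candidate use cases identified by literature review."""
    labels = [
        ("lactate_trauma", "Lactate testing in trauma"),
        ("sars_cov_2", "SARS-CoV-2 testing in suspected respiratory tract infection"),
        ("lactate_sepsis", "Lactate testing in sepsis"),
        ("troponin_ami", "Troponin for acute myocardial infarction"),
        ("coagulation_trauma", "Coagulation testing in trauma"),
        ("blood_gas_copd", "Blood gas testing in COPD"),
        ("ketones_dka", "Blood ketone testing to diagnose diabetic ketoacidosis"),
        ("ntprobnp_ahf", "NT-proBNP to identify heart failure (natriuretic peptides)"),
        ("ntprobnp_sepsis", "NT-proBNP to identify sepsis"),
        ("crp_sepsis", "C-reactive protein (CRP) testing in sepsis"),
        ("beta_hcg", "Beta-HCG testing to identify pregnancy (whole blood)"),
        ("tbi_biomarkers", "Biomarkers of traumatic brain injury"),
    ]
    return tuple(Option(id=i, label=lab) for i, lab in labels)


def named_exclusions() -> tuple[str, ...]:
    """The seven use cases struck before scoring by stakeholder decision."""
    return (
        "coagulation_trauma",
        "blood_gas_copd",
        "ntprobnp_ahf",
        "ntprobnp_sepsis",
        "crp_sepsis",
        "beta_hcg",
        "tbi_biomarkers",
    )


def scored_options() -> tuple[Option, ...]:
    """The five use cases that actually appear in the workshop record."""
    want = ("troponin_ami", "ntprobnp_ahf", "lactate_sepsis", "lactate_trauma", "ketones_dka")
    by_id = {o.id: o for o in candidate_options()}
    return tuple(by_id[i] for i in want)


def usecase_config() -> DecisionConfig:
    """Full screening problem: 12 candidates, 4 criteria, 7 exclusions."""
    return DecisionConfig(
        criteria=usecase_criteria(),
        options=candidate_options(),
        excluded_option_ids=named_exclusions(),
        rounding_dp=2,
        top_k=3,
    )


def scoring_config() -> DecisionConfig:
    """Scoring problem as recorded: the five scored use cases."""
    return DecisionConfig(
        criteria=usecase_criteria(), options=scored_options(), rounding_dp=2, top_k=3
    )


def device_config(options: tuple[Option, ...] = ()) -> DecisionConfig:
    """Device-evaluation problem; pass the devices to score as options."""
    if not options:
        options = (Option(id="device_a", label="Example device"),)
    return DecisionConfig(criteria=device_criteria(), options=options, rounding_dp=2, top_k=3)


# Published workshop record: per-cell mean ratings and printed weighted
# ("final") scores, in scoring_config() option/criterion order.
_WORKSHOP_ROWS = [
    # option, criterion, mean, printed final score
    ("troponin_ami", "pathway", 2.85, 27.32),
    ("troponin_ami", "diag_accuracy", 3.33, 29.33),
    ("troponin_ami", "clin_effectiveness", 3.17, 22.17),
    ("troponin_ami", "population", 0.0, 0.00),
    ("ntprobnp_ahf", "pathway", 2.42, 23.19),
    ("ntprobnp_ahf", "diag_accuracy", 2.15, 18.95),
    ("ntprobnp_ahf", "clin_effectiveness", 0.42, 2.92),
    ("ntprobnp_ahf", "population", 0.0, 0.00),
    ("lactate_sepsis", "pathway", 2.54, 24.36),
    ("lactate_sepsis", "diag_accuracy", 3.08, 27.08),
    ("lactate_sepsis", "clin_effectiveness", 2.15, 15.08),
    ("lactate_sepsis", "population", 1.0, 5.90),
    ("lactate_trauma", "pathway", 2.15, 20.67),
    ("lactate_trauma", "diag_accuracy", 2.62, 23.02),
    ("lactate_trauma", "clin_effectiveness", 1.62, 11.31),
    ("lactate_trauma", "population", 1.0, 5.90),
    ("ketones_dka", "pathway", 2.54, 24.36),
    ("ketones_dka", "diag_accuracy", 1.69, 14.89),
    ("ketones_dka", "clin_effectiveness", 1.77, 12.38),
    ("ketones_dka", "population", 0.0, 0.00),
]


def workshop_cells() -> pd.DataFrame:
    """Published cell means and weighted scores (long format).

    Columns ``option``, ``criterion``, ``mean``, ``final``; all values at
    the published 2-dp display precision.  The 14-participant panel's raw
    votes were not published, only these means.
    """
    return pd.DataFrame(_WORKSHOP_ROWS, columns=["option", "criterion", "mean", "final"])


def workshop_totals() -> dict[str, float]:
    """Published option totals."""
    return {
        "troponin_ami": 78.82,
        "ntprobnp_ahf": 45.06,
        "lactate_sepsis": 72.42,
        "lactate_trauma": 60.89,
        "ketones_dka": 51.64,
    }
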