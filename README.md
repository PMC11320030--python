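# pocmcda

Weighted-sum multiple-criteria decision analysis (MCDA) with satisfice
screening, built for prioritising prehospital point-of-care (POC) test
use cases — e.g. deciding which of a dozen candidate ambulance
diagnostics (lactate in sepsis, troponin in chest pain, ketones in
suspected DKA, ...) should enter a platform trial — but generic over any
criteria/options configuration.

## Who it is for

Health-technology-assessment and decision-science teams running
stakeholder prioritisation exercises: importance surveys, scoring
workshops, and the arithmetic in between. The package turns those stages
into a reproducible, validated pipeline and adds the robustness analysis
such exercises usually lack.

## The method

1. **Weight elicitation.** Each stakeholder scores each criterion's
   importance on an 11-point (0–10) scale. The criterion weight is the
   arithmetic mean of those scores, used raw:
   `w_c = mean(importance scores for c)`.
2. **Satisfice screening.** A criterion may carry a "deal-breaker" rule:
   a contiguous tail of its rating scale (e.g. codes {0, 1, 2} on a 0–4
   certainty-of-evidence scale, or the single top code {4} meaning "so
   well-evidenced a trial is unnecessary"). Options struck by an explicit
   stakeholder decision are excluded before scoring; during scoring, each
   cell's *mean* rating is compared against the rule's threshold
   (low tail: mean ≤ t; high tail: mean ≥ t) and flagged options are
   marked ineligible but still scored.
3. **Scoring.** Stakeholders vote each surviving option on each
   criterion's ordinal scale. The cell statistic is the mean vote
   `s_{o,c}`; the weighted score is `f_{o,c} = w_c · s_{o,c}`; the option
   total is `T_o = Σ_c f_{o,c}`. Options are ranked by descending total
   (stable, annotated ties) and the top-k (default 3) are selected.
4. **Robustness.** A stakeholder jackknife (leave-one-out re-scoring)
   and a weight-perturbation Monte Carlo (each weight multiplied by an
   independent log-normal factor with unit median) quantify how stable
   the ranking and the top-k set are.
5. **Synthetic panels.** A clamp-and-round normal response model with
   per-cell latent consensus and dispersion generates vote and survey
   tables with known ground truth, so recovery error of every stage is
   measurable.

All arithmetic is at full precision; rounding (half-up, 2 dp by default)
is display-only. A verification mode re-derives `w × mean` for a
*published* matrix and flags rows whose printed scores imply a different
multiplier than the printed weight.

## Worked example

The bundled dataset (`pocmcda.datasets`) is a real UK exercise that
prioritised ambulance POC-testing use cases: four survey-weighted
criteria, five scored use cases, published cell means.

```python
from pocmcda import datasets as ds, matrix_from_means
from pocmcda.report import render_matrix

cfg = ds.scoring_config()
m = matrix_from_means(cfg, ds.workshop_cells()[["option", "criterion", "mean"]])
print(render_matrix(m))
```

prints (abridged):

```
Size of population affected (call volume)
  weighting                                   5.90   5.90   5.90   5.90   5.90
  mean stakeholder score                      0.00   0.00   1.00   1.00   0.00
  satisfice criteria met?                       No     No     No     No     No
  final score                                 0.00   0.00   5.90   5.90   0.00
------------------------------------------------------------------------------
Total                                        72.01  39.28  66.34  55.78  45.55

Ranking (top-3 flagged):
  1. Troponin for acute myocardial infarction (72.01)  [top-3]
  2. Lactate testing in sepsis (66.34)  [top-3]
  3. Lactate testing in trauma (55.78)  [top-3]
  4. Blood ketone testing ... (45.55)  [satisfice met - ineligible]
  5. NT-proBNP to identify heart failure ... (39.28)
```

Troponin leads, the lactate use cases follow, and the ketones use case —
despite a respectable total — is flagged ineligible because its mean
diagnostic-accuracy rating (1.69) falls in that criterion's {0, 1, 2}
deal-breaker tail. Exactly one of the twenty cells is flagged.

The re-scored totals differ from the published ones in one systematic
way: the published care-pathway row's final scores imply a multiplier of
about 9.59 although the printed weight is 7.20. The package does not
silently reproduce that row; `pocmcda.verify_printed_matrix` flags its
five cells:

```python
from pocmcda import verify_printed_matrix
for d in verify_printed_matrix(cfg, ds.workshop_cells(), ds.workshop_totals()):
    print(d)
# cell troponin_ami x pathway: printed 27.32 vs expected 20.5200
#   (tolerance 0.0410); implied multiplier 9.59
# ... (one line per scored option, all in the pathway row)
```

Summing the published per-criterion scores instead reproduces the
published totals exactly: 78.82 (troponin/AMI), 72.42 (lactate/sepsis),
45.06 (NT-proBNP/heart failure) — and the same top-3 selection.

A command-line interface mirrors the pipeline stages
(`pocmcda weights | screen | score | rank | sensitivity | simulate | run`);
see `pocmcda --help`.

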