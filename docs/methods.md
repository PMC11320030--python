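# Methods

## Decision model

The pipeline implements quantitative weighted-sum MCDA for panels of
stakeholders scoring options against criteria on ordinal rating scales.
For option *o* and criterion *c* with weight *w_c* and panel-mean rating
*s₍o,c₎*:

    f₍o,c₎ = w_c · s₍o,c₎        T_o = Σ_c f₍o,c₎

Options are ranked by descending *T_o*; the top-*k* (default k = 3, a
config field) are selected. Assumptions inherited from the weighted-sum
form: criteria contribute additively and independently; the ordinal
rating codes are treated as interval-scaled once averaged; weights are
ratio-scaled multipliers.

**Weights are used raw.** They are the arithmetic means of 0–10
importance-survey scores and are *not* normalised to sum to one.
Normalisation would rescale every total by the same constant and leave
the ranking unchanged, but raw weights keep totals on the scale in which
such exercises publish their matrices. Median/min/max and respondent
count are carried along purely for reporting. Survey response is
partial by design: summaries are computed over the responses present,
and the even-*n* median is the midpoint of the central pair (a
convention choice; published medians are printed as integers and do not
pin it down).

**Satisfice (deal-breaker) rules** are stored as the set of excluded
scale codes and reduced to a contiguous tail with one threshold: a set
containing the scale minimum is a low tail with threshold `max(set)`, a
set containing the maximum is a high tail with threshold `min(set)`.
Any other set (non-contiguous, touching both ends, or interior) is
rejected as ambiguous rather than guessed at. Flags are evaluated on
the **mean** rating at full precision, not on the rounded category:
with a low tail at threshold 2, a mean of 1.69 meets the rule while
2.15 does not, even though both round to category 2 — rounding-based
membership cannot reproduce published flag patterns. A flagged option
is still scored and totalled; it is marked ineligible, never dropped,
so the full matrix stays inspectable. Pre-scoring exclusions (options
struck by an explicit panel decision) are taken as an id list, because
the deliberation behind them is not reconstructible from printed data.

**Ties** in ranking keep the input (configuration) order and are
annotated as tied. Real exercises rarely hit exact ties; the rule
exists so that the engine is total and deterministic.

## Numerical conventions

All arithmetic is IEEE double precision; nothing is rounded internally.
Display rounding is half-up (0.005 → 0.01) at `rounding_dp` decimals
(default 2), applied only by the report renderer. Published matrices
are consistent with this: a printed mean of 3.08 alongside a printed
weighted score of 27.08 implies an unrounded mean of 40/13 under weight
8.8.

**Verification of printed matrices.** Because a published cell shows a
rounded mean and a rounded score, `printed_final` may differ from
`w · printed_mean` by up to `(w + 1) · ½·10^-dp` without any real
inconsistency; printed totals may differ from the sum of printed scores
by up to `(n_criteria + 1) · ½·10^-dp`. `verify_printed_matrix` flags
only violations beyond these bounds and reports the implied multiplier
`printed_final / printed_mean`. On the bundled example this flags
exactly the care-pathway row (printed weight 7.20, implied multiplier
≈ 9.59) — an inconsistency in the source record that the package
detects rather than reproduces.

## Sensitivity analysis

*Jackknife*: one full re-scoring per removed stakeholder; replicates
whose removal empties any cell are reported as incomplete, not dropped.
A panel of identical voters yields zero rank changes (tested).

*Weight perturbation*: each replicate multiplies every weight by an
independent `exp(N(0, noise_scale))` factor. Multiplicative log-normal
noise is chosen over additive noise because it preserves
non-negativity by construction and perturbs *relative* importance,
which is what weights encode; unit median means no systematic inflation.
Defaults: 10 000 replicates, `noise_scale = 0.1` (≈ ±10 % typical weight
wobble) — conservative choices for a method whose sources report no
weight uncertainty. Rankings within replicates use the same
stable-tie rule as the engine. Reported: per-option rank distribution,
first-place frequencies, and the frequency with which the baseline
top-k *set* is retained. Fixed seed ⇒ bit-identical reports.

## Synthetic panel generator

The generator stands in for human survey and workshop data. Each
option × criterion cell has a latent consensus μ (a real value on the
scale interval) and dispersion σ; a vote is drawn `N(μ, σ)`, clamped to
the scale interval, and rounded half-up to the nearest *code* (scales
with gaps, such as a call-volume scale coded 0, 1, 3, 4, round to the
nearest existing code). Importance responses use the same mechanism on
the integer 0–10 scale. Each (stakeholder, question) pair is answered
independently with probability `participation`, emulating partial
response (e.g. 28 invitees at 54 % participation ≈ 15 respondents, the
response pattern typical of such surveys). Seeds are mandatory; there
is no global random state.

This is the simplest model with a consensus-plus-dispersion reading and
is documented as replaceable. What it does **not** emulate:
inter-stakeholder correlation, anchoring, deliberation or convergence
during workshops, non-normal (e.g. bimodal) opinion distributions, and
informative non-response. Passing recovery tests therefore show the
*pipeline arithmetic* is unbiased and convergent under this model — not
that real panels behave this way.

**Edge bias is real and surfaced.** Clamping and rounding shift the
expected response toward the scale interior when μ is within ~2σ of an
edge: for μ = 8.8, σ = 1.5 on 0–10 the expected response is ≈ 8.62.
`recovery_experiment` reports this bias rather than hiding it, and the
test suite checks generated means against the closed-form expectation
of the clamp-and-round model (an independent oracle) instead of
pretending recovery to μ is exact at edges. Recovery-to-μ assertions
use interior consensus values (μ within [1.5, 2.5] on a 0–4 scale with
σ = 0.5), where the discretisation bias is far below Monte-Carlo noise.

## Problem sizes in the test suite

Chosen to exercise every property at high power while keeping the suite
quick to run: oracle-equivalence sweeps cover every panel shape up to
4 stakeholders × 3 options × 3 criteria with random refills;
monotonicity and permutation invariance run over 1000 random panels;
synthetic recovery uses a 1000-stakeholder panel (σ = 0.5, 3 × 3 cells);
perturbation symmetry uses 10 000 replicates. The whole suite completes
in well under a minute.

## Design choices where the design was open

- **Two criteria sets, one code path.** Use-case criteria and
  POC-device criteria are plain configurations of the same types. The
  device set ships with a generic five-level 0–4 suitability scale
  because no scale text was published for it; all-zero satisfice levels
  are encoded as low tails `{0}`, and the precision criterion (whose
  rule was left "to be developed") carries no satisfice tail.
- **The ambiguous call-volume scale** (codes 0, 1, 3, 4 with
  interval-style labels and no level 2) is stored verbatim; its labels
  are never interpreted as numeric boundaries.
- **The scored option set is data, not inference.** The bundled
  example's exclusion list and its scored set disagree in one slot
  (one use case appears in both; another survives screening but was
  never scored); both are exposed as-is.
- **Config-driven exclusions.** The package never attempts to
  reconstruct why a consensus decision narrowed the candidate list.

## Known limitations

- Weighted-sum MCDA cannot express criteria interactions or
  non-compensatory preferences beyond the satisfice rules.
- The jackknife requires ≥ 1 remaining vote per cell; very sparse
  panels yield mostly incomplete replicates.
- The generator's normality and independence assumptions understate the
  rank instability that correlated stakeholder blocs would produce.
- Verification of printed matrices can detect inconsistency but not
  attribute it (wrong weight vs wrong scores vs transcription error).
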