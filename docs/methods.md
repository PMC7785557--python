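# Methods

## Problem and model

The unit of assessment is the affiliate-month.  For each PV impact factor
*f* — the four modeled ones are Compliance to the ICSR process, to risk
minimization activities, to DHPC activities, and to safety updates to local
labels — the risk `p[a, t, f]` is defined as the probability that an audit
of affiliate *a* in month *t* would produce at least one finding mapped to
*f*.  An audit outcome is treated as a Bernoulli(p) draw; finding severity
is deliberately ignored because severity grading is auditor-subjective, and
counts are collapsed to a binary "any finding in this factor" because
finding counts mix unrelated issues.  The excluded risk areas (locally
managed PASS, health-authority commitments, CAPA, business-partner
oversight) are not modeled at all; their statements stay UNMAPPED and never
contribute to an outcome.

A curated code table maps finding statements to impact factors.  Each
statement maps to at most one factor.  The shipped table contains the
published example statements plus the synthetic generator's DHPC pool; the
full controlled vocabulary of a real audit management system would simply
extend this file.

## Window covariates

Covariates are computed per affiliate on a monthly grid covering the corpus
span.  All windows are half-open `[t − W, t)` anchored at the first day of
month *t*: the value available at month *t* uses strictly pre-*t* data, so
an audit conducted in month *t* never sees its own month's events in its
covariates.  The long window is 24 months (matching the 12–18-month
lookback quality strategists use, with margin for slow-moving streams); the
short window is 6 months and only enters the cross-window reporting-rate
change.  Case-derived events (including submissions, which may lack a
submission date when the case was deliberately not submitted) are windowed
on the case's received date, keeping one windowing rule for every
case-linked record.

Feature kinds and conventions:

- **window_ratio** — numerator count / denominator count; MISSING (NaN)
  when the denominator is zero.  Ratios where the numerator events are a
  subset of the denominator events always lie in [0, 1].
- **source_mix** — per-source share of all AEs in the long window; shares
  sum to 1 unless the window is empty (then all MISSING).
- **quantile_set** — lower nearest-rank quantiles (levels 0.5, 0.9, 1.0 by
  default) of submission lateness in days: deterministic, integer-valued,
  no interpolation.
- **cross_window_change** — (short-window AE count / units sold) divided by
  the long-window analogue; MISSING when either window has zero sales or
  the long-window rate is zero, rather than ±inf.
- **Active studies without AEs** — studies whose active interval overlaps
  the long window and with no window AE linked by study id, as a share of
  active studies.  The "average number" wording in the source taxonomy is
  read as the plain window count; no inner averaging is defined anywhere.

The batch evaluator aggregates events into per-month counts and reduces
windows by cumulative sums, which is exact (counts are integers, and
generated sales are whole units) and agrees cell-for-cell with the
single-cell reference computations; the test suite enforces that equality
against independent brute-force loops.

## Risk model

Per factor, each audit contributes one training row: the covariate vector
at its calendar month, restricted to the factor's features, with outcome
from the statement mapping.  MISSING covariates are median-imputed from the
non-missing training values (prediction reuses the training medians);
rows with every feature MISSING are dropped rather than imputed wholesale.
Audits and inspections are pooled with equal weight.

The fit maximizes the binomial log-likelihood with an L2 penalty of
λ/2·‖β‖² on standardized coefficients (intercept unpenalized), by damped
Newton iteration to a max-gradient tolerance of 1e-6.  Defaults: λ = 1
(audit outcomes are scarce relative to the covariate count, so shrinkage is
on by default), constant features dropped, z-scoring by training mean and
population sd.  The solver is written in-house because the contract — which
coefficients are penalized, the exact stopping rule, bitwise determinism —
is part of the package's reproducibility guarantees; tests cross-check it
against an independent Newton–Raphson oracle (λ = 0) and scikit-learn's
ridge logistic (λ > 0).

A factor falls back to *descriptive mode* when it has no quantitative
features in the catalog, fewer than `min_audits` (default 30) usable rows,
or a single-class outcome.  Descriptive factors flow through the identical
surface/color/export path with raw feature values instead of probabilities.
In this corpus schema the three non-ICSR factors have no observable
covariates — mirroring the data-availability gap that motivates the
fallback in practice — so only the ICSR-process factor is fitted.

Calibration reporting uses the Brier score and the calibration slope, the
MLE of *s* in `y ~ Bernoulli(σ(s·lp))` — a one-parameter recalibration of
the linear predictor; 1 indicates a well-calibrated model.

## Surfaces and colors

A surface is the affiliate × month matrix of risk (or a descriptive
feature).  Display starts at the first grid month whose long window lies
fully inside the corpus span, so every shown cell rests on a complete
window.  Anchors are the minimum, arithmetic mean (median available by
option) and maximum over non-MISSING cells, computed per impact factor over
the full displayed surface.  Colors: value ≤ min → (0,255,0); value =
average → (255,255,0); value ≥ max → (255,0,0); linear per-channel
interpolation within each segment, rounded half-up; fully degenerate
anchors render all-yellow; MISSING cells carry no color.  Exports (long
CSV and structured JSON) are byte-deterministic; floats are written with
`repr` so re-imports are exact.

## Synthetic corpus generator

The generator emulates the statistical shape of a real multi-year PV
operational corpus.  Per named rate (late submission, invalidated AEs,
quality-review updates, …) each affiliate follows a logit-scale latent
process: a persistent level drawn Normal(logit(base), spread), a linear
drift over the span, and stationary AR(1) monthly noise.  Case, submission,
sales and study records are drawn monthly from these rates; audit and
inspection events are scheduled deterministically (the configured number
per calendar year, affiliates assigned by a seeded round-robin so
per-affiliate counts are balanced) and their per-factor outcomes drawn
Bernoulli(p\*) with

    p* = σ(b₀ + Σⱼ bⱼ · z(θ̄ⱼ)),

where θ̄ⱼ is the trailing 24-month mean of the latent rate — the quantity
the pipeline's window ratios estimate — standardized over all
(affiliate, month) cells.  Generating outcomes from the same functional
form the model fits makes parameter recovery a well-posed end-to-end test.
Every positive (event, factor) outcome receives at least one finding from
that factor's statement pool; with a fixed finding total the remainder is
allocated by a seeded multinomial, so the default profile matches its
target corpus size exactly rather than in expectation.

The default profile: 104 affiliates over 8 full years (2011–2018), 24
audits + 2 inspections per calendar year (208 events, exactly 2 per
affiliate), exactly 1171 findings (≈ 6 per event), 8 cases per
affiliate-month — enough volume for stable 24-month ratios while keeping
the corpus around 80k cases.  The non-ICSR factors are driven by
latent-only quality traits, since the corpus schema carries no observable
events for them.

What the generator does **not** emulate: real MedDRA-coded narratives,
country-specific submission deadline calendars, risk-biased audit targeting
(real audit schedules oversample suspicious affiliates; the balanced
round-robin is a deliberate simplification), cross-correlated anomaly rates,
and reporting volume tied to actual product portfolios.  Tests passing on
this corpus therefore demonstrate the pipeline's internal correctness and
identifiability, not predictive validity on any real affiliate network.

## Problem sizes for the heavier checks

Parameter recovery uses a 5000-event profile: 600 audits + 25 inspections
per year × 8 years over 125 affiliates (exactly 40 events each), 40 cases
per affiliate-month, true ICSR coefficients (−1.5, 1.0, −0.5, 2.0).  At
that volume a 24-month window holds ≈ 900 submissions, so the empirical
ratio noise (sd ≈ 0.012) is small against the cross-affiliate signal
(sd ≈ 0.09), bounding measurement-error attenuation of the coefficients
below ~3% — comfortably inside the 0.2 recovery tolerance, with fit
standard errors of a few hundredths.  Calibration self-consistency draws
10,000 held-out outcomes from the fitted model at resampled grid cells and
checks the Brier score against the constant-prevalence predictor and the
calibration slope against [0.8, 1.2].

## Numerical and design notes

- Duplicate record identifiers abort reading instead of being merged;
  silent dedup could mask generator or upstream bugs.
- `read_corpus` validates the parsed corpus and rejects any file set that
  violates an invariant, so reading never yields an invalid in-memory
  corpus; `validate_corpus` itself never raises and reports one issue per
  violated rule with record id and field.
- The corpus span travels in a `meta.json` sidecar so write→read is the
  identity even when no record touches the span endpoints; without it the
  span is derived from observed dates.
- Submissions live in their own `submissions.csv` keyed by case id; a
  JSON-lines cases file with nested submissions is supported for lossless
  single-file round-trips.
- The per-factor outcome labeling (rather than "any finding at all") is the
  default because each factor's model only sees its own features; the
  audit-level variant is available via `any_finding=True`.
- Models are fitted once per invocation on all supplied audits; no temporal
  refit schedule is imposed.  `evaluate_model` supports forward validation
  when a held-out set is supplied.
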