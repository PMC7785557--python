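# pvrisk

Quantitative, time-varying audit risk assessment for pharmacovigilance (PV)
affiliate networks.

Quality assurance teams at marketing authorization holders must decide which
of their many affiliates (local commercial entities) to audit for PV
compliance each cycle.  Traditional annual risk assessments review
operational data by hand against predefined *impact factors* — curated risk
areas such as "Compliance to Individual Case Safety Report (ICSR) process".
`pvrisk` automates that assessment: it turns streams of PV operational
events into monthly risk covariates per affiliate, fits one logistic model
per impact factor on past audit outcomes, and renders the estimated risk as
affiliate × month heatmap surfaces.

## The model

The risk of affiliate *a* at month *t* for impact factor *f* is the
unobserved probability *p* that an audit conducted then would yield at least
one finding mapped to *f*; an observed audit outcome is a realization of
Bernoulli(*p*).  Risk covariates x are summary statistics — mostly ratios,
so affiliates of different sizes stay comparable — computed over trailing
windows of the operational event streams (24-month long window, 6-month
short window, half-open `[t − W, t)` so covariates at an audit month use
strictly pre-audit data).  The shipped catalog covers case-processing and
submission timeliness ratios, unjustified-nonsubmission ratios split by
health authority and license partner, the invalidated-AE ratio, quality
review ratios, the primary-source reporting mix, submission-lateness
quantiles, active studies without reported AEs, and the cross-window
AE-per-unit-sold reporting-rate change.

Past audits are single points in each affiliate's covariate time series, so
the model is a logistic regression on the covariates at those points:

    p = σ(β₀ + Σⱼ βⱼ zⱼ),   zⱼ = (xⱼ − μⱼ) / σⱼ

with z-scoring by training statistics and an L2 penalty (λ = 1 by default,
intercept unpenalized) fitted by damped Newton iteration.  Impact factors
with too few usable audits or no quantitative features fall back to
descriptive surfaces.  Surfaces carry three color anchors — minimum,
average, maximum over displayed cells — rendered green, yellow, red with
linear per-channel interpolation.

The real corpora such a tool runs on are proprietary, so the package
includes a seeded synthetic generator (`pvrisk.synthetic`) whose default
profile matches the published corpus statistics (8 years, 24 audits + 2
inspections/year over 104 affiliates, exactly 1171 findings ≈ 6 per event)
and whose latent truth makes every stage testable end to end, including
parameter recovery.

## Worked example

```python
from pvrisk import (
    paper_profile_config, generate_corpus, build_feature_series,
    default_catalog, WindowSpec, assemble_training_set, fit_risk_model,
    predict_risk_series, build_risk_surface, default_mapping,
    ImpactFactor, FitConfig,
)

corpus, truth = generate_corpus(paper_profile_config(), seed=1)
series = build_feature_series(corpus, default_catalog(), WindowSpec())
train = assemble_training_set(series, corpus, default_mapping(),
                              ImpactFactor.ICSR_PROCESS)
model = fit_risk_model(train, FitConfig())
risk = predict_risk_series(model, series)
surface = build_risk_surface(risk, ImpactFactor.ICSR_PROCESS, span=corpus.span)
```

prints, with the summaries shown in the example script:

```
corpus: 79670 cases, 208 events, 1171 findings, 104 affiliates
ICSR_PROCESS: fitted on 205 audit rows, 114 with findings
intercept +0.478
  invalidated_ae_ratio         +0.872
  qc_updated_ratio             +0.868
  late_submission_ratio        +0.619
surface 104 affiliates x 72 months, anchors min=0.022 avg=0.559 max=0.999
```

The fitted coefficients are on the standardized scale: one standard
deviation more invalidated AEs in an affiliate's 24-month window raises the
log-odds of an ICSR-process finding by ≈ 0.87.  The surface spans 72 months
because display starts only once a full 24-month window fits inside the
8-year corpus; its anchors set the green/yellow/red color ramp.

The same pipeline is scriptable from the shell:

```sh
pvrisk --config config.yaml run-all --seed 1 --outdir out/
```

which writes the corpus, feature series, fitted models, predictions and
per-factor surface exports (CSV + JSON) under `out/`, byte-identically for
a given seed.

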