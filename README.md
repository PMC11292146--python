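# screenpref

Discrete choice experiment (DCE) analysis for cancer-screening preferences:
blocked design generation, synthetic cohort simulation, panel **mixed logit**
and latent-class (**mixed-mixed multinomial logit**) estimation by maximum
simulated likelihood, and post-estimation summaries — attribute importance
and predicted screening uptake.

The package is built for health-preference researchers studying how a
population trades off the attributes of colorectal-cancer screening tests —
procedure (colonoscopy, CT colonography, stool tests, a blood test), pain,
sensitivity, recommendation source, out-of-pocket cost and procedural risk —
and for methodologists who need a fully synthetic, seed-reproducible
test bed for these estimators.

## The model

Respondents repeatedly choose between two screening profiles and an opt-out.
Utilities follow a random-utility model

    U_ijt = x_jt' β_i + δ·1[j = left] + ε_ijt,   ε iid Gumbel,
    β_i ~ N(μ, diag(σ²)),

with dummy-coded attribute levels, a random opt-out constant and a fixed
left-position constant. The panel mixed logit integrates each respondent's
task-product of logit probabilities over β (quasi-Monte-Carlo with scrambled
Halton draws); the latent-class variant mixes C such models with a
multinomial-logit class-membership model over respondent covariates.
Estimators follow scikit-learn conventions (`fit`, fitted `*_` attributes,
`get_params`). See `docs/methods.md` for the full specification.

## Worked example

```python
import screenpref as sp

# 1. a 20-block x 10-task design with realism prohibitions and a fixed
#    dominant validity task
design = sp.generate_design(seed=1)
print(sp.coverage_report(design).estimable)        # True
print(sp.johnson_orme_min_n(c=5, t=2, a=10))       # 125

# 2. simulate a cohort from the built-in reference parameters
cohort = sp.simulate_respondents(1021, seed=1)
data = sp.simulate_choices(design, cohort, params=sp.reference_mxl_params(),
                           seed=1)
analysis, report = sp.apply_sample_filters(data)
print(report.to_dict())
# {'n_initial': 1021, 'n_missing_covariates': 0, 'n_failed_validity': 28,
#  'n_excluded': 28, 'n_analyzed': 993, 'pct_excluded': 2.74...}

# 3. fit the panel mixed logit (maximum simulated likelihood, 200 draws)
est = sp.MixedLogit(n_draws=200, seed=1, compute_se=False).fit(analysis)
p = est.params_
print(round(p.means[p.index("procedure=blood")], 2))   # 0.56
print(round(p.means[p.index("optout")], 2))            # -1.85

# 4. attribute importance and uptake
cri = sp.conditional_relative_importance(est.params_)
print(cri.normalized.idxmax())                     # 'cost'
base = {"procedure": "stool_2day", "pain": "no_pain", "sensitivity": "80",
        "recommendation": "hpb", "cost": "5", "risk": "no_risk"}
blood = {**base, "procedure": "blood"}
change = sp.uptake_change(est.params_, base, blood, mode="relative", seed=1)
print(round(change.change, 3))                     # 0.056
```

The simulated cohort (1021 respondents) loses 28 respondents to the
internal-validity filter; the refit recovers the generating blood-test
preference (0.40) and opt-out constant (−1.74) up to sampling noise; cost
carries the largest normalized conditional relative importance; and offering
the blood test instead of the 2-day stool test at the same price raises
predicted relative uptake by about 6%.

A command-line interface mirrors the pipeline
(`screenpref design generate`, `simulate`, `filter`, `fit-mxl`, `fit-mmml`,
`post cri`, `post uptake`, `report`); every subcommand takes `--seed` and
is byte-reproducible.

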