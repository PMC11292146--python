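"""Parameter-recovery experiments: simulate from the reference process, refit.

These are the package's end-to-end correctness checks: choices are simulated
from the built-in reference parameter sets on a generated design, the
estimators are run on the synthetic data, and the recovered parameters are
compared with the data-generating values.  Both the test suite and the
reproduction script drive these functions.

The recovery fits use the full simulated sample — every respondent and all
of their tasks, including the fixed validity task — since the estimand is
the data-generating parameter vector itself and no respondent filtering is
part of the data-generating process.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream_seed
from .cohort import default_covariate_spec, draw_individual_coefficients, simulate_choices, simulate_respondents
from .design import generate_design
from .mmml import LatentClassMixedLogit
from .mxl import MixedLogit
from .params import reference_mmml_params, reference_mxl_params

__all__ = ["mxl_recovery", "mmml_recovery", "MXL_RECOVERY_TARGETS"]

#: Coefficients tracked by the single-population recovery experiment:
#: (kind, coefficient name, data-generating value).
MXL_RECOVERY_TARGETS = [
    ("mean", "procedure=blood", 0.40),
    ("mean", "optout", -1.74),
    ("mean", "cost=1000", -3.88),
    ("sd", "sensitivity=60", 1.74),
]


def mxl_recovery(
    seed: int,
    n_replicates: int = 10,
    n_respondents: int = 1021,
    n_draws: int = 200,
    design_seed: int = 1,
) -> pd.DataFrame:
    """Simulate-and-refit replicates of the single-population mixed logit.

    Each replicate draws a fresh cohort and fresh choices from the reference
    parameter set on the same seed-``design_seed`` design (20 blocks x 10
    tasks) and refits by maximum simulated likelihood.  Returns one row per
    replicate with the recovered values of the tracked coefficients.
    """
    design = generate_design(seed=design_seed)
    params = reference_mxl_params()
    rows = []
    for r in range(n_replicates):
        rep_seed = substream_seed(seed, f"mxl_recovery{r}")
        cohort = simulate_respondents(n_respondents, seed=rep_seed)
        ds = simulate_choices(design, cohort, params=params, seed=rep_seed)
        est = MixedLogit(
            n_draws=n_draws, seed=rep_seed, compute_se=False, include_validity=True
        ).fit(ds)
        p = est.params_
        row = {"replicate": r, "seed": rep_seed, "loglik": est.loglik_,
               "converged": est.converged_}
        for kind, name, truth in MXL_RECOVERY_TARGETS:
            vec = p.means if kind == "mean" else p.sds
            row[f"{kind}:{name}"] = float(vec[p.index(name)])
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean recovered value, Monte-Carlo SE and truth per tracked coefficient."""
    out = []
    for kind, name, truth in MXL_RECOVERY_TARGETS:
        col = table[f"{kind}:{name}"]
        mcse = col.std(ddof=1) / np.sqrt(len(col))
        out.append(
            {"parameter": f"{kind}:{name}", "truth": truth,
             "recovered": col.mean(), "mc_se": mcse,
             "abs_bias_over_mcse": abs(col.mean() - truth) / mcse}
        )
    return pd.DataFrame(out).set_index("parameter")


def mmml_recovery(
    seed: int,
    n_respondents: int = 600,
    n_draws: int = 100,
    n_starts: int = 10,
    design_seed: int = 1,
    with_bic_baseline: bool = True,
) -> dict:
    """Simulate from the 2-class reference process and refit at reduced scale.

    Covariates come from the default spec, classes from the reference
    membership logit, choices from the class-specific coefficient
    distributions.  Returns the recovered weak-supporter blood coefficient,
    class shares, and (optionally) the BIC comparison against the
    single-population fit on the same data.
    """
    design = generate_design(seed=design_seed)
    mm = reference_mmml_params()
    rep_seed = substream_seed(seed, "mmml_recovery")
    cohort = simulate_respondents(
        n_respondents, default_covariate_spec(), seed=rep_seed
    )
    betas, lefts, classes = draw_individual_coefficients(
        mm, n_respondents, seed=rep_seed, covariates=cohort
    )
    ds = simulate_choices(design, cohort, betas=betas, lefts=lefts, seed=rep_seed)
    est = LatentClassMixedLogit(
        n_classes=2, n_draws=n_draws, seed=rep_seed, n_starts=n_starts,
        compute_se=False,
    ).fit(ds)
    weak = est.params_.classes[est.params_.class_labels.index("weak_supporters")]
    out = {
        "weak_blood_mean": float(weak.means[weak.index("procedure=blood")]),
        "truth_weak_blood_mean": 0.66,
        "true_class_shares": np.bincount(classes, minlength=2) / n_respondents,
        "shares_modal": est.posterior_.shares_modal,
        "shares_posterior": est.posterior_.shares_posterior,
        "loglik_2class": est.loglik_,
        "bic_2class": est.result_.bic,
        "converged": est.converged_,
        "degenerate": est.degenerate_,
        "n_respondents": n_respondents,
    }
    if with_bic_baseline:
        one = MixedLogit(
            n_draws=n_draws, seed=rep_seed, compute_se=False
        ).fit(ds)
        out["loglik_1class"] = one.loglik_
        out["bic_1class"] = one.result_.bic
        out["bic_prefers_2"] = bool(out["bic_2class"] < out["bic_1class"])
    return out
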