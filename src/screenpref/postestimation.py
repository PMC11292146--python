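"""Post-estimation summaries: attribute importance and screening uptake.

Conditional relative importance (CRI) measures, per attribute, the spread
between its best and worst level preference weights (the reference level
entering at zero); profile-based normalization rescales the CRIs to sum to
one.  Uptake prediction feeds a single program profile through the binary
take/opt-out logit, integrating over the coefficient mixing distribution,
and uptake changes carry simulation-based (Krinsky–Robb) confidence
intervals when estimator uncertainty is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream_seed
from .dataset import encode_dummies
from .design import AttributeSpace, Profile, default_space
from .likelihood import halton_normal_draws
from .params import MXLParams, OPTOUT

__all__ = [
    "CRITable",
    "UptakeEstimate",
    "conditional_relative_importance",
    "predict_uptake",
    "uptake_change",
]


@dataclass
class CRITable:
    """Raw (utility-unit) and normalized conditional relative importance."""

    table: pd.DataFrame  # index attribute, columns raw / normalized
    method: str

    @property
    def raw(self) -> pd.Series:
        return self.table["raw"]

    @property
    def normalized(self) -> pd.Series:
        return self.table["normalized"]


def _level_weights(params: MXLParams, space: AttributeSpace) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for a in space.attributes:
        weights = {}
        for lv in a.levels:
            if lv == a.reference:
                weights[lv] = 0.0
            else:
                weights[lv] = float(params.means[params.index(f"{a.name}={lv}")])
        out[a.name] = weights
    return out


def conditional_relative_importance(
    params: MXLParams,
    space: AttributeSpace | None = None,
    method: str = "population",
    n_draws: int = 2000,
    seed: int = 0,
) -> CRITable:
    """Conditional relative importance of each attribute.

    ``method="population"`` applies max - min to the population mean weights
    (references at 0).  ``method="individual"`` instead averages the per-draw
    max - min over the coefficient mixing distribution, which can reorder
    attributes whose heterogeneity differs; both are offered because the two
    definitions genuinely diverge.  Alternative-specific constants (opt-out,
    left) are excluded.  Normalized values sum to one.
    """
    space = space or default_space()
    names = [a.name for a in space.attributes]
    if method == "population":
        weights = _level_weights(params, space)
        raw = np.array(
            [max(weights[n].values()) - min(weights[n].values()) for n in names]
        )
    elif method == "individual":
        z = halton_normal_draws(n_draws, params.n_random, seed=seed)
        betas = params.means[None, :] + params.sds[None, :] * z  # (R, K)
        raw = np.empty(len(names))
        for i, a in enumerate(space.attributes):
            cols = np.zeros((n_draws, len(a.levels)))
            for j, lv in enumerate(a.levels):
                if lv != a.reference:
                    cols[:, j] = betas[:, params.index(f"{a.name}={lv}")]
            raw[i] = (cols.max(axis=1) - cols.min(axis=1)).mean()
    else:
        raise ValueError("method must be 'population' or 'individual'")
    total = raw.sum()
    normalized = raw / total if total > 0 else np.full_like(raw, np.nan)
    table = pd.DataFrame(
        {"raw": raw, "normalized": normalized},
        index=pd.Index(names, name="attribute"),
    )
    return CRITable(table=table, method=method)


@dataclass
class UptakeEstimate:
    """Predicted uptake of a program offer and its change versus a base."""

    uptake_base: float
    uptake_alt: float
    change: float
    mode: str
    ci_low: float
    ci_high: float
    n_coeff_draws: int
    reps: int
    seed: int
    undefined: bool = False


def _program_vector(
    program: Profile | dict, params: MXLParams, space: AttributeSpace
) -> np.ndarray:
    """Dummy vector of a program aligned to the random-coefficient order.

    The opt-out entry is zero: the program's utility excludes the opt-out
    constant, which sits on the opposite side of the take/decline logit.
    """
    if isinstance(program, dict):
        program = Profile.from_dict(program)
    x16 = encode_dummies(program, space)
    x = np.zeros(params.n_random)
    dummy_names = space.dummy_names()
    for val, name in zip(x16, dummy_names):
        x[params.index(name)] = val
    return x


def predict_uptake(
    params: MXLParams,
    program: Profile | dict,
    space: AttributeSpace | None = None,
    n_coeff_draws: int = 10_000,
    seed: int = 0,
) -> float:
    """Probability of taking a single offered program versus opting out.

    P(take) = E_beta[ exp(V) / (exp(V) + exp(ASC_optout)) ] with V = x'beta;
    no left constant enters (a lone offer has no position).  The expectation
    over the coefficient distribution (including the random opt-out
    constant) is taken by quasi-Monte-Carlo; with all SDs at zero this is
    the closed-form logistic.
    """
    space = space or default_space()
    x = _program_vector(program, params, space)
    asc_ix = params.index(OPTOUT)
    if np.all(params.sds == 0):
        v = float(x @ params.means) - float(params.means[asc_ix])
        return float(1.0 / (1.0 + np.exp(-v)))
    z = halton_normal_draws(
        n_coeff_draws, params.n_random, seed=substream_seed(seed, "uptake")
    )
    betas = params.means[None, :] + params.sds[None, :] * z
    v = betas @ x - betas[:, asc_ix]
    return float(np.mean(1.0 / (1.0 + np.exp(-v))))


def uptake_change(
    params: MXLParams,
    base: Profile | dict,
    alt: Profile | dict,
    mode: str = "relative",
    space: AttributeSpace | None = None,
    reps: int = 1000,
    n_coeff_draws: int = 2000,
    seed: int = 0,
    se: np.ndarray | pd.Series | None = None,
) -> UptakeEstimate:
    """Uptake change from switching the offered program, with a 95% CI.

    ``relative`` mode returns (P_alt - P_base) / P_base, ``absolute``
    P_alt - P_base.  When standard errors of the fitted means and SDs are
    supplied (``se``: length 2K, means then SDs, as produced by the fit
    table), the CI comes from Krinsky–Robb parametric resampling: parameter
    vectors are redrawn from the estimator's asymptotic normal, the change
    recomputed for each, and the 2.5/97.5 percentiles taken.  Without
    uncertainty information the CI is reported as NaN.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    space = space or default_space()
    p_base = predict_uptake(params, base, space, n_coeff_draws, seed)
    p_alt = predict_uptake(params, alt, space, n_coeff_draws, seed)
    undefined = mode == "relative" and p_base == 0.0
    if undefined:
        change = float("nan")
    elif mode == "relative":
        change = (p_alt - p_base) / p_base
    else:
        change = p_alt - p_base

    ci_low = ci_high = float("nan")
    if se is not None and not undefined:
        se = np.asarray(se, dtype=float)
        K = params.n_random
        if se.size != 2 * K:
            raise ValueError("se must stack mean and SD standard errors (2K values)")
        rng = np.random.default_rng(substream_seed(seed, "krinsky_robb"))
        draws_mu = params.means[None, :] + se[:K][None, :] * rng.standard_normal(
            (reps, K)
        )
        draws_sd = np.abs(
            params.sds[None, :] + se[K:][None, :] * rng.standard_normal((reps, K))
        )
        z = halton_normal_draws(
            n_coeff_draws, K, seed=substream_seed(seed, "uptake")
        )
        x_base = _program_vector(base, params, space)
        x_alt = _program_vector(alt, params, space)
        asc_ix = params.index(OPTOUT)
        changes = np.empty(reps)
        for j in range(reps):
            betas = draws_mu[j][None, :] + draws_sd[j][None, :] * z
            pb = np.mean(1.0 / (1.0 + np.exp(-(betas @ x_base - betas[:, asc_ix]))))
            pa = np.mean(1.0 / (1.0 + np.exp(-(betas @ x_alt - betas[:, asc_ix]))))
            changes[j] = (pa - pb) / pb if mode == "relative" else pa - pb
        ci_low, ci_high = np.percentile(changes, [2.5, 97.5])
    return UptakeEstimate(
        uptake_base=p_base,
        uptake_alt=p_alt,
        change=change,
        mode=mode,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_coeff_draws=n_coeff_draws,
        reps=reps,
        seed=seed,
        undefined=undefined,
    )
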