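"""Synthetic respondents and simulated two-stage choices.

The study's raw survey data are not public, so every downstream stage is
exercised on synthetic cohorts: respondent covariates drawn from a
documented specification, individual preference coefficients drawn from a
mixed-logit (or 2-class latent-class) population, and choices generated from
the random-utility model with i.i.d. Gumbel noise.  The two-stage task
(pick the better of two test profiles, then decide whether to actually take
the preferred test) is generated in its collapsed three-alternative form
{left, right, opt-out}, matching how the estimators model it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .dataset import ALTERNATIVES, ChoiceDataset, encode_dummies
from .design import Design
from .likelihood import class_prior_probs
from .params import MEMBERSHIP_COVARIATES, MMMLParams, MXLParams

__all__ = [
    "CovariateSpec",
    "default_covariate_spec",
    "simulate_respondents",
    "draw_individual_coefficients",
    "simulate_choices",
    "plant_missing_covariates",
    "plant_validity_failures",
]

EDUCATION_DUMMIES = ("educ_primary_secondary", "educ_university")


@dataclass
class CovariateSpec:
    """Marginal distributions of the respondent covariates.

    Binary covariates are independent Bernoulli; education is a 3-category
    draw (primary/secondary, pre-university, university+) coded as two
    dummies against the pre-university reference; the four psychosocial
    scores are independent normals that are median-centred within the
    simulated sample before any use, mirroring how continuous inventory
    scores enter the membership model.
    """

    binary: dict[str, float] = field(
        default_factory=lambda: {
            "female": 0.51,
            "chinese": 0.74,
            "age_61plus": 0.35,
            "income_high": 0.40,
            "married": 0.70,
            "housing_private": 0.20,
            "working": 0.60,
            "famhist_crc": 0.10,
            "screened_before": 0.40,
        }
    )
    education: tuple[float, float, float] = (0.45, 0.25, 0.30)
    continuous: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "safety_score": (20.0, 4.0),
            "social_support": (30.0, 6.0),
            "present_orientation": (30.0, 8.0),
            "intolerance_uncertainty": (60.0, 15.0),
        }
    )

    def validate(self) -> None:
        for name, p in self.binary.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability of {name!r} not in [0, 1]: {p}")
        if abs(sum(self.education) - 1.0) > 1e-9 or min(self.education) < 0:
            raise ValueError("education category probabilities must sum to 1")
        for name, (_, scale) in self.continuous.items():
            if scale < 0:
                raise ValueError(f"negative scale for {name!r}")


def default_covariate_spec() -> CovariateSpec:
    """Census-like marginals for an urban Asian population aged 40+."""
    return CovariateSpec()


def simulate_respondents(
    n: int,
    spec: CovariateSpec | None = None,
    seed: int = 0,
    n_blocks: int = 20,
) -> pd.DataFrame:
    """Draw a cohort of respondents with covariates and block assignments.

    Returns a frame keyed by ``respondent_id`` with binary dummies, the two
    education dummies, the median-centred psychosocial scores and a ``block``
    column (round-robin over blocks after a random shuffle).
    """
    if n < 1:
        raise ValueError("need at least one respondent")
    spec = spec or default_covariate_spec()
    spec.validate()
    rng = substream(seed, "cohort")
    out: dict[str, np.ndarray] = {"respondent_id": np.arange(1, n + 1)}
    for name, p in spec.binary.items():
        out[name] = (rng.random(n) < p).astype(float)
    edu = rng.choice(3, size=n, p=list(spec.education))
    out["educ_primary_secondary"] = (edu == 0).astype(float)
    out["educ_university"] = (edu == 2).astype(float)
    for name, (loc, scale) in spec.continuous.items():
        raw = rng.normal(loc, scale, size=n)
        out[name] = raw - np.median(raw)  # demedianed scores
    blocks = np.arange(n) % n_blocks
    rng.shuffle(blocks)
    out["block"] = blocks
    cols = (
        ["respondent_id"]
        + [c for c in MEMBERSHIP_COVARIATES]
        + ["block"]
    )
    return pd.DataFrame(out)[cols]


def draw_individual_coefficients(
    params: MXLParams | MMMLParams,
    n: int,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Draw per-respondent coefficient vectors from the population model.

    For a mixed logit each random coefficient is an independent
    Normal(mean, SD) draw; the fixed left constant is copied.  For the
    latent-class model each respondent's class is first drawn from the
    membership logit on their covariates, then coefficients from that
    class's distribution.

    Returns ``(betas, lefts, classes)`` with shapes (n, K), (n,) and (n,)
    (``classes`` is None for a plain mixed logit).
    """
    rng = substream(seed, "coefficients")
    if isinstance(params, MXLParams):
        if np.any(params.sds < 0):
            raise ValueError("negative SD")
        z = rng.standard_normal((n, params.n_random))
        betas = params.means[None, :] + params.sds[None, :] * z
        return betas, np.full(n, params.left), None
    if not isinstance(params, MMMLParams):
        raise TypeError("params must be MXLParams or MMMLParams")
    if covariates is None:
        raise ValueError("latent-class simulation needs respondent covariates")
    Z = np.column_stack(
        [
            np.ones(n),
            covariates[params.membership_names].to_numpy(dtype=float),
        ]
    )
    pi = class_prior_probs(params.gamma, Z)
    u = rng.random(n)
    classes = (u[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)
    K = params.classes[0].n_random
    betas = np.empty((n, K))
    lefts = np.empty(n)
    z = rng.standard_normal((n, K))
    for c, cls in enumerate(params.classes):
        sel = classes == c
        betas[sel] = cls.means[None, :] + cls.sds[None, :] * z[sel]
        lefts[sel] = cls.left
    return betas, lefts, classes


def _block_templates(design: Design):
    """Per-block long-format row templates and numeric feature arrays."""
    space = design.space
    n_dum = space.n_dummies()
    A = len(ALTERNATIVES)
    templates = []
    for b, block in enumerate(design.blocks):
        T = len(block)
        X = np.zeros((T, A, n_dum + 2))
        cols: dict[str, list] = {name: [] for name in space.names}
        cols["task_id"] = []
        cols["alt"] = []
        cols["is_validity"] = []
        for t, task in enumerate(block):
            task_id = f"b{b:02d}_t{t:02d}"
            for a_i, (alt, profile) in enumerate(
                zip(ALTERNATIVES, (task.left, task.right, None))
            ):
                cols["task_id"].append(task_id)
                cols["alt"].append(alt)
                cols["is_validity"].append(task.is_validity_task)
                if profile is None:  # opt-out: no attributes
                    for name in space.names:
                        cols[name].append("")
                    X[t, a_i, n_dum] = 1.0
                else:
                    d = profile.as_dict
                    for name in space.names:
                        cols[name].append(d[name])
                    X[t, a_i, :n_dum] = encode_dummies(profile, space)
            X[t, 0, n_dum + 1] = 1.0  # left-position flag
        templates.append((cols, X))
    return templates


def simulate_choices(
    design: Design,
    cohort: pd.DataFrame,
    params: MXLParams | MMMLParams | None = None,
    betas: np.ndarray | None = None,
    lefts: np.ndarray | None = None,
    seed: int = 0,
) -> ChoiceDataset:
    """Simulate every respondent's choices on their assigned block.

    Utilities are U = x'beta_i (+ left constant for the left alternative,
    opt-out constant via the opt-out indicator) plus i.i.d. Gumbel noise;
    the chosen alternative is the argmax — the collapsed three-alternative
    representation of the two-stage task.  Pass ``params`` to draw
    individual coefficients internally, or ``betas``/``lefts`` to reuse
    externally drawn ones.
    """
    if "block" not in cohort.columns:
        raise ValueError("every respondent needs a block assignment")
    blocks = cohort["block"].to_numpy()
    if np.any(blocks < 0) or np.any(blocks >= design.n_blocks):
        raise ValueError("block assignment outside the design's blocks")
    n = len(cohort)
    if betas is None:
        if params is None:
            raise ValueError("provide params or explicit betas")
        betas, lefts, _ = draw_individual_coefficients(
            params, n, seed=seed, covariates=cohort
        )
    if lefts is None:
        raise ValueError("explicit betas also need explicit lefts")

    templates = _block_templates(design)
    K = betas.shape[1]
    T = design.tasks_per_block
    A = len(ALTERNATIVES)
    Xs = np.stack([tpl[1] for tpl in templates])  # (B, T, A, K+2)
    Xresp = Xs[blocks]  # (n, T, A, K+2)
    V = np.einsum("ntak,nk->nta", Xresp[..., :K], betas, optimize=True)
    V += lefts[:, None, None] * Xresp[..., K]  # left-position flag column
    rng = substream(seed, "gumbel")
    U = V + rng.gumbel(size=(n, T, A))
    chosen_alt = U.argmax(axis=2)  # (n, T)

    # assemble the long frame block-template-wise
    space = design.space
    col_names = ["task_id", "alt", "is_validity"] + space.names
    data_cols: dict[str, list] = {name: [] for name in col_names}
    resp_col = np.repeat(cohort["respondent_id"].to_numpy(), T * A)
    for b in blocks:
        tpl = templates[b][0]
        for name in col_names:
            data_cols[name].extend(tpl[name])
    alt_pattern = np.tile(np.arange(A), n * T)
    chosen_flat = np.repeat(chosen_alt.reshape(-1), A)
    df = pd.DataFrame(data_cols)
    df.insert(0, "respondent_id", resp_col)
    df["chosen"] = (alt_pattern == chosen_flat).astype(int)
    covariates = cohort.drop(columns=["block"])
    return ChoiceDataset(df, space=space, covariates=covariates)


# ---------------------------------------------------------------------------
# Planted data problems (for exercising the sample filters)
# ---------------------------------------------------------------------------

def plant_missing_covariates(
    cohort: pd.DataFrame, respondent_ids, column: str = "safety_score"
) -> pd.DataFrame:
    """Return a copy with one covariate blanked for the given respondents."""
    out = cohort.copy()
    out.loc[out["respondent_id"].isin(set(respondent_ids)), column] = np.nan
    return out


def plant_validity_failures(dataset: ChoiceDataset, respondent_ids) -> ChoiceDataset:
    """Force the given respondents to fail the internal-validity task.

    Their chosen alternative on every validity task is moved to the right
    (dominated) profile.
    """
    df = dataset.data.copy()
    sel = df["is_validity"].astype(bool) & df["respondent_id"].isin(
        set(respondent_ids)
    )
    df.loc[sel, "chosen"] = 0
    df.loc[sel & (df["alt"] == "right"), "chosen"] = 1
    return ChoiceDataset(df, dataset.space, dataset.covariates)
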