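"""Parameter containers for mixed logit and latent-class mixed logit models.

Also provides the built-in reference parameter sets — population preference
weights estimated from a large Singapore survey of colorectal-cancer
screening preferences — which the synthetic cohort uses as its default
data-generating process, so that parameter-recovery experiments target
realistic magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import AttributeSpace, default_space

__all__ = [
    "OPTOUT",
    "MXLParams",
    "MMMLParams",
    "MEMBERSHIP_COVARIATES",
    "reference_mxl_params",
    "reference_mmml_params",
]

#: Name of the opt-out alternative-specific constant among random coefficients.
OPTOUT = "optout"

#: Covariates of the class-membership model, in canonical column order.
#: Binary dummies are coded 1 for the named category; the four trailing
#: psychosocial scores enter median-centred.
MEMBERSHIP_COVARIATES = [
    "female",
    "chinese",
    "age_61plus",
    "income_high",
    "married",
    "educ_primary_secondary",
    "educ_university",
    "housing_private",
    "working",
    "famhist_crc",
    "screened_before",
    "safety_score",
    "social_support",
    "present_orientation",
    "intolerance_uncertainty",
]


@dataclass
class MXLParams:
    """Population parameters of a panel mixed logit.

    ``coef_names`` lists the random coefficients: one dummy per non-reference
    attribute level plus the opt-out alternative-specific constant.  Each is
    independently normal with mean ``means[k]`` and standard deviation
    ``sds[k]`` across respondents.  ``left`` is the fixed (non-random)
    left-position constant capturing reading-order bias.
    """

    coef_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    left: float = 0.0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.abs(np.asarray(self.sds, dtype=float))
        if not (len(self.coef_names) == self.means.size == self.sds.size):
            raise ValueError("coef_names, means and sds must have equal length")

    @property
    def n_random(self) -> int:
        return len(self.coef_names)

    def index(self, name: str) -> int:
        return self.coef_names.index(name)

    def to_dict(self) -> dict:
        return {
            "coef_names": list(self.coef_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "left": float(self.left),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MXLParams":
        return cls(
            coef_names=list(d["coef_names"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            left=float(d["left"]),
        )


@dataclass
class MMMLParams:
    """Parameters of a C-class mixed-mixed multinomial logit.

    Each latent class carries its own :class:`MXLParams`.  Class membership
    follows a multinomial logit on respondent covariates with class 1 as the
    reference: ``gamma`` has one row per non-reference class (classes 2..C)
    over ``["intercept"] + membership_names``.
    """

    classes: list[MXLParams]
    gamma: np.ndarray
    membership_names: list[str] = field(default_factory=lambda: list(MEMBERSHIP_COVARIATES))
    class_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if len(self.classes) < 2:
            raise ValueError("a latent-class model needs at least 2 classes")
        if self.gamma.shape != (len(self.classes) - 1, len(self.membership_names) + 1):
            raise ValueError(
                "gamma must be (n_classes - 1) x (1 + n_membership_covariates)"
            )

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def to_dict(self) -> dict:
        return {
            "classes": [c.to_dict() for c in self.classes],
            "gamma": self.gamma.tolist(),
            "membership_names": list(self.membership_names),
            "class_labels": self.class_labels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MMMLParams":
        return cls(
            classes=[MXLParams.from_dict(c) for c in d["classes"]],
            gamma=np.asarray(d["gamma"], dtype=float),
            membership_names=list(d["membership_names"]),
            class_labels=d.get("class_labels"),
        )


def random_coef_names(space: AttributeSpace | None = None) -> list[str]:
    """Names of the random coefficients: attribute dummies then the opt-out."""
    if space is None:
        space = default_space()
    return space.dummy_names() + [OPTOUT]


# Reference estimates (mean, SD) of the single-population mixed logit for the
# default six-attribute space; utility units.  SDs measure between-respondent
# preference heterogeneity.
_MXL_REFERENCE = {
    "procedure=colonoscopy": (-0.73, 0.98),
    "procedure=ct_colonography": (-0.75, 0.65),
    "procedure=stool_1day": (0.27, 0.93),
    "procedure=blood": (0.40, 0.91),
    "pain=mild_pain": (-0.54, 0.26),
    "sensitivity=100": (1.63, 0.09),
    "sensitivity=95": (0.70, 0.02),
    "sensitivity=60": (-1.26, 1.74),
    "recommendation=hpb": (0.88, 0.11),
    "recommendation=doctors": (0.68, 0.01),
    "recommendation=family_friends": (0.35, 0.21),
    "cost=5": (-0.35, 0.38),
    "cost=30": (-0.81, 0.08),
    "cost=400": (-2.39, 0.46),
    "cost=1000": (-3.88, 1.53),
    "risk=1pct_adverse": (-0.74, 0.05),
    OPTOUT: (-1.74, 3.86),
}
_MXL_REFERENCE_LEFT = 0.13

# Reference class means of the 2-class model.  Class 1 ("strong supporters")
# has a strongly negative opt-out constant — they screen almost regardless of
# the offer; class 2 ("weak supporters") is closer to indifferent about
# screening but clearly prefers the blood test to the 2-day stool test.
_MMML_CLASS_MEANS = {
    "strong_supporters": {
        "left": 0.28,
        OPTOUT: -5.13,
        "procedure=colonoscopy": -0.35,
        "procedure=ct_colonography": -0.53,
        "procedure=stool_1day": -0.20,
        "procedure=blood": 0.06,
        "pain=mild_pain": -0.25,
        "sensitivity=100": 2.92,
        "sensitivity=95": 1.58,
        "sensitivity=60": -1.65,
        "recommendation=hpb": 1.24,
        "recommendation=doctors": 0.89,
        "recommendation=family_friends": 0.17,
        "cost=5": -0.67,
        "cost=30": -0.97,
        "cost=400": -2.24,
        "cost=1000": -4.00,
        "risk=1pct_adverse": -0.60,
    },
    "weak_supporters": {
        "left": 0.08,
        OPTOUT: -0.86,
        "procedure=colonoscopy": -1.05,
        "procedure=ct_colonography": -1.01,
        "procedure=stool_1day": 0.63,
        "procedure=blood": 0.66,
        "pain=mild_pain": -0.84,
        "sensitivity=100": 1.25,
        "sensitivity=95": 0.42,
        "sensitivity=60": -0.96,
        "recommendation=hpb": 0.79,
        "recommendation=doctors": 0.67,
        "recommendation=family_friends": 0.40,
        "cost=5": -0.33,
        "cost=30": -0.83,
        "cost=400": -2.93,
        "cost=1000": -4.46,
        "risk=1pct_adverse": -1.04,
    },
}

# Class-membership coefficients for class 2 (weak supporters) vs class 1.
# The intercept is this package's own calibration: chosen so that, under the
# default covariate spec, prior class shares approximate the reference
# 38% / 62% strong/weak split.
_MMML_GAMMA2 = {
    "intercept": 0.76,
    "female": 0.19,
    "chinese": 0.52,
    "age_61plus": -0.52,
    "income_high": -0.13,
    "married": -0.06,
    "educ_primary_secondary": 0.08,
    "educ_university": 0.02,
    "housing_private": -0.47,
    "working": -0.24,
    "famhist_crc": -0.74,
    "screened_before": -0.52,
    "safety_score": -0.16,
    "social_support": -0.03,
    "present_orientation": -0.03,
    "intolerance_uncertainty": -0.01,
}

#: Stand-in scaling for the within-class coefficient SDs of the reference
#: 2-class model (the class-specific SDs are not published): the
#: single-population SDs shrunk by this factor, since part of the population
#: heterogeneity is absorbed by the class split.
WITHIN_CLASS_SD_SCALE = 0.7


def reference_mxl_params(space: AttributeSpace | None = None) -> MXLParams:
    """The built-in single-population mixed-logit parameter set."""
    names = random_coef_names(space)
    missing = [n for n in names if n not in _MXL_REFERENCE]
    if missing:
        raise ValueError(f"no reference values for coefficients {missing}")
    means = np.array([_MXL_REFERENCE[n][0] for n in names])
    sds = np.array([_MXL_REFERENCE[n][1] for n in names])
    return MXLParams(coef_names=names, means=means, sds=sds, left=_MXL_REFERENCE_LEFT)


def reference_mmml_params(
    space: AttributeSpace | None = None,
    sd_scale: float = WITHIN_CLASS_SD_SCALE,
) -> MMMLParams:
    """The built-in 2-class parameter set with stand-in within-class SDs."""
    names = random_coef_names(space)
    base_sds = np.array([_MXL_REFERENCE[n][1] for n in names])
    classes = []
    labels = list(_MMML_CLASS_MEANS)
    for label in labels:
        table = _MMML_CLASS_MEANS[label]
        classes.append(
            MXLParams(
                coef_names=names,
                means=np.array([table[n] for n in names]),
                sds=sd_scale * base_sds,
                left=table["left"],
            )
        )
    gamma = np.array(
        [[_MMML_GAMMA2["intercept"]] + [_MMML_GAMMA2[n] for n in MEMBERSHIP_COVARIATES]]
    )
    return MMMLParams(
        classes=classes,
        gamma=gamma,
        membership_names=list(MEMBERSHIP_COVARIATES),
        class_labels=labels,
    )
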