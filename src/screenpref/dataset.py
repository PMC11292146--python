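"""Long-format choice data and its numeric panel encoding.

A :class:`ChoiceDataset` stores one row per (respondent, task, alternative)
with the alternative's attribute levels, a chosen flag and a left-position
flag, together with an optional respondent covariate table.  Estimation works
on the dense :class:`PanelArrays` encoding: a respondents x tasks x
alternatives x features array of dummy-coded regressors.

Alternatives are ordered left, right, opt-out.  The opt-out alternative has
every attribute dummy at zero and a dedicated indicator that carries its
alternative-specific constant; the left alternative alone carries the
left-position indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import AttributeSpace, Profile, default_space
from .params import MEMBERSHIP_COVARIATES, OPTOUT

__all__ = [
    "ALTERNATIVES",
    "LEFT_FLAG",
    "ChoiceDataset",
    "PanelArrays",
    "encode_dummies",
    "profile_dummy_vector",
]

ALTERNATIVES = ("left", "right", "optout")
LEFT_FLAG = "left_const"


def encode_dummies(profile: Profile | dict, space: AttributeSpace) -> np.ndarray:
    """Dummy-code a profile: one indicator per non-reference level.

    Reference levels contribute all-zeros, so the all-reference profile maps
    to the zero vector.  Vector length is ``space.n_dummies()`` (16 for the
    default space), in ``space.dummy_names()`` order.
    """
    if isinstance(profile, dict):
        profile = Profile.from_dict(profile)
    space.validate_profile(profile)
    d = profile.as_dict
    out = np.zeros(space.n_dummies())
    i = 0
    for a in space.attributes:
        for lv in a.levels:
            if lv != a.reference:
                if d[a.name] == lv:
                    out[i] = 1.0
                i += 1
    return out


# Backwards-compatible alias used by the design diagnostics.
profile_dummy_vector = encode_dummies


@dataclass
class PanelArrays:
    """Dense numeric encoding of a balanced choice panel.

    Attributes
    ----------
    X : ndarray, shape (N, T, 3, K)
        Feature array; columns are the attribute dummies, then the opt-out
        indicator, then the left-position indicator (the last column is the
        only fixed-coefficient feature).
    chosen : ndarray of int, shape (N, T)
        Index of the chosen alternative per task.
    mask : ndarray of bool, shape (N, T)
        False for padding when respondents have unequal task counts.
    resp_ids : ndarray, shape (N,)
    feature_names : list of str
    """

    X: np.ndarray
    chosen: np.ndarray
    mask: np.ndarray
    resp_ids: np.ndarray
    feature_names: list[str]

    @property
    def n_respondents(self) -> int:
        return self.X.shape[0]

    @property
    def n_random(self) -> int:
        """Number of random-coefficient features (all but the left flag)."""
        return self.X.shape[3] - 1

    @property
    def n_choices(self) -> int:
        """Total number of observed choice tasks (mask-aware)."""
        return int(self.mask.sum())


class ChoiceDataset:
    """Long-format panel of discrete choices plus respondent covariates."""

    def __init__(
        self,
        data: pd.DataFrame,
        space: AttributeSpace | None = None,
        covariates: pd.DataFrame | None = None,
    ):
        self.space = space if space is not None else default_space()
        self.data = data.reset_index(drop=True)
        self.covariates = covariates
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        required = {"respondent_id", "task_id", "alt", "chosen"} | set(self.space.names)
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"choice data missing columns: {sorted(missing)}")
        errors: list[str] = []
        bad_alt = set(self.data["alt"].unique()) - set(ALTERNATIVES)
        if bad_alt:
            errors.append(f"unknown alternatives {sorted(bad_alt)}")
        for a in self.space.attributes:
            col = self.data.loc[self.data["alt"] != "optout", a.name]
            bad = set(col.dropna().astype(str).unique()) - set(a.levels)
            if bad:
                errors.append(f"unknown levels {sorted(bad)} for attribute {a.name!r}")
        grp = self.data.groupby(["respondent_id", "task_id"], sort=False)
        sizes = grp.size()
        if (sizes != len(ALTERNATIVES)).any():
            bad_tasks = sizes.index[sizes != len(ALTERNATIVES)].tolist()[:5]
            errors.append(
                f"each task needs exactly {len(ALTERNATIVES)} alternative rows; "
                f"offending tasks (first 5): {bad_tasks}"
            )
        n_chosen = grp["chosen"].sum()
        if (n_chosen != 1).any():
            bad_tasks = n_chosen.index[n_chosen != 1].tolist()[:5]
            errors.append(
                f"each task needs exactly one chosen row; offending tasks "
                f"(first 5): {bad_tasks}"
            )
        if errors:
            raise ValueError("invalid choice data: " + "; ".join(errors))

    # -- accessors ----------------------------------------------------------

    @property
    def respondent_ids(self) -> np.ndarray:
        return self.data["respondent_id"].unique()

    @property
    def n_respondents(self) -> int:
        return self.respondent_ids.size

    def drop_validity_tasks(self) -> "ChoiceDataset":
        if "is_validity" not in self.data.columns:
            return self
        keep = self.data[~self.data["is_validity"].astype(bool)]
        return ChoiceDataset(keep, self.space, self.covariates)

    def subset(self, respondent_ids) -> "ChoiceDataset":
        keep = self.data[self.data["respondent_id"].isin(set(respondent_ids))]
        cov = self.covariates
        if cov is not None:
            cov = cov[cov["respondent_id"].isin(set(respondent_ids))].reset_index(
                drop=True
            )
        return ChoiceDataset(keep, self.space, cov)

    # -- numeric encoding ---------------------------------------------------

    def to_panel(self) -> PanelArrays:
        """Encode to dense arrays (respondents x tasks x 3 alts x features)."""
        space = self.space
        n_dum = space.n_dummies()
        feature_names = space.dummy_names() + [OPTOUT, LEFT_FLAG]
        df = self.data
        resp_ids = df["respondent_id"].unique()
        resp_index = {r: i for i, r in enumerate(resp_ids)}
        alt_index = {a: i for i, a in enumerate(ALTERNATIVES)}

        tasks_per_resp = df.groupby("respondent_id", sort=False)["task_id"].nunique()
        T = int(tasks_per_resp.max())
        N = resp_ids.size
        X = np.zeros((N, T, len(ALTERNATIVES), n_dum + 2))
        X[:, :, alt_index["optout"], n_dum] = 1.0
        X[:, :, alt_index["left"], n_dum + 1] = 1.0
        chosen = np.zeros((N, T), dtype=np.int64)
        mask = np.zeros((N, T), dtype=bool)

        # dummy-code every non-optout row in one vectorized pass
        non_opt = df[df["alt"] != "optout"]
        cols = []
        for a in space.attributes:
            lv = non_opt[a.name].astype(str)
            for level in a.levels:
                if level != a.reference:
                    cols.append((lv == level).to_numpy(dtype=float))
        dummies = np.column_stack(cols) if cols else np.zeros((len(non_opt), 0))

        task_slot: dict[tuple, int] = {}
        next_slot = np.zeros(N, dtype=np.int64)
        ridx = df["respondent_id"].map(resp_index).to_numpy()
        tids = df["task_id"].to_numpy()
        for key in zip(ridx, tids):
            if key not in task_slot:
                task_slot[key] = int(next_slot[key[0]])
                next_slot[key[0]] += 1
        tslot = np.array([task_slot[k] for k in zip(ridx, tids)])
        aidx = df["alt"].map(alt_index).to_numpy()

        non_opt_mask = (df["alt"] != "optout").to_numpy()
        X[ridx[non_opt_mask], tslot[non_opt_mask], aidx[non_opt_mask], :n_dum] = dummies
        mask[ridx, tslot] = True
        ch = df["chosen"].astype(int).to_numpy()
        sel = ch == 1
        chosen[ridx[sel], tslot[sel]] = aidx[sel]
        return PanelArrays(
            X=X,
            chosen=chosen,
            mask=mask,
            resp_ids=resp_ids,
            feature_names=feature_names,
        )

    def covariate_matrix(
        self, names: list[str] | None = None, add_intercept: bool = True
    ) -> tuple[np.ndarray, list[str]]:
        """Covariate design matrix aligned to panel respondent order.

        Respondents with any missing covariate get NaN rows (the sample
        filter removes them before estimation).
        """
        if self.covariates is None:
            raise ValueError("dataset has no covariate table")
        if names is None:
            names = [c for c in MEMBERSHIP_COVARIATES if c in self.covariates.columns]
        cov = self.covariates.set_index("respondent_id").reindex(self.respondent_ids)
        Z = cov[names].to_numpy(dtype=float)
        if add_intercept:
            Z = np.column_stack([np.ones(len(Z)), Z])
            return Z, ["intercept"] + list(names)
        return Z, list(names)
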