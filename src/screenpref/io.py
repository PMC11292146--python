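"""Reading, writing and filtering of choice data, designs and parameters.

CSV formats are plain RFC-4180 UTF-8; JSON outputs carry a
``schema_version`` field.  The sample filters reproduce the study-style
exclusions: respondents with incomplete covariates and respondents who chose
the dominated alternative in the internal-validity task are removed (as a
union — the two failure sets may overlap), and validity-task rows are
dropped from the analysis set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .dataset import ChoiceDataset
from .design import (
    Attribute,
    AttributeSpace,
    ChoiceTask,
    Design,
    Profile,
    Prohibition,
    is_dominant,
)
from .params import MMMLParams, MXLParams

SCHEMA_VERSION = 1

__all__ = [
    "FilterReport",
    "design_to_json",
    "design_from_json",
    "write_design",
    "read_design",
    "write_choice_csv",
    "validate_choice_csv",
    "read_covariates_csv",
    "write_params",
    "read_params",
    "apply_sample_filters",
]


# ---------------------------------------------------------------------------
# Design JSON
# ---------------------------------------------------------------------------

def design_to_json(design: Design) -> dict:
    space = design.space
    return {
        "schema_version": SCHEMA_VERSION,
        "seed": design.seed,
        "attributes": [
            {
                "name": a.name,
                "levels": list(a.levels),
                "reference": a.reference,
                "order": list(a.ranking) if a.ranking else None,
            }
            for a in space.attributes
        ],
        "prohibitions": [sorted(p.clauses) for p in design.prohibitions],
        "blocks": [
            [
                {
                    "left": t.left.as_dict,
                    "right": t.right.as_dict,
                    "validity": t.is_validity_task,
                }
                for t in block
            ]
            for block in design.blocks
        ],
    }


def design_from_json(doc: dict) -> Design:
    space = AttributeSpace(
        tuple(
            Attribute(
                name=a["name"],
                levels=tuple(a["levels"]),
                reference=a["reference"],
                ranking=tuple(a["order"]) if a.get("order") else None,
            )
            for a in doc["attributes"]
        )
    )
    prohibitions = tuple(
        Prohibition(frozenset(tuple(clause) for clause in p))
        for p in doc["prohibitions"]
    )
    blocks = []
    fixed = None
    for block in doc["blocks"]:
        tasks = []
        for t in block:
            task = ChoiceTask(
                left=Profile.from_dict(t["left"]),
                right=Profile.from_dict(t["right"]),
                is_validity_task=bool(t["validity"]),
            )
            if task.is_validity_task and fixed is None:
                fixed = task
            tasks.append(task)
        blocks.append(tuple(tasks))
    if fixed is None:
        raise ValueError("design JSON contains no validity task")
    return Design(
        space=space,
        blocks=tuple(blocks),
        fixed_task=fixed,
        prohibitions=prohibitions,
        seed=int(doc.get("seed", 0)),
    )


def write_design(design: Design, path) -> None:
    Path(path).write_text(json.dumps(design_to_json(design), indent=1))


def read_design(path) -> Design:
    return design_from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Choice / covariate CSV
# ---------------------------------------------------------------------------

def write_choice_csv(dataset: ChoiceDataset, path) -> None:
    df = dataset.data.copy()
    df["left_flag"] = (df["alt"] == "left").astype(int)
    df.to_csv(path, index=False)


def validate_choice_csv(path, space: AttributeSpace | None = None) -> ChoiceDataset:
    """Read and schema-check a long-format choice CSV.

    Raises ``ValueError`` itemizing the problems (duplicate chosen rows,
    unknown levels, malformed tasks) when the file is invalid.
    """
    df = pd.read_csv(path, dtype={"respondent_id": "int64"}, keep_default_na=False)
    for col, dtype in (("chosen", int),):
        if col in df.columns:
            df[col] = df[col].astype(dtype)
    df = df.drop(columns=[c for c in ("left_flag",) if c in df.columns])
    if "is_validity" in df.columns:
        df["is_validity"] = df["is_validity"].astype(str).isin(("True", "true", "1"))
    return ChoiceDataset(df, space=space)


def read_covariates_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Parameter JSON
# ---------------------------------------------------------------------------

def write_params(params: MXLParams | MMMLParams, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": "mmml" if isinstance(params, MMMLParams) else "mxl",
        "params": params.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_params(path) -> MXLParams | MMMLParams:
    doc = json.loads(Path(path).read_text())
    cls = MMMLParams if doc["kind"] == "mmml" else MXLParams
    return cls.from_dict(doc["params"])


# ---------------------------------------------------------------------------
# Sample filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Exclusion bookkeeping for the analysis sample."""

    n_initial: int
    n_missing_covariates: int
    n_failed_validity: int
    n_excluded: int
    n_analyzed: int

    @property
    def pct_excluded(self) -> float:
        return 100.0 * self.n_excluded / self.n_initial if self.n_initial else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pct_excluded"] = self.pct_excluded
        return d


def _validity_failures(dataset: ChoiceDataset) -> set:
    """Respondents who chose the dominated profile in a validity task."""
    df = dataset.data
    if "is_validity" not in df.columns:
        return set()
    vdf = df[df["is_validity"].astype(bool)]
    if vdf.empty:
        return set()
    space = dataset.space
    failures = set()
    dominated_cache: dict[tuple, str | None] = {}
    for (resp, _), grp in vdf.groupby(["respondent_id", "task_id"], sort=False):
        rows = grp.set_index("alt")
        profiles = {
            alt: Profile.from_dict(
                {name: str(rows.loc[alt, name]) for name in space.names}
            )
            for alt in ("left", "right")
        }
        key = (profiles["left"].assignment, profiles["right"].assignment)
        if key not in dominated_cache:
            task = ChoiceTask(left=profiles["left"], right=profiles["right"],
                              is_validity_task=True)
            dominated: str | None = None
            if is_dominant(task, space):
                left_wins = _profile_weakly_better(
                    profiles["left"], profiles["right"], space
                )
                dominated = "right" if left_wins else "left"
            dominated_cache[key] = dominated
        dominated = dominated_cache[key]
        if dominated is None:
            continue
        chosen_alt = grp.loc[grp["chosen"] == 1, "alt"].iloc[0]
        if chosen_alt == dominated:
            failures.add(resp)
    return failures


def _profile_weakly_better(a: Profile, b: Profile, space: AttributeSpace) -> bool:
    strict = False
    for attr in space.attributes:
        la, lb = a[attr.name], b[attr.name]
        if attr.ranking is None:
            if la != lb:
                return False
        else:
            ra, rb = attr.rank(la), attr.rank(lb)
            if ra > rb:
                return False
            if ra < rb:
                strict = True
    return strict


def apply_sample_filters(
    dataset: ChoiceDataset, covariates: pd.DataFrame | None = None
) -> tuple[ChoiceDataset, FilterReport]:
    """Drop respondents with missing covariates or a failed validity task.

    The two exclusion sets are combined as a union (they may overlap), the
    marginal counts are reported separately, and validity-task rows are
    removed from the returned analysis dataset.
    """
    cov = covariates if covariates is not None else dataset.covariates
    all_ids = set(dataset.respondent_ids)
    n_initial = len(all_ids)

    missing: set = set()
    if cov is not None:
        value_cols = [c for c in cov.columns if c != "respondent_id"]
        bad = cov[cov[value_cols].isna().any(axis=1)]["respondent_id"]
        missing = set(bad) & all_ids
        # respondents absent from the covariate table count as incomplete
        missing |= all_ids - set(cov["respondent_id"])

    failed = _validity_failures(dataset)
    excluded = missing | failed
    keep = all_ids - excluded
    filtered = dataset.subset(keep).drop_validity_tasks()
    report = FilterReport(
        n_initial=n_initial,
        n_missing_covariates=len(missing),
        n_failed_validity=len(failed),
        n_excluded=len(excluded),
        n_analyzed=len(keep),
    )
    return filtered, report
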