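"""Decision-criteria universe and panel-response validation.

An MCDA appraisal is organized around a matrix of quantitative decision
criteria grouped into four clusters — quality of evidence, disease impact,
intervention, and economics — plus qualitative *contextual* criteria that
never enter the quantitative model. Committee members rate each active
matrix criterion twice: a *weight* (importance, integers 1–5) elicited
independently of the intervention, and a *score* (appraisal of the
intervention, integers 0–3) based on the evidence report.

The bundled default configuration describes a 15-criterion matrix of which
one criterion (Q1, adherence to decisionmaking-body requirements) is
excluded, leaving 14 active criteria, together with four contextual
criteria supplied by the healthcare funder.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "Criterion",
    "ContextualCriterion",
    "CriteriaSet",
    "PanelFragment",
    "CriteriaConfigError",
    "PanelValidationError",
    "RangeError",
    "ExclusionError",
    "load_criteria_set",
    "default_criteria_set",
    "validate_panel",
]

CLUSTERS = ("quality_of_evidence", "disease_impact", "intervention", "economics")


class CriteriaConfigError(ValueError):
    """Raised when a criteria configuration document is invalid."""


class PanelValidationError(ValueError):
    """Raised when a panel response matrix violates the criteria set."""


class RangeError(PanelValidationError):
    """An entry lies outside the criterion's weight or score scale."""


class ExclusionError(PanelValidationError):
    """The matrix contains a column for an excluded or unknown criterion."""


def _check_interval(bounds: tuple[int, int], label: str) -> tuple[int, int]:
    lo, hi = int(bounds[0]), int(bounds[1])
    if lo >= hi:
        raise ValueError(f"{label} must be a non-empty integer interval with min < max")
    return lo, hi


class Criterion(BaseModel):
    """One quantitative criterion of the MCDA matrix."""

    model_config = ConfigDict(frozen=True)

    id: str
    name: str
    cluster: Literal["quality_of_evidence", "disease_impact", "intervention", "economics"]
    weight_scale: tuple[int, int] = (1, 5)
    score_scale: tuple[int, int] = (0, 3)
    active: bool = True
    anchors: tuple[str, str] = ("Lowest", "Highest")

    @field_validator("weight_scale")
    @classmethod
    def _weight_interval(cls, v):
        return _check_interval(v, "weight_scale")

    @field_validator("score_scale")
    @classmethod
    def _score_interval(cls, v):
        return _check_interval(v, "score_scale")


class ContextualCriterion(BaseModel):
    """A qualitative consideration recorded as a directional impact on value."""

    model_config = ConfigDict(frozen=True)

    name: str
    narrative: str = ""
    impact: Literal["positive", "negative", "undetermined"] = "undetermined"


class CriteriaSet(BaseModel):
    """Ordered matrix criteria plus contextual criteria and exclusions."""

    criteria: list[Criterion]
    contextual: list[ContextualCriterion] = Field(default_factory=list)
    excluded_ids: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _validate(self) -> "CriteriaSet":
        ids = [c.id for c in self.criteria]
        if not ids:
            raise ValueError("criteria set must contain at least one criterion")
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate criterion id(s): {sorted(dupes)}")
        unknown = set(self.excluded_ids) - set(ids)
        if unknown:
            raise ValueError(f"excluded_ids not present in criteria: {sorted(unknown)}")
        # reconcile per-criterion active flags with the exclusion list
        excluded = set(self.excluded_ids)
        object.__setattr__(
            self,
            "criteria",
            [c.model_copy(update={"active": c.id not in excluded}) for c in self.criteria],
        )
        return self

    @property
    def active(self) -> list[Criterion]:
        return [c for c in self.criteria if c.active]

    @property
    def active_ids(self) -> list[str]:
        return [c.id for c in self.active]

    def __getitem__(self, cid: str) -> Criterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def cluster_sizes(self) -> dict[str, int]:
        sizes = {k: 0 for k in CLUSTERS}
        for c in self.criteria:
            sizes[c.cluster] += 1
        return sizes

    def to_dict(self) -> dict:
        d = self.model_dump(mode="json")
        for c in d["criteria"]:
            c.pop("active", None)  # derived from excluded_ids
        return d


def load_criteria_set(source) -> CriteriaSet:
    """Load and validate a criteria set from YAML/JSON (path, text or mapping).

    Raises :class:`CriteriaConfigError` naming the offending field if the
    document violates the schema (duplicate ids, unknown cluster, exclusion
    of an id not present, empty criteria list).
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        def _is_path(s) -> bool:
            try:
                return Path(s).exists()
            except OSError:  # e.g. document text longer than a filename
                return False

        if isinstance(source, (str, Path)) and _is_path(source):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        try:
            doc = yaml.safe_load(text)  # YAML is a superset of JSON
        except yaml.YAMLError as exc:  # pragma: no cover - parser detail
            raise CriteriaConfigError(f"config does not parse: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise CriteriaConfigError("criteria config must be a mapping")
    try:
        return CriteriaSet.model_validate(doc)
    except Exception as exc:
        raise CriteriaConfigError(str(exc)) from exc


def default_criteria_set() -> CriteriaSet:
    """The bundled 15-criterion matrix (14 active) with contextual criteria."""
    text = resources.files("mcdakit.data").joinpath("default_criteria.yaml").read_text("utf-8")
    return load_criteria_set(text)


class PanelFragment(BaseModel):
    """A validated member × criterion response table of one kind.

    ``incomplete_members`` lists members with at least one missing entry;
    they are retained here but are dropped from the quantitative model
    downstream (a complete weight vector is required for normalization).
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    kind: Literal["weights", "scores"]
    table: pd.DataFrame
    incomplete_members: list[str] = Field(default_factory=list)


def validate_panel(matrix: pd.DataFrame, cs: CriteriaSet, kind: str) -> PanelFragment:
    """Validate a member × criterion integer table against a criteria set.

    Parameters
    ----------
    matrix
        Rows indexed by member id, columns labelled by criterion id.
    cs
        The criteria set; every column must map to an *active* criterion.
    kind
        ``"weights"`` (checked against each criterion's weight scale) or
        ``"scores"`` (checked against the score scale).

    Returns a :class:`PanelFragment`; members with missing entries are
    flagged, out-of-scale or non-integer entries raise :class:`RangeError`,
    columns for excluded or unknown criteria raise :class:`ExclusionError`.
    """
    if kind not in ("weights", "scores"):
        raise ValueError("kind must be 'weights' or 'scores'")
    excluded = set(cs.excluded_ids)
    active = set(cs.active_ids)
    for col in matrix.columns:
        if col in excluded:
            raise ExclusionError(
                f"criterion {col!r} is excluded from appraisal and may not appear in the panel"
            )
        if col not in active:
            raise ExclusionError(f"column {col!r} does not map to an active criterion")

    table = matrix.copy()
    incomplete: list[str] = []
    for member, row in table.iterrows():
        if row.isna().any():
            incomplete.append(str(member))
    for cid in table.columns:
        crit = cs[cid]
        lo, hi = crit.weight_scale if kind == "weights" else crit.score_scale
        col = table[cid]
        for member, value in col.items():
            if pd.isna(value):
                continue
            if float(value) != int(value):
                raise RangeError(
                    f"{kind[:-1]} for member {member!r}, criterion {cid!r} is not an integer: {value!r}"
                )
            if not lo <= int(value) <= hi:
                raise RangeError(
                    f"{kind[:-1]} {int(value)} for member {member!r}, criterion {cid!r} "
                    f"is outside the scale [{lo}, {hi}]"
                )
    return PanelFragment(kind=kind, table=table, incomplete_members=incomplete)


def criteria_set_to_json(cs: CriteriaSet) -> str:
    """Serialize a criteria set to a JSON document (round-trips via load)."""
    return json.dumps(cs.to_dict(), indent=2, ensure_ascii=False)
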