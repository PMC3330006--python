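"""Tallying of categorical committee surveys.

Two surveys accompany a panel appraisal: whether each decision criterion
should *always / sometimes / never* be considered in decisionmaking, and
whether the structured process is *improved / same / worse* compared with
the committee's existing approach. Tallies are purely descriptive: counts
and integer percentages (half away from zero) per item, computed on the
item's own responder count — denominators may legitimately differ across
items when not every member answered every question.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._rounding import percent

__all__ = [
    "SurveyResponseSet",
    "TallyTable",
    "tally",
    "tally_counts",
    "acceptance_summary",
]


@dataclass
class SurveyResponseSet:
    """Per-item member→choice responses over an ordered category set."""

    choice_set: list[str]
    responses: dict[str, dict[str, str]]  # item -> {member: choice}
    items: list[str] = field(default_factory=list)  # display order
    groups: dict[str, str] = field(default_factory=dict)  # item -> group label

    def __post_init__(self) -> None:
        if not self.items:
            self.items = list(self.responses)
        cats = set(self.choice_set)
        for item, answers in self.responses.items():
            for member, choice in answers.items():
                if choice not in cats:
                    raise ValueError(
                        f"unknown category {choice!r} for item {item!r}, member {member!r} "
                        f"(choice set: {self.choice_set})"
                    )


@dataclass
class TallyTable:
    """Counts and integer percentages per item over a shared category set."""

    choice_set: list[str]
    table: pd.DataFrame  # index item; columns n, count:<cat>..., pct:<cat>...
    groups: dict[str, str] = field(default_factory=dict)

    def percent_of(self, item: str, category: str) -> int:
        return int(self.table.loc[item, f"pct:{category}"])

    def count_of(self, item: str, category: str) -> int:
        return int(self.table.loc[item, f"count:{category}"])


def tally_counts(counts: dict[str, dict[str, int]], choice_set: list[str],
                 items: list[str] | None = None,
                 groups: dict[str, str] | None = None) -> TallyTable:
    """Build a tally table directly from per-item category counts."""
    items = list(items or counts)
    rows = {}
    for item in items:
        cat_counts = {c: int(counts[item].get(c, 0)) for c in choice_set}
        n = sum(cat_counts.values())
        if n == 0:
            warnings.warn(f"item {item!r} has zero responses; omitted from tally")
            continue
        unknown = set(counts[item]) - set(choice_set)
        if unknown:
            raise ValueError(f"unknown category {sorted(unknown)} for item {item!r}")
        row = {"n": n}
        row.update({f"count:{c}": cat_counts[c] for c in choice_set})
        row.update({f"pct:{c}": percent(cat_counts[c], n) for c in choice_set})
        rows[item] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "item"
    return TallyTable(choice_set=list(choice_set), table=table, groups=dict(groups or {}))


def tally(responses: SurveyResponseSet) -> TallyTable:
    """Tally per-item counts and rounded percentages of a response set.

    Items with zero responses are omitted with a warning; percentages use
    each item's own responder count as denominator.
    """
    counts = {
        item: pd.Series(list(answers.values())).value_counts().to_dict()
        for item, answers in responses.responses.items()
    }
    return tally_counts(counts, responses.choice_set, responses.items, responses.groups)


def acceptance_summary(t: TallyTable, category: str, threshold: float,
                       group: str | None = None) -> pd.DataFrame:
    """Items whose percentage for ``category`` is at or above ``threshold``.

    Optionally restrict to items belonging to one group label. Returns a
    DataFrame (item index; columns n, count, percent) in tally order.
    """
    if category not in t.choice_set:
        raise ValueError(f"category {category!r} not in choice set {t.choice_set}")
    rows = {}
    for item in t.table.index:
        if group is not None and t.groups.get(item) != group:
            continue
        pct = t.percent_of(item, category)
        if pct >= threshold:
            rows[item] = {"n": int(t.table.loc[item, "n"]),
                          "count": t.count_of(item, category), "percent": pct}
    return pd.DataFrame.from_dict(rows, orient="index", dtype=int)
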