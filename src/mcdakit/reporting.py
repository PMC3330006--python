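"""Readers, writers and the by-criterion appraisal report.

All tabular IO uses one CSV dialect: comma-delimited, UTF-8, header row,
"." decimal separator. Panel matrices carry the member id in the first
column and one criterion id per remaining column. Survey responses are
accepted in long form (item, member, choice) or wide form (item, optional
group, one count column per category).

The appraisal report combines the quantitative results (panel estimate,
per-criterion contributions), qualitative contextual impacts and survey
tallies into a deterministic Markdown or JSON document: integer percents
for value estimates and shares, 1 dp for raw-scale statistics. Rendering
is pure — identical inputs (including the provenance block) yield
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._rounding import round_half_away
from .criteria import CriteriaSet
from .model import ContributionBreakdown, MCDAEstimate
from .panel import PanelAppraisal
from .survey import SurveyResponseSet, TallyTable, tally, tally_counts

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "read_survey_csv",
    "write_tally_csv",
    "AppraisalReport",
    "render_report",
]

NOT_COMPUTED = "not computed"


def read_panel_csv(path) -> pd.DataFrame:
    """Read a member × criterion matrix (first column = member id)."""
    df = pd.read_csv(path, encoding="utf-8")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "member"
    return df


def write_panel_csv(matrix: pd.DataFrame, path) -> None:
    matrix = matrix.copy()
    matrix.index.name = matrix.index.name or "member"
    matrix.to_csv(path, encoding="utf-8")


def read_survey_csv(path, choice_set: list[str]):
    """Read survey responses; auto-detects long vs wide layout.

    Long form (columns item, member, choice) returns a
    :class:`~mcdakit.survey.SurveyResponseSet`; wide form (item, optional
    group, one integer column per category) returns a
    :class:`~mcdakit.survey.TallyTable` directly.
    """
    df = pd.read_csv(path, encoding="utf-8")
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if {"item", "member", "choice"}.issubset(cols):
        responses: dict[str, dict[str, str]] = {}
        items: list[str] = []
        for _, row in df.iterrows():
            item = str(row["item"])
            if item not in responses:
                responses[item] = {}
                items.append(item)
            if str(row["member"]) in responses[item]:
                raise ValueError(f"duplicate response for item {item!r}, member {row['member']!r}")
            responses[item][str(row["member"])] = str(row["choice"])
        return SurveyResponseSet(choice_set=list(choice_set), responses=responses, items=items)
    missing = [c for c in choice_set if c not in cols]
    if "item" not in cols or missing:
        raise ValueError(
            f"survey CSV must be long (item,member,choice) or wide (item,{','.join(choice_set)}); "
            f"missing columns: {missing or ['item']}"
        )
    counts = {str(r["item"]): {c: int(r[c]) for c in choice_set} for _, r in df.iterrows()}
    groups = ({str(r["item"]): str(r["group"]) for _, r in df.iterrows()}
              if "group" in cols else {})
    return tally_counts(counts, list(choice_set), list(counts), groups)


def write_tally_csv(t: TallyTable, path) -> None:
    out = t.table.copy()
    out.index.name = "item"
    out.to_csv(path, encoding="utf-8")


def _pct(x: float) -> int:
    return int(round_half_away(100.0 * x, 0))


@dataclass
class AppraisalReport:
    """Assembled by-criterion appraisal results ready for rendering."""

    criteria_table: pd.DataFrame | None = None
    estimate: MCDAEstimate | None = None
    breakdown: ContributionBreakdown | None = None
    contextual: list[dict] = field(default_factory=list)
    tallies: dict[str, TallyTable] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @classmethod
    def build(cls, cs: CriteriaSet, panel: PanelAppraisal,
              estimate: MCDAEstimate, breakdown: ContributionBreakdown,
              tallies: dict[str, TallyTable] | None = None,
              provenance: dict | None = None) -> "AppraisalReport":
        """Assemble the per-criterion table from a fitted appraisal."""
        rows = []
        for cid in panel.criterion_ids:
            crit = cs[cid]
            w = panel.weights[cid].astype(float)
            s = panel.scores[cid].astype(float)
            rows.append({
                "id": cid,
                "name": crit.name,
                "cluster": crit.cluster,
                "mean_weight": float(round_half_away(w.mean(), 1)),
                "sd_weight": float(round_half_away(w.std(ddof=1), 1)),
                "mean_score": float(round_half_away(s.mean(), 1)),
                "sd_score": float(round_half_away(s.std(ddof=1), 1)),
                "mean_contribution": breakdown.mean_contribution[cid],
                "share_percent": (breakdown.share_percent[cid]
                                  if breakdown.share_percent else None),
            })
        table = pd.DataFrame(rows).set_index("id")
        contextual = [{"name": c.name, "impact": c.impact, "narrative": c.narrative}
                      for c in cs.contextual]
        return cls(criteria_table=table, estimate=estimate, breakdown=breakdown,
                   contextual=contextual, tallies=dict(tallies or {}),
                   provenance=dict(provenance or {}))

    def to_dict(self) -> dict:
        d: dict = {"provenance": self.provenance}
        if self.estimate is not None:
            d["estimate"] = {
                "mean_percent": _pct(self.estimate.mean),
                "sd_percent": _pct(self.estimate.sd),
                "min_percent": _pct(self.estimate.min),
                "max_percent": _pct(self.estimate.max),
                "per_member_percent": {m: _pct(v) for m, v in self.estimate.per_member.items()},
            }
        else:
            d["estimate"] = NOT_COMPUTED
        if self.criteria_table is not None:
            d["criteria"] = [
                {"id": cid, **{k: (None if pd.isna(v) else v) for k, v in row.items()}}
                for cid, row in self.criteria_table.to_dict(orient="index").items()
            ]
        else:
            d["criteria"] = NOT_COMPUTED
        d["contextual"] = self.contextual if self.contextual else NOT_COMPUTED
        d["tallies"] = {
            name: {"choice_set": t.choice_set,
                   "items": t.table.reset_index()
                             .rename(columns={"index": "item"})
                             .to_dict(orient="records")}
            for name, t in self.tallies.items()
        } or NOT_COMPUTED
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, ensure_ascii=False, sort_keys=False)

    def to_markdown(self) -> str:
        lines = ["# MCDA appraisal report", ""]
        if self.provenance:
            lines.append("## Provenance")
            lines.append("")
            for k in sorted(self.provenance):
                lines.append(f"- {k}: {self.provenance[k]}")
            lines.append("")
        lines.append("## Panel value estimate")
        lines.append("")
        if self.estimate is not None:
            e = self.estimate
            lines.append(
                f"Mean MCDA value estimate: **{_pct(e.mean)}%** of the potential maximum "
                f"(SD {_pct(e.sd)}%), individual range {_pct(e.min)}%–{_pct(e.max)}% "
                f"over {len(e.per_member)} members."
            )
        else:
            lines.append(f"*{NOT_COMPUTED}*")
        lines.append("")
        lines.append("## Criteria")
        lines.append("")
        if self.criteria_table is not None:
            lines.append("| id | criterion | cluster | mean weight (SD) | mean score (SD) | share |")
            lines.append("|----|-----------|---------|------------------|-----------------|-------|")
            for cid, row in self.criteria_table.iterrows():
                share = f"{int(row['share_percent'])}%" if row["share_percent"] is not None else NOT_COMPUTED
                lines.append(
                    f"| {cid} | {row['name']} | {row['cluster']} "
                    f"| {row['mean_weight']:.1f} ({row['sd_weight']:.1f}) "
                    f"| {row['mean_score']:.1f} ({row['sd_score']:.1f}) | {share} |"
                )
        else:
            lines.append(f"*{NOT_COMPUTED}*")
        lines.append("")
        lines.append("## Contextual criteria")
        lines.append("")
        if self.contextual:
            for c in self.contextual:
                lines.append(f"- **{c['name']}** — {c['impact']} impact. {c['narrative']}")
        else:
            lines.append(f"*{NOT_COMPUTED}*")
        lines.append("")
        for name, t in self.tallies.items():
            lines.append(f"## Survey: {name}")
            lines.append("")
            header = "| item | n | " + " | ".join(t.choice_set) + " |"
            lines.append(header)
            lines.append("|" + "----|" * (len(t.choice_set) + 2))
            for item in t.table.index:
                cells = " | ".join(
                    f"{t.count_of(item, c)} ({t.percent_of(item, c)}%)" for c in t.choice_set
                )
                lines.append(f"| {item} | {int(t.table.loc[item, 'n'])} | {cells} |")
            lines.append("")
        return "\n".join(lines) + "\n"


def render_report(report: AppraisalReport, format: str = "markdown") -> str:
    """Render an appraisal report deterministically as Markdown or JSON."""
    if format == "markdown":
        return report.to_markdown()
    if format == "json":
        return report.to_json()
    raise ValueError(f"unknown format {format!r}")
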