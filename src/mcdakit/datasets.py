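"""Bundled example data: a committee appraisal of a screening technology.

These tables are reconstructions of published summary tables (per-item
counts over 7–9 respondents); they are small, exact and suitable both as
worked examples and as regression fixtures.
"""

from __future__ import annotations

from importlib import resources

from .survey import TallyTable
from .reporting import read_survey_csv

__all__ = ["criteria_consideration_survey", "process_feedback_survey"]

CONSIDERATION_CATEGORIES = ["always", "sometimes", "never"]
FEEDBACK_CATEGORIES = ["improved", "same", "worse"]


def _bundled(name: str, categories: list[str]) -> TallyTable:
    with resources.as_file(resources.files("mcdakit.data").joinpath(name)) as path:
        return read_survey_csv(path, categories)


def criteria_consideration_survey() -> TallyTable:
    """Tally of whether each decision criterion should always/sometimes/never
    be considered in decisionmaking (22 items, 9 respondents each)."""
    return _bundled("survey_criteria.csv", CONSIDERATION_CATEGORIES)


def process_feedback_survey() -> TallyTable:
    """Tally of committee feedback comparing the structured process with the
    committee's existing approach (improved/same/worse; 7–9 respondents)."""
    return _bundled("survey_feedback.csv", FEEDBACK_CATEGORIES)
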