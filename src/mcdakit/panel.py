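"""Container for a committee panel's weight and score matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class PanelAppraisal:
    """Aligned member × active-criterion integer tables of weights and scores.

    ``weights`` holds importance ratings (typically 1–5), ``scores`` the
    intervention appraisal (typically 0–3). Both tables share the same
    member index and criterion columns. ``provenance`` optionally records,
    per criterion and kind, how a column was obtained (e.g. observed,
    reconstructed from printed statistics, mid-scale fill-in).
    """

    weights: pd.DataFrame
    scores: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.weights.index) != list(self.scores.index):
            raise ValueError("weights and scores must share the same member index")
        if list(self.weights.columns) != list(self.scores.columns):
            raise ValueError("weights and scores must share the same criterion columns")

    @property
    def members(self) -> list[str]:
        return [str(m) for m in self.weights.index]

    @property
    def criterion_ids(self) -> list[str]:
        return [str(c) for c in self.weights.columns]

    @property
    def n_members(self) -> int:
        return len(self.weights.index)
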