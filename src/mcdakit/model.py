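"""Linear additive MCDA value model.

Each committee member's raw importance weights are normalized to sum to 1
across the active criteria, each score is standardized by division by the
scale maximum (3), and the member's *value estimate* is the weighted sum

    V_m = sum_c  w_m(c) / sum_k w_m(k)  *  s_m(c) / s_max ,

a fraction of the maximum attainable value, in [0, 1]. Panel-level results
are the mean, sample standard deviation (n − 1), minimum and maximum of
the member estimates, plus a per-criterion decomposition: the mean value
contribution of each criterion and its integer-percent share of the panel
mean estimate.

The model is deliberately additive and non-interacting: a criterion's
contribution depends only on its own weight and score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._rounding import round_half_away
from .panel import PanelAppraisal

__all__ = [
    "MCDAValueModel",
    "MCDAEstimate",
    "ContributionBreakdown",
    "AlignmentError",
    "normalize_weights",
    "standardize_score",
    "member_value_estimate",
    "panel_estimate",
    "contribution_breakdown",
    "summarize_criterion_stats",
]


class AlignmentError(ValueError):
    """Weight and score vectors refer to different criterion sets."""


@dataclass
class MCDAEstimate:
    """Panel value estimate: per-member values and their dispersion."""

    per_member: dict[str, float]
    mean: float
    sd: float
    min: float
    max: float


@dataclass
class ContributionBreakdown:
    """Per-criterion mean value contribution and share of the panel mean.

    ``share_percent`` is ``None`` when the panel mean estimate is zero
    (shares are undefined rather than divided by zero).
    """

    mean_contribution: dict[str, float]
    share_percent: dict[str, int] | None = None
    shares_defined: bool = True
    note: str = ""
    extras: dict = field(default_factory=dict)


class MCDAValueModel(BaseEstimator):
    """Estimator computing the linear additive MCDA value of an intervention.

    Parameters
    ----------
    score_max : int, default 3
        Upper bound of the scoring scale; scores are standardized by
        division by this value.
    share_method : {"panel_mean", "per_member"}, default "panel_mean"
        How per-criterion percentage shares are computed: as the mean
        contribution divided by the panel mean estimate, or as the
        per-member shares averaged across members.
    drop_incomplete : bool, default True
        Drop members with any missing weight or score before fitting (no
        imputation — normalization requires a complete weight vector). If
        False, a missing entry raises instead.

    Attributes
    ----------
    members_ : list of str
        Members retained in the fit.
    dropped_members_ : list of str
        Members excluded because of missing entries.
    criteria_ : list of str
        Criterion ids (column order preserved).
    normalized_weights_ : DataFrame
        Per-member weights normalized to sum to 1.
    contribution_matrix_ : DataFrame
        Member × criterion value contributions (normalized weight ×
        standardized score).
    member_values_ : Series
        Per-member value estimates in [0, 1].
    mean_, sd_, min_, max_ : float
        Panel statistics of the member estimates (sd uses n − 1; NaN for a
        single-member panel).
    mean_contribution_ : Series
        Per-criterion mean contribution; sums to ``mean_``.
    share_percent_ : Series or None
        Integer percent share per criterion (half away from zero); None if
        the panel mean estimate is zero.
    pooled_estimate_ : float
        Diagnostic only: estimate obtained by first averaging weights and
        scores across the panel, then combining. Not the model's estimate.
    """

    def __init__(self, score_max: int = 3, share_method: str = "panel_mean",
                 drop_incomplete: bool = True):
        self.score_max = score_max
        self.share_method = share_method
        self.drop_incomplete = drop_incomplete

    def fit(self, weights, scores=None):
        """Fit the model on aligned member × criterion weight/score tables.

        ``weights`` may be a :class:`~mcdakit.panel.PanelAppraisal`, in
        which case ``scores`` is taken from it.
        """
        if isinstance(weights, PanelAppraisal):
            scores = weights.scores
            weights = weights.weights
        if scores is None:
            raise ValueError("scores are required")
        weights = pd.DataFrame(weights).astype(float)
        scores = pd.DataFrame(scores).astype(float)
        if list(weights.columns) != list(scores.columns):
            raise AlignmentError(
                f"criterion sets differ: {list(weights.columns)} vs {list(scores.columns)}"
            )
        if list(weights.index) != list(scores.index):
            raise AlignmentError("member sets differ between weights and scores")
        if weights.empty:
            raise ValueError("panel is empty")
        if self.share_method not in ("panel_mean", "per_member"):
            raise ValueError(f"unknown share_method {self.share_method!r}")

        incomplete = weights.isna().any(axis=1) | scores.isna().any(axis=1)
        self.dropped_members_ = [str(m) for m in weights.index[incomplete]]
        if self.dropped_members_ and not self.drop_incomplete:
            raise ValueError(f"missing entries for member(s) {self.dropped_members_}")
        weights = weights.loc[~incomplete]
        scores = scores.loc[~incomplete]
        if weights.empty:
            raise ValueError("no complete members remain after dropping missing responses")

        self.members_ = [str(m) for m in weights.index]
        self.criteria_ = [str(c) for c in weights.columns]
        self.n_features_in_ = len(self.criteria_)

        self.normalized_weights_ = normalize_weights(weights)
        std_scores = scores / float(self.score_max)
        self.contribution_matrix_ = self.normalized_weights_ * std_scores
        self.member_values_ = self.contribution_matrix_.sum(axis=1)
        self.mean_ = float(self.member_values_.mean())
        self.sd_ = float(self.member_values_.std(ddof=1)) if len(self.members_) > 1 else float("nan")
        self.min_ = float(self.member_values_.min())
        self.max_ = float(self.member_values_.max())
        self.mean_contribution_ = self.contribution_matrix_.mean(axis=0)

        if self.mean_ == 0.0:
            self.share_percent_ = None
        elif self.share_method == "per_member":
            per_member_shares = self.contribution_matrix_.div(self.member_values_, axis=0)
            self.share_percent_ = pd.Series(
                round_half_away(100.0 * per_member_shares.mean(axis=0).to_numpy(), 0),
                index=self.mean_contribution_.index, dtype=int,
            )
        else:
            self.share_percent_ = pd.Series(
                round_half_away(100.0 * (self.mean_contribution_ / self.mean_).to_numpy(), 0),
                index=self.mean_contribution_.index, dtype=int,
            )

        # diagnostic alternative aggregation (average first, combine after)
        mean_w = weights.mean(axis=0)
        self.pooled_estimate_ = float(
            ((mean_w / mean_w.sum()) * (scores.mean(axis=0) / self.score_max)).sum()
        )
        return self

    def estimate_(self) -> MCDAEstimate:
        """The fitted panel estimate as a plain result object."""
        return MCDAEstimate(
            per_member={m: float(v) for m, v in self.member_values_.items()},
            mean=self.mean_, sd=self.sd_, min=self.min_, max=self.max_,
        )

    def breakdown_(self) -> ContributionBreakdown:
        """The fitted contribution decomposition as a plain result object."""
        if self.share_percent_ is None:
            return ContributionBreakdown(
                mean_contribution={c: float(v) for c, v in self.mean_contribution_.items()},
                share_percent=None, shares_defined=False,
                note="panel mean estimate is zero; shares undefined",
            )
        return ContributionBreakdown(
            mean_contribution={c: float(v) for c, v in self.mean_contribution_.items()},
            share_percent={c: int(v) for c, v in self.share_percent_.items()},
        )


def normalize_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Normalize each member's raw weights to sum to 1 across criteria.

    Raises if any entry is missing (naming the member) — the model requires
    a complete weight vector per member.
    """
    weights = pd.DataFrame(weights).astype(float)
    missing = weights.isna().any(axis=1)
    if missing.any():
        raise ValueError(f"missing weight entries for member(s) {list(weights.index[missing])}")
    row_sums = weights.sum(axis=1)
    if (row_sums <= 0).any():
        raise ValueError("weight row sums must be positive")
    return weights.div(row_sums, axis=0)


def standardize_score(score, score_max: int = 3) -> float:
    """Map an integer score on [0, score_max] to a fraction of the maximum."""
    arr = np.asarray(score, dtype=float)
    if np.any((arr < 0) | (arr > score_max)) or np.any(arr != np.floor(arr)):
        raise ValueError(f"score must be an integer in [0, {score_max}], got {score!r}")
    out = arr / float(score_max)
    return float(out) if out.ndim == 0 else out


def member_value_estimate(norm_weights, scores, score_max: int = 3) -> float:
    """Value estimate for one member: Σ_c w_norm(c) · score(c)/score_max."""
    w = pd.Series(norm_weights, dtype=float)
    s = pd.Series(scores, dtype=float)
    if list(w.index) != list(s.index):
        raise AlignmentError(f"criterion sets differ: {list(w.index)} vs {list(s.index)}")
    return float((w * (s / float(score_max))).sum())


def panel_estimate(panel: PanelAppraisal, score_max: int = 3) -> MCDAEstimate:
    """Panel mean/SD/min/max of per-member value estimates."""
    return MCDAValueModel(score_max=score_max).fit(panel).estimate_()


def contribution_breakdown(panel: PanelAppraisal, score_max: int = 3,
                           share_method: str = "panel_mean") -> ContributionBreakdown:
    """Per-criterion mean contributions and integer-percent shares."""
    return MCDAValueModel(score_max=score_max, share_method=share_method).fit(panel).breakdown_()


def summarize_criterion_stats(matrix: pd.DataFrame, dp: int = 1) -> pd.DataFrame:
    """Per-criterion mean and sample SD (n − 1), rounded half away from zero.

    Returns a DataFrame indexed by criterion with columns ``mean`` and
    ``sd``. Requires at least two non-missing responses per criterion.
    """
    matrix = pd.DataFrame(matrix).astype(float)
    out = {}
    for cid in matrix.columns:
        col = matrix[cid].dropna()
        if len(col) < 2:
            raise ValueError(f"criterion {cid!r} has fewer than two responses")
        out[cid] = (
            round_half_away(col.mean(), dp),
            round_half_away(col.std(ddof=1), dp),
        )
    return pd.DataFrame(out, index=["mean", "sd"]).T
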