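"""Synthetic committee panels with prescribed statistical structure.

The raw member-level weights and scores behind a published panel appraisal
are typically unavailable; only per-criterion summary statistics (mean and
sample SD, printed at 1 decimal place) survive. This module makes every
pipeline stage testable without the raw data, by two complementary routes:

* **Exact reconstruction** — for small panels (n ≤ 12) on narrow integer
  scales, exhaustively enumerate all multisets of in-scale integers and
  return one whose mean and sample SD *round* (half away from zero, 1 dp)
  to the printed targets. Rounded-moment matching is the criterion because
  exact printed moments are generally unattainable with a handful of
  integers. When no multiset matches, that is a finding, not an error: an
  infeasibility report lists the nearest achievable (mean, SD) pairs.

* **Seeded sampling** — draw columns independently from a discrete
  distribution on the scale whose exact moments are the closest achievable
  to the targets (constrained least squares over the pmf), redrawing a
  bounded number of times until the sample's rounded moments land within a
  tolerance. One top-level seed; per-criterion substreams are derived by
  stable hashing of the criterion id, so a column is reproducible
  regardless of criterion order.

Columns are generated independently: nothing is known about the true
member-level correlation between criteria, and none is imposed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._rounding import round_half_away
from .panel import PanelAppraisal

__all__ = [
    "MomentTarget",
    "SyntheticPanelSpec",
    "ReconstructionResult",
    "SamplingError",
    "reconstruct_vector",
    "moment_matched_pmf",
    "sample_panel",
    "default_panel_spec",
    "fixture_published_panel",
    "TEXT_WEIGHT_STATS",
    "TEXT_SCORE_STATS",
]

MAX_EXHAUSTIVE_N = 12


@dataclass(frozen=True)
class MomentTarget:
    """Printed 1-dp moment targets for one criterion column.

    ``target_sd`` may be ``None`` when only the mean was printed; the
    reconstruction then matches the mean and minimizes the rounded SD.
    """

    criterion_id: str
    scale: tuple[int, int]
    target_mean: float
    target_sd: float | None
    n_members: int = 9

    def __post_init__(self) -> None:
        lo, hi = self.scale
        if not lo <= self.target_mean <= hi:
            raise ValueError(
                f"target mean {self.target_mean} outside scale [{lo}, {hi}] "
                f"for {self.criterion_id!r}"
            )
        if self.target_sd is not None and self.target_sd < 0:
            raise ValueError("target_sd must be non-negative")
        if self.n_members < 2:
            raise ValueError("n_members must be at least 2")


@dataclass
class ReconstructionResult:
    """Outcome of the exhaustive rounded-moment reconstruction."""

    target: MomentTarget
    feasible: bool
    values: tuple[int, ...] | None = None  # sorted descending
    achieved: tuple[float, float] | None = None  # rounded (mean, sd)
    nearest: list[dict] = field(default_factory=list)  # for infeasible targets


class SamplingError(RuntimeError):
    """Sampling could not reach the tolerance; carries achieved moments."""

    def __init__(self, msg: str, achieved: tuple[float, float]):
        super().__init__(msg)
        self.achieved = achieved


@lru_cache(maxsize=64)
def _enumerate_multisets(scale: tuple[int, int], n: int):
    """All n-multisets of integers in scale with their rounded 1-dp moments."""
    lo, hi = scale
    out = []
    for combo in combinations_with_replacement(range(hi, lo - 1, -1), n):
        arr = np.array(combo, dtype=float)
        rmean = float(round_half_away(arr.mean(), 1))
        rsd = float(round_half_away(arr.std(ddof=1), 1))
        out.append((combo, rmean, rsd))
    return out


def reconstruct_vector(t: MomentTarget) -> ReconstructionResult:
    """Find an integer vector whose rounded moments equal the printed targets.

    Enumerates every multiset of ``n_members`` integers within the scale;
    among feasible multisets the lexicographically largest sorted-descending
    one is returned (an arbitrary but deterministic tie-break). If no
    multiset matches, the result reports the nearest achievable rounded
    (mean, SD) pairs with an example vector each.
    """
    if t.n_members > MAX_EXHAUSTIVE_N:
        raise ValueError(f"exhaustive search supports n ≤ {MAX_EXHAUSTIVE_N}")
    universe = _enumerate_multisets(t.scale, t.n_members)

    if t.target_sd is None:
        matches = [(v, m, s) for v, m, s in universe if m == t.target_mean]
        if matches:
            min_sd = min(s for _, _, s in matches)
            best = max(v for v, _, s in matches if s == min_sd)
            return ReconstructionResult(t, True, best, (t.target_mean, min_sd))
    else:
        matches = [v for v, m, s in universe if m == t.target_mean and s == t.target_sd]
        if matches:
            best = max(matches)
            return ReconstructionResult(t, True, best, (t.target_mean, t.target_sd))

    # infeasible: rank achievable rounded-moment pairs by squared distance
    tsd = t.target_sd if t.target_sd is not None else 0.0
    pairs: dict[tuple[float, float], tuple[int, ...]] = {}
    for v, m, s in universe:
        key = (m, s)
        if key not in pairs or v > pairs[key]:
            pairs[key] = v
    ranked = sorted(
        pairs.items(),
        key=lambda kv: ((kv[0][0] - t.target_mean) ** 2 + (kv[0][1] - tsd) ** 2,
                        kv[0][0], kv[0][1]),
    )
    nearest = [
        {"mean": m, "sd": s,
         "distance": round(float((m - t.target_mean) ** 2 + (s - tsd) ** 2), 6),
         "example": vec}
        for (m, s), vec in ranked[:5]
    ]
    return ReconstructionResult(t, False, None, None, nearest)


def moment_matched_pmf(scale: tuple[int, int], mean: float, sd: float) -> np.ndarray:
    """Pmf on the scale's integers whose moments best match (mean, sd).

    Solved as a constrained least-squares problem over the probability
    simplex (SLSQP): minimize the squared error of the distribution's mean
    and SD against the targets. ``sd == 0`` degenerates to a point mass at
    the rounded mean.
    """
    lo, hi = scale
    values = np.arange(lo, hi + 1, dtype=float)
    if sd == 0:
        pmf = np.zeros_like(values)
        pmf[int(round_half_away(mean, 0)) - lo] = 1.0
        return pmf

    def objective(p):
        mu = p @ values
        var = p @ (values - mu) ** 2
        return (mu - mean) ** 2 + (np.sqrt(max(var, 0.0)) - sd) ** 2

    k = len(values)
    res = minimize(
        objective, np.full(k, 1.0 / k), method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    pmf = np.clip(res.x, 0.0, None)
    return pmf / pmf.sum()


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator keyed by a stable hash of the label."""
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


#: dispersion assumed when only a mean was printed — typical of the
#: printed SDs on these scales; the SD is then not checked when sampling
DEFAULT_UNPRINTED_SD = 0.5


def _sample_column(t: MomentTarget, rng: np.random.Generator,
                   tolerance: float, max_retries: int) -> np.ndarray:
    lo, hi = t.scale
    values = np.arange(lo, hi + 1)
    tsd = t.target_sd if t.target_sd is not None else DEFAULT_UNPRINTED_SD
    pmf = moment_matched_pmf(t.scale, t.target_mean, tsd)
    achieved = (float("nan"), float("nan"))
    for _ in range(max_retries):
        draw = rng.choice(values, size=t.n_members, p=pmf)
        rmean = float(round_half_away(draw.mean(), 1))
        rsd = float(round_half_away(draw.std(ddof=1), 1))
        achieved = (rmean, rsd)
        ok = abs(rmean - t.target_mean) <= tolerance
        if t.target_sd is not None:
            ok = ok and abs(rsd - t.target_sd) <= tolerance
        if ok:
            return draw.astype(int)
    raise SamplingError(
        f"criterion {t.criterion_id!r}: rounded moments {achieved} not within "
        f"{tolerance} of targets ({t.target_mean}, {t.target_sd}) "
        f"after {max_retries} draws", achieved,
    )


@dataclass
class SyntheticPanelSpec:
    """Targets and controls for sampling a full synthetic panel."""

    weight_targets: list[MomentTarget]
    score_targets: list[MomentTarget]
    seed: int = 0
    tolerance: float = 0.2
    max_retries: int = 200

    def __post_init__(self) -> None:
        w_ids = [t.criterion_id for t in self.weight_targets]
        s_ids = [t.criterion_id for t in self.score_targets]
        if w_ids != s_ids:
            raise ValueError("weight and score targets must cover the same criteria, in order")
        ns = {t.n_members for t in self.weight_targets + self.score_targets}
        if len(ns) > 1:
            raise ValueError("all targets must share the same panel size")


def sample_panel(spec: SyntheticPanelSpec) -> PanelAppraisal:
    """Draw a reproducible panel whose columns hit the moment targets.

    Each criterion column (weights and scores separately) is drawn from its
    moment-matched pmf on a dedicated substream of the seed, redrawing up
    to ``max_retries`` times until the sample's rounded 1-dp moments are
    within ``tolerance`` of the targets.
    """
    n = spec.weight_targets[0].n_members
    members = [f"m{i + 1}" for i in range(n)]
    cols_w, cols_s = {}, {}
    for kind, targets, cols in (("weights", spec.weight_targets, cols_w),
                                ("scores", spec.score_targets, cols_s)):
        for t in targets:
            rng = _substream(spec.seed, f"{kind}:{t.criterion_id}")
            cols[t.criterion_id] = _sample_column(t, rng, spec.tolerance, spec.max_retries)
    ids = [t.criterion_id for t in spec.weight_targets]
    return PanelAppraisal(
        weights=pd.DataFrame(cols_w, index=members, columns=ids),
        scores=pd.DataFrame(cols_s, index=members, columns=ids),
        provenance={"seed": spec.seed, "tolerance": spec.tolerance, "kind": "sampled"},
    )


# ---------------------------------------------------------------------------
# Printed committee statistics (9 members; weights on 1–5, scores on 0–3).
# Only statistics printed as text are recorded here; statistics shown solely
# in figures are left out and receive documented fill-ins instead.

TEXT_WEIGHT_STATS: dict[str, tuple[float, float | None]] = {
    "E1": (4.7, 0.5),   # budget impact on health plan
    "E2": (4.7, 0.5),   # cost-effectiveness of intervention
    "Q2": (4.7, 0.5),   # completeness/consistency of reporting evidence
    "I3": (4.4, None),  # improvement of efficacy/effectiveness (mean only)
    "Q3": (4.4, None),  # relevance and validity of evidence (mean only)
    "I4": (3.9, None),  # improvement of safety & tolerability (mean only)
    "I6": (3.8, 1.0),   # public health interest
    "D2": (None, 1.0),  # size of population: SD printed, mean figure-only
}

TEXT_SCORE_STATS: dict[str, tuple[float, float]] = {
    "Q3": (2.5, 0.3),   # relevance and validity (infeasible for 9 integers)
    "D1": (2.2, 0.4),   # disease severity
    "E2": (0.3, 0.7),   # cost-effectiveness
    "I4": (1.0, 0.0),   # safety & tolerability (unanimous)
    "Q2": (1.0, 0.0),   # completeness of reporting (unanimous)
    "I7": (2.0, 0.0),   # type of medical service (unanimous)
    "I1": (2.0, 1.2),   # clinical guidelines (full-range disagreement)
    "I6": (2.0, 0.9),   # public health interest
}

# documented fill-in targets for figure-only columns (mid-scale mean with a
# moderate spread); flagged in provenance, never asserted against
_FILL_WEIGHT = (3.0, 1.0)
_FILL_SCORE = (1.5, 0.8)

_ACTIVE_IDS = ["D1", "D2", "I1", "I2", "I3", "I4", "I5", "I6", "I7",
               "E1", "E2", "E3", "Q2", "Q3"]


def default_panel_spec(seed: int = 0, n_members: int = 9,
                       tolerance: float = 0.2) -> SyntheticPanelSpec:
    """Sampling spec for a 9 × 14 committee: printed targets plus fill-ins."""
    w_targets, s_targets = [], []
    for cid in _ACTIVE_IDS:
        if cid in TEXT_WEIGHT_STATS:
            # keep the printed statistics as-is: a mean-only target stays
            # mean-only rather than being given an invented SD
            wm, wsd = TEXT_WEIGHT_STATS[cid]
            if wm is None:
                wm = _FILL_WEIGHT[0]
        else:
            wm, wsd = _FILL_WEIGHT
        w_targets.append(MomentTarget(cid, (1, 5), float(wm), wsd, n_members))
        sm, ssd = TEXT_SCORE_STATS.get(cid, _FILL_SCORE)
        s_targets.append(MomentTarget(cid, (0, 3), float(sm), ssd, n_members))
    return SyntheticPanelSpec(w_targets, s_targets, seed=seed, tolerance=tolerance)


def _fixture_column(cid: str, scale: tuple[int, int],
                    stats: tuple[float | None, float | None] | None,
                    fill: tuple[float, float], mid: int) -> tuple[np.ndarray, str]:
    """Reconstruct one fixture column and label its provenance."""
    if stats is None:
        return np.full(9, mid), "fill_in_mid_scale"
    mean, sd = stats
    if mean is None:  # SD printed but mean figure-only: mid-scale mean
        res = reconstruct_vector(MomentTarget(cid, scale, float(fill[0]), sd, 9))
        label = "fill_in_mean_text_sd"
    else:
        res = reconstruct_vector(MomentTarget(cid, scale, mean, sd, 9))
        label = "text"
    if not res.feasible:
        # printed statistics unattainable by any integer vector: take the
        # nearest achievable pair's example, flagged as such
        return np.array(res.nearest[0]["example"]), "nearest_feasible"
    return np.array(res.values), label


def fixture_published_panel() -> PanelAppraisal:
    """Deterministic 9-member reconstruction of the published committee.

    Every criterion whose (mean, SD) statistics are printed as text is
    reconstructed exactly by :func:`reconstruct_vector`; mean-only columns
    take the minimum-SD vector matching the mean; figure-only columns get
    constant mid-scale fill-ins. One printed score target (mean 2.5, SD
    0.3 over 9 members on 0–3) is provably infeasible for integer
    responses and is replaced by the nearest achievable vector. Provenance
    labels every column; this is a *reconstruction consistent with the
    printed statistics*, not the study's raw data.

    Within each column the sorted-descending values are rotated by the
    criterion's position so that no synthetic member holds every extreme.
    """
    members = [f"m{i + 1}" for i in range(9)]
    cols_w, cols_s, prov = {}, {}, {"weights": {}, "scores": {}, "kind": "reconstruction"}
    for j, cid in enumerate(_ACTIVE_IDS):
        w_vec, w_src = _fixture_column(
            cid, (1, 5), TEXT_WEIGHT_STATS.get(cid), _FILL_WEIGHT, mid=3)
        s_vec, s_src = _fixture_column(
            cid, (0, 3), TEXT_SCORE_STATS.get(cid), _FILL_SCORE, mid=2)
        cols_w[cid] = np.roll(np.sort(w_vec)[::-1], j)
        cols_s[cid] = np.roll(np.sort(s_vec)[::-1], j)
        prov["weights"][cid] = w_src
        prov["scores"][cid] = s_src
    return PanelAppraisal(
        weights=pd.DataFrame(cols_w, index=members, columns=_ACTIVE_IDS),
        scores=pd.DataFrame(cols_s, index=members, columns=_ACTIVE_IDS),
        provenance=prov,
    )
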