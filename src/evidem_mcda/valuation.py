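"""The linear additive MCDA value estimate.

Given an aggregated committee panel, each intervention's value estimate is

    V = sum_x Vx = sum_x (Wx * Sx)

over the n criteria of the quantitative core model, where

* ``Wx`` is the criterion's normalized weight — its mean elicited weight
  divided by the sum of mean weights over the normalization denominator set,
  so that the included weights sum to 1;
* ``Sx`` is the standardized score — the mean elicited score divided by 5, so
  an absolute criterion maps into [0, 1] and a relative (vs-comparator)
  criterion into [−1, 1], preserving the sign of comparative harms.

V is dimensionless, bounded by [−1, 1], and lies in [0, 1] whenever no
criterion scores negative.

Missing-criterion policy
------------------------
Committees sometimes weight a criterion but never score it (no evidence), or
drop a criterion entirely.  Two arithmetically natural treatments are exposed:

``retain_weights`` (default)
    Unscored criteria keep their mean weight in the normalization denominator
    and contribute Sx = 0.  The committee's stated importance structure is
    preserved; absent evidence is valued as neutral.
``renormalize_excluding``
    Unscored or unweighted criteria are removed before normalization, so the
    remaining weights are rescaled to sum to 1.

Both policies apply the same denominator to every intervention, so the value
*ordering* is identical under either; only the absolute V level shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .panel import AggregatedPanel, PanelMatrices, aggregate_panel
from .registry import SCALE_BOUNDS, CriterionModel

__all__ = [
    "MissingCriterionPolicy",
    "RETAIN_WEIGHTS",
    "RENORMALIZE_EXCLUDING",
    "get_policy",
    "NormalizedPanel",
    "ValueEstimate",
    "EvidemValuator",
    "normalize_weights",
    "standardize_score",
    "compute_value",
    "rank_interventions",
    "decompose_value",
]

_ATOL = 1e-9


@dataclass(frozen=True)
class MissingCriterionPolicy:
    """Arithmetic treatment of criteria that were weighted but never scored."""

    mode: str
    description: str


RETAIN_WEIGHTS = MissingCriterionPolicy(
    mode="retain_weights",
    description=(
        "Unscored criteria keep their weight in the normalization denominator "
        "and contribute a standardized score of 0."
    ),
)

RENORMALIZE_EXCLUDING = MissingCriterionPolicy(
    mode="renormalize_excluding",
    description=(
        "Unscored and unweighted criteria are removed before weight "
        "normalization; remaining weights are rescaled to unit sum."
    ),
)

_POLICIES = {p.mode: p for p in (RETAIN_WEIGHTS, RENORMALIZE_EXCLUDING)}


def get_policy(policy) -> MissingCriterionPolicy:
    """Resolve a policy object or mode string; unknown modes raise ValueError."""
    if isinstance(policy, MissingCriterionPolicy):
        if policy.mode not in _POLICIES:
            raise ValueError(f"unknown missing-criterion policy mode {policy.mode!r}")
        return policy
    try:
        return _POLICIES[policy]
    except KeyError:
        raise ValueError(
            f"unknown missing-criterion policy {policy!r}; "
            f"choose one of {sorted(_POLICIES)}"
        ) from None


@dataclass(frozen=True)
class NormalizedPanel:
    """Normalized weights and standardized scores entering the additive sum.

    ``W`` sums to 1 over ``included_criteria``; ``S`` holds Sx per included
    criterion per intervention (0 for retained-but-unscored criteria).
    """

    W: pd.Series
    S: pd.DataFrame
    included_criteria: tuple[str, ...]
    policy: MissingCriterionPolicy

    def __post_init__(self) -> None:
        if abs(float(self.W.sum()) - 1.0) > _ATOL:
            raise ValueError(f"normalized weights sum to {self.W.sum()}, not 1")


@dataclass(frozen=True)
class ValueEstimate:
    """One intervention's value estimate and its per-criterion decomposition."""

    intervention: str
    contributions: dict[str, float]  # criterion id -> Vx
    total: float  # V
    n_criteria: int
    weights: dict[str, float] = field(default_factory=dict)  # Wx
    scores: dict[str, float] = field(default_factory=dict)  # Sx

    def __post_init__(self) -> None:
        s = sum(self.contributions.values())
        if abs(s - self.total) > _ATOL:
            raise ValueError(f"total {self.total} != sum of contributions {s}")
        if not -1.0 - _ATOL <= self.total <= 1.0 + _ATOL:
            raise ValueError(f"value estimate {self.total} outside [-1, 1]")


def standardize_score(score_mean: float, scale_kind: str) -> float:
    """Map a mean elicited score to the standardized Sx = score / 5.

    Absolute scores (0–5) map to [0, 1]; relative scores (−5..+5) map to
    [−1, 1], keeping the sign of worse-than-comparator performance.
    """
    try:
        lo, hi = SCALE_BOUNDS[scale_kind]
    except KeyError:
        raise ValueError(f"cannot standardize a {scale_kind!r} criterion") from None
    if not lo <= score_mean <= hi:
        raise ValueError(
            f"score {score_mean} outside the {scale_kind} scale [{lo:g}, {hi:g}]"
        )
    return score_mean / 5.0


def _included_and_denominator(agg: AggregatedPanel,
                              policy: MissingCriterionPolicy):
    """Criterion set entering the sum and the weight-normalization denominator."""
    weighted = [c for c in agg.criteria if c not in agg.unweighted]
    usable = [c for c in weighted if c not in agg.unscored]
    if not usable:
        raise ValueError("no criterion is both weighted and scored")
    included = weighted if policy.mode == "retain_weights" else usable
    denominator = float(agg.weight_mean[included].sum())
    if not denominator > 0:
        raise ValueError(f"weight normalization denominator is {denominator}")
    return included, denominator


def normalize_weights(agg: AggregatedPanel, policy=RETAIN_WEIGHTS) -> NormalizedPanel:
    """Normalize panel mean weights to unit sum and standardize the scores.

    Under ``retain_weights`` the denominator spans every weighted criterion
    (unscored ones contribute Sx = 0); under ``renormalize_excluding`` it
    spans only criteria that are both weighted and scored.
    """
    policy = get_policy(policy)
    included, denominator = _included_and_denominator(agg, policy)
    W = agg.weight_mean[included] / denominator
    S = pd.DataFrame(0.0, index=included, columns=list(agg.interventions))
    for cid in included:
        if cid in agg.unscored:
            continue  # retained without evidence: neutral contribution
        kind = agg.scale_kinds[cid]
        for drug in agg.interventions:
            S.loc[cid, drug] = standardize_score(agg.score_mean.loc[cid, drug], kind)
    return NormalizedPanel(W=W, S=S, included_criteria=tuple(included),
                           policy=policy)


def compute_value(agg: AggregatedPanel, policy=RETAIN_WEIGHTS) -> list[ValueEstimate]:
    """Value estimates V = Σ Wx·Sx for every intervention, in input order."""
    policy = get_policy(policy)
    for drug in agg.interventions:
        if agg.score_mean[drug].isna().all():
            raise ValueError(f"intervention {drug!r} has no scores at all")
    norm = normalize_weights(agg, policy)
    estimates = []
    for drug in agg.interventions:
        sx = norm.S[drug]
        vx = norm.W * sx
        estimates.append(ValueEstimate(
            intervention=drug,
            contributions={c: float(vx[c]) for c in norm.included_criteria},
            total=float(vx.sum()),
            n_criteria=len(norm.included_criteria),
            weights={c: float(norm.W[c]) for c in norm.included_criteria},
            scores={c: float(sx[c]) for c in norm.included_criteria},
        ))
    return estimates


def rank_interventions(estimates) -> list[tuple[int, str, float]]:
    """Order interventions by descending V.

    Ties share the minimum (competition) rank and are listed alphabetically
    within the tie; the result does not depend on input order.
    """
    if not estimates:
        raise ValueError("cannot rank an empty sequence of estimates")
    ordered = sorted(estimates, key=lambda e: (-e.total, e.intervention))
    ranked = []
    for i, est in enumerate(ordered):
        rank = 1 + sum(1 for other in estimates if other.total > est.total)
        ranked.append((rank, est.intervention, est.total))
    return ranked


def decompose_value(estimate: ValueEstimate) -> pd.DataFrame:
    """Per-criterion breakdown of one estimate.

    Columns: criterion, Wx, Sx, Vx, share (Vx / V; shares sum to 1 when
    V ≠ 0 and are reported empty otherwise).
    """
    rows = []
    v = estimate.total
    for cid, vx in estimate.contributions.items():
        rows.append({
            "criterion": cid,
            "Wx": estimate.weights.get(cid, math.nan),
            "Sx": estimate.scores.get(cid, math.nan),
            "Vx": vx,
            "share": vx / v if v != 0 else math.nan,
        })
    return pd.DataFrame(rows, columns=["criterion", "Wx", "Sx", "Vx", "share"])


class EvidemValuator(BaseEstimator):
    """Additive MCDA valuation as an sklearn-style estimator.

    Parameters
    ----------
    policy : str or MissingCriterionPolicy, default "retain_weights"
        Treatment of weighted-but-unscored criteria (see module docstring).

    Attributes
    ----------
    agg_ : AggregatedPanel
        The aggregated panel the model was fitted on.
    normalized_ : NormalizedPanel
        Normalized weights Wx and standardized scores Sx.
    estimates_ : list of ValueEstimate
        One value estimate per intervention, in input order.
    values_ : pandas.Series
        Total V per intervention.
    ranking_ : list of (rank, intervention, V)
        Descending order, ties alphabetical at shared min rank.

    Examples
    --------
    >>> from evidem_mcda import load_dpp4_fixture, EvidemValuator
    >>> model, agg = load_dpp4_fixture()
    >>> valuator = EvidemValuator().fit(agg)
    >>> valuator.ranking_[0][1]
    'Sitagliptin'
    """

    def __init__(self, policy="retain_weights"):
        self.policy = policy

    def fit(self, X, y=None, model: CriterionModel | None = None):
        """Fit on an :class:`AggregatedPanel` or a raw :class:`PanelMatrices`.

        Raw matrices are aggregated first (``model`` required unless the
        panel already carries one).
        """
        if isinstance(X, PanelMatrices):
            X = aggregate_panel(X, model=model)
        if not isinstance(X, AggregatedPanel):
            raise TypeError(
                f"X must be an AggregatedPanel or PanelMatrices, got {type(X)}"
            )
        policy = get_policy(self.policy)
        self.agg_ = X
        self.normalized_ = normalize_weights(X, policy)
        self.estimates_ = compute_value(X, policy)
        self.values_ = pd.Series(
            {e.intervention: e.total for e in self.estimates_},
            name="V",
        )
        self.ranking_ = rank_interventions(self.estimates_)
        return self

    def value_table(self) -> pd.DataFrame:
        """Ranking as a DataFrame with columns rank, intervention, V."""
        self._check_fitted()
        return pd.DataFrame(self.ranking_, columns=["rank", "intervention", "V"])

    def decomposition(self, intervention: str) -> pd.DataFrame:
        """Per-criterion contribution table for one intervention."""
        self._check_fitted()
        for est in self.estimates_:
            if est.intervention == intervention:
                return decompose_value(est)
        raise KeyError(f"no estimate for intervention {intervention!r}")

    def _check_fitted(self) -> None:
        if not hasattr(self, "estimates_"):
            raise AttributeError("EvidemValuator is not fitted; call fit first")
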