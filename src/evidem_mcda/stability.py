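"""Rank-stability analysis: propagate panel dispersion through the value model.

A committee's mean weights and scores come with standard deviations that the
point estimate V ignores.  This module resamples weights and scores from
truncated normal distributions centred on the panel means, recomputes V and
the ranking for each draw, and tabulates how often each intervention lands on
each rank — a rank-acceptability table in the spirit of stochastic
multicriteria acceptability analysis (SMAA), but anchored to the elicited
dispersion rather than an uninformed weight space.

By default the sampling scale is the standard error of the panel mean,
``SD / sqrt(n_panelists)``: the question answered is "how stable is the
ordering given the committee's uncertainty about its own mean position?".
Passing ``uncertainty="sd"`` samples at the raw panelist SD instead, probing
panel heterogeneity rather than mean uncertainty.

Weights are truncated to [1, 5] and scores to their criterion's scale; draws
are independent across criteria (no covariance is elicited).  Ranks within a
draw are ordinal: ties (probability zero unless SDs vanish) break
alphabetically, so each draw yields a full permutation and the resulting
table is doubly stochastic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .panel import AggregatedPanel
from .registry import SCALE_BOUNDS
from .valuation import RETAIN_WEIGHTS, get_policy, _included_and_denominator

__all__ = ["RankStabilityResult", "RankStabilitySimulator", "simulate_ranks"]


@dataclass(frozen=True)
class RankStabilityResult:
    """Monte-Carlo rank-probability table and V summaries.

    ``rank_probability`` is intervention × rank; every row and every column
    sums to 1 (each draw assigns each intervention exactly one rank).
    ``interval`` holds the central 95% interval of V per intervention.
    """

    n_draws: int
    seed: int | None
    rank_probability: pd.DataFrame
    mean_V: pd.Series
    interval: pd.DataFrame  # columns: lower, upper
    policy_mode: str

    def __post_init__(self) -> None:
        tol = 1.0 / math.sqrt(self.n_draws)
        rows = self.rank_probability.sum(axis=1)
        cols = self.rank_probability.sum(axis=0)
        if (abs(rows - 1.0) > tol).any() or (abs(cols - 1.0) > tol).any():
            raise ValueError("rank-probability table is not doubly stochastic")

    def to_dict(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "policy": self.policy_mode,
            "rank_probability": {
                drug: {str(r): float(p) for r, p in row.items()}
                for drug, row in self.rank_probability.iterrows()
            },
            "mean_V": {d: float(v) for d, v in self.mean_V.items()},
            "interval": {
                d: [float(row["lower"]), float(row["upper"])]
                for d, row in self.interval.iterrows()
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _truncnorm_draws(rng, mean, scale, lo, hi, size):
    """Truncated-normal draws; a zero scale is the degenerate point mass."""
    out = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    scale_arr = np.broadcast_to(np.asarray(scale, dtype=float), size)
    active = scale_arr > 0
    if active.any():
        mu = out[active]
        sig = scale_arr[active]
        a = (lo - mu) / sig
        b = (hi - mu) / sig
        out[active] = stats.truncnorm.rvs(a, b, loc=mu, scale=sig,
                                          random_state=rng)
    return out


class RankStabilitySimulator(BaseEstimator):
    """Monte-Carlo rank-acceptability simulation, sklearn-style.

    Parameters
    ----------
    n_draws : int, default 10_000
        Number of resampled panels.
    random_state : int or None
        Seed; identical seeds give bit-identical tables.
    policy : str or MissingCriterionPolicy, default "retain_weights"
        Missing-criterion policy applied inside each draw.
    uncertainty : {"sem", "sd"}, default "sem"
        Sampling scale: standard error of the panel mean, or the raw SD.

    Attributes
    ----------
    result_ : RankStabilityResult
    rank_probability_ : pandas.DataFrame
    mean_V_ : pandas.Series
    """

    def __init__(self, n_draws=10_000, random_state=None,
                 policy="retain_weights", uncertainty="sem"):
        self.n_draws = n_draws
        self.random_state = random_state
        self.policy = policy
        self.uncertainty = uncertainty

    def fit(self, X: AggregatedPanel, y=None):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.uncertainty not in ("sem", "sd"):
            raise ValueError("uncertainty must be 'sem' or 'sd'")
        policy = get_policy(self.policy)
        agg = X
        included, _ = _included_and_denominator(agg, policy)
        scored = [c for c in included if c not in agg.unscored]
        drugs = list(agg.interventions)
        m = len(drugs)
        n_draws = int(self.n_draws)

        w_sd = agg.weight_sd[included]
        s_sd = agg.score_sd.loc[scored, drugs]
        if w_sd.isna().any() or s_sd.isna().to_numpy().any():
            missing = sorted(
                set(w_sd.index[w_sd.isna()])
                | set(s_sd.index[s_sd.isna().any(axis=1)])
            )
            raise ValueError(
                f"SDs missing for {missing}; a dispersion-free panel has no "
                "rank uncertainty — use compute_value for the point estimate"
            )

        shrink = 1.0 / math.sqrt(agg.n_panelists) if self.uncertainty == "sem" else 1.0
        rng = np.random.default_rng(self.random_state)

        # weights: (n_draws, k_included), truncated to the 1-5 importance scale
        w_draws = _truncnorm_draws(
            rng,
            agg.weight_mean[included].to_numpy(),
            w_sd.to_numpy() * shrink,
            1.0, 5.0,
            (n_draws, len(included)),
        )
        # scores: one (n_draws, m) block per scored criterion, truncated to its scale
        s_blocks = np.zeros((len(included), n_draws, m))
        for i, cid in enumerate(included):
            if cid not in scored:
                continue  # retained without evidence: Sx = 0 in every draw
            lo, hi = SCALE_BOUNDS[agg.scale_kinds[cid]]
            s_blocks[i] = _truncnorm_draws(
                rng,
                agg.score_mean.loc[cid, drugs].to_numpy(),
                agg.score_sd.loc[cid, drugs].to_numpy() * shrink,
                lo, hi,
                (n_draws, m),
            )

        W = w_draws / w_draws.sum(axis=1, keepdims=True)
        S = s_blocks / 5.0
        V = np.einsum("dk,kdm->dm", W, S)  # (n_draws, m)

        # ordinal ranks, descending V, alphabetical tiebreak
        alpha_prior = np.array(
            [[drugs[k] < drugs[j] for k in range(m)] for j in range(m)]
        )  # alpha_prior[j, k]: drug k precedes drug j alphabetically
        beats = (V[:, None, :] > V[:, :, None]) | (
            (V[:, None, :] == V[:, :, None]) & alpha_prior[None, :, :]
        )
        ranks = 1 + beats.sum(axis=2)  # (n_draws, m)

        counts = np.zeros((m, m), dtype=float)
        for j in range(m):
            counts[j] = np.bincount(ranks[:, j] - 1, minlength=m)
        prob = counts / n_draws

        self.rank_probability_ = pd.DataFrame(
            prob, index=drugs, columns=range(1, m + 1)
        )
        self.mean_V_ = pd.Series(V.mean(axis=0), index=drugs, name="mean_V")
        lower, upper = np.percentile(V, [2.5, 97.5], axis=0)
        self.interval_ = pd.DataFrame(
            {"lower": lower, "upper": upper}, index=drugs
        )
        self.result_ = RankStabilityResult(
            n_draws=n_draws,
            seed=self.random_state,
            rank_probability=self.rank_probability_,
            mean_V=self.mean_V_,
            interval=self.interval_,
            policy_mode=policy.mode,
        )
        return self


def simulate_ranks(agg: AggregatedPanel, n_draws: int, seed: int | None,
                   policy=RETAIN_WEIGHTS,
                   uncertainty: str = "sem") -> RankStabilityResult:
    """Resample the panel ``n_draws`` times and tabulate rank frequencies.

    See :class:`RankStabilitySimulator` for the sampling model.
    """
    sim = RankStabilitySimulator(
        n_draws=n_draws, random_state=seed, policy=policy,
        uncertainty=uncertainty,
    ).fit(agg)
    return sim.result_
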