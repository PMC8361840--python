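"""Synthetic committee panels with prescribed aggregate structure.

Raw panelist-level elicitation data are rarely published; appraisal reports
print only per-criterion means and SDs.  This module generates raw
panelist × criterion (× intervention) matrices whose aggregates target those
printed summaries, so the whole pipeline — validation, aggregation,
valuation, rank stability — can be exercised end-to-end without any real
committee.

Generation model, per column (one criterion, or one criterion–intervention
pair), given a target (mean, SD) and the column's scale bounds:

* **SD = 0** — a unanimous committee: every panelist sits at the target mean,
  rounded to the nearest scale point if the column is integer-valued.
* **integer scores** — draws from a truncated normal at (mean, SD) are
  rounded to scale points, then a repair pass nudges random entries by ±1
  until the column sum equals a randomized integer target whose expectation
  is ``n × mean``.  Over replicate panels the grand mean is therefore
  unbiased even when no exact integer solution exists (e.g. mean 4.67 at
  n = 6); the SD is matched only in distribution ("soft").
* **fractional weights** — truncated-normal draws recentred onto the target
  mean and clipped to [1, 5] (recentre/clip iterated a few times).

Panelist-role structure (doctor vs pharmacist) and inter-criterion
correlations are deliberately not modelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .panel import SCORE_COLUMNS, PanelMatrices
from .registry import SCALE_BOUNDS, QUALITATIVE, CriterionModel, build_core_model

__all__ = ["PanelProfile", "generate_panel", "dpp4_profile"]

#: Reference committee size: two doctors, one nurse, one pharmacist, one
#: health economist and one decision-maker.
REFERENCE_N_PANELISTS = 6


class InfeasibleTargetError(ValueError):
    """A (mean, SD) target cannot be realized on the criterion's scale."""


@dataclass
class PanelProfile:
    """Statistical targets a synthetic panel should aggregate to.

    ``weight_targets`` maps criterion id to (mean, SD) on the 1–5 importance
    scale; ``score_targets`` maps criterion id to {intervention: (mean, SD)}
    on the criterion's score scale.  Criteria absent from a mapping come out
    unweighted / unscored, mirroring a committee that skipped them.
    """

    n_panelists: int
    interventions: tuple[str, ...]
    weight_targets: dict[str, tuple[float, float]]
    score_targets: dict[str, dict[str, tuple[float, float]]]
    scale_kinds: dict[str, str]
    integer_scores: bool = True
    fractional_weights: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        self.interventions = tuple(self.interventions)
        self.validate()

    def validate(self) -> None:
        if self.n_panelists < 1:
            raise InfeasibleTargetError("n_panelists must be >= 1")
        any_sd = any(sd > 0 for _, sd in self.weight_targets.values()) or any(
            sd > 0
            for per_drug in self.score_targets.values()
            for _, sd in per_drug.values()
        )
        if any_sd and self.n_panelists < 2:
            raise InfeasibleTargetError(
                "a nonzero SD target needs at least 2 panelists"
            )
        for cid, (mean, sd) in self.weight_targets.items():
            self._check_target(cid, mean, sd, 1.0, 5.0,
                               integer=not self.fractional_weights)
        for cid, per_drug in self.score_targets.items():
            kind = self.scale_kinds.get(cid)
            if kind not in SCALE_BOUNDS:
                raise InfeasibleTargetError(
                    f"score target for {cid!r} without a quantitative scale kind"
                )
            lo, hi = SCALE_BOUNDS[kind]
            for drug, (mean, sd) in per_drug.items():
                self._check_target(f"{cid}/{drug}", mean, sd, lo, hi,
                                   integer=self.integer_scores)

    def _check_target(self, name, mean, sd, lo, hi, integer):
        if not lo <= mean <= hi:
            raise InfeasibleTargetError(
                f"target mean {mean} for {name!r} outside scale [{lo:g}, {hi:g}]"
            )
        if sd < 0:
            raise InfeasibleTargetError(f"negative SD target for {name!r}")
        # largest sample SD on a bounded scale: half the panel at each end
        n = self.n_panelists
        if sd > 0 and n >= 2:
            sd_max = (hi - lo) / 2.0 * math.sqrt(n / (n - 1))
            if sd > sd_max + 1e-12:
                raise InfeasibleTargetError(
                    f"SD target {sd} for {name!r} unreachable on "
                    f"[{lo:g}, {hi:g}] with n={n} (max {sd_max:.3f})"
                )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["interventions"] = list(self.interventions)
        d["weight_targets"] = {c: list(t) for c, t in self.weight_targets.items()}
        d["score_targets"] = {
            c: {drug: list(t) for drug, t in per.items()}
            for c, per in self.score_targets.items()
        }
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PanelProfile":
        return cls(
            n_panelists=int(data["n_panelists"]),
            interventions=tuple(data["interventions"]),
            weight_targets={
                c: tuple(t) for c, t in data["weight_targets"].items()
            },
            score_targets={
                c: {drug: tuple(t) for drug, t in per.items()}
                for c, per in data["score_targets"].items()
            },
            scale_kinds=dict(data["scale_kinds"]),
            integer_scores=bool(data.get("integer_scores", True)),
            fractional_weights=bool(data.get("fractional_weights", True)),
            seed=data.get("seed"),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PanelProfile":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        elif isinstance(source, str) and "\n" in source:
            data = yaml.safe_load(source)
        else:
            with open(source, encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)


def _truncnorm_column(rng, mean, sd, lo, hi, n):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)


def _integer_column(rng, mean, sd, lo, hi, n):
    """Integer column on [lo, hi] whose sum is unbiased for n*mean."""
    lo_i, hi_i = int(lo), int(hi)
    if sd == 0:
        return np.full(n, int(np.clip(round(mean), lo_i, hi_i)))
    target = n * mean
    base = math.floor(target)
    s_target = base + (1 if rng.random() < (target - base) else 0)
    s_target = int(np.clip(s_target, n * lo_i, n * hi_i))
    col = np.clip(np.rint(_truncnorm_column(rng, mean, sd, lo, hi, n)),
                  lo_i, hi_i).astype(int)
    while col.sum() != s_target:
        step = 1 if col.sum() < s_target else -1
        movable = np.flatnonzero(col < hi_i if step > 0 else col > lo_i)
        col[rng.choice(movable)] += step
    return col


def _fractional_column(rng, mean, sd, lo, hi, n):
    """Continuous column on [lo, hi] recentred onto the target mean."""
    if sd == 0:
        return np.full(n, float(np.clip(mean, lo, hi)))
    col = _truncnorm_column(rng, mean, sd, lo, hi, n)
    for _ in range(4):  # recentre, then clip back onto the scale
        col = np.clip(col + (mean - col.mean()), lo, hi)
    return col


def generate_panel(profile: PanelProfile, seed: int | None = None) -> PanelMatrices:
    """Draw one raw panel realizing the profile's targets.

    Deterministic under a fixed seed (``seed`` argument overrides
    ``profile.seed``).  Every generated panel satisfies the elicitation-scale
    bounds by construction and passes :func:`~evidem_mcda.panel.validate_panel`
    unmodified.
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    n = profile.n_panelists
    panelists = [f"p{i + 1}" for i in range(n)]

    weights = {}
    for cid, (mean, sd) in profile.weight_targets.items():
        if profile.fractional_weights:
            weights[cid] = _fractional_column(rng, mean, sd, 1.0, 5.0, n)
        else:
            weights[cid] = _integer_column(rng, mean, sd, 1, 5, n).astype(float)
    weights_df = pd.DataFrame(weights, index=panelists)
    weights_df.index.name = "panelist_id"

    rows = []
    for cid, per_drug in profile.score_targets.items():
        lo, hi = SCALE_BOUNDS[profile.scale_kinds[cid]]
        for drug in profile.interventions:
            if drug not in per_drug:
                continue
            mean, sd = per_drug[drug]
            if profile.integer_scores:
                col = _integer_column(rng, mean, sd, lo, hi, n).astype(float)
            else:
                col = _fractional_column(rng, mean, sd, lo, hi, n)
            for pid, value in zip(panelists, col):
                rows.append((pid, cid, drug, float(value)))
    scores_df = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))

    return PanelMatrices(
        weights=weights_df, scores=scores_df,
        interventions=profile.interventions,
    )


def dpp4_profile() -> PanelProfile:
    """Profile whose targets are the DPP-4 worked example's aggregates.

    Six panelists, integer scores, fractional weights; the unweighted /
    unscored criteria of the worked example carry no targets, so generated
    panels reproduce its missingness pattern.
    """
    from . import dpp4

    model = build_core_model()
    return PanelProfile(
        n_panelists=dpp4.N_PANELISTS,
        interventions=dpp4.INTERVENTIONS,
        weight_targets={c: t for c, t in dpp4.WEIGHTS.items()},
        score_targets={
            c: {d: t for d, t in per.items()} for c, per in dpp4.SCORES.items()
        },
        scale_kinds={c.id: c.scale_kind for c in model
                     if c.scale_kind != QUALITATIVE},
        integer_scores=True,
        fractional_weights=True,
    )
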