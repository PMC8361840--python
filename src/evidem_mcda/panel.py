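"""Panelist-level elicitation matrices and their aggregated (mean ± SD) form.

A committee appraisal produces two raw matrices:

* **weights** — panelist × criterion importance ratings on a 1–5 scale
  (5 = most important).  Fractional values are allowed, since committees
  sometimes rescale individual ratings before pooling.
* **scores** — panelist × criterion × intervention performance ratings, on
  0–5 for absolute criteria and −5..+5 for relative criteria.

Missing entries are explicit (``NaN`` in memory, empty fields on disk), never
zeros: "did not rate" is a different fact from "rated zero", and the two are
treated differently downstream.

Aggregation pools each column into a mean and a sample standard deviation
(``ddof=1``); a single respondent yields SD 0.  A criterion counts as *scored*
only if it has at least one non-missing score for **every** intervention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .registry import (
    SCALE_BOUNDS,
    QUALITATIVE,
    CriterionModel,
    build_core_model,
)

__all__ = [
    "PanelMatrices",
    "AggregatedPanel",
    "PanelValidationError",
    "validate_panel",
    "aggregate_panel",
    "load_dpp4_fixture",
    "round_half_up",
]

SCORE_COLUMNS = ("panelist_id", "criterion_id", "intervention", "score")

WEIGHT_BOUNDS = (1.0, 5.0)


def round_half_up(x: float, digits: int = 2) -> float:
    """Round with ties away from zero, matching committee-report formatting."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return x
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class PanelValidationError(ValueError):
    """All range/consistency violations of a raw panel, reported together."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        msg = "invalid panel matrices:\n" + "\n".join(f"  - {p}" for p in problems)
        super().__init__(msg)


@dataclass
class PanelMatrices:
    """Raw panelist-level weight and score matrices.

    Parameters
    ----------
    weights : pandas.DataFrame
        Rows indexed by panelist id, one column per criterion id; ``NaN``
        marks a missing rating.
    scores : pandas.DataFrame
        Long format with columns ``panelist_id, criterion_id, intervention,
        score``; ``NaN`` score marks a missing rating.
    interventions : tuple of str
        Intervention name order (defaults to first appearance in ``scores``).
    model : CriterionModel, optional
        The criterion model the matrices refer to; attached by
        :func:`validate_panel`.
    """

    weights: pd.DataFrame
    scores: pd.DataFrame
    interventions: tuple[str, ...] = ()
    model: CriterionModel | None = None

    def __post_init__(self) -> None:
        self.scores = self.scores.reset_index(drop=True)
        missing_cols = set(SCORE_COLUMNS) - set(self.scores.columns)
        if missing_cols:
            raise ValueError(f"scores table lacks columns {sorted(missing_cols)}")
        self.scores = self.scores.loc[:, list(SCORE_COLUMNS)]
        if not self.interventions:
            self.interventions = tuple(
                pd.unique(self.scores["intervention"].astype(str))
            )
        else:
            self.interventions = tuple(self.interventions)

    @property
    def panelist_ids(self) -> tuple[str, ...]:
        return tuple(str(p) for p in self.weights.index)

    @property
    def n_panelists(self) -> int:
        return len(self.weights.index)

    def score_table(self, criterion_id: str) -> pd.DataFrame:
        """Panelist × intervention score table for one criterion."""
        sub = self.scores[self.scores["criterion_id"] == criterion_id]
        return sub.pivot_table(
            index="panelist_id", columns="intervention", values="score",
            aggfunc="first", dropna=False,
        ).reindex(columns=list(self.interventions))

    # -- CSV dialect ------------------------------------------------------
    # weights: wide CSV, rows = panelists, columns = criterion ids.
    # scores: long CSV (panelist_id, criterion_id, intervention, score),
    # empty score field = missing.  UTF-8, comma separated, header required.

    def to_csv(self, weights_path, scores_path) -> None:
        self.weights.to_csv(weights_path, index_label="panelist_id")
        self.scores.to_csv(scores_path, index=False)

    @classmethod
    def from_csv(cls, weights_path, scores_path,
                 model: CriterionModel | None = None) -> "PanelMatrices":
        weights = pd.read_csv(weights_path, index_col="panelist_id")
        weights.index = weights.index.astype(str)
        scores = pd.read_csv(
            scores_path,
            dtype={"panelist_id": str, "criterion_id": str, "intervention": str},
        )
        return cls(weights=weights, scores=scores, model=model)


def validate_panel(raw: PanelMatrices, model: CriterionModel) -> PanelMatrices:
    """Check a raw panel against a criterion model; report every violation.

    Checks: criterion ids exist in the model; weights lie in [1, 5] or are
    missing; scores lie within the bounds of their criterion's scale kind or
    are missing; qualitative criteria carry no scores at all.

    Returns the matrices with the model attached.  Raises
    :class:`PanelValidationError` listing panelist, criterion, intervention
    and offending value for every violation at once.
    """
    problems: list[str] = []

    unknown_w = [c for c in raw.weights.columns if c not in model]
    if unknown_w:
        problems.append(f"weight columns not in model {model.name!r}: {unknown_w}")
    unknown_s = sorted(
        set(raw.scores["criterion_id"]) - set(model.ids)
    )
    if unknown_s:
        problems.append(f"score criterion ids not in model {model.name!r}: {unknown_s}")

    lo_w, hi_w = WEIGHT_BOUNDS
    for cid in raw.weights.columns:
        col = raw.weights[cid]
        bad = col[(col.notna()) & ((col < lo_w) | (col > hi_w))]
        for panelist, value in bad.items():
            problems.append(
                f"weight out of range [1, 5]: panelist={panelist!r} "
                f"criterion={cid!r} value={value}"
            )

    for row in raw.scores.itertuples(index=False):
        if row.criterion_id not in model:
            continue
        crit = model[row.criterion_id]
        if crit.scale_kind == QUALITATIVE:
            problems.append(
                f"score given for qualitative criterion {crit.id!r}: "
                f"panelist={row.panelist_id!r} intervention={row.intervention!r}"
            )
            continue
        if pd.isna(row.score):
            continue
        lo, hi = SCALE_BOUNDS[crit.scale_kind]
        if not lo <= row.score <= hi:
            problems.append(
                f"score out of range [{lo:g}, {hi:g}] ({crit.scale_kind}): "
                f"panelist={row.panelist_id!r} criterion={crit.id!r} "
                f"intervention={row.intervention!r} value={row.score}"
            )

    if problems:
        raise PanelValidationError(problems)
    return replace(raw, model=model)


def _col_mean_sd(values: pd.Series) -> tuple[float, float]:
    v = values.dropna()
    if len(v) == 0:
        return float("nan"), float("nan")
    if len(v) == 1:
        return float(v.iloc[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1))


@dataclass
class AggregatedPanel:
    """Per-criterion mean ± SD weights and per-criterion, per-intervention
    mean ± SD scores — the pooled form of a committee elicitation.

    ``NaN`` means the committee never produced that quantity: a ``NaN``
    weight mean flags an *unweighted* criterion; a criterion with any ``NaN``
    score mean is *unscored* (it lacks a pooled score for at least one
    intervention and cannot enter a fair comparison).
    """

    criteria: tuple[str, ...]
    interventions: tuple[str, ...]
    weight_mean: pd.Series
    weight_sd: pd.Series
    score_mean: pd.DataFrame  # index = criteria, columns = interventions
    score_sd: pd.DataFrame
    n_panelists: int
    scale_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.criteria = tuple(self.criteria)
        self.interventions = tuple(self.interventions)
        idx = list(self.criteria)
        self.weight_mean = self.weight_mean.reindex(idx).astype(float)
        self.weight_sd = self.weight_sd.reindex(idx).astype(float)
        self.score_mean = self.score_mean.reindex(
            index=idx, columns=list(self.interventions)).astype(float)
        self.score_sd = self.score_sd.reindex(
            index=idx, columns=list(self.interventions)).astype(float)
        self._check()

    def _check(self) -> None:
        problems = []
        wm = self.weight_mean.dropna()
        lo_w, hi_w = WEIGHT_BOUNDS
        if ((wm < lo_w) | (wm > hi_w)).any():
            problems.append("weight mean outside [1, 5]")
        for sd in (self.weight_sd.dropna(),):
            if (sd < 0).any():
                problems.append("negative weight SD")
        if (self.score_sd.stack().dropna() < 0).any():
            problems.append("negative score SD")
        if self.n_panelists < 1:
            problems.append("n_panelists must be >= 1")
        if self.n_panelists == 1:
            if (self.weight_sd.dropna() != 0).any() or \
                    (self.score_sd.stack().dropna() != 0).any():
                problems.append("SD must be 0 when n_panelists == 1")
        for cid in self.criteria:
            kind = self.scale_kinds.get(cid)
            if kind in SCALE_BOUNDS:
                lo, hi = SCALE_BOUNDS[kind]
                row = self.score_mean.loc[cid].dropna()
                if ((row < lo) | (row > hi)).any():
                    problems.append(f"score mean outside scale for {cid!r}")
        if problems:
            raise PanelValidationError(problems)

    # -- missing-criterion roles ------------------------------------------

    @property
    def unweighted(self) -> frozenset[str]:
        """Criteria with no pooled weight."""
        return frozenset(self.weight_mean.index[self.weight_mean.isna()])

    @property
    def unscored(self) -> frozenset[str]:
        """Criteria lacking a pooled score for at least one intervention."""
        return frozenset(
            self.score_mean.index[self.score_mean.isna().any(axis=1)]
        )

    @property
    def weighted_criteria(self) -> tuple[str, ...]:
        return tuple(c for c in self.criteria if c not in self.unweighted)

    @property
    def scored_criteria(self) -> tuple[str, ...]:
        return tuple(c for c in self.criteria if c not in self.unscored)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_tables(cls, model: CriterionModel, interventions, weights, scores,
                    n_panelists: int) -> "AggregatedPanel":
        """Build from ``{criterion: (mean, sd)}`` weights and
        ``{criterion: {intervention: (mean, sd)}}`` scores; criteria absent
        from a mapping are flagged missing in that role."""
        quantitative = [c.id for c in model if c.scale_kind != QUALITATIVE]
        interventions = tuple(interventions)
        wm = pd.Series({c: weights.get(c, (np.nan,))[0] for c in quantitative})
        ws = pd.Series(
            {c: weights[c][1] if c in weights else np.nan for c in quantitative}
        )
        sm = pd.DataFrame(np.nan, index=quantitative, columns=list(interventions))
        ss = sm.copy()
        for cid, per_drug in scores.items():
            for drug, (m, s) in per_drug.items():
                sm.loc[cid, drug] = m
                ss.loc[cid, drug] = s
        return cls(
            criteria=tuple(quantitative), interventions=interventions,
            weight_mean=wm, weight_sd=ws, score_mean=sm, score_sd=ss,
            n_panelists=n_panelists,
            scale_kinds={c.id: c.scale_kind for c in model
                         if c.scale_kind != QUALITATIVE},
        )

    # -- serialization -----------------------------------------------------

    @staticmethod
    def _none_nan(x):
        return None if x is None or (isinstance(x, float) and math.isnan(x)) else x

    def to_dict(self) -> dict:
        nn = self._none_nan
        return {
            "criteria": list(self.criteria),
            "interventions": list(self.interventions),
            "n_panelists": self.n_panelists,
            "scale_kinds": dict(self.scale_kinds),
            "weight_mean": {c: nn(self.weight_mean[c]) for c in self.criteria},
            "weight_sd": {c: nn(self.weight_sd[c]) for c in self.criteria},
            "score_mean": {
                c: {d: nn(self.score_mean.loc[c, d]) for d in self.interventions}
                for c in self.criteria
            },
            "score_sd": {
                c: {d: nn(self.score_sd.loc[c, d]) for d in self.interventions}
                for c in self.criteria
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AggregatedPanel":
        criteria = list(data["criteria"])
        interventions = list(data["interventions"])
        as_series = lambda m: pd.Series(
            {c: (np.nan if m.get(c) is None else m[c]) for c in criteria}
        )
        as_frame = lambda m: pd.DataFrame(
            {
                d: {c: (np.nan if m[c].get(d) is None else m[c][d])
                    for c in criteria}
                for d in interventions
            }
        )
        return cls(
            criteria=tuple(criteria),
            interventions=tuple(interventions),
            weight_mean=as_series(data["weight_mean"]),
            weight_sd=as_series(data["weight_sd"]),
            score_mean=as_frame(data["score_mean"]),
            score_sd=as_frame(data["score_sd"]),
            n_panelists=int(data["n_panelists"]),
            scale_kinds=dict(data.get("scale_kinds", {})),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "AggregatedPanel":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    data = json.load(fh)
        return cls.from_dict(data)


def aggregate_panel(panel: PanelMatrices,
                    model: CriterionModel | None = None) -> AggregatedPanel:
    """Pool a raw panel into per-criterion means and sample SDs.

    The sample standard deviation uses the n−1 denominator; a column with a
    single respondent gets SD 0, and a column nobody answered stays missing.

    Parameters
    ----------
    panel : PanelMatrices
        A validated panel (see :func:`validate_panel`).
    model : CriterionModel, optional
        Needed only if the panel does not already carry one.
    """
    model = model or panel.model
    if model is None:
        raise ValueError("panel carries no criterion model; pass model= or "
                         "run validate_panel first")
    if panel.n_panelists == 0:
        raise ValueError("cannot aggregate an empty panel (no panelists)")

    quantitative = [c.id for c in model if c.scale_kind != QUALITATIVE]
    wm, ws = {}, {}
    for cid in quantitative:
        if cid in panel.weights.columns:
            wm[cid], ws[cid] = _col_mean_sd(panel.weights[cid])
        else:
            wm[cid], ws[cid] = float("nan"), float("nan")

    interventions = list(panel.interventions)
    sm = pd.DataFrame(np.nan, index=quantitative, columns=interventions)
    ss = sm.copy()
    grouped = panel.scores.groupby(["criterion_id", "intervention"])["score"]
    for (cid, drug), values in grouped:
        if cid in sm.index and drug in sm.columns:
            sm.loc[cid, drug], ss.loc[cid, drug] = _col_mean_sd(values)

    return AggregatedPanel(
        criteria=tuple(quantitative),
        interventions=tuple(interventions),
        weight_mean=pd.Series(wm), weight_sd=pd.Series(ws),
        score_mean=sm, score_sd=ss,
        n_panelists=panel.n_panelists,
        scale_kinds={c.id: c.scale_kind for c in model
                     if c.scale_kind != QUALITATIVE},
    )


def load_dpp4_fixture():
    """Return ``(core_model, AggregatedPanel)`` for the DPP-4 worked example."""
    from .dpp4 import load_dpp4_fixture as _load

    return _load()
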