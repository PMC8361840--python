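"""Pipeline orchestration and the structured appraisal report.

A run ties the stages together: load (or aggregate) a panel, normalize
weights, compute value estimates, rank, optionally simulate rank stability,
and emit a single JSON report in which every number is traceable to a stage
output.  The report schema is defined by the pydantic models below; the JSON
schema shipped at ``evidem_mcda/schemas/report.schema.json`` is generated
from :class:`Report` and kept in lockstep by the test suite.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from importlib import resources
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .panel import AggregatedPanel, PanelMatrices, aggregate_panel, \
    round_half_up, validate_panel
from .registry import build_core_model
from .stability import simulate_ranks
from .valuation import (
    compute_value,
    decompose_value,
    get_policy,
    normalize_weights,
    rank_interventions,
)

__all__ = [
    "RunConfig",
    "Report",
    "run_pipeline",
    "render_contribution_chart_data",
    "load_report_schema",
]

log = logging.getLogger("evidem_mcda")

SCHEMA_VERSION = "1"


class RunConfig(BaseModel):
    """Configuration for one pipeline run."""

    panel: str | None = None  # aggregated-panel JSON
    weights_csv: str | None = None  # raw panel CSV pair
    scores_csv: str | None = None
    policy: str = "retain_weights"
    digits: int = 2
    seed: int | None = None
    draws: int = 0
    out: str | None = None
    verbosity: str = "INFO"

    @field_validator("policy")
    @classmethod
    def _known_policy(cls, v: str) -> str:
        get_policy(v)  # raises ValueError on unknown modes
        return v

    @field_validator("digits")
    @classmethod
    def _nonneg_digits(cls, v: int) -> int:
        if v < 0:
            raise ValueError("digits must be >= 0")
        return v

    @field_validator("draws")
    @classmethod
    def _nonneg_draws(cls, v: int) -> int:
        if v < 0:
            raise ValueError("draws must be >= 0")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class CriterionContribution(BaseModel):
    criterion: str
    Wx: float
    Sx: float
    Vx: float


class InterventionReport(BaseModel):
    intervention: str
    V: float
    V_rounded: float
    n_criteria: int
    contributions: list[CriterionContribution]


class RankingEntry(BaseModel):
    rank: int
    intervention: str
    V: float


class Report(BaseModel):
    """Full appraisal report; every numeric field is a stage output."""

    schema_version: str = SCHEMA_VERSION
    generated_at: str = ""
    policy: str
    seed: int | None = None
    n_panelists: int
    included_criteria: list[str]
    unweighted_criteria: list[str]
    unscored_criteria: list[str]
    weight_denominator: float
    normalized_weights: dict[str, float]
    interventions: list[InterventionReport]
    ranking: list[RankingEntry]
    rank_stability: dict | None = None


def _load_panel(config: RunConfig) -> AggregatedPanel:
    if config.panel:
        return AggregatedPanel.from_json(Path(config.panel))
    if config.weights_csv and config.scores_csv:
        model = build_core_model()
        raw = PanelMatrices.from_csv(config.weights_csv, config.scores_csv)
        raw = validate_panel(raw, model)
        return aggregate_panel(raw)
    raise ValueError(
        "config must provide either 'panel' (aggregated JSON) or both "
        "'weights_csv' and 'scores_csv'"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full appraisal pipeline and return the report as a dict.

    Stages: load → normalize weights → value estimates → ranking →
    (optional) rank-stability simulation.  Any stage error propagates with
    its stage name; the report file (``config.out``) is written only after
    every stage succeeded.
    """
    policy = get_policy(config.policy)
    stage = "load"
    try:
        agg = _load_panel(config)
        stage = "normalize"
        norm = normalize_weights(agg, policy)
        denominator = float(agg.weight_mean[list(norm.included_criteria)].sum())
        log.info(
            "panel: n_panelists=%d policy=%s included=%d unweighted=%s "
            "unscored=%s weight denominator=%.4f",
            agg.n_panelists, policy.mode, len(norm.included_criteria),
            sorted(agg.unweighted), sorted(agg.unscored), denominator,
        )
        stage = "value"
        estimates = compute_value(agg, policy)
        stage = "rank"
        ranking = rank_interventions(estimates)
        stability = None
        if config.draws > 0:
            stage = "simulate"
            result = simulate_ranks(agg, n_draws=config.draws,
                                    seed=config.seed, policy=policy)
            stability = result.to_dict()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = Report(
        generated_at=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        policy=policy.mode,
        seed=config.seed,
        n_panelists=agg.n_panelists,
        included_criteria=list(norm.included_criteria),
        unweighted_criteria=sorted(agg.unweighted),
        unscored_criteria=sorted(agg.unscored),
        weight_denominator=denominator,
        normalized_weights={c: float(norm.W[c]) for c in norm.included_criteria},
        interventions=[
            InterventionReport(
                intervention=e.intervention,
                V=e.total,
                V_rounded=round_half_up(e.total, config.digits),
                n_criteria=e.n_criteria,
                contributions=[
                    CriterionContribution(
                        criterion=row.criterion, Wx=row.Wx, Sx=row.Sx, Vx=row.Vx,
                    )
                    for row in decompose_value(e).itertuples(index=False)
                ],
            )
            for e in estimates
        ],
        ranking=[RankingEntry(rank=r, intervention=d, V=v)
                 for r, d, v in ranking],
        rank_stability=stability,
    )
    doc = report.model_dump()
    if config.out:
        with open(config.out, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return doc


def render_contribution_chart_data(estimates) -> pd.DataFrame:
    """Long-format (intervention, criterion, Vx) table for stacked-bar plots.

    Criteria whose contribution is zero for every intervention (criteria
    retained without evidence) are dropped; per-intervention Vx sums still
    equal each intervention's V exactly.
    """
    if not estimates:
        raise ValueError("no estimates to render")
    carried = [
        cid for cid in estimates[0].contributions
        if any(e.contributions.get(cid, 0.0) != 0.0 for e in estimates)
    ]
    rows = [
        {"intervention": e.intervention, "criterion": cid,
         "Vx": e.contributions[cid]}
        for e in estimates
        for cid in carried
    ]
    return pd.DataFrame(rows, columns=["intervention", "criterion", "Vx"])


def load_report_schema() -> dict:
    """The JSON schema of :class:`Report` shipped with the package."""
    text = resources.files("evidem_mcda").joinpath(
        "schemas/report.schema.json").read_text(encoding="utf-8")
    return json.loads(text)
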