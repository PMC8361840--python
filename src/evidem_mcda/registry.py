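"""Criterion models: the EVIDEM quantitative core model and qualitative contextual tool.

The EVIDEM (Evidence and Value: Impact on Decision Making) framework appraises a
health technology against a fixed set of criteria.  The *core model* is the
quantitative part: 13 criteria in five domains, each scored on a numeric scale
and entering the additive value estimate.  The *contextual tool* is qualitative:
7 criteria in three groups that a committee deliberates on but never scores into
the value.

Two scale kinds exist for quantitative criteria:

``absolute``
    The intervention is rated 0–5 on its own merits (e.g. disease severity).
``relative``
    The intervention is rated −5..+5 against a comparator (here, placebo);
    negative means worse than the comparator.

Criterion ids are lowercase snake-case slugs used as join keys across weight
files, score files and reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator

import yaml

__all__ = [
    "ScaleKind",
    "CriterionDefinition",
    "CriterionModel",
    "build_core_model",
    "build_contextual_tool",
    "lookup_criterion",
    "UnknownCriterionError",
    "SCALE_BOUNDS",
]

#: Valid scale kinds.
ScaleKind = str
ABSOLUTE = "absolute"
RELATIVE = "relative"
QUALITATIVE = "qualitative"
_SCALE_KINDS = (ABSOLUTE, RELATIVE, QUALITATIVE)

#: Elicitation score bounds per scale kind (qualitative criteria are not scored).
SCALE_BOUNDS: dict[str, tuple[float, float]] = {
    ABSOLUTE: (0.0, 5.0),
    RELATIVE: (-5.0, 5.0),
}


class UnknownCriterionError(KeyError):
    """Raised when a criterion id is not present in a model."""


@dataclass(frozen=True)
class CriterionDefinition:
    """One appraisal criterion.

    Parameters
    ----------
    id : str
        Short stable token, unique within a model.
    label : str
        Display name.
    domain_label : str
        The domain (core model) or group (contextual tool) the criterion
        belongs to.
    scale_kind : {"absolute", "relative", "qualitative"}
        How the criterion is scored; ``qualitative`` criteria are never scored.
    comparator_note : str
        Free text for relative criteria, e.g. ``"vs placebo"``.
    """

    id: str
    label: str
    domain_label: str
    scale_kind: ScaleKind
    comparator_note: str = ""

    def __post_init__(self) -> None:
        if self.scale_kind not in _SCALE_KINDS:
            raise ValueError(
                f"scale_kind must be one of {_SCALE_KINDS}, got {self.scale_kind!r}"
            )


@dataclass(frozen=True)
class CriterionModel:
    """An ordered, validated set of criteria."""

    name: str
    criteria: tuple[CriterionDefinition, ...]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.criteria]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate criterion ids in model {self.name!r}: {dupes}")
        object.__setattr__(self, "criteria", tuple(self.criteria))

    def __iter__(self) -> Iterator[CriterionDefinition]:
        return iter(self.criteria)

    def __len__(self) -> int:
        return len(self.criteria)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    @property
    def domains(self) -> tuple[str, ...]:
        """Domain labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.criteria:
            seen.setdefault(c.domain_label, None)
        return tuple(seen)

    def __getitem__(self, criterion_id: str) -> CriterionDefinition:
        return lookup_criterion(self, criterion_id)

    def __contains__(self, criterion_id: str) -> bool:
        return any(c.id == criterion_id for c in self.criteria)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {"name": self.name, "criteria": [asdict(c) for c in self.criteria]}

    @classmethod
    def from_dict(cls, data: dict) -> "CriterionModel":
        return cls(
            name=data["name"],
            criteria=tuple(CriterionDefinition(**c) for c in data["criteria"]),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CriterionModel":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    data = json.load(fh)
        return cls.from_dict(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "CriterionModel":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        elif isinstance(source, str) and "\n" in source:
            data = yaml.safe_load(source)
        else:
            with open(source, encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)


def _c(id, label, domain, kind, note=""):
    return CriterionDefinition(id, label, domain, kind, note)


_VS_PLACEBO = "vs placebo"

_CORE_CRITERIA = (
    _c("disease_severity", "Disease severity", "Need for Intervention", ABSOLUTE),
    _c("size_of_affected_population", "Size of affected population",
       "Need for Intervention", ABSOLUTE),
    _c("unmet_needs", "Unmet needs", "Need for Intervention", ABSOLUTE),
    _c("comparative_effectiveness", "Comparative effectiveness",
       "Comparative Outcomes of Intervention", RELATIVE, _VS_PLACEBO),
    _c("comparative_safety_tolerability", "Comparative safety/tolerability",
       "Comparative Outcomes of Intervention", RELATIVE, _VS_PLACEBO),
    _c("comparative_patient_perceived_health_pro",
       "Comparative patient-perceived health / PRO",
       "Comparative Outcomes of Intervention", RELATIVE, _VS_PLACEBO),
    _c("type_of_preventive_benefit", "Type of preventive benefit",
       "Type of Benefit of Intervention", ABSOLUTE),
    _c("type_of_therapeutic_benefit", "Type of therapeutic benefit",
       "Type of Benefit of Intervention", ABSOLUTE),
    _c("cost_of_intervention",
       "Comparative cost consequences - cost of intervention",
       "Economic Consequences of Intervention", RELATIVE, _VS_PLACEBO),
    _c("other_medical_costs",
       "Comparative cost consequences - other medical costs",
       "Economic Consequences of Intervention", RELATIVE, _VS_PLACEBO),
    _c("non_medical_costs",
       "Comparative cost consequences - non-medical costs",
       "Economic Consequences of Intervention", RELATIVE, _VS_PLACEBO),
    _c("quality_of_evidence", "Quality of evidence",
       "Knowledge about Intervention", ABSOLUTE),
    _c("expert_consensus_guidelines",
       "Expert consensus/clinical practice guidelines",
       "Knowledge about Intervention", ABSOLUTE),
)

_CONTEXTUAL_CRITERIA = (
    _c("mandate_and_scope_of_healthcare_system",
       "Mandate and scope of healthcare system",
       "Normative Contextual Criteria", QUALITATIVE),
    _c("population_priorities_and_access", "Population priorities and access",
       "Normative Contextual Criteria", QUALITATIVE),
    _c("common_goal_and_specific", "Common goal and specific",
       "Normative Contextual Criteria", QUALITATIVE),
    _c("environmental_impact", "Environmental impact",
       "Normative Contextual Criteria", QUALITATIVE),
    _c("system_capacity_and_appropriate_use",
       "System capacity and appropriate use of intervention",
       "Feasibility Contextual Criteria", QUALITATIVE),
    _c("political_historical_cultural_context",
       "Political/historical/cultural context",
       "Feasibility Contextual Criteria", QUALITATIVE),
    _c("opportunity_costs_and_affordability",
       "Opportunity costs and affordability", "Opportunity Cost", QUALITATIVE),
)


def build_core_model() -> CriterionModel:
    """Return the 13-criterion quantitative core model.

    Seven criteria are absolute (need, type of benefit, knowledge domains) and
    six are relative, rated against placebo (comparative outcomes and the three
    cost-consequence criteria).
    """
    return CriterionModel(name="EVIDEM core model", criteria=_CORE_CRITERIA)


def build_contextual_tool() -> CriterionModel:
    """Return the 7-criterion qualitative contextual tool.

    Contextual criteria are deliberated on, never scored; they do not enter the
    quantitative value estimate.
    """
    return CriterionModel(name="EVIDEM contextual tool", criteria=_CONTEXTUAL_CRITERIA)


def lookup_criterion(model: CriterionModel, criterion_id: str) -> CriterionDefinition:
    """Return the criterion with the given id, or raise :class:`UnknownCriterionError`."""
    for c in model.criteria:
        if c.id == criterion_id:
            return c
    raise UnknownCriterionError(
        f"unknown criterion {criterion_id!r} in model {model.name!r}; "
        f"available ids: {list(model.ids)}"
    )
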