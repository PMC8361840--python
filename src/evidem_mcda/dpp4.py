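"""Built-in worked example: a six-member committee appraisal of five DPP-4 inhibitors.

This module holds the aggregated panel elicitation for the five dipeptidyl
peptidase-4 inhibitors marketed in China (Saxagliptin, Alogliptin, Sitagliptin,
Linagliptin, Vildagliptin), as produced by a six-member hospital appraisal
committee (two doctors, a nurse, a pharmacist, a health economist and a
decision-maker): per-criterion mean ± SD weights and per-criterion,
per-intervention mean ± SD scores.

Two criteria are incomplete by design, reflecting the committee's actual
deliberation:

* ``type_of_preventive_benefit`` — neither weighted nor scored (no evidence
  was available on preventive benefit);
* ``other_medical_costs`` — weighted but not scored (no Chinese cost data on
  other medical costs).

The raw panelist-level matrices behind these aggregates were never published;
:mod:`evidem_mcda.synthetic` can generate statistically matching stand-ins.
"""

from __future__ import annotations

from .registry import CriterionModel, build_core_model

__all__ = [
    "INTERVENTIONS",
    "WEIGHTS",
    "SCORES",
    "N_PANELISTS",
    "UNWEIGHTED",
    "UNSCORED",
    "load_dpp4_fixture",
]

#: Intervention column order of the aggregated score table.
INTERVENTIONS: tuple[str, ...] = (
    "Saxagliptin", "Alogliptin", "Sitagliptin", "Linagliptin", "Vildagliptin",
)

N_PANELISTS = 6

#: criterion id -> (mean weight, SD) on the 1-5 importance scale.
WEIGHTS: dict[str, tuple[float, float]] = {
    "disease_severity": (3.58, 0.75),
    "size_of_affected_population": (3.58, 0.75),
    "unmet_needs": (3.01, 0.55),
    "comparative_effectiveness": (3.73, 0.82),
    "comparative_safety_tolerability": (3.58, 0.98),
    "comparative_patient_perceived_health_pro": (3.44, 0.63),
    "type_of_therapeutic_benefit": (3.58, 1.17),
    "cost_of_intervention": (3.58, 0.75),
    "other_medical_costs": (3.30, 0.98),
    "non_medical_costs": (2.87, 1.03),
    "quality_of_evidence": (4.01, 0.52),
    "expert_consensus_guidelines": (3.44, 0.63),
}

#: criterion id -> intervention -> (mean score, SD) on the criterion's scale.
#: Score order within each row follows :data:`INTERVENTIONS`.
SCORES: dict[str, dict[str, tuple[float, float]]] = {
    "disease_severity": {d: (4.00, 1.26) for d in INTERVENTIONS},
    "size_of_affected_population": {d: (4.33, 0.52) for d in INTERVENTIONS},
    "unmet_needs": {d: (3.50, 0.55) for d in INTERVENTIONS},
    "comparative_effectiveness": {
        "Saxagliptin": (3.50, 1.64),
        "Alogliptin": (4.33, 1.03),
        "Sitagliptin": (4.67, 0.52),
        "Linagliptin": (4.33, 1.03),
        "Vildagliptin": (3.67, 1.51),
    },
    "comparative_safety_tolerability": {
        "Saxagliptin": (0.17, 0.98),
        "Alogliptin": (0.33, 0.82),
        "Sitagliptin": (0.83, 0.75),
        "Linagliptin": (0.67, 1.21),
        "Vildagliptin": (0.67, 0.82),
    },
    "comparative_patient_perceived_health_pro": {
        "Saxagliptin": (-0.17, 0.41),
        "Alogliptin": (-0.33, 0.52),
        "Sitagliptin": (-0.17, 0.41),
        "Linagliptin": (-0.17, 0.41),
        "Vildagliptin": (-0.50, 0.55),
    },
    "type_of_therapeutic_benefit": {d: (4.00, 0.00) for d in INTERVENTIONS},
    "cost_of_intervention": {
        "Saxagliptin": (-1.83, 1.33),
        "Alogliptin": (-1.83, 1.33),
        "Sitagliptin": (-1.50, 0.84),
        "Linagliptin": (-1.33, 0.82),
        "Vildagliptin": (-1.17, 0.98),
    },
    "non_medical_costs": {
        "Saxagliptin": (-1.83, 1.47),
        "Alogliptin": (-1.67, 1.51),
        "Sitagliptin": (-1.33, 1.03),
        "Linagliptin": (-1.50, 1.05),
        "Vildagliptin": (-1.33, 1.21),
    },
    "quality_of_evidence": {d: (3.33, 0.82) for d in INTERVENTIONS},
    "expert_consensus_guidelines": {d: (3.67, 1.51) for d in INTERVENTIONS},
}

#: Criteria the committee never weighted.
UNWEIGHTED: frozenset[str] = frozenset({"type_of_preventive_benefit"})

#: Criteria the committee never scored (for any intervention).
UNSCORED: frozenset[str] = frozenset(
    {"type_of_preventive_benefit", "other_medical_costs"}
)


def load_dpp4_fixture() -> tuple[CriterionModel, "AggregatedPanel"]:
    """Return the core criterion model and the aggregated DPP-4 panel.

    Returns
    -------
    model : CriterionModel
        The 13-criterion quantitative core model.
    agg : AggregatedPanel
        Mean/SD weights and scores for the five DPP-4 inhibitors, with
        ``type_of_preventive_benefit`` flagged unweighted and unscored and
        ``other_medical_costs`` flagged unscored.
    """
    from .panel import AggregatedPanel  # deferred: avoid import cycle

    model = build_core_model()
    agg = AggregatedPanel.from_tables(
        model=model,
        interventions=INTERVENTIONS,
        weights=WEIGHTS,
        scores=SCORES,
        n_panelists=N_PANELISTS,
    )
    return model, agg
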