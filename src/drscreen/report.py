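"""Run-report assembly and presentation rounding.

All model and ledger arithmetic is carried at full precision; the
conventions below exist only to render numbers at the granularity used
in published summaries of this kind of programme: per-patient cost
components to the nearest INR 5, headline per-patient aggregates to the
nearest INR 100, stage totals to the nearest INR 0.1 million, component
QALYs to whole QALYs.  Each report carries both the full-precision and
the rendered figure, plus the switchable model conventions in effect,
so every printed number is traceable to a computation.
"""

from __future__ import annotations

from typing import Any

from .cea import CeaResult, Scenario
from .costing import (
    CostLedger,
    examination_cost_per_patient,
    screening_cost_per_patient,
)
from .life_tables import LifeTable
from .markov import life_expectancy, run_cohort

__all__ = ["round_to", "to_millions", "build_run_report"]


def round_to(x: float, base: float) -> float:
    """Round to the nearest multiple of ``base`` (half away from zero)."""
    import math

    return base * math.floor(x / base + 0.5)


def to_millions(x: float, digits: int = 1) -> float:
    return round(x / 1e6, digits)


def build_run_report(
    scenario: Scenario,
    lt: LifeTable,
    result: CeaResult,
    ledger: CostLedger,
) -> dict[str, Any]:
    """Assemble the deterministic run report as a plain dict.

    Regenerating the report from the same config (and seed, where
    stochastic steps are involved) yields an identical document: nothing
    time- or path-dependent is included.
    """
    p = scenario.params
    le_untreated = life_expectancy(run_cohort(p, lt, treated=False),
                                   p.half_cycle_correction)
    le_treated = life_expectancy(run_cohort(p, lt, treated=True),
                                 p.half_cycle_correction)
    screen_pp = screening_cost_per_patient(scenario.unit_costs, scenario.counts.n_screened)
    exam_pp = examination_cost_per_patient(scenario.unit_costs)
    n_treated = scenario.counts.n_treated
    return {
        "scenario": scenario.name,
        "life_table": {"min_age": lt.min_age, "max_age": lt.max_age},
        "life_expectancy_years": {
            "untreated": le_untreated,
            "treated": le_treated,
        },
        "per_person_qaly_gain": {
            "stdr_laser": result.gain_stdr,
            "cataract_surgery": result.gain_cataract,
        },
        "costs_inr": {
            "screening_per_patient": screen_pp,
            "screening_per_patient_rendered": round_to(screen_pp, 100),
            "examination_per_patient": exam_pp,
            "examination_per_patient_rendered": round_to(exam_pp, 5),
            "screening_total": ledger.screening_total,
            "examination_total": ledger.examination_total,
            "pathway_total": ledger.pathway_total,
            "laser_total": ledger.laser_total,
            "cataract_total": ledger.cataract_total,
            "programme_total": ledger.programme_total,
            "programme_total_millions_rendered": to_millions(ledger.programme_total),
            "cost_per_person_treated": (
                ledger.programme_total / n_treated if n_treated else None
            ),
            "cost_per_person_treated_rendered": (
                round_to(ledger.programme_total / n_treated, 100) if n_treated else None
            ),
        },
        "qalys": {
            "stdr": result.qalys_stdr,
            "cataract": result.qalys_cataract,
            "total": result.total_qalys,
            "stdr_rendered": round(result.qalys_stdr),
            "cataract_rendered": round(result.qalys_cataract),
            "total_rendered": round(result.qalys_stdr) + round(result.qalys_cataract),
            "per_person_treated": result.qalys_per_treated,
        },
        "icer_inr_per_qaly": result.icer,
        "classification": result.classification,
        "conventions": {
            "half_cycle_correction": p.half_cycle_correction,
            "blind_uplift_combined": p.blind_uplift_combined,
            "decline_in_stdr_model": p.decline_in_stdr_model,
            "discounting_starts_at_cycle": 1,
            "rounding": "presentation only; all totals full precision",
        },
    }
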