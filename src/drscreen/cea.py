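"""Cost-effectiveness assembly: QALY totals, ICER, threshold
classification and net monetary benefit.

The comparator is an explicit no-screening arm with zero cost and zero
QALYs — the analysis assumes that without the programme the treated
patients would have lost their sight — so the incremental cost and
incremental QALYs equal the programme totals.  Classification follows the
WHO convention: an ICER strictly below 1x GDP per capita per QALY is
highly cost-effective, below 3x cost-effective, otherwise not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

from .costing import (
    CascadeCounts,
    CostLedger,
    UnitCosts,
    build_cost_ledger,
    screening_cost_per_patient,
)
from .life_tables import LifeTable
from .markov import ModelParams, cataract_qaly_gain, stdr_qaly_gain

__all__ = [
    "Thresholds",
    "CeaResult",
    "Scenario",
    "total_qalys",
    "icer",
    "classify",
    "net_monetary_benefit",
    "evaluate_scenario",
]

HIGHLY_CE = "highly cost-effective"
CE = "cost-effective"
NOT_CE = "not cost-effective"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class Thresholds:
    """Willingness-to-pay reference values (INR per QALY)."""

    gdp_per_capita: float = 144_000.0
    multiplier_highly: float = 1.0
    multiplier_ce: float = 3.0

    def __post_init__(self) -> None:
        if self.gdp_per_capita <= 0 or self.multiplier_highly <= 0 or self.multiplier_ce <= 0:
            raise ValueError("thresholds must be positive")


def total_qalys(
    counts: CascadeCounts, gain_stdr: float, gain_cataract: float
) -> tuple[float, float, float]:
    """(QALYs from STDR treatment, from cataract surgery, total).

    Component QALYs are count x per-person discounted gain; the
    no-screening comparator contributes zero.
    """
    if gain_stdr < 0 or gain_cataract < 0:
        raise ValueError("per-person QALY gains must be non-negative")
    q_stdr = counts.n_stdr_treated * gain_stdr
    q_cat = counts.n_cataract_treated * gain_cataract
    return q_stdr, q_cat, q_stdr + q_cat


def icer(total_cost: float, qalys: float) -> float:
    """Incremental cost per QALY; NaN when the QALY denominator is not
    positive (indeterminate, never a division crash)."""
    if qalys <= 0:
        return math.nan
    return total_cost / qalys


def classify(icer_value: float, th: Thresholds = Thresholds()) -> str:
    """WHO-style band: strict less-than at each threshold, so a value
    exactly at 1x GDP falls into the plain cost-effective band."""
    if math.isnan(icer_value):
        return INDETERMINATE
    if icer_value < th.multiplier_highly * th.gdp_per_capita:
        return HIGHLY_CE
    if icer_value < th.multiplier_ce * th.gdp_per_capita:
        return CE
    return NOT_CE


def net_monetary_benefit(wtp: float, cost: float, qalys: float) -> float:
    """NMB = wtp x QALYs - cost; positive iff the ICER is below wtp."""
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    return wtp * qalys - cost


@dataclass(frozen=True)
class CeaResult:
    """Headline cost-effectiveness result for one scenario."""

    total_cost: float
    qalys_stdr: float
    qalys_cataract: float
    n_treated: int
    gain_stdr: float
    gain_cataract: float
    thresholds: Thresholds = Thresholds()

    @property
    def total_qalys(self) -> float:
        return self.qalys_stdr + self.qalys_cataract

    @property
    def icer(self) -> float:
        return icer(self.total_cost, self.total_qalys)

    @property
    def classification(self) -> str:
        return classify(self.icer, self.thresholds)

    @property
    def qalys_per_treated(self) -> float:
        if self.n_treated == 0:
            return math.nan
        return self.total_qalys / self.n_treated

    def as_dict(self) -> dict[str, Any]:
        return {
            "total_cost_inr": self.total_cost,
            "qalys_stdr": self.qalys_stdr,
            "qalys_cataract": self.qalys_cataract,
            "total_qalys": self.total_qalys,
            "n_treated": self.n_treated,
            "gain_stdr_per_person": self.gain_stdr,
            "gain_cataract_per_person": self.gain_cataract,
            "qalys_per_treated": self.qalys_per_treated,
            "icer_inr_per_qaly": self.icer,
            "classification": self.classification,
        }


@dataclass(frozen=True)
class Scenario:
    """Everything needed to evaluate one programme configuration."""

    name: str = "scenario"
    params: ModelParams = field(default_factory=ModelParams)
    unit_costs: UnitCosts = field(default_factory=UnitCosts)
    counts: CascadeCounts = field(default_factory=CascadeCounts)
    thresholds: Thresholds = field(default_factory=Thresholds)
    dsa: Any = None  # DsaSpec, attached by the sensitivity layer
    psa: Any = None  # PsaSpec
    life_table: Any = None  # SyntheticLifeTableSpec or CSV path

    def with_(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


# override keys routed to ModelParams vs UnitCosts by evaluate_scenario
_PARAM_KEYS = {
    "p_blind_untreated",
    "p_blind_treated",
    "rr_diabetes",
    "rr_blind",
    "u_stdr",
    "u_blind",
    "u_gain_cataract",
    "hrqol_decline",
    "discount_rate",
}
_COST_KEYS = {
    "laser_package",
    "cataract_surgery",
    "attendance_societal",
    "camera_price",
    "training_total",
    "staff_cost_per_screen",
    "exam_staff_admin",
}
SCREENING_COST_KEY = "screening_cost_per_patient"


def evaluate_scenario(
    scenario: Scenario,
    lt: LifeTable,
    overrides: Mapping[str, float] | None = None,
) -> CeaResult:
    """Run the full pipeline — Markov QALY gains, cost ledger, CEA — for
    one scenario, optionally with parameter overrides.

    ``overrides`` maps parameter names (model parameters, unit costs, or
    the aggregate ``screening_cost_per_patient``) to replacement values;
    it is the hook the deterministic and probabilistic sensitivity
    analyses use to perturb the pipeline without rebuilding scenarios.
    """
    overrides = dict(overrides or {})
    params = scenario.params
    uc = scenario.unit_costs
    param_over = {k: overrides.pop(k) for k in list(overrides) if k in _PARAM_KEYS}
    cost_over = {k: overrides.pop(k) for k in list(overrides) if k in _COST_KEYS}
    screen_pp = overrides.pop(SCREENING_COST_KEY, None)
    if overrides:
        raise KeyError(f"unknown override(s): {sorted(overrides)}")
    if param_over:
        params = params.with_(**param_over)
    if cost_over:
        uc = uc.with_(**cost_over)

    gain_stdr = stdr_qaly_gain(params, lt)
    gain_cat = cataract_qaly_gain(params, lt)
    ledger = build_cost_ledger(uc, scenario.counts)
    total_cost = ledger.programme_total
    if screen_pp is not None:
        baseline = screening_cost_per_patient(uc, scenario.counts.n_screened)
        total_cost += (screen_pp - baseline) * scenario.counts.n_screened

    # direct products, not total_qalys(): a sensitivity draw may yield a
    # negative gain (e.g. sampled u_stdr < u_blind) and must keep its sign
    q_stdr = scenario.counts.n_stdr_treated * gain_stdr
    q_cat = scenario.counts.n_cataract_treated * gain_cat
    return CeaResult(
        total_cost=total_cost,
        qalys_stdr=q_stdr,
        qalys_cataract=q_cat,
        n_treated=scenario.counts.n_treated,
        gain_stdr=gain_stdr,
        gain_cataract=gain_cat,
        thresholds=scenario.thresholds,
    )


def ledger_for(scenario: Scenario) -> CostLedger:
    """Cost ledger of a scenario at its central unit costs."""
    return build_cost_ledger(scenario.unit_costs, scenario.counts)
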