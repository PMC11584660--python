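"""Synthetic inputs: a plausible adult life table, stochastic screening
cascades, and the pinned 2019 Kerala pilot replication scenario.

The published analysis used Registrar-General mortality data for India
that carry no public accession, so desk-scale work runs on a
Gompertz-Makeham life table: hazard mu(x) = c + a e^{bx}, an
age-independent background term plus exponentially rising senescent
mortality.  The default parameters are calibrated so that the
diabetes-uplifted (x1.9) remaining life expectancy at age 59 falls in
the 12-13 year range, the magnitude the cohort model operates at for
this population, making synthetic runs exercise realistic numbers.  Any
real single-year or abridged table can be dropped in through the CSV
reader for replication against official mortality data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cea import Scenario, Thresholds
from .costing import CascadeCounts, UnitCosts
from .life_tables import LifeTable, MortalityUplift, apply_uplift
from .markov import ModelParams
from .sensitivity import DsaSpec, PsaSpec

__all__ = [
    "SyntheticLifeTableSpec",
    "SyntheticCascadeSpec",
    "synth_life_table",
    "synth_cascade",
    "kerala_2019_scenario",
    "implied_life_expectancy",
]


@dataclass(frozen=True)
class SyntheticLifeTableSpec:
    """Gompertz-Makeham hazard: mu(x) = makeham + gompertz_a * exp(gompertz_b * x).

    qx = 1 - exp(-mu(x)); generation is deterministic.  Defaults give a
    general-population remaining life expectancy at age 59 of about 17.4
    years and a x1.9-uplifted one of about 12.8 years.
    """

    makeham: float = 0.0015
    gompertz_a: float = 1.8e-5
    gompertz_b: float = 0.11
    age_min: int = 30
    age_max: int = 110

    def __post_init__(self) -> None:
        if self.makeham < 0 or self.gompertz_a < 0 or self.gompertz_b < 0:
            raise ValueError("hazard parameters must be non-negative")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be below age_max")


def synth_life_table(spec: SyntheticLifeTableSpec = SyntheticLifeTableSpec()) -> LifeTable:
    """Deterministic single-year life table from the hazard parameters.

    The terminal age closes the table with qx = 1.  Parameters so severe
    that qx reaches 1 before age 60 are rejected: they cannot represent
    an adult population a screening cohort is drawn from.
    """
    ages = np.arange(spec.age_min, spec.age_max + 1)
    hazard = spec.makeham + spec.gompertz_a * np.exp(spec.gompertz_b * ages)
    qx = 1.0 - np.exp(-hazard)
    early = ages < 60
    if np.any(qx[early] >= 1.0 - 1e-9):
        raise ValueError("hazard parameters give certain death before age 60")
    qx = np.minimum(qx, 1.0)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def implied_life_expectancy(lt: LifeTable, age: int, relative_risk: float = 1.0) -> float:
    """Remaining life expectancy at ``age`` under an optional mortality
    uplift — the calibration handle for synthetic tables (end-of-year
    counting, consistent with the cohort model)."""
    if relative_risk != 1.0:
        lt = apply_uplift(lt, MortalityUplift(relative_risk))
    le = 0.0
    surv = 1.0
    for a in range(age, lt.max_age + 1):
        surv *= 1.0 - lt.q(a)
        le += surv
    return le


@dataclass(frozen=True)
class SyntheticCascadeSpec:
    """Branch probabilities of the screening cascade.

    Defaults reproduce the pilot's flow in expectation: 31.3% of screened
    referred, 50% of referred attend an examination, 59.4% of attendees
    diagnosed with STDR of whom 70% are treated; 48.1% of referrals had
    ungradable images (mostly cataract), 20% of whom receive surgery.
    """

    n_screened: int = 5307
    p_referral: float = 0.313
    p_attendance: float = 0.50
    p_stdr_diagnosis: float = 0.594
    p_treatment_uptake: float = 0.70
    p_ungradable: float = 0.481
    p_cataract_uptake: float = 0.20

    def __post_init__(self) -> None:
        for name in (
            "p_referral",
            "p_attendance",
            "p_stdr_diagnosis",
            "p_treatment_uptake",
            "p_ungradable",
            "p_cataract_uptake",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_screened < 0:
            raise ValueError("n_screened must be non-negative")


def synth_cascade(spec: SyntheticCascadeSpec, seed: int) -> CascadeCounts:
    """One stochastic realisation of the cascade: sequential binomial
    draws down the referral tree, reproducible for a given seed."""
    rng = np.random.default_rng(seed)
    n_referred = int(rng.binomial(spec.n_screened, spec.p_referral))
    n_examined = int(rng.binomial(n_referred, spec.p_attendance))
    n_stdr_diag = int(rng.binomial(n_examined, spec.p_stdr_diagnosis))
    n_stdr_treated = int(rng.binomial(n_stdr_diag, spec.p_treatment_uptake))
    n_ungradable = int(rng.binomial(n_referred, spec.p_ungradable))
    n_cataract = int(rng.binomial(n_ungradable, spec.p_cataract_uptake))
    return CascadeCounts(
        n_screened=spec.n_screened,
        n_referred=n_referred,
        n_examined=n_examined,
        n_stdr_treated=n_stdr_treated,
        n_cataract_treated=n_cataract,
    )


def kerala_2019_scenario() -> Scenario:
    """The pinned replication scenario of the 2019 Kerala pilot.

    Every parameter and cascade count is fixed at its published value:
    5307 screened, 1662 referred, 830 examined, 345 treated with laser
    photocoagulation, 160 cataract surgeries; STDR→blind 9%/2% per year
    untreated/treated; mortality uplifts 1.9 (diabetes) and 2.34
    (blindness); utilities 0.70/0.55, cataract gain 0.20/year declining
    0.07%/year; 3% discounting from age 59; GDP per capita threshold
    INR 144,000.  Explicit counts take precedence over the published
    percentages, which are not exactly self-consistent.
    """
    return Scenario(
        name="kerala_2019",
        params=ModelParams(),
        unit_costs=UnitCosts(),
        counts=CascadeCounts(bilateral_fraction=0.0),
        thresholds=Thresholds(),
        dsa=DsaSpec(),
        psa=PsaSpec(),
        life_table=SyntheticLifeTableSpec(),
    )
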