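"""Bottom-up costing of the screening programme.

The programme cost has three blocks: primary-care screening (annuitized
cameras, staff training, staff time, administration, community health
worker support), secondary-care eye examinations (staff plus patient and
attendant travel and opportunity costs), and treatment (laser
photocoagulation for STDR, cataract surgery), each with its secondary-care
attendance costs.  Lines are tagged by payer — health system or societal —
so the ledger can be collapsed to either perspective.  All arithmetic is
kept at full precision in INR; rounding to the granularity used in
reports (nearest INR 5 or 100 per patient, nearest 0.1 million for
totals) is purely presentational.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "UnitCosts",
    "CascadeCounts",
    "CostLine",
    "CostLedger",
    "annuitize",
    "screening_cost_per_patient",
    "examination_cost_per_patient",
    "treatment_costs",
    "build_cost_ledger",
    "cascade_from_rates",
]

HEALTH_SYSTEM = "health-system"
SOCIETAL = "societal"

# attendances bundled with each treatment package
LASER_ATTENDANCES = 3
CATARACT_ATTENDANCES = 1


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs (INR) and resource quantities of the screening cascade.

    ``staff_cost_per_screen`` and ``exam_staff_admin`` are the collapsed
    salary-derived figures (INR 70 per screen, INR 205 per examination);
    the underlying staff minutes are retained so scenarios with explicit
    wage rates can re-derive them.
    """

    camera_price: float = 300_000.0
    camera_life: float = 5.0
    n_cameras: int = 16
    training_total: float = 560_000.0
    nurse_minutes_screen: float = 12.0
    doctor_minutes_screen: float = 1.0
    grader_minutes: float = 5.0
    oncost_rate: float = 0.10
    admin_per_screen: float = 15.0
    asha_per_screen: float = 15.0
    staff_cost_per_screen: float = 70.0
    exam_staff_admin: float = 205.0
    travel_patient: float = 350.0
    travel_attendant: float = 350.0
    opp_cost_patient: float = 100.0
    opp_cost_attendant: float = 150.0
    laser_package: float = 12_000.0
    attendance_societal: float = 950.0
    cataract_surgery: float = 18_000.0
    annuity_rate: float = 0.03

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"unit cost {name} must be non-negative")

    def with_(self, **kwargs) -> "UnitCosts":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CascadeCounts:
    """Patient counts down the screening cascade."""

    n_screened: int = 5307
    n_referred: int = 1662
    n_examined: int = 830
    n_stdr_treated: int = 345
    n_cataract_treated: int = 160
    bilateral_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.n_screened >= self.n_referred >= self.n_examined >= 0:
            raise ValueError(
                "cascade must be non-increasing: screened >= referred >= examined"
            )
        if self.n_stdr_treated < 0 or self.n_cataract_treated < 0:
            raise ValueError("treated counts must be non-negative")
        if not 0.0 <= self.bilateral_fraction <= 1.0:
            raise ValueError("bilateral_fraction must be in [0, 1]")

    @property
    def n_treated(self) -> int:
        return self.n_stdr_treated + self.n_cataract_treated

    def with_(self, **kwargs) -> "CascadeCounts":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CostLine:
    stage: str
    payer: str
    amount: float


@dataclass(frozen=True)
class CostLedger:
    """Itemised programme costs with stage totals.

    ``pathway_total`` covers screening plus examinations (the path to
    diagnosis); ``programme_total`` adds both treatment blocks.
    """

    lines: tuple[CostLine, ...]
    screening_total: float = field(init=False)
    examination_total: float = field(init=False)
    laser_total: float = field(init=False)
    cataract_total: float = field(init=False)

    def __post_init__(self) -> None:
        def stage_sum(stage: str) -> float:
            return sum(l.amount for l in self.lines if l.stage == stage)

        object.__setattr__(self, "screening_total", stage_sum("screening"))
        object.__setattr__(self, "examination_total", stage_sum("examination"))
        object.__setattr__(self, "laser_total", stage_sum("laser"))
        object.__setattr__(self, "cataract_total", stage_sum("cataract"))

    @property
    def pathway_total(self) -> float:
        return self.screening_total + self.examination_total

    @property
    def programme_total(self) -> float:
        return self.pathway_total + self.laser_total + self.cataract_total

    def total(self, payer: str | None = None) -> float:
        if payer is None:
            return self.programme_total
        return sum(l.amount for l in self.lines if l.payer == payer)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": l.stage, "payer": l.payer, "amount_inr": l.amount} for l in self.lines]
        )


def annuitize(capital: float, lifetime: float, rate: float) -> float:
    """Equivalent constant annual cost of a capital outlay.

    Annuity-immediate: payment = capital * r / (1 - (1+r)^-L); at r = 0
    this degenerates to straight-line capital / lifetime.
    """
    if capital < 0:
        raise ValueError("capital must be non-negative")
    if lifetime < 1:
        raise ValueError(f"asset lifetime must be at least 1 year (got {lifetime})")
    if rate == 0.0:
        return capital / lifetime
    return capital * rate / (1.0 - (1.0 + rate) ** (-lifetime))


def screening_cost_per_patient(uc: UnitCosts, n_screened: int) -> float:
    """Full-precision cost per patient screened, INR.

    Annuitized camera cost and training are spread over the screened
    population; staff, administration and community-health-worker support
    are per-screen unit costs.
    """
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    camera_annual = annuitize(uc.camera_price * uc.n_cameras, uc.camera_life, uc.annuity_rate)
    return (
        camera_annual / n_screened
        + uc.training_total / n_screened
        + uc.staff_cost_per_screen
        + uc.admin_per_screen
        + uc.asha_per_screen
    )


def examination_cost_per_patient(uc: UnitCosts) -> float:
    """Cost per secondary-care eye examination, INR (staff/admin plus
    patient-side travel and opportunity costs)."""
    return (
        uc.exam_staff_admin
        + uc.travel_patient
        + uc.travel_attendant
        + uc.opp_cost_patient
        + uc.opp_cost_attendant
    )


def treatment_costs(uc: UnitCosts, counts: CascadeCounts) -> tuple[float, float]:
    """(laser_total, cataract_total) in INR.

    Laser: package price plus three secondary-care attendances per
    patient; a ``bilateral_fraction`` of laser patients incurs one extra
    package (health-care cost only — no additional attendance cost).
    Cataract: surgery price plus one attendance.
    """
    laser_per_patient = uc.laser_package + LASER_ATTENDANCES * uc.attendance_societal
    laser_total = counts.n_stdr_treated * laser_per_patient
    laser_total += counts.bilateral_fraction * counts.n_stdr_treated * uc.laser_package
    cataract_per_patient = uc.cataract_surgery + CATARACT_ATTENDANCES * uc.attendance_societal
    cataract_total = counts.n_cataract_treated * cataract_per_patient
    return laser_total, cataract_total


def build_cost_ledger(uc: UnitCosts, counts: CascadeCounts) -> CostLedger:
    """Assemble the itemised programme ledger from unit costs and counts."""
    n = counts.n_screened
    lines: list[CostLine] = []
    if n > 0:
        camera_annual = annuitize(uc.camera_price * uc.n_cameras, uc.camera_life, uc.annuity_rate)
        lines += [
            CostLine("screening", HEALTH_SYSTEM, camera_annual),
            CostLine("screening", HEALTH_SYSTEM, uc.training_total),
            CostLine("screening", HEALTH_SYSTEM, uc.staff_cost_per_screen * n),
            CostLine("screening", HEALTH_SYSTEM, uc.admin_per_screen * n),
            CostLine("screening", HEALTH_SYSTEM, uc.asha_per_screen * n),
        ]
    m = counts.n_examined
    lines += [
        CostLine("examination", HEALTH_SYSTEM, uc.exam_staff_admin * m),
        CostLine("examination", SOCIETAL, uc.travel_patient * m),
        CostLine("examination", SOCIETAL, uc.travel_attendant * m),
        CostLine("examination", SOCIETAL, uc.opp_cost_patient * m),
        CostLine("examination", SOCIETAL, uc.opp_cost_attendant * m),
    ]
    k = counts.n_stdr_treated
    lines += [
        CostLine("laser", HEALTH_SYSTEM, uc.laser_package * k),
        CostLine("laser", HEALTH_SYSTEM, counts.bilateral_fraction * k * uc.laser_package),
        CostLine("laser", SOCIETAL, LASER_ATTENDANCES * uc.attendance_societal * k),
    ]
    c = counts.n_cataract_treated
    lines += [
        CostLine("cataract", HEALTH_SYSTEM, uc.cataract_surgery * c),
        CostLine("cataract", SOCIETAL, CATARACT_ATTENDANCES * uc.attendance_societal * c),
    ]
    return CostLedger(lines=tuple(lines))


def _round_half_even(x: float) -> int:
    return int(round(x))


def cascade_from_rates(
    n_screened: int,
    referral_rate: float,
    attendance_rate: float,
    stdr_diagnosed: int,
    treat_rate_stdr: float,
    ungradable: int,
    cataract_rate: float,
    explicit: CascadeCounts | None = None,
) -> CascadeCounts:
    """Derive cascade counts from branch rates (round half to even).

    When ``explicit`` supplies printed counts they take precedence over
    the rate-derived values; discrepancies are logged, since published
    percentages are rarely exactly consistent with published counts.
    """
    import logging

    for name, r in (
        ("referral_rate", referral_rate),
        ("attendance_rate", attendance_rate),
        ("treat_rate_stdr", treat_rate_stdr),
        ("cataract_rate", cataract_rate),
    ):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [0, 1]")
    n_referred = _round_half_even(n_screened * referral_rate)
    n_examined = _round_half_even(n_referred * attendance_rate)
    n_stdr_treated = _round_half_even(stdr_diagnosed * treat_rate_stdr)
    n_cataract = _round_half_even(ungradable * cataract_rate)
    computed = CascadeCounts(
        n_screened=n_screened,
        n_referred=n_referred,
        n_examined=n_examined,
        n_stdr_treated=n_stdr_treated,
        n_cataract_treated=n_cataract,
    )
    if explicit is None:
        return computed
    log = logging.getLogger(__name__)
    for f in ("n_referred", "n_examined", "n_stdr_treated", "n_cataract_treated"):
        got, want = getattr(computed, f), getattr(explicit, f)
        if got != want:
            log.info("cascade %s: rate-derived %d overridden by explicit %d", f, got, want)
    return explicit
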