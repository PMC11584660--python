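"""Deterministic (one-way / tornado) and probabilistic sensitivity
analysis of the cost-effectiveness result.

One-way analysis moves each input 10% below and above its central value
(probabilities and utilities are clipped back into [0, 1] with a warning)
and records the ICER at each leg; the tornado table is sorted by the
ICER span.

The probabilistic analysis assigns a gamma distribution to inputs with a
zero lower bound and no upper bound (unit costs, the blind-mortality
relative risk) and a beta distribution to inputs confined to the unit
interval (utilities, transition probabilities, the HRQoL decline rate),
each fitted by the method of moments with SD = 25% of the point
estimate.  Draws are independent across parameters, with one child
random stream per parameter keyed by the parameter's name so that adding
or removing a parameter leaves the other streams untouched.  Each
iteration re-runs the full model and ledger; the cost-effectiveness
acceptability curve (CEAC) is the fraction of iterations with positive
net monetary benefit at each willingness-to-pay value.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import SCREENING_COST_KEY, Scenario, evaluate_scenario, net_monetary_benefit
from .costing import screening_cost_per_patient
from .life_tables import LifeTable

logger = logging.getLogger(__name__)

__all__ = [
    "DsaSpec",
    "PsaSpec",
    "PsaDraws",
    "one_way_dsa",
    "fit_gamma_moments",
    "fit_beta_moments",
    "run_psa",
    "ceac",
    "central_values",
]

GAMMA = "gamma"
BETA = "beta"

# parameter -> distribution family; beta for quantities confined to [0, 1],
# gamma for non-negative unbounded ones
DEFAULT_FAMILIES: dict[str, str] = {
    "u_stdr": BETA,
    "u_blind": BETA,
    "u_gain_cataract": BETA,
    "hrqol_decline": BETA,
    "p_blind_untreated": BETA,
    "p_blind_treated": BETA,
    "rr_blind": GAMMA,
    "laser_package": GAMMA,
    "cataract_surgery": GAMMA,
    SCREENING_COST_KEY: GAMMA,
}

UNIT_INTERVAL_PARAMS = {k for k, v in DEFAULT_FAMILIES.items() if v == BETA}


@dataclass(frozen=True)
class DsaSpec:
    """One-way sensitivity analysis specification."""

    parameters: tuple[str, ...] = tuple(DEFAULT_FAMILIES)
    low_factor: float = 0.9
    high_factor: float = 1.1


@dataclass(frozen=True)
class PsaSpec:
    """Probabilistic sensitivity analysis specification."""

    n_iterations: int = 10_000
    sd_fraction: float = 0.25
    families: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    wtp_grid: tuple[float, ...] = (
        0.0,
        25_000.0,
        50_000.0,
        75_000.0,
        100_000.0,
        144_000.0,
        200_000.0,
        300_000.0,
        432_000.0,
        1_000_000.0,
    )
    enforce_treated_below_untreated: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.sd_fraction <= 0:
            raise ValueError("sd_fraction must be positive")
        if 144_000.0 not in self.wtp_grid:
            raise ValueError("wtp grid must include the 144,000 INR/QALY threshold")


def central_values(scenario: Scenario, parameters) -> dict[str, float]:
    """Central value of each varied parameter, read off the scenario."""
    out: dict[str, float] = {}
    for name in parameters:
        if name == SCREENING_COST_KEY:
            out[name] = screening_cost_per_patient(
                scenario.unit_costs, scenario.counts.n_screened
            )
        elif hasattr(scenario.params, name):
            out[name] = getattr(scenario.params, name)
        elif hasattr(scenario.unit_costs, name):
            out[name] = getattr(scenario.unit_costs, name)
        else:
            raise KeyError(f"unknown sensitivity parameter {name!r}")
    return out


def _clip_unit(name: str, value: float) -> float:
    if name in UNIT_INTERVAL_PARAMS and not 0.0 <= value <= 1.0:
        clipped = min(max(value, 0.0), 1.0)
        logger.warning("DSA leg for %s clipped from %g to %g", name, value, clipped)
        return clipped
    return value


def one_way_dsa(
    scenario: Scenario, lt: LifeTable, spec: DsaSpec | None = None
) -> pd.DataFrame:
    """Tornado table: ICER at the low and high leg of each parameter.

    Columns ``parameter, central, low_value, high_value, icer_low,
    icer_high, span, icer_central``, sorted by descending span.  A failed
    evaluator leg flags the parameter (NaN legs) and the run continues.
    """
    spec = spec or (scenario.dsa if isinstance(scenario.dsa, DsaSpec) else DsaSpec())
    centrals = central_values(scenario, spec.parameters)
    icer_central = evaluate_scenario(scenario, lt).icer
    rows = []
    for name, central in centrals.items():
        legs = {}
        for leg, factor in (("low", spec.low_factor), ("high", spec.high_factor)):
            value = _clip_unit(name, central * factor)
            try:
                legs[leg] = evaluate_scenario(scenario, lt, {name: value}).icer
            except Exception:  # pragma: no cover - defensive
                logger.exception("DSA leg failed for %s=%g", name, value)
                legs[leg] = math.nan
        span = abs(legs["high"] - legs["low"])
        rows.append(
            {
                "parameter": name,
                "central": central,
                "low_value": central * spec.low_factor,
                "high_value": central * spec.high_factor,
                "icer_low": legs["low"],
                "icer_high": legs["high"],
                "span": span,
                "icer_central": icer_central,
            }
        )
    df = pd.DataFrame(rows).sort_values("span", ascending=False, kind="mergesort")
    return df.reset_index(drop=True)


def fit_gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments gamma fit: (shape, scale).

    shape = (mean/sd)^2, scale = sd^2/mean; the fitted distribution
    reproduces the requested mean and SD exactly.  With SD = 25% of the
    mean, the shape is always 16.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError(f"gamma moments need positive mean and sd (got {mean}, {sd})")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def fit_beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta fit: (alpha, beta).

    Requires sd^2 < mean(1-mean); nu = mean(1-mean)/sd^2 - 1, alpha =
    mean nu, beta = (1-mean) nu.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1) (got {mean})")
    if sd <= 0:
        raise ValueError("beta sd must be positive")
    if sd**2 >= mean * (1.0 - mean):
        raise ValueError(
            f"sd^2 = {sd**2:g} must be below mean(1-mean) = {mean * (1 - mean):g} "
            f"for a beta fit at mean {mean}"
        )
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def _param_rng(root_seed: int, name: str) -> np.random.Generator:
    """Independent stream per parameter, keyed by name: stable under
    addition or removal of other parameters."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([root_seed, key]))


@dataclass(frozen=True)
class PsaDraws:
    """Sampled parameters and per-iteration (cost, QALY, ICER, NMB)."""

    frame: pd.DataFrame
    seed: int
    wtp_grid: tuple[float, ...]

    @property
    def n_iterations(self) -> int:
        return len(self.frame)


def sample_parameters(
    scenario: Scenario, spec: PsaSpec, seed: int
) -> pd.DataFrame:
    """Draw the per-iteration parameter matrix (no model evaluation)."""
    centrals = central_values(scenario, spec.families)
    n = spec.n_iterations
    cols: dict[str, np.ndarray] = {}
    for name in sorted(spec.families):
        family = spec.families[name]
        mean = centrals[name]
        sd = spec.sd_fraction * mean
        rng = _param_rng(seed, name)
        if mean == 0.0 or sd == 0.0:
            cols[name] = np.full(n, mean)
            continue
        if family == GAMMA:
            shape, scale = fit_gamma_moments(mean, sd)
            cols[name] = rng.gamma(shape, scale, size=n)
        elif family == BETA:
            alpha, beta = fit_beta_moments(mean, sd)
            cols[name] = rng.beta(alpha, beta, size=n)
        else:
            raise ValueError(f"unknown distribution family {family!r} for {name}")
    return pd.DataFrame(cols)


def run_psa(
    scenario: Scenario,
    lt: LifeTable,
    spec: PsaSpec | None = None,
    seed: int = 0,
) -> PsaDraws:
    """Monte Carlo propagation of joint parameter uncertainty.

    Each iteration draws one value per parameter, re-runs the Markov
    model and cost ledger, and records total cost, total QALYs, the ICER
    and the net monetary benefit at every willingness-to-pay value in
    the grid.  Reproducible given the seed.
    """
    spec = spec or (scenario.psa if isinstance(scenario.psa, PsaSpec) else PsaSpec())
    samples = sample_parameters(scenario, spec, seed)
    if spec.enforce_treated_below_untreated and {
        "p_blind_treated",
        "p_blind_untreated",
    } <= set(samples.columns):
        rng = _param_rng(seed, "__resample_ordering__")
        bad = samples["p_blind_treated"] > samples["p_blind_untreated"]
        n_bad = int(bad.sum())
        while bad.any():
            # resample the treated rate for offending rows
            mean = central_values(scenario, ["p_blind_treated"])["p_blind_treated"]
            alpha, beta = fit_beta_moments(mean, spec.sd_fraction * mean)
            samples.loc[bad, "p_blind_treated"] = rng.beta(alpha, beta, size=int(bad.sum()))
            bad = samples["p_blind_treated"] > samples["p_blind_untreated"]
        logger.info("resampled treated rate in %d iterations to enforce ordering", n_bad)

    records = []
    for i in range(len(samples)):
        overrides = samples.iloc[i].to_dict()
        res = evaluate_scenario(scenario, lt, overrides)
        rec = dict(overrides)
        rec["total_cost"] = res.total_cost
        rec["total_qalys"] = res.total_qalys
        rec["icer"] = res.icer
        for wtp in spec.wtp_grid:
            rec[f"nmb_{int(wtp)}"] = net_monetary_benefit(wtp, res.total_cost, res.total_qalys)
        records.append(rec)
    return PsaDraws(frame=pd.DataFrame(records), seed=seed, wtp_grid=spec.wtp_grid)


def ceac(draws: PsaDraws, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay value, the probability that the programme
    is cost-effective is the fraction of iterations with positive net
    monetary benefit.  The curve is monotone non-decreasing in wtp
    whenever all drawn QALY totals are non-negative; a (rare) negative
    total-QALY draw counts against the programme at every wtp.
    """
    if draws.n_iterations == 0:
        raise ValueError("no draws")
    grid = tuple(wtp_grid) if wtp_grid is not None else draws.wtp_grid
    cost = draws.frame["total_cost"].to_numpy()
    qalys = draws.frame["total_qalys"].to_numpy()
    probs = [float(np.mean(w * qalys - cost > 0.0)) for w in grid]
    return pd.DataFrame({"wtp": grid, "probability": probs})


def probability_cost_effective(draws: PsaDraws, wtp: float = 144_000.0) -> float:
    """P(NMB > 0) at a single willingness-to-pay value."""
    cost = draws.frame["total_cost"].to_numpy()
    qalys = draws.frame["total_qalys"].to_numpy()
    return float(np.mean(wtp * qalys - cost > 0.0))
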