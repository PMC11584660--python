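"""Life tables: loading, validation, expansion and mortality uplifts.

A life table here is the minimal actuarial object the cohort model needs:
age-specific annual probabilities of death ``qx`` for the general
population, on a contiguous single-year age grid, closed by a terminal age
at which ``qx = 1``.  Abridged (age-band) tables are expanded by holding
the band value constant within the band.

Excess mortality in a disease state is expressed as a relative-risk
multiplier on ``qx`` (capped at 1), the convention used when an "uplift on
the mortality rate" is quoted for people with diabetes or blindness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LifeTable",
    "MortalityUplift",
    "load_life_table",
    "write_life_table",
    "apply_uplift",
]


class LifeTableError(ValueError):
    """Raised when a life table violates its invariants."""


@dataclass(frozen=True)
class LifeTable:
    """Single-year life table: contiguous integer ages and annual death
    probabilities, with ``qx = 1`` at the terminal age."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or qx.ndim != 1 or len(ages) != len(qx):
            raise LifeTableError("ages and qx must be 1-d arrays of equal length")
        if len(ages) == 0:
            raise LifeTableError("life table is empty")
        steps = np.diff(ages)
        if np.any(steps <= 0):
            bad = int(np.argmax(steps <= 0))
            raise LifeTableError(
                f"ages must be strictly increasing; violation at row {bad} "
                f"(age {ages[bad]} followed by {ages[bad + 1]})"
            )
        if np.any(steps != 1):
            bad = int(np.argmax(steps != 1))
            raise LifeTableError(
                f"ages must be contiguous after expansion; gap after row {bad} "
                f"(age {ages[bad]})"
            )
        bad_q = np.where((qx < 0) | (qx > 1) | ~np.isfinite(qx))[0]
        if bad_q.size:
            i = int(bad_q[0])
            raise LifeTableError(
                f"qx outside [0, 1] at row {i} (age {ages[i]}, qx={qx[i]})"
            )
        if qx[-1] != 1.0:
            raise LifeTableError(
                f"terminal age {ages[-1]} must have qx = 1 (got {qx[-1]}); "
                "use ensure_terminal() or supply a closing band"
            )

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        """Terminal age, at which death within the year is certain."""
        return int(self.ages[-1])

    def q(self, age: int) -> float:
        """Annual probability of death at exact integer ``age``."""
        if not self.min_age <= age <= self.max_age:
            raise LifeTableError(
                f"age {age} outside life-table range "
                f"[{self.min_age}, {self.max_age}]"
            )
        return float(self.qx[int(age) - self.min_age])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


@dataclass(frozen=True)
class MortalityUplift:
    """Relative risk applied multiplicatively to annual death probabilities.

    The resulting probability is ``min(relative_risk * qx, cap)`` with the
    cap fixed at 1.  Multiplication on the probability scale (rather than
    on the hazard ``-log(1 - q)``) is the default reading of a published
    "uplift on the mortality rate"; the hazard-scale variant is available
    through ``scale="hazard"``.
    """

    relative_risk: float
    scale: str = "probability"  # or "hazard"

    def __post_init__(self) -> None:
        if self.relative_risk < 0:
            raise LifeTableError(
                f"relative risk must be non-negative (got {self.relative_risk})"
            )
        if self.scale not in ("probability", "hazard"):
            raise LifeTableError(f"unknown uplift scale {self.scale!r}")

    def apply(self, qx: np.ndarray) -> np.ndarray:
        qx = np.asarray(qx, dtype=float)
        if self.scale == "probability":
            return np.minimum(self.relative_risk * qx, 1.0)
        # hazard scale: q' = 1 - (1 - q)^rr
        with np.errstate(divide="ignore"):
            return 1.0 - np.power(1.0 - qx, self.relative_risk)

    def apply_scalar(self, q: float) -> float:
        if self.scale == "probability":
            return min(self.relative_risk * q, 1.0)
        return 1.0 - (1.0 - q) ** self.relative_risk


def _ensure_terminal(ages: np.ndarray, qx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Close an open table by appending a terminal age with qx = 1."""
    if qx[-1] == 1.0:
        return ages, qx
    logger.warning(
        "life table ends at age %d with qx=%g < 1; appending terminal age %d "
        "with qx=1",
        ages[-1],
        qx[-1],
        ages[-1] + 1,
    )
    return np.append(ages, ages[-1] + 1), np.append(qx, 1.0)


def load_life_table(path, dialect: str = "single-year") -> LifeTable:
    """Read a life table from CSV.

    ``dialect="single-year"`` expects columns ``age,qx``;
    ``dialect="abridged"`` expects ``age_start,age_end,qx`` and expands
    each band by repeating its qx at every age in the band.  A table whose
    last row has qx < 1 is closed with an appended terminal age (warning
    logged).
    """
    df = pd.read_csv(path)
    if dialect == "single-year":
        required = {"age", "qx"}
        if not required.issubset(df.columns):
            raise LifeTableError(f"single-year table needs columns {sorted(required)}")
        _check_numeric(df, ["age", "qx"])
        ages = df["age"].to_numpy(dtype=int)
        qx = df["qx"].to_numpy(dtype=float)
    elif dialect == "abridged":
        required = {"age_start", "age_end", "qx"}
        if not required.issubset(df.columns):
            raise LifeTableError(f"abridged table needs columns {sorted(required)}")
        _check_numeric(df, ["age_start", "age_end", "qx"])
        ages_list: list[int] = []
        qx_list: list[float] = []
        for i, row in df.iterrows():
            lo, hi = int(row["age_start"]), int(row["age_end"])
            if hi < lo:
                raise LifeTableError(f"row {i}: band end {hi} before start {lo}")
            ages_list.extend(range(lo, hi + 1))
            qx_list.extend([float(row["qx"])] * (hi - lo + 1))
        ages = np.asarray(ages_list, dtype=int)
        qx = np.asarray(qx_list, dtype=float)
    else:
        raise LifeTableError(f"unknown dialect {dialect!r}")

    for i, q in enumerate(qx):
        if not (0.0 <= q <= 1.0) or not math.isfinite(q):
            raise LifeTableError(f"row for age {ages[i]}: qx={q} outside [0, 1]")
    ages, qx = _ensure_terminal(ages, qx)
    return LifeTable(ages=ages, qx=qx)


def _check_numeric(df: pd.DataFrame, cols: list[str]) -> None:
    for c in cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise LifeTableError(f"column {c!r} must be numeric")
        if df[c].isna().any():
            i = int(df[c].isna().idxmax())
            raise LifeTableError(f"row {i}: missing value in column {c!r}")


def write_life_table(lt: LifeTable, path) -> None:
    """Write a single-year table as CSV (``age,qx``)."""
    lt.to_frame().to_csv(path, index=False)


def apply_uplift(lt: LifeTable, uplift: MortalityUplift) -> LifeTable:
    """Return a new table with the uplift applied to every qx.

    The terminal age keeps qx = 1 regardless of the relative risk, so the
    uplifted table is still a closed life table.
    """
    qx = uplift.apply(lt.qx)
    qx[-1] = 1.0
    return LifeTable(ages=lt.ages.copy(), qx=qx)
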