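"""Synthetic life table: all-cause and breast-cancer-specific mortality.

The survival model needs annual all-cause mortality (national vital
statistics) and annual breast-cancer-specific mortality by stage (cancer
registry).  Neither table is distributed with the package, so a synthetic
stand-in is generated: all-cause mortality follows a Gompertz hazard
calibrated to a target life expectancy at birth (default 80 years, the
population the model describes), and breast-cancer-specific mortality is a
stage-specific annual excess probability that decays exponentially after
the fifth year post diagnosis.  The table is an ordinary CSV
(``age, q_allcause, q_bc_stage2, q_bc_stage3, q_bc_stage4``) so real
registry data can be dropped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("stage2", "stage3", "stage4")
DEFAULT_STAGE_WEIGHTS = {"stage2": 0.50, "stage3": 0.35, "stage4": 0.15}
DEFAULT_STAGE_MORTALITY = {"stage2": 0.010, "stage3": 0.022, "stage4": 0.060}


class LifeTableError(ValueError):
    pass


@dataclass
class LifeTable:
    """Annual mortality probabilities indexed by integer age.

    ``table`` columns: age, q_allcause, q_bc_stage2, q_bc_stage3,
    q_bc_stage4.  ``stage_weights`` blends the stage-specific
    breast-cancer columns into a single cohort-level probability.
    """

    table: pd.DataFrame
    stage_weights: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_WEIGHTS))

    def __post_init__(self) -> None:
        required = ["age", "q_allcause"] + [f"q_bc_{s}" for s in STAGES]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise LifeTableError(f"life table missing columns: {missing}")
        qcols = [c for c in required if c != "age"]
        vals = self.table[qcols].to_numpy()
        if np.any(vals < 0) or np.any(vals > 1):
            raise LifeTableError("mortality probabilities must lie in [0, 1]")
        w = sum(self.stage_weights.get(s, 0.0) for s in STAGES)
        if abs(w - 1.0) > 1e-9:
            raise LifeTableError(f"stage weights must sum to 1, got {w}")
        self._by_age = self.table.set_index("age")

    def _lookup(self, age: float, column: str) -> float:
        a = int(np.floor(age))
        try:
            return float(self._by_age.loc[a, column])
        except KeyError:
            raise LifeTableError(f"life table does not cover age {a}") from None

    def q_allcause(self, age: float) -> float:
        """Annual all-cause mortality probability at (integer) age."""
        return self._lookup(age, "q_allcause")

    def q_bc(self, age: float) -> float:
        """Stage-weighted annual breast-cancer-specific mortality at age."""
        return sum(self.stage_weights[s] * self._lookup(age, f"q_bc_{s}")
                   for s in STAGES)

    def covers(self, age_lo: float, age_hi: float) -> bool:
        ages = set(self._by_age.index)
        return all(a in ages for a in range(int(np.floor(age_lo)),
                                            int(np.floor(age_hi)) + 1))

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, stage_weights: dict | None = None) -> "LifeTable":
        kw = {} if stage_weights is None else {"stage_weights": stage_weights}
        return cls(pd.read_csv(path), **kw)


def gompertz_q(ages: np.ndarray, a0: float, slope: float) -> np.ndarray:
    """Annual death probability under a Gompertz hazard h(a) = a0*exp(slope*a)."""
    # integrate the hazard over the year [a, a+1)
    h_int = a0 / slope * (np.exp(slope * (ages + 1)) - np.exp(slope * ages))
    return 1.0 - np.exp(-h_int)


def _life_expectancy(a0: float, slope: float, max_age: int) -> float:
    ages = np.arange(max_age + 1)
    q = gompertz_q(ages, a0, slope)
    survival = np.cumprod(1.0 - q)
    # person-years: survivors each year plus half-year for the dying
    l = np.concatenate([[1.0], survival])
    return float(np.sum(0.5 * (l[:-1] + l[1:])))


def calibrate_gompertz(slope: float = 0.09, e0_target: float = 80.0,
                       max_age: int = 110, tol: float = 1e-4) -> float:
    """Solve for the Gompertz level a0 matching a life expectancy at birth."""
    lo, hi = 1e-8, 1e-2   # e0 decreasing in a0
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        e0 = _life_expectancy(mid, slope, max_age)
        if abs(e0 - e0_target) < tol:
            return mid
        if e0 > e0_target:
            lo = mid
        else:
            hi = mid
    return mid


def make_life_table(start_age: float = 45.0,
                    slope: float = 0.09,
                    e0_target: float = 80.0,
                    max_age: int = 110,
                    stage_mortality: dict | None = None,
                    stage_weights: dict | None = None,
                    decay_after_years: int = 5,
                    decay_rate: float = 0.15) -> LifeTable:
    """Generate the synthetic life table used by the survival model.

    Breast-cancer-specific columns are written relative to a diagnosis at
    ``start_age``: the stage-specific annual probability applies for
    ``decay_after_years`` years and then decays as
    ``exp(-decay_rate * years_beyond)``.
    """
    stage_mortality = dict(DEFAULT_STAGE_MORTALITY if stage_mortality is None
                           else stage_mortality)
    a0 = calibrate_gompertz(slope, e0_target, max_age)
    ages = np.arange(max_age + 1)
    q_all = np.clip(gompertz_q(ages.astype(float), a0, slope), 0.0, 1.0)
    years_since = np.maximum(ages - start_age, 0.0)
    beyond = np.maximum(years_since - decay_after_years, 0.0)
    decay = np.exp(-decay_rate * beyond)
    data = {"age": ages, "q_allcause": q_all}
    for s in STAGES:
        data[f"q_bc_{s}"] = np.clip(stage_mortality[s] * decay, 0.0, 1.0)
    kw = {} if stage_weights is None else {"stage_weights": stage_weights}
    return LifeTable(pd.DataFrame(data), **kw)


def life_table_from_config(cfg: dict, start_age: float) -> LifeTable:
    """Build the life table from the ``life_table`` configuration section."""
    return make_life_table(
        start_age=start_age,
        slope=cfg["gompertz_slope"],
        e0_target=cfg["life_expectancy_at_birth"],
        max_age=cfg["max_age"],
        stage_mortality={s: cfg[f"bc_mortality_{s}"] for s in STAGES},
        stage_weights={s: cfg[f"stage_weight_{s}"] for s in STAGES},
        decay_after_years=cfg["bc_decay_after_years"],
        decay_rate=cfg["bc_decay_rate"],
    )
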