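"""Deterministic and probabilistic sensitivity analysis.

One-way deterministic analysis (DSA) reruns the full two-model pipeline
with each parameter at its low/high bound (±15% by default; 3%/7% for the
discount rate) and reports tornado entries sorted by swing.  Probabilistic
analysis (PSA) draws every uncertain parameter from a beta (probabilities,
utilities) or gamma (costs) distribution — explicitly parameterized where
(α, β) are known, moment-matched at SE = 15% of the mean otherwise — and
records the incremental cost/QALY cloud feeding the cost-effectiveness
plane and the acceptability curve (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .analyze import run_base_case
from .lifetable import LifeTable
from .params import ParameterError, ParameterSet

# ----------------------------------------------------------------------
# distributions
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """A PSA sampling distribution for one parameter.

    Either explicit (``alpha``/``beta`` for a beta distribution,
    ``shape``/``scale`` for a gamma) or moment-based (``mean``/``se``
    solved by the method of moments).  ``kind="fixed"`` pins the parameter
    at ``value``.
    """

    kind: str                       # "beta" | "gamma" | "fixed"
    alpha: float | None = None
    beta: float | None = None
    shape: float | None = None
    scale: float | None = None
    mean: float | None = None
    se: float | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "gamma", "fixed"):
            raise ParameterError(f"unknown distribution kind {self.kind!r}")


class Sampler:
    """A frozen, seed-independent sampler for one parameter."""

    def __init__(self, dist, fixed_value: float | None = None):
        self._dist = dist
        self._fixed = fixed_value

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self._fixed is not None:
            return np.full(size, self._fixed)
        return self._dist.rvs(size=size, random_state=rng)

    def mean(self) -> float:
        if self._fixed is not None:
            return self._fixed
        return float(self._dist.mean())


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (α, β) for a beta with the given mean and SE."""
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta moment-matching needs mean in (0,1), got {mean}")
    var = se ** 2
    if var >= mean * (1 - mean):
        raise ParameterError(
            f"variance {var} too large for a beta with mean {mean}")
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale) for a gamma distribution."""
    if mean <= 0 or se <= 0:
        raise ParameterError("gamma moment-matching needs mean > 0 and se > 0")
    shape = (mean / se) ** 2
    return shape, se ** 2 / mean


def fit_distribution(spec: DistributionSpec) -> Sampler:
    """Build a sampler from a distribution spec."""
    if spec.kind == "fixed":
        if spec.value is None:
            raise ParameterError("fixed spec requires a value")
        return Sampler(None, fixed_value=spec.value)
    if spec.kind == "beta":
        if spec.alpha is not None and spec.beta is not None:
            if spec.alpha <= 0 or spec.beta <= 0:
                raise ParameterError("beta parameters must be > 0")
            return Sampler(stats.beta(spec.alpha, spec.beta))
        a, b = beta_from_moments(spec.mean, spec.se)
        return Sampler(stats.beta(a, b))
    # gamma
    if spec.shape is not None and spec.scale is not None:
        if spec.shape <= 0 or spec.scale <= 0:
            raise ParameterError("gamma parameters must be > 0")
        return Sampler(stats.gamma(spec.shape, scale=spec.scale))
    shape, scale = gamma_from_moments(spec.mean, spec.se)
    return Sampler(stats.gamma(shape, scale=scale))


#: parameters sampled from a beta in the PSA (probabilities and utilities)
PSA_BETA_PARAMS = (
    "p_fn_peg", "p_fn_rhg",
    "p_infection_given_fn_peg", "p_infection_given_fn_rhg",
    "p_death_fn", "p_death_infection",
    "utility_chemotherapy", "utility_fn", "utility_infection",
    "p_rdi_low_if_fn", "p_rdi_low_no_fn_lt65",
    "utility_years_1_5", "utility_years_gt5",
)

#: parameters sampled from a gamma in the PSA (unit costs)
PSA_GAMMA_PARAMS = (
    "cost_gcsf_peg_per_cycle", "cost_gcsf_rhg_per_cycle",
    "cost_docetaxel_per_vial", "cost_cyclophosphamide_per_vial",
    "cost_fn_inpatient", "cost_infection_given_fn",
    "cost_hospitalization_per_cycle",
)


def default_psa_specs(params: ParameterSet,
                      explicit: Mapping[str, Mapping] | None = None,
                      se_fraction: float = 0.15) -> dict[str, DistributionSpec]:
    """Distribution specs for every sampled parameter.

    ``explicit`` entries (e.g. ``{"p_rdi_low_if_fn": {"kind": "beta",
    "alpha": 191, "beta": 191}}``) override the moment-matched defaults;
    the ratio parameters (RR/OR/HR), for which no distribution is
    tabulated, stay fixed.
    """
    specs: dict[str, DistributionSpec] = {}
    for name in PSA_BETA_PARAMS:
        specs[name] = DistributionSpec(kind="beta", mean=getattr(params, name),
                                       se=se_fraction * getattr(params, name))
    for name in PSA_GAMMA_PARAMS:
        specs[name] = DistributionSpec(kind="gamma", mean=getattr(params, name),
                                       se=se_fraction * getattr(params, name))
    if explicit:
        for name, kw in explicit.items():
            if name not in specs:
                raise ParameterError(f"explicit PSA spec for unknown parameter "
                                     f"{name!r}")
            specs[name] = DistributionSpec(**kw)
    return specs


def fixed_psa_specs(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Degenerate specs pinning every sampled parameter at its base value."""
    names = PSA_BETA_PARAMS + PSA_GAMMA_PARAMS
    return {name: DistributionSpec(kind="fixed", value=getattr(params, name))
            for name in names}


# ----------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ----------------------------------------------------------------------

DSA_OUTCOMES = ("incremental_cost", "incremental_qaly_chemo",
                "incremental_qaly_postchemo", "incremental_qaly_total")


@dataclass(frozen=True)
class DSARange:
    """Low/high bound for one parameter in the one-way analysis."""

    parameter: str
    low: float
    high: float
    source: str = "pct15"     # "pct15" | "ci95" | "discount_3_7"

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ParameterError(
                f"DSA range for {self.parameter}: low {self.low} > high {self.high}")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def default_dsa_ranges(params: ParameterSet,
                       fraction: float = 0.15) -> list[DSARange]:
    """±15% on every substantive model input; 3-7% on the discount rate.

    Probabilities and utilities are capped at 1 after scaling.
    """
    varied = PSA_BETA_PARAMS + PSA_GAMMA_PARAMS + (
        "rr_rdi_low_age_ge65", "or_rdi_low_fn", "hr_mortality_rdi_low")
    bounded = set(PSA_BETA_PARAMS)
    ranges = []
    for name in varied:
        base = getattr(params, name)
        low, high = base * (1 - fraction), base * (1 + fraction)
        if name in bounded:
            high = min(high, 1.0)
        ranges.append(DSARange(name, low, high))
    ranges.append(DSARange("postchemo_discount_rate", 0.03, 0.07,
                           source="discount_3_7"))
    return ranges


def _outcome_value(result, outcome: str) -> float:
    return {
        "incremental_cost": result.delta_cost,
        "incremental_qaly_chemo": result.delta_qalys_chemo,
        "incremental_qaly_postchemo": result.delta_qalys_postchemo,
        "incremental_qaly_total": result.delta_qalys_total,
    }[outcome]


def one_way_dsa(params: ParameterSet, life_table: LifeTable,
                ranges: Iterable[DSARange], outcome: str) -> list[TornadoEntry]:
    """Rerun the full pipeline at each parameter's bounds, others at base.

    Entries come back sorted by descending swing (ties broken
    alphabetically by parameter name).
    """
    if outcome not in DSA_OUTCOMES:
        raise ParameterError(f"unknown DSA outcome {outcome!r}; "
                             f"expected one of {DSA_OUTCOMES}")
    valid = set(ParameterSet.__dataclass_fields__)
    entries = []
    for r in ranges:
        if r.parameter not in valid:
            raise ParameterError(
                f"unknown parameter {r.parameter!r}; valid names: "
                f"{sorted(valid)}")
        out = {}
        for label, value in (("low", r.low), ("high", r.high)):
            res = run_base_case(params.replace(**{r.parameter: value}), life_table)
            out[label] = _outcome_value(res, outcome)
        entries.append(TornadoEntry(r.parameter, r.low, r.high,
                                    out["low"], out["high"]))
    return sorted(entries, key=lambda e: (-e.swing, e.parameter))


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter, "low": e.low, "high": e.high,
        "outcome_low": e.outcome_low, "outcome_high": e.outcome_high,
        "swing": e.swing} for e in entries])


# ----------------------------------------------------------------------
# probabilistic sensitivity analysis
# ----------------------------------------------------------------------


@dataclass
class PSACloud:
    """Paired (Δcost, ΔQALY) Monte-Carlo draws with the sampled inputs."""

    delta_cost: np.ndarray
    delta_qalys: np.ndarray            # chemo + post-chemo QALYs
    delta_qalys_chemo: np.ndarray
    delta_qalys_postchemo: np.ndarray
    parameter_draws: pd.DataFrame
    seed: int
    failures: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.delta_cost)


def run_psa(params: ParameterSet, life_table: LifeTable,
            specs: Mapping[str, DistributionSpec],
            n_draws: int = 1000, seed: int = 0) -> PSACloud:
    """Monte-Carlo PSA: sample all parameters per draw, rerun both models.

    Shared parameters (event costs, case fatality, utilities) are sampled
    once per draw and applied to both arms.  Draws on which the model
    raises are logged in ``cloud.failures`` and skipped.
    """
    if n_draws < 1:
        raise ParameterError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    names = sorted(specs)
    draws = {name: fit_distribution(specs[name]).rvs(n_draws, rng)
             for name in names}
    dc = np.empty(n_draws)
    dq = np.empty(n_draws)
    dq_chemo = np.empty(n_draws)
    dq_post = np.empty(n_draws)
    ok = np.ones(n_draws, dtype=bool)
    failures = []
    for i in range(n_draws):
        values = {name: float(draws[name][i]) for name in names}
        try:
            res = run_base_case(params.replace(**values), life_table)
        except Exception as exc:   # a bad draw aborts only that draw
            ok[i] = False
            failures.append((i, repr(exc)))
            continue
        dc[i] = res.delta_cost
        dq_chemo[i] = res.delta_qalys_chemo
        dq_post[i] = res.delta_qalys_postchemo
        dq[i] = res.delta_qalys_total
    frame = pd.DataFrame(draws).loc[ok].reset_index(drop=True)
    return PSACloud(delta_cost=dc[ok], delta_qalys=dq[ok],
                    delta_qalys_chemo=dq_chemo[ok],
                    delta_qalys_postchemo=dq_post[ok],
                    parameter_draws=frame,
                    seed=seed, failures=failures)


def ceac(cloud: PSACloud, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Probability cost-effective per willingness-to-pay value.

    ``P(λ) = fraction of draws with λ·ΔQALY − Δcost > 0``.
    """
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ParameterError("WTP grid must be nonempty")
    if np.any(wtp_grid < 0):
        raise ParameterError("WTP values must be >= 0")
    if cloud.n == 0:
        raise ParameterError("PSA cloud is empty")
    nmb = wtp_grid[:, None] * cloud.delta_qalys[None, :] - cloud.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp_grid, "probability_cost_effective": prob})


def probability_cost_effective(cloud: PSACloud, wtp: float) -> float:
    return float(ceac(cloud, [wtp])["probability_cost_effective"].iloc[0])


def ce_plane(cloud: PSACloud) -> pd.DataFrame:
    """Tidy CE-plane table: one row per draw with its quadrant label.

    Quadrants: NE (costlier, more effective), NW (costlier, less
    effective), SE (cheaper, more effective — dominant), SW (cheaper, less
    effective).  Boundary draws fall to the more-effective side.
    """
    if cloud.n == 0:
        raise ParameterError("PSA cloud is empty")
    dc, dq = cloud.delta_cost, cloud.delta_qalys
    quadrant = np.where(dc > 0, np.where(dq >= 0, "NE", "NW"),
                        np.where(dq >= 0, "SE", "SW"))
    return pd.DataFrame({"draw": np.arange(cloud.n), "delta_cost": dc,
                         "delta_qalys": dq, "quadrant": quadrant})
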