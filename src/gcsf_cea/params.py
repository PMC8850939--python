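"""Model parameters and configuration loading.

The whole analysis is driven by a single flat :class:`ParameterSet` holding
every base-case input of the two Markov models (transition probabilities,
unit costs in 2019 CNY, utilities, discounting, horizon) plus the analysis
switches.  Sensitivity analyses vary parameters by attribute name, so the
set deliberately stays flat rather than nested per model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from importlib import resources
from typing import Any, Mapping

import yaml


class ParameterError(ValueError):
    """Raised when a parameter value or configuration file is invalid."""


ARMS = ("PEG", "RHG")

#: Fields that must lie in [0, 1].
_PROBABILITY_FIELDS = (
    "p_fn_peg",
    "p_fn_rhg",
    "p_infection_given_fn_peg",
    "p_infection_given_fn_rhg",
    "p_death_fn",
    "p_death_infection",
    "p_rdi_low_if_fn",
    "p_rdi_low_no_fn_lt65",
    "utility_chemotherapy",
    "utility_fn",
    "utility_infection",
    "utility_years_1_5",
    "utility_years_gt5",
)

#: Fields that must be non-negative.
_NONNEGATIVE_FIELDS = (
    "cost_gcsf_peg_per_cycle",
    "cost_gcsf_rhg_per_cycle",
    "cost_docetaxel_per_vial",
    "cost_cyclophosphamide_per_vial",
    "cost_fn_inpatient",
    "cost_infection_given_fn",
    "cost_hospitalization_per_cycle",
    "chemo_discount_rate",
    "postchemo_discount_rate",
    "horizon_years",
    "wtp_per_qaly",
)

#: Fields that must be strictly positive.
_POSITIVE_FIELDS = (
    "docetaxel_vial_mg",
    "cyclophosphamide_vial_mg",
    "docetaxel_dose_mg_per_m2",
    "cyclophosphamide_dose_mg_per_m2",
    "body_surface_area_m2",
    "rr_rdi_low_age_ge65",
    "or_rdi_low_fn",
    "hr_mortality_rdi_low",
    "n_chemo_cycles",
    "chemo_cycle_weeks",
)

WEEKS_PER_YEAR = 52.18


@dataclass(frozen=True)
class ParameterSet:
    """Base-case inputs for both Markov models.

    Defaults are the published base-case values: per-cycle febrile
    neutropenia (FN) risk 0.0116 (long-acting, PEG) vs 0.0404
    (short-acting, RHG); infection risk given FN 0.0547 vs 0.547; case
    fatality 0.034 for FN and for infection; G-CSF acquisition cost
    3315.74 vs 734.34 CNY per cycle; FN admission 25 000 CNY and infection
    treatment 50 000 CNY per event; utilities 0.70 on chemotherapy and
    0.33 during FN/infection.  The survival model links FN history to the
    probability of a relative dose intensity (RDI) below 85% (0.500 with
    FN vs 0.247 without, below age 65), which carries a mortality hazard
    ratio of 1.73, with survivor utilities 0.86 (years 1-5) and 0.96
    (beyond year 5) discounted at 5%/year over a 35-year horizon.
    """

    # ------------------------------------------------------------------
    # chemotherapy model (12 weeks, four 3-week cycles, no discounting)
    p_fn_peg: float = 0.0116
    p_fn_rhg: float = 0.0404
    p_infection_given_fn_peg: float = 0.0547
    p_infection_given_fn_rhg: float = 0.547
    p_death_fn: float = 0.034
    p_death_infection: float = 0.034
    cost_gcsf_peg_per_cycle: float = 3315.74
    cost_gcsf_rhg_per_cycle: float = 734.34
    cost_docetaxel_per_vial: float = 1792.74   # 20 mg / 0.5 ml vial
    docetaxel_vial_mg: float = 20.0
    docetaxel_dose_mg_per_m2: float = 75.0
    cost_cyclophosphamide_per_vial: float = 120.75  # 0.2 g vial
    cyclophosphamide_vial_mg: float = 200.0
    cyclophosphamide_dose_mg_per_m2: float = 600.0
    cost_fn_inpatient: float = 25000.0
    cost_infection_given_fn: float = 50000.0
    cost_hospitalization_per_cycle: float = 14811.10
    utility_chemotherapy: float = 0.70
    utility_fn: float = 0.33
    utility_infection: float = 0.33
    n_chemo_cycles: int = 4
    chemo_cycle_weeks: float = 3.0
    body_surface_area_m2: float = 1.6
    chemo_discount_rate: float = 0.0

    # ------------------------------------------------------------------
    # post-chemotherapy survival model (annual cycles, 35 years, 5%/yr)
    p_rdi_low_if_fn: float = 0.500
    p_rdi_low_no_fn_lt65: float = 0.247
    rr_rdi_low_age_ge65: float = 1.380
    or_rdi_low_fn: float = 1.580
    hr_mortality_rdi_low: float = 1.730
    utility_years_1_5: float = 0.86
    utility_years_gt5: float = 0.96
    postchemo_discount_rate: float = 0.05
    horizon_years: int = 35
    start_age: float = 45.0

    # ------------------------------------------------------------------
    # structural switches
    equalize_infection_risk: bool = False   # set PEG infection risk to the RHG value
    rdi_or_mode: bool = False               # odds-ratio link instead of measured 0.500
    course_level_fn: bool = False           # read FN risk as per-course, convert to per-cycle
    half_cycle_correction: bool = False

    # ------------------------------------------------------------------
    # analysis
    wtp_per_qaly: float = 72371.0           # 2020 Chinese GDP per capita

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in _NONNEGATIVE_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if v <= 0:
                raise ParameterError(f"{name} must be > 0, got {v}")
        if self.start_age < 18:
            raise ParameterError(f"start_age must be >= 18, got {self.start_age}")

    def replace(self, **changes: Any) -> "ParameterSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    # -- per-arm accessors ---------------------------------------------
    def p_fn(self, arm: str) -> float:
        p = {"PEG": self.p_fn_peg, "RHG": self.p_fn_rhg}[_norm_arm(arm)]
        if self.course_level_fn:
            # reinterpret the tabulated value as a per-course risk and
            # spread it over the four cycles on the hazard scale
            p = 1.0 - (1.0 - p) ** (1.0 / self.n_chemo_cycles)
        return p

    def p_infection_given_fn(self, arm: str) -> float:
        if self.equalize_infection_risk:
            return self.p_infection_given_fn_rhg
        return {
            "PEG": self.p_infection_given_fn_peg,
            "RHG": self.p_infection_given_fn_rhg,
        }[_norm_arm(arm)]

    def cost_gcsf_per_cycle(self, arm: str) -> float:
        return {
            "PEG": self.cost_gcsf_peg_per_cycle,
            "RHG": self.cost_gcsf_rhg_per_cycle,
        }[_norm_arm(arm)]

    @property
    def chemo_cycle_years(self) -> float:
        return self.chemo_cycle_weeks / WEEKS_PER_YEAR


def _norm_arm(arm: str) -> str:
    a = arm.upper()
    if a not in ARMS:
        raise ParameterError(f"unknown arm {arm!r}; expected one of {ARMS}")
    return a


# ----------------------------------------------------------------------
# configuration file handling
# ----------------------------------------------------------------------

#: maps YAML section name -> tuple of ParameterSet field names
_SECTIONS: dict[str, tuple[str, ...]] = {
    "chemotherapy_model": (
        "p_fn_peg", "p_fn_rhg",
        "p_infection_given_fn_peg", "p_infection_given_fn_rhg",
        "p_death_fn", "p_death_infection",
        "cost_gcsf_peg_per_cycle", "cost_gcsf_rhg_per_cycle",
        "cost_docetaxel_per_vial", "docetaxel_vial_mg", "docetaxel_dose_mg_per_m2",
        "cost_cyclophosphamide_per_vial", "cyclophosphamide_vial_mg",
        "cyclophosphamide_dose_mg_per_m2",
        "cost_fn_inpatient", "cost_infection_given_fn",
        "cost_hospitalization_per_cycle",
        "utility_chemotherapy", "utility_fn", "utility_infection",
        "n_chemo_cycles", "chemo_cycle_weeks", "body_surface_area_m2",
        "chemo_discount_rate",
    ),
    "post_chemotherapy_model": (
        "p_rdi_low_if_fn", "p_rdi_low_no_fn_lt65", "rr_rdi_low_age_ge65",
        "or_rdi_low_fn", "hr_mortality_rdi_low",
        "utility_years_1_5", "utility_years_gt5",
        "postchemo_discount_rate", "horizon_years", "start_age",
    ),
    "switches": (
        "equalize_infection_risk", "rdi_or_mode", "course_level_fn",
        "half_cycle_correction",
    ),
    "analysis": ("wtp_per_qaly",),
}


def parameters_to_mapping(params: ParameterSet) -> dict[str, dict[str, Any]]:
    """Serialize a ParameterSet to the sectioned configuration layout."""
    return {
        section: {name: getattr(params, name) for name in names}
        for section, names in _SECTIONS.items()
    }


def parameters_from_mapping(mapping: Mapping[str, Any]) -> ParameterSet:
    """Build a ParameterSet from a sectioned mapping, strictly.

    Every section and every key must be present; unknown sections or keys
    are rejected so that silent typos cannot change the base case.
    """
    known_sections = set(_SECTIONS)
    extra_sections = set(mapping) - known_sections - {"cohort", "life_table", "psa"}
    if extra_sections:
        raise ParameterError(f"unknown configuration sections: {sorted(extra_sections)}")
    values: dict[str, Any] = {}
    for section, names in _SECTIONS.items():
        if section not in mapping:
            raise ParameterError(f"missing configuration section {section!r}")
        sub = mapping[section]
        if not isinstance(sub, Mapping):
            raise ParameterError(f"section {section!r} must be a mapping")
        unknown = set(sub) - set(names)
        if unknown:
            raise ParameterError(
                f"unknown keys in section {section!r}: {sorted(unknown)}"
            )
        for name in names:
            if name not in sub:
                raise ParameterError(f"missing required parameter {name!r} "
                                     f"in section {section!r}")
            values[name] = sub[name]
    return ParameterSet(**values)


def default_config_text() -> str:
    """The packaged default configuration file (YAML source text)."""
    return resources.files("gcsf_cea.data").joinpath("default_config.yaml").read_text()


def load_config(path: str | None = None) -> dict[str, Any]:
    """Load a YAML configuration file (the packaged default when ``path`` is None)."""
    if path is None:
        raw = default_config_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = fh.read()
    data = yaml.safe_load(raw)
    if not isinstance(data, dict):
        raise ParameterError("configuration file must contain a mapping at top level")
    return data


def load_parameters(path: str | None = None) -> ParameterSet:
    """Read a ParameterSet from a configuration file (default when None)."""
    return parameters_from_mapping(load_config(path))


def write_parameters(params: ParameterSet, path: str) -> None:
    """Write a ParameterSet back out as a loadable YAML configuration."""
    cfg = load_config(None)  # keep cohort / life-table / psa sections from default
    cfg.update(parameters_to_mapping(params))
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def parameter_names() -> list[str]:
    """All varyable parameter names (for sensitivity-analysis lookups)."""
    return [f.name for f in fields(ParameterSet)]
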