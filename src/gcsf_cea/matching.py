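"""Propensity-score estimation and 1:1 nearest-neighbour matching.

The score is the fitted probability of being in the long-acting (PEG) arm
from a logistic regression on baseline covariates (age, insurance type,
number of concomitant diseases by default; gender is accepted but dropped
automatically when constant, the cohort being all-female).  Matching is
greedy nearest-neighbour on the score without replacement, treated
patients processed in descending score order, with an optional caliper
(default 0.2 standard deviations of the logit of the score).  Balance is
reported as standardized mean differences before and after matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

DEFAULT_COVARIATES = ("age", "insurance_type", "n_concomitant_diseases")


class SeparationError(RuntimeError):
    """Perfect separation in the propensity model; review the covariates."""


@dataclass(frozen=True)
class PropensityModelSpec:
    """Covariates and link for the propensity model (logistic only)."""

    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    link: str = "logistic"

    def __post_init__(self) -> None:
        if self.link != "logistic":
            raise ValueError(f"only the logistic link is supported, got {self.link!r}")


@dataclass
class MatchedCohort:
    """1:1 matched pairs of (PEG patient id, RHG patient id)."""

    pairs: list[tuple[str, str]]
    scores: pd.Series                      # propensity score per patient_id
    caliper: float | None = None

    @property
    def n_matched_per_arm(self) -> int:
        return len(self.pairs)

    @property
    def mean_ps_peg(self) -> float:
        if not self.pairs:
            return float("nan")
        return float(np.mean([self.scores[p] for p, _ in self.pairs]))

    @property
    def mean_ps_rhg(self) -> float:
        if not self.pairs:
            return float("nan")
        return float(np.mean([self.scores[r] for _, r in self.pairs]))

    def matched_ids(self) -> set[str]:
        return {pid for pair in self.pairs for pid in pair}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"peg_id": p, "rhg_id": r,
              "ps_peg": self.scores[p], "ps_rhg": self.scores[r]}
             for p, r in self.pairs])


def _design_matrix(records: pd.DataFrame, covariates: tuple[str, ...]
                   ) -> pd.DataFrame:
    cols = []
    for cov in covariates:
        if cov not in records.columns:
            raise ValueError(f"covariate {cov!r} not present in patient records")
        col = records[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            if dummies.shape[1] == 0:
                warnings.warn(f"dropping constant covariate(s): [{cov!r}]")
                continue
            cols.append(dummies)
        else:
            cols.append(col.astype(float).to_frame(cov))
    if not cols:
        return pd.DataFrame(index=records.index)
    X = pd.concat(cols, axis=1)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant covariate(s): {constant}")
        X = X.drop(columns=constant)
    return X


def estimate_propensity(records: pd.DataFrame,
                        spec: PropensityModelSpec = PropensityModelSpec()
                        ) -> pd.Series:
    """Fitted probability of PEG membership, indexed by patient_id."""
    for arm in ("PEG", "RHG"):
        if (records["arm"] == arm).sum() < 2:
            raise ValueError(f"need at least 2 patients in arm {arm}")
    y = (records["arm"] == "PEG").astype(float).to_numpy()
    X = _design_matrix(records, spec.covariates)
    X = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # statsmodels convergence chatter
            fit = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        # a singular Hessian on a binary fit is the separation signature
        raise SeparationError(
            "perfect separation in the propensity model; "
            "review the covariate list") from exc
    scores = np.asarray(fit.predict(X.to_numpy(dtype=float)))
    if np.any(scores <= 1e-10) | np.any(scores >= 1 - 1e-10):
        raise SeparationError(
            "propensity scores degenerate at 0/1 (quasi-separation); "
            "review the covariate list")
    return pd.Series(scores, index=records["patient_id"].to_numpy(),
                     name="propensity")


def default_caliper(scores: pd.Series) -> float:
    """0.2 standard deviations of the logit of the propensity score."""
    logit = np.log(scores / (1.0 - scores))
    return float(0.2 * np.std(logit, ddof=1))


def match_1to1(records: pd.DataFrame, scores: pd.Series,
               caliper: float | str | None = "auto",
               seed: int = 0) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Distances are computed on the logit of the propensity score (the
    scale the conventional caliper is defined on).  PEG patients are
    processed in descending score order; each takes the unused RHG
    patient with the closest logit score.  Pairs whose logit distance
    exceeds the caliper are discarded (``caliper=None`` disables the
    check; ``"auto"`` uses 0.2 SD of the logit).  Ties in score are
    broken by patient_id, then by a seeded shuffle for exact duplicates.
    """
    if caliper == "auto":
        cal = default_caliper(scores)
    else:
        cal = caliper
    rng = np.random.default_rng(seed)
    logit = np.log(scores / (1.0 - scores))

    def ordered(arm: str) -> list[str]:
        ids = records.loc[records["arm"] == arm, "patient_id"].to_numpy()
        perm = rng.permutation(len(ids))   # seed breaks exact duplicates
        order = sorted(range(len(ids)),
                       key=lambda i: (-scores[ids[i]], ids[i], perm[i]))
        return [ids[i] for i in order]

    treated = ordered("PEG")
    control = ordered("RHG")
    ctrl_logit = np.array([logit[c] for c in control])
    used = np.zeros(len(control), dtype=bool)
    pairs: list[tuple[str, str]] = []
    for pid in treated:
        if used.all():
            break
        dist = np.abs(ctrl_logit - logit[pid])
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if cal is not None and dist[j] > cal:
            continue
        used[j] = True
        pairs.append((pid, control[j]))
    if not pairs:
        warnings.warn("no pairs found within the caliper; matched cohort is empty")
    return MatchedCohort(pairs=pairs, scores=scores,
                         caliper=None if cal is None else float(cal))


def _smd(x1: np.ndarray, x2: np.ndarray, binary: bool) -> float:
    """Standardized mean difference (proportion difference for binaries)."""
    m1, m2 = np.mean(x1), np.mean(x2)
    if binary:
        return float(m1 - m2)
    v1 = np.var(x1, ddof=1) if len(x1) > 1 else 0.0
    v2 = np.var(x2, ddof=1) if len(x2) > 1 else 0.0
    pooled = np.sqrt((v1 + v2) / 2.0)
    if pooled == 0.0:
        if m1 == m2:
            return 0.0
        return float("nan")   # undefined: different means, zero spread
    return float((m1 - m2) / pooled)


def balance_table(records: pd.DataFrame, matched: MatchedCohort,
                  covariates: tuple[str, ...] = DEFAULT_COVARIATES
                  ) -> pd.DataFrame:
    """Standardized mean differences per covariate, before vs after matching.

    Categorical covariates are expanded to one indicator per level;
    indicators are compared on the raw proportion-difference scale.
    """
    if matched.n_matched_per_arm == 0:
        raise ValueError("matched cohort is empty; no balance to report")
    matched_ids = matched.matched_ids()
    after = records[records["patient_id"].isin(matched_ids)]

    def columns(df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for cov in covariates:
            col = df[cov]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                for level in sorted(records[cov].dropna().unique()):
                    out[f"{cov}={level}"] = (col == level).astype(float)
            elif col.dtype == bool:
                out[cov] = col.astype(float)
            else:
                out[cov] = col.astype(float)
        return pd.DataFrame(out, index=df.index)

    rows = []
    for label, df in (("before", records), ("after", after)):
        X = columns(df)
        is_peg = (df["arm"] == "PEG").to_numpy()
        for name in X.columns:
            binary = ("=" in name) or set(np.unique(X[name])) <= {0.0, 1.0}
            rows.append({
                "covariate": name, "stage": label,
                "smd": _smd(X[name].to_numpy()[is_peg],
                            X[name].to_numpy()[~is_peg], binary),
            })
    tidy = pd.DataFrame(rows)
    return tidy.pivot(index="covariate", columns="stage", values="smd")[
        ["before", "after"]]
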