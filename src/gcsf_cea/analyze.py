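"""Full two-model evaluation of a parameter set (both arms)."""

from __future__ import annotations

from dataclasses import dataclass

from .cea import CEAResult, compare
from .chemo import ChemoOutcome, run_chemo
from .lifetable import LifeTable
from .params import ParameterSet
from .postchemo import PostChemoOutcome, run_postchemo


@dataclass(frozen=True)
class BaseCaseResult:
    """Outcomes of both Markov models for both arms, with increments.

    ``cea_chemo`` compares 12-week costs and QALYs; ``cea_total`` adds the
    post-chemotherapy QALYs to the chemotherapy QALYs (costs accrue only
    during chemotherapy).
    """

    chemo: dict[str, ChemoOutcome]
    postchemo: dict[str, PostChemoOutcome]
    cea_chemo: CEAResult
    cea_postchemo: CEAResult
    cea_total: CEAResult

    @property
    def delta_cost(self) -> float:
        return self.cea_chemo.delta_cost

    @property
    def delta_qalys_chemo(self) -> float:
        return self.cea_chemo.delta_qalys

    @property
    def delta_qalys_postchemo(self) -> float:
        return self.cea_postchemo.delta_qalys

    @property
    def delta_qalys_total(self) -> float:
        return self.cea_total.delta_qalys

    def summary_table(self):
        """Per-arm costs/QALYs with increments, one row per model and arm."""
        import pandas as pd
        rows = []
        for arm in ("PEG", "RHG"):
            rows.append({
                "model": "chemotherapy", "strategy": arm,
                "cost": self.chemo[arm].total_cost,
                "qalys": self.chemo[arm].total_qalys,
                "incremental_cost": self.delta_cost if arm == "PEG" else None,
                "incremental_qalys": (self.delta_qalys_chemo
                                      if arm == "PEG" else None),
                "icer": self.cea_chemo.icer if arm == "PEG" else None,
            })
        for arm in ("PEG", "RHG"):
            rows.append({
                "model": "post_chemotherapy", "strategy": arm,
                "cost": 0.0,
                "qalys": self.postchemo[arm].total_qalys,
                "incremental_cost": None,
                "incremental_qalys": (self.delta_qalys_postchemo
                                      if arm == "PEG" else None),
                "icer": None,
            })
        return pd.DataFrame(rows)


def run_base_case(params: ParameterSet, life_table: LifeTable) -> BaseCaseResult:
    """Run both models for both arms and assemble incremental results."""
    chemo = run_chemo(params)
    p_fn_course = {arm: chemo[arm].p_fn_course for arm in chemo}
    post = run_postchemo(params, p_fn_course, life_table)
    wtp = params.wtp_per_qaly
    cea_chemo = compare(chemo["PEG"].total_cost, chemo["PEG"].total_qalys,
                        chemo["RHG"].total_cost, chemo["RHG"].total_qalys, wtp)
    cea_post = compare(0.0, post["PEG"].total_qalys,
                       0.0, post["RHG"].total_qalys, wtp)
    cea_total = compare(chemo["PEG"].total_cost,
                        chemo["PEG"].total_qalys + post["PEG"].total_qalys,
                        chemo["RHG"].total_cost,
                        chemo["RHG"].total_qalys + post["RHG"].total_qalys, wtp)
    return BaseCaseResult(chemo=chemo, postchemo=post, cea_chemo=cea_chemo,
                          cea_postchemo=cea_post, cea_total=cea_total)
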