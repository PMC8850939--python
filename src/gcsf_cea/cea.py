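"""Incremental cost-effectiveness metrics."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of two strategies at a willingness-to-pay.

    ``icer`` is Δcost/ΔQALY in CNY per QALY; it is flagged undefined when
    ΔQALY is exactly zero, and the comparison is labelled *dominant* when
    the new strategy is cheaper and at least as effective (or equally
    priced and more effective).  ``nmb`` is the incremental net monetary
    benefit ``wtp*ΔQALY − Δcost``.
    """

    cost_new: float
    cost_ref: float
    qalys_new: float
    qalys_ref: float
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.cost_new - self.cost_ref

    @property
    def delta_qalys(self) -> float:
        return self.qalys_new - self.qalys_ref

    @property
    def icer_defined(self) -> bool:
        return self.delta_qalys != 0.0

    @property
    def icer(self) -> float:
        if not self.icer_defined:
            return float("nan")
        return self.delta_cost / self.delta_qalys

    @property
    def dominant(self) -> bool:
        dc, dq = self.delta_cost, self.delta_qalys
        return (dc < 0 and dq >= 0) or (dc <= 0 and dq > 0)

    @property
    def dominated(self) -> bool:
        dc, dq = self.delta_cost, self.delta_qalys
        return (dc > 0 and dq <= 0) or (dc >= 0 and dq < 0)

    @property
    def nmb(self) -> float:
        return self.wtp * self.delta_qalys - self.delta_cost

    def as_dict(self) -> dict:
        return {
            "cost_new": self.cost_new,
            "cost_ref": self.cost_ref,
            "qalys_new": self.qalys_new,
            "qalys_ref": self.qalys_ref,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "icer": self.icer if self.icer_defined else None,
            "dominant": self.dominant,
            "dominated": self.dominated,
            "wtp": self.wtp,
            "nmb": self.nmb,
        }


def compare(cost_new: float, qalys_new: float,
            cost_ref: float, qalys_ref: float, wtp: float) -> CEAResult:
    """Build a :class:`CEAResult` from per-arm totals."""
    return CEAResult(cost_new=cost_new, cost_ref=cost_ref,
                     qalys_new=qalys_new, qalys_ref=qalys_ref, wtp=wtp)
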