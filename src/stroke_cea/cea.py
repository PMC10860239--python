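"""Incremental cost-effectiveness analysis and willingness-to-pay decisions.

The headline statistic is the incremental cost-effectiveness ratio
ICER = deltaC / deltaE (CNY per QALY gained).  When the intervention is both
cheaper and more effective it *dominates* the comparator and the ICER is not
a meaningful decision quantity; the net monetary benefit
NMB(lambda) = lambda * deltaE - deltaC is reported instead, at each
configured willingness-to-pay threshold (1x and 3x Chinese GDP per capita
by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .cohort import ArmResult

__all__ = ["CEAResult", "incremental_analysis", "net_monetary_benefit"]


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """NMB(lambda) = lambda * deltaE - deltaC; positive favours the intervention."""
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be >= 0")
    return wtp * delta_qaly - delta_cost


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of intervention vs comparator.

    ``label`` is ``"dominant"`` (cheaper and more effective), ``"dominated"``
    (costlier and less effective) or ``"ICER"``.  ``icer`` is the raw ratio
    deltaC/deltaE whenever deltaE != 0 (signed +/-inf when deltaE == 0 and
    deltaC != 0, with ``icer_defined`` False); it is populated even under
    dominance because one-way sensitivity analyses track it.
    """

    delta_cost: float
    delta_qaly: float
    label: str
    icer: float
    icer_defined: bool
    nmb: dict[float, float] = field(default_factory=dict)


def incremental_analysis(
    intervention: ArmResult,
    comparator: ArmResult,
    wtp_list: Iterable[float] = (),
) -> CEAResult:
    """Compute deltaC, deltaE, dominance class, ICER and NMB per threshold."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qaly - comparator.total_qaly

    if d_cost < 0 and d_qaly > 0:
        label = "dominant"
    elif d_cost > 0 and d_qaly < 0:
        label = "dominated"
    else:
        label = "ICER"

    if d_qaly != 0.0:
        icer = d_cost / d_qaly
        defined = True
    elif d_cost == 0.0:
        icer = math.nan
        defined = False
    else:
        icer = math.inf if d_cost > 0 else -math.inf
        defined = False

    nmb = {
        float(w): net_monetary_benefit(d_cost, d_qaly, float(w)) for w in wtp_list
    }
    return CEAResult(
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        label=label,
        icer=icer,
        icer_defined=defined,
        nmb=nmb,
    )
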