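"""Deterministic cost-effectiveness outputs.

Incremental analysis with dominance classification, one-way (tornado)
sensitivity analysis over the configured parameter ranges, and the threshold
utility-gain gap at which two strategies break even in net benefit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .decision_model import StrategyOutcome, annuity_factor, evaluate_strategies
from .parameters import ModelConfig, ParameterSet

__all__ = [
    "IncrementalRow",
    "TornadoEntry",
    "incremental_analysis",
    "incremental_table",
    "one_way_sensitivity",
    "tornado",
    "threshold_utility_gain",
    "METRICS",
]


@dataclass(frozen=True)
class IncrementalRow:
    """Pairwise comparison of two strategies: deltas and ICER or dominance flag."""

    strategy: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    #: one of {"icer", "dominant", "dominated", "undefined"}
    classification: str
    icer: float | None

    def __post_init__(self):
        if self.classification == "icer" and self.icer is None:
            raise ValueError("classification 'icer' requires a ratio")


def _compare(a: StrategyOutcome, b: StrategyOutcome) -> IncrementalRow:
    """Compare strategy ``a`` against comparator ``b``."""
    dc = a.expected_cost - b.expected_cost
    dq = a.expected_qaly - b.expected_qaly
    if dc >= 0 and dq <= 0 and (dc > 0 or dq < 0):
        cls, icer = "dominated", None
    elif dc <= 0 and dq >= 0 and (dc < 0 or dq > 0):
        cls, icer = "dominant", None
    elif dq == 0:
        # equal effect; equal cost too (else dominated above) -> no trade-off
        cls, icer = ("undefined", None) if dc != 0 else ("icer", 0.0)
    else:
        cls, icer = "icer", dc / dq
    return IncrementalRow(a.strategy, b.strategy, dc, dq, cls, icer)


def incremental_analysis(outcomes: Sequence[StrategyOutcome]) -> list[IncrementalRow]:
    """Pairwise rows versus the conservative comparator, plus the surgical head-to-head.

    With an arbitrary list of >= 2 outcomes (no conservative arm), all ordered
    pairs against the first entry are returned.
    """
    if len(outcomes) < 2:
        raise ValueError("incremental analysis needs at least two strategies")
    by_name = {o.strategy: o for o in outcomes}
    rows: list[IncrementalRow] = []
    if {"conservative", "trapeziectomy", "lrti"} <= set(by_name):
        rows.append(_compare(by_name["trapeziectomy"], by_name["conservative"]))
        rows.append(_compare(by_name["lrti"], by_name["conservative"]))
        rows.append(_compare(by_name["lrti"], by_name["trapeziectomy"]))
    else:
        ref = outcomes[0]
        rows.extend(_compare(o, ref) for o in outcomes[1:])
    return rows


def incremental_table(rows: Sequence[IncrementalRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strategy": [r.strategy for r in rows],
            "comparator": [r.comparator for r in rows],
            "delta_cost": [r.delta_cost for r in rows],
            "delta_qaly": [r.delta_qaly for r in rows],
            "classification": [r.classification for r in rows],
            "icer": [r.icer for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# One-way sensitivity
# ---------------------------------------------------------------------------


def _metric_inb_trap_vs_lrti(params: ParameterSet) -> float:
    o = evaluate_strategies(params)
    return o["trapeziectomy"].net_benefit - o["lrti"].net_benefit


def _metric_icer_trap_vs_cons(params: ParameterSet) -> float:
    o = evaluate_strategies(params)
    row = _compare(o["trapeziectomy"], o["conservative"])
    return row.icer if row.icer is not None else np.nan


def _metric_preferred(params: ParameterSet) -> float:
    """Index (0/1/2) of the net-benefit-maximising strategy."""
    o = evaluate_strategies(params)
    nbs = [o[s].net_benefit for s in ("conservative", "trapeziectomy", "lrti")]
    return float(int(np.argmax(nbs)))


def _metric_nb(strategy: str) -> Callable[[ParameterSet], float]:
    def metric(params: ParameterSet) -> float:
        return evaluate_strategies(params)[strategy].net_benefit

    return metric


#: Named output metrics for one-way sensitivity analysis.
METRICS: dict[str, Callable[[ParameterSet], float]] = {
    "inb_trap_vs_lrti": _metric_inb_trap_vs_lrti,
    "icer_trap_vs_cons": _metric_icer_trap_vs_cons,
    "preferred_strategy": _metric_preferred,
    "nb_conservative": _metric_nb("conservative"),
    "nb_trapeziectomy": _metric_nb("trapeziectomy"),
    "nb_lrti": _metric_nb("lrti"),
}


@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar: the model output at a parameter's low and high value."""

    parameter: str
    output_low: float
    output_high: float
    output_base: float

    @property
    def swing(self) -> float:
        return abs(self.output_high - self.output_low)


def one_way_sensitivity(
    config: ModelConfig,
    param: str,
    low: float,
    high: float,
    metric: str | Callable[[ParameterSet], float] = "inb_trap_vs_lrti",
) -> TornadoEntry:
    """Re-evaluate the full model at ``param``'s low and high, all else at base."""
    if param not in ParameterSet.names():
        raise ValueError(f"unknown parameter {param!r}")
    if low > high:
        raise ValueError("require low <= high")
    fn = METRICS[metric] if isinstance(metric, str) else metric
    base = config.base
    return TornadoEntry(
        parameter=param,
        output_low=fn(base.replace(**{param: low})),
        output_high=fn(base.replace(**{param: high})),
        output_base=fn(base),
    )


def tornado(
    config: ModelConfig,
    metric: str | Callable[[ParameterSet], float] = "inb_trap_vs_lrti",
) -> pd.DataFrame:
    """One-way sensitivity of every uncertain parameter, sorted by swing (desc).

    The default metric is the incremental net benefit of trapeziectomy versus
    LRTI at the configured willingness to pay — the decision of interest.
    """
    entries = [
        one_way_sensitivity(config, name, spec.low, spec.high, metric)
        for name, spec in config.uncertain.items()
    ]
    df = pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "output_low": [e.output_low for e in entries],
            "output_high": [e.output_high for e in entries],
            "output_base": [e.output_base for e in entries],
            "swing": [e.swing for e in entries],
        }
    )
    return df.sort_values("swing", ascending=False, kind="mergesort").reset_index(drop=True)


def threshold_utility_gain(delta_cost: float, wtp: float, annuity: float) -> float:
    """Utility-gain gap at which two strategies' net benefits are equal.

    A strategy costing ``delta_cost`` more breaks even when its lifetime
    utility gain exceeds the comparator's by ``delta_cost / (wtp * annuity)``.
    """
    denom = wtp * annuity
    if denom <= 0:
        raise ValueError("wtp * annuity must be positive")
    return delta_cost / denom


def breakeven_gap(config: ModelConfig) -> float:
    """Convenience: the LRTI-vs-trapeziectomy break-even utility-gain gap at base."""
    o = evaluate_strategies(config.base)
    dc = o["lrti"].expected_cost - o["trapeziectomy"].expected_cost
    horizon = config.base.life_expectancy - config.base.age
    return threshold_utility_gain(dc, config.base.wtp, annuity_factor(horizon, config.base.discount_rate))
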