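"""Decision-tree evaluation: lifetime cost, discounted QALYs and net benefit.

The tree has three arms for end-stage thumb CMC arthritis:

* conservative management — no intervention, zero expenditure, baseline utility;
* trapeziectomy alone (CPT 25210);
* trapeziectomy with ligament reconstruction and tendon interposition
  (LRTI, CPT 25447).

Surgery is a one-shot event at time zero.  Costs (all incurred at time 0,
undiscounted) are the procedure's direct fees, lost wages during recovery,
and expectation-weighted complication costs from single-level branches:
complex regional pain syndrome (CRPS) adds a physician management fee,
tendon rupture adds a full repair episode, and unresolved pain adds no cost.
Health benefit is the 12-month EQ-5D utility held constant for the remaining
life expectancy and discounted annually in arrears.

Every function broadcasts over numpy arrays, so the same code evaluates one
base case or a full Monte Carlo draw matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import STRATEGIES, ParameterSet

__all__ = [
    "StrategyOutcome",
    "CostBreakdown",
    "annuity_factor",
    "indirect_cost",
    "strategy_cost",
    "strategy_qaly",
    "net_benefit",
    "evaluate_strategies",
    "evaluate_draws",
    "basecase_table",
]


def annuity_factor(years, rate):
    """Present value of one unit per year for ``years`` years at ``rate``.

    Payments in arrears, annual cycles: sum_{t=1..T} (1+r)^(-t), evaluated by
    the closed form (1 - (1+r)^-T) / r, which extends the integer-year sum
    continuously (non-integer horizons arise when ages are sampled).
    At rate 0 the factor is T.
    """
    years = np.asarray(years, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(years < 0) or np.any(rate < 0):
        raise ValueError("annuity_factor requires non-negative years and rate")
    with np.errstate(divide="ignore", invalid="ignore"):
        # -expm1(-T*log1p(r))/r is stable down to r -> 0 (limit T)
        out = np.where(
            rate > 0,
            -np.expm1(-years * np.log1p(rate)) / np.where(rate > 0, rate, 1.0),
            years,
        )
    return out if out.ndim else float(out)


def indirect_cost(annual_wage, days_off, age, retirement_age):
    """Lost wages during recovery: wage prorated by calendar days, zero past retirement."""
    annual_wage = np.asarray(annual_wage, dtype=float)
    days_off = np.asarray(days_off, dtype=float)
    working = np.asarray(age, dtype=float) < np.asarray(retirement_age, dtype=float)
    out = np.where(working, annual_wage * days_off / 365.0, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CostBreakdown:
    """Expected lifetime cost of one strategy, split into its three components."""

    direct: float
    indirect: float
    expected_complication: float

    @property
    def total(self) -> float:
        return self.direct + self.indirect + self.expected_complication


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected cost, discounted QALYs and net monetary benefit for one strategy."""

    strategy: str
    expected_cost: float
    expected_qaly: float
    net_benefit: float
    breakdown: CostBreakdown | None = None


def _cost_components(strategy: str, p) -> tuple:
    """Direct, indirect and expected-complication cost (broadcastable)."""
    if strategy == "conservative":
        zero = np.zeros_like(np.asarray(p.u_baseline, dtype=float))
        return zero, zero, zero
    if strategy == "trapeziectomy":
        direct = (
            p.fee_physician_trap
            + p.fee_anesthesia_trap
            + p.fee_facility_trap
            + p.fee_hand_therapy_trap
        )
        indirect = indirect_cost(p.annual_wage, p.days_off_trap, p.age, p.retirement_age)
        compl = p.p_crps_trap * p.fee_crps_physician + p.p_rupture_trap * (
            p.fee_repair_physician + p.fee_repair_anesthesia + p.fee_repair_hospital
        )
        return np.asarray(direct, float), indirect, np.asarray(compl, float)
    if strategy == "lrti":
        direct = (
            p.fee_physician_lrti
            + p.fee_anesthesia_lrti
            + p.fee_facility_lrti
            + p.fee_hand_therapy_lrti
        )
        indirect = indirect_cost(p.annual_wage, p.days_off_lrti, p.age, p.retirement_age)
        compl = p.p_crps_lrti * p.fee_crps_physician + p.p_rupture_lrti * (
            p.fee_repair_physician + p.fee_repair_anesthesia + p.fee_repair_hospital
        )
        return np.asarray(direct, float), indirect, np.asarray(compl, float)
    raise ValueError(f"unknown strategy {strategy!r}")


def strategy_cost(strategy: str, params: ParameterSet) -> CostBreakdown:
    """Expected lifetime cost of one strategy for a scalar parameter set."""
    direct, indirect, compl = _cost_components(strategy, params)
    return CostBreakdown(float(direct), float(indirect), float(compl))


def _effective_utility(strategy: str, p):
    u = np.asarray(p.u_baseline, dtype=float)
    if strategy == "conservative":
        return u - p.p_fail_cons * p.du_fail_decrement
    if strategy == "trapeziectomy":
        return (
            u
            + p.du_trap
            - p.p_crps_trap * p.du_crps_decrement
            - p.p_fail_trap * p.du_fail_decrement
        )
    if strategy == "lrti":
        return (
            u
            + p.du_lrti
            - p.p_crps_lrti * p.du_crps_decrement
            - p.p_fail_lrti * p.du_fail_decrement
        )
    raise ValueError(f"unknown strategy {strategy!r}")


def strategy_qaly(strategy: str, params) -> float | np.ndarray:
    """Discounted lifetime QALYs: effective utility times the remaining-life annuity."""
    u = _effective_utility(strategy, params)
    horizon = np.asarray(params.life_expectancy, float) - np.asarray(params.age, float)
    q = u * annuity_factor(horizon, params.discount_rate)
    return q if np.ndim(q) else float(q)


def net_benefit(expected_cost, expected_qaly, wtp):
    """Net monetary benefit at willingness-to-pay ``wtp``: wtp * QALY - cost."""
    if np.any(np.asarray(wtp) < 0):
        raise ValueError("wtp must be non-negative")
    nb = np.asarray(wtp, float) * np.asarray(expected_qaly, float) - np.asarray(
        expected_cost, float
    )
    return nb if nb.ndim else float(nb)


def evaluate_strategies(params: ParameterSet, wtp: float | None = None) -> dict[str, StrategyOutcome]:
    """Evaluate all three arms for one parameter set; keyed by strategy id."""
    wtp = params.wtp if wtp is None else wtp
    out: dict[str, StrategyOutcome] = {}
    for s in STRATEGIES:
        cb = strategy_cost(s, params)
        q = strategy_qaly(s, params)
        out[s] = StrategyOutcome(
            strategy=s,
            expected_cost=cb.total,
            expected_qaly=q,
            net_benefit=net_benefit(cb.total, q, wtp),
            breakdown=cb,
        )
    return out


class _ArrayParams:
    """Attribute view over a draws table, falling back to base-case scalars."""

    def __init__(self, table: pd.DataFrame, base: ParameterSet):
        self._cols = {c: table[c].to_numpy() for c in table.columns}
        self._base = base

    def __getattr__(self, name):
        cols = object.__getattribute__(self, "_cols")
        if name in cols:
            return cols[name]
        return getattr(object.__getattribute__(self, "_base"), name)


def evaluate_draws(
    table: pd.DataFrame, base: ParameterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised model evaluation over a draw matrix.

    Returns ``(costs, qalys)``, each of shape ``(n_draws, 3)`` in the order of
    :data:`~cmcvoi.parameters.STRATEGIES`.  Columns missing from ``table``
    are held at their base-case values.
    """
    p = _ArrayParams(table, base)
    n = len(table)
    costs = np.empty((n, len(STRATEGIES)))
    qalys = np.empty((n, len(STRATEGIES)))
    for j, s in enumerate(STRATEGIES):
        d, i, c = _cost_components(s, p)
        costs[:, j] = np.broadcast_to(d + i + c, (n,))
        qalys[:, j] = np.broadcast_to(strategy_qaly(s, p), (n,))
    return costs, qalys


def basecase_table(outcomes: Mapping[str, StrategyOutcome]) -> pd.DataFrame:
    """One row per strategy: cost breakdown, QALYs and net benefit."""
    rows = []
    for s, o in outcomes.items():
        cb = o.breakdown or CostBreakdown(np.nan, np.nan, np.nan)
        rows.append(
            {
                "strategy": s,
                "direct_cost": cb.direct,
                "indirect_cost": cb.indirect,
                "expected_complication_cost": cb.expected_complication,
                "total_cost": o.expected_cost,
                "qaly": o.expected_qaly,
                "net_benefit": o.net_benefit,
            }
        )
    return pd.DataFrame(rows)
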