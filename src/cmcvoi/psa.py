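"""Probabilistic sensitivity analysis.

Propagates the Table-of-variables uncertainty through the decision tree by
Monte Carlo: each draw samples every uncertain parameter from its
distribution, evaluates all three arms, and records per-draw cost and QALYs.
Outputs feed the cost-effectiveness plane, the cost-effectiveness
acceptability curve (CEAC) and the value-of-information stack.

An optional rank-correlation request induces a Spearman correlation between
complication probabilities and the utility gains of the same arm (an
Iman-Conover-style rank reordering that preserves all marginals exactly),
emulating the sensitivity analysis in which worse complication profiles
accompany smaller quality-of-life gains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decision_model import evaluate_draws
from .parameters import STRATEGIES, ModelConfig, ParameterDraws, sample_parameter_draws

__all__ = ["PSAResult", "CeacCurve", "run_psa", "ceac", "DEFAULT_CORRELATION_PAIRS"]

#: (complication-probability column, utility-gain anchor column) pairs used when
#: a scalar correlation is requested: each arm's complication rates move
#: against that arm's utility gain.
DEFAULT_CORRELATION_PAIRS = (
    ("p_crps_trap", "du_trap"),
    ("p_fail_trap", "du_trap"),
    ("p_crps_lrti", "du_lrti"),
    ("p_rupture_lrti", "du_lrti"),
    ("p_fail_lrti", "du_lrti"),
)


@dataclass
class PSAResult:
    """Per-draw costs and QALYs for every strategy, plus the draws that produced them."""

    draws: ParameterDraws
    costs: np.ndarray  # (n_draws, 3), strategy order = STRATEGIES
    qalys: np.ndarray  # (n_draws, 3)
    strategies: tuple[str, ...] = STRATEGIES
    correlation: float | None = None

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    @property
    def seed(self) -> int:
        return self.draws.seed

    def net_benefit(self, wtp: float) -> np.ndarray:
        """(n_draws, n_strategies) net monetary benefit matrix at ``wtp``."""
        return wtp * self.qalys - self.costs

    def table(self) -> pd.DataFrame:
        """Per-draw cost/QALY table (one column pair per strategy)."""
        data = {}
        for j, s in enumerate(self.strategies):
            data[f"cost_{s}"] = self.costs[:, j]
            data[f"qaly_{s}"] = self.qalys[:, j]
        return pd.DataFrame(data)


def _induce_rank_correlation(
    table: pd.DataFrame,
    pairs,
    rho: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Reorder target columns to a Spearman correlation ``rho`` with their anchors.

    Gaussian-copula reordering: latent normal scores correlated with the
    anchor's normal scores decide the new rank order of the target's values,
    so the target's marginal distribution is preserved exactly.  The latent
    Pearson coefficient is adjusted (2 sin(pi rho / 6)) so the realised
    Spearman correlation matches the request.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValueError(f"rank correlation {rho} outside [-1, 1]")
    rho_p = 2.0 * np.sin(np.pi * rho / 6.0)
    n = len(table)
    out = table.copy()
    for target, anchor in pairs:
        if target not in table.columns or anchor not in table.columns:
            continue  # point-mass parameters are not in the draw table
        if table[target].nunique() <= 1:
            continue
        z_anchor = stats.norm.ppf((stats.rankdata(table[anchor]) - 0.5) / n)
        latent = rho_p * z_anchor + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
        order = np.argsort(np.argsort(latent))  # ranks of latent, 0-based
        sorted_vals = np.sort(out[target].to_numpy())
        out[target] = sorted_vals[order]
    return out


def run_psa(
    config: ModelConfig,
    n_draws: int = 10_000,
    seed: int = 0,
    correlation: float | None = None,
    correlation_pairs=DEFAULT_CORRELATION_PAIRS,
) -> PSAResult:
    """Run the probabilistic sensitivity analysis.

    Parameters
    ----------
    config
        Base-case values and distribution specs.
    n_draws
        Monte Carlo sample size (default 10,000).
    seed
        Seed for all randomness; identical seeds give bit-identical results.
    correlation
        Optional Spearman rank correlation to induce between each complication
        probability and its arm's utility gain (e.g. ``-0.5``); marginal
        distributions are preserved exactly.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    draws = sample_parameter_draws(config.uncertain, n_draws, seed)
    table = draws.table
    if correlation is not None:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0x1C0)))
        table = _induce_rank_correlation(table, correlation_pairs, correlation, rng)
        draws = ParameterDraws(table=table, seed=seed)
    costs, qalys = evaluate_draws(table, config.base)
    return PSAResult(draws=draws, costs=costs, qalys=qalys, correlation=correlation)


@dataclass
class CeacCurve:
    """Cost-effectiveness acceptability: P(strategy maximises NB) on a WTP grid."""

    wtp_grid: np.ndarray
    probabilities: pd.DataFrame  # index = wtp grid, one column per strategy

    def at(self, wtp: float) -> pd.Series:
        idx = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        return self.probabilities.iloc[idx]

    def table(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out.insert(0, "wtp", self.wtp_grid)
        return out.reset_index(drop=True)


def ceac(psa: PSAResult, wtp_grid) -> CeacCurve:
    """Fraction of draws in which each strategy has the highest net benefit.

    Draws where several strategies tie for the maximum are split equally
    among the tied strategies, so the probabilities sum to one at every
    willingness-to-pay point.
    """
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if psa.n_draws == 0:
        raise ValueError("empty PSA")
    probs = np.zeros((len(wtp_grid), len(psa.strategies)))
    for i, wtp in enumerate(wtp_grid):
        nb = psa.net_benefit(wtp)
        best = nb.max(axis=1, keepdims=True)
        is_max = nb == best
        weights = is_max / is_max.sum(axis=1, keepdims=True)
        probs[i] = weights.mean(axis=0)
    return CeacCurve(
        wtp_grid=wtp_grid,
        probabilities=pd.DataFrame(probs, columns=list(psa.strategies)),
    )


def ce_plane_table(psa: PSAResult, origin: str = "conservative") -> pd.DataFrame:
    """Incremental cost/QALY scatter of each surgical arm against ``origin``."""
    j0 = psa.strategies.index(origin)
    data = {}
    for j, s in enumerate(psa.strategies):
        if j == j0:
            continue
        data[f"delta_cost_{s}"] = psa.costs[:, j] - psa.costs[:, j0]
        data[f"delta_qaly_{s}"] = psa.qalys[:, j] - psa.qalys[:, j0]
    return pd.DataFrame(data)
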