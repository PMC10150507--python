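"""Value-of-information stack: EVPI, EVPPI, EVSI, ENBS.

All quantities are per-person US dollars at a given willingness to pay and
derive from the probabilistic sensitivity analysis:

* EVPI — expected value of perfect information, ``E[max_s NB_s] - max_s E[NB_s]``;
* EVPPI — the same with perfect knowledge restricted to a parameter subset,
  estimated by two-level nested Monte Carlo (with a regression-based
  single-loop estimator as a cross-check);
* EVSI — expected value of sample information for a two-arm trial measuring
  12-month EQ-5D utility change after trapeziectomy and after LRTI, via a
  conjugate normal-normal preposterior analysis on the two utility-gain
  means;
* ENBS — population EVSI minus trial operating costs, with the population of
  future patients discounted as an annuity-due over the decision horizon.

The decision tree's net benefit is linear in the two utility gains, so the
conditional expectation of net benefit given the gains is computed exactly
from the PSA draws (intercept and slope per strategy) rather than by an
inner simulation loop; the generic nested estimator remains available for
arbitrary parameter subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .decision_model import evaluate_draws
from .parameters import (
    STRATEGIES,
    DistributionSpec,
    ModelConfig,
    sample_parameter_draws,
)
from .psa import PSAResult

__all__ = [
    "TrialDesign",
    "PopulationSpec",
    "VOIResult",
    "evpi",
    "evpi_from_nb",
    "evpi_curve",
    "evppi_nested",
    "evppi_regression",
    "evppi_gains",
    "GainLinearModel",
    "evsi",
    "evsi_curve",
    "calibrate_sigma_individual",
    "effective_population",
    "enbs",
]

GAIN_PARAMS = ("du_trap", "du_lrti")


@dataclass(frozen=True)
class TrialDesign:
    """A two-arm trial (trapeziectomy vs LRTI) measuring EQ-5D utility change."""

    n_per_arm: int
    cost_per_participant: float = 10_000.0
    sigma_individual: float = 0.30

    def __post_init__(self):
        if self.n_per_arm < 0:
            raise ValueError("n_per_arm must be >= 0")
        if self.cost_per_participant < 0:
            raise ValueError("cost_per_participant must be >= 0")
        if self.sigma_individual <= 0:
            raise ValueError("sigma_individual must be > 0")

    @property
    def total_cost(self) -> float:
        return 2.0 * self.n_per_arm * self.cost_per_participant


@dataclass(frozen=True)
class PopulationSpec:
    """Annual incident cases to whom the decision applies, over a fixed horizon."""

    annual_cases: float = 40_000.0
    horizon_years: int = 10
    discount_rate: float = 0.03

    def __post_init__(self):
        if min(self.annual_cases, self.horizon_years, self.discount_rate) < 0:
            raise ValueError("population inputs must be non-negative")


@dataclass
class VOIResult:
    """Bundle of the VOI outputs at one willingness to pay."""

    wtp: float
    evpi_per_person: float
    evppi: dict[str, float]
    evsi_curve: pd.DataFrame  # n_per_arm, evsi_per_person, population_evsi, trial_cost, enbs
    effective_population: float


# ---------------------------------------------------------------------------
# EVPI
# ---------------------------------------------------------------------------


def evpi_from_nb(nb: np.ndarray) -> float:
    """EVPI from an (n_draws, n_strategies) net-benefit matrix."""
    nb = np.asarray(nb, dtype=float)
    if nb.ndim != 2 or nb.shape[0] == 0:
        raise ValueError("need a non-empty (draws, strategies) matrix")
    return float(nb.max(axis=1).mean() - nb.mean(axis=0).max())


def evpi(psa: PSAResult, wtp: float) -> float:
    """Per-person expected value of perfect information at ``wtp``."""
    return evpi_from_nb(psa.net_benefit(wtp))


def evpi_curve(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """EVPI across a willingness-to-pay grid."""
    wtps = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    return pd.DataFrame({"wtp": wtps, "evpi_per_person": [evpi(psa, w) for w in wtps]})


# ---------------------------------------------------------------------------
# EVPPI
# ---------------------------------------------------------------------------


def evppi_nested(
    config: ModelConfig,
    subset: list[str] | tuple[str, ...],
    wtp: float | None = None,
    n_outer: int = 1000,
    n_inner: int = 1000,
    seed: int = 0,
    max_block_rows: int = 250_000,
) -> float:
    """Two-level nested Monte Carlo EVPPI for an arbitrary parameter subset.

    Outer draws fix the subset; inner draws integrate the remaining
    parameters.  ``EVPPI = E_outer[max_s E_inner NB_s] - max_s E[NB_s]``.
    """
    uncertain = config.uncertain
    unknown = [p for p in subset if p not in config.specs]
    if unknown:
        raise ValueError(f"unknown parameters in subset: {unknown}")
    if not subset:
        raise ValueError("subset must be non-empty")
    wtp = config.base.wtp if wtp is None else wtp

    subset_specs = {k: uncertain[k] for k in subset if k in uncertain}
    rest_specs = {k: v for k, v in uncertain.items() if k not in subset_specs}

    outer = sample_parameter_draws(subset_specs, n_outer, seed).table if subset_specs else None
    if outer is None:
        return 0.0  # subset is entirely fixed: knowing it has no value

    block = max(1, max_block_rows // n_inner)
    cond_max = np.empty(n_outer)
    sum_nb = np.zeros(len(STRATEGIES))
    inner_seed = np.random.SeedSequence((seed, 0xE1))
    children = inner_seed.spawn((n_outer + block - 1) // block)
    for bi, start in enumerate(range(0, n_outer, block)):
        stop = min(start + block, n_outer)
        b = stop - start
        rest = sample_parameter_draws(
            rest_specs, b * n_inner, int(children[bi].generate_state(1)[0] % 2**31)
        ).table
        tiled = outer.iloc[start:stop].loc[outer.index[start:stop].repeat(n_inner)].reset_index(
            drop=True
        )
        full = pd.concat([tiled, rest], axis=1)
        costs, qalys = evaluate_draws(full, config.base)
        nb = (wtp * qalys - costs).reshape(b, n_inner, len(STRATEGIES))
        cond = nb.mean(axis=1)  # (b, strategies)
        cond_max[start:stop] = cond.max(axis=1)
        sum_nb += cond.sum(axis=0)
    return float(cond_max.mean() - (sum_nb / n_outer).max())


def _poly_design(x: np.ndarray, degree: int) -> np.ndarray:
    """Full polynomial basis (with interactions) of degree <= ``degree``."""
    from itertools import combinations_with_replacement

    n, k = x.shape
    cols = [np.ones(n)]
    for d in range(1, degree + 1):
        for combo in combinations_with_replacement(range(k), d):
            cols.append(np.prod(x[:, combo], axis=1))
    return np.column_stack(cols)


def evppi_regression(
    psa: PSAResult, subset: list[str] | tuple[str, ...], wtp: float, degree: int = 2
) -> float:
    """Single-loop regression EVPPI: fit E[NB_s | subset] by polynomial least squares.

    A fast consistency cross-check for the nested estimator; adequate when the
    conditional net benefit is smooth in the subset (here it is linear in the
    utility gains and mildly nonlinear elsewhere).
    """
    missing = [p for p in subset if p not in psa.draws.table.columns]
    if missing:
        raise ValueError(f"subset parameters not in PSA draws: {missing}")
    x = psa.draws.table[list(subset)].to_numpy()
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    design = _poly_design(x, degree)
    nb = psa.net_benefit(wtp)
    fitted = np.empty_like(nb)
    for j in range(nb.shape[1]):
        coef, *_ = np.linalg.lstsq(design, nb[:, j], rcond=None)
        fitted[:, j] = design @ coef
    return float(fitted.max(axis=1).mean() - fitted.mean(axis=0).max())


# ---------------------------------------------------------------------------
# Linear conditional net benefit in the two utility gains
# ---------------------------------------------------------------------------


class GainLinearModel:
    """Exact conditional expected net benefit given the two utility gains.

    Net benefit is linear in (du_trap, du_lrti) with coefficients that depend
    only on the other parameters, so ``E[NB_s | du]`` is an affine function
    whose intercept and slopes are obtained by re-evaluating the model on the
    PSA draw matrix with the gain columns overridden (du = 0 and du = e_j).
    Requires independent draws (no induced correlation).
    """

    def __init__(self, psa: PSAResult, config: ModelConfig, wtp: float | None = None):
        if psa.correlation is not None:
            raise ValueError("gain-linear decomposition requires independent PSA draws")
        self.wtp = config.base.wtp if wtp is None else wtp
        self.config = config
        table = psa.draws.table.copy()
        nS = len(STRATEGIES)

        def mean_nb(dt: float, dl: float) -> np.ndarray:
            t = table.copy()
            t["du_trap"] = dt
            t["du_lrti"] = dl
            costs, qalys = evaluate_draws(t, config.base)
            return (self.wtp * qalys - costs).mean(axis=0)

        self.intercept = mean_nb(0.0, 0.0)  # (3,)
        self.slope_trap = mean_nb(1.0, 0.0) - self.intercept
        self.slope_lrti = mean_nb(0.0, 1.0) - self.intercept
        assert self.intercept.shape == (nS,)

    def nb(self, du_trap, du_lrti) -> np.ndarray:
        """E[NB | gains] for each strategy; broadcasts over arrays of gains."""
        dt = np.asarray(du_trap, dtype=float)[..., None]
        dl = np.asarray(du_lrti, dtype=float)[..., None]
        return self.intercept + self.slope_trap * dt + self.slope_lrti * dl

    def prior_means(self) -> tuple[float, float]:
        specs = self.config.specs
        return specs["du_trap"].mean(), specs["du_lrti"].mean()

    def max_expected_nb(self) -> float:
        mt, ml = self.prior_means()
        return float(self.nb(mt, ml).max())


def evppi_gains(
    psa: PSAResult,
    config: ModelConfig,
    wtp: float | None = None,
    n_outer: int = 100_000,
    seed: int = 0,
) -> float:
    """EVPPI of the two utility gains via the exact linear conditional NB."""
    g = GainLinearModel(psa, config, wtp)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE2)))
    dt = config.specs["du_trap"].sample(rng, n_outer)
    dl = config.specs["du_lrti"].sample(rng, n_outer)
    cond = g.nb(dt, dl)  # (n_outer, 3)
    return float(cond.max(axis=1).mean() - g.max_expected_nb())


# ---------------------------------------------------------------------------
# EVSI
# ---------------------------------------------------------------------------


def _gain_priors(config: ModelConfig) -> tuple[tuple[float, float], tuple[float, float]]:
    """(mean, sd) normal priors for the two utility gains from the config specs."""
    priors = []
    for name in GAIN_PARAMS:
        spec: DistributionSpec = config.specs[name]
        if spec.family != "normal":
            raise ValueError(f"{name} must have a normal prior for conjugate EVSI")
        priors.append((spec.base, spec.sd))
    return priors[0], priors[1]


def _evsi_from_noise(
    g: GainLinearModel,
    priors,
    n_per_arm: int,
    sigma_individual: float,
    true_gains: np.ndarray,
    noise: np.ndarray,
) -> float:
    """EVSI given pre-drawn true gains and standard-normal trial noise (CRN)."""
    if n_per_arm == 0:
        return 0.0
    post = np.empty_like(true_gains)  # posterior means, (n_outer, 2)
    for j, (m0, s0) in enumerate(priors):
        se = sigma_individual / np.sqrt(n_per_arm)  # SE of the arm mean
        xbar = true_gains[:, j] + se * noise[:, j]
        w = s0**2 / (s0**2 + se**2)
        post[:, j] = m0 + w * (xbar - m0)
    cond = g.nb(post[:, 0], post[:, 1])
    return float(cond.max(axis=1).mean() - g.max_expected_nb())


def evsi(
    psa: PSAResult,
    config: ModelConfig,
    design: TrialDesign,
    wtp: float | None = None,
    n_outer: int = 100_000,
    seed: int = 0,
) -> float:
    """Per-person expected value of sample information for a two-arm utility trial.

    For each outer draw of the true utility gains, a trial outcome (per-arm
    mean EQ-5D change with standard error ``sigma_individual / sqrt(n)``) is
    simulated, the normal priors are updated by conjugate normal-normal
    updating, and the post-trial decision is scored by the expected net
    benefit at the posterior means.
    """
    g = GainLinearModel(psa, config, wtp)
    priors = _gain_priors(config)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE3)))
    true_gains = np.column_stack(
        [m + s * rng.standard_normal(n_outer) for m, s in priors]
    )
    noise = rng.standard_normal((n_outer, 2))
    return _evsi_from_noise(
        g, priors, design.n_per_arm, design.sigma_individual, true_gains, noise
    )


def evsi_curve(
    psa: PSAResult,
    config: ModelConfig,
    n_grid,
    sigma_individual: float | None = None,
    cost_per_participant: float | None = None,
    wtp: float | None = None,
    n_outer: int = 100_000,
    seed: int = 0,
    population: float | None = None,
) -> pd.DataFrame:
    """EVSI and ENBS across trial sizes, using common random numbers.

    The same outer draws of true gains and the same standard-normal trial
    noise are reused at every ``n``, so the curve's shape is stable and its
    monotone rise is not drowned in Monte Carlo noise.
    """
    study = config.study
    sigma = study.sigma_individual if sigma_individual is None else sigma_individual
    cpp = study.cost_per_participant if cost_per_participant is None else cost_per_participant
    if population is None:
        population = effective_population(
            PopulationSpec(study.annual_cases, study.horizon_years, study.population_discount_rate)
        )
    g = GainLinearModel(psa, config, wtp)
    priors = _gain_priors(config)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE3)))
    true_gains = np.column_stack([m + s * rng.standard_normal(n_outer) for m, s in priors])
    noise = rng.standard_normal((n_outer, 2))

    rows = []
    for n in n_grid:
        design = TrialDesign(int(n), cpp, sigma)
        e = _evsi_from_noise(g, priors, design.n_per_arm, sigma, true_gains, noise)
        rows.append(
            {
                "n_per_arm": int(n),
                "evsi_per_person": e,
                "population_evsi": e * population,
                "trial_cost": design.total_cost,
                "enbs": enbs(e, population, design),
            }
        )
    return pd.DataFrame(rows)


def calibrate_sigma_individual(
    psa: PSAResult,
    config: ModelConfig,
    target_evsi: float,
    n_per_arm: int,
    wtp: float | None = None,
    n_outer: int = 100_000,
    seed: int = 0,
    bounds: tuple[float, float] = (0.02, 2.0),
) -> float:
    """Find the individual-level EQ-5D change SD matching a supplied EVSI point.

    Under common random numbers EVSI is a smooth, strictly decreasing function
    of ``sigma_individual`` (a noisier instrument is less informative), so a
    scalar root-find recovers the SD implied by a published EVSI curve value.
    """
    g = GainLinearModel(psa, config, wtp)
    priors = _gain_priors(config)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE3)))
    true_gains = np.column_stack([m + s * rng.standard_normal(n_outer) for m, s in priors])
    noise = rng.standard_normal((n_outer, 2))

    def f(sigma: float) -> float:
        return (
            _evsi_from_noise(g, priors, n_per_arm, sigma, true_gains, noise) - target_evsi
        )

    lo, hi = bounds
    if f(lo) < 0:
        raise ValueError(
            f"target EVSI {target_evsi} unattainable: even sigma={lo} gives less value"
        )
    if f(hi) > 0:
        raise ValueError(f"target EVSI {target_evsi} below the value at sigma={hi}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-4))


# ---------------------------------------------------------------------------
# Population scaling
# ---------------------------------------------------------------------------


def effective_population(pop: PopulationSpec) -> float:
    """Discounted number of future patients the decision applies to.

    Annuity-due over the decision horizon: ``annual_cases *
    sum_{t=0}^{H-1} (1+r)^-t`` — the current year's cohort is undiscounted.
    """
    t = np.arange(pop.horizon_years)
    return float(pop.annual_cases * np.sum((1.0 + pop.discount_rate) ** -t))


def enbs(evsi_per_person: float, population: float, design: TrialDesign) -> float:
    """Expected net benefit of sampling: population EVSI minus trial cost."""
    if evsi_per_person < 0 or population < 0:
        raise ValueError("evsi_per_person and population must be non-negative")
    return evsi_per_person * population - design.total_cost


def voi_summary(
    psa: PSAResult,
    config: ModelConfig,
    wtp: float | None = None,
    evppi_subsets: dict[str, tuple[str, ...]] | None = None,
    n_outer: int = 50_000,
    seed: int = 0,
) -> VOIResult:
    """Convenience wrapper assembling EVPI, gain EVPPI and the EVSI/ENBS curve."""
    study = config.study
    wtp = config.base.wtp if wtp is None else wtp
    pop = effective_population(
        PopulationSpec(study.annual_cases, study.horizon_years, study.population_discount_rate)
    )
    evppi_out = {"utility_gains": evppi_gains(psa, config, wtp, n_outer=n_outer, seed=seed)}
    for name, subset in (evppi_subsets or {}).items():
        evppi_out[name] = evppi_nested(config, subset, wtp, seed=seed)
    curve = evsi_curve(psa, config, study.trial_n_grid, wtp=wtp, n_outer=n_outer, seed=seed)
    return VOIResult(
        wtp=wtp,
        evpi_per_person=evpi(psa, wtp),
        evppi=evppi_out,
        evsi_curve=curve,
        effective_population=pop,
    )
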