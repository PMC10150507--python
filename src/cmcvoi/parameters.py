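"""Model parameter space: base-case values, sampling distributions, and PSA draws.

The model of thumb carpometacarpal (CMC) arthritis treatment is driven by a
flat parameter set: patient demographics, per-procedure complication
probabilities, 2020 Medicare fee-schedule amounts, wage/productivity inputs,
and EQ-5D utilities.  Each uncertain parameter carries a (base, low, high)
triplet and a distribution family; every non-uniform family is parameterised
with mean equal to the base value and standard deviation equal to one quarter
of the (high - low) range, which is the convention used to build the
probabilistic sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "STRATEGIES",
    "ConfigError",
    "ValidationError",
    "DistributionSpec",
    "ParameterSet",
    "ParameterDraws",
    "ModelConfig",
    "StudyDesign",
    "build_distribution",
    "load_model_config",
    "load_default_config",
    "sample_parameter_draws",
    "apply_scenario",
]

#: The three treatment arms.  Conservative management is the zero-cost comparator.
STRATEGIES = ("conservative", "trapeziectomy", "lrti")

#: EQ-5D index support (UK tariff): worst imaginable state to full health.
EQ5D_SUPPORT = (-0.594, 1.0)

FAMILIES = ("point", "uniform", "normal", "truncated_normal_positive", "beta")


class ConfigError(KeyError):
    """A required configuration key is missing or unparseable."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


# ---------------------------------------------------------------------------
# Distribution specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one uncertain parameter.

    ``sd`` is derived as ``(high - low) / 4`` for the normal, truncated-normal
    and beta families; the uniform family uses its endpoints directly, and a
    degenerate range (``low == high``) collapses to a point mass at ``base``
    regardless of the requested family.

    ``support`` optionally clips draws to a closed interval (used for the
    baseline EQ-5D utility, whose normal spread exceeds the index support).
    """

    family: str
    base: float
    low: float
    high: float
    support: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"require low <= base <= high, got ({self.base}, {self.low}, {self.high})"
            )
        if self.family == "beta":
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValidationError("beta parameters must lie in [0, 1]")
            if not self.is_point:
                m, v = self.base, self.sd**2
                if v >= m * (1.0 - m):
                    raise ValidationError(
                        f"beta method-of-moments infeasible: sd^2={v:.4g} >= mean(1-mean)={m * (1 - m):.4g}"
                    )

    # -- derived hyperparameters ------------------------------------------------

    @property
    def is_point(self) -> bool:
        return self.family == "point" or self.low == self.high

    @property
    def sd(self) -> float:
        """Quarter-range standard deviation (0 for point; range/sqrt(12) for uniform)."""
        if self.is_point:
            return 0.0
        if self.family == "uniform":
            return (self.high - self.low) / np.sqrt(12.0)
        return (self.high - self.low) / 4.0

    @property
    def beta_ab(self) -> tuple[float, float]:
        """Method-of-moments Beta(alpha, beta) matching mean=base, sd=range/4."""
        if self.family != "beta" or self.is_point:
            raise ValidationError("beta hyperparameters only defined for non-degenerate beta")
        m, v = self.base, self.sd**2
        nu = m * (1.0 - m) / v - 1.0
        return m * nu, (1.0 - m) * nu

    def frozen(self):
        """The scipy.stats frozen distribution backing this spec (non-point only)."""
        if self.is_point:
            raise ValidationError("point mass has no scipy distribution")
        if self.family == "uniform":
            return stats.uniform(loc=self.low, scale=self.high - self.low)
        if self.family == "normal":
            return stats.norm(loc=self.base, scale=self.sd)
        if self.family == "truncated_normal_positive":
            a = (0.0 - self.base) / self.sd
            return stats.truncnorm(a, np.inf, loc=self.base, scale=self.sd)
        if self.family == "beta":
            a, b = self.beta_ab
            return stats.beta(a, b)
        raise AssertionError(self.family)

    def mean(self) -> float:
        """Analytic mean of the sampling distribution (post truncation/clipping)."""
        if self.is_point:
            return self.base
        m = float(self.frozen().mean())
        if self.support is not None:
            # clipping shift is negligible at the spreads used here; compute anyway
            lo, hi = self.support
            d = self.frozen()
            m = float(
                lo * d.cdf(lo)
                + hi * d.sf(hi)
                + d.expect(lb=lo, ub=hi)
            )
        return m

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.is_point:
            return np.full(size, self.base, dtype=float)
        out = np.asarray(
            self.frozen().rvs(size=size, random_state=rng), dtype=float
        )
        if self.support is not None:
            out = np.clip(out, *self.support)
        return out

    def to_dict(self) -> dict:
        d = {"base": self.base, "low": self.low, "high": self.high, "family": self.family}
        if self.support is not None:
            d["support"] = list(self.support)
        return d


def build_distribution(
    family: str,
    base: float,
    low: float,
    high: float,
    support: tuple[float, float] | None = None,
) -> DistributionSpec:
    """Build a :class:`DistributionSpec`, degenerating to a point mass if low == high."""
    if low == high:
        family = "point"
    return DistributionSpec(family, float(base), float(low), float(high), support)


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """All scalar inputs needed for one evaluation of the decision tree.

    Units: ages and horizons in years, fees and wages in 2020 USD,
    probabilities as fractions, utilities on the EQ-5D index scale,
    ``wtp`` in USD per QALY.
    """

    age: float = 62.0
    life_expectancy: float = 86.0
    discount_rate: float = 0.03
    retirement_age: float = 66.0
    annual_wage: float = 51_960.0
    days_off_trap: float = 30.0
    days_off_lrti: float = 30.0

    p_fail_cons: float = 1.0
    p_crps_trap: float = 0.029
    p_rupture_trap: float = 0.0
    p_fail_trap: float = 0.079
    p_crps_lrti: float = 0.04
    p_rupture_lrti: float = 0.043
    p_fail_lrti: float = 0.066

    fee_physician_trap: float = 508.39
    fee_anesthesia_trap: float = 151.0
    fee_facility_trap: float = 2830.40
    fee_hand_therapy_trap: float = 477.28
    fee_physician_lrti: float = 854.53
    fee_anesthesia_lrti: float = 194.0
    fee_facility_lrti: float = 2830.40
    fee_hand_therapy_lrti: float = 477.28
    fee_crps_physician: float = 444.0
    fee_repair_physician: float = 822.05
    fee_repair_anesthesia: float = 124.7233
    fee_repair_hospital: float = 2623.34

    u_baseline: float = 0.675
    du_trap: float = 0.16
    du_lrti: float = 0.14
    du_crps_decrement: float = 0.0
    du_fail_decrement: float = 0.0

    wtp: float = 100_000.0

    _PROBS = (
        "p_fail_cons",
        "p_crps_trap",
        "p_rupture_trap",
        "p_fail_trap",
        "p_crps_lrti",
        "p_rupture_lrti",
        "p_fail_lrti",
    )
    _FEES = tuple(
        f"fee_{x}"
        for x in (
            "physician_trap",
            "anesthesia_trap",
            "facility_trap",
            "hand_therapy_trap",
            "physician_lrti",
            "anesthesia_lrti",
            "facility_lrti",
            "hand_therapy_lrti",
            "crps_physician",
            "repair_physician",
            "repair_anesthesia",
            "repair_hospital",
        )
    )

    def validate(self) -> "ParameterSet":
        for name in self._PROBS:
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name}={p} outside [0, 1]")
        for name in self._FEES + ("annual_wage", "days_off_trap", "days_off_lrti", "wtp"):
            if getattr(self, name) < 0.0:
                raise ValidationError(f"{name} must be non-negative")
        if self.discount_rate < 0.0:
            raise ValidationError("discount_rate must be non-negative")
        if self.life_expectancy < self.age + 1.0:
            raise ValidationError(
                f"life_expectancy {self.life_expectancy} must exceed age {self.age} by >= 1 year"
            )
        if not (EQ5D_SUPPORT[0] <= self.u_baseline <= EQ5D_SUPPORT[1]):
            raise ValidationError("u_baseline outside the EQ-5D index support")
        return self

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs).validate()

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


def apply_scenario(params: ParameterSet, scenario: Mapping[str, object]) -> ParameterSet:
    """Apply a named scenario (a mapping of parameter overrides) to a base set.

    Values may be plain numbers or ``{"offset_from": <param>, "offset": <x>}``
    to express overrides relative to another parameter, e.g. setting the LRTI
    utility gain to 0.01 above the trapeziectomy gain.
    """
    overrides: dict[str, float] = {}
    for name, value in scenario.items():
        if name not in ParameterSet.names():
            raise ConfigError(f"scenario refers to unknown parameter {name!r}")
        if isinstance(value, Mapping):
            ref = value.get("offset_from")
            if ref not in ParameterSet.names():
                raise ConfigError(f"scenario offset_from unknown parameter {ref!r}")
            overrides[name] = getattr(params, ref) + float(value.get("offset", 0.0))
        else:
            overrides[name] = float(value)
    return params.replace(**overrides)


# ---------------------------------------------------------------------------
# Study design (population / trial inputs for the VOI stack)
# ---------------------------------------------------------------------------


@dataclass
class StudyDesign:
    """Population and trial-cost assumptions for the value-of-information stack."""

    annual_cases: float = 40_000.0
    horizon_years: int = 10
    population_discount_rate: float = 0.03
    cost_per_participant: float = 10_000.0
    sigma_individual: float = 0.30
    trial_n_grid: tuple[int, ...] = (250, 500, 750, 1000, 1250)
    #: published EVSI curve anchor used by the sigma calibration helper:
    #: {"n_per_arm": int, "evsi_per_person": USD}
    evsi_calibration: dict | None = None


@dataclass
class ModelConfig:
    """A validated base-case parameter set plus its sampling distributions."""

    base: ParameterSet
    specs: dict[str, DistributionSpec]
    study: StudyDesign = field(default_factory=StudyDesign)
    scenarios: dict[str, dict] = field(default_factory=dict)

    def scenario(self, name: str) -> ParameterSet:
        if name not in self.scenarios:
            raise ConfigError(f"unknown scenario {name!r}")
        return apply_scenario(self.base, self.scenarios[name])

    @property
    def uncertain(self) -> dict[str, DistributionSpec]:
        """Specs that actually vary (non-point) — the PSA sampling space."""
        return {k: s for k, s in self.specs.items() if not s.is_point}


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------


def _parse_entry(name: str, entry) -> tuple[float, DistributionSpec]:
    if isinstance(entry, (int, float)):
        base = float(entry)
        return base, build_distribution("point", base, base, base)
    if not isinstance(entry, Mapping) or "base" not in entry:
        raise ConfigError(f"parameter {name!r} must be a number or a mapping with 'base'")
    base = float(entry["base"])
    family = entry.get("family", "point")
    low = float(entry.get("low", base))
    high = float(entry.get("high", base))
    support = tuple(entry["support"]) if "support" in entry else None
    try:
        spec = build_distribution(family, base, low, high, support)
    except ValidationError as exc:
        raise ValidationError(f"parameter {name!r}: {exc}") from exc
    return base, spec


def _config_from_mapping(raw: Mapping) -> ModelConfig:
    if "parameters" not in raw:
        raise ConfigError("missing top-level key 'parameters'")
    required = set(ParameterSet.names())
    given = raw["parameters"]
    missing = required - set(given)
    if missing:
        raise ConfigError(f"missing parameter keys: {sorted(missing)}")
    unknown = set(given) - required
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")

    bases: dict[str, float] = {}
    specs: dict[str, DistributionSpec] = {}
    for name, entry in given.items():
        bases[name], specs[name] = _parse_entry(name, entry)
    base = ParameterSet(**bases).validate()

    study_raw = dict(raw.get("study", {}))
    if "trial_n_grid" in study_raw:
        study_raw["trial_n_grid"] = tuple(int(n) for n in study_raw["trial_n_grid"])
    study = StudyDesign(**study_raw)
    scenarios = {str(k): dict(v) for k, v in dict(raw.get("scenarios", {})).items()}
    return ModelConfig(base=base, specs=specs, study=study, scenarios=scenarios)


def load_model_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML model configuration.

    Raises :class:`ConfigError` for missing/unknown keys and
    :class:`ValidationError` for invariant violations (e.g. low > high).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path} did not parse to a mapping")
    return _config_from_mapping(raw)


def load_default_config() -> ModelConfig:
    """The packaged base-case configuration (2020 US fee schedule inputs)."""
    ref = resources.files("cmcvoi.data").joinpath("base_case.yaml")
    raw = yaml.safe_load(ref.read_text())
    return _config_from_mapping(raw)


def default_config_path() -> Path:
    """Filesystem path of the packaged base-case configuration."""
    return Path(str(resources.files("cmcvoi.data").joinpath("base_case.yaml")))


def write_model_config(config: ModelConfig, path: str | Path) -> None:
    """Write a config back to YAML; round-trips exactly through load_model_config."""
    raw = {
        "parameters": {k: s.to_dict() for k, s in config.specs.items()},
        "study": {
            "annual_cases": config.study.annual_cases,
            "horizon_years": config.study.horizon_years,
            "population_discount_rate": config.study.population_discount_rate,
            "cost_per_participant": config.study.cost_per_participant,
            "sigma_individual": config.study.sigma_individual,
            "trial_n_grid": list(config.study.trial_n_grid),
            "evsi_calibration": config.study.evsi_calibration,
        },
        "scenarios": config.scenarios,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Monte Carlo draws
# ---------------------------------------------------------------------------


@dataclass
class ParameterDraws:
    """A rectangular matrix of sampled parameter values (one row per draw)."""

    table: pd.DataFrame
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.table)

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def sample_parameter_draws(
    specs: Mapping[str, DistributionSpec],
    n_draws: int,
    seed: int,
) -> ParameterDraws:
    """Draw independent samples of every parameter, parameter-major for reproducibility.

    The joint constraint ``life_expectancy >= age + 1`` is enforced by
    rejection: offending pairs are redrawn from their marginals, which leaves
    the marginals untouched whenever the constraint region has full measure
    (as with the packaged ranges, where ages top out 18 years below the
    lowest life expectancy).
    """
    if n_draws < 0:
        raise ValidationError("n_draws must be >= 0")
    rng = np.random.default_rng(seed)
    cols = {name: spec.sample(rng, n_draws) for name, spec in specs.items()}

    if "age" in cols and "life_expectancy" in cols and n_draws:
        age_spec, le_spec = specs["age"], specs["life_expectancy"]
        for _ in range(1000):
            bad = cols["life_expectancy"] < cols["age"] + 1.0
            if not bad.any():
                break
            k = int(bad.sum())
            cols["age"][bad] = age_spec.sample(rng, k)
            cols["life_expectancy"][bad] = le_spec.sample(rng, k)
        else:
            raise ValidationError("could not satisfy life_expectancy >= age + 1 by rejection")

    # keep n_draws rows even when every parameter is a point mass
    table = pd.DataFrame(cols, index=pd.RangeIndex(n_draws))
    return ParameterDraws(table=table, seed=seed)
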