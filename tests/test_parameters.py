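"""Distribution construction, config I/O and Monte Carlo draw properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from cmcvoi.parameters import (
    ConfigError,
    DistributionSpec,
    ParameterSet,
    ValidationError,
    apply_scenario,
    build_distribution,
    load_model_config,
    sample_parameter_draws,
    write_model_config,
)


class TestBuildDistribution:
    def test_beta_method_of_moments(self):
        """Beta hyperparameters must reproduce mean=base, sd=quarter-range.

        Expected alpha/beta frozen from solving the moment equations for the
        trapeziectomy CRPS rate (mean 0.029, sd 0.01975) and verified by
        numerical integration of the resulting density.
        """
        spec = build_distribution("beta", 0.029, 0.016, 0.095)
        a, b = spec.beta_ab
        assert a == pytest.approx(2.0645, abs=5e-4)
        assert b == pytest.approx(69.126, abs=5e-3)
        # independent check: integrate the density for its first two moments
        pdf = stats.beta(a, b).pdf
        m1, _ = integrate.quad(lambda x: x * pdf(x), 0, 1)
        m2, _ = integrate.quad(lambda x: x * x * pdf(x), 0, 1)
        assert m1 == pytest.approx(0.029, abs=1e-9)
        assert np.sqrt(m2 - m1**2) == pytest.approx((0.095 - 0.016) / 4, abs=1e-9)

    def test_truncated_normal_hyperparameters(self):
        spec = build_distribution("truncated_normal_positive", 508.39, 448.62, 702.02)
        assert spec.base == 508.39
        assert spec.sd == pytest.approx((702.02 - 448.62) / 4)
        assert spec.sd == pytest.approx(63.35)

    def test_zero_range_degenerates_to_point(self):
        spec = build_distribution("beta", 0.043, 0.043, 0.043)
        assert spec.is_point
        assert spec.sd == 0.0
        assert spec.mean() == 0.043

    def test_low_above_high_rejected(self):
        with pytest.raises(ValidationError):
            DistributionSpec("uniform", 5.0, 6.0, 4.0)

    def test_base_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            build_distribution("normal", 10.0, 0.0, 5.0)

    def test_beta_moments_infeasible(self):
        # sd^2 >= mean(1-mean): quarter-range sd of 0.25 at mean 0.5 is fine,
        # but a full [0,1] range at mean 0.05 is not
        with pytest.raises(ValidationError):
            build_distribution("beta", 0.05, 0.0, 1.0).beta_ab
        with pytest.raises(ValidationError):
            DistributionSpec("beta", 0.05, 0.0, 1.0)

    @given(
        st.tuples(
            st.floats(0.01, 0.99), st.floats(0.0, 1.0), st.floats(0.0, 1.0)
        ).filter(lambda t: min(t[1], t[2]) <= t[0] <= max(t[1], t[2]))
    )
    def test_point_iff_zero_range(self, triplet):
        base, lo, hi = triplet
        spec = build_distribution("uniform", base, min(lo, hi), max(lo, hi))
        assert spec.is_point == (min(lo, hi) == max(lo, hi))


class TestSampling:
    def test_same_seed_reproduces_bitwise(self, cfg):
        d1 = sample_parameter_draws(cfg.uncertain, 500, seed=42)
        d2 = sample_parameter_draws(cfg.uncertain, 500, seed=42)
        assert d1.table.equals(d2.table)

    def test_zero_draws(self, cfg):
        d = sample_parameter_draws(cfg.uncertain, 0, seed=0)
        assert d.n_draws == 0

    def test_sample_means_match_analytic(self, cfg):
        """Empirical mean of 50k draws within 3 SE of the analytic mean."""
        n = 50_000
        draws = sample_parameter_draws(cfg.uncertain, n, seed=7)
        for name, spec in cfg.uncertain.items():
            x = draws.column(name)
            target = spec.mean()
            se = x.std(ddof=1) / np.sqrt(n)
            assert abs(x.mean() - target) < 3 * se, name

    def test_truncation_shift_negligible_for_fees(self, cfg):
        """Truncating fee normals at 0 moves the mean by < 0.1% of base."""
        for name, spec in cfg.uncertain.items():
            if spec.family == "truncated_normal_positive" and name.startswith("fee_"):
                assert abs(spec.mean() - spec.base) < 1e-3 * spec.base, name

    def test_support_bounds(self, cfg):
        draws = sample_parameter_draws(cfg.uncertain, 20_000, seed=3)
        for name, spec in cfg.uncertain.items():
            x = draws.column(name)
            if spec.family == "beta":
                assert ((x >= 0) & (x <= 1)).all(), name
            elif spec.family == "truncated_normal_positive":
                assert (x > 0).all(), name
            elif spec.family == "uniform":
                assert ((x >= spec.low) & (x <= spec.high)).all(), name
            if spec.support is not None:
                assert ((x >= spec.support[0]) & (x <= spec.support[1])).all(), name

    def test_life_expectancy_exceeds_age(self, cfg):
        draws = sample_parameter_draws(cfg.uncertain, 10_000, seed=5)
        assert (draws.column("life_expectancy") >= draws.column("age") + 1.0).all()

    def test_life_expectancy_constraint_rejection(self):
        # overlapping ranges: the constraint actually binds and must hold
        specs = {
            "age": build_distribution("uniform", 62, 60, 80),
            "life_expectancy": build_distribution("uniform", 75, 65, 90),
        }
        draws = sample_parameter_draws(specs, 5000, seed=9)
        assert (draws.column("life_expectancy") >= draws.column("age") + 1.0).all()


class TestConfig:
    def test_default_config_base_values(self, cfg):
        assert cfg.base.discount_rate == 0.03
        assert cfg.base.annual_wage == 51_960
        assert cfg.base.days_off_trap == 30
        assert cfg.base.wtp == 100_000
        assert cfg.base.p_fail_cons == 1.0
        assert cfg.specs["discount_rate"].is_point

    def test_roundtrip(self, cfg, tmp_path):
        path = tmp_path / "cfg.yaml"
        write_model_config(cfg, path)
        back = load_model_config(path)
        assert back.base == cfg.base
        assert back.specs == cfg.specs
        assert back.study == cfg.study

    def test_missing_key_names_it(self, cfg, tmp_path):
        import yaml

        raw = {"parameters": {k: s.to_dict() for k, s in cfg.specs.items()}}
        del raw["parameters"]["annual_wage"]
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(raw))
        with pytest.raises(ConfigError, match="annual_wage"):
            load_model_config(path)

    def test_invalid_range_is_validation_error(self, cfg, tmp_path):
        import yaml

        raw = {"parameters": {k: s.to_dict() for k, s in cfg.specs.items()}}
        raw["parameters"]["du_trap"] = {"base": 0.16, "low": 0.19, "high": 0.14, "family": "normal"}
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(raw))
        with pytest.raises(ValidationError, match="du_trap"):
            load_model_config(path)

    def test_all_point_config(self, cfg, tmp_path):
        import yaml

        raw = {
            "parameters": {
                k: {"base": s.base, "low": s.base, "high": s.base, "family": s.family}
                for k, s in cfg.specs.items()
            }
        }
        path = tmp_path / "pt.yaml"
        path.write_text(yaml.safe_dump(raw))
        back = load_model_config(path)
        assert all(s.is_point for s in back.specs.values())
        assert back.uncertain == {}

    def test_scenario_offset(self, cfg):
        p = cfg.scenario("lrti_gain_plus_001")
        assert p.du_lrti == pytest.approx(p.du_trap + 0.01)
        with pytest.raises(ConfigError):
            cfg.scenario("nope")
        with pytest.raises(ConfigError):
            apply_scenario(cfg.base, {"not_a_param": 1.0})

    def test_parameter_set_validation(self):
        with pytest.raises(ValidationError):
            ParameterSet(p_crps_trap=1.5).validate()
        with pytest.raises(ValidationError):
            ParameterSet(fee_crps_physician=-1.0).validate()
        with pytest.raises(ValidationError):
            ParameterSet(age=86.0, life_expectancy=86.5).validate()
        with pytest.raises(ValidationError):
            ParameterSet(discount_rate=-0.01).validate()
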