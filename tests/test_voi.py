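"""EVPI/EVPPI/EVSI/ENBS estimators against oracles and each other."""

import numpy as np
import pytest
from scipy import stats

import cmcvoi
from cmcvoi.psa import run_psa
from cmcvoi.voi import (
    GAIN_PARAMS,
    PopulationSpec,
    TrialDesign,
    calibrate_sigma_individual,
    effective_population,
    enbs,
    evpi,
    evpi_curve,
    evpi_from_nb,
    evppi_gains,
    evppi_nested,
    evppi_regression,
    evsi,
    evsi_curve,
)


def _normal_evpi(mu, sigma):
    """Closed form for a two-strategy decision with normal incremental NB."""
    t = abs(mu) / sigma
    return sigma * stats.norm.pdf(t) - abs(mu) * stats.norm.cdf(-t)


class TestEvpi:
    def test_enumeration_example(self):
        """NB_A in {10, 0} equiprobable vs NB_B = 4: E[max]=7, max E=5, EVPI=2."""
        nb = np.array([[10.0, 4.0], [0.0, 4.0]])
        assert evpi_from_nb(nb) == pytest.approx(2.0)

    def test_no_uncertainty_gives_zero(self):
        nb = np.tile([5.0, 3.0, 1.0], (100, 1))
        assert evpi_from_nb(nb) == 0.0

    @pytest.mark.parametrize("mu,sigma", [(0.0, 1.0), (1.0, 1.0), (-2.0, 1.5), (5.0, 10.0)])
    def test_matches_closed_form_normal_oracle(self, mu, sigma):
        """Monte Carlo EVPI equals sigma*phi(mu/sigma) - |mu|*Phi(-|mu|/sigma)
        on constructed two-strategy instances, within 3 MC standard errors."""
        rng = np.random.default_rng(12345)
        n = 400_000
        delta = mu + sigma * rng.standard_normal(n)
        nb = np.column_stack([np.zeros(n), delta])
        est = evpi_from_nb(nb)
        truth = _normal_evpi(mu, sigma)
        se = np.maximum(delta, 0.0).std(ddof=1) / np.sqrt(n) + sigma / np.sqrt(n)
        assert abs(est - truth) < 3 * se

    def test_model_evpi_positive_and_stable(self, cfg, psa20):
        v = evpi(psa20, 100_000)
        assert v > 0
        curve = evpi_curve(psa20, [50_000, 100_000, 200_000])
        assert (curve["evpi_per_person"] > 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evpi_from_nb(np.empty((0, 3)))


class TestEvppi:
    def test_full_subset_equals_evpi(self, cfg, psa20):
        """Perfect information on every uncertain parameter is perfect information."""
        full = tuple(cfg.uncertain)
        est = evppi_nested(cfg, full, n_outer=4000, n_inner=1, seed=2)
        ref = evpi(psa20, cfg.base.wtp)
        assert est == pytest.approx(ref, rel=0.12)

    def test_inert_parameter_has_no_value(self, cfg):
        """Unresolved-pain probability enters neither costs nor utilities when
        the failure decrement is zero, so its EVPPI is ~0."""
        est = evppi_nested(cfg, ("p_fail_trap",), n_outer=200, n_inner=500, seed=3)
        assert abs(est) < 50.0

    def test_unknown_subset_rejected(self, cfg, psa20):
        with pytest.raises(ValueError):
            evppi_nested(cfg, ("not_a_param",))
        with pytest.raises(ValueError):
            evppi_regression(psa20, ("not_a_param",), 100_000)

    def test_gain_subset_nested_vs_linear_agree(self, cfg, psa20):
        nested = evppi_nested(cfg, GAIN_PARAMS, n_outer=500, n_inner=800, seed=4)
        linear = evppi_gains(psa20, cfg, seed=4)
        assert nested == pytest.approx(linear, rel=0.15)

    def test_gain_subset_regression_agrees(self, cfg, psa20):
        reg = evppi_regression(psa20, GAIN_PARAMS, cfg.base.wtp)
        linear = evppi_gains(psa20, cfg, seed=5)
        assert reg == pytest.approx(linear, rel=0.10)

    def test_utility_gains_dominate_ranking(self, cfg, psa20):
        """The utility gains carry the largest EVPPI of any parameter."""
        gains = evppi_regression(psa20, GAIN_PARAMS, cfg.base.wtp)
        others = [p for p in cfg.uncertain if p not in GAIN_PARAMS]
        for p in others:
            assert evppi_regression(psa20, (p,), cfg.base.wtp) < gains, p


class TestEvsi:
    def test_zero_trial_zero_value(self, cfg, psa20):
        assert evsi(psa20, cfg, TrialDesign(0), seed=1) == 0.0

    def test_perfect_information_limit(self, cfg, psa20):
        """EVSI at a huge trial approaches EVPPI of the utility gains."""
        big = evsi(psa20, cfg, TrialDesign(10_000_000), n_outer=200_000, seed=6)
        ppi = evppi_gains(psa20, cfg, n_outer=200_000, seed=6)
        assert big == pytest.approx(ppi, rel=0.03)

    def test_ordering_invariant(self, cfg, psa20):
        """0 <= EVSI(n) <= EVPPI(gains) <= EVPI at every tested trial size."""
        ppi = evppi_gains(psa20, cfg, seed=7)
        vpi = evpi(psa20, cfg.base.wtp)
        slack = 150.0  # ~3 MC standard errors at 20k draws
        assert ppi <= vpi + slack
        for n in (250, 500, 1000, 100_000):
            e = evsi(psa20, cfg, TrialDesign(n), seed=7)
            assert 0.0 <= e <= ppi + slack, n

    def test_monotone_in_n_under_crn(self, cfg, psa20):
        curve = evsi_curve(psa20, cfg, [250, 500, 750, 1000, 1250], seed=8)
        e = curve["evsi_per_person"].to_numpy()
        assert (np.diff(e) > -1e-9).all()

    def test_noisier_instrument_worth_less(self, cfg, psa20):
        lo = evsi(psa20, cfg, TrialDesign(250, sigma_individual=0.15), seed=9)
        hi = evsi(psa20, cfg, TrialDesign(250, sigma_individual=0.60), seed=9)
        assert hi < lo

    def test_calibration_recovers_sigma(self, cfg, psa20):
        """Calibrating to the EVSI produced by a known sigma recovers it."""
        sigma_true = 0.35
        target = evsi(psa20, cfg, TrialDesign(250, sigma_individual=sigma_true), seed=10)
        sigma_hat = calibrate_sigma_individual(psa20, cfg, target, 250, seed=10)
        assert sigma_hat == pytest.approx(sigma_true, abs=0.005)

    def test_correlated_psa_rejected(self, cfg):
        corr = run_psa(cfg, 1000, seed=1, correlation=-0.5)
        with pytest.raises(ValueError):
            evsi(corr, cfg, TrialDesign(250), seed=1)


class TestPopulationAndEnbs:
    def test_effective_population_annuity_due(self):
        """40,000/yr over 10 years at 3%, current cohort undiscounted."""
        pop = effective_population(PopulationSpec(40_000, 10, 0.03))
        assert pop == pytest.approx(351_444, abs=1)

    def test_zero_rate_and_single_year(self):
        assert effective_population(PopulationSpec(40_000, 10, 0.0)) == 400_000
        assert effective_population(PopulationSpec(40_000, 1, 0.03)) == 40_000

    def test_enbs_identity(self):
        d = TrialDesign(250, cost_per_participant=10_000)
        assert enbs(713.0, 351_444.36, d) == pytest.approx(713.0 * 351_444.36 - 5_000_000)
        assert enbs(0.0, 351_444.36, d) == -5_000_000

    def test_enbs_linearity(self):
        d = TrialDesign(100, cost_per_participant=1000)
        base = enbs(10.0, 1000.0, d)
        assert enbs(10.0, 2000.0, d) - enbs(10.0, 1000.0, d) == pytest.approx(10.0 * 1000.0)
        assert enbs(20.0, 1000.0, d) == pytest.approx(base + 10.0 * 1000.0)
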