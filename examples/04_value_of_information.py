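"""The value-of-information stack: EVPI, EVPPI, EVSI and ENBS.

Quantifies what it would be worth to resolve the uncertainty in the model.
EVPI prices perfect knowledge of everything; EVPPI shows that essentially
all of that value sits in the two 12-month utility gains; EVSI prices a
finite two-arm trial measuring those gains, and ENBS nets off trial costs
against the value to the ~351,000 discounted future patients over 10 years.
The ENBS curve rises steeply and flattens near 1,000 patients per arm.
"""

from cmcvoi import (
    PopulationSpec,
    calibrate_sigma_individual,
    effective_population,
    evpi,
    evppi_gains,
    evsi_curve,
    load_default_config,
    run_psa,
)
from cmcvoi.voi import evpi_curve

cfg = load_default_config()
psa = run_psa(cfg, n_draws=20_000, seed=1)

print("EVPI per person across willingness-to-pay values:")
print(evpi_curve(psa, [50_000, 100_000, 150_000, 200_000]).round(0).to_string(index=False))

ppi = evppi_gains(psa, cfg, seed=1)
print(f"\nEVPPI of the two utility gains: ${ppi:,.0f}/person "
      f"({ppi / evpi(psa, 100_000):.0%} of EVPI)")

pop = effective_population(PopulationSpec(40_000, 10, 0.03))
print(f"Effective population (40,000/yr, 10 yr, 3%): {pop:,.0f} persons")

# individual-level EQ-5D change SD calibrated to the published EVSI anchor
anchor = cfg.study.evsi_calibration
sigma = calibrate_sigma_individual(
    psa, cfg, anchor["evsi_per_person"], anchor["n_per_arm"], seed=1
)
print(f"Calibrated individual-level SD: {sigma:.3f} EQ-5D units\n")

curve = evsi_curve(psa, cfg, cfg.study.trial_n_grid, sigma_individual=sigma, seed=1)
curve["enbs_millions"] = curve["enbs"] / 1e6
print("EVSI/ENBS by trial size per arm ($10,000 per participant):")
print(curve[["n_per_arm", "evsi_per_person", "trial_cost", "enbs_millions"]]
      .round(1).to_string(index=False))
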