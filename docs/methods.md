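# Methods

## The decision problem

End-stage thumb carpometacarpal (CMC) arthritis in a 62-year-old patient can
be managed three ways: continued conservative care (splints, injections),
trapeziectomy alone (CPT 25210), or trapeziectomy with ligament
reconstruction and tendon interposition (LRTI, CPT 25447). `cmcvoi`
implements a societal-perspective decision tree over these three arms,
propagates parameter uncertainty through it by Monte Carlo, and prices the
value of running a further trial comparing the two operations.

## Decision-tree model

Surgery is a single event at time zero. Each surgical arm accrues:

* **direct costs** — physician, anesthesia, facility and hand-therapy fees
  from the 2020 US Medicare fee schedule;
* **indirect costs** — lost wages during recovery,
  `annual_wage × days_off / 365`, zero if the patient is at or past
  retirement age (calendar-day proration; together with the complication
  wiring below this reconstructs the published arm totals to within a
  dollar);
* **expected complication costs** — single-level branches weighted by their
  probabilities: complex regional pain syndrome (CRPS) adds one physician
  management fee; tendon rupture adds a full repair episode (physician +
  anesthesia + hospital, CPT 26356); unresolved pain adds no cost. CRPS and
  rupture are treated as independent events.

All costs fall at time 0 and are not discounted. Conservative management
costs nothing (its clinic follow-up is assumed equal to post-operative
follow-up).

Health benefit: the 12-month EQ-5D index is assumed constant for the rest of
life. Effective utility is `u_baseline` plus the arm's utility gain
(`du_trap` = 0.16, `du_lrti` = 0.14), minus optional per-complication
decrements (default 0 — the published lifetime QALYs are reproduced exactly
by the decrement-free product, so decrements are exposed but off). QALYs are
`utility × annuity(life_expectancy − age, discount_rate)` with the annuity in
arrears, annual cycles, no half-cycle correction:

```
A(T, r) = Σ_{t=1..T} (1+r)^(−t) = (1 − (1+r)^(−T)) / r
```

evaluated via `expm1`/`log1p` for stability, and used as the continuous
extension when sampled ages make `T` non-integer. Base case: 24 years at 3%,
A = 16.9355.

Net monetary benefit at willingness to pay λ is `λ·QALY − cost`; the
base-case threshold is λ = $100,000/QALY. Incremental analysis classifies
dominance (strictly cheaper and more effective) before reporting any ICER.

## Parameter uncertainty

Each uncertain parameter carries a (base, low, high) triplet and a family:
uniform (ages), beta (complication probabilities), positive-truncated normal
(fees, wages, days off work, retirement age) or normal (utilities). Every
non-uniform family takes mean = base and **sd = (high − low)/4**. Beta
hyperparameters come from method of moments; infeasible moment combinations
raise an error. Degenerate ranges (low = high, e.g. the LRTI tendon-rupture
probability 0.043) collapse to point masses. The truncated normals are
parameterised by their pre-truncation mean/sd and truncated at 0; for the
fee parameters this moves the mean by < 0.1% (asserted in tests), but for
the annual wage (sd $60,000) the truncated mean sits well above the base
value — a property of the published range, retained as specified, and the
reason the PSA's mean cost exceeds the base-case cost.

Baseline utility is Normal(0.675, 0.135) clipped to the EQ-5D index support
[−0.594, 1]. The clipped draw may still leave `u_baseline + gain` slightly
above 1 in a minority of draws; the sum is deliberately not clamped, because
it is the population-mean utility (not an individual's) and clamping would
bias the mean QALY by ~0.007 utility and break base-case reproduction.

Age and life expectancy are uniform with the joint constraint
`life_expectancy ≥ age + 1`, enforced by rejection redraws (vacuous at the
packaged ranges, active for user configs with overlapping ranges).

A single integer seed drives all sampling (parameter-major order);
identical seeds give bit-identical draws.

## PSA, CEAC and rank correlation

The PSA (default 10,000 draws) evaluates the full tree per draw, vectorised.
The cost-effectiveness acceptability curve reports, per λ on a grid, the
fraction of draws in which each strategy has the strictly highest net
benefit, splitting ties equally so probabilities always sum to 1.

An optional sensitivity analysis induces a Spearman rank correlation
(default −0.5, user-settable; the published analysis states only that the
correlation is negative) between each arm's complication probabilities and
that arm's utility gain, by Gaussian-copula rank reordering
(Iman–Conover style): latent normal scores correlated with the anchor's
normal scores determine the new rank order of the complication draws, so all
marginals are preserved exactly; the latent Pearson coefficient is
`2 sin(πρ/6)` so the realised Spearman correlation matches the request.
With the default zero utility decrements, complications do not touch
utilities, so this correlation moves value-of-information results only
through the (small) complication costs.

## Value of information

All VOI quantities are per-person USD at λ = $100,000/QALY by default (an
EVPI curve over $50,000–$200,000 is also exported).

**EVPI** = `E[max_s NB_s] − max_s E[NB_s]` over the PSA draws.

**EVPPI** for an arbitrary subset uses two-level nested Monte Carlo
(defaults 1,000 × 1,000; outer fixes the subset, inner integrates the rest),
with a polynomial-regression single-loop estimator on the existing PSA
draws as a fast cross-check. For the subset that matters — the two utility
gains — net benefit is *linear* in the gains, so `E[NB_s | gains]` is affine
with intercept/slopes obtained exactly by re-evaluating the model on the PSA
draw matrix with the gain columns overridden; the gain-EVPPI then needs only
an outer loop over the gains' priors.

**EVSI** prices a two-arm trial (equal arms, n per arm) measuring the
12-month EQ-5D change after each operation. Priors on the two mean gains are
the PSA normals (0.16 ± 0.0125 and 0.14 ± 0.015). For each outer draw of
true gains, the observed arm means are simulated with standard error
`σ_ind/√n`, the priors are updated by conjugate normal–normal updating, and
the post-trial decision is scored by the expected net benefit at the
posterior means (exact under the linear conditional-NB decomposition). EVSI
is the mean post-trial maximum minus the no-trial maximum. The trial grid
(250–1,250 per arm) shares outer draws and noise across n (common random
numbers), making the curve smooth and monotone.

`σ_ind`, the individual-level SD of EQ-5D change scores, defaults to 0.30.
Because no individual-level dispersion is published for this registry, a
calibration helper root-finds the σ that reproduces a supplied EVSI curve
point; the packaged config anchors the calibration at the published
$713/person for a 250-per-arm trial, which lands at σ ≈ 0.234. Under common
random numbers EVSI is smooth and strictly decreasing in σ, so the root is
unique.

**Effective population** = `annual_cases × Σ_{t=0}^{H−1} (1+r)^(−t)`
(annuity-due: this year's cohort undiscounted). Defaults 40,000 cases/yr,
10 years, 3% → 351,444 persons. **ENBS** = `EVSI × population −
2 n × cost_per_participant`, with $10,000 per participant.

Perfect implementation is assumed: every future case benefits from the
post-trial decision. Complication rates are not sampled in the trial model;
the trial informs the utility gains only.

## Synthetic registry and bootstrap

The registry generator emulates the individual-level data behind the utility
inputs: per record a baseline EQ-5D index (Normal(0.675, 0.135), clipped to
the support) and a 12-month index equal to baseline plus a normal change
score with SD `σ_ind`, clipped to the support. Post-surgical EQ-5D indices
pile up at the ceiling of 1, and at these spreads roughly 30% of simulated
records are censored there — enough to drag the naive mean change ~0.065
below its location parameter. The generator therefore treats the requested
gain as the *observed-mean* estimand: it solves (quadrature over the
baseline distribution plus scalar root-finding) for the pre-censoring
location whose censored mean change equals the requested gain. Records stay
inside the EQ-5D support and the per-arm mean change is unbiased (asserted
< 0.002 in tests).

The utility-gain estimator is a nonparametric bootstrap of the mean change
score (default B = 2,000) with a percentile interval — the simplest
defensible interval given only means and CIs are published. Interim 3-/6-
month visits, loss to follow-up and tariff computation from EQ-5D dimension
profiles are not modelled; passing tests therefore show estimator
correctness under a clean censored-normal registry, not robustness to
real-registry missingness or value-set artefacts.

## Numerical and design choices

* Dollar values are rounded only in written reports; all internal arithmetic
  is full precision.
* CEAC ties split equally (measure-zero with continuous draws; matters for
  point-mass configs, where the CEAC is degenerate at the base-case
  maximiser).
* The tornado's default metric is the incremental net benefit of
  trapeziectomy vs LRTI at λ — the decision of interest. The annual wage has
  exactly zero swing on that metric because both arms take the same 30 days
  off; this is a feature of the model, not a bug.
* Nested EVPPI chunks outer×inner evaluation at ≤ 250,000 model rows per
  block to bound memory.
* Default problem sizes: 10,000 PSA draws (CLI default), 50,000 draws and
  100,000 preposterior draws in the acceptance pipeline, 1,000 × 1,000
  nested EVPPI. All are configurable.

## Known limitations

* The published EVPI of $1,503/person (reported as insensitive to λ) is not
  reproducible from the published parameter table under any simple
  distributional reading; this implementation's EVPI rises steadily with λ
  and is ~$2,800/person at λ = $100,000/QALY, driven almost entirely by the
  utility-gain priors. (Curiously, the model's EVPI at λ = $50,000/QALY is
  ~$1,500/person — one candidate reconciliation.) The estimator itself is
  verified against the closed-form normal-NB EVPI on constructed instances.
* The negative-correlation sensitivity changes VOI only marginally while
  utility decrements are zero (see above); reproducing a "+10%" effect would
  require nonzero complication decrements, whose magnitude is not published.
* A lifetime horizon with fixed life expectancy, no revision-surgery
  cascade, no age-dependent mortality, and no imperfect implementation of
  trial results.
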