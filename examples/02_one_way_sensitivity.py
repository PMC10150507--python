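"""One-way (tornado) sensitivity analysis and the utility threshold.

Sweeps every uncertain parameter across its published range, holding the
rest at base, and ranks parameters by the swing they induce in the
incremental net benefit of trapeziectomy vs LRTI. The two 12-month utility
gains dominate everything else. The threshold scenario shows how fragile
the head-to-head ranking is: a 0.01 utility edge for LRTI makes it
cost-effective at $3,233/QALY.
"""

from cmcvoi import evaluate_strategies, load_default_config, tornado
from cmcvoi.cea import breakeven_gap, incremental_analysis

cfg = load_default_config()

tab = tornado(cfg)
print("Tornado (incremental NB of trapeziectomy vs LRTI at $100k/QALY):")
print(tab.head(8).round(1).to_string(index=False))

gap = breakeven_gap(cfg)
print(f"\nBreak-even utility-gain gap (LRTI vs trapeziectomy): {gap:.2e}")

scen = cfg.scenario("lrti_gain_plus_001")
rows = incremental_analysis(list(evaluate_strategies(scen).values()))
head = next(r for r in rows if (r.strategy, r.comparator) == ("lrti", "trapeziectomy"))
print(
    f"With LRTI's gain 0.01 above trapeziectomy's: head-to-head ICER "
    f"${head.icer:,.0f}/QALY — LRTI becomes the cost-effective choice."
)
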