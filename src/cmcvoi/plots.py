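"""Optional figure outputs: CE plane, acceptability curves, ENBS curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .psa import CeacCurve, PSAResult, ce_plane_table

__all__ = ["plot_ce_plane", "plot_ceac", "plot_enbs"]

_LABELS = {
    "conservative": "Conservative management",
    "trapeziectomy": "Trapeziectomy alone",
    "lrti": "Trapeziectomy + LRTI",
}


def plot_ce_plane(psa: PSAResult, path: str | Path, wtp: float | None = None) -> None:
    """Incremental cost-effectiveness scatter vs conservative management."""
    tab = ce_plane_table(psa)
    fig, ax = plt.subplots(figsize=(6, 5))
    for s in ("trapeziectomy", "lrti"):
        ax.scatter(
            tab[f"delta_qaly_{s}"], tab[f"delta_cost_{s}"],
            s=4, alpha=0.25, label=_LABELS[s],
        )
    if wtp:
        import numpy as np

        q = np.linspace(*ax.get_xlim(), 10)
        ax.plot(q, wtp * q, "k--", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    ax.set_xlabel("Incremental QALYs vs conservative")
    ax.set_ylabel("Incremental cost (USD)")
    ax.legend(markerscale=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CeacCurve, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for s in curve.probabilities.columns:
        ax.plot(curve.wtp_grid, curve.probabilities[s], label=_LABELS.get(s, s))
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enbs(curve_table: pd.DataFrame, path: str | Path) -> None:
    """ENBS (in $M) against trial size per arm."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve_table["n_per_arm"], curve_table["enbs"] / 1e6, "o-")
    ax.set_xlabel("Trial size per arm")
    ax.set_ylabel("Expected net benefit of sampling ($M)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
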