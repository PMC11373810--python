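"""Generic run-level figures: session statistics and model diagnostics.

Saved by the pipeline into ``<run>/figures/``; they replace the visual
residual inspection step of an interactive analysis with reproducible
artifacts.  All figures are rendered with the Agg backend and deterministic
PNG metadata so identical runs produce identical bytes.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_META = {"Software": "nestcoord"}


def _save(fig, path: Path) -> None:
    fig.savefig(path, dpi=110, metadata=_META)
    plt.close(fig)


def save_summary_plots(results: pd.DataFrame, out_dir) -> list[str]:
    """Write the standard per-run figures; returns the file names created."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created = []

    inc = results[results["stage"] == "INCUBATION"]
    if not inc.empty:
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        axes[0].hist(inc["p_value"], bins=20, range=(0, 1), color="#4477aa")
        axes[0].set_xlabel("session p-value")
        axes[0].set_ylabel("sessions")
        axes[0].set_title("Incubation randomization")
        for year, sub in inc.groupby("year"):
            sub = sub.sort_values("phase")
            axes[1].scatter(
                pd.to_numeric(sub["phase"]), sub["observed_prop"], s=12, label=str(year)
            )
        axes[1].invert_xaxis()
        axes[1].set_xlabel("days before hatching")
        axes[1].set_ylabel("opposite-activity share")
        axes[1].legend(frameon=False, fontsize=8)
        fig.tight_layout()
        _save(fig, out / "incubation_overview.png")
        created.append("figures/incubation_overview.png")

    chick = results[results["stage"] == "CHICK_REARING"].dropna(subset=["index"])
    if not chick.empty:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        groups = [
            (f"{phase} {year}", sub["index"].to_numpy())
            for (phase, year), sub in chick.groupby(["phase", "year"])
        ]
        ax.violinplot([g[1] for g in groups], showmeans=True)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_xticks(range(1, len(groups) + 1), [g[0] for g in groups], fontsize=8)
        ax.set_ylabel("coordination index")
        ax.set_title("Chick rearing: short x long trip coordination")
        fig.tight_layout()
        _save(fig, out / "chick_index.png")
        created.append("figures/chick_index.png")
    return created


def save_trend_diagnostics(df: pd.DataFrame, response: str, fitted: np.ndarray, out_path) -> None:
    """Residual-vs-fitted and normal QQ panels for a fitted trend model."""
    from scipy import stats

    resid = df[response].to_numpy() - fitted
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    axes[0].scatter(fitted, resid, s=12)
    axes[0].axhline(0, color="grey", lw=0.8)
    axes[0].set_xlabel("fitted")
    axes[0].set_ylabel("residual")
    stats.probplot(resid, plot=axes[1])
    axes[1].set_title("Normal Q-Q")
    fig.tight_layout()
    _save(fig, Path(out_path))
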