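"""Four-panel design-performance figure: power, CV, active exposure, duration."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_performance"]

_PANELS = [
    ("power_pct", "(a) Power (%)"),
    ("cv_pct", "(b) Variability, CV of effect (%)"),
    ("mean_n_active", "(c) Patients under active treatment"),
    ("mean_duration", "(d) Trial duration (arbitrary units)"),
]


def plot_performance(performances, path=None, scenario: str | None = None):
    """Bar-chart comparison of designs on the four headline metrics.

    ``performances`` is a performance table (DataFrame or DesignPerformance
    list); with several scenarios, ``scenario`` selects the one to plot.
    """
    if not isinstance(performances, pd.DataFrame):
        performances = pd.DataFrame([vars(p) for p in performances])
    df = performances
    if scenario is not None:
        df = df[df["scenario"] == scenario]
    elif df["scenario"].nunique() > 1:
        raise ValueError("several scenarios present; pass scenario=...")
    fig, axes = plt.subplots(2, 2, figsize=(11, 8))
    labels = df["design"].tolist()
    for ax, (col, title) in zip(axes.ravel(), _PANELS):
        ax.bar(range(len(df)), df[col].fillna(0.0), color="#4878b0")
        ax.set_xticks(range(len(df)))
        ax.set_xticklabels(labels, rotation=30, ha="right", fontsize=8)
        ax.set_title(title, fontsize=10)
    fig.suptitle(df["scenario"].iloc[0] if len(df) else "", fontsize=11)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
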