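"""Bar charts for the model-comparison and variable-contribution reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_comparison(comparison: "pd.DataFrame", path) -> None:
    """Cross-validated Brier score per characterization (lower is better)."""
    df = comparison.sort_values("brier")
    fig, ax = plt.subplots(figsize=(7, 0.3 * len(df) + 1.5))
    ax.barh(df["characterization"], df["brier"], xerr=df["brier_sd"], color="#4878a8")
    ax.set_xlabel("cross-validated Brier score")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_contributions(contributions: "pd.DataFrame", path) -> None:
    """Brier-score increase when each adjustment variable is omitted."""
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(contributions) + 1.5))
    ax.barh(contributions["variable"], contributions["brier_delta"], color="#a85448")
    ax.set_xlabel("increase in cross-validated Brier score when omitted")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
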