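"""Diagnostic figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .engine import ORDraws  # noqa: E402


def plot_or_distribution(draws: ORDraws, path: str | Path, bins: int = 60):
    """Histogram of the bias-adjusted odds-ratio distribution."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(draws.values, bins=bins, color="#4878b0", edgecolor="white")
    ax.axvline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("adjusted odds ratio")
    ax.set_ylabel("replicates")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
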