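"""Base-vs-scenario overlay plots (the style of the headline figures)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .scenarios import RunPair  # noqa: E402

__all__ = ["plot_overlay"]


def plot_overlay(pair: RunPair, series: str, path) -> Path:
    """Overlay one series of the base and scenario runs; PNG or SVG by suffix."""
    for traj in (pair.base, pair.scenario):
        if series not in traj.series:
            raise KeyError(f"series {series!r} missing from trajectory")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(pair.base.times, pair.base.series[series], label="base", color="tab:blue")
    ax.plot(
        pair.scenario.times,
        pair.scenario.series[series],
        label=pair.name or "scenario",
        color="tab:red",
    )
    ax.set_xlabel("year")
    unit = pair.base.units.get(series, "")
    ax.set_ylabel(f"{series} [{unit}]" if unit else series)
    ax.set_title(f"{series}: base vs {pair.name or 'scenario'}")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
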