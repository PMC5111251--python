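"""Best-effort plot of the Cartesian eubiotic/dysbiotic impact plane.

The tabular output of :func:`dysbiota.impact.cartesian_plane_data` is the
contract; this image is a convenience. Harmful and harmless genera sit on the
x-axis, cumulated |Δg| on the y-axis, one panel per condition pair: upward
bars are abundance increases, downward bars decreases, so quadrant 1
(harmless up) and 3 (harmful down) are the eubiotic contributions.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

_X = {"harmless": 1.0, "harmful": -1.0}
_COLORS = {"eubiotic": "#2a7e43", "dysbiotic": "#b23a48"}


def plot_cartesian(data: pd.DataFrame, dest: str | Path) -> Path:
    """Render the quadrant plot to *dest* (PNG/SVG by extension)."""
    pairs = list(dict.fromkeys(data["condition_pair"]))
    fig, axes = plt.subplots(
        1, len(pairs), figsize=(4 * len(pairs), 4), squeeze=False, sharey=True
    )
    for ax, pair in zip(axes[0], pairs):
        sub = data[data["condition_pair"] == pair]
        for _, row in sub.iterrows():
            y = row["sum_abs_delta"]
            if row["direction"] == "decrease":
                y = -y
            ax.bar(
                _X[row["label"]], y, width=0.8,
                color=_COLORS[row["impact_class"]],
                label=row["impact_class"],
            )
        ax.axhline(0, color="black", lw=0.8)
        ax.axvline(0, color="black", lw=0.8)
        ax.set_xticks([-1, 1], ["harmful", "harmless"])
        ax.set_title(pair)
        ax.set_ylabel("cumulated |Δg| (increase ↑ / decrease ↓)")
    handles, labels = axes[0][0].get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    fig.legend(seen.values(), seen.keys(), loc="upper right")
    fig.tight_layout()
    dest = Path(dest)
    fig.savefig(dest, dpi=150)
    plt.close(fig)
    return dest
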