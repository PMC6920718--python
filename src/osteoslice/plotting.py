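"""Mean ± SE profile curves with a p-value heat-map strip.

The rendering mirrors the conventional presentation of slice-wise group
comparisons: both group means with SE envelopes, the |difference| curve
colour-coded by sign, and a horizontal band strip along the bottom where
each 1%-grid cell is coloured by significance band (black NS, blue
.05 > p ≥ .01, green .01 > p ≥ .001, yellow .001 > p ≥ .0001, red
p < .0001).
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .group_stats import GroupResult

BAND_COLORS = {"NS": "black", "p05": "tab:blue", "p01": "tab:green",
               "p001": "gold", "p0001": "tab:red"}


def plot_group_profile(result: GroupResult, path=None, *,
                       label_a: str = "Control", label_b: str = "Test"):
    """Render one parameter's group comparison; optionally save to file."""
    fig, (ax, axp) = plt.subplots(
        2, 1, figsize=(7, 4.5), sharex=True,
        gridspec_kw={"height_ratios": [12, 1], "hspace": 0.05})
    x = result.grid_percent
    ax.plot(x, result.mean_a, color="tab:blue", label=label_a)
    ax.fill_between(x, result.mean_a - result.se_a, result.mean_a + result.se_a,
                    color="tab:blue", alpha=0.25, linewidth=0)
    ax.plot(x, result.mean_b, color="tab:red", label=label_b)
    ax.fill_between(x, result.mean_b - result.se_b, result.mean_b + result.se_b,
                    color="tab:red", alpha=0.25, linewidth=0)
    pos = result.diff >= 0
    ax.plot(x, np.abs(result.diff), color="tab:green", linestyle="--",
            label=f"|{label_a} − {label_b}|")
    if (~pos).any():
        ax.plot(x[~pos], np.abs(result.diff)[~pos], color="darkgoldenrod",
                linestyle="--")
    ax.set_ylabel(result.parameter_name)
    ax.legend(frameon=False, fontsize=8)

    colors = [BAND_COLORS[b] for b in result.band]
    axp.bar(x, np.ones_like(x), width=x[1] - x[0], color=colors, align="center")
    axp.set_ylim(0, 1)
    axp.set_yticks([])
    axp.set_xlabel("bone length (%)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return path
    return fig
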