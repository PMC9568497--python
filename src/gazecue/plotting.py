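"""Minimal plots for the standard outputs (rate curves, cueing effects,
direction density maps). Each function draws on a provided or fresh Axes and
returns it, so figures compose the usual matplotlib way."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np


def plot_rate_curve(curve, ax=None, label=None):
    """Microsaccade rate over time with its across-subject 95% band."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.bin_centers_ms, curve.rate_hz, label=label)
    ax.fill_between(curve.bin_centers_ms, curve.ci_low, curve.ci_high,
                    alpha=0.3)
    ax.set_xlabel(f"time from {curve.anchor} (ms)")
    ax.set_ylabel("microsaccade rate (Hz)")
    if label:
        ax.legend()
    return ax


def plot_cueing_effects(group_effects, measure="delta_dprime", ax=None):
    """Bar chart of mean valid-minus-invalid effects per condition x SOA."""
    if ax is None:
        _, ax = plt.subplots()
    sub = group_effects[group_effects["measure"] == measure]
    labels = [f"{c}\n{s} ms" for c, s in zip(sub["condition"], sub["soa_ms"])]
    x = np.arange(len(sub))
    ax.bar(x, sub["mean"], yerr=sub["se"], capsize=3)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(x, labels, fontsize=8)
    ax.set_ylabel(measure)
    return ax


def plot_density_map(dmap, ax=None):
    """Cue-mirrored displacement density (+x is toward the cue)."""
    if ax is None:
        _, ax = plt.subplots()
    extent = [dmap.x_edges_deg[0], dmap.x_edges_deg[-1],
              dmap.y_edges_deg[0], dmap.y_edges_deg[-1]]
    ax.imshow(dmap.density.T, origin="lower", extent=extent, cmap="gray_r",
              aspect="equal")
    ax.axvline(0.0, color="tab:red", lw=0.5)
    ax.set_xlabel("horizontal displacement toward cue (deg)")
    ax.set_ylabel("vertical displacement (deg)")
    return ax
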