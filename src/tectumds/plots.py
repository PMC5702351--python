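"""Polar plots of tuning curves and population summaries."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def _close(theta, r):
    return np.append(theta, theta[0]), np.append(r, r[0])


def polar_tuning(directions_deg, curves: dict, path, title: str = None):
    """Overlayed polar plot of normalized tuning curves (label -> values)."""
    fig, ax = plt.subplots(subplot_kw=dict(projection="polar"), figsize=(4, 4))
    theta = np.deg2rad(np.asarray(directions_deg, dtype=float))
    for label, vals in curves.items():
        t, v = _close(theta, np.asarray(vals, dtype=float))
        ax.plot(t, v, label=str(label))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    if title:
        ax.set_title(title)
    if len(curves) > 1:
        ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=7)
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
    return path


def polar_population(summary, path):
    """Mean +/- 1 SD normalized response per subtype, one panel each."""
    labels = sorted(summary.mean_curves)
    fig, axes = plt.subplots(1, max(len(labels), 1), figsize=(3.2 * max(len(labels), 1), 3.2),
                             subplot_kw=dict(projection="polar"))
    axes = np.atleast_1d(axes)
    theta = np.deg2rad(summary.directions)
    for ax, lab in zip(axes, labels):
        m, sd = summary.mean_curves[lab], summary.sd_curves[lab]
        t, mm = _close(theta, m)
        ax.plot(t, mm, color="k")
        ax.plot(*_close(theta, np.clip(m - sd, 0, None)), color="k", ls="--", lw=0.8)
        ax.plot(*_close(theta, m + sd), color="k", ls="--", lw=0.8)
        ax.set_theta_zero_location("N")
        ax.set_theta_direction(-1)
        ax.set_title(f"subtype {lab} (n={summary.n_cells[lab]})\n"
                     f"pref {summary.preferred_direction_deg[lab]:.0f} deg, "
                     f"DSI {summary.mean_dsi[lab]:.2f}", fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
    return path
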