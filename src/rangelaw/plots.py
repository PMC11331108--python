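"""Optional diagnostic plots: per-transform curve panels.

A panel row per candidate transform, each with the trimmed curve's points,
the OLS line and its R^2 — the visual the best-transform test is based on.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .classify import DecayClass, transform_curve
from .curves import FittingCurve


def curve_panel(curve: FittingCurve, decay: DecayClass, title: str, path) -> None:
    """Save a panel figure with one subplot per fitted transform."""
    fits = decay.fits
    fig, axes = plt.subplots(1, max(1, len(fits)), figsize=(3.2 * max(1, len(fits)), 3.0),
                             squeeze=False)
    for ax, fit in zip(axes[0], fits):
        x, y = transform_curve(curve, fit.transform)
        ax.plot(x, y, "o", ms=3, color="0.3")
        ax.plot(x, fit.intercept + fit.slope * x, "-", color="crimson", lw=1)
        ax.set_title(str(fit.transform), fontsize=9)
        ax.text(0.95, 0.95, f"$R^2$={fit.r2:.3f}", ha="right", va="top",
                transform=ax.transAxes, fontsize=8)
    fig.suptitle(f"{title} — best: {decay.formatted}", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
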