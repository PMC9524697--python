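"""Optional matplotlib views of a report: per-level curves and backside profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import AssessmentReport, report_to_frame


def plot_level_curves(report: AssessmentReport, label: str | None = None):
    """R² and both area asymmetries against vertebral level (three panels)."""
    frame = report_to_frame(report)
    fig, axes = plt.subplots(3, 1, figsize=(7, 9), sharex=True)
    panels = (
        ("r_squared_full", "R$^2$ (left vs right)"),
        ("backside_area_asym", "backside area asymmetry"),
        ("lr_area_asym", "left-right area asymmetry"),
    )
    for ax, (col, title) in zip(axes, panels):
        ax.plot(frame["level"], frame[col], "o-", label=label)
        ax.set_ylabel(title)
        ax.grid(True, alpha=0.3)
    axes[-1].set_xlabel("vertebral level")
    if label:
        axes[0].legend()
    fig.tight_layout()
    return fig


def plot_backside_profiles(report: AssessmentReport, level: str):
    """Dist_VB and backside relative radius around the SP for one level."""
    s = report.level(level)
    n = len(s.rad_back_right)
    offsets = range(n)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    ax1.plot([-o for o in offsets], s.dist_vb_left, "o-", label="left (SP to BLSP)")
    ax1.plot(list(offsets), s.dist_vb_right, "s-", label="right (SP to BRSP)")
    ax1.set_ylabel("Dist$_{VB}$ (mm)")
    ax1.legend()
    ax1.grid(True, alpha=0.3)
    ax2.plot([-o for o in offsets], s.rad_back_left, "o-")
    ax2.plot(list(offsets), s.rad_back_right, "s-")
    ax2.set_ylabel("backside relative radius")
    ax2.set_xlabel("angular offset from SP (deg)")
    ax2.grid(True, alpha=0.3)
    fig.suptitle(f"backside profiles at {level}")
    fig.tight_layout()
    return fig
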