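"""Diagnostic figures: waveform overlays, hysteresis loops, Bland-Altman panels."""

from __future__ import annotations

import numpy as np


def waveform_overlay(ax, true_pulse, est_pulse, fs: float, ylabel: str = "P [mmHg]"):
    """True (blue) vs estimated (red) pulse on one axis."""
    t = np.arange(len(true_pulse)) / fs
    ax.plot(t, true_pulse, color="tab:blue", label="true")
    ax.plot(np.arange(len(est_pulse)) / fs, est_pulse, color="tab:red", label="estimated")
    ax.set_xlabel("time [s]")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    return ax


def loop_overlay(ax, pressure_true, strain_true, pressure_est, strain_est,
                 beta_true=None, beta_est=None):
    """Pressure-strain hysteresis loops with optional regression slopes."""
    ax.plot(strain_true, pressure_true, color="tab:blue", label="true")
    ax.plot(strain_est, pressure_est, color="tab:red", label="estimated")
    for strain, pressure, beta, style in (
        (strain_true, pressure_true, beta_true, "--"),
        (strain_est, pressure_est, beta_est, ":"),
    ):
        if beta is not None:
            e = np.array([np.min(strain), np.max(strain)])
            p = np.mean(pressure) + beta * (e - np.mean(strain))
            ax.plot(e, p, style, color="black", linewidth=1)
    ax.set_xlabel("strain [%]")
    ax.set_ylabel("P [mmHg]")
    ax.legend(frameon=False)
    return ax


def bland_altman_panel(ax, true_values, est_values, label: str):
    """Differences (true − estimated) against means, with LOA lines."""
    from .evaluation import bland_altman

    t = np.asarray(true_values, dtype=float)
    e = np.asarray(est_values, dtype=float)
    ba = bland_altman(t, e)
    ax.scatter((t + e) / 2.0, t - e, s=12, color="tab:blue", alpha=0.7)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="black", linewidth=1)
    ax.set_xlabel(f"mean {label}")
    ax.set_ylabel(f"difference {label}")
    return ax


def evaluation_figure(report, out_path=None):
    """Four Bland-Altman panels (SBP, DBP, D_max, D_min) from an EvalReport."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.per_subject
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    panels = [
        ("SBP [mmHg]", "sbp_true", "sbp_est"),
        ("DBP [mmHg]", "dbp_true", "dbp_est"),
        ("D_max [cm]", "dmax_true", "dmax_est"),
        ("D_min [cm]", "dmin_true", "dmin_est"),
    ]
    for ax, (label, tc, ec) in zip(axes.ravel(), panels):
        bland_altman_panel(ax, df[tc], df[ec], label)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
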