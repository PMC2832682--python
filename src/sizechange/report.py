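"""Text reports and figures for fitted results.

Confusion results render as a per-condition bar chart with 1-MADC error
bars and a dashed reference line at confusion 1 (the image-only boundary);
noise estimates render as per-cue σ bars.  Plots are optional and never
load-bearing; the tidy CSV tables are the primary output.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "confusion_table",
    "noise_table",
    "format_confusion_report",
    "format_noise_report",
    "plot_confusion",
    "plot_noise",
]


def confusion_table(results) -> pd.DataFrame:
    """Tidy one-row-per-condition table of ConfusionResults."""
    rows = []
    for res in results:
        rows.append(
            {
                "condition": res.condition.label,
                "confusion": res.confusion,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "madc_se": res.madc_se,
                "boundary_slope": res.boundary.slope_k,
                "boundary_intercept_mm_s": res.boundary.intercept,
                "n_bootstrap": len(res.bootstrap_confusions),
                "n_bootstrap_failed": res.n_bootstrap_failed,
            }
        )
    return pd.DataFrame(rows)


def noise_table(estimates) -> pd.DataFrame:
    rows = []
    for est in estimates:
        rows.append(
            {
                "condition": est.condition.label,
                "cue": "haptic" if est.condition.haptic else "binocular",
                "sigma_mm_s": est.sigma,
                "madc_se_mm_s": est.madc_se,
                "jnd_approaching_mm_s": est.per_standard_jnds[0],
                "jnd_receding_mm_s": est.per_standard_jnds[1],
                "n_bootstrap": len(est.bootstrap_sigmas),
            }
        )
    return pd.DataFrame(rows)


def format_confusion_report(results) -> str:
    lines = [
        "Size-change confusion by distance-cue condition",
        "(1 = image-only boundary, 0 = veridical size judgments)",
        "",
    ]
    for res in results:
        lines.append(
            f"  {res.condition.label}: confusion = {res.confusion:6.3f} "
            f"+/- {res.madc_se:.3f} (MADC), 95% CI "
            f"[{res.ci_low:.3f}, {res.ci_high:.3f}]"
        )
    return "\n".join(lines) + "\n"


def format_noise_report(estimates) -> str:
    lines = ["Distance-change cue noise (sigma, mm/s)", ""]
    for est in estimates:
        cue = "haptic" if est.condition.haptic else "binocular"
        lines.append(
            f"  {est.condition.label} ({cue}): sigma = {est.sigma:6.2f} "
            f"+/- {est.madc_se:.2f} mm/s (MADC); per-standard JNDs "
            f"{est.per_standard_jnds[0]:.2f}, {est.per_standard_jnds[1]:.2f}"
        )
    return "\n".join(lines) + "\n"


def plot_confusion(results, path) -> None:
    """Bar chart of confusion per condition with 1-MADC error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [r.condition.label for r in results]
    values = [r.confusion for r in results]
    errors = [r.madc_se for r in results]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(labels, values, yerr=errors, capsize=4, color="0.7", edgecolor="k")
    ax.axhline(1.0, ls="--", c="k", lw=1, label="image-only boundary")
    ax.axhline(0.0, ls=":", c="k", lw=1)
    ax.set_ylabel("size-change confusion")
    ax.set_xlabel("distance-cue condition")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_noise(estimates, path) -> None:
    """Bar chart of single-cue noise sigma with 1-MADC error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = ["haptic" if e.condition.haptic else "binocular" for e in estimates]
    values = [e.sigma for e in estimates]
    errors = [e.madc_se for e in estimates]
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.bar(labels, values, yerr=errors, capsize=4, color=["0.8", "0.4"][: len(labels)])
    ax.set_ylabel("cue noise sigma (mm/s)")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
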