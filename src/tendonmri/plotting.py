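"""Plot helpers: ratio-scale Bland–Altman plots and level-shift line plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .stats import BlandAltmanResult  # noqa: E402


def bland_altman_plot(result: BlandAltmanResult, path: str | Path,
                      title: str = "") -> None:
    """Per-pair ratio vs pair geometric mean on a log-scaled y axis, with
    the mean ratio and the 95% limits of agreement as horizontal lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.pair_means, result.ratios, s=12, alpha=0.6)
    for y, style in ((result.mean_ratio, "-"), (result.loa_lower, "--"),
                     (result.loa_upper, "--")):
        ax.axhline(y, color="tab:red", linestyle=style, linewidth=1)
    ax.set_yscale("log")
    ax.set_xlabel("pair mean (geometric)")
    ax.set_ylabel("ratio method A / method B")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def level_shift_plot(samples: pd.DataFrame, path: str | Path) -> None:
    """Per-subject maximum-level shift (mm) over examination time points;
    positive values are shifts toward proximal."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for subject, grp in samples.groupby("subject_id"):
        ax.plot(grp["time_point"], grp["level_shift_mm"], marker="o",
                label=str(subject))
    ax.axhline(0, color="grey", linewidth=0.8)
    ax.set_xlabel("examination time point")
    ax.set_ylabel("shift of maximum lesion level (mm, + = proximal)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def study_plots(results: dict, output_dir: str | Path) -> None:
    """Standard figure set for a full pipeline run."""
    from .stats import bland_altman_log

    out = Path(output_dir)
    roi = results.get("roi_comparison")
    if roi is not None:
        for roi_type in ("circle_max", "circle_1mm2"):
            ba = bland_altman_log(roi.samples[roi_type], roi.samples["whole"])
            bland_altman_plot(ba, out / f"bland_altman_{roi_type}.png",
                              title=f"{roi_type} vs whole-lesion SI")
    csa = results.get("csa_study")
    if csa is not None:
        level_shift_plot(csa.samples, out / "level_shift.png")
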