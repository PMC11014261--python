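"""Figure rendering: valence timelines with attention banding, regression
overlays and juror-count-vs-correlation-threshold curves.

Every figure is written together with the tabular data behind it so the
numbers stay inspectable without the image.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .inference import fit_segment_trend
from .session import InsufficientDataError, attention_band, smooth_series

__all__ = ["plot_valence_timeline", "plot_threshold_curve"]

_BAND_COLORS = {"attentive": "tab:red", "intermediate": "tab:orange",
                "inattentive": "gold"}


def plot_valence_timeline(
    analysis, out_path, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Smoothed valence coloured by the smoothed-attention band, with grey
    bars between comparisons, green lines between the two sounds of each
    pair and the per-sub-segment regression lines overlaid.

    Returns the table behind the figure (timestamp, smoothed valence,
    smoothed attention, band), also written next to the image as CSV.
    """
    cfg = cfg or PipelineConfig()
    frames = pd.concat(
        [pd.concat([s.frames_first, s.frames_second]) for s in analysis.segments]
    ).sort_values("timestamp_s")
    t = frames["timestamp_s"].to_numpy()
    v = smooth_series(frames["valence"].to_numpy(), cfg.smoothing_window)
    attn = smooth_series(
        frames["attention"].to_numpy(dtype=float), cfg.smoothing_window
    )
    bands = attention_band(attn)

    fig, ax = plt.subplots(figsize=(14, 4))
    for band, color in _BAND_COLORS.items():
        mask = bands == band
        ax.plot(np.where(mask, t, np.nan), np.where(mask, v, np.nan),
                color=color, lw=1.2, label=band)
    for seg in analysis.segments:
        c = seg.comparison
        ax.axvline(c.t_start_first, color="grey", lw=2, alpha=0.5)
        ax.axvline(c.t_start_second, color="green", lw=1, alpha=0.6)
        for frames_sub in (seg.frames_first, seg.frames_second):
            try:
                fit = fit_segment_trend(frames_sub)
            except InsufficientDataError:
                continue
            ts = frames_sub["timestamp_s"].to_numpy()
            ax.plot(ts, fit.intercept + fit.slope * ts, color="k", lw=1, ls="--")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("valence")
    ax.set_title(f"{analysis.juror_id}: smoothed valence with attention banding")
    ax.legend(loc="upper right", ncol=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)

    table = pd.DataFrame(
        {"timestamp_s": t, "valence_smoothed": v,
         "attention_smoothed": attn, "band": bands}
    )
    table.to_csv(Path(out_path).with_suffix(".csv"), index=False)
    return table


def plot_threshold_curve(summary: dict, out_path) -> pd.DataFrame:
    """Number of jurors above each correlation threshold, per question and
    variant (all frames vs attentive frames only)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    rows = []
    styles = {"q1": "o-", "q2": "*-"}
    colors = {"n_all": "tab:blue", "n_filtered": "tab:red"}
    for q, curve in summary["threshold_curves"].items():
        taus = curve["threshold"]
        for key, color in colors.items():
            ax.plot(taus, curve[key], styles[q], color=color, ms=4,
                    label=f"{q} {'all' if key == 'n_all' else 'attention = 1'}")
            rows += [
                {"question": q, "variant": key[2:], "threshold": tau, "count": c}
                for tau, c in zip(taus, curve[key])
            ]
    ax.set_xlabel("correlation threshold ρ")
    ax.set_ylabel("number of jurors with ρ ≥ threshold")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    table = pd.DataFrame(rows)
    table.to_csv(Path(out_path).with_suffix(".csv"), index=False)
    return table
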