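"""Participant timeline plots: daily dosing ticks with CAS episode markers
coloured by coverage status, on the changepoint-centred time axis."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

STATUS_COLOURS = {"covered": "#2a9d8f", "uncovered": "#e76f51", "unassessable": "#8d99ae"}


def participant_timeline(panel: pd.DataFrame, episodes: pd.DataFrame, participant_id: str, ax=None):
    """Dose ticks (bottom) and CAS markers coloured by coverage (top)."""
    sub = panel[panel["participant_id"] == participant_id].sort_values("date")
    if sub.empty:
        raise ValueError(f"no panel rows for {participant_id}")
    eps = episodes[episodes["participant_id"] == participant_id]
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2.2))
    dosed = sub[sub["dose_day"] == 1]
    ax.vlines(dosed["t"], 0.0, 0.35, color="#4062bb", lw=0.8, label="PrEP dose")
    for status, colour in STATUS_COLOURS.items():
        pts = eps[eps["status"] == status]
        if len(pts):
            ax.scatter(pts["t"], [0.7] * len(pts), s=22, color=colour, label=f"CAS {status}")
    ax.axvline(0, color="black", ls="--", lw=0.8)
    ax.set_ylim(-0.05, 1.0)
    ax.set_yticks([])
    ax.set_xlabel("days since control measures (t = 0)")
    ax.set_title(participant_id)
    ax.legend(loc="upper right", fontsize=7, ncol=2, frameon=False)
    return ax


def cohort_timelines(panel, episodes, participant_ids, path=None):
    fig, axes = plt.subplots(len(participant_ids), 1, figsize=(9, 2.2 * len(participant_ids)), squeeze=False)
    for ax, pid in zip(axes[:, 0], participant_ids):
        participant_timeline(panel, episodes, pid, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
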