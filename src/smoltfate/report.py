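"""Reporting helpers: abacus detection plots and day/night activity counts."""

from __future__ import annotations

import datetime as dt

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .io import TriggerSummary
from .layout import ArrayLayout


def abacus_plot(
    records: pd.DataFrame,
    layout: ArrayLayout,
    trigger: TriggerSummary | None = None,
    path=None,
    release_time: pd.Timestamp | None = None,
):
    """Detection-time vs. receiver-station scatter for one tag.

    Stations are ordered by along-axis position; a dashed vertical line
    marks release and a red marker the estimated trigger time for
    triggered predator tags.
    """
    if records.empty:
        raise ValueError("abacus_plot requires at least one detection")
    order = [st.station_id for st in layout.stations]
    ypos = {sid: i for i, sid in enumerate(order)}
    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.scatter(
        records["timestamp"],
        [ypos[r] for r in records["receiver_id"]],
        s=8,
        color="tab:blue",
        alpha=0.6,
    )
    if release_time is not None:
        ax.axvline(release_time, linestyle="--", color="grey", lw=1)
    if trigger is not None and trigger.triggered:
        near = records.iloc[
            (records["timestamp"] - trigger.estimated_trigger_time).abs().argsort().iloc[0]
        ]
        ax.plot(
            [trigger.estimated_trigger_time],
            [ypos[near["receiver_id"]]],
            "o",
            color="red",
            ms=9,
            zorder=5,
            label="tag triggered",
        )
        ax.legend(loc="upper right")
    ax.set_yticks(range(len(order)), order)
    ax.set_xlabel("time (UTC)")
    ax.set_ylabel("station")
    tag = records["transmitter_id"].iloc[0]
    ax.set_title(f"tag {tag}")
    fig.autofmt_xdate()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig


def day_night_summary(
    records: pd.DataFrame,
    twilight_start: str | dt.time = "04:14",
    twilight_end: str | dt.time = "20:57",
) -> pd.DataFrame:
    """Detections per section split day/night by civil-twilight clock times.

    Night runs from the end of evening civil twilight to its morning
    start; the defaults are the study-period values for the site.
    """
    t_start = _clock(twilight_start)
    t_end = _clock(twilight_end)
    if records.empty:
        return pd.DataFrame(columns=["section", "day", "night"])
    tod = pd.to_datetime(records["timestamp"], utc=True).dt.time
    night = (tod >= t_end) | (tod < t_start)
    out = (
        pd.DataFrame({"section": records.get("section", "all"), "night": night})
        .groupby("section", sort=True)["night"]
        .agg(day=lambda s: int((~s).sum()), night=lambda s: int(s.sum()))
        .reset_index()
    )
    return out


def _clock(value: str | dt.time) -> dt.time:
    if isinstance(value, dt.time):
        return value
    return dt.time.fromisoformat(str(value))
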