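"""Per-tag migration metrics from detection series.

Each tag detected beyond the lake is summarised into the metric vector
both classifiers consume: detection counts, time on array, directional
speed statistics, number of reversals (direction changes between
stations), per-section residencies, and (for predator tags) hours from
release to the digestion trigger.  Directions are taken along the
migration axis: seaward is downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .io import TriggerSummary
from .layout import ArrayLayout, Section

#: nine-variable set used when the array lacks an inner-bay line and no
#: digestion sensors were deployed
VARIABLES_BASE = [
    "total_detections",
    "total_time_detected_h",
    "mean_down_speed_ms",
    "max_down_speed_ms",
    "mean_up_speed_ms",
    "max_up_speed_ms",
    "n_reversals",
    "residency_lake_h",
    "residency_estuary_h",
]
#: eleven-variable set for the extended array with predator tags
VARIABLES_EXTENDED = VARIABLES_BASE + ["time_to_trigger_h", "residency_innerbay_h"]


@dataclass(frozen=True)
class MovementEvent:
    from_station: str
    to_station: str
    departure: pd.Timestamp
    arrival: pd.Timestamp
    distance_m: float
    speed_ms: float
    direction: str  # "downstream" (seaward) or "upstream"


@dataclass
class MetricVector:
    transmitter_id: str
    total_detections: int = 0
    total_time_detected_h: float = 0.0
    mean_down_speed_ms: float = 0.0
    max_down_speed_ms: float = 0.0
    mean_up_speed_ms: float = 0.0
    max_up_speed_ms: float = 0.0
    n_reversals: int = 0
    residency_lake_h: float = 0.0
    residency_estuary_h: float = 0.0
    residency_innerbay_h: float = 0.0
    time_to_trigger_h: float = 0.0


def _event_arrays(
    records: pd.DataFrame, layout: ArrayLayout, max_speed_ms: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised event extraction: (pair start index, speed, seaward?)."""
    t = records["timestamp"].astype("int64").to_numpy()
    station_pos = {st.station_id: st.position_m for st in layout.stations}
    pos = records["receiver_id"].map(station_pos).to_numpy(dtype=float)
    if np.isnan(pos).any():
        bad = sorted(records.loc[np.isnan(pos), "receiver_id"].unique())
        raise KeyError(f"receivers absent from layout: {bad}")
    dt = np.diff(t) / 1e9
    dp = np.diff(pos)
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.abs(dp) / dt
    ok = (dp != 0) & (dt > 0) & (speed <= max_speed_ms)
    idx = np.flatnonzero(ok)
    return idx, speed[idx], dp[idx] > 0


def extract_movement_events(
    records: pd.DataFrame, layout: ArrayLayout, max_speed_ms: float = 5.0
) -> list[MovementEvent]:
    """Inter-station movement events from one transmitter's sorted records.

    One event per consecutive pair of detections at distinct stations; the
    speed is along-axis distance over elapsed time.  Zero-elapsed pairs and
    physically impossible speeds (above ``max_speed_ms``) are dropped, the
    latter being the standard velocity-based quality screen on raw
    detections.
    """
    if records.empty:
        return []
    idx, speeds, seaward = _event_arrays(records, layout, max_speed_ms)
    st = records["receiver_id"].to_numpy()
    t = records["timestamp"]
    pos = {s.station_id: s.position_m for s in layout.stations}
    return [
        MovementEvent(
            from_station=str(st[i]),
            to_station=str(st[i + 1]),
            departure=t.iloc[i],
            arrival=t.iloc[i + 1],
            distance_m=abs(pos[st[i + 1]] - pos[st[i]]),
            speed_ms=float(sp),
            direction="downstream" if sea else "upstream",
        )
        for i, sp, sea in zip(idx, speeds, seaward)
    ]


def count_reversals(events: list[MovementEvent]) -> int:
    """Number of adjacent event pairs whose directions differ."""
    dirs = [e.direction for e in events]
    return int(sum(a != b for a, b in zip(dirs[:-1], dirs[1:])))


_RESIDENCY_FIELDS = {
    Section.LAKE: "residency_lake_h",
    Section.LAKE_EXIT: "residency_lake_h",
    Section.ESTUARY: "residency_estuary_h",
    Section.ESTUARY_EXIT: "residency_estuary_h",
    Section.INNER_BAY: "residency_innerbay_h",
}


def compute_metrics(
    records: pd.DataFrame,
    layout: ArrayLayout,
    trigger: TriggerSummary | None = None,
    release_time: pd.Timestamp | None = None,
) -> MetricVector:
    """Summarise one transmitter's records into a :class:`MetricVector`.

    Residency per section is the union of maximal runs of consecutive
    same-section detections (predators re-enter sections, so first-to-last
    spans would double count).  Directions with no events contribute zeros.
    ``time_to_trigger_h`` is hours from release to the estimated trigger for
    triggered tags and 0 otherwise.  The lake-exit and estuary-exit gates
    are pooled with their parent sections for residency.
    """
    if records.empty:
        raise ValueError("compute_metrics requires at least one detection")
    ids = records["transmitter_id"].unique()
    if len(ids) != 1:
        raise ValueError("records must belong to exactly one transmitter")
    records = records.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    if "section" not in records.columns:
        from .io import assign_sections

        records = assign_sections(records, layout)

    vec = MetricVector(transmitter_id=str(ids[0]))
    vec.total_detections = int(len(records))
    t = records["timestamp"]
    vec.total_time_detected_h = float((t.iloc[-1] - t.iloc[0]).total_seconds() / 3600.0)

    _, speeds, seaward = _event_arrays(records, layout, max_speed_ms=5.0)
    down, up = speeds[seaward], speeds[~seaward]
    vec.mean_down_speed_ms = float(down.mean()) if len(down) else 0.0
    vec.max_down_speed_ms = float(down.max()) if len(down) else 0.0
    vec.mean_up_speed_ms = float(up.mean()) if len(up) else 0.0
    vec.max_up_speed_ms = float(up.max()) if len(up) else 0.0
    vec.n_reversals = int(np.sum(seaward[1:] != seaward[:-1])) if len(seaward) > 1 else 0

    sec = records["section"].to_numpy()
    run_start = np.concatenate([[0], np.flatnonzero(sec[1:] != sec[:-1]) + 1])
    run_end = np.concatenate([run_start[1:] - 1, [len(sec) - 1]])
    for a, b in zip(run_start, run_end):
        field = _RESIDENCY_FIELDS.get(Section(sec[a]))
        if field is None:
            continue
        span_h = (t.iloc[int(b)] - t.iloc[int(a)]).total_seconds() / 3600.0
        setattr(vec, field, getattr(vec, field) + float(span_h))

    if trigger is not None and trigger.triggered and release_time is not None:
        vec.time_to_trigger_h = float(
            max((trigger.estimated_trigger_time - release_time).total_seconds() / 3600.0, 0.0)
        )
    return vec


def build_metric_matrix(
    vectors: list[MetricVector], variable_set: list[str] | None = None
) -> pd.DataFrame:
    """Tags x variables matrix with transmitter ids as the row index."""
    variable_set = variable_set or VARIABLES_EXTENDED
    valid = {f.name for f in fields(MetricVector)}
    unknown = [v for v in variable_set if v not in valid]
    if unknown:
        raise ValueError(f"unknown metric variables: {unknown}")
    ids = [v.transmitter_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transmitter ids in metric vectors")
    data = {var: [getattr(v, var) for v in vectors] for var in variable_set}
    return pd.DataFrame(data, index=pd.Index(ids, name="transmitter_id"))


def detected_beyond_lake(records: pd.DataFrame, layout: ArrayLayout) -> list[str]:
    """Transmitters with at least one detection at the estuary or beyond.

    Tags never heard past the lake exit carry too little movement
    information to classify and are excluded from the metric matrix.
    """
    if "section" not in records.columns:
        from .io import assign_sections

        records = assign_sections(records, layout)
    beyond = {
        Section.ESTUARY.value,
        Section.ESTUARY_EXIT.value,
        Section.INNER_BAY.value,
        Section.CLARE_ISLAND.value,
    }
    mask = records["section"].isin(beyond)
    return sorted(records.loc[mask, "transmitter_id"].unique())
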