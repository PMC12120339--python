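"""Ground-truthed synthetic acoustic-telemetry data for a smolt migration study.

Simulates a cohort of tagged salmon smolts migrating seaward through a
1-D receiver corridor (lake -> estuary -> inner bay -> island line), with

* ~2-day lake residency followed by unidirectional seaward movement, with
  at most one short foray back from the first estuary station (two
  direction changes), as live smolts show;
* section- and origin-specific predation hazard; once eaten, the tag moves
  with the predator: many direction changes (4-51 per tag), sustained
  bidirectional swimming, day-and-night activity and long lake/estuary
  residency, until the tag is expelled 0.7-45 days later;
* predator tags whose digestion sensor flips 10-62 h after ingestion and
  thereafter encodes hours-since-trigger (0.1 h quantisation); the
  temperature variant alternates digestion and temperature payloads
  (ambient ~12.7 deg C before the trigger, predator core temperature
  ~36.6 deg C after);
* co-ingestion: a new predation event may attach to an already-active
  predator, so several tags share one track;
* per-station detection probability inside a hard detection radius,
  spurious (false) detections at a Poisson rate, and a small fraction of
  tagging mortalities detected at most at one station;
* non-predation loss (the fish dies or leaves undetected and the tag goes
  silent), so apparent survival is below one even in the predator-free
  subcohort.

All randomness flows from a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import ArrayLayout, Section

HOUR_S = 3600.0
DAY_S = 86400.0


class TagType(enum.Enum):
    PLAIN = "plain"
    PREDATOR = "predator"
    PREDATOR_TEMP = "predator_temp"


class Origin(enum.Enum):
    WILD = "wild"
    RANCHED = "ranched"


@dataclass(frozen=True)
class TagSpec:
    tag_type: TagType
    interval_min_s: float
    interval_max_s: float
    tag_life_days: float
    tag_weight_g: float

    def __post_init__(self):
        if not (0 < self.interval_min_s < self.interval_max_s):
            raise ValueError("require 0 < interval_min_s < interval_max_s")
        if self.tag_life_days <= 0 or self.tag_weight_g <= 0:
            raise ValueError("tag_life_days and tag_weight_g must be positive")


#: Transmitter presets used by default (sensor type, transmit interval
#: bounds in seconds, rated life in days, weight in grams in air).
TAG_PRESETS: dict[str, TagSpec] = {
    "V7-2x": TagSpec(TagType.PLAIN, 20, 40, 69, 1.5),
    "V8-4x": TagSpec(TagType.PLAIN, 20, 40, 98, 2.0),
    "V7D-2x": TagSpec(TagType.PREDATOR, 30, 90, 100, 1.7),
    "V7DT-2x": TagSpec(TagType.PREDATOR_TEMP, 20, 40, 57, 1.7),
}


@dataclass
class FishSpec:
    fish_id: str
    origin: Origin
    fork_length_mm: float
    mass_g: float
    release_time: pd.Timestamp
    tag: TagSpec

    def __post_init__(self):
        if self.fork_length_mm < 140:
            raise ValueError("smolts under 140 mm fork length are not tagged")

    @property
    def tag_mass_ratio(self) -> float:
        return self.tag.tag_weight_g / self.mass_g


class Fate(enum.Enum):
    SMOLT = "smolt"
    PREDATED = "predated"
    TAGGING_MORTALITY = "tagging_mortality"


@dataclass
class GroundTruthFate:
    fish_id: str
    fate: Fate
    predation_time: pd.Timestamp | None = None
    predation_section: Section | None = None
    trigger_time: pd.Timestamp | None = None
    predator_id: str | None = None
    retention_end: pd.Timestamp | None = None
    predator_type: str | None = None
    loss_time: pd.Timestamp | None = None  # non-predation disappearance

    def __post_init__(self):
        if self.trigger_time is not None and self.predation_time is not None:
            if self.trigger_time <= self.predation_time:
                raise ValueError("trigger_time must follow predation_time")
        if self.retention_end is not None and self.trigger_time is not None:
            if self.retention_end <= self.trigger_time:
                raise ValueError("retention_end must follow trigger_time")


@dataclass
class Track:
    """Piecewise-linear 1-D track: seconds since release vs. along-axis metres.

    ``hidden`` lists [start, end) spans (seconds) during which the animal is
    out of detection range regardless of along-axis position (resting in
    shallow margins, hauled out), so long dwells do not rain detections.
    """

    times_s: np.ndarray
    pos_m: np.ndarray
    hidden: list[tuple[float, float]] = field(default_factory=list)

    @property
    def end_s(self) -> float:
        return float(self.times_s[-1]) if len(self.times_s) else 0.0

    def position_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times_s, self.pos_m)

    def visible_mask(self, t: np.ndarray) -> np.ndarray:
        mask = np.ones(len(t), dtype=bool)
        for a, b in self.hidden:
            mask &= ~((t >= a) & (t < b))
        return mask


@dataclass
class SmoltParams:
    #: ~2-day typical lake residency, with the wide scatter real cohorts
    #: show (a few fish linger for weeks before committing seaward)
    lake_residency_h_med: float = 40.0
    lake_residency_sdlog: float = 0.75
    lake_cruise_speed_ms: float = 0.30
    seaward_speed_mean_ms: float = 0.60
    seaward_speed_sd_ms: float = 0.20
    seaward_speed_min_ms: float = 0.20
    seaward_speed_max_ms: float = 1.30
    #: a small minority of live smolts make one foray back into the lake
    #: (roughly 2% of tagged fish across cohorts)
    reversal_prob: float = 0.03
    max_reversals: int = 2  # a single foray is two direction changes
    lake_dwell_visible_prob: float = 0.15
    station_dwell_min_h: float = 0.05
    station_dwell_max_h: float = 0.60


@dataclass
class PredatorParams:
    reversal_min: int = 4
    reversal_max: int = 51
    speed_min_ms: float = 0.80
    speed_max_ms: float = 1.60
    #: direction changes placed inside the first hours in the gut -- the
    #: post-capture hunting bout -- so even the shortest retention (0.7 d)
    #: shows predator-like movement
    early_reversals: int = 6
    early_window_h: float = 16.0
    active_span_days: float = 45.0
    dwell_visible_prob: float = 0.05
    section_occupancy: dict[Section, float] = field(
        default_factory=lambda: {
            Section.LAKE: 0.45,
            Section.ESTUARY: 0.40,
            Section.INNER_BAY: 0.15,
        }
    )


def _default_predation_hazard() -> dict[Origin, dict[Section, float]]:
    # per-hour hazard while in section; ranched fish are naive to predators
    ranched = {
        Section.LAKE: 0.0065,
        Section.LAKE_EXIT: 0.0065,
        Section.ESTUARY: 0.10,
        Section.ESTUARY_EXIT: 0.02,
        Section.INNER_BAY: 0.0,
        Section.CLARE_ISLAND: 0.0,
    }
    wild = {sec: 0.25 * r for sec, r in ranched.items()}
    return {Origin.RANCHED: ranched, Origin.WILD: wild}


def _default_loss_prob() -> dict[Section, float]:
    # probability the fish disappears (tag silent) while transiting a section
    return {
        Section.LAKE: 0.04,
        Section.LAKE_EXIT: 0.01,
        Section.ESTUARY: 0.03,
        Section.ESTUARY_EXIT: 0.03,
        Section.INNER_BAY: 0.12,
        Section.CLARE_ISLAND: 0.12,
    }


@dataclass
class MovementParams:
    smolt: SmoltParams = field(default_factory=SmoltParams)
    predator: PredatorParams = field(default_factory=PredatorParams)
    predation_hazard_per_h: dict[Origin, dict[Section, float]] = field(
        default_factory=_default_predation_hazard
    )
    loss_prob: dict[Section, float] = field(default_factory=_default_loss_prob)
    digestion_delay_h: tuple[float, float] = (10.0, 62.0)
    retention_days: tuple[float, float] = (0.7, 45.0)
    post_trigger_temp_C: tuple[float, float] = (36.6, 0.2)  # mean, sd
    ambient_temp_C: tuple[float, float] = (12.7, 0.4)
    coingestion_prob: float = 0.3
    tagging_mortality_prob: float = 0.02
    predator_type_weights: dict[str, float] = field(
        default_factory=lambda: {"mammal": 1.0}
    )

    def __post_init__(self):
        for table in self.predation_hazard_per_h.values():
            for rate in table.values():
                if rate < 0:
                    raise ValueError("predation hazard rates must be >= 0")
        for p in self.loss_prob.values():
            if not 0 <= p <= 1:
                raise ValueError("loss probabilities must be in [0, 1]")
        if not 0 <= self.coingestion_prob <= 1:
            raise ValueError("coingestion_prob must be in [0, 1]")


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(
    n_wild: int,
    n_ranched: int,
    n_predator_tags: int,
    specs: dict[str, TagSpec] | None = None,
    seed: int | np.random.Generator = 0,
    release_start: pd.Timestamp | str = "2022-04-25 00:00:00+00:00",
    release_span_days: float = 7.0,
    fl_wild: tuple[float, float] = (160.0, 12.0),
    fl_ranched: tuple[float, float] = (205.0, 15.0),
) -> list[FishSpec]:
    """Draw a tagged cohort.

    Predator tags are deployed in ranched fish only, so
    ``n_predator_tags <= n_ranched``.  Fork lengths are drawn per origin from
    truncated normal distributions (left-truncated at the 140 mm tagging
    threshold); mass follows Fulton condition ~0.9 with lognormal scatter.
    """
    if min(n_wild, n_ranched, n_predator_tags) < 0:
        raise ValueError("cohort counts must be non-negative")
    if n_predator_tags > n_ranched:
        raise ValueError("predator tags are deployed in ranched fish only")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    specs = dict(TAG_PRESETS, **(specs or {}))
    start = pd.Timestamp(release_start)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")

    fish: list[FishSpec] = []
    plan = [(Origin.WILD, "V7-2x")] * n_wild
    plan += [(Origin.RANCHED, "V7DT-2x")] * n_predator_tags
    plan += [(Origin.RANCHED, "V8-4x")] * (n_ranched - n_predator_tags)
    for i, (origin, tag_name) in enumerate(plan):
        mu, sd = fl_wild if origin is Origin.WILD else fl_ranched
        fl = 0.0
        while fl < 140.0:
            fl = rng.normal(mu, sd)
        k = 0.9 * np.exp(rng.normal(0.0, 0.08))  # Fulton condition factor
        mass = k * (fl / 10.0) ** 3 / 100.0
        release = start + pd.to_timedelta(
            rng.uniform(0, release_span_days * DAY_S), unit="s"
        )
        fish.append(
            FishSpec(
                fish_id=f"S{1000 + i}",
                origin=origin,
                fork_length_mm=float(fl),
                mass_g=float(mass),
                release_time=release.floor("s"),
                tag=specs[tag_name],
            )
        )
    return fish


# ---------------------------------------------------------------------------
# movement


def _section_boundaries(layout: ArrayLayout) -> tuple[np.ndarray, list[Section]]:
    """Along-axis bin edges between consecutive sections (midpoints)."""
    secs = layout.sections
    edges = []
    for a, b in zip(secs[:-1], secs[1:]):
        last_a = max(st.position_m for st in layout.stations_in(a))
        first_b = min(st.position_m for st in layout.stations_in(b))
        edges.append(0.5 * (last_a + first_b))
    return np.asarray(edges), secs


def section_at(pos: float | np.ndarray, layout: ArrayLayout):
    """Section of an along-axis position (vectorised)."""
    edges, secs = _section_boundaries(layout)
    idx = np.searchsorted(edges, np.asarray(pos, dtype=float), side="right")
    if np.isscalar(pos) or np.asarray(pos).ndim == 0:
        return secs[int(idx)]
    return [secs[i] for i in np.atleast_1d(idx)]


def _truncnorm(rng, mean, sd, lo, hi):
    x = rng.normal(mean, sd)
    return float(min(max(x, lo), hi))


def _smolt_track(fish: FishSpec, layout: ArrayLayout, sp: SmoltParams, rng) -> Track:
    times = [0.0]
    pos = [layout.release_position_m]
    hidden: list[tuple[float, float]] = []
    t = 0.0
    p = layout.release_position_m

    def move_to(target: float, speed: float):
        nonlocal t, p
        t += abs(target - p) / speed
        p = target
        times.append(t)
        pos.append(p)

    def dwell(duration_s: float, visible: bool):
        nonlocal t
        if duration_s <= 0:
            return
        if not visible:
            hidden.append((t, t + duration_s))
        t += duration_s
        times.append(t)
        pos.append(p)

    lake_sts = layout.stations_in(Section.LAKE)
    residency_s = float(
        np.exp(np.log(sp.lake_residency_h_med) + rng.normal(0, sp.lake_residency_sdlog))
        * HOUR_S
    )
    travel_s = sum(
        abs(b.position_m - a.position_m) / sp.lake_cruise_speed_ms
        for a, b in zip([None] + lake_sts[:-1], lake_sts)
        if a is not None
    ) + (lake_sts[0].position_m - layout.release_position_m) / sp.lake_cruise_speed_ms
    dwell_total = max(residency_s - travel_s, 0.2 * residency_s)
    shares = rng.dirichlet(np.ones(len(lake_sts)))
    for st, share in zip(lake_sts, shares):
        move_to(st.position_m, sp.lake_cruise_speed_ms)
        dwell(share * dwell_total, visible=rng.random() < sp.lake_dwell_visible_prob)

    v = _truncnorm(
        rng,
        sp.seaward_speed_mean_ms,
        sp.seaward_speed_sd_ms,
        sp.seaward_speed_min_ms,
        sp.seaward_speed_max_ms,
    )
    seaward = [st for st in layout.stations if st.section is not Section.LAKE]
    foray_done = False
    lake_exit = layout.stations_in(Section.LAKE_EXIT)
    for st in seaward:
        move_to(st.position_m, v * rng.uniform(0.85, 1.15))
        dwell(rng.uniform(sp.station_dwell_min_h, sp.station_dwell_max_h) * HOUR_S, True)
        if (
            not foray_done
            and st.section is Section.ESTUARY
            and sp.max_reversals >= 2
            and lake_exit
            and rng.random() < sp.reversal_prob
        ):
            # one short foray back to the last lake station -- a slow drift
            # landward on the flood tide -- and out again
            foray_done = True
            move_to(lake_exit[-1].position_m, 0.35 * v * rng.uniform(0.85, 1.15))
            dwell(rng.uniform(0.5, 3.0) * HOUR_S, rng.random() < 0.5)
            move_to(st.position_m, v * rng.uniform(0.85, 1.15))
    move_to(p + 2000.0, v)  # departs seaward past the outer line
    return Track(np.asarray(times), np.asarray(pos), hidden)


def _mortality_track(layout: ArrayLayout, rng) -> Track:
    """Tagging mortality: never detected, or briefly near one lake station."""
    if rng.random() < 0.5:
        return Track(np.array([0.0, HOUR_S]), np.full(2, layout.release_position_m))
    st = layout.stations_in(Section.LAKE)[0]
    dur = rng.uniform(0.5, 4.0) * HOUR_S
    return Track(
        np.array([0.0, 600.0, 600.0 + dur]),
        np.array([layout.release_position_m, st.position_m, st.position_m]),
    )


@dataclass
class _Predator:
    predator_id: str
    ptype: str
    start_s: float  # absolute seconds on the cohort clock
    track: Track  # times on the cohort clock


class CohortSimulator:
    """Simulates tracks for a cohort, sharing predator state for co-ingestion.

    All track times are kept on a single cohort clock (seconds since the
    earliest release) internally; per-fish tracks are returned on the
    fish's own release clock.
    """

    def __init__(self, layout: ArrayLayout, params: MovementParams, rng):
        self.layout = layout
        self.params = params
        self.rng = rng
        self.predators: list[_Predator] = []
        self._next_pred = 1

    # -- predator movement ------------------------------------------------

    def _predator_track(self, start_s: float, start_pos: float) -> Track:
        pp = self.params.predator
        rng = self.rng
        allowed = [
            st
            for st in self.layout.stations
            if st.section
            in (
                Section.LAKE,
                Section.LAKE_EXIT,
                Section.ESTUARY,
                Section.ESTUARY_EXIT,
                Section.INNER_BAY,
            )
        ]
        if len(allowed) < 2:
            allowed = self.layout.stations
        positions = np.array([st.position_m for st in allowed])
        occupancy = np.array(
            [pp.section_occupancy.get(st.section, 0.05) for st in allowed]
        )

        n_rev = int(rng.integers(pp.reversal_min, pp.reversal_max + 1))
        span_s = pp.active_span_days * DAY_S
        early = min(pp.early_window_h * HOUR_S, span_s)
        n_early = min(pp.early_reversals, n_rev)
        rev_times = np.sort(
            np.concatenate(
                [rng.uniform(0, early, n_early), rng.uniform(0, span_s, n_rev - n_early)]
            )
        )

        times = [0.0]
        pos = [start_pos]
        hidden: list[tuple[float, float]] = []
        t = 0.0
        idx = int(np.argmin(np.abs(positions - start_pos)))
        p = start_pos
        direction = 1 if idx < len(allowed) / 2 else -1
        for k in range(n_rev + 1):
            room = (len(allowed) - 1 - idx) if direction > 0 else idx
            if room == 0:  # at a corridor end; the next run leads away
                direction *= -1
                room = (len(allowed) - 1 - idx) if direction > 0 else idx
            # run terminus sampled ahead of the current station, weighted by
            # section occupancy: hunting sweeps cover lake <-> estuary
            ahead = (
                np.arange(idx + 1, len(allowed))
                if direction > 0
                else np.arange(0, idx)
            )
            w = occupancy[ahead]
            idx = int(rng.choice(ahead, p=w / w.sum()))
            speed = rng.uniform(pp.speed_min_ms, pp.speed_max_ms)
            t += abs(positions[idx] - p) / speed
            p = positions[idx]
            times.append(t)
            pos.append(p)
            until = rev_times[k] if k < n_rev else span_s
            if until > t:
                w = occupancy[idx] / occupancy.max()
                dwell_end = t + (until - t) * (0.5 + 0.5 * w)
                # rest near the station in <=24 h stretches, surfacing into
                # range for the last half hour of each: the tag is heard at
                # least daily while in the gut
                while t < dwell_end - 1.0:
                    seg_end = min(t + 24 * HOUR_S, dwell_end)
                    if rng.random() >= pp.dwell_visible_prob:
                        hidden.append((t, max(t, seg_end - 0.5 * HOUR_S)))
                    t = seg_end
                times.append(t)
                pos.append(p)
            direction *= -1
        return Track(np.asarray(times) + start_s, np.asarray(pos), [
            (a + start_s, b + start_s) for a, b in hidden
        ])

    @staticmethod
    def _reversals_in_window(track: Track, t0: float, t1: float) -> int:
        m = (track.times_s >= t0) & (track.times_s <= t1)
        d = np.diff(track.pos_m[m])
        d = d[d != 0]
        return int(np.sum(np.sign(d[1:]) != np.sign(d[:-1]))) if len(d) > 1 else 0

    def _assign_predator(self, t_abs: float, pos: float, retention_s: float):
        rng = self.rng
        if rng.random() < self.params.coingestion_prob:
            candidates = [
                pr
                for pr in self.predators
                if pr.start_s <= t_abs <= pr.track.end_s
                and self._reversals_in_window(pr.track, t_abs, t_abs + retention_s)
                >= self.params.predator.early_reversals
            ]
            if candidates:
                return candidates[int(rng.integers(len(candidates)))]
        weights = self.params.predator_type_weights
        kinds = sorted(weights)
        probs = np.array([weights[k] for k in kinds], dtype=float)
        ptype = kinds[int(rng.choice(len(kinds), p=probs / probs.sum()))]
        pred = _Predator(
            predator_id=f"P{self._next_pred}",
            ptype=ptype,
            start_s=t_abs,
            track=self._predator_track(t_abs, pos),
        )
        self._next_pred += 1
        self.predators.append(pred)
        return pred

    # -- per-fish simulation ----------------------------------------------

    def simulate_track(self, fish: FishSpec, t0_abs: float = 0.0) -> tuple[Track, GroundTruthFate]:
        """Simulate one fish released ``t0_abs`` seconds into the cohort clock."""
        params, layout, rng = self.params, self.layout, self.rng
        if rng.random() < params.tagging_mortality_prob:
            track = _mortality_track(layout, rng)
            return track, GroundTruthFate(fish.fish_id, Fate.TAGGING_MORTALITY)

        track = _smolt_track(fish, layout, params.smolt, rng)
        pred_time = self._draw_predation_time(track, fish.origin)
        loss_time = self._draw_loss_time(track)
        if loss_time is not None and (pred_time is None or loss_time < pred_time):
            track = _truncate(track, loss_time)
            return track, GroundTruthFate(
                fish.fish_id,
                Fate.SMOLT,
                loss_time=_ts(fish.release_time, loss_time),
            )
        if pred_time is None:
            return track, GroundTruthFate(fish.fish_id, Fate.SMOLT)

        # predation: splice the predator's shared track onto the smolt track
        delay_s = rng.uniform(*params.digestion_delay_h) * HOUR_S
        retention_s = rng.uniform(*params.retention_days) * DAY_S
        if retention_s <= delay_s + 30 * HOUR_S:
            # the tag must outlast digestion long enough for the triggered
            # payload to reach a receiver
            retention_s = delay_s + rng.uniform(30.0, 54.0) * HOUR_S
        pos_at = float(track.position_at(np.array([pred_time]))[0])
        pred = self._assign_predator(t0_abs + pred_time, pos_at, retention_s)
        section = section_at(
            float(pred.track.position_at(np.array([t0_abs + pred_time]))[0])
            if pred.start_s < t0_abs + pred_time
            else pos_at,
            layout,
        )
        track = _splice(
            _truncate(track, pred_time),
            pred.track,
            t0_abs,
            pred_time,
            pred_time + retention_s,
        )
        rel = fish.release_time
        return track, GroundTruthFate(
            fish_id=fish.fish_id,
            fate=Fate.PREDATED,
            predation_time=_ts(rel, pred_time),
            predation_section=section,
            trigger_time=_ts(rel, pred_time + delay_s),
            predator_id=pred.predator_id,
            retention_end=_ts(rel, pred_time + retention_s),
            predator_type=pred.ptype,
        )

    def _draw_predation_time(self, track: Track, origin: Origin) -> float | None:
        rates = self.params.predation_hazard_per_h.get(origin, {})
        if not rates or all(r == 0 for r in rates.values()):
            return None
        threshold = self.rng.exponential(1.0)
        cum = 0.0
        mid_sections = section_at(
            0.5 * (track.pos_m[:-1] + track.pos_m[1:]), self.layout
        )
        for i, sec in enumerate(mid_sections):
            dt_h = (track.times_s[i + 1] - track.times_s[i]) / HOUR_S
            rate = rates.get(sec, 0.0)
            if cum + rate * dt_h >= threshold:
                return float(track.times_s[i] + (threshold - cum) / rate * HOUR_S)
            cum += rate * dt_h
        return None

    def _draw_loss_time(self, track: Track) -> float | None:
        mid_sections = section_at(
            0.5 * (track.pos_m[:-1] + track.pos_m[1:]), self.layout
        )
        entered: dict[Section, tuple[float, float]] = {}
        for i, sec in enumerate(mid_sections):
            t0, t1 = float(track.times_s[i]), float(track.times_s[i + 1])
            if sec not in entered:
                entered[sec] = (t0, t1)
            else:
                entered[sec] = (entered[sec][0], t1)
        losses = []
        for sec, (t0, t1) in entered.items():
            if self.rng.random() < self.params.loss_prob.get(sec, 0.0):
                losses.append(self.rng.uniform(t0, max(t1, t0 + 1.0)))
        return min(losses) if losses else None


def _ts(release: pd.Timestamp, seconds: float) -> pd.Timestamp:
    return release + pd.to_timedelta(round(seconds, 3), unit="s")


def _truncate(track: Track, t_end: float) -> Track:
    m = track.times_s < t_end
    times = np.append(track.times_s[m], t_end)
    pos = np.append(track.pos_m[m], track.position_at(np.array([t_end]))[0])
    hidden = [(a, min(b, t_end)) for a, b in track.hidden if a < t_end]
    return Track(times, pos, hidden)


def _splice(
    smolt_part: Track, pred_track: Track, t0_abs: float, t_start: float, t_end: float
) -> Track:
    """Append the predator track slice [t_start, t_end) (fish clock)."""
    pa, pb = t0_abs + t_start, t0_abs + t_end
    m = (pred_track.times_s > pa) & (pred_track.times_s < pb)
    times = np.concatenate(
        [
            smolt_part.times_s,
            [t_start],
            pred_track.times_s[m] - t0_abs,
            [t_end],
        ]
    )
    pos = np.concatenate(
        [
            smolt_part.pos_m,
            pred_track.position_at(np.array([pa])) ,
            pred_track.pos_m[m],
            pred_track.position_at(np.array([pb])),
        ]
    )
    keep = np.concatenate([[True], np.diff(times) > 0])
    hidden = smolt_part.hidden + [
        (max(a - t0_abs, t_start), min(b - t0_abs, t_end))
        for a, b in pred_track.hidden
        if b - t0_abs > t_start and a - t0_abs < t_end
    ]
    return Track(times[keep], pos[keep], hidden)


def simulate_track(
    fish: FishSpec, layout: ArrayLayout, params: MovementParams, rng
) -> tuple[Track, GroundTruthFate]:
    """Single-fish convenience wrapper (no co-ingestion context)."""
    return CohortSimulator(layout, params, rng).simulate_track(fish)


# ---------------------------------------------------------------------------
# detections


def simulate_detections(
    track: Track,
    fate: GroundTruthFate,
    layout: ArrayLayout,
    fish: FishSpec,
    detect_prob: float | dict[str, float] = 0.85,
    false_rate_per_day: float = 0.5,
    rng: np.random.Generator | None = None,
    params: MovementParams | None = None,
) -> pd.DataFrame:
    """Transmission-by-transmission detection records for one tag.

    Transmissions are spaced uniformly within the tag's interval bounds and
    stop at the earliest of track end, tag expulsion, and rated tag life.  A
    transmission is logged at every station within the hard detection radius,
    each with probability ``detect_prob``, unless the track is in a hidden
    (out-of-range) span.  Spurious records -- signal collisions attributed to
    this transmitter -- arrive at ``false_rate_per_day`` over the tag's
    transmitting life and carry no sensor payload.
    """
    rng = np.random.default_rng() if rng is None else rng
    params = params or MovementParams()
    tag = fish.tag
    if isinstance(detect_prob, dict):
        probs = np.array([detect_prob[st.station_id] for st in layout.stations])
    else:
        probs = np.full(len(layout.stations), float(detect_prob))
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("detect_prob must be within [0, 1]")

    life_s = tag.tag_life_days * DAY_S
    end_s = min(track.end_s, life_s)
    rel = fish.release_time
    if fate.retention_end is not None:
        end_s = min(end_s, (fate.retention_end - rel).total_seconds())

    n_max = int(end_s / tag.interval_min_s) + 2
    gaps = rng.uniform(tag.interval_min_s, tag.interval_max_s, n_max)
    tx = np.cumsum(gaps)
    tx = tx[tx < end_s]

    trigger_s = (
        (fate.trigger_time - rel).total_seconds() if fate.trigger_time is not None else None
    )
    frames = []
    if len(tx):
        positions = track.position_at(tx)
        visible = track.visible_mask(tx)
        station_pos = np.array([st.position_m for st in layout.stations])
        cand = np.flatnonzero(visible)  # only audible transmissions matter
        in_range = (
            np.abs(positions[cand, None] - station_pos[None, :]) <= layout.detection_radius_m
        )
        hit = in_range & (rng.random((len(cand), len(station_pos))) < probs[None, :])
        kinds, values = _payloads(tag, tx, trigger_s, params, rng)
        c_idx, s_idx = np.nonzero(hit)
        t_idx = cand[c_idx]
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": rel + pd.to_timedelta(np.round(tx[t_idx], 3), unit="s"),
                    "receiver_id": np.array([st.station_id for st in layout.stations])[s_idx],
                    "transmitter_id": fish.fish_id,
                    "payload_kind": kinds[t_idx],
                    "payload_value": values[t_idx],
                }
            )
        )

    window_s = min(life_s, end_s if fate.retention_end is not None else life_s)
    n_false = rng.poisson(false_rate_per_day * window_s / DAY_S)
    if n_false:
        ft = rng.uniform(0, window_s, n_false)
        stations = rng.choice([st.station_id for st in layout.stations], n_false)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": rel + pd.to_timedelta(np.round(ft, 3), unit="s"),
                    "receiver_id": stations,
                    "transmitter_id": fish.fish_id,
                    "payload_kind": "none",
                    "payload_value": np.nan,
                    "is_false": True,
                }
            )
        )
    if not frames:
        return _empty_detections()
    for f in frames:
        if "is_false" not in f.columns:
            f["is_false"] = False
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def _payloads(tag: TagSpec, tx: np.ndarray, trigger_s, params: MovementParams, rng):
    kinds = np.full(len(tx), "none", dtype=object)
    values = np.full(len(tx), np.nan)
    if tag.tag_type is TagType.PLAIN:
        return kinds, values
    post = np.zeros(len(tx), dtype=bool) if trigger_s is None else tx >= trigger_s
    digestion = np.where(post, np.round((tx - (trigger_s or 0.0)) / HOUR_S, 1), 0.0)
    if tag.tag_type is TagType.PREDATOR:
        kinds[:] = "digestion"
        values[:] = digestion
    else:  # temperature variant alternates the two sensors 1:1
        temp_slot = np.arange(len(tx)) % 2 == 1
        kinds[:] = "digestion"
        values[:] = digestion
        kinds[temp_slot] = "temperature"
        mu_a, sd_a = params.ambient_temp_C
        mu_p, sd_p = params.post_trigger_temp_C
        # physiological truncation: a mammalian gut never reads below ~36 C,
        # ambient water stays within seasonal bounds
        temps = np.where(
            post,
            np.clip(rng.normal(mu_p, sd_p, len(tx)), 36.1, 38.5),
            np.clip(rng.normal(mu_a, sd_a, len(tx)), 5.0, 20.0),
        )
        values[temp_slot] = np.round(temps[temp_slot], 1)
    return kinds, values


def _empty_detections() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
            "receiver_id": pd.Series(dtype=object),
            "transmitter_id": pd.Series(dtype=object),
            "payload_kind": pd.Series(dtype=object),
            "payload_value": pd.Series(dtype=float),
            "is_false": pd.Series(dtype=bool),
        }
    )


# ---------------------------------------------------------------------------
# dataset-level convenience


@dataclass
class SimulatedDataset:
    layout: ArrayLayout
    fish: list[FishSpec]
    truth: list[GroundTruthFate]
    tracks: dict[str, Track]
    detections: pd.DataFrame  # includes ground-truth `is_false` marker

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for f, tr in zip(self.fish, self.truth):
            rows.append(
                {
                    "fish_id": tr.fish_id,
                    "origin": f.origin.value,
                    "fork_length_mm": f.fork_length_mm,
                    "mass_g": f.mass_g,
                    "tag_type": f.tag.tag_type.value,
                    "release_time": f.release_time,
                    "fate": tr.fate.value,
                    "predation_time": tr.predation_time,
                    "predation_section": tr.predation_section.value
                    if tr.predation_section
                    else None,
                    "trigger_time": tr.trigger_time,
                    "predator_id": tr.predator_id,
                    "retention_end": tr.retention_end,
                    "predator_type": tr.predator_type,
                    "loss_time": tr.loss_time,
                }
            )
        return pd.DataFrame(rows)

    def true_passage(self) -> pd.DataFrame:
        """Ground-truth per-section passage of the *live* fish.

        A fish passed a section if it was alive (not yet predated or lost)
        when its track first reached the section's first station.
        """
        rows = []
        for f, tr in zip(self.fish, self.truth):
            track = self.tracks[tr.fish_id]
            death_s = np.inf
            for t in (tr.predation_time, tr.loss_time):
                if t is not None:
                    death_s = min(death_s, (t - f.release_time).total_seconds())
            if tr.fate is Fate.TAGGING_MORTALITY:
                death_s = 0.0
            row = {"fish_id": tr.fish_id, "origin": f.origin.value}
            for sec in self.layout.sections:
                first = min(st.position_m for st in self.layout.stations_in(sec))
                alive = track.times_s <= death_s
                row[sec.value] = bool((track.pos_m[alive] >= first).any())
            rows.append(row)
        return pd.DataFrame(rows)


def simulate_dataset(
    n_wild: int = 50,
    n_ranched: int = 100,
    n_predator_tags: int = 25,
    layout: ArrayLayout | None = None,
    params: MovementParams | None = None,
    detect_prob: float | dict[str, float] = 0.85,
    false_rate_per_day: float = 0.5,
    seed: int | np.random.Generator = 0,
    **cohort_kwargs,
) -> SimulatedDataset:
    """Simulate a full cohort: tracks, fates, and detection records.

    The defaults emulate the study conditions this package targets: 150
    tagged smolts (50 wild, 100 ranched) of which 25 ranched fish carry
    temperature predator tags.
    """
    from . import layout as layout_mod

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    layout = layout or layout_mod.build_array_layout("full")
    params = params or MovementParams()
    fish = simulate_cohort(n_wild, n_ranched, n_predator_tags, seed=rng, **cohort_kwargs)
    sim = CohortSimulator(layout, params, rng)
    t_origin = min((f.release_time for f in fish), default=pd.Timestamp(0, tz="UTC"))
    truths: list[GroundTruthFate] = []
    tracks: dict[str, Track] = {}
    frames = []
    for f in sorted(fish, key=lambda f: f.release_time):
        t0_abs = (f.release_time - t_origin).total_seconds()
        track, fate = sim.simulate_track(f, t0_abs=t0_abs)
        truths.append(fate)
        tracks[f.fish_id] = track
        frames.append(
            simulate_detections(
                track,
                fate,
                layout,
                f,
                detect_prob=detect_prob,
                false_rate_per_day=false_rate_per_day,
                rng=rng,
                params=params,
            )
        )
    order = {f.fish_id: i for i, f in enumerate(fish)}
    truths.sort(key=lambda tr: order[tr.fish_id])
    detections = (
        pd.concat(frames, ignore_index=True)
        .sort_values("timestamp", kind="mergesort")
        .reset_index(drop=True)
        if frames
        else _empty_detections()
    )
    return SimulatedDataset(layout, fish, truths, tracks, detections)
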