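import numpy as np
import pandas as pd
import pytest

import smoltfate
from smoltfate import io
from smoltfate.layout import ArrayLayout, Section, Station, build_array_layout
from smoltfate.pipeline import classify_fates, decode_all, metrics_matrix, training_smolts


@pytest.fixture(scope="session")
def full_layout():
    return build_array_layout("full")


@pytest.fixture(scope="session")
def small_sim():
    """A modest cohort for distributional checks (shared, read-only)."""
    return smoltfate.simulate_dataset(n_wild=15, n_ranched=35, n_predator_tags=10, seed=7)


@pytest.fixture(scope="session")
def default_run():
    """The default study-condition cohort taken through filter -> decode ->
    metrics -> both classifiers.  Computed once; tests must not mutate it."""
    sim = smoltfate.simulate_dataset(seed=1)
    layout = sim.layout
    kept, flagged = io.filter_false_detections(sim.detections.drop(columns="is_false"))
    kept, _ = io.confirm_station_visits(kept)
    kept = io.assign_sections(kept, layout)
    summaries = decode_all(kept, sim)
    matrix = metrics_matrix(kept, layout, sim, summaries)
    anchors = {
        s.transmitter_id: "predator"
        for s in summaries.values()
        if s.triggered and s.transmitter_id in matrix.index
    }
    smolt_training = training_smolts(
        matrix, kept, sim, summaries, ("untriggered_predator_tags", "outermost_arrivals")
    )
    cls = classify_fates(matrix, anchors, smolt_training, cluster_k=2, seed=1)
    truth = (
        sim.truth_frame()
        .set_index("fish_id")["fate"]
        .map({"predated": "predator", "smolt": "smolt", "tagging_mortality": "smolt"})
    )
    return {
        "sim": sim,
        "layout": layout,
        "kept": kept,
        "flagged": flagged,
        "summaries": summaries,
        "matrix": matrix,
        "anchors": anchors,
        "smolt_training": smolt_training,
        "cls": cls,
        "truth": truth,
    }


@pytest.fixture()
def two_station_layout():
    return ArrayLayout(
        stations=[
            Station("A", 100.0, Section.LAKE),
            Station("B", 900.0, Section.ESTUARY),
        ]
    )


def make_records(rows):
    """Detection DataFrame from (timestamp, receiver, transmitter[, kind, value])."""
    recs = []
    for r in rows:
        ts, rec, tx = r[:3]
        kind = r[3] if len(r) > 3 else "none"
        val = r[4] if len(r) > 4 else np.nan
        ts = pd.Timestamp(ts)
        recs.append(
            {
                "timestamp": ts.tz_localize("UTC") if ts.tzinfo is None else ts,
                "receiver_id": rec,
                "transmitter_id": tx,
                "payload_kind": kind,
                "payload_value": val,
            }
        )
    return pd.DataFrame(recs)
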