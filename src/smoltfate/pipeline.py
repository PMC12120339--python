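"""End-to-end orchestration: simulate -> filter -> decode -> metrics ->
classify -> survival, with every stage output written as plain CSV so any
stage can be re-run or audited on its own."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, cjs, io, metrics
from .layout import ArrayLayout, build_array_layout
from .simulate import MovementParams, SimulatedDataset, TagType, simulate_dataset

log = logging.getLogger("smoltfate")


@dataclass
class PipelineConfig:
    seed: int = 1
    layout: str = "full"
    n_wild: int = 50
    n_ranched: int = 100
    n_predator_tags: int = 25
    detect_prob: float = 0.85
    false_rate_per_day: float = 0.5
    filter_window_min: float = 30.0
    variable_set: str = "extended"  # or "base"
    cluster_k: int | None = None
    k_max: int = 10
    n_tree_grid: tuple[int, ...] = (25, 50, 100, 250, 500)
    mtry_grid: tuple[int, ...] | None = None
    #: forest training labels: "cluster" trains on cluster-assigned fates;
    #: "anchors" trains only on sensor-confirmed predators + known smolts
    label_source: str = "cluster"
    #: smolt training labels used when label_source="anchors":
    #: non-triggered predator-tagged fish and/or outermost-line arrivals
    smolt_labels: tuple[str, ...] = ("untriggered_predator_tags", "outermost_arrivals")
    cjs_models: tuple = (
        (".", "."),
        ("Location", "."),
        (".", "Location"),
        ("Location", "Location"),
        ("Origin", "."),
        ("FL", "."),
        ("TMR", "."),
    )
    gof_n_sim: int = 200
    out_dir: str = "smoltfate_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.seed is None:
            raise ValueError("config must set a seed")
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def classify_fates(
    sim_metrics: pd.DataFrame,
    anchors: dict[str, str],
    smolt_training: list[str] | None = None,
    cluster_k: int | None = None,
    seed: int = 0,
    n_tree_grid=(25, 50, 100, 250, 500),
    mtry_grid=None,
    k_max: int = 10,
    label_source: str = "cluster",
) -> dict:
    """Run both classifiers on a metric matrix and report their agreement.

    The hierarchical clustering runs first, anchored by the triggered
    predator tags.  The random forest is then trained according to
    ``label_source``:

    * ``"cluster"`` (default): on the full matrix with cluster-assigned
      fates -- the supervised model cross-checks the unsupervised grouping,
      and its out-of-bag error measures how separable the fates are;
    * ``"anchors"``: only on sensor-confirmed predators plus the
      known-fate smolts in ``smolt_training``, and predicts the rest.

    Returns cluster and forest results, the consolidated per-tag fate
    table, and the cluster-vs-forest agreement over non-anchor tags.
    """
    cluster = classify.cluster_and_label(sim_metrics, anchors, k=cluster_k, k_max=k_max)
    if label_source == "cluster":
        labels = cluster.fates.copy()
        for t, f in anchors.items():
            labels.loc[t] = f
    elif label_source == "anchors":
        labels = pd.Series(
            {
                **{t: classify.PREDATOR for t in anchors},
                **{t: classify.SMOLT for t in smolt_training or []},
            }
        )
        labels = labels.loc[labels.index.intersection(sim_metrics.index)]
    else:
        raise ValueError("label_source must be 'cluster' or 'anchors'")
    forest = classify.fit_random_forest(
        sim_metrics, labels, n_tree_grid=n_tree_grid, mtry_grid=mtry_grid, seed=seed
    )
    predicted = classify.predict_fates(forest, sim_metrics)
    non_anchor = sim_metrics.index.difference(list(anchors))
    agreement = classify.classifier_agreement(
        cluster.fates.loc[non_anchor], predicted.loc[non_anchor, "fate"]
    )
    rows = []
    for tag in sim_metrics.index:
        if tag in anchors:
            provenance = "sensor"
        elif tag in labels.index:
            provenance = "cluster+forest" if label_source == "cluster" else "training"
        else:
            provenance = "forest"
        fate = classify.PREDATOR if tag in anchors else predicted.loc[tag, "fate"]
        rows.append(
            {
                "transmitter_id": tag,
                "fate": fate,
                "fate_cluster": cluster.fates.loc[tag],
                "provenance": provenance,
                "vote": float(predicted.loc[tag, "vote"]),
            }
        )
    return {
        "cluster": cluster,
        "forest": forest,
        "fates": pd.DataFrame(rows).set_index("transmitter_id"),
        "agreement_unlabeled": agreement,
    }


def run_pipeline(config: PipelineConfig, params: MovementParams | None = None) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stage outputs: detections.csv (export dialect), layout.csv, truth.csv,
    metrics.csv, trigger_summaries.csv, fates.csv, model_table.csv,
    estimates.csv, success_profile.csv and summary.json (manifest + key
    numbers).  Byte-identical across runs with the same config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    t0 = time.time()

    def _stage(name):
        log.info("stage %-10s +%.1fs", name, time.time() - t0)

    try:
        _stage("simulate")
        layout = build_array_layout(config.layout)
        sim = simulate_dataset(
            n_wild=config.n_wild,
            n_ranched=config.n_ranched,
            n_predator_tags=config.n_predator_tags,
            layout=layout,
            params=params,
            detect_prob=config.detect_prob,
            false_rate_per_day=config.false_rate_per_day,
            seed=config.seed,
        )
        layout.to_csv(out / "layout.csv")
        io.write_detections(sim.detections, out / "detections.csv")
        sim.truth_frame().to_csv(out / "truth.csv", index=False)
        manifest += ["layout.csv", "detections.csv", "truth.csv"]
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("simulate", exc) from exc

    try:
        _stage("filter")
        records = io.read_detections(out / "detections.csv")
        kept, flagged = io.filter_false_detections(records, config.filter_window_min)
        kept, unconfirmed = io.confirm_station_visits(kept, config.filter_window_min)
        flagged = pd.concat([flagged, unconfirmed], ignore_index=True)
        kept = io.assign_sections(kept, layout)
    except Exception as exc:
        raise StageError("filter", exc) from exc

    try:
        _stage("decode")
        summaries = decode_all(kept, sim)
        io.trigger_summaries_frame(summaries.values()).to_csv(
            out / "trigger_summaries.csv", index=False
        )
        manifest.append("trigger_summaries.csv")
    except Exception as exc:
        raise StageError("decode", exc) from exc

    try:
        _stage("metrics")
        matrix = metrics_matrix(kept, layout, sim, summaries, config.variable_set)
        matrix.to_csv(out / "metrics.csv")
        manifest.append("metrics.csv")
    except Exception as exc:
        raise StageError("metrics", exc) from exc

    try:
        _stage("classify")
        anchors = {s.transmitter_id: classify.PREDATOR for s in summaries.values() if s.triggered}
        anchors = {t: f for t, f in anchors.items() if t in matrix.index}
        if not anchors:
            raise ValueError(
                "no triggered predator tags to anchor the classifiers; deploy "
                "predator tags or supply explicit labels"
            )
        smolt_training = training_smolts(matrix, kept, sim, summaries, config.smolt_labels)
        cls = classify_fates(
            matrix,
            anchors,
            smolt_training,
            config.cluster_k,
            config.seed,
            n_tree_grid=config.n_tree_grid,
            mtry_grid=config.mtry_grid,
            k_max=config.k_max,
            label_source=config.label_source,
        )
        cls["fates"].to_csv(out / "fates.csv")
        cls["forest"].importance.to_csv(out / "importance.csv")
        manifest += ["fates.csv", "importance.csv"]
    except Exception as exc:
        raise StageError("classify", exc) from exc

    try:
        _stage("survival")
        cohort = sim.truth_frame().rename(columns={"fish_id": "fish_id"})
        cohort["tag_weight_g"] = [f.tag.tag_weight_g for f in sim.fish]
        fates = cls["fates"]["fate"]
        hb = cjs.build_capture_histories(kept, layout, cohort, mode="biased")
        hu = cjs.build_capture_histories(kept, layout, cohort, fates=fates, mode="unbiased")
        profile = cjs.migration_success_profile(hb, hu, layout)
        profile.to_csv(out / "success_profile.csv", index=False)

        fits = [
            cjs.fit_cjs(hu, layout, phi, p, seed=config.seed) for phi, p in config.cjs_models
        ]
        global_fit = max(fits, key=lambda f: f.K)
        gof = cjs.bootstrap_gof(global_fit, hu, layout, n_sim=config.gof_n_sim, seed=config.seed)
        table = cjs.rank_models_qaicc(fits, c_hat=gof.c_hat)
        table.to_csv(out / "model_table.csv", index=False)
        averaged = cjs.model_average(fits)
        est = pd.concat(
            {
                "phi": averaged["phi"].assign(
                    interval=[s.value for s in layout.sections]
                ),
                "p": averaged["p"].assign(interval=[s.value for s in layout.sections]),
            },
            names=["quantity"],
        )
        est.to_csv(out / "estimates.csv")
        manifest += ["success_profile.csv", "model_table.csv", "estimates.csv"]
    except Exception as exc:
        raise StageError("survival", exc) from exc

    summary = {
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(config).items()},
        "n_fish": len(sim.fish),
        "n_detections": int(len(records)),
        "n_flagged_false": int(len(flagged)),
        "n_classified": int(len(matrix)),
        "n_anchors": len(anchors),
        "cluster_k": int(cls["cluster"].k),
        "forest": {
            "n_trees": cls["forest"].n_trees,
            "mtry": cls["forest"].mtry,
            "oob_error": cls["forest"].oob_error,
            "auroc": cls["forest"].auroc,
            "f1": cls["forest"].f1,
        },
        "classifier_agreement": cls["agreement_unlabeled"],
        "c_hat": gof.c_hat,
        "best_model": table["model"].iloc[0],
        "outputs": sorted(manifest),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _stage("done")
    return out


def decode_all(kept: pd.DataFrame, sim: SimulatedDataset) -> dict[str, io.TriggerSummary]:
    """Trigger summaries for every predator-type tag with detections."""
    out: dict[str, io.TriggerSummary] = {}
    by_tag = dict(tuple(kept.groupby("transmitter_id", sort=False)))
    for fish in sim.fish:
        if fish.tag.tag_type is TagType.PLAIN:
            continue
        recs = by_tag.get(fish.fish_id)
        if recs is None or recs.empty:
            continue
        out[fish.fish_id] = io.decode_predator_tag(recs, fish.tag)
    return out


def metrics_matrix(
    kept: pd.DataFrame,
    layout: ArrayLayout,
    sim: SimulatedDataset,
    summaries: dict[str, io.TriggerSummary],
    variable_set: str = "extended",
) -> pd.DataFrame:
    """Metric matrix over tags detected beyond the lake."""
    release = {f.fish_id: f.release_time for f in sim.fish}
    vectors = []
    ids = metrics.detected_beyond_lake(kept, layout)
    for tag_id, recs in kept.groupby("transmitter_id", sort=False):
        if tag_id not in ids:
            continue
        vectors.append(
            metrics.compute_metrics(
                recs, layout, trigger=summaries.get(tag_id), release_time=release.get(tag_id)
            )
        )
    variables = (
        metrics.VARIABLES_EXTENDED if variable_set == "extended" else metrics.VARIABLES_BASE
    )
    return metrics.build_metric_matrix(vectors, variables)


def training_smolts(
    matrix: pd.DataFrame,
    kept: pd.DataFrame,
    sim: SimulatedDataset,
    summaries: dict[str, io.TriggerSummary],
    sources: tuple[str, ...],
) -> list[str]:
    """Known-fate smolt training tags, per the configured label sources."""
    smolts: set[str] = set()
    if "untriggered_predator_tags" in sources:
        for fish in sim.fish:
            if fish.tag.tag_type is not TagType.PLAIN:
                s = summaries.get(fish.fish_id)
                if s is not None and not s.triggered and fish.fish_id in matrix.index:
                    smolts.add(fish.fish_id)
    if "outermost_arrivals" in sources:
        # a live fish passing the outermost line logs a burst of detections;
        # require several so a stray pair of coincident false records cannot
        # fake a known-fate smolt
        outer = sim.layout.sections[-1].value
        at_outer = kept.loc[kept["section"] == outer].groupby("transmitter_id").size()
        arrived = set(at_outer.index[at_outer >= 3])
        triggered = {t for t, s in summaries.items() if s.triggered}
        smolts |= {t for t in arrived if t in matrix.index and t not in triggered}
    return sorted(smolts)
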