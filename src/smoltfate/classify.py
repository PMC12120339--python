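"""Smolt/predator fate assignment from migration metrics.

Two classifiers over the same standardized metric matrix:

* unsupervised Ward hierarchical clustering (Euclidean distances,
  minimum-variance criterion, Euclidean-scale heights), with the cluster
  count confirmed by silhouette analysis and the within-cluster
  sum-of-squares (elbow) curve, and clusters labelled by the triggered
  predator-tag anchors they contain (or a movement-metric heuristic when
  anchor-free);
* a supervised random forest trained on known fates (triggered tags are
  predators; non-triggered predator-tagged fish and tags reaching the
  outermost line are smolts), with ntree/mtry chosen by out-of-bag error.

Agreement between the two is the study's cross-validation of fate calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import f1_score, roc_auc_score, silhouette_score

SMOLT = "smolt"
PREDATOR = "predator"


@dataclass
class ClusterResult:
    merge_tree: np.ndarray  # scipy linkage matrix, Euclidean-scale heights
    k: int
    assignments: pd.Series  # tag -> cluster index (1..k)
    cluster_fates: dict[int, str]
    silhouette_by_k: dict[int, float]
    wss_by_k: dict[int, float]

    @property
    def fates(self) -> pd.Series:
        return self.assignments.map(self.cluster_fates)


@dataclass
class ForestResult:
    n_trees: int
    mtry: int
    oob_error: float
    class_errors: dict[str, float]
    confusion: pd.DataFrame
    importance: pd.DataFrame  # mean_decrease_accuracy, mean_decrease_gini
    auroc: float
    f1: float
    model: RandomForestClassifier = field(repr=False)
    feature_names: list[str] = field(default_factory=list)
    oob_grid: pd.DataFrame | None = None


def standardize_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each column and scale to unit sample standard deviation.

    Zero-variance columns are left at zero after centering, so a variable
    with no information cannot perturb the distance structure.
    """
    if len(matrix) < 2:
        raise ValueError("standardization requires at least two rows")
    centered = matrix - matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    sd = sd.where(sd > 0, 1.0)
    return centered / sd


def ward_cluster(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Agglomerative merge tree under Ward's minimum-variance criterion.

    Heights follow the Euclidean-scale convention (the merge of two
    singletons sits at their Euclidean distance).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("ward_cluster requires a 2-D matrix with >= 2 rows")
    return linkage(X, method="ward")


def cut_tree(merge_tree: np.ndarray, k: int) -> np.ndarray:
    """Cluster indices (1..k) from a merge tree."""
    return fcluster(merge_tree, t=k, criterion="maxclust")


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def choose_k(
    merge_tree: np.ndarray, matrix: pd.DataFrame | np.ndarray, k_max: int = 10
) -> tuple[int, dict[int, float], dict[int, float]]:
    """Silhouette-optimal cluster count, with the WSS (elbow) curve.

    Returns ``(k, silhouette_by_k, wss_by_k)``; the silhouette argmax over
    k in [2, k_max] decides, ties broken toward smaller k.  The WSS curve
    is reported for the elbow diagnostic.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    X = np.asarray(matrix, dtype=float)
    k_max = min(k_max, len(X) - 1)
    sil: dict[int, float] = {}
    wss: dict[int, float] = {}
    for k in range(2, k_max + 1):
        labels = cut_tree(merge_tree, k)
        wss[k] = _wss(X, labels)
        if len(np.unique(labels)) < 2:
            sil[k] = -1.0
            continue
        sil[k] = float(silhouette_score(X, labels, metric="euclidean"))
    best = max(sil, key=lambda k: (sil[k], -k))
    return best, sil, wss


@dataclass
class LabelHeuristic:
    """Metric thresholds for labelling anchor-free clusters.

    A cluster is called a predator group when its median reversal count or
    upstream speed exceeds live-smolt behaviour, or when its median
    lake+estuary residency is several times the cohort's (the prolonged
    lake-resident group predated by a different predator).
    """

    max_smolt_reversals: float = 2.0
    max_smolt_up_speed_ms: float = 0.3
    residency_ratio: float = 3.0


def label_clusters(
    assignments: pd.Series,
    anchors: dict[str, str] | pd.Series | None,
    metrics: pd.DataFrame | None = None,
    heuristic: LabelHeuristic | None = LabelHeuristic(),
) -> dict[int, str]:
    """Label each cluster smolt or predator.

    A cluster containing at least one triggered-predator-tag anchor is a
    predator cluster (majority across anchors on conflict).  Anchor-free
    clusters fall back to the metric heuristic; with neither anchors nor a
    heuristic the call is ambiguous and raises.
    """
    anchors = dict(anchors) if anchors is not None else {}
    fates: dict[int, str] = {}
    for c in sorted(assignments.unique()):
        members = assignments.index[assignments == c]
        votes = [anchors[t] for t in members if t in anchors]
        if votes:
            fates[int(c)] = PREDATOR if votes.count(PREDATOR) * 2 >= len(votes) else SMOLT
            continue
        if heuristic is None or metrics is None:
            raise ValueError(
                f"cluster {c} has no sensor-confirmed anchors; provide metrics and a "
                "labelling heuristic or explicit labels"
            )
        checks = []
        if "n_reversals" in metrics.columns:
            checks.append(
                float(metrics.loc[members, "n_reversals"].median())
                > heuristic.max_smolt_reversals
            )
        if "mean_up_speed_ms" in metrics.columns:
            checks.append(
                float(metrics.loc[members, "mean_up_speed_ms"].median())
                > heuristic.max_smolt_up_speed_ms
            )
        if {"residency_lake_h", "residency_estuary_h"} <= set(metrics.columns):
            resid = metrics["residency_lake_h"] + metrics["residency_estuary_h"]
            cohort_med = float(resid.median())
            checks.append(
                cohort_med > 0
                and float(resid.loc[members].median())
                > heuristic.residency_ratio * cohort_med
            )
        if not checks:
            raise ValueError(
                f"cluster {c} has no anchors and the metric table carries none of "
                "the heuristic variables"
            )
        fates[int(c)] = PREDATOR if any(checks) else SMOLT
    return fates


def cluster_and_label(
    matrix: pd.DataFrame,
    anchors: dict[str, str] | None,
    k: int | None = None,
    k_max: int = 10,
    heuristic: LabelHeuristic | None = LabelHeuristic(),
    label_metrics: pd.DataFrame | None = None,
) -> ClusterResult:
    """standardize -> Ward -> (choose k) -> label, in one call.

    ``label_metrics`` lets the labelling heuristic consult the full metric
    table when the clustering itself ran on a reduced variable subset.
    """
    Z = ward_cluster(standardize_matrix(matrix))
    if k is None:
        k, sil, wss = choose_k(Z, standardize_matrix(matrix), k_max=k_max)
    else:
        _, sil, wss = choose_k(Z, standardize_matrix(matrix), k_max=max(k_max, k))
    labels = pd.Series(cut_tree(Z, k), index=matrix.index)
    fates = label_clusters(
        labels,
        anchors,
        metrics=matrix if label_metrics is None else label_metrics,
        heuristic=heuristic,
    )
    return ClusterResult(Z, k, labels, fates, sil, wss)


def sensitivity_analysis(
    matrix: pd.DataFrame,
    variable_subsets: dict[str, list[str]],
    anchors: dict[str, str] | None,
    k: int | None = None,
    heuristic: LabelHeuristic | None = LabelHeuristic(),
) -> pd.Series:
    """Count fate changes when removing named variable combinations.

    ``variable_subsets`` maps a trial name to the variables removed for
    that trial; each trial reruns standardize -> cluster -> label and the
    result counts tags whose fate differs from the all-variable run.
    """
    base = cluster_and_label(matrix, anchors, k=k, heuristic=heuristic).fates
    changes = {}
    for name, removed in variable_subsets.items():
        kept = [c for c in matrix.columns if c not in set(removed)]
        if len(kept) < 2:
            raise ValueError(f"trial {name!r} leaves fewer than two variables")
        trial = cluster_and_label(
            matrix[kept], anchors, k=k, heuristic=heuristic, label_metrics=matrix
        ).fates
        changes[name] = int((trial != base).sum())
    return pd.Series(changes, name="fate_changes")


def fit_random_forest(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_tree_grid: tuple[int, ...] = (25, 50, 100, 250, 500),
    mtry_grid: tuple[int, ...] | None = None,
    class_weights: dict[str, float] | str | None = None,
    seed: int = 0,
    oob_stable_tol: float = 0.005,
) -> ForestResult:
    """Random forest over labelled rows with OOB-driven ntree/mtry choice.

    mtry is the candidate minimising OOB error (at the largest ntree);
    ntree is the smallest grid value from which OOB error stays within
    ``oob_stable_tol`` (0.5 percentage points) of all later grid values.
    Out-of-bag predictions supply the confusion matrix, per-class error,
    AUROC and F1.  Deterministic for a fixed seed.
    """
    labels = labels.loc[matrix.index.intersection(labels.index)]
    X = matrix.loc[labels.index]
    y = labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    p = X.shape[1]
    mtry_grid = tuple(mtry_grid or sorted({max(1, int(np.sqrt(p))), max(1, p // 3), max(1, p // 2), p - 1 or 1}))
    n_tree_grid = tuple(sorted(n_tree_grid))

    def _fit(nt: int, mt: int) -> RandomForestClassifier:
        rf = RandomForestClassifier(
            n_estimators=nt,
            max_features=min(mt, p),
            oob_score=True,
            class_weight=class_weights,
            random_state=seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
            rf.fit(X, y)
        return rf

    rows = []
    for mt in mtry_grid:
        rf = _fit(max(n_tree_grid), mt)
        rows.append({"mtry": mt, "n_trees": max(n_tree_grid), "oob_error": 1 - rf.oob_score_})
    best_mtry = int(min(rows, key=lambda r: (r["oob_error"], r["mtry"]))["mtry"])

    errs = {}
    for nt in n_tree_grid:
        errs[nt] = 1 - _fit(nt, best_mtry).oob_score_
        rows.append({"mtry": best_mtry, "n_trees": nt, "oob_error": errs[nt]})
    grid = list(n_tree_grid)
    best_nt = grid[-1]
    for i, nt in enumerate(grid):
        later = [errs[m] for m in grid[i:]]
        if max(later) - min(later) < oob_stable_tol:
            best_nt = nt
            break

    rf = _fit(best_nt, best_mtry)
    classes = list(rf.classes_)
    proba = rf.oob_decision_function_
    missing = np.isnan(proba).any(axis=1)
    if missing.any():  # rows never out of bag at small ntree
        proba = proba.copy()
        proba[missing] = rf.predict_proba(X.iloc[missing.nonzero()[0]])
    oob_pred = np.array(classes)[np.argmax(proba, axis=1)]
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(oob_pred, name="oob_pred"), dropna=False
    ).reindex(index=classes, columns=classes, fill_value=0)
    class_errors = {
        c: float(1 - confusion.loc[c, c] / confusion.loc[c].sum()) if confusion.loc[c].sum() else 0.0
        for c in classes
    }
    pred_col = classes.index(PREDATOR)
    auroc = float(roc_auc_score((y == PREDATOR).astype(int), proba[:, pred_col]))
    f1 = float(f1_score(y, oob_pred, pos_label=PREDATOR))
    perm = permutation_importance(
        rf, X, y, n_repeats=10, random_state=seed, n_jobs=1
    )
    importance = pd.DataFrame(
        {
            "mean_decrease_accuracy": perm.importances_mean,
            "mean_decrease_gini": rf.feature_importances_,
        },
        index=X.columns,
    )
    return ForestResult(
        n_trees=best_nt,
        mtry=best_mtry,
        oob_error=float(np.mean(oob_pred != y)),
        class_errors=class_errors,
        confusion=confusion,
        importance=importance,
        auroc=auroc,
        f1=f1,
        model=rf,
        feature_names=list(X.columns),
        oob_grid=pd.DataFrame(rows),
    )


def predict_fates(forest: ForestResult, matrix: pd.DataFrame) -> pd.DataFrame:
    """Predict fates for unlabelled tags; returns fate and vote fraction."""
    if list(matrix.columns) != forest.feature_names:
        raise ValueError(
            f"feature mismatch: expected {forest.feature_names}, got {list(matrix.columns)}"
        )
    if matrix.empty:
        return pd.DataFrame(columns=["fate", "vote"], index=matrix.index)
    proba = forest.model.predict_proba(matrix)
    classes = list(forest.model.classes_)
    idx = np.argmax(proba, axis=1)
    return pd.DataFrame(
        {
            "fate": np.array(classes)[idx],
            "vote": proba[np.arange(len(matrix)), idx],
        },
        index=matrix.index,
    )


def classifier_agreement(fates_a: pd.Series, fates_b: pd.Series) -> float:
    """Fraction of tags assigned the same fate by two classifiers."""
    if set(fates_a.index) != set(fates_b.index):
        raise ValueError("classifier fate maps cover different tag sets")
    if len(fates_a) == 0:
        return 1.0
    b = fates_b.loc[fates_a.index]
    return float((fates_a == b).mean())


def mds_projection(dissimilarity: np.ndarray | pd.DataFrame, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates of a dissimilarity matrix."""
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("dissimilarities must be non-negative")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)
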