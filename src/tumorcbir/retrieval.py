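"""Patient-stratified retrieval evaluation: ranking, AP/mAP, prec@n.

Patients (not slices) are randomly dealt into folds, so slices of one
patient never span the training database and the query set.  Each held-out
slice queries the training database; database images are ranked by
ascending distance (exact ties broken by database index).  A database image
is relevant iff it shares the query's class.  AP averages the precision at
every rank holding a relevant image over the full ranking; mAP averages AP
over queries; prec@n is the relevant fraction of the top n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ._logging import stage_timer
from .config import PipelineConfig, stage_seed
from .data import Cohort
from .metric import MetricModel, build_pair_scatter, fit_cfml, project
from .pipeline import encode_cases, fit_feature_models

__all__ = [
    "FoldSplit",
    "FoldEncodings",
    "RankingResult",
    "patient_cv_split",
    "rank_database",
    "average_precision",
    "prec_at_n",
    "encode_folds",
    "evaluate_encoded",
    "evaluate_pipeline",
    "permute_patient_labels",
    "empirical_chance_map",
]


@dataclass(frozen=True)
class FoldSplit:
    """Patient-to-fold assignment for cross-validation."""

    assignments: dict[str, int]
    n_folds: int
    seed: int

    def fold_indices(self, cohort: Cohort, fold: int) -> np.ndarray:
        """Indices of cohort slices whose patient is in ``fold``."""
        return np.array(
            [i for i, c in enumerate(cohort) if self.assignments[c.patient_id] == fold],
            dtype=int,
        )


@dataclass
class RankingResult:
    """One query's ranking over the database."""

    order: np.ndarray  # database indices, ascending distance
    distances: np.ndarray  # distances in ranked order
    relevance: np.ndarray | None = None  # bool flags in ranked order
    ap: float | None = None
    prec: dict[int, float] | None = None


def patient_cv_split(cohort: Cohort, folds: int, seed: int) -> FoldSplit:
    """Shuffle patients with ``seed`` and deal them round-robin into folds."""
    patients = sorted({c.patient_id for c in cohort})
    if len(patients) < folds:
        raise ValueError(f"only {len(patients)} patients for {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    assignments = {patients[p]: i % folds for i, p in enumerate(order)}
    return FoldSplit(assignments=assignments, n_folds=folds, seed=seed)


def rank_database(
    query: np.ndarray,
    database: np.ndarray,
    metric: MetricModel | str = "euclidean",
    query_label: int | None = None,
    database_labels: Sequence[int] | None = None,
    prec_ns: Sequence[int] = (),
) -> RankingResult:
    """Rank database rows by ascending distance to the query.

    ``metric`` is either a fitted :class:`MetricModel` (learned squared
    Mahalanobis distance, computed via the rank-D projections) or the string
    ``"euclidean"``.  Ties are broken by database index.  When labels are
    supplied, relevance flags, AP and the requested prec@n are filled in.
    """
    database = np.asarray(database, dtype=float)
    if database.ndim != 2 or database.shape[0] == 0:
        raise ValueError("database must be a nonempty (n, F) matrix")
    q = np.asarray(query, dtype=float)[None, :]
    if isinstance(metric, MetricModel):
        d = cdist(project(metric, q), project(metric, database), "sqeuclidean")[0]
    elif metric == "euclidean":
        d = cdist(q, database, "euclidean")[0]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    order = np.argsort(d, kind="stable")  # stable sort: ties keep db index order
    result = RankingResult(order=order, distances=d[order])
    if query_label is not None and database_labels is not None:
        labels = np.asarray(database_labels)
        result.relevance = labels[order] == query_label
        result.ap = average_precision(result.relevance)
        result.prec = {n: prec_at_n(result.relevance, n) for n in prec_ns}
    return result


def _relevance_array(ranking: RankingResult | np.ndarray) -> np.ndarray:
    if isinstance(ranking, RankingResult):
        if ranking.relevance is None:
            raise ValueError("ranking carries no relevance flags")
        return ranking.relevance
    return np.asarray(ranking, dtype=bool)


def average_precision(ranking: RankingResult | np.ndarray) -> float:
    """Mean of precision-at-p over all ranks p holding a relevant item."""
    rel = _relevance_array(ranking)
    if not rel.any():
        raise ValueError("average precision undefined with zero relevant items")
    positions = np.nonzero(rel)[0] + 1
    precisions = np.cumsum(rel)[rel.astype(bool)] / positions
    return float(precisions.mean())


def prec_at_n(ranking: RankingResult | np.ndarray, n: int) -> float:
    """Relevant fraction of the top-n ranked database images."""
    rel = _relevance_array(ranking)
    if not 1 <= n <= rel.size:
        raise ValueError(f"n must be in [1, {rel.size}], got {n}")
    return float(rel[:n].mean())


def permute_patient_labels(cohort: Cohort, seed: int) -> np.ndarray:
    """Per-case labels after shuffling labels among patients (null model)."""
    patients = sorted({c.patient_id for c in cohort})
    labels = {p: next(c.label for c in cohort if c.patient_id == p) for p in patients}
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation([labels[p] for p in patients])
    new = dict(zip(patients, shuffled))
    return np.array([new[c.patient_id] for c in cohort], dtype=int)


def _fold_metrics(
    aps: np.ndarray, precs: dict[int, np.ndarray], query_labels: np.ndarray
) -> dict:
    if aps.size == 0:  # every query skipped: fold contributes nothing
        return {"mAP": float("nan"),
                **{f"prec@{n}": float("nan") for n in precs}, "per_class": {}}
    out = {
        "mAP": float(aps.mean()),
        **{f"prec@{n}": float(v.mean()) for n, v in precs.items()},
        "per_class": {},
    }
    for c in np.unique(query_labels):
        sel = query_labels == c
        out["per_class"][int(c)] = {
            "mAP": float(aps[sel].mean()),
            "n_queries": int(sel.sum()),
            **{f"prec@{n}": float(v[sel].mean()) for n, v in precs.items()},
        }
    return out


@dataclass
class FoldEncodings:
    """Signatures of one CV fold, encoded with training-fold-only models."""

    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    X_train: np.ndarray
    X_test: np.ndarray


def encode_folds(
    cohort: Cohort, config: PipelineConfig, n_folds: int = 5
) -> list[FoldEncodings]:
    """Fit models and encode signatures for every CV fold.

    Encoding never looks at labels, so the result can be re-scored under
    any labeling (learned metric refit included) without re-encoding —
    used for the label-permutation null.
    """
    split = patient_cv_split(cohort, n_folds, stage_seed(config.seed, "cv"))
    out = []
    for fold in range(n_folds):
        test_idx = split.fold_indices(cohort, fold)
        train_idx = np.setdiff1d(np.arange(len(cohort)), test_idx)
        train_cases = [cohort.cases[i] for i in train_idx]
        test_cases = [cohort.cases[i] for i in test_idx]
        with stage_timer(f"fold {fold}"):
            models = fit_feature_models(train_cases, config)
            X_train = encode_cases(train_cases, models)
            X_test = encode_cases(test_cases, models)
        out.append(
            FoldEncodings(
                fold=fold, train_idx=train_idx, test_idx=test_idx,
                X_train=X_train, X_test=X_test,
            )
        )
    return out


def evaluate_encoded(
    fold_encodings: Sequence[FoldEncodings],
    labels: np.ndarray,
    config: PipelineConfig,
    metrics: Sequence[str] = ("cfml",),
    prec_ns: Sequence[int] = (10, 20),
) -> dict:
    """Score pre-encoded folds under a labeling (metric refit per fold).

    ``prec@n`` is evaluated at min(n, database size), so small databases
    degrade to the overall relevant fraction instead of erroring.  Queries
    whose class is absent from the training database have undefined AP and
    are skipped (counted per fold as ``n_skipped``).
    """
    for m in metrics:
        if m not in ("cfml", "euclidean"):
            raise ValueError(f"unknown metric {m!r}")
    labels = np.asarray(labels)
    report: dict = {
        "n_folds": len(fold_encodings),
        "metrics": {m: {"folds": []} for m in metrics},
    }
    for enc in fold_encodings:
        y_train, y_test = labels[enc.train_idx], labels[enc.test_idx]
        eff_ns = {n: min(n, len(y_train)) for n in prec_ns}
        for m in metrics:
            if m == "cfml":
                scatter = build_pair_scatter(enc.X_train, y_train)
                metric_obj: MetricModel | str = fit_cfml(
                    scatter, config.D, config.lambda_reg
                )
            else:
                metric_obj = "euclidean"
            keep = np.isin(y_test, y_train)
            aps = np.empty(int(keep.sum()))
            precs = {n: np.empty(int(keep.sum())) for n in prec_ns}
            for i, qi in enumerate(np.nonzero(keep)[0]):
                r = rank_database(
                    enc.X_test[qi], enc.X_train, metric_obj,
                    query_label=int(y_test[qi]), database_labels=y_train,
                    prec_ns=sorted(set(eff_ns.values())),
                )
                aps[i] = r.ap
                for n in prec_ns:
                    precs[n][i] = r.prec[eff_ns[n]]
            fold_report = _fold_metrics(aps, precs, y_test[keep])
            fold_report["n_skipped"] = int((~keep).sum())
            report["metrics"][m]["folds"].append(fold_report)
    for m in metrics:
        folds = report["metrics"][m]["folds"]
        for key in ["mAP"] + [f"prec@{n}" for n in prec_ns]:
            vals = np.array([f[key] for f in folds])
            vals = vals[~np.isnan(vals)]
            report["metrics"][m][key] = {
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "std": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            }
    return report


def evaluate_pipeline(
    cohort: Cohort,
    config: PipelineConfig,
    n_folds: int = 5,
    metrics: Sequence[str] = ("cfml",),
    prec_ns: Sequence[int] = (10, 20),
    labels_override: np.ndarray | None = None,
) -> dict:
    """Patient-stratified cross-validated retrieval evaluation.

    For each fold, PCA, the vocabulary and the metric are fitted on the
    training folds only; every held-out slice then queries the training
    database.  ``metrics`` may contain ``"cfml"`` and/or ``"euclidean"``
    (both are evaluated on the same signatures).  ``labels_override``
    replaces the per-case labels everywhere (metric fitting and relevance);
    it is used for permutation-null experiments.

    Returns a report with per-fold values, mean and std over folds, and a
    per-class breakdown, for each requested metric.
    """
    labels = (
        cohort.labels if labels_override is None else np.asarray(labels_override)
    )
    if labels.shape[0] != len(cohort):
        raise ValueError("labels_override length must match the cohort")
    encodings = encode_folds(cohort, config, n_folds)
    return evaluate_encoded(encodings, labels, config, metrics, prec_ns)


def empirical_chance_map(
    cohort: Cohort,
    config: PipelineConfig,
    n_folds: int = 5,
    labels_override: np.ndarray | None = None,
    reps: int = 20,
    seed: int = 0,
) -> float:
    """Chance-level mAP: mean AP of random rankings under the same CV split.

    This is the class-prior baseline against which a label-permutation run
    should be compared (slightly above the raw relevant fraction because AP
    conditions on relevant positions).
    """
    labels = (
        cohort.labels if labels_override is None else np.asarray(labels_override)
    )
    split = patient_cv_split(cohort, n_folds, stage_seed(config.seed, "cv"))
    rng = np.random.default_rng(seed)
    aps = []
    for fold in range(n_folds):
        test_idx = split.fold_indices(cohort, fold)
        train_idx = np.setdiff1d(np.arange(len(cohort)), test_idx)
        for i in test_idx:
            rel = labels[train_idx] == labels[i]
            for _ in range(reps):
                aps.append(average_precision(rng.permutation(rel)))
    return float(np.mean(aps))
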