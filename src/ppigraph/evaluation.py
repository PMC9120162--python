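"""Binary-classifier evaluation: threshold metrics, ranking metrics, CV.

The metric suite matches the standard PPI benchmarking set: accuracy,
sensitivity (recall on positives), specificity, precision, F-score,
Matthews correlation coefficient, AUROC and AUPRC. Threshold metrics use
the >= 0.5 decision rule; any 0/0 ratio is reported as 0 with a warning
flag so cross-validation aggregation stays total.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold

from ppigraph.data import PairDataset
from ppigraph.errors import MetricError

METRIC_NAMES = ("acc", "Sn", "Sp", "Pr", "F_score", "MCC", "AUROC", "AUPRC")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvaluationReport:
    """The eight benchmark metrics, optionally with per-fold mean +- sd."""

    acc: float = math.nan
    Sn: float = math.nan
    Sp: float = math.nan
    Pr: float = math.nan
    F_score: float = math.nan
    MCC: float = math.nan
    AUROC: float = math.nan
    AUPRC: float = math.nan
    warnings: list[str] = field(default_factory=list)
    folds: list[dict] = field(default_factory=list)
    sd: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        if self.warnings:
            d["warnings"] = list(self.warnings)
        if self.folds:
            d["folds"] = self.folds
            d["sd"] = self.sd
        return d

    def to_json(self, path, extra: dict | None = None) -> None:
        payload = self.as_dict()
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _check_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError(
            f"scores/labels must be equal-length and non-empty, "
            f"got {scores.shape} vs {labels.shape}"
        )
    return scores, labels


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts under the 'predict positive iff score >= threshold' rule."""
    scores, labels = _check_scores(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float, name: str, warnings: list[str]) -> float:
    if den == 0:
        warnings.append(f"{name} undefined (0/0); reported as 0")
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> EvaluationReport:
    """Threshold metrics from confusion counts (AUROC/AUPRC left NaN).

    acc = (TP+TN)/n, Sn = TP/(TP+FN), Sp = TN/(TN+FP), Pr = TP/(TP+FP),
    F = 2*Pr*Sn/(Pr+Sn),
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    warnings: list[str] = []
    sn = _ratio(c.TP, c.TP + c.FN, "Sn", warnings)
    sp = _ratio(c.TN, c.TN + c.FP, "Sp", warnings)
    pr = _ratio(c.TP, c.TP + c.FP, "Pr", warnings)
    f = _ratio(2 * pr * sn, pr + sn, "F_score", warnings)
    mcc_den = math.sqrt(float((c.TP + c.FP) * (c.TP + c.FN)
                              * (c.TN + c.FP) * (c.TN + c.FN)))
    mcc = _ratio(c.TP * c.TN - c.FP * c.FN, mcc_den, "MCC", warnings)
    return EvaluationReport(acc=(c.TP + c.TN) / c.n, Sn=sn, Sp=sp, Pr=pr,
                            F_score=f, MCC=mcc, warnings=warnings)


def auroc(scores, labels) -> float:
    """Area under the ROC curve; ties get half credit (Mann-Whitney)."""
    scores, labels = _check_scores(scores, labels)
    if len(set(labels.tolist())) < 2:
        raise MetricError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    scores, labels = _check_scores(scores, labels)
    if len(set(labels.tolist())) < 2:
        raise MetricError("AUPRC undefined: only one class present")
    return float(average_precision_score(labels, scores))


def evaluate_scores(scores, labels, threshold: float = 0.5) -> EvaluationReport:
    """Full 8-metric report for a set of scored pairs."""
    report = metrics(confusion(scores, labels, threshold))
    try:
        report.AUROC = auroc(scores, labels)
        report.AUPRC = auprc(scores, labels)
    except MetricError as exc:
        report.warnings.append(str(exc))
    return report


def kfold_split(dataset: PairDataset, k: int = 5, seed: int = 0,
                stratified: bool = True) -> list[tuple[list[int], list[int]]]:
    """Deterministic k-fold (train_idx, test_idx) partitions.

    Stratification preserves the class ratio within +-1 item per fold and
    requires at least k members per class.
    """
    n = len(dataset)
    if n < k:
        raise ValueError(f"cannot split {n} pairs into {k} folds")
    labels = np.asarray(dataset.labels)
    if stratified:
        counts = np.bincount(labels, minlength=2)
        if counts.min() < k:
            raise MetricError(
                f"stratified {k}-fold needs >= {k} members per class, "
                f"got counts {counts.tolist()}"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train.tolist(), test.tolist())
            for train, test in splitter.split(np.zeros(n), labels)]


def train_test_split_pairs(dataset: PairDataset, test_fraction: float = 0.2,
                           seed: int = 0) -> tuple[PairDataset, PairDataset]:
    """Stratified hold-out split (default 80/20), deterministic per seed."""
    labels = np.asarray(dataset.labels)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_test = int(round(len(idx) * test_fraction))
        test_idx.extend(rng.permutation(idx)[:n_test].tolist())
    test_set = set(test_idx)
    train_idx = [i for i in range(len(dataset)) if i not in test_set]
    return dataset.subset(train_idx), dataset.subset(sorted(test_set))


def cross_validate(dataset: PairDataset, graphs: dict, features: dict,
                   config, k: int = 5, stratified: bool = True) -> EvaluationReport:
    """k-fold cross-validation of the pair model; mean +- sample sd per metric.

    Trains on k-1 folds and evaluates on the held-out fold; folds and
    training are both seeded from the config, so a rerun with the same
    inputs reproduces the report exactly.
    """
    from ppigraph.ppi_model import predict_dataset, train

    folds = kfold_split(dataset, k=k, seed=config.seed, stratified=stratified)
    per_fold: list[dict] = []
    for train_idx, test_idx in folds:
        params, _ = train(dataset.subset(train_idx), graphs, features, config)
        test_set = dataset.subset(test_idx)
        probs = predict_dataset(test_set, graphs, features, params, config)
        per_fold.append(evaluate_scores(probs, test_set.labels).as_dict())

    report = EvaluationReport()
    report.folds = per_fold
    for name in METRIC_NAMES:
        vals = np.array([f[name] for f in per_fold], dtype=float)
        setattr(report, name, float(np.mean(vals)))
        report.sd[name] = float(np.std(vals, ddof=1))
    return report


def layer_depth_experiment(dataset: PairDataset, graphs: dict, features: dict,
                           base_config, depths=(1, 2, 3),
                           test_fraction: float = 0.2) -> dict[int, dict]:
    """Hold-out evaluation of 1-, 2- and 3-layer GNN encoders.

    Trains one model per depth on the same stratified split (everything
    else taken from ``base_config``) and returns a depth -> 8-metric
    report table, the over-smoothing comparison harness.
    """
    import dataclasses

    from ppigraph.ppi_model import predict_dataset, train

    train_set, test_set = train_test_split_pairs(dataset, test_fraction,
                                                 base_config.seed)
    table: dict[int, dict] = {}
    for depth in depths:
        config = dataclasses.replace(base_config, n_gnn_layers=depth)
        params, _ = train(train_set, graphs, features, config)
        probs = predict_dataset(test_set, graphs, features, params, config)
        table[depth] = evaluate_scores(probs, test_set.labels).as_dict()
    return table
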