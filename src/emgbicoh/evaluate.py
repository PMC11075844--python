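"""Evaluation protocol: repeated random subsampling, seven metrics, and
across-muscle statistical comparison.

The dataset is re-partitioned into train / validation / test splits
(70/15/15 by default) several times (five by default); a classifier is
trained per run and the per-run confusion matrix yields accuracy,
precision, sensitivity, specificity, F-measure, Matthews correlation
coefficient (MCC) and AUC, each computed with both classes as positive.
Results are reported as mean with sample standard deviation across runs.
Muscle groups are compared with a one-way ANOVA on the per-run values
followed by Tukey's HSD post-hoc test at alpha = 0.05.

Splits can be drawn at the image level or — the safer default for cohort
data where class is a property of the subject — at the subject level, so no
subject contributes images to more than one partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .cnn import CompactCNNClassifier

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "ConfusionMatrix",
    "EvaluationReport",
    "METRIC_NAMES",
    "split_dataset",
    "train_classifier",
    "predict",
    "confusion_from_predictions",
    "compute_metrics",
    "aggregate_runs",
    "run_protocol",
    "compare_groups",
]

METRIC_NAMES = (
    "accuracy",
    "precision",
    "sensitivity",
    "specificity",
    "f_measure",
    "mcc",
    "auc",
)


@dataclass(frozen=True)
class TrainConfig:
    """Classifier training hyperparameters (Adam defaults)."""

    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 60
    validation_frequency: int = 3
    seed: int = 0
    backbone: str = "compact_cnn"

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class SplitPlan:
    """Repeated random subsampling layout."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    unit: str = "subject"
    n_runs: int = 5
    seed: int = 0

    def validate(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("all fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"fractions must sum to 1, got {sum(self.fractions)}"
            )
        if self.unit not in ("image", "subject"):
            raise ValueError(f"unit must be 'image' or 'subject', got {self.unit!r}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with an explicit positive class."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive: str = "KOA"

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class EvaluationReport:
    """Per-run metrics plus mean +- sample STD across runs for one group."""

    group: str
    per_run: pd.DataFrame
    summary: pd.DataFrame
    confusions: list[ConfusionMatrix] = field(default_factory=list)


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total`` closest to real ``targets``."""
    base = np.floor(targets).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(targets - base), kind="stable")
        base[order[:short]] += 1
    return base


def split_dataset(
    manifest: pd.DataFrame, plan: SplitPlan, run_index: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stratified (train, validation, test) partition of a manifest.

    Partition sizes hit the fractions exactly up to rounding, globally and
    as closely as possible within each class. With ``unit='subject'`` whole
    subjects are assigned to partitions, so no subject spans two of them.
    Deterministic in (plan.seed, run_index).
    """
    plan.validate()
    if manifest.empty:
        raise ValueError("manifest is empty")
    if run_index >= plan.n_runs or run_index < 0:
        raise ValueError(f"run_index {run_index} outside 0..{plan.n_runs - 1}")
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, run_index]))

    if plan.unit == "subject":
        units = (
            manifest[["subject_id", "class_label"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )
        key = "subject_id"
    else:
        units = manifest.reset_index(drop=True).copy()
        units["_row"] = np.arange(len(units))
        key = "_row"

    n = len(units)
    fracs = np.asarray(plan.fractions)
    global_counts = _largest_remainder(fracs * n, n)
    if (global_counts == 0).any():
        raise ValueError(
            f"a partition would be empty: {n} units at fractions {plan.fractions}"
        )

    classes = sorted(units["class_label"].unique())
    # per-class floors, then greedily assign the leftover units to the
    # partitions still short of their global counts, largest remainder first;
    # exact global sizes, within-class stratification exact up to rounding
    targets = {
        c: fracs * (units["class_label"] == c).sum() for c in classes
    }
    alloc = {c: np.floor(targets[c]).astype(int) for c in classes}
    leftover = {c: int((units["class_label"] == c).sum() - alloc[c].sum()) for c in classes}
    need = global_counts - np.sum([alloc[c] for c in classes], axis=0)
    candidates = sorted(
        ((c, p) for c in classes for p in range(3)),
        key=lambda cp: (-(targets[cp[0]][cp[1]] - alloc[cp[0]][cp[1]]), cp[1], cp[0]),
    )
    for c, p in candidates:
        if need[p] > 0 and leftover[c] > 0:
            alloc[c][p] += 1
            leftover[c] -= 1
            need[p] -= 1
    # any residue (rare): place remaining units wherever capacity remains
    for c in classes:
        for p in range(3):
            while leftover[c] > 0 and need[p] > 0:
                alloc[c][p] += 1
                leftover[c] -= 1
                need[p] -= 1

    part_keys: list[list] = [[], [], []]
    for c in classes:
        keys = units.loc[units["class_label"] == c, key].to_numpy()
        keys = keys[rng.permutation(len(keys))]
        counts = alloc[c]
        start = 0
        for p in range(3):
            part_keys[p].extend(keys[start : start + counts[p]])
            start += counts[p]

    if plan.unit == "subject":
        parts = tuple(
            manifest[manifest["subject_id"].isin(pk)].reset_index(drop=True)
            for pk in part_keys
        )
    else:
        parts = tuple(
            manifest.iloc[sorted(pk)].reset_index(drop=True) for pk in part_keys
        )
    if any(len(p) == 0 for p in parts):
        raise ValueError("a partition is empty after splitting")
    return parts


def train_classifier(
    X_train,
    y_train,
    X_val,
    y_val,
    config: TrainConfig = TrainConfig(),
    backbone=None,
):
    """Fit the configured backbone; returns the trained model.

    ``backbone='compact_cnn'`` (default) builds :class:`CompactCNNClassifier`
    from the config; any object with the sklearn classifier API may be
    passed explicitly instead (``backbone='external'``).
    """
    config.validate()
    if len(np.unique(np.asarray(y_train))) < 2:
        raise ValueError("training set contains a single class")
    if backbone is None:
        if config.backbone != "compact_cnn":
            raise ValueError(
                f"backbone {config.backbone!r} requires an explicit model object"
            )
        backbone = CompactCNNClassifier(
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            validation_frequency=config.validation_frequency,
            seed=config.seed,
        )
    try:
        backbone.fit(X_train, y_train, X_val=X_val, y_val=y_val)
    except TypeError:  # external backbones without a validation-set hook
        backbone.fit(X_train, y_train)
    return backbone


def predict(model, X) -> np.ndarray:
    """Class probabilities per image, rows summing to 1."""
    return model.predict_proba(np.asarray(X))


def confusion_from_predictions(
    y_true, y_pred, positive: str = "KOA"
) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        positive=positive,
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else math.nan


def compute_metrics(
    cm: ConfusionMatrix, scores=None, labels=None
) -> dict[str, float]:
    """Seven-metric set from a confusion matrix and (optionally) scores.

    ``scores`` are positive-class probabilities for the test items and
    ``labels`` the true labels; AUC is the tie-corrected rank statistic
    (equivalently the Mann-Whitney estimator). Ratios with zero denominator
    are reported as NaN rather than coerced to 0.
    """
    if cm.total == 0:
        raise ValueError("empty test set")
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    precision = _safe_div(tp, tp + fp)
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f_measure = _safe_div(2 * precision * sensitivity, precision + sensitivity)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    auc = math.nan
    if scores is not None and labels is not None:
        y = np.asarray(labels) == cm.positive
        if y.all() or not y.any():
            auc = math.nan
        else:
            auc = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    return {
        "accuracy": (tp + tn) / cm.total,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f_measure": f_measure,
        "mcc": mcc,
        "auc": auc,
    }


def aggregate_runs(per_run: pd.DataFrame, group: str = "ALL") -> EvaluationReport:
    """Mean and sample (n-1) standard deviation of each metric across runs."""
    if per_run["run"].nunique() < 2:
        raise ValueError("need at least 2 runs to aggregate")
    cols = [c for c in METRIC_NAMES if c in per_run.columns]
    grouped = per_run.groupby("positive_class")[cols] if "positive_class" in per_run else None
    if grouped is not None:
        summary = grouped.agg(["mean", "std"])
    else:
        summary = per_run[cols].agg(["mean", "std"]).T
    return EvaluationReport(group=group, per_run=per_run, summary=summary)


def run_protocol(
    images: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
    plan: SplitPlan = SplitPlan(),
    train_config: TrainConfig = TrainConfig(),
    group: str = "ALL",
    positive: str = "KOA",
    backbone_factory=None,
) -> EvaluationReport:
    """Full repeated-random-subsampling evaluation of one image set.

    For each of ``plan.n_runs`` runs: split, train the backbone on the
    train partition with validation-based model selection, score the test
    partition, and compute the seven metrics with each class as positive.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    manifest = pd.DataFrame(
        {"subject_id": subjects, "class_label": labels}
    )
    manifest["_idx"] = np.arange(len(manifest))
    classes = sorted(np.unique(labels))
    rows = []
    confusions = []
    for run in range(plan.n_runs):
        tr, va, te = split_dataset(manifest, plan, run)
        cfg = TrainConfig(
            optimizer=train_config.optimizer,
            learning_rate=train_config.learning_rate,
            batch_size=train_config.batch_size,
            max_epochs=train_config.max_epochs,
            validation_frequency=train_config.validation_frequency,
            seed=int(np.random.SeedSequence([train_config.seed, run]).generate_state(1)[0] % (2**31)),
            backbone=train_config.backbone,
        )
        backbone = backbone_factory(cfg) if backbone_factory else None
        model = train_classifier(
            images[tr["_idx"]],
            labels[tr["_idx"]],
            images[va["_idx"]],
            labels[va["_idx"]],
            cfg,
            backbone=backbone,
        )
        te_idx = te["_idx"].to_numpy()
        probs = predict(model, images[te_idx])
        pred = np.asarray(model.classes_)[np.argmax(probs, axis=1)]
        y_te = labels[te_idx]
        for pos in classes:
            cm = confusion_from_predictions(y_te, pred, positive=pos)
            pos_col = list(model.classes_).index(pos)
            metrics = compute_metrics(cm, scores=probs[:, pos_col], labels=y_te)
            rows.append({"run": run, "positive_class": pos, **metrics})
            if pos == positive:
                confusions.append(cm)
    per_run = pd.DataFrame(rows)
    report = aggregate_runs(per_run, group=group)
    report.confusions = confusions
    return report


def compare_groups(
    group_values: dict[str, np.ndarray], alpha: float = 0.05
) -> dict:
    """One-way ANOVA across groups plus Tukey HSD pairwise decisions.

    ``group_values`` maps a group label (muscle name) to its per-run metric
    values. Returns the ANOVA F statistic and p-value and a tidy Tukey
    table with a boolean ``reject`` column at the given alpha.
    """
    if len(group_values) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in group_values.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if all(np.ptp(v) == 0 for v in arrays.values()):
        raise ValueError(
            "degenerate design: zero within-group variance in every group"
        )
    f_stat, p_value = stats.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    groups = np.concatenate(
        [np.repeat(g, v.size) for g, v in arrays.items()]
    )
    tukey = pairwise_tukeyhsd(values, groups, alpha=alpha)
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    table["reject"] = table["reject"].astype(bool)
    return {
        "f_statistic": float(f_stat),
        "p_value": float(p_value),
        "alpha": alpha,
        "tukey": table,
    }
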