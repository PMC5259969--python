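"""Confusion-matrix analytics and experiment drivers.

The headline accuracy throughout is the "diagonal average": the mean of
per-class correct fractions of a confusion matrix. With balanced classes
it coincides with trace/total; both are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import classifier as clf
from .classifier import NetworkSpec, SplitSpec

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "confusion_matrix",
    "accuracy_report",
    "averaged_confusion",
    "training_size_sweep",
    "SweepResult",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.labels)
        if c.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def pretty(self) -> str:
        return self.to_frame().to_string()


@dataclass(frozen=True)
class AccuracyReport:
    """Per-class and overall percentages of one confusion matrix."""

    labels: tuple[str, ...]
    per_class_accuracy: tuple[float, ...]  # percent
    overall_accuracy: float  # diagonal average, percent (headline number)
    trace_accuracy: float  # trace/total, percent
    n_total: float


def confusion_matrix(
    true_labels: Sequence[str], predicted_labels: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    """Tally counts[i][j] = #(true = labels[i], predicted = labels[j])."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    order = tuple(str(l) for l in labels)
    pos = {lab: i for i, lab in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if str(t) not in pos or str(p) not in pos:
            raise ValueError(f"label outside declared set: {t!r} / {p!r}")
        counts[pos[str(t)], pos[str(p)]] += 1
    return ConfusionMatrix(labels=order, counts=counts)


def accuracy_report(cm: ConfusionMatrix) -> AccuracyReport:
    """Per-class percentage and the diagonal-average overall accuracy."""
    counts = np.asarray(cm.counts, dtype=float)
    row_sums = counts.sum(axis=1)
    if (row_sums <= 0).any():
        empty = [cm.labels[i] for i in np.flatnonzero(row_sums <= 0)]
        raise ValueError(f"empty class row(s): {empty}")
    per_class = 100.0 * np.diag(counts) / row_sums
    return AccuracyReport(
        labels=cm.labels,
        per_class_accuracy=tuple(float(v) for v in per_class),
        overall_accuracy=float(per_class.mean()),
        trace_accuracy=float(100.0 * np.trace(counts) / counts.sum()),
        n_total=float(counts.sum()),
    )


def averaged_confusion(
    run: Callable[[int], ConfusionMatrix],
    n_reps: int,
    seed: int = 0,
    retry_cap: int = 3,
) -> tuple[ConfusionMatrix, AccuracyReport]:
    """Element-wise mean of ``n_reps`` repeated identification runs.

    ``run(rep_seed)`` performs one full split/train/identify cycle and
    returns its confusion matrix; rep seeds derive from ``seed``. A failing
    repetition is resampled with a fresh seed up to ``retry_cap`` times.
    The overall accuracy is the diagonal average of the mean matrix.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    mats = []
    labels = None
    for _ in range(n_reps):
        for attempt in range(retry_cap + 1):
            rep_seed = int(rng.integers(2**31))
            try:
                cm = run(rep_seed)
                break
            except Exception:
                if attempt == retry_cap:
                    raise
        if labels is None:
            labels = cm.labels
        elif cm.labels != labels:
            raise ValueError("repetitions disagree on the label set")
        mats.append(np.asarray(cm.counts, dtype=float))
    mean_cm = ConfusionMatrix(labels=labels, counts=np.mean(mats, axis=0))
    return mean_cm, accuracy_report(mean_cm)


def two_stage_experiment(
    table: pd.DataFrame,
    seed: int = 0,
    n_restarts: int = 5,
    n_hidden: int = 10,
    split: SplitSpec | None = None,
    flat: bool = False,
    max_epochs: int = 300,
) -> tuple[ConfusionMatrix, AccuracyReport]:
    """Split, train, and test one full identification experiment.

    ``table`` is a descriptor table with ``view``, ``klass`` and the seven
    feature columns. Rows are split stratified on the composite
    ``view:klass`` label. In hierarchical mode (default) the training rows
    fit the stage-1 view network plus one stage-2 network per view, and a
    test row counts as correct only when both stages are; in ``flat`` mode
    a single 12-output network over the composite labels is fitted on the
    same split. Returns the composite-label test confusion matrix and its
    accuracy report.
    """
    from .shape_features import FEATURE_NAMES

    x = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    views = table["view"].to_numpy()
    klasses = table["klass"].to_numpy()
    composite = np.array([f"{v}:{k}" for v, k in zip(views, klasses)])
    split = split or SplitSpec(seed=seed)
    tr, va, te = clf.split_dataset(composite, split)

    if flat:
        net = clf.train_flat_12(
            x, composite, spec=NetworkSpec(n_hidden=n_hidden, n_outputs=12),
            split=(tr, va, te), n_restarts=n_restarts, seed=seed,
            max_epochs=max_epochs,
        )
        pred = [net.labels[k] for k in np.argmax(net.forward(x[te]), axis=1)]
    else:
        # stage networks reuse the experiment's own partition: the training
        # rows drive the gradient, the validation rows drive early stopping
        stage1 = clf.train_network(
            x, views, spec=NetworkSpec(n_hidden=n_hidden, n_outputs=3),
            split=(tr, va, te), n_restarts=n_restarts, seed=seed,
            max_epochs=max_epochs,
        )
        stage2 = {}
        for view in np.unique(views):
            vtr = tr[views[tr] == view]
            vva = va[views[va] == view]
            vte = te[views[te] == view]
            stage2[view] = clf.train_network(
                x, klasses, spec=NetworkSpec(n_hidden=n_hidden, n_outputs=4),
                split=(vtr, vva, vte), n_restarts=n_restarts,
                seed=seed + 1, max_epochs=max_epochs,
            )
        pred = []
        for i in te:
            res = clf.identify_features(x[i], stage1, stage2)
            pred.append(f"{res.view}:{res.klass}")
    order = sorted(set(composite))
    cm = confusion_matrix(composite[te], pred, order)
    return cm, accuracy_report(cm)


@dataclass(frozen=True)
class SweepResult:
    """One row per training percentage; task accuracies plus their mean."""

    table: pd.DataFrame

    COLUMNS = ("train_pct", "test_pct", "val_pct",
               "all_views", "dorsal", "lateral", "jaw", "average")

    def __post_init__(self) -> None:
        if tuple(self.table.columns) != self.COLUMNS:
            raise ValueError(f"sweep columns must be {self.COLUMNS}")


def _nested_split(
    labels: np.ndarray, train_pct: float, order: dict
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # prefix of a fixed per-class shuffle => training sets grow by inclusion
    train, val, test = [], [], []
    for k, idx in order.items():
        n_tr = int(np.floor(train_pct / 100.0 * len(idx)))
        rest = idx[n_tr:]
        n_te = int(np.ceil(len(rest) / 2.0))
        train.append(idx[:n_tr])
        test.append(rest[:n_te])
        val.append(rest[n_te:])
    return (np.sort(np.concatenate(train)),
            np.sort(np.concatenate(val)),
            np.sort(np.concatenate(test)))


def training_size_sweep(
    table: pd.DataFrame,
    percentages: Sequence[float] = (50, 60, 70, 80, 90),
    seed: int = 0,
    n_restarts: int = 3,
    n_hidden: int = 10,
    max_epochs: int = 300,
) -> SweepResult:
    """Test accuracy of the four tasks as the training share grows.

    ``table`` is a descriptor table with ``view``, ``klass`` and the seven
    feature columns (as produced by
    :func:`shrewid.synthetic_imaging.generate_feature_table`). For each
    percentage p, p% of each class (a prefix of one fixed per-class
    shuffle, so the 50% training set is a subset of the 90% one) trains the
    network and the remainder is split equally into test and validation.
    Four tasks are evaluated: view classification over all rows, and
    class classification within each view; the ``average`` column is the
    arithmetic mean of the four test accuracies.
    """
    from .shape_features import FEATURE_NAMES

    for p in percentages:
        if not (0.0 < p < 100.0):
            raise ValueError("percentages must lie in (0, 100)")
    feats = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    tasks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tasks["all_views"] = (np.arange(len(table)), table["view"].to_numpy())
    for view in ("dorsal", "lateral", "jaw"):
        rows = np.flatnonzero((table["view"] == view).to_numpy())
        tasks[view] = (rows, table["klass"].to_numpy()[rows])

    # one fixed shuffle per task and class, reused across percentages
    orders = {}
    for name, (rows, labs) in tasks.items():
        orders[name] = {
            k: rng.permutation(np.flatnonzero(labs == k)) for k in np.unique(labs)
        }

    out_rows = []
    for p in sorted(percentages):
        accs = {}
        for name, (rows, labs) in tasks.items():
            tr, va, te = _nested_split(labs, p, orders[name])
            net = clf.train_network(
                feats[rows], labs,
                spec=NetworkSpec(n_hidden=n_hidden, n_outputs=len(set(labs))),
                split=(tr, va, te), n_restarts=n_restarts,
                seed=seed + 1, max_epochs=max_epochs,
            )
            order = net.labels
            pred = [order[k] for k in np.argmax(net.forward(feats[rows][te]), axis=1)]
            cm = confusion_matrix(labs[te], pred, order)
            accs[name] = accuracy_report(cm).overall_accuracy
        rest = (100.0 - p) / 2.0
        out_rows.append((p, rest, rest, accs["all_views"], accs["dorsal"],
                         accs["lateral"], accs["jaw"],
                         float(np.mean([accs[t] for t in
                                        ("all_views", "dorsal", "lateral", "jaw")]))))
    return SweepResult(pd.DataFrame(out_rows, columns=list(SweepResult.COLUMNS)))
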