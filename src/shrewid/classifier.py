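"""Two-layer feed-forward softmax networks and the two-stage identifier.

Stage 1 assigns the skull view (dorsal / jaw / lateral) from the seven
shape descriptors; stage 2 holds one network per view that assigns the
population-sex class (NM / NF / SM / SF). A flat single-network variant
over the 12 composite view x class labels is provided for comparison.

Training minimizes multiclass cross-entropy on one-hot targets by
full-batch gradient descent with an adaptive step (the step is accepted
only if the training loss does not increase, so the training trajectory is
monotone). Early stopping watches the validation cross-entropy: after
``max_fail`` consecutive epochs without improvement training halts and the
best-validation weights are restored. The whole procedure is repeated for
``n_restarts`` independent initializations and the restart with the lowest
validation cross-entropy wins — the "train several times, keep the best
network" protocol.

Everything is deterministic under the given integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .shape_features import FEATURE_NAMES, FeatureVector

__all__ = [
    "NetworkSpec",
    "SplitSpec",
    "TrainedNetwork",
    "TrainingReport",
    "IdentificationResult",
    "DegenerateFeatureError",
    "normalize_features",
    "split_dataset",
    "train_network",
    "train_flat_12",
    "predict",
    "two_stage_identify",
    "identify_features",
]


class DegenerateFeatureError(ValueError):
    """A feature column was constant on the training split."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture: 7 inputs -> tanh hidden layer -> softmax outputs."""

    n_inputs: int = 7
    n_hidden: int = 10
    n_outputs: int = 3

    def __post_init__(self) -> None:
        if self.n_inputs != len(FEATURE_NAMES):
            raise ValueError(f"n_inputs must be {len(FEATURE_NAMES)} (one per descriptor)")
        if self.n_hidden < 1 or self.n_outputs < 2:
            raise ValueError("need n_hidden >= 1 and n_outputs >= 2")


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation/test fractions (default 70/15/15)."""

    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(not (0.0 < f < 1.0) for f in fracs):
            raise ValueError("all split fractions must lie strictly in (0, 1)")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class TrainingReport:
    """Per-epoch cross-entropy trajectories and restart bookkeeping."""

    cross_entropy: dict[str, list[float]]  # keys: train, val, test
    best_epoch: int
    n_restarts_run: int
    selected_restart: int
    confusion: dict[str, np.ndarray] = field(default_factory=dict)
    labels: tuple[str, ...] = ()


@dataclass
class TrainedNetwork:
    """Weights, feature normalization, label order, and training report."""

    w1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray
    w2: np.ndarray  # (n_outputs, n_hidden)
    b2: np.ndarray
    feat_min: np.ndarray
    feat_max: np.ndarray
    labels: tuple[str, ...]
    spec: NetworkSpec
    report: TrainingReport | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Softmax posteriors for (n, 7) raw (unnormalized) features."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xn = _apply_norm(x, self.feat_min, self.feat_max)
        return _softmax(np.tanh(xn @ self.w1.T + self.b1) @ self.w2.T + self.b2)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "labels": list(self.labels),
            "spec": {"n_inputs": self.spec.n_inputs, "n_hidden": self.spec.n_hidden,
                     "n_outputs": self.spec.n_outputs},
            "weights": {k: getattr(self, k).tolist() for k in ("w1", "b1", "w2", "b2")},
            "normalization": {"min": self.feat_min.tolist(), "max": self.feat_max.tolist()},
            "report": None if self.report is None else {
                "best_epoch": self.report.best_epoch,
                "n_restarts_run": self.report.n_restarts_run,
                "selected_restart": self.report.selected_restart,
                "final_val_cross_entropy": self.report.cross_entropy["val"][
                    self.report.best_epoch - 1],
            },
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedNetwork":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            w1=np.array(doc["weights"]["w1"]),
            b1=np.array(doc["weights"]["b1"]),
            w2=np.array(doc["weights"]["w2"]),
            b2=np.array(doc["weights"]["b2"]),
            feat_min=np.array(doc["normalization"]["min"]),
            feat_max=np.array(doc["normalization"]["max"]),
            labels=tuple(doc["labels"]),
            spec=NetworkSpec(**doc["spec"]),
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _apply_norm(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def normalize_features(
    table: np.ndarray, params: tuple[np.ndarray, np.ndarray] | None = None
):
    """Per-feature min-max mapping to [-1, 1].

    Fit mode (``params is None``) returns ``(normalized, (min, max))``;
    apply mode returns the normalized array only. Values outside the fitted
    range map outside [-1, 1] and are passed through without clipping.
    """
    x = np.atleast_2d(np.asarray(table, dtype=float))
    if params is None:
        lo = x.min(axis=0)
        hi = x.max(axis=0)
        if np.any(hi - lo <= 0):
            bad = [FEATURE_NAMES[i] for i in np.flatnonzero(hi - lo <= 0)
                   if i < len(FEATURE_NAMES)]
            raise DegenerateFeatureError(f"constant feature column(s) at fit time: {bad}")
        return _apply_norm(x, lo, hi), (lo, hi)
    lo, hi = params
    return _apply_norm(x, lo, hi)


def _apportion(n: int, fracs: Sequence[float]) -> list[int]:
    # largest-remainder apportionment; ties go to the earlier set
    base = [math.floor(f * n) for f in fracs]
    rem = [f * n - b for f, b in zip(fracs, base)]
    for _ in range(n - sum(base)):
        i = max(range(len(fracs)), key=lambda j: (rem[j], -j))
        base[i] += 1
        rem[i] = -1.0
    return base


def split_dataset(
    labels: Sequence[str], spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, per-class stratified (train, val, test) indices.

    Counts per class follow largest-remainder rounding in set order
    (train, val, test), so n=30 at 70/15/15 gives 21/5/4. Deterministic
    under ``spec.seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    train, val, test = [], [], []
    groups = (
        [labels == k for k in np.unique(labels)] if spec.stratified
        else [np.ones(len(labels), dtype=bool)]
    )
    for sel in groups:
        idx = np.flatnonzero(sel)
        if spec.stratified and len(idx) < 3:
            raise ValueError("every class needs >= 3 members for a stratified split")
        idx = rng.permutation(idx)
        n_tr, n_va, n_te = _apportion(len(idx), (spec.train_frac, spec.val_frac, spec.test_frac))
        train.append(idx[:n_tr])
        val.append(idx[n_tr:n_tr + n_va])
        test.append(idx[n_tr + n_va:])
    return (np.sort(np.concatenate(train)),
            np.sort(np.concatenate(val)),
            np.sort(np.concatenate(test)))


def _loss_and_grad(params, shapes, xn, y):
    w1, b1, w2, b2 = _unpack(params, shapes)
    h = np.tanh(xn @ w1.T + b1)
    p = _softmax(h @ w2.T + b2)
    n = len(xn)
    eps = 1e-12
    loss = -float(np.sum(y * np.log(p + eps))) / n
    dz2 = (p - y) / n
    gw2 = dz2.T @ h
    gb2 = dz2.sum(axis=0)
    dh = (dz2 @ w2) * (1.0 - h**2)
    gw1 = dh.T @ xn
    gb1 = dh.sum(axis=0)
    return loss, np.concatenate([gw1.ravel(), gb1, gw2.ravel(), gb2])


def _unpack(params, shapes):
    out = []
    k = 0
    for s in shapes:
        size = int(np.prod(s))
        out.append(params[k:k + size].reshape(s))
        k += size
    return out


def _cross_entropy(params, shapes, xn, y):
    if len(xn) == 0:
        return math.nan
    w1, b1, w2, b2 = _unpack(params, shapes)
    p = _softmax(np.tanh(xn @ w1.T + b1) @ w2.T + b2)
    return -float(np.sum(y * np.log(p + 1e-12))) / len(xn)


def _fit_once(xn, y, splits, spec, rng, max_epochs, max_fail, lr0):
    tr, va, te = splits
    shapes = [(spec.n_hidden, spec.n_inputs), (spec.n_hidden,),
              (spec.n_outputs, spec.n_hidden), (spec.n_outputs,)]
    n_par = sum(int(np.prod(s)) for s in shapes)
    params = rng.normal(0.0, 0.5, size=n_par)
    lr = lr0
    traj = {"train": [], "val": [], "test": []}
    best_val = math.inf
    best_params = params.copy()
    best_epoch = 0
    fails = 0
    loss, grad = _loss_and_grad(params, shapes, xn[tr], y[tr])
    for epoch in range(1, max_epochs + 1):
        stepped = False
        for _ in range(40):  # backtrack until the training loss does not rise
            cand = params - lr * grad
            new_loss, new_grad = _loss_and_grad(cand, shapes, xn[tr], y[tr])
            if math.isfinite(new_loss) and new_loss <= loss:
                params, loss, grad = cand, new_loss, new_grad
                lr *= 1.2
                stepped = True
                break
            lr *= 0.5
            if lr < 1e-14:
                break
        traj["train"].append(loss)
        # an empty validation split (possible in extreme sweep shares) falls
        # back to the training loss for stopping and restart selection
        val_ce = _cross_entropy(params, shapes, xn[va], y[va]) if len(va) else loss
        traj["val"].append(val_ce)
        traj["test"].append(_cross_entropy(params, shapes, xn[te], y[te]))
        if val_ce < best_val - 1e-12:
            best_val = val_ce
            best_params = params.copy()
            best_epoch = epoch
            fails = 0
        else:
            fails += 1
        if fails >= max_fail or not stepped:
            break
    return best_params, best_val, best_epoch, traj, shapes


def train_network(
    features: np.ndarray,
    labels: Sequence[str],
    spec: NetworkSpec | None = None,
    split: SplitSpec | tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    max_epochs: int = 300,
    max_fail: int = 6,
    learning_rate: float = 0.1,
) -> TrainedNetwork:
    """Train one softmax network; keep the best of ``n_restarts`` restarts.

    ``split`` is either a :class:`SplitSpec` (an internal stratified split
    is drawn) or explicit (train, val, test) index arrays. Feature
    normalization is fitted on the training rows only. Restart selection is
    by validation cross-entropy; the test split never influences selection.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray([str(l) for l in labels])
    label_order = tuple(sorted(set(labels)))
    if len(label_order) < 2:
        raise ValueError("need at least 2 classes")
    if split is None:
        split = SplitSpec(seed=seed)
    if isinstance(split, SplitSpec):
        splits = split_dataset(labels, split)
    else:
        splits = tuple(np.asarray(s, dtype=int) for s in split)
    tr, va, te = splits
    spec = spec or NetworkSpec(n_outputs=len(label_order))
    if spec.n_outputs != len(label_order):
        raise ValueError(f"spec.n_outputs={spec.n_outputs} but {len(label_order)} classes present")

    _, (lo, hi) = normalize_features(x[tr])
    xn = _apply_norm(x, lo, hi)
    y = np.zeros((len(labels), len(label_order)))
    for j, lab in enumerate(label_order):
        y[labels == lab, j] = 1.0

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(17,))
    children = ss.spawn(n_restarts)
    best = None
    n_run = 0
    for r in range(n_restarts):
        rng = np.random.default_rng(children[r])
        try:
            result = _fit_once(xn, y, splits, spec, rng, max_epochs, max_fail, learning_rate)
        except FloatingPointError:  # pragma: no cover - abort restart, keep going
            continue
        n_run += 1
        if not math.isfinite(result[1]):
            continue
        if best is None or result[1] < best[1][1]:
            best = (r, result)
    if best is None:
        raise RuntimeError("all restarts diverged")
    r_sel, (params, _, best_epoch, traj, shapes) = best
    w1, b1, w2, b2 = (a.copy() for a in _unpack(params, shapes))

    net = TrainedNetwork(w1=w1, b1=b1, w2=w2, b2=b2, feat_min=lo, feat_max=hi,
                         labels=label_order, spec=spec)
    report = TrainingReport(
        cross_entropy=traj, best_epoch=best_epoch, n_restarts_run=n_run,
        selected_restart=r_sel, labels=label_order,
    )
    for name, idx in (("train", tr), ("val", va), ("test", te)):
        if len(idx):
            pred = [label_order[k] for k in np.argmax(net.forward(x[idx]), axis=1)]
            report.confusion[name] = _counts(labels[idx], pred, label_order)
    net.report = report
    return net


def _counts(true_labels, pred_labels, order) -> np.ndarray:
    k = len(order)
    pos = {lab: i for i, lab in enumerate(order)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        cm[pos[t], pos[p]] += 1
    return cm


def predict(net: TrainedNetwork, features: np.ndarray) -> tuple[str, np.ndarray]:
    """Label (argmax posterior, ties to the lowest label index) and posteriors."""
    x = np.asarray(features, dtype=float)
    if isinstance(features, FeatureVector):
        x = features.as_array()
    if x.ndim != 1 or len(x) != net.spec.n_inputs:
        raise ValueError(f"expected a feature vector of length {net.spec.n_inputs}")
    probs = net.forward(x)[0]
    return net.labels[int(np.argmax(probs))], probs


def train_flat_12(
    features: np.ndarray,
    labels_view_region_sex: Sequence[str],
    spec: NetworkSpec | None = None,
    split: SplitSpec | tuple | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    **kwargs,
) -> TrainedNetwork:
    """Single 12-class network over composite ``view:klass`` labels."""
    labs = [str(l) for l in labels_view_region_sex]
    present = sorted(set(labs))
    if len(present) != 12:
        raise ValueError(f"all 12 composite labels must be present, got {len(present)}")
    spec = spec or NetworkSpec(n_outputs=12)
    if spec.n_outputs != 12:
        raise ValueError("flat network must have 12 outputs")
    return train_network(features, labs, spec=spec, split=split,
                         n_restarts=n_restarts, seed=seed, **kwargs)


@dataclass(frozen=True)
class IdentificationResult:
    """Two-stage identification outcome for one image."""

    view: str
    view_probs: np.ndarray
    klass: str
    klass_probs: np.ndarray
    features: FeatureVector
    roi_area: int

    def validate(self) -> None:
        for p in (self.view_probs, self.klass_probs):
            if abs(float(p.sum()) - 1.0) > 1e-9:
                raise ValueError("posterior vector must sum to 1")


def identify_features(
    fv: FeatureVector | np.ndarray,
    stage1: TrainedNetwork,
    stage2: Mapping[str, TrainedNetwork],
    roi_area: int = 0,
) -> IdentificationResult:
    """Route a feature vector through stage 1 (view) then stage 2 (class)."""
    missing = [v for v in stage1.labels if v not in stage2]
    if missing:
        raise ValueError(f"stage-2 map is missing networks for views: {missing}")
    x = fv.as_array() if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float)
    view, vp = predict(stage1, x)
    klass, kp = predict(stage2[view], x)
    fvv = fv if isinstance(fv, FeatureVector) else None
    if fvv is None:
        from .shape_features import FeatureVector as FV

        fvv = FV(*x)
    res = IdentificationResult(view=view, view_probs=vp, klass=klass,
                               klass_probs=kp, features=fvv, roi_area=roi_area)
    res.validate()
    return res


def two_stage_identify(
    image: np.ndarray,
    stage1: TrainedNetwork,
    stage2: Mapping[str, TrainedNetwork],
    seg_cfg=None,
) -> IdentificationResult:
    """Segment an RGB raster, measure it, and identify view then class.

    The stage-2 map is validated against stage 1's label set before any
    image work. Segmentation failures propagate as
    :class:`shrewid.segmentation.NoObjectError` with the failing stage.
    """
    missing = [v for v in stage1.labels if v not in stage2]
    if missing:
        raise ValueError(f"stage-2 map is missing networks for views: {missing}")
    from .segmentation import extract_roi
    from .shape_features import extract_features

    mask = extract_roi(image, seg_cfg)
    fv = extract_features(mask)
    return identify_features(fv, stage1, stage2, roi_area=int(mask.sum()))
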