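"""Posture classification from humidity-curve images.

Each 10-minute window of the session is rendered as a small chart-like
image: the selected humidity channels, min-max normalized jointly over the
window, drawn as colored polylines on a white canvas (no axes or legend)
and resized to a square raster. Which sensors sit high, low, or crossing
encodes the posture, so a compact CNN (two 3x3 conv layers with 32 and 64
filters, a 128-unit dense layer and a 3-way softmax) separates supine,
left and right reliably. Real overnight label distributions are heavily
supine-dominated, so training uses inverse-frequency class weights.

Besides the 3-class report, a binary change/no-change report is derived by
ordering validation windows in time within each session and flagging a
posture change whenever consecutive predicted labels differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import _cnn
from .simulate import POSTURES, SleepSession

__all__ = [
    "SENSOR_PALETTE",
    "PostureImageDataset",
    "ClassifierSpec",
    "ClassificationReport",
    "CurveImageCNN",
    "render_window_image",
    "build_dataset",
    "train_and_evaluate",
]

#: Fixed per-sensor polyline colors (RGB), H1..H7.
SENSOR_PALETTE = (
    (128, 0, 128),   # H1 purple
    (165, 42, 42),   # H2 reddish brown
    (75, 0, 130),    # H3 dark purple
    (0, 128, 0),     # H4 green
    (255, 0, 0),     # H5 red
    (255, 140, 0),   # H6 orange
    (0, 0, 255),     # H7 blue
)


def render_window_image(
    session: SleepSession,
    sensors=None,
    window: tuple[float, float] | None = None,
    size: int = 224,
    line_width: int = 2,
) -> np.ndarray:
    """Render one window's humidity curves as a (size, size, 3) uint8 image.

    Curves are normalized jointly over the window (preserving which sensors
    sit high or low, the posture signature); a constant window renders as
    mid-height horizontal lines. Drawing happens at 2x resolution and is
    downsampled for clean lines; the output is fully deterministic.
    """
    t0, t1 = window if window is not None else (session.timestamps[0], session.timestamps[-1] + session.sampling_period_s)
    mask = (session.timestamps >= t0) & (session.timestamps < t1)
    H = session.humidity[mask]
    if H.shape[0] < 2:
        raise ValueError("window must contain at least two samples")
    idx = np.asarray(list(sensors), dtype=int) - 1 if sensors is not None else np.arange(H.shape[1])
    H = H[:, idx]

    lo, hi = H.min(), H.max()
    Y = (H - lo) / (hi - lo) if hi > lo else np.full_like(H, 0.5)

    canvas = 2 * size
    margin = max(2, line_width)
    img = Image.new("RGB", (canvas, canvas), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    xs = np.linspace(margin, canvas - 1 - margin, H.shape[0])
    for col, k in enumerate(idx):
        ys = (1.0 - Y[:, col]) * (canvas - 1 - 2 * margin) + margin
        pts = list(zip(xs.tolist(), ys.tolist()))
        draw.line(pts, fill=SENSOR_PALETTE[k % len(SENSOR_PALETTE)], width=2 * line_width)
    img = img.resize((size, size), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


@dataclass
class PostureImageDataset:
    """Rendered curve images with posture labels and class weights."""

    images: np.ndarray  # (n, size, size, 3) uint8
    labels: np.ndarray  # (n,) posture strings
    window_starts: np.ndarray  # (n,) seconds
    session_ids: np.ndarray  # (n,) int
    window_s: float
    class_counts: dict = field(default_factory=dict)
    class_weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("one label per image required")


def _class_weights(labels: np.ndarray) -> tuple[dict, dict]:
    classes, counts = np.unique(labels, return_counts=True)
    total = counts.sum()
    weights = {c: total / (len(classes) * n) for c, n in zip(classes, counts)}
    return dict(zip(classes, (int(n) for n in counts))), weights


def build_dataset(
    sessions: list[SleepSession],
    window_s: float = 600.0,
    stride_s: float | None = None,
    sensors=None,
    size: int = 224,
) -> PostureImageDataset:
    """Tile sessions into windows, render each, label by majority posture.

    A window straddling a transition takes the posture occupying most of
    it; an exact tie goes to the later posture.
    """
    stride_s = window_s if stride_s is None else stride_s
    images, labels, starts, sess_ids = [], [], [], []
    for sid, session in enumerate(sessions):
        if session.truth is None:
            raise ValueError(f"session {sid} has no ground-truth schedule")
        dt = session.sampling_period_s
        t_end = session.timestamps[-1] + dt
        t0 = float(session.timestamps[0])
        while t0 + window_s <= t_end + 1e-9:
            img = render_window_image(session, sensors, (t0, t0 + window_s), size)
            mask = (session.timestamps >= t0) & (session.timestamps < t0 + window_s)
            postures = session.truth.posture_at(session.timestamps[mask])
            classes, counts = np.unique(postures, return_counts=True)
            top = counts.max()
            tied = [c for c, n in zip(classes, counts) if n == top]
            if len(tied) == 1:
                label = tied[0]
            else:  # tie -> the later posture within the window
                last_seen = {p: i for i, p in enumerate(postures)}
                label = max(tied, key=lambda c: last_seen[c])
            images.append(img)
            labels.append(label)
            starts.append(t0)
            sess_ids.append(sid)
            t0 += stride_s
    labels = np.array(labels, dtype=object)
    counts, weights = _class_weights(labels)
    return PostureImageDataset(
        images=np.stack(images),
        labels=labels,
        window_starts=np.array(starts),
        session_ids=np.array(sess_ids),
        window_s=window_s,
        class_counts=counts,
        class_weights=weights,
    )


class CurveImageCNN(ClassifierMixin, BaseEstimator):
    """The two-conv-layer posture CNN as a scikit-learn classifier.

    conv(32, 3x3) -> maxpool -> conv(64, 3x3) -> maxpool -> flatten ->
    dense(128) -> softmax, trained with plain SGD (momentum) and
    inverse-frequency class weights. Images are resized to ``input_size``
    and scaled to [0, 1] before entering the network.
    """

    def __init__(
        self,
        input_size: int = 96,
        lr: float = 0.01,
        momentum: float = 0.9,
        batch_size: int = 32,
        max_epochs: int = 30,
        patience: int = 6,
        clip_norm: float | None = 1.0,
        class_weight: str | dict | None = "balanced",
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.clip_norm = clip_norm
        self.class_weight = class_weight
        self.random_state = random_state

    def _prepare(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError("expected images of shape (n, H, W, 3)")
        if X.shape[1] != self.input_size:
            resized = np.empty((len(X), self.input_size, self.input_size, 3), np.uint8)
            for i, img in enumerate(X):
                resized[i] = np.asarray(
                    Image.fromarray(np.asarray(img, np.uint8)).resize(
                        (self.input_size, self.input_size), Image.BILINEAR
                    )
                )
            X = resized
        return np.asarray(X, np.float32) / np.float32(255.0)

    def fit(self, X, y, eval_set: tuple | None = None):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to train")
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_to_idx[c] for c in y])
        Xf = self._prepare(X)

        if self.class_weight == "balanced":
            _, weights = _class_weights(y)
        elif isinstance(self.class_weight, dict):
            weights = self.class_weight
        else:
            weights = {c: 1.0 for c in self.classes_}
        w = np.array([weights[c] for c in y], np.float32)

        rng = np.random.default_rng(self.random_state)
        params = _cnn.init_params(self.input_size, 3, len(self.classes_), rng)
        ev = None
        if eval_set is not None:
            Xv, yv = eval_set
            yvi = np.array([class_to_idx[c] for c in np.asarray(yv)])
            wv = np.array([weights.get(c, 1.0) for c in np.asarray(yv)], np.float32)
            ev = (self._prepare(Xv), yvi, wv)
        self.params_, self.loss_history_ = _cnn.train(
            params,
            Xf,
            yi,
            w,
            rng,
            lr=self.lr,
            momentum=self.momentum,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            clip_norm=self.clip_norm,
            eval_set=ev,
        )
        self.n_features_in_ = Xf[0].size
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        return _cnn._forward_batched(self.params_, self._prepare(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass(frozen=True)
class ClassifierSpec:
    """Training protocol for the posture CNN."""

    input_size: int = 96
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 6
    val_fraction: float = 0.2
    class_weighting: bool = True
    seed: int = 0


@dataclass
class ClassificationReport:
    """Multiclass and derived binary change/no-change evaluation."""

    label_order: tuple[str, ...]
    confusion: np.ndarray  # (3, 3), rows = true
    accuracy: float
    per_class: dict  # label -> {precision, recall, f1, support}
    auc: dict  # label -> one-vs-rest AUC
    roc: dict  # label -> (fpr, tpr)
    binary_confusion: np.ndarray  # (2, 2), rows = true (no-change, change)
    binary_accuracy: float
    binary_precision: float
    binary_recall: float
    binary_f1: float
    n_validation: int
    val_predictions: np.ndarray | None = None
    val_labels: np.ndarray | None = None


def _binary_change_report(order, true_labels, pred_labels, session_ids, starts):
    """Compare consecutive in-time validation windows per session."""
    true_pairs, pred_pairs = [], []
    for sid in np.unique(session_ids):
        sel = np.nonzero(session_ids == sid)[0]
        sel = sel[np.argsort(starts[sel])]
        for a, b in zip(sel, sel[1:]):
            true_pairs.append(true_labels[a] != true_labels[b])
            pred_pairs.append(pred_labels[a] != pred_labels[b])
    t = np.asarray(true_pairs, bool)
    p = np.asarray(pred_pairs, bool)
    cm = confusion_matrix(t, p, labels=[False, True])
    tn, fp, fn, tp = cm.ravel()
    acc = (tp + tn) / cm.sum() if cm.sum() else 1.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return cm, acc, prec, rec, f1


def train_and_evaluate(
    dataset: PostureImageDataset, spec: ClassifierSpec = ClassifierSpec()
) -> ClassificationReport:
    """Stratified 80/20 split, class-weighted training, full evaluation."""
    labels_present = np.unique(dataset.labels)
    if len(labels_present) < 2:
        raise ValueError("dataset must contain at least two classes")
    order = tuple(p for p in POSTURES if p in labels_present)

    idx = np.arange(len(dataset.labels))
    train_idx, val_idx = train_test_split(
        idx,
        test_size=spec.val_fraction,
        stratify=dataset.labels,
        random_state=spec.seed,
    )
    clf = CurveImageCNN(
        input_size=spec.input_size,
        lr=spec.lr,
        momentum=spec.momentum,
        batch_size=spec.batch_size,
        max_epochs=spec.max_epochs,
        patience=spec.patience,
        class_weight="balanced" if spec.class_weighting else None,
        random_state=spec.seed,
    )
    clf.fit(
        dataset.images[train_idx],
        dataset.labels[train_idx],
        eval_set=(dataset.images[val_idx], dataset.labels[val_idx]),
    )
    probs = clf.predict_proba(dataset.images[val_idx])
    pred = clf.classes_[np.argmax(probs, axis=1)]
    true = dataset.labels[val_idx]

    cm = confusion_matrix(true, pred, labels=list(order))
    accuracy = float(np.trace(cm) / cm.sum())
    per_class = {}
    for i, lab in enumerate(order):
        tp = cm[i, i]
        prec = tp / cm[:, i].sum() if cm[:, i].sum() else 0.0
        rec = tp / cm[i].sum() if cm[i].sum() else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[lab] = {
            "precision": float(prec),
            "recall": float(rec),
            "f1": float(f1),
            "support": int(cm[i].sum()),
        }

    aucs, rocs = {}, {}
    for lab in order:
        col = int(np.nonzero(clf.classes_ == lab)[0][0])
        y_bin = (true == lab).astype(int)
        if y_bin.min() == y_bin.max():
            continue  # class absent from validation fold
        fpr, tpr, _ = roc_curve(y_bin, probs[:, col])
        rocs[lab] = (fpr, tpr)
        aucs[lab] = float(auc(fpr, tpr))

    bcm, bacc, bprec, brec, bf1 = _binary_change_report(
        order,
        true,
        pred,
        dataset.session_ids[val_idx],
        dataset.window_starts[val_idx],
    )
    return ClassificationReport(
        label_order=order,
        confusion=cm,
        accuracy=accuracy,
        per_class=per_class,
        auc=aucs,
        roc=rocs,
        binary_confusion=bcm,
        binary_accuracy=float(bacc),
        binary_precision=float(bprec),
        binary_recall=float(brec),
        binary_f1=float(bf1),
        n_validation=len(val_idx),
        val_predictions=pred,
        val_labels=true,
    )
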