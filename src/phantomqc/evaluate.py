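"""Metric protocol: lesion-level confusion metrics, existence /
abnormality ROC curves, F1-maximizing decision thresholds, bootstrap
confidence intervals, stratified splitting, and the hierarchical
(lesion / feature / phantom) evaluation of a scorer.

Conventions: the existence ROC treats scores 1.0 and 0.5 as positive
and 0.0 as negative; the abnormality ROC is restricted to lesions
scored 1.0 or 0.5, with 0.5 positive.  Reported F1 is the macro
average over the three score classes.  Bootstrap resampling is done at
the phantom-case level by default, preserving within-case correlation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix as _confusion_matrix
from sklearn.metrics import precision_recall_fscore_support, roc_curve

from .layout import DEFAULT_LAYOUT, FIBER, MASS, SPECKS, GridLayout, TYPE_COUNTS
from .qualify import qualify_phantom
from .scores import Score

_CLASSES = (Score.ZERO, Score.HALF, Score.FULL)
_CLASS_LABELS = ("0.0", "0.5", "1.0")


# ---------------------------------------------------------------------------
# lesion-level confusion metrics


@dataclass
class ConfusionReport:
    matrix: np.ndarray  # rows = true, cols = predicted, order 0.0/0.5/1.0
    precision: dict
    recall: dict
    accuracy: float
    macro_f1: float
    support: dict
    zero_division: bool

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "classes": list(_CLASS_LABELS),
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "support": self.support,
        }


def confusion_metrics(y_true, y_pred) -> ConfusionReport:
    """Multiclass confusion accounting over the three score classes.

    Inputs may be Score values, floats or strings; N/A entries are not
    allowed here (filter them before calling).  Zero-division in
    precision/recall is reported as 0 with a flag.
    """
    yt = [Score.from_value(s) for s in y_true]
    yp = [Score.from_value(s) for s in y_pred]
    if len(yt) != len(yp):
        raise ValueError("length mismatch")
    if len(yt) == 0:
        raise ValueError("empty input")
    if any(s.is_na for s in yt) or any(s.is_na for s in yp):
        raise ValueError("N/A labels must be excluded from confusion metrics")
    ti = [_CLASSES.index(s) for s in yt]
    pi = [_CLASSES.index(s) for s in yp]
    mat = _confusion_matrix(ti, pi, labels=[0, 1, 2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, supp = precision_recall_fscore_support(
            ti, pi, labels=[0, 1, 2], zero_division=0
        )
    zero_div = bool(
        any((mat[:, j].sum() == 0) for j in range(3))
        or any((mat[i, :].sum() == 0) for i in range(3))
    )
    return ConfusionReport(
        matrix=mat,
        precision=dict(zip(_CLASS_LABELS, prec.tolist())),
        recall=dict(zip(_CLASS_LABELS, rec.tolist())),
        accuracy=float(np.trace(mat) / mat.sum()),
        macro_f1=float(f1.mean()),
        support=dict(zip(_CLASS_LABELS, supp.tolist())),
        zero_division=zero_div,
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _roc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    if labels.size == 0 or labels.all() or not labels.any():
        raise ValueError("ROC undefined: need both classes present")
    fpr, tpr, thr = roc_curve(labels.astype(int), scores)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_auc(fpr, tpr)))


def roc_existence(probs, truths) -> RocResult:
    """ROC of ``p_exist``: scores 1.0/0.5 positive, 0.0 negative."""
    p = np.asarray(probs, dtype=float)
    p = p[:, 0] if p.ndim == 2 else p
    y = [Score.from_value(s) for s in truths]
    keep = np.array([not s.is_na for s in y])
    labels = np.array([s is not Score.ZERO for s in y])
    return _roc(p[keep], labels[keep])


def roc_abnormality(probs, truths) -> RocResult:
    """ROC of ``p_abnormal`` among lesions scored 1.0 or 0.5 (0.5
    positive); 0.0-scored lesions are excluded entirely."""
    p = np.asarray(probs, dtype=float)
    p = p[:, 1] if p.ndim == 2 else p
    y = [Score.from_value(s) for s in truths]
    keep = np.array([s in (Score.HALF, Score.FULL) for s in y])
    if not keep.any():
        raise ValueError("no 0.5/1.0-scored lesions left after exclusion")
    labels = np.array([s is Score.HALF for s in y])
    return _roc(p[keep], labels[keep])


# ---------------------------------------------------------------------------
# thresholds


def _best_f1_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold (predict positive when score >= t) maximizing binary
    F1; exhaustive over observed scores, ties -> smallest threshold."""
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(int)
    n_pos = y.sum()
    cands, first = np.unique(s, return_index=True)
    # positives with score >= t, for each candidate threshold
    tail_pos = n_pos - np.concatenate([[0], np.cumsum(y)])[first]
    tail_n = len(s) - first
    tp = tail_pos
    fp = tail_n - tail_pos
    fn = n_pos - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    return float(cands[np.argmax(f1)])  # argmax returns first (smallest) tie


def pick_thresholds(probs, truths):
    """F1-maximizing decision thresholds for the two outputs.

    Existence F1 is computed over all graded lesions (positive = score
    1.0 or 0.5); abnormality F1 over the 1.0/0.5 subset (positive =
    0.5).  Degenerate cases fall back to 0.5 with a warning.
    """
    from .learned import DecisionThresholds

    p = np.asarray(probs, dtype=float)
    y = [Score.from_value(s) for s in truths]
    keep = np.array([not s.is_na for s in y])
    exist_y = np.array([s is not Score.ZERO for s in y])[keep]
    t_exist = 0.5
    if exist_y.any() and not exist_y.all():
        t_exist = _best_f1_threshold(p[keep, 0], exist_y)
    else:
        warnings.warn("existence threshold degenerate; falling back to 0.5")
    ab_keep = np.array([s in (Score.HALF, Score.FULL) for s in y])
    ab_y = np.array([s is Score.HALF for s in y])[ab_keep]
    t_ab = 0.5
    if ab_y.size and ab_y.any() and not ab_y.all():
        t_ab = _best_f1_threshold(p[ab_keep, 1], ab_y)
    else:
        warnings.warn("abnormality threshold degenerate; falling back to 0.5")
    clip = lambda t: float(min(max(t, 1e-6), 1 - 1e-6))
    return DecisionThresholds(clip(t_exist), clip(t_ab))


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapCI:
    low: float
    high: float
    point: float
    n_resamples: int
    n_redrawn: int

    def __iter__(self):  # unpacks as (low, high)
        return iter((self.low, self.high))


def bootstrap_ci(
    metric_fn,
    data,
    n_resamples: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap interval of ``metric_fn`` over resamples of
    ``data`` (a sequence of resampling units — phantom cases by
    default in this package).  Resamples on which the metric is
    undefined (raises or returns non-finite) are redrawn and counted."""
    data = list(data)
    if not data:
        raise ValueError("empty data")
    rng = np.random.default_rng(seed)
    n = len(data)
    stats = []
    redrawn = 0
    attempts = 0
    while len(stats) < n_resamples:
        attempts += 1
        if attempts > 20 * n_resamples:
            raise RuntimeError("metric undefined on too many resamples")
        idx = rng.integers(0, n, n)
        try:
            val = float(metric_fn([data[i] for i in idx]))
        except (ValueError, ZeroDivisionError):
            redrawn += 1
            continue
        if not np.isfinite(val):
            redrawn += 1
            continue
        stats.append(val)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return BootstrapCI(
        low=float(lo),
        high=float(hi),
        point=float(metric_fn(data)),
        n_resamples=n_resamples,
        n_redrawn=redrawn,
    )


# ---------------------------------------------------------------------------
# stratified split


@dataclass
class SplitAssignment:
    fractions: tuple
    counts: dict  # stratum -> tuple of counts per subset
    assignment: dict  # stratum -> int array of subset index per item
    seed: int

    def subset_sizes(self) -> tuple:
        return tuple(
            int(sum(c[j] for c in self.counts.values()))
            for j in range(len(self.fractions))
        )


def largest_remainder(size: int, fractions) -> list[int]:
    """Integer allocation of ``size`` by ``fractions``: floor of each
    share, remaining units to the largest fractional parts."""
    raw = np.asarray(fractions, dtype=float) * size
    base = np.floor(raw).astype(int)
    rem = size - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for j in order[:rem]:
        base[j] += 1
    return base.tolist()


def stratified_split(stratum_sizes, fractions, seed: int = 0) -> SplitAssignment:
    """Allocate each stratum across subsets proportionally (largest-
    remainder rounding, so every stratum's allocations sum exactly to
    its size) and randomize the within-stratum assignment."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if isinstance(stratum_sizes, dict):
        items = list(stratum_sizes.items())
    else:
        items = list(enumerate(stratum_sizes))
    rng = np.random.default_rng(seed)
    counts, assignment = {}, {}
    for name, size in items:
        size = int(size)
        if size < 0:
            raise ValueError("stratum sizes must be non-negative")
        alloc = largest_remainder(size, fractions)
        labels = np.repeat(np.arange(len(fractions)), alloc)
        rng.shuffle(labels)
        counts[name] = tuple(alloc)
        assignment[name] = labels
    return SplitAssignment(
        fractions=tuple(fractions), counts=counts, assignment=assignment, seed=seed
    )


# ---------------------------------------------------------------------------
# system evaluation


@dataclass
class EvalReport:
    per_type: dict  # lesion_type -> ConfusionReport
    f1_ci: dict  # lesion_type -> BootstrapCI | None
    roc: dict  # lesion_type -> {"existence": RocResult, "abnormality": ...}
    feature_level: dict  # lesion_type -> {"accuracy", "precision", "recall"}
    phantom_level: dict  # {"accuracy", "precision", "recall"}
    n_cases: int

    def to_json(self, path=None) -> str:
        def ci(c):
            return None if c is None else [c.low, c.high]

        payload = {
            "n_cases": self.n_cases,
            "per_type": {t: r.to_dict() for t, r in self.per_type.items()},
            "f1_ci": {t: ci(c) for t, c in self.f1_ci.items()},
            "roc_auc": {
                t: {k: (v.auc if v else None) for k, v in d.items()}
                for t, d in self.roc.items()
            },
            "feature_level": self.feature_level,
            "phantom_level": self.phantom_level,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _binary_prf(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    acc = (tp + tn) / max(len(y_true), 1)
    return {"accuracy": acc, "precision": prec, "recall": rec,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def evaluate_system(
    scorer,
    dataset,
    layout: GridLayout = DEFAULT_LAYOUT,
    n_boot: int = 10000,
    seed: int = 0,
) -> EvalReport:
    """Hierarchical evaluation of a tile scorer.

    ``dataset`` is a sequence of ``(tiles, true_scores)`` pairs — 16
    tiles and 16 grades per phantom case.  Lesion-level confusion
    excludes cells where either grade is N/A; qualification treats N/A
    as contributing nothing, at every level.  ROC sections are filled
    only for probabilistic scorers (``predict_proba``).
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    has_proba = hasattr(scorer, "predict_proba")

    cases = []
    for tiles, truths in dataset:
        if len(tiles) != 16 or len(truths) != 16:
            raise ValueError("each case needs 16 tiles and 16 true scores")
        truths = [Score.from_value(s) for s in truths]
        preds = scorer.predict(tiles)
        probs = np.asarray(scorer.predict_proba(tiles)) if has_proba else None
        cases.append({"tiles": tiles, "true": truths, "pred": preds, "probs": probs})

    per_type, f1_ci, roc = {}, {}, {}
    for t in TYPE_COUNTS:
        def _pairs(case_list, t=t):
            yt, yp = [], []
            for c in case_list:
                for cell in range(16):
                    lt, _ = layout.lesion_at(cell)
                    if lt != t:
                        continue
                    if c["true"][cell].is_na or c["pred"][cell].is_na:
                        continue
                    yt.append(c["true"][cell])
                    yp.append(c["pred"][cell])
            return yt, yp

        yt, yp = _pairs(cases)
        per_type[t] = confusion_metrics(yt, yp)
        if n_boot > 0:
            f1_ci[t] = bootstrap_ci(
                lambda cs: confusion_metrics(*_pairs(cs)).macro_f1,
                cases, n_resamples=n_boot, seed=seed,
            )
        else:
            f1_ci[t] = None
        roc[t] = {"existence": None, "abnormality": None}
        if has_proba:
            probs, truths_t = [], []
            for c in cases:
                for cell in range(16):
                    lt, _ = layout.lesion_at(cell)
                    if lt != t or c["true"][cell].is_na:
                        continue
                    probs.append(c["probs"][cell])
                    truths_t.append(c["true"][cell])
            probs = np.asarray(probs)
            try:
                roc[t]["existence"] = roc_existence(probs, truths_t)
            except ValueError:
                pass
            try:
                roc[t]["abnormality"] = roc_abnormality(probs, truths_t)
            except ValueError:
                pass

    feature_level = {}
    true_q = np.zeros(len(cases), bool)
    pred_q = np.zeros(len(cases), bool)
    per_feature_true = {t: np.zeros(len(cases), bool) for t in TYPE_COUNTS}
    per_feature_pred = {t: np.zeros(len(cases), bool) for t in TYPE_COUNTS}
    for i, c in enumerate(cases):
        qt = qualify_phantom(c["true"], layout)
        qp = qualify_phantom(c["pred"], layout)
        true_q[i], pred_q[i] = qt.qualified, qp.qualified
        for t in TYPE_COUNTS:
            per_feature_true[t][i] = qt.per_feature[t].passed
            per_feature_pred[t][i] = qp.per_feature[t].passed
    for t in TYPE_COUNTS:
        feature_level[t] = _binary_prf(per_feature_true[t], per_feature_pred[t])
    phantom_level = _binary_prf(true_q, pred_q)

    return EvalReport(
        per_type=per_type,
        f1_ci=f1_ci,
        roc=roc,
        feature_level=feature_level,
        phantom_level=phantom_level,
        n_cases=len(cases),
    )


# ---------------------------------------------------------------------------
# figures


def plot_confusion(report: EvalReport, path):
    """Per-type confusion heatmaps (one row of three panels)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.6))
    for ax, (t, rep) in zip(axes, report.per_type.items()):
        ax.imshow(rep.matrix, cmap="Blues")
        for i in range(3):
            for j in range(3):
                ax.text(j, i, str(rep.matrix[i, j]), ha="center", va="center")
        ax.set_xticks(range(3), _CLASS_LABELS)
        ax.set_yticks(range(3), _CLASS_LABELS)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(f"{t} (acc {rep.accuracy:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(report: EvalReport, path):
    """Existence / abnormality ROC curves per lesion type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.6))
    for ax, (t, curves) in zip(axes, report.roc.items()):
        for name, color in (("existence", "tab:orange"), ("abnormality", "tab:green")):
            r = curves.get(name)
            if r is not None:
                ax.plot(r.fpr, r.tpr, color=color,
                        label=f"{name} (AUC {r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(t)
        ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
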