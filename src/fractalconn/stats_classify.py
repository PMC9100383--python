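"""ANOVA feature selection and cross-validated two-group classification.

Each subject contributes a flattened v x v connectivity matrix (all
v*v entries, both triangles plus the diagonal, so v = 116 regions give
13,456 connection features).  A one-way ANOVA per connection scores the
group difference; connections with p <= alpha (default 0.05, no
multiple-testing correction) form the reduced feature vector fed to a
classifier under stratified k-fold cross-validation.

Two selection protocols are offered.  The default, ``selection="fold"``,
refits the ANOVA inside every training fold so the held-out subjects
never influence which connections are used — the statistically sound
choice.  ``selection="global"`` selects once on all subjects before
splitting; it is the protocol commonly seen in connectome-classification
studies and is kept available (as the ``--paper-protocol`` CLI switch)
for comparability, with the caveat that it leaks test information into
the feature choice and inflates accuracy estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .connectivity import ConnectivityMatrix

__all__ = [
    "ConnectivityStack",
    "PValueMap",
    "ClassifierSpec",
    "EvalReport",
    "anova_pvalues",
    "select_features",
    "flatten_features",
    "crossval_classify",
    "compute_metrics",
    "roc_auc",
]

CLASSIFIER_KINDS = ("svm_linear", "knn", "decision_tree", "bagged_trees")


@dataclass(frozen=True)
class ConnectivityStack:
    """n_subjects connectivity matrices of one kind plus binary labels."""

    matrices: np.ndarray
    labels: np.ndarray
    kind: str = "nonfractal"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must be n_subjects x v x v")
        if labels.shape != (m.shape[0],):
            raise ValueError("labels length must equal n_subjects")
        object.__setattr__(self, "matrices", m)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_matrices(
        cls, mats: list[ConnectivityMatrix], labels: np.ndarray
    ) -> "ConnectivityStack":
        kinds = {m.kind for m in mats}
        if len(kinds) != 1:
            raise ValueError(f"mixed connectivity kinds in stack: {sorted(kinds)}")
        return cls(np.stack([m.values for m in mats]), labels, kinds.pop())

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]

    def flattened(self) -> np.ndarray:
        """Row-major flattening to n_subjects x (v*v) features."""
        return self.matrices.reshape(self.n_subjects, -1)


@dataclass(frozen=True)
class PValueMap:
    """Per-connection one-way ANOVA p-values in row-major connection order."""

    p: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.n_regions * self.n_regions,):
            raise ValueError("p must have length n_regions**2")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        object.__setattr__(self, "p", p)

    def connection(self, index: int) -> tuple[int, int]:
        """(row, column) region pair of a flattened connection index."""
        return divmod(index, self.n_regions)


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family plus the fixed hyperparameter presets."""

    kind: str = "svm_linear"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        defaults = {
            "svm_linear": {"C": 1.0},
            "knn": {"n_neighbors": 11, "metric": "cosine"},
            "decision_tree": {"criterion": "gini"},
            "bagged_trees": {"n_estimators": 30},
        }[self.kind]
        merged = {**defaults, **self.params}
        unknown = set(merged) - set(defaults)
        if unknown:
            raise ValueError(
                f"unknown hyperparameter(s) {sorted(unknown)} for {self.kind}"
            )
        object.__setattr__(self, "params", merged)

    def build(self, random_state: int | None = None):
        p = self.params
        if self.kind == "svm_linear":
            return SVC(kernel="linear", C=p["C"])
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=p["n_neighbors"], metric=p["metric"])
        if self.kind == "decision_tree":
            return DecisionTreeClassifier(
                criterion=p["criterion"], random_state=random_state
            )
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(criterion="gini"),
            n_estimators=p["n_estimators"],
            random_state=random_state,
        )


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts, rates (percent), AUC and cross-validation spread."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    fpr: float
    auc: float
    fold_accuracies: tuple[float, ...]
    repeat_accuracies: tuple[float, ...]
    mean_accuracy: float
    sd_accuracy: float
    scores: tuple[float, ...] = ()
    y_true: tuple[int, ...] = ()


def _two_group_f_pvalues(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Vectorized one-way (two-group) ANOVA p-value per column.

    Equivalent to the squared pooled-variance t-test.  Degenerate columns:
    zero variance everywhere -> p = 1 (no evidence of a difference);
    zero within-group variance but distinct means -> p = 0.
    """
    n0, n1 = x0.shape[0], x1.shape[0]
    if n0 < 2 or n1 < 2:
        raise ValueError("each group needs at least 2 subjects for ANOVA")
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    grand = (n0 * m0 + n1 * m1) / (n0 + n1)
    ss_between = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ss_within = ((x0 - m0) ** 2).sum(axis=0) + ((x1 - m1) ** 2).sum(axis=0)
    df1, df2 = 1, n0 + n1 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
        p = stats.f.sf(f, df1, df2)
    p = np.where(ss_within == 0, np.where(ss_between == 0, 1.0, 0.0), p)
    return np.where((ss_within > 0) & (ss_between == 0), 1.0, p)


def anova_pvalues(stack: ConnectivityStack) -> PValueMap:
    """Per-connection one-way ANOVA p-values across the two groups."""
    groups = np.unique(stack.labels)
    if groups.size < 2:
        raise ValueError("both groups must be present")
    x = stack.flattened()
    p = _two_group_f_pvalues(x[stack.labels == 0], x[stack.labels == 1])
    return PValueMap(p, stack.n_regions)


def select_features(
    p: PValueMap | np.ndarray, alpha: float = 0.05, top_k: int | None = None
) -> np.ndarray:
    """Connection indices ordered by ascending p-value.

    Default mode keeps every connection with p <= alpha (inclusive).
    ``top_k`` instead keeps exactly the k smallest-p connections (ties
    broken by connection index), for fixed-length feature comparisons.
    """
    pv = p.p if isinstance(p, PValueMap) else np.asarray(p, dtype=float)
    if top_k is not None:
        if not 0 < top_k <= pv.size:
            raise ValueError("top_k out of range")
        order = np.lexsort((np.arange(pv.size), pv))
        return order[:top_k]
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    keep = np.flatnonzero(pv <= alpha)
    return keep[np.lexsort((keep, pv[keep]))]


def flatten_features(stack: ConnectivityStack, indices: np.ndarray) -> np.ndarray:
    """Gather the selected connections into an n_subjects x k feature table."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty feature selection: nothing to classify")
    flat = stack.flattened()
    if indices.min() < 0 or indices.max() >= flat.shape[1]:
        raise ValueError("connection index out of range")
    return flat[:, indices]


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Confusion-matrix rates as percentages.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
    (TP+TN)/total, precision = TP/(TP+FP), FPR = FP/(TN+FP) = 100 -
    specificity.  A zero-denominator rate is undefined and reported as
    NaN, never as 0.
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("all confusion counts are zero")

    def rate(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "sensitivity": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "accuracy": rate(tp + tn, tp + tn + fp + fn),
        "precision": rate(tp, tp + fp),
        "fpr": rate(fp, tn + fp),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve (ties handled by midrank)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points of the ROC curve, one row per threshold."""
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def _decision_scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(x), dtype=float)
    proba = model.predict_proba(x)
    pos = list(model.classes_).index(1)
    return np.asarray(proba[:, pos], dtype=float)


def crossval_classify(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    k_folds: int = 10,
    seed: int = 0,
    n_repeats: int = 5,
    alpha: float = 0.05,
    selection: str = "fold",
    top_k: int | None = None,
) -> EvalReport:
    """Stratified k-fold cross-validated classification.

    ``features`` is the full flattened connection table.  With
    ``selection="fold"`` the ANOVA screen (p <= alpha, or top_k) is refit
    on every training fold; ``"global"`` selects once on all subjects
    first (leaks the held-out labels into the screen); ``"none"`` uses
    the columns as given.  Confusion counts, rates and AUC come from the
    pooled out-of-fold predictions of the first repeat; accuracy spread
    is reported over ``n_repeats`` reseeded repetitions.  Class 1 is the
    positive class.  Deterministic given ``seed``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("features must be n_subjects x n_features")
    if selection not in ("fold", "global", "none"):
        raise ValueError("selection must be 'fold', 'global' or 'none'")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects < k_folds={k_folds}; "
            "reduce k_folds"
        )

    def fold_select(xtr: np.ndarray, ytr: np.ndarray) -> np.ndarray:
        p = _two_group_f_pvalues(xtr[ytr == 0], xtr[ytr == 1])
        idx = select_features(p, alpha=alpha, top_k=top_k)
        if idx.size == 0:  # never classify on an empty table
            idx = np.array([int(np.argmin(p))])
        return idx

    if selection == "global":
        global_idx = fold_select(x, y)

    rng = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(n_repeats)]

    repeat_acc: list[float] = []
    first: dict = {}
    for rep, rs in enumerate(repeat_seeds):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=rs)
        y_pred = np.empty_like(y)
        scores = np.empty(y.size, dtype=float)
        fold_acc: list[float] = []
        for tr, te in skf.split(x, y):
            if selection == "fold":
                idx = fold_select(x[tr], y[tr])
            elif selection == "global":
                idx = global_idx
            else:
                idx = np.arange(x.shape[1])
            model = spec.build(random_state=rs)
            model.fit(x[np.ix_(tr, idx)], y[tr])
            xte = x[np.ix_(te, idx)]
            y_pred[te] = model.predict(xte)
            scores[te] = _decision_scores(model, xte)
            fold_acc.append(float(np.mean(y_pred[te] == y[te])) * 100.0)
        repeat_acc.append(float(np.mean(y_pred == y)) * 100.0)
        if rep == 0:
            first = {
                "tp": int(np.sum((y == 1) & (y_pred == 1))),
                "tn": int(np.sum((y == 0) & (y_pred == 0))),
                "fp": int(np.sum((y == 0) & (y_pred == 1))),
                "fn": int(np.sum((y == 1) & (y_pred == 0))),
                "fold_acc": tuple(fold_acc),
                "scores": tuple(float(s) for s in scores),
            }

    metrics = compute_metrics(first["tp"], first["tn"], first["fp"], first["fn"])
    return EvalReport(
        tp=first["tp"],
        tn=first["tn"],
        fp=first["fp"],
        fn=first["fn"],
        auc=roc_auc(np.asarray(first["scores"]), y),
        fold_accuracies=first["fold_acc"],
        repeat_accuracies=tuple(repeat_acc),
        mean_accuracy=float(np.mean(repeat_acc)),
        sd_accuracy=float(np.std(repeat_acc, ddof=1)) if n_repeats > 1 else 0.0,
        scores=first["scores"],
        y_true=tuple(int(t) for t in y),
        **metrics,
    )
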