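"""Viability prediction from zygote features with an RBF-kernel SVM.

Blastocyst formation is the ground-truth label; features are the fitted
mechanical parameters (k1, log-transformed η1, k0, and the uninformative
η0) optionally combined with time-lapse cell-cycle intervals (c1–c3).
The workflow mirrors the measurement study: hyperparameters (box constraint
``c`` and RBF width ``sigma``) are tuned by 10-fold cross-validated
accuracy; performance is summarised by 100 Monte-Carlo repetitions of
stratified 10-fold cross-validation, pooling out-of-fold decision scores
into one ROC and one PR curve per repetition; and greedy forward feature
selection (hyperparameters re-tuned at every step) yields the predictive
ordering of the features.

Kernel convention: K(x, z) = exp(−‖x−z‖² / (2σ²)), so sklearn's
``gamma = 1/(2σ²)``.  Features are z-scored per training fold — the
mechanical features mix N·m⁻¹ and N·s·m⁻¹ scales, which an RBF kernel
cannot absorb otherwise; the standardization never sees test-fold rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "MECHANICAL_FEATURES",
    "EvalResult",
    "MCResult",
    "TrainedClassifier",
    "feature_matrix",
    "combine_features",
    "tune_hyperparams",
    "mc_cross_validate",
    "forward_feature_select",
    "roc_pr_curves",
    "operating_points",
    "DEFAULT_GRID",
    "SELECTION_GRID",
]

MECHANICAL_FEATURES = ("k1", "log_eta1", "k0", "eta0")
CELLCYCLE_FEATURES = ("c1", "c2", "c3")

#: default tuning grid: log-spaced, c ∈ 2^[−5, 15], σ ∈ 2^[−10, 5]
DEFAULT_GRID = {
    "c": 2.0 ** np.arange(-5, 16, 2, dtype=float),
    "sigma": 2.0 ** np.arange(-10, 6, 2, dtype=float),
}
#: coarser grid used inside forward selection, where tuning is repeated at
#: every step for every candidate
SELECTION_GRID = {
    "c": 2.0 ** np.array([-1.0, 3.0, 7.0]),
    "sigma": 2.0 ** np.array([-2.0, 0.0, 2.0]),
}


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains missing or non-finite values")
    return X, y


def feature_matrix(cohort: pd.DataFrame, features=MECHANICAL_FEATURES):
    """Build (X, y) from a cohort table.

    ``log_eta1`` is derived as the natural log of ``eta1``; ``y`` is the
    blastocyst label.  Returns a DataFrame indexed by embryo_id and a
    0/1 label array.
    """
    df = cohort.set_index("embryo_id") if "embryo_id" in cohort.columns else cohort
    cols = {}
    for f in features:
        if f == "log_eta1":
            eta1 = df["eta1"].to_numpy(float)
            if np.any(eta1 <= 0):
                raise ValueError("eta1 must be positive to take log_eta1")
            cols[f] = np.log(eta1)
        else:
            cols[f] = df[f].to_numpy(float)
    X = pd.DataFrame(cols, index=df.index)
    y = df["blastocyst"].astype(bool).astype(int).to_numpy()
    return X, y


def combine_features(mechanical: pd.DataFrame, cellcycle: pd.DataFrame) -> pd.DataFrame:
    """Join mechanical and cell-cycle feature tables on embryo id."""
    only_m = mechanical.index.difference(cellcycle.index)
    only_c = cellcycle.index.difference(mechanical.index)
    if len(only_m) or len(only_c):
        raise ValueError(
            "embryo id mismatch between feature tables; "
            f"only in mechanical: {list(only_m)}; only in cellcycle: {list(only_c)}"
        )
    overlap = mechanical.columns.intersection(cellcycle.columns)
    if len(overlap):
        raise ValueError(f"duplicated feature columns: {list(overlap)}")
    return mechanical.join(cellcycle).loc[mechanical.index]


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffled stratified fold assignment (0..k-1 per row)."""
    folds = np.empty(y.size, int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls} has {idx.size} members, fewer than {k} folds"
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def _svc(c: float, sigma: float) -> SVC:
    return SVC(C=c, kernel="rbf", gamma=1.0 / (2.0 * sigma * sigma))


def _cv_scores(X, y, c, sigma, folds) -> np.ndarray:
    """Pooled out-of-fold decision scores; z-scoring fitted per training fold."""
    scores = np.empty(y.size)
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        clf = _svc(c, sigma).fit((X[tr] - mu) / sd, y[tr])
        scores[te] = clf.decision_function((X[te] - mu) / sd)
    return scores


def tune_hyperparams(X, y, k_folds: int = 10, grid: dict | None = None, seed: int = 0):
    """Choose (c, sigma) maximizing mean CV accuracy on a log-spaced grid.

    Ties are broken toward smaller ``c`` and then larger ``sigma`` — the
    smoother, less overfitting-prone model.
    """
    X, y = _as_xy(X, y)
    grid = grid or DEFAULT_GRID
    folds = _stratified_folds(y, k_folds, np.random.default_rng(seed))
    best = None
    for sigma in sorted(grid["sigma"], reverse=True):
        for c in sorted(grid["c"]):
            acc = float(np.mean((_cv_scores(X, y, c, sigma, folds) > 0) == y))
            if best is None or acc > best[0] + 1e-12:
                best = (acc, c, sigma)
    return best[1], best[2]


@dataclass
class EvalResult:
    """Threshold-swept ROC and PR curves with trapezoidal areas.

    ``thresholds`` are the distinct score values in descending order; the
    leading ROC point (0, 0) / PR recall-0 anchor corresponds to a
    threshold above every score.  ``tps``/``fps`` give the confusion counts
    at each threshold so operating points can be recomputed exactly.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    tps: np.ndarray
    fps: np.ndarray
    n_pos: int
    n_neg: int
    auc_roc: float
    auc_pr: float


def roc_pr_curves(scores, labels) -> EvalResult:
    """ROC and PR curves by threshold sweep over the distinct scores.

    Equal scores are grouped into a single threshold, which makes the
    trapezoidal ROC area exactly the Mann–Whitney statistic
    P(score⁺ > score⁻) + ½·P(score⁺ = score⁻).
    """
    scores = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos

    order = np.argsort(-scores, kind="mergesort")
    s, yy = scores[order], y[order]
    boundary = np.flatnonzero(np.diff(s) != 0)
    last = np.r_[boundary, s.size - 1]  # last index of each tie group
    tps = np.cumsum(yy)[last]
    fps = (last + 1) - tps
    thresholds = s[last]

    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc_roc = float(np.trapezoid(tpr, fpr))

    prec = tps / (tps + fps)
    recall = np.r_[0.0, tps / n_pos]
    precision = np.r_[prec[0], prec]  # anchor recall-0 at the first precision
    auc_pr = float(np.trapezoid(precision, recall))

    return EvalResult(
        fpr=fpr, tpr=tpr, precision=precision, recall=recall,
        thresholds=thresholds, tps=tps, fps=fps,
        n_pos=n_pos, n_neg=n_neg, auc_roc=auc_roc, auc_pr=auc_pr,
    )


@dataclass
class OperatingPoint:
    criterion: str
    threshold: float | None
    sensitivity: float
    specificity: float
    precision: float
    feasible: bool = True


def operating_points(ev: EvalResult, criterion: str = "youden", target: float = 0.95):
    """Operating point of the curve under a threshold-picking criterion.

    ``youden`` maximizes sensitivity + specificity − 1; ``specificity``
    returns the most sensitive point with specificity ≥ target;
    ``precision`` the highest-recall point with precision ≥ target.  An
    unachievable constraint is reported with ``feasible=False`` rather than
    silently clipped.
    """
    sens = ev.tps / ev.n_pos
    spec = 1.0 - ev.fps / ev.n_neg
    prec = ev.tps / (ev.tps + ev.fps)

    def make(i):
        return OperatingPoint(criterion, float(ev.thresholds[i]),
                              float(sens[i]), float(spec[i]), float(prec[i]))

    if criterion == "youden":
        return make(int(np.argmax(sens + spec - 1.0)))
    if criterion == "specificity":
        ok = np.flatnonzero(spec >= target)
        if ok.size == 0:
            return OperatingPoint(criterion, None, 0.0, 1.0, 1.0, feasible=False)
        return make(ok[np.argmax(sens[ok])])
    if criterion == "precision":
        ok = np.flatnonzero(prec >= target)
        if ok.size == 0:
            return OperatingPoint(criterion, None, 0.0, 1.0, 0.0, feasible=False)
        return make(ok[np.argmax(sens[ok])])
    raise ValueError(f"unknown criterion {criterion!r}")


@dataclass
class MCResult:
    mean_auc_roc: float
    sd_auc_roc: float
    mean_auc_pr: float
    sd_auc_pr: float
    per_rep: pd.DataFrame = field(repr=False)


def mc_cross_validate(
    X, y, c: float, sigma: float,
    n_mc: int = 100, k_folds: int = 10, seed: int = 0,
) -> MCResult:
    """Monte-Carlo repeated, stratified k-fold cross-validation.

    Each repetition reshuffles the stratified fold assignment, pools the
    out-of-fold decision scores into one ROC and one PR curve, and
    contributes one AUC pair; the across-repetition mean and s.d. are
    returned.
    """
    X, y = _as_xy(X, y)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_mc):
        folds = _stratified_folds(y, k_folds, rng)
        ev = roc_pr_curves(_cv_scores(X, y, c, sigma, folds), y)
        rows.append((ev.auc_roc, ev.auc_pr))
    per_rep = pd.DataFrame(rows, columns=["auc_roc", "auc_pr"])
    return MCResult(
        mean_auc_roc=float(per_rep.auc_roc.mean()),
        sd_auc_roc=float(per_rep.auc_roc.std(ddof=1)) if n_mc > 1 else 0.0,
        mean_auc_pr=float(per_rep.auc_pr.mean()),
        sd_auc_pr=float(per_rep.auc_pr.std(ddof=1)) if n_mc > 1 else 0.0,
        per_rep=per_rep,
    )


def forward_feature_select(
    X: pd.DataFrame, y, k_folds: int = 10, seed: int = 0,
    grid: dict | None = None, n_rep: int = 5,
) -> pd.DataFrame:
    """Greedy forward feature selection ranked by cross-validated ROC AUC.

    Starting from the empty set, every remaining feature is tried in turn:
    hyperparameters are re-tuned (CV accuracy on ``grid``, coarser than the
    standalone tuning grid since tuning repeats at every step) and the
    candidate's pooled out-of-fold ROC AUC is averaged over ``n_rep``
    stratified fold reshuffles shared by all candidates of that step — at
    cohort scale a single 10-fold AUC estimate is noisy enough to scramble
    near-tied candidates, so selection uses a small Monte-Carlo average of
    the same estimator the final evaluation uses.  The best candidate is
    added and the process repeats until no features remain, so the full
    path — and the plateau at the optimal feature count — can be read off
    the result.

    Returns a DataFrame with one row per step: feature added, CV ROC AUC,
    and the tuned (c, sigma).
    """
    if X.shape[1] < 2:
        raise ValueError("forward selection needs at least 2 candidate features")
    _, y = _as_xy(X.to_numpy(float), y)
    grid = grid or SELECTION_GRID
    rng = np.random.default_rng(seed)
    remaining = list(X.columns)
    selected: list[str] = []
    rows = []
    while remaining:
        fold_sets = [_stratified_folds(y, k_folds, rng) for _ in range(n_rep)]
        step_seed = int(rng.integers(2**31 - 1))
        best = None
        for cand in remaining:
            cols = selected + [cand]
            Xc = X[cols].to_numpy(float)
            c, sigma = tune_hyperparams(Xc, y, k_folds, grid, seed=step_seed)
            auc = float(np.mean([
                roc_pr_curves(_cv_scores(Xc, y, c, sigma, folds), y).auc_roc
                for folds in fold_sets
            ]))
            if best is None or auc > best[0] + 1e-12:
                best = (auc, cand, c, sigma)
        auc, cand, c, sigma = best
        selected.append(cand)
        remaining.remove(cand)
        rows.append({"feature": cand, "auc_roc": auc, "c": c, "sigma": sigma})
    return pd.DataFrame(rows)


@dataclass
class TrainedClassifier:
    """A fitted RBF-SVM with its feature subset and standardization state."""

    features: list[str]
    c: float
    sigma: float
    center: np.ndarray
    scale: np.ndarray
    svc: SVC = field(repr=False)

    @classmethod
    def train(cls, X: pd.DataFrame, y, features=None, c: float = 1.0,
              sigma: float = 1.0) -> "TrainedClassifier":
        features = list(features) if features is not None else list(X.columns)
        Xf, y = _as_xy(X[features].to_numpy(float), y)
        mu = Xf.mean(axis=0)
        sd = Xf.std(axis=0)
        sd[sd == 0] = 1.0
        svc = _svc(c, sigma).fit((Xf - mu) / sd, y)
        return cls(features=features, c=c, sigma=sigma, center=mu, scale=sd, svc=svc)

    def _transform(self, X: pd.DataFrame) -> np.ndarray:
        return (X[self.features].to_numpy(float) - self.center) / self.scale

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self.svc.decision_function(self._transform(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.svc.predict(self._transform(X)).astype(bool)
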