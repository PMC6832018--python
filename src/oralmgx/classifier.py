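"""Marker-species disease classifier.

Candidate species are those differing between groups at raw rank-sum
P < 0.01. Candidates are ordered by mRMR (minimum-redundancy,
maximum-relevance, MID difference criterion on median-binarised
features). Nested prefixes of the order — every 5 species plus the full
set — are evaluated by leave-one-out cross-validation of a two-class
linear discriminant (pooled covariance with a small diagonal ridge), and
the grid winner is the smallest prefix with the highest Matthews
correlation coefficient, then refined by scanning the prefix sizes in
the interval-wide window around the winner (so e.g. a 7-species panel
can emerge from a 5-interval grid); window ties resolve toward the
larger prefix so a tie never discards candidate markers. The final classifier is an RBF-kernel SVM (cost 1,
kernel scale 1/n_features on standardised features) with probabilities
from a logistic calibration of its decision values; ROC AUC uses the
rank (Mann-Whitney) formulation with DeLong 95% confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score, roc_curve
from sklearn.svm import SVC

from .diffabund import _ranksum_p


# ------------------------------------------------------------- candidates

def candidate_features(matrix: pd.DataFrame, labels, p_max: float = 0.01) -> list:
    """Species with unadjusted two-sided rank-sum p < p_max (raw p by
    design, not FDR-adjusted)."""
    labels = pd.Series(labels, index=matrix.columns) if not isinstance(labels, pd.Series) else labels
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("candidate selection requires exactly two groups")
    cols1 = labels.index[labels == groups[0]]
    cols2 = labels.index[labels == groups[1]]
    candidates = []
    for feature in matrix.index:
        x = matrix.loc[feature, cols1].to_numpy(dtype=float)
        y = matrix.loc[feature, cols2].to_numpy(dtype=float)
        if len(np.unique(np.concatenate([x, y]))) == 1:
            continue
        _, p = _ranksum_p(x, y)
        if p < p_max:
            candidates.append(feature)
    if not candidates:
        raise ValueError(
            f"no features below raw p {p_max}; relax the threshold"
        )
    return candidates


# ------------------------------------------------------------------- mRMR

def _binarise(matrix: pd.DataFrame) -> np.ndarray:
    """Two-bin discretisation at the per-feature median."""
    X = matrix.to_numpy(dtype=float)
    return (X > np.median(X, axis=1, keepdims=True)).astype(int)


def mrmr_rank(matrix: pd.DataFrame, labels) -> list:
    """Greedy mRMR (MID) ordering of the matrix's features.

    The first feature maximises mutual information with the class label;
    each subsequent feature maximises MI(feature; label) minus the mean
    MI with the already-selected features. Ties break lexicographically
    on feature id, making the order deterministic.
    """
    features = list(matrix.index)
    if not features:
        raise ValueError("no candidate features to rank")
    y = pd.factorize(pd.Series(list(labels)))[0]
    B = _binarise(matrix)
    relevance = np.array([mutual_info_score(b, y) for b in B])
    n = len(features)
    pair_mi = np.zeros((n, n))
    selected: list[int] = []
    remaining = set(range(n))
    order: list = []
    while remaining:
        best, best_score = None, None
        for i in sorted(remaining, key=lambda k: features[k]):
            if selected:
                red = np.mean([_pair_mi(pair_mi, B, i, j) for j in selected])
            else:
                red = 0.0
            score = relevance[i] - red
            if best_score is None or score > best_score + 1e-15:
                best, best_score = i, score
        selected.append(best)
        remaining.discard(best)
        order.append(features[best])
    return order


def _pair_mi(cache: np.ndarray, B: np.ndarray, i: int, j: int) -> float:
    if cache[i, j] == 0.0 and i != j:
        cache[i, j] = cache[j, i] = mutual_info_score(B[i], B[j])
    return cache[i, j] if i != j else mutual_info_score(B[i], B[i])


# ---------------------------------------------------------- LDA + LOO-CV

class LinearDiscriminant:
    """Two-class LDA with pooled covariance and a diagonal ridge
    (1e-6 x mean diagonal) for stability when p approaches n."""

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray):
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("LinearDiscriminant is two-class only")
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        means, pooled = [], np.zeros((p, p))
        for c in self.classes_:
            Xc = X[y == c]
            means.append(Xc.mean(axis=0))
            pooled += (Xc - Xc.mean(axis=0)).T @ (Xc - Xc.mean(axis=0))
        pooled /= max(n - 2, 1)
        pooled += self.ridge * (np.trace(pooled) / p if np.trace(pooled) > 0 else 1.0) * np.eye(p)
        self.means_ = np.array(means)
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        self._inv = np.linalg.inv(pooled)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Positive favours the second class."""
        X = np.asarray(X, dtype=float)
        scores = []
        for k in range(2):
            m = self.means_[k]
            s = X @ self._inv @ m - 0.5 * m @ self._inv @ m + np.log(self.priors_[k])
            scores.append(s)
        return scores[1] - scores[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


def mcc_from_confusion(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def loo_evaluate(X: np.ndarray, y: np.ndarray, positive) -> dict:
    """Pooled leave-one-out confusion of the LDA on (X, y).

    Folds whose training split is single-class are skipped with a warning
    count. Returns error rate, MCC, and the per-sample LOO scores.
    """
    n = len(y)
    preds = np.empty(n, dtype=object)
    scores = np.full(n, np.nan)
    skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            skipped += 1
            continue
        model = LinearDiscriminant().fit(X[mask], y[mask])
        preds[i] = model.predict(X[i : i + 1])[0]
        # orient the decision score toward the positive class
        raw = model.decision_function(X[i : i + 1])[0]
        scores[i] = raw if model.classes_[1] == positive else -raw
    valid = np.array([p is not None for p in preds])
    yy, pp = y[valid], preds[valid]
    tp = int(((yy == positive) & (pp == positive)).sum())
    tn = int(((yy != positive) & (pp != positive)).sum())
    fp = int(((yy != positive) & (pp == positive)).sum())
    fn = int(((yy == positive) & (pp != positive)).sum())
    total = max(tp + tn + fp + fn, 1)
    return {
        "error_rate": (fp + fn) / total,
        "mcc": mcc_from_confusion(tp, tn, fp, fn),
        "scores": scores,
        "skipped_folds": skipped,
    }


@dataclass
class MarkerPanel:
    ordered_candidates: list
    subset_sizes: list
    error_rates: list
    mccs: list
    panel: list = field(default_factory=list)

    def validate(self) -> None:
        if self.panel != self.ordered_candidates[: len(self.panel)]:
            raise ValueError("chosen panel must be a prefix of the mRMR order")


def evaluate_subsets(
    ordered: list,
    matrix: pd.DataFrame,
    labels,
    positive,
    interval: int = 5,
    refine: bool = True,
) -> MarkerPanel:
    """LOO-LDA over nested prefixes of the mRMR order.

    Grid sizes are interval, 2*interval, ... plus the full set; the panel
    is the smallest grid prefix attaining the maximum MCC. With
    ``refine`` the sizes inside the winning interval-wide window are also
    scanned and the smallest size matching the window's best MCC wins.
    """
    if not ordered:
        raise ValueError("empty feature order")
    y = np.asarray(list(labels))
    sizes = list(range(interval, len(ordered) + 1, interval))
    if not sizes or sizes[-1] != len(ordered):
        sizes.append(len(ordered))
    errors, mccs = [], []
    for k in sizes:
        X = matrix.loc[ordered[:k]].to_numpy(dtype=float).T
        res = loo_evaluate(X, y, positive)
        errors.append(res["error_rate"])
        mccs.append(res["mcc"])
    best_mcc = max(mccs)
    k_best = sizes[int(np.argmax(np.array(mccs) >= best_mcc - 1e-12))]
    panel_size, panel_mcc = k_best, best_mcc
    if refine:
        # scan the interval-wide window around the grid winner; pick the
        # window's best MCC, resolving ties toward the larger prefix so a
        # tie never discards candidate markers
        lo = max(1, k_best - interval + 1)
        hi = min(len(ordered), k_best + interval - 1)
        for k in range(lo, hi + 1):
            if k == k_best:
                continue
            X = matrix.loc[ordered[:k]].to_numpy(dtype=float).T
            mcc_k = loo_evaluate(X, y, positive)["mcc"]
            if mcc_k > panel_mcc - 1e-12 and (mcc_k > panel_mcc + 1e-12 or k > panel_size):
                panel_size, panel_mcc = k, max(panel_mcc, mcc_k)
    panel = MarkerPanel(
        ordered_candidates=list(ordered),
        subset_sizes=sizes,
        error_rates=errors,
        mccs=mccs,
        panel=list(ordered[:panel_size]),
    )
    panel.validate()
    return panel


# ------------------------------------------------------------------- SVM

@dataclass
class ClassifierModel:
    panel: list
    positive: str
    svc: SVC
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    calib_coef: float
    calib_intercept: float

    def _prepare(self, matrix: pd.DataFrame) -> np.ndarray:
        X = matrix.loc[self.panel].to_numpy(dtype=float).T
        return (X - self.scaler_mean) / self.scaler_scale

    def decision_values(self, matrix: pd.DataFrame) -> np.ndarray:
        return self.svc.decision_function(self._prepare(matrix))

    def predict_proba(self, matrix: pd.DataFrame) -> np.ndarray:
        """Probability of the positive class via logistic calibration."""
        d = self.decision_values(matrix)
        return 1.0 / (1.0 + np.exp(-(self.calib_coef * d + self.calib_intercept)))

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        return np.where(self.predict_proba(matrix) > 0.5, self.positive, "other")

    def to_json(self) -> str:
        payload = {
            "panel": self.panel,
            "positive": self.positive,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "calibration": [self.calib_coef, self.calib_intercept],
            "support_vectors": self.svc.support_vectors_.tolist(),
            "dual_coef": self.svc.dual_coef_.tolist(),
            "intercept": self.svc.intercept_.tolist(),
            "gamma": float(self.svc._gamma),
        }
        return json.dumps(payload, indent=2)


def train_and_score(
    panel: list, matrix: pd.DataFrame, labels, positive
) -> tuple[ClassifierModel, np.ndarray]:
    """Fit the RBF SVM (cost 1, kernel scale 1/n_features after
    standardisation) on the panel and return per-sample caries
    probabilities for the training samples."""
    y = np.asarray(list(labels))
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    X = matrix.loc[panel].to_numpy(dtype=float).T
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    informative = scale > 0
    scale[~informative] = 1.0
    Xs = (X - mean) / scale
    # constant features standardise to zero and are inert; the kernel
    # scale counts only the informative ones so adding a constant feature
    # cannot change the fitted machine
    n_eff = max(int(informative.sum()), 1)
    svc = SVC(C=1.0, kernel="rbf", gamma=1.0 / n_eff, random_state=0)
    svc.fit(Xs, (y == positive).astype(int))
    d = svc.decision_function(Xs)
    coef, intercept = _platt(d, (y == positive).astype(int))
    model = ClassifierModel(
        panel=list(panel),
        positive=positive,
        svc=svc,
        scaler_mean=mean,
        scaler_scale=scale,
        calib_coef=coef,
        calib_intercept=intercept,
    )
    return model, model.predict_proba(matrix)


def _platt(decision: np.ndarray, y01: np.ndarray, n_iter: int = 200) -> tuple[float, float]:
    """Monotone logistic calibration of decision values (Newton steps)."""
    a, b = 1.0, 0.0
    for _ in range(n_iter):
        z = a * decision + b
        p = 1.0 / (1.0 + np.exp(-z))
        w = p * (1 - p) + 1e-12
        g = np.array([((p - y01) * decision).sum(), (p - y01).sum()])
        h = np.array(
            [
                [(w * decision ** 2).sum() + 1e-9, (w * decision).sum()],
                [(w * decision).sum(), w.sum() + 1e-9],
            ]
        )
        step = np.linalg.solve(h, g)
        a, b = a - step[0], b - step[1]
        if np.abs(step).max() < 1e-10:
            break
    if a < 0:  # keep the calibration monotone increasing
        a, b = 1.0, 0.0
    return float(a), float(b)


# -------------------------------------------------------------------- ROC

@dataclass
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    method: str
    curve: pd.DataFrame  # threshold, sensitivity, specificity

    def validate(self) -> None:
        if not (0.0 <= self.auc <= 1.0 and self.ci_lower <= self.auc <= self.ci_upper):
            raise ValueError("inconsistent AUC / CI")


def _midrank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def delong_auc_variance(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """AUC (Mann-Whitney, ties at half credit) and its DeLong variance."""
    m, n = len(pos_scores), len(neg_scores)
    all_scores = np.concatenate([pos_scores, neg_scores])
    rank_all = _midrank(all_scores)
    rank_pos = _midrank(pos_scores)
    rank_neg = _midrank(neg_scores)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (rank_all[:m] - rank_pos) / n  # structural components, positives
    v10 = 1.0 - (rank_all[m:] - rank_neg) / m  # negatives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def roc_auc(scores, labels, positive) -> RocResult:
    """ROC curve, AUC and DeLong 95% CI for the given scores."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(list(labels))
    pos, neg = scores[y == positive], scores[y != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    auc, var = delong_auc_variance(pos, neg)
    half = 1.959963984540054 * np.sqrt(var)
    fpr, tpr, thresholds = roc_curve((y == positive).astype(int), scores)
    curve = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": tpr, "specificity": 1 - fpr}
    )
    result = RocResult(
        auc=auc,
        ci_lower=float(max(0.0, min(auc, auc - half))),
        ci_upper=float(min(1.0, max(auc, auc + half))),
        method="delong",
        curve=curve,
    )
    result.validate()
    return result


LOG_PSEUDOCOUNT = 1e-10  # well below any realistic relative abundance


def build_classifier(
    matrix: pd.DataFrame,
    labels,
    positive,
    p_max: float = 0.01,
    interval: int = 5,
    refine: bool = True,
    log_transform: bool = True,
):
    """Full classifier stage: candidates -> mRMR -> subset LOO -> SVM.

    Candidate selection and mRMR act on relative abundances directly
    (both are rank/median based, so monotone transforms are irrelevant);
    the discriminant and SVM see log10 abundances by default, since
    relative abundances are heavily right-skewed and the discriminant
    assumes roughly Gaussian features.

    Returns (MarkerPanel, ClassifierModel, RocResult over LOO-LDA scores
    of the chosen panel).
    """
    candidates = candidate_features(matrix, labels, p_max=p_max)
    order = mrmr_rank(matrix.loc[candidates], labels)
    feats = np.log10(matrix + LOG_PSEUDOCOUNT) if log_transform else matrix
    panel = evaluate_subsets(order, feats, labels, positive, interval=interval, refine=refine)
    y = np.asarray(list(labels))
    X = feats.loc[panel.panel].to_numpy(dtype=float).T
    loo = loo_evaluate(X, y, positive)
    roc = roc_auc(loo["scores"], y, positive)
    model, _ = train_and_score(panel.panel, feats, labels, positive)
    return panel, model, roc
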