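"""Dimension reduction, classification and agreement statistics.

The feature table is reduced with correlation-matrix PCA (features are
z-scored so every feature enters with unit variance); the first four
principal components summarise the drawing and feed binary
bradykinesia-vs-dyskinesia classifiers evaluated with stratified 10-fold
cross-validation.  Agreement between raters, and between classifier and
raters, is summarised with Cohen's weighted kappa, percentage agreement
and predicted-class-conditional sensitivity/specificity; reliability of
the component scores uses the mean of all pairwise correlations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

BRADYKINESIA = "bradykinesia"
DYSKINESIA = "dyskinesia"

CLASSIFIERS = ("MLP", "RF", "SVM_rbf", "SVM_linear", "LR")

__all__ = [
    "PCModel",
    "ConfusionMatrix2x2",
    "EvalReport",
    "CLASSIFIERS",
    "fit_pca",
    "assemble_learning_set",
    "cross_validated_evaluation",
    "confusion_metrics",
    "pairwise_rater_agreement",
    "mean_pairwise_icc",
    "pc_rating_correlations",
]


# -------------------------------------------------------------------- PCA


@dataclass(frozen=True)
class PCModel:
    """Correlation-matrix PCA: standardisation constants plus loadings.

    ``loadings`` has orthonormal columns (one per retained component);
    ``explained_variance_fraction`` holds the retained components'
    shares of total (standardised) variance, non-increasing and summing
    to <= 1.
    """

    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    n_components: int

    def transform(self, X) -> np.ndarray:
        """Component scores for rows of X (columns = feature_names)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(float)
        Z = (np.asarray(X, float) - self.feature_means) / self.feature_sds
        return Z @ self.loadings

    def score_frame(self, X, index=None) -> pd.DataFrame:
        scores = self.transform(X)
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        if index is None and isinstance(X, pd.DataFrame):
            index = X.index
        return pd.DataFrame(scores, columns=cols, index=index)


def fit_pca(feature_table, n_components: int = 4) -> PCModel:
    """PCA on the correlation matrix of a trials-by-features table.

    Features are z-scored (sample sd), zero-variance features dropped
    with a warning, and the correlation structure eigendecomposed via
    SVD.  Component signs follow a deterministic convention: the
    largest-|loading| entry of each component is positive.
    """
    if isinstance(feature_table, pd.DataFrame):
        names = list(feature_table.columns)
        X = feature_table.to_numpy(float)
    else:
        X = np.asarray(feature_table, float)
        names = [f"f{i}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 complete rows")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values; drop incomplete rows first")
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped)
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
        sds = sds[keep]
    p = X.shape[1]
    if n_components > p:
        raise ValueError(f"requested {n_components} components from {p} features")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    # SVD of Z/sqrt(n-1): squared singular values are the correlation
    # matrix eigenvalues
    _, s, vt = np.linalg.svd(Z / math.sqrt(X.shape[0] - 1), full_matrices=False)
    eigvals = s**2
    fractions = eigvals / eigvals.sum()
    loadings = vt[:n_components].T.copy()
    for j in range(n_components):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return PCModel(
        feature_names=names,
        feature_means=means,
        feature_sds=sds,
        loadings=loadings,
        explained_variance_fraction=fractions[:n_components],
        n_components=n_components,
    )


# --------------------------------------------------------- learning set


def assemble_learning_set(
    ratings: pd.DataFrame,
    pc_scores_by_case: pd.DataFrame,
    impairment_threshold: float = 5.0,
    seed: int = 0,
    impairment_by_case: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Build (PC scores, symptom label) examples, one per retained case.

    Cases whose mean impairment falls below ``impairment_threshold``
    are excluded (only moderately-to-severely impaired drawings show
    symptom-specific deficits).  Each retained case keeps the rating of
    exactly one rater, sampled uniformly at random among raters who
    labelled the case bradykinesia or dyskinesia, so all raters are
    equally represented in expectation.

    Parameters
    ----------
    ratings : columns ``case_id, rater_id, impairment, symptom`` (other
        rating columns pass through unused).
    pc_scores_by_case : indexed by case_id, columns PC1..PCk.
    impairment_by_case : optional external per-case impairment scores;
        defaults to the mean of the raters' impairment column.
    """
    rng = np.random.default_rng(seed)
    if impairment_by_case is None:
        impairment_by_case = ratings.groupby("case_id")["impairment"].mean()
    else:
        impairment_by_case = pd.Series(impairment_by_case)
    rows = []
    n_no_eligible = 0
    for case_id, grp in ratings.groupby("case_id", sort=True):
        if case_id not in pc_scores_by_case.index:
            continue
        if float(impairment_by_case.get(case_id, 0.0)) < impairment_threshold:
            continue
        eligible = grp[grp["symptom"].isin([BRADYKINESIA, DYSKINESIA])]
        if eligible.empty:
            n_no_eligible += 1
            continue
        pick = eligible.iloc[rng.integers(0, len(eligible))]
        row = {"case_id": case_id, "rater_id": pick["rater_id"], "label": pick["symptom"]}
        row.update(pc_scores_by_case.loc[case_id].to_dict())
        rows.append(row)
    if n_no_eligible:
        logger.info("excluded %d case(s) with no bradykinesia/dyskinesia rating", n_no_eligible)
    return pd.DataFrame(rows)


def aggregate_case_scores(trial_scores: pd.DataFrame, case_col: str = "occasion_id") -> pd.DataFrame:
    """Per-case PC scores: mean of the case's per-trial scores."""
    pc_cols = [c for c in trial_scores.columns if c.startswith("PC")]
    return trial_scores.groupby(case_col)[pc_cols].mean()


# ---------------------------------------------------------- classification


def make_classifier(method: str, n_features: int, seed: int = 0):
    """Instantiate one of the five evaluated classifiers.

    Concrete defaults (kept fixed across all experiments): MLP with a
    single hidden layer of ceil((inputs+classes)/2) logistic units
    trained by SGD (learning rate 0.3, momentum 0.2, 500 epochs);
    SVMs with C = 1 (RBF gamma = 1/inputs); unpenalised logistic
    regression; random forest with 100 trees.
    """
    if method == "MLP":
        hidden = math.ceil((n_features + 2) / 2)
        return MLPClassifier(
            hidden_layer_sizes=(hidden,),
            activation="logistic",
            solver="sgd",
            learning_rate_init=0.3,
            momentum=0.2,
            max_iter=500,
            random_state=seed,
        )
    if method == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if method == "SVM_linear":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if method == "SVM_rbf":
        return SVC(kernel="rbf", C=1.0, gamma="auto", random_state=seed)
    if method == "LR":
        # C = inf -> unpenalised maximum-likelihood fit
        return LogisticRegression(C=np.inf, max_iter=1000)
    raise ValueError(f"unknown method {method!r}; choose from {CLASSIFIERS}")


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Rater-by-classifier table with bradykinesia as the positive class.

    ``tp``: both say bradykinesia; ``fn``: rater bradykinesia,
    classifier dyskinesia; ``fp``: rater dyskinesia, classifier
    bradykinesia; ``tn``: both dyskinesia.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass(frozen=True)
class EvalReport:
    method: str
    folds: int
    seed: int
    confusion: ConfusionMatrix2x2
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    sensitivity_row_pct: float
    specificity_row_pct: float
    weighted_kappa: float
    auc: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "folds": self.folds,
            "seed": self.seed,
            "confusion": self.confusion.to_dict(),
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "sensitivity_row_pct": self.sensitivity_row_pct,
            "specificity_row_pct": self.specificity_row_pct,
            "weighted_kappa": self.weighted_kappa,
            "auc": self.auc,
        }


def confusion_metrics(cm: ConfusionMatrix2x2) -> dict[str, float]:
    """Accuracy, sensitivity, specificity (%) and weighted kappa.

    Sensitivity and specificity condition on the *predicted* class
    (column margins): sensitivity = tp / (tp + fp), the share of
    predicted-bradykinesia calls confirmed by the raters, and
    specificity = tn / (tn + fn).  The conventional row-margin variants
    are returned as ``sensitivity_row_pct``/``specificity_row_pct``.
    Weighted kappa with linear weights coincides with Cohen's kappa for
    two categories.
    """
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * (tp + tn) / total
    col_pos, col_neg = tp + fp, tn + fn
    row_pos, row_neg = tp + fn, fp + tn
    sens = 100.0 * tp / col_pos if col_pos else math.nan
    spec = 100.0 * tn / col_neg if col_neg else math.nan
    sens_row = 100.0 * tp / row_pos if row_pos else math.nan
    spec_row = 100.0 * tn / row_neg if row_neg else math.nan
    p_o = (tp + tn) / total
    p_e = (row_pos * col_pos + row_neg * col_neg) / total**2
    if (row_pos and row_neg and col_pos and col_neg) and p_e < 1.0:
        kappa = (p_o - p_e) / (1.0 - p_e)
    else:
        kappa = math.nan
    return {
        "accuracy_pct": accuracy,
        "sensitivity_pct": sens,
        "specificity_pct": spec,
        "sensitivity_row_pct": sens_row,
        "specificity_row_pct": spec_row,
        "weighted_kappa": kappa,
    }


def cross_validated_evaluation(
    examples: pd.DataFrame,
    method: str = "MLP",
    folds: int = 10,
    seed: int = 0,
    label_col: str = "label",
) -> EvalReport:
    """Stratified k-fold evaluation of one classifier.

    Out-of-fold predictions are pooled into a single confusion matrix
    (bradykinesia positive); the AUC uses the pooled out-of-fold
    probability (or decision-function) rankings.  Deterministic given
    the seed.
    """
    pc_cols = [c for c in examples.columns if c.startswith("PC")]
    X = examples[pc_cols].to_numpy(float)
    y = np.asarray(examples[label_col])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} examples; use <= {counts.min()} folds"
        )
    pos = BRADYKINESIA if BRADYKINESIA in classes else classes[0]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    score = np.empty(len(y), dtype=float)
    for fold_i, (tr, te) in enumerate(skf.split(X, y)):
        clf = make_classifier(method, X.shape[1], seed=seed + fold_i)
        clf.fit(X[tr], y[tr])
        pred[te] = clf.predict(X[te])
        if hasattr(clf, "predict_proba"):
            proba = clf.predict_proba(X[te])
            score[te] = proba[:, list(clf.classes_).index(pos)]
        else:
            df = clf.decision_function(X[te])
            score[te] = df if clf.classes_[1] == pos else -df
    cm = ConfusionMatrix2x2(
        tp=int(((y == pos) & (pred == pos)).sum()),
        fn=int(((y == pos) & (pred != pos)).sum()),
        fp=int(((y != pos) & (pred == pos)).sum()),
        tn=int(((y != pos) & (pred != pos)).sum()),
    )
    metrics = confusion_metrics(cm)
    auc = float(roc_auc_score((y == pos).astype(int), score))
    return EvalReport(
        method=method,
        folds=folds,
        seed=seed,
        confusion=cm,
        auc=auc,
        **{k: metrics[k] for k in (
            "accuracy_pct",
            "sensitivity_pct",
            "specificity_pct",
            "sensitivity_row_pct",
            "specificity_row_pct",
            "weighted_kappa",
        )},
    )


# ------------------------------------------------------------- agreement


def pairwise_rater_agreement(labels_a, labels_b) -> dict[str, float]:
    """Agreement of two raters' binary symptom labels on shared cases.

    Returns Cohen's kappa, percentage agreement, and false-positive /
    false-negative rates (%) with rater A as reference and bradykinesia
    positive: fp_rate is the share of A's dyskinesia cases that B
    called bradykinesia, fn_rate the share of A's bradykinesia cases
    that B called dyskinesia.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size or a.size < 2:
        raise ValueError("need >= 2 shared cases with labels from both raters")
    agree = float((a == b).mean())
    a_pos, b_pos = a == BRADYKINESIA, b == BRADYKINESIA
    p_e = float(a_pos.mean() * b_pos.mean() + (1 - a_pos.mean()) * (1 - b_pos.mean()))
    kappa = (agree - p_e) / (1.0 - p_e) if p_e < 1.0 else math.nan
    n_neg, n_pos = int((~a_pos).sum()), int(a_pos.sum())
    fp_rate = 100.0 * float((b_pos & ~a_pos).sum()) / n_neg if n_neg else math.nan
    fn_rate = 100.0 * float((~b_pos & a_pos).sum()) / n_pos if n_pos else math.nan
    return {
        "weighted_kappa": kappa,
        "percent_agreement": 100.0 * agree,
        "fp_rate": fp_rate,
        "fn_rate": fn_rate,
    }


def mean_pairwise_icc(score_vectors) -> float:
    """Mean of all pairwise Pearson correlations among k parallel vectors.

    Used both for inter-rater reliability (k raters -> k(k-1)/2 pairs)
    and test-retest reliability of component scores across the three
    trials of an occasion (k = 3 -> 3 pairs).  Zero-variance vectors
    are excluded from pairing with a warning.
    """
    vecs = [np.asarray(v, float) for v in score_vectors]
    if len(vecs) < 2:
        raise ValueError("need >= 2 vectors")
    length = vecs[0].size
    if any(v.size != length for v in vecs) or length < 3:
        raise ValueError("vectors must share a length >= 3")
    usable = [v for v in vecs if v.std() > 0]
    if len(usable) < len(vecs):
        logger.warning("excluded %d zero-variance vector(s)", len(vecs) - len(usable))
    if len(usable) < 2:
        raise ValueError("fewer than 2 vectors with nonzero variance")
    cors = [float(np.corrcoef(u, v)[0, 1]) for u, v in combinations(usable, 2)]
    return float(np.mean(cors))


def pc_rating_correlations(
    pc_scores_by_case: pd.DataFrame, mean_ratings_by_case: pd.DataFrame
) -> pd.DataFrame:
    """Absolute Spearman correlations of each PC with each mean rating.

    Rows are rating dimensions, columns components; entries lie in
    [0, 1] (nan for a constant rating column).  Requires >= 5 cases
    present in both tables.
    """
    shared = pc_scores_by_case.index.intersection(mean_ratings_by_case.index)
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared cases, got {len(shared)}")
    pcs = pc_scores_by_case.loc[shared]
    ratings = mean_ratings_by_case.loc[shared]
    out = pd.DataFrame(index=ratings.columns, columns=pcs.columns, dtype=float)
    for rcol in ratings.columns:
        for pcol in pcs.columns:
            if ratings[rcol].nunique() < 2:
                out.loc[rcol, pcol] = math.nan
                continue
            rho = stats.spearmanr(pcs[pcol], ratings[rcol]).statistic
            out.loc[rcol, pcol] = abs(float(rho))
    return out
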