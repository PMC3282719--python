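"""Differentiation-stage classification from histone-modification features.

Cell lines are classified into P (pluripotent), M (multipotent) or U/D
(unipotent/differentiated) from one of three data representations -- raw bin
signal, gene-level mark scores, or integer-coded chromatin states -- with a
support vector machine evaluated by leave-one-out cross-validation (LOOCV).
Everything that adapts to the data (feature selection for the bin
representation, standardization, the radial-kernel width) happens inside each
training fold, so the held-out line never leaks into the model.

A deliberately simple alternative uses just three numbers per cell line: the
fraction of genes in each of the Core / PRC / MYC embryonic-stem-cell
regulatory modules that sit in the non-active chromatin state, fed into a
multinomial logistic regression.  A line is assigned to class j only when its
predicted probability exceeds 0.5; otherwise it is "unknown".

Cancer lines (label C) are never used for training; they are classified by
models trained on the normal lines only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial.distance import pdist, squareform
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

# radial-kernel width grid: multipliers of the "scale" heuristic
# gamma0 = 1 / (n_features * var(X)), searched by inner cross-validation
GAMMA_FACTORS = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class ClassifierReport:
    """LOOCV outcome: per-line truth and prediction, plus headline accuracy."""

    cell_lines: list
    true_labels: list
    predicted: list
    kernel: str
    representation: str
    skipped: list = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        pairs = [(t, p) for cl, t, p in zip(self.cell_lines, self.true_labels, self.predicted)
                 if cl not in self.skipped]
        if not pairs:
            return float("nan")
        return 100.0 * sum(t == p for t, p in pairs) / len(pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_line": self.cell_lines,
            "true": self.true_labels,
            "predicted": self.predicted,
        })


def select_top_variable_features(X: pd.DataFrame, n_features: int) -> pd.DataFrame:
    """Keep the ``n_features`` columns with the largest across-line variance.

    Ties break deterministically toward the earlier (genomic-order) column;
    the selected columns keep their original order.
    """
    if n_features >= X.shape[1]:
        return X
    var = X.var(axis=0, ddof=1).to_numpy()
    order = np.argsort(-var, kind="stable")[:n_features]
    return X.iloc[:, np.sort(order)]


def _fit_fold(X_tr, y_tr, kernel, C, seed, select_n):
    cols = None
    if select_n is not None:
        Xf = select_top_variable_features(pd.DataFrame(X_tr), select_n)
        cols = Xf.columns.to_numpy()
        X_tr = Xf.to_numpy()
    scaler = StandardScaler().fit(X_tr)
    Xs = scaler.transform(X_tr)
    if kernel == "linear":
        clf = SVC(kernel="linear", C=C).fit(Xs, y_tr)
    elif kernel == "radial":
        min_class = min(np.bincount(pd.factorize(y_tr)[0]))
        n_splits = max(2, min(3, min_class))
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        var = float(Xs.var())
        gamma0 = 1.0 / (Xs.shape[1] * var) if var > 0 else 1.0 / Xs.shape[1]
        grid = [f * gamma0 for f in GAMMA_FACTORS]
        # cost must be searched jointly with gamma: at small C the radial
        # model gives the minority classes no dual weight and degenerates to
        # the majority-class rule
        search = GridSearchCV(SVC(kernel="rbf"),
                              {"gamma": grid, "C": [C, 10 * C, 100 * C]}, cv=cv)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(Xs, y_tr)
        clf = search.best_estimator_
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return cols, scaler, clf


def loocv_svm(features: pd.DataFrame, labels, kernel: str = "linear",
              C: float = 1.0, seed: int = 0, select_n: int | None = None,
              representation: str = "state") -> ClassifierReport:
    """Leave-one-out cross-validated SVM accuracy.

    ``features`` is cell lines x features; ``labels`` the P/M/U-D classes.
    Standardization, optional most-variable-feature selection (``select_n``)
    and, for the radial kernel, the width parameter gamma (inner
    cross-validated grid search) are all fit on each training fold only.
    Folds whose training set loses a class entirely are skipped with a
    warning and excluded from the accuracy denominator.
    """
    X = features.to_numpy(float)
    y = np.asarray(labels)
    lines = list(features.index)
    preds, skipped = [], []
    n_classes = len(pd.unique(y))
    for i in range(len(lines)):
        mask = np.ones(len(lines), dtype=bool)
        mask[i] = False
        if len(pd.unique(y[mask])) < n_classes:
            warnings.warn(f"fold {lines[i]}: a class vanished from training; skipped")
            skipped.append(lines[i])
            preds.append("skipped")
            continue
        cols, scaler, clf = _fit_fold(X[mask], y[mask], kernel, C, seed, select_n)
        x = X[i : i + 1]
        if cols is not None:
            x = x[:, cols]
        preds.append(str(clf.predict(scaler.transform(x))[0]))
    return ClassifierReport(lines, list(y), preds, kernel, representation, skipped)


def classify_new_lines(features: pd.DataFrame, labels, new_features: pd.DataFrame,
                       kernel: str = "linear", C: float = 1.0, seed: int = 0,
                       select_n: int | None = None) -> pd.Series:
    """Train on the labeled (normal) lines, classify held-out (cancer) lines."""
    cols, scaler, clf = _fit_fold(features.to_numpy(float), np.asarray(labels),
                                  kernel, C, seed, select_n)
    Xn = new_features.to_numpy(float)
    if cols is not None:
        Xn = Xn[:, cols]
    return pd.Series(clf.predict(scaler.transform(Xn)), index=new_features.index)


def null_model_accuracy(labels) -> float:
    """Accuracy (%) of always predicting the largest class."""
    counts = pd.Series(labels).value_counts()
    return 100.0 * counts.iloc[0] / counts.sum()


# ---------------------------------------------------------------------------
# module-fraction logistic model
# ---------------------------------------------------------------------------

def module_fractions(state_matrix: pd.DataFrame, modules: dict,
                     target_state: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per cell line, fraction of each module's genes in the target state.

    Module genes absent from the annotation are dropped from the denominator;
    the second return value reports how many were present/absent per module.
    ``target_state`` defaults to 2 (non-active); pass 1 for the null state.
    """
    out = {}
    report = []
    for name, genes in modules.items():
        present = [g for g in genes if g in state_matrix.index]
        report.append((name, len(genes), len(present)))
        if not present:
            raise ValueError(f"module {name!r} has no genes in the state matrix")
        sub = state_matrix.loc[present]
        out[name] = (sub == target_state).mean(axis=0)
    fracs = pd.DataFrame(out)
    rep = pd.DataFrame(report, columns=["module", "n_genes", "n_present"])
    return fracs, rep


@dataclass
class ModuleLogitModel:
    """Ridge-penalized multinomial logit on the three module fractions.

    With ~24 training points and near-separable fractions the unpenalized
    maximum-likelihood estimate diverges; a mild ridge penalty keeps the
    class probabilities well-defined.  The 0.5 probability threshold (with an
    "unknown" outcome when no class clears it) is part of the classification
    rule, not of the fit.
    """

    estimator: LogisticRegression
    classes: list
    threshold: float = 0.5

    def predict_proba(self, x: pd.DataFrame) -> pd.DataFrame:
        p = self.estimator.predict_proba(x.to_numpy(float))
        return pd.DataFrame(p, index=x.index, columns=self.classes)

    def classify(self, x: pd.DataFrame) -> pd.Series:
        proba = self.predict_proba(x)
        out = []
        for _, row in proba.iterrows():
            j = row.idxmax()
            out.append(j if row[j] > self.threshold else "unknown")
        return pd.Series(out, index=x.index)


def fit_module_logit(fractions: pd.DataFrame, labels, ridge: float = 0.1,
                     threshold: float = 0.5) -> ModuleLogitModel:
    """Fit the multinomial logit of class on the three module fractions.

    ``ridge`` is the L2 penalty weight (sklearn C = 1/ridge).
    """
    y = np.asarray(labels)
    if len(pd.unique(y)) < 2:
        raise ValueError("need at least two classes to fit the logit model")
    est = LogisticRegression(C=1.0 / ridge, max_iter=10_000)
    est.fit(fractions.to_numpy(float), y)
    return ModuleLogitModel(est, list(est.classes_), threshold)


def classify_module_logit(model: ModuleLogitModel, fractions: pd.DataFrame) -> pd.Series:
    return model.classify(fractions)


# ---------------------------------------------------------------------------
# hierarchical clustering of cell lines
# ---------------------------------------------------------------------------

def hierarchical_cluster_cell_lines(state_matrix: pd.DataFrame, n_clusters: int = 3):
    """Average-linkage clustering of cell lines on state Hamming distance.

    Distance between two lines is the fraction of genes whose chromatin state
    differs.  Returns ``(linkage matrix, leaf order, flat cluster labels)``;
    leaf order and flat labels are aligned to the state-matrix columns.
    """
    X = state_matrix.to_numpy().T         # lines x genes
    D = pdist(X, metric="hamming")
    Z = average(D)
    leaves = [state_matrix.columns[i] for i in leaves_list(Z)]
    flat = pd.Series(fcluster(Z, t=n_clusters, criterion="maxclust"),
                     index=state_matrix.columns)
    return Z, leaves, flat


def hamming_distance_matrix(state_matrix: pd.DataFrame) -> pd.DataFrame:
    X = state_matrix.to_numpy().T
    D = squareform(pdist(X, metric="hamming"))
    return pd.DataFrame(D, index=state_matrix.columns, columns=state_matrix.columns)
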