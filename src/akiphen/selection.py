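"""Regularized variable-selection validation: logistic lasso and a regularized forest.

These selectors cross-check the stepwise additive-model selection: if independent
shrinkage-based methods pick (mostly) the same features, the selected risk-factor set
is unlikely to be an artefact of the stepwise procedure.

* Lasso: L1-penalized logistic regression over a decreasing lambda path; lambda chosen
  by repeated cross-validation maximizing out-of-fold AUC; selected = nonzero
  coefficients at the chosen lambda.
* Regularized random forest: iterative importance-gated feature entry over random
  forests — a feature joins the selected set only when its impurity importance exceeds
  a penalty fraction ``gamma`` of the current best selected importance, mimicking a
  gain penalty on new features.  Final importances are permutation AUC drops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold


@dataclass
class SelectionResult:
    method: str
    selected: list
    importance: pd.Series          # descending
    oof_auc: np.ndarray            # out-of-fold AUC per CV split
    parameter: float               # chosen lambda (lasso) / gamma (forest)


def lasso_lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda that zeroes every coefficient (KKT bound at the null model):
    max_j |x_j' (y - ybar)| / n."""
    ybar = y.mean()
    return float(np.max(np.abs(X.T @ (y - ybar))) / len(y))


def lasso_select(X: pd.DataFrame, y, n_lambdas: int = 30, cv_repeats: int = 5,
                 cv_folds: int = 10, seed: int = 0) -> SelectionResult:
    """Coordinate-descent logistic lasso (liblinear) over a lambda path with
    repeated-CV AUC selection."""
    cols = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    lam_max = lasso_lambda_max(Xa, y)
    lambdas = lam_max * np.logspace(0, -3, n_lambdas)
    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats,
                                 random_state=seed)
    splits = list(cv.split(Xa, y))
    mean_auc = np.full(n_lambdas, -np.inf)
    fold_aucs = {}
    for i, lam in enumerate(lambdas):
        C = 1.0 / max(lam * n, 1e-12)
        aucs = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                     max_iter=2000)
            clf.fit(Xa[tr], y[tr])
            aucs.append(roc_auc_score(y[te], clf.decision_function(Xa[te])))
        if aucs:
            mean_auc[i] = float(np.mean(aucs))
            fold_aucs[i] = np.array(aucs)
    best = int(np.argmax(mean_auc))
    lam = float(lambdas[best])
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / max(lam * n, 1e-12),
                             solver="liblinear", max_iter=5000)
    clf.fit(Xa, y)
    coefs = pd.Series(np.abs(clf.coef_[0]), index=cols).sort_values(ascending=False)
    selected = coefs[coefs > 0].index.tolist()
    return SelectionResult(method="lasso", selected=selected, importance=coefs,
                           oof_auc=fold_aucs.get(best, np.array([])), parameter=lam)


def _permutation_auc_drop(model, X: np.ndarray, y: np.ndarray, cols,
                          rng) -> pd.Series:
    base = roc_auc_score(y, model.predict_proba(X)[:, 1])
    drops = {}
    for j, c in enumerate(cols):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        drops[c] = base - roc_auc_score(y, model.predict_proba(Xp)[:, 1])
    return pd.Series(drops).sort_values(ascending=False)


def regularized_forest_select(X: pd.DataFrame, y, gamma: float = 0.3,
                              n_trees: int = 300, cv_repeats: int = 5,
                              cv_folds: int = 10, seed: int = 0,
                              max_rounds: int = 10) -> SelectionResult:
    """Importance-gated forest selection with gain penalty coefficient ``gamma``.

    Starting from the single most important feature of a full forest, repeatedly
    refit on the selected set plus all candidates and admit any candidate whose
    impurity importance exceeds ``gamma`` times the top selected importance; stop at
    a fixed point.  Smaller gamma admits more features.
    """
    cols = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)

    def forest(seed_):
        return RandomForestClassifier(n_estimators=n_trees, min_samples_leaf=5,
                                      random_state=seed_)

    full = forest(seed).fit(Xa, y)
    imp = pd.Series(full.feature_importances_, index=cols)
    selected = [imp.idxmax()]
    for _round in range(max_rounds):
        top = imp[selected].max()
        entrants = [c for c in cols if c not in selected and imp[c] >= gamma * top]
        if not entrants:
            break
        selected.extend(entrants)
        sub = forest(seed + 1 + _round).fit(Xa[:, [cols.index(c) for c in selected]], y)
        sub_imp = pd.Series(sub.feature_importances_, index=selected)
        imp.loc[selected] = sub_imp

    importance = _permutation_auc_drop(full, Xa, y, cols, rng)
    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats,
                                 random_state=seed)
    sel_idx = [cols.index(c) for c in selected]
    aucs = []
    for tr, te in cv.split(Xa, y):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            continue
        m = forest(seed).fit(Xa[np.ix_(tr, sel_idx)], y[tr])
        aucs.append(roc_auc_score(y[te], m.predict_proba(Xa[np.ix_(te, sel_idx)])[:, 1]))
    order = [c for c in importance.index if c in selected]
    return SelectionResult(method="regularized_random_forest", selected=order,
                           importance=importance, oof_auc=np.array(aucs),
                           parameter=gamma)


def regularized_selection(X: pd.DataFrame, y, methods=("lasso",
                                                       "regularized_random_forest"),
                          seed: int = 0, **kwargs) -> dict:
    """Run the configured selectors; returns ``{method: SelectionResult}``."""
    out = {}
    for m in methods:
        if m == "lasso":
            out[m] = lasso_select(X, y, seed=seed, **kwargs.get("lasso", {}))
        elif m == "regularized_random_forest":
            out[m] = regularized_forest_select(X, y, seed=seed,
                                               **kwargs.get("rrf", {}))
        else:
            raise ValueError(f"unknown selection method {m!r}")
    return out
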