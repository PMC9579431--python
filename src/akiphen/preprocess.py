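"""Cohort preprocessing: power normalisation, bagged-tree imputation, collinearity pruning.

Numeric covariates are brought to a common, roughly Gaussian scale by a Yeo-Johnson
power transform (maximum-likelihood exponent per feature) followed by centring and
scaling.  Binary covariates pass through untouched as 0/1.  Missing cells are filled by
an ensemble of bootstrap-resampled CART trees per feature, and near-duplicate features
(|Pearson r| above a threshold, 0.8 by default) are pruned greedily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.ensemble import BaggingClassifier, BaggingRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor


# ---------------------------------------------------------------------------
# Yeo-Johnson
# ---------------------------------------------------------------------------

def apply_yeo_johnson(x, lmbda: float):
    """Yeo-Johnson transform, elementwise; monotone increasing in x for every lambda."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    if abs(lmbda) > 1e-12:
        out[pos] = ((x[pos] + 1.0) ** lmbda - 1.0) / lmbda
    else:
        out[pos] = np.log1p(x[pos])
    if abs(lmbda - 2.0) > 1e-12:
        out[~pos] = -(((-x[~pos] + 1.0) ** (2.0 - lmbda)) - 1.0) / (2.0 - lmbda)
    else:
        out[~pos] = -np.log1p(-x[~pos])
    return out if out.ndim else float(out)


def _yj_loglik(lmbda: float, x: np.ndarray) -> float:
    """Profile log-likelihood of the Gaussian model on the transformed values."""
    z = apply_yeo_johnson(x, lmbda)
    n = len(x)
    var = z.var()
    if var <= 0:
        return -np.inf
    # Jacobian: d/dx YJ(x) = (x+1)^(l-1) for x>=0, (1-x)^(1-l) for x<0
    jac = (lmbda - 1.0) * np.sum(np.sign(x) * np.log1p(np.abs(x)))
    return -0.5 * n * np.log(var) + jac


def fit_yeo_johnson(values, grid_step: float = 0.05, bounds=(-3.0, 3.0)) -> float:
    """Maximum-likelihood Yeo-Johnson exponent.

    Coarse grid search over ``bounds`` then golden-section refinement to 1e-4.
    Requires at least 10 finite values with nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("need at least 10 finite values to fit lambda")
    if x.var() == 0:
        raise ValueError("constant input: lambda is not identified")
    grid = np.arange(bounds[0], bounds[1] + grid_step / 2, grid_step)
    ll = np.array([_yj_loglik(l, x) for l in grid])
    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda l: -_yj_loglik(l, x), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x)


@dataclass
class TransformParams:
    """Per-feature Yeo-Johnson exponent plus post-transform centre/scale."""

    lmbda: dict = field(default_factory=dict)
    center: dict = field(default_factory=dict)
    scale: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["feature\tlambda\tcenter\tscale"]
        for name in self.lmbda:
            lines.append(
                f"{name}\t{self.lmbda[name]:.10g}\t{self.center[name]:.10g}\t{self.scale[name]:.10g}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "TransformParams":
        params = cls()
        for line in text.strip().splitlines()[1:]:
            name, l, c, s = line.split("\t")
            params.lmbda[name] = float(l)
            params.center[name] = float(c)
            params.scale[name] = float(s)
        return params


def is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return len(vals) <= 2 and set(vals) <= {0, 1, 0.0, 1.0, True, False}


def fit_transform_params(table: pd.DataFrame, numeric_cols=None) -> TransformParams:
    """Fit Yeo-Johnson + centre/scale per numeric (non-binary) column."""
    params = TransformParams()
    cols = numeric_cols if numeric_cols is not None else [
        c for c in table.columns if not is_binary(table[c])
    ]
    for c in cols:
        x = table[c].dropna().to_numpy(dtype=float)
        lam = fit_yeo_johnson(x)
        z = apply_yeo_johnson(x, lam)
        params.lmbda[c] = lam
        params.center[c] = float(z.mean())
        sd = float(z.std(ddof=0))
        params.scale[c] = sd if sd > 0 else 1.0
    return params


def transform_table(table: pd.DataFrame, params: TransformParams) -> pd.DataFrame:
    """Apply fitted transform; missing cells stay missing, binary columns untouched."""
    out = table.copy()
    for c, lam in params.lmbda.items():
        obs = out[c].notna()
        z = apply_yeo_johnson(out.loc[obs, c].to_numpy(dtype=float), lam)
        out.loc[obs, c] = (z - params.center[c]) / params.scale[c]
    return out


# ---------------------------------------------------------------------------
# Bagged-tree imputation
# ---------------------------------------------------------------------------

def bagged_impute(table: pd.DataFrame, n_trees: int = 25, seed: int = 0,
                  exclude=()) -> pd.DataFrame:
    """Fill every missing cell with a bagged-CART prediction from the other features.

    One ensemble of ``n_trees`` unlimited-depth trees (minimum leaf size 5) is fitted
    per feature with missingness, trained on the rows where that feature is observed;
    the remaining features enter as predictors with their own missing entries filled by
    column medians (predictor-side only).  Numeric targets get the ensemble mean,
    binary targets the majority vote.  Observed cells are never changed.
    """
    out = table.copy()
    cols = [c for c in table.columns if c not in exclude]
    missing_cols = [c for c in cols if out[c].isna().any()]
    if not missing_cols:
        return out
    rng = np.random.default_rng(seed)
    median_filled = out[cols].apply(
        lambda s: s.fillna(s.median()) if s.notna().any() else s
    )
    for c in missing_cols:
        if out[c].notna().sum() == 0:
            raise ValueError(f"feature {c!r} is missing in every row")
        predictors = [p for p in cols if p != c]
        obs = out[c].notna().to_numpy()
        X_train = median_filled.loc[obs, predictors].to_numpy(dtype=float)
        y_train = out.loc[obs, c].to_numpy(dtype=float)
        X_pred = median_filled.loc[~obs, predictors].to_numpy(dtype=float)
        state = int(rng.integers(2**31 - 1))
        if is_binary(table[c]):
            base = DecisionTreeClassifier(min_samples_leaf=5)
            model = BaggingClassifier(base, n_estimators=n_trees, random_state=state)
            model.fit(X_train, y_train.astype(int))
            filled = model.predict(X_pred).astype(float)
        else:
            base = DecisionTreeRegressor(min_samples_leaf=5)
            model = BaggingRegressor(base, n_estimators=n_trees, random_state=state)
            model.fit(X_train, y_train)
            filled = model.predict(X_pred)
        out.loc[~obs, c] = filled
    return out


# ---------------------------------------------------------------------------
# Collinearity pruning
# ---------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    correlation: pd.DataFrame
    removed: list
    threshold: float

    def to_text(self) -> str:
        lines = [f"threshold\t{self.threshold}"]
        for name in self.removed:
            lines.append(f"removed\t{name}")
        return "\n".join(lines) + "\n"


def prune_collinear(table: pd.DataFrame, threshold: float = 0.8) -> CollinearityReport:
    """Greedy removal of collinear features.

    While any pair exceeds ``threshold`` in |Pearson r|, drop — from the worst
    offending pair — the member with the larger mean absolute correlation to all other
    surviving features.  Guarantees no surviving pair exceeds the threshold.
    """
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise ValueError("need at least 2 numeric features")
    corr = numeric.corr()
    removed: list = []
    keep = list(corr.columns)
    while True:
        sub = corr.loc[keep, keep].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= threshold:
            break
        mean_i = sub[i].sum() / (len(keep) - 1)
        mean_j = sub[j].sum() / (len(keep) - 1)
        drop = keep[i] if mean_i >= mean_j else keep[j]
        removed.append(drop)
        keep.remove(drop)
    return CollinearityReport(correlation=corr, removed=removed, threshold=threshold)
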