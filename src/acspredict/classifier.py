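"""SVM biomarker-pattern scoring and the composite risk score.

The pattern classifier embeds each sample as the vector of log2
amplitudes of the panel peptides (undetected encoded as 0) and fits a
soft-margin support vector machine with a radial basis function kernel.
The classification score of a sample is its signed distance to the
separating hyperplane in feature space; positive scores lie on the
case side.  Shipped kernel defaults are C = 1638.4 and gamma =
0.000256, appropriate for raw (unstandardized) log2 intensities of a
~75-peptide panel; a stratified cross-validation lattice search is
provided for re-tuning.

The composite predictor combines the pattern score with an external
coronary-artery-disease pattern score and age through fixed linear
weights (default 0.2 / 2.6 / 0.15 with decision threshold 10.256);
weights can be re-derived by logistic regression on a training split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "DEFAULT_C",
    "DEFAULT_GAMMA",
    "CompositeWeights",
    "PatternModel",
    "feature_transform",
    "train_pattern",
    "tune_hyperparameters",
    "score_samples",
    "composite_score",
    "fit_composite_weights",
]

DEFAULT_C = 1638.4
DEFAULT_GAMMA = 0.000256


def feature_transform(matrix: pd.DataFrame, panel_ids,
                      undetected: str = "zero") -> pd.DataFrame:
    """log2-transform panel amplitudes into SVM coordinates.

    ``undetected="zero"`` (default) encodes amplitude 0 as feature 0 —
    note this collides with a detected amplitude of exactly 1;
    ``undetected="log1p"`` uses log2(amplitude + 1) instead, which is
    monotone and collision-free.
    """
    panel_ids = list(panel_ids)
    missing = [p for p in panel_ids if p not in matrix.columns]
    if missing:
        raise KeyError(f"panel peptides missing from matrix: {missing[:5]}")
    a = matrix[panel_ids].to_numpy(dtype=float)
    if undetected == "zero":
        feats = np.where(a > 0, np.log2(np.where(a > 0, a, 1.0)), 0.0)
    elif undetected == "log1p":
        feats = np.log2(a + 1.0)
    else:
        raise ValueError(f"unknown undetected encoding {undetected!r}")
    return pd.DataFrame(feats, index=matrix.index, columns=panel_ids)


@dataclass
class PatternModel:
    """Fitted RBF-SVM pattern with enough state to score new samples.

    The decision function is evaluated directly from the stored support
    vectors, so a serialized and reloaded model scores bit-identically.
    """

    panel_ids: list[str]
    C: float
    gamma: float
    seed: int
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    training_meta: dict = field(default_factory=dict)

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        d2 = ((x[:, None, :] - self.support_vectors[None, :, :]) ** 2
              ).sum(axis=2)
        k = np.exp(-self.gamma * d2)
        return k @ self.dual_coef + self.intercept

    def to_json(self) -> str:
        return json.dumps(
            {
                "panel_ids": self.panel_ids,
                "C": self.C,
                "gamma": self.gamma,
                "seed": self.seed,
                "support_vectors": self.support_vectors.tolist(),
                "dual_coef": self.dual_coef.tolist(),
                "intercept": self.intercept,
                "training_meta": self.training_meta,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PatternModel":
        d = json.loads(text)
        return cls(
            panel_ids=list(d["panel_ids"]),
            C=float(d["C"]),
            gamma=float(d["gamma"]),
            seed=int(d["seed"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            training_meta=dict(d.get("training_meta", {})),
        )


def train_pattern(features: pd.DataFrame, labels: pd.Series,
                  C: float = DEFAULT_C, gamma: float = DEFAULT_GAMMA,
                  seed: int = 0) -> PatternModel:
    """Fit the soft-margin RBF SVM (cases as the positive class).

    Training sensitivity and specificity at score threshold 0 are
    recorded in ``training_meta``.
    """
    y = labels.reindex(features.index).astype(int).to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    svc = SVC(C=C, gamma=gamma, kernel="rbf", random_state=seed)
    svc.fit(features.to_numpy(dtype=float), y)
    model = PatternModel(
        panel_ids=list(features.columns),
        C=float(C), gamma=float(gamma), seed=int(seed),
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
    )
    scores = model.decision_function(features.to_numpy(dtype=float))
    pred = scores > 0
    model.training_meta = {
        "n_train": int(y.size),
        "n_support": int(svc.support_vectors_.shape[0]),
        "train_sensitivity": float(pred[y == 1].mean()),
        "train_specificity": float((~pred[y == 0]).mean()),
    }
    return model


def tune_hyperparameters(features: pd.DataFrame, labels: pd.Series,
                         C_grid, gamma_grid, k_folds: int = 5,
                         seed: int = 0) -> tuple[float, float, pd.DataFrame]:
    """Stratified k-fold CV error over the (C, gamma) lattice.

    Returns ``(C, gamma, table)`` with the argmin of mean CV error;
    ties resolve to the smallest C, then the smallest gamma.  Folds
    whose training part degenerates to one class are skipped with a
    warning and the error averaged over the valid folds.
    """
    C_grid = sorted(float(c) for c in C_grid)
    gamma_grid = sorted(float(g) for g in gamma_grid)
    if k_folds < 2 or not C_grid or not gamma_grid:
        raise ValueError("need k_folds >= 2 and non-empty grids")
    X = features.to_numpy(dtype=float)
    y = labels.reindex(features.index).astype(int).to_numpy()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    rows = []
    for C in C_grid:
        for gamma in gamma_grid:
            errs = []
            for tr, te in folds:
                if np.unique(y[tr]).size < 2:
                    warnings.warn("skipping CV fold with a single class")
                    continue
                svc = SVC(C=C, gamma=gamma, kernel="rbf", random_state=seed)
                svc.fit(X[tr], y[tr])
                errs.append(float((svc.predict(X[te]) != y[te]).mean()))
            rows.append({"C": C, "gamma": gamma,
                         "cv_error": float(np.mean(errs)) if errs else np.nan,
                         "n_folds_used": len(errs)})
    table = pd.DataFrame(rows)
    best = table.sort_values(["cv_error", "C", "gamma"],
                             kind="stable").iloc[0]
    return float(best["C"]), float(best["gamma"]), table


def score_samples(model: PatternModel, features: pd.DataFrame) -> pd.Series:
    """Signed distance of each sample to the separating hyperplane."""
    if list(features.columns) != list(model.panel_ids):
        raise ValueError("feature columns do not match the model panel")
    scores = model.decision_function(features.to_numpy(dtype=float))
    return pd.Series(scores, index=features.index, name="score")


@dataclass(frozen=True)
class CompositeWeights:
    """Linear weights of the composite predictor and its threshold."""

    w_pattern: float = 0.2
    w_cad: float = 2.6
    w_age: float = 0.15
    threshold: float = 10.256
    pvalues: dict = field(default_factory=dict)
    warnings: tuple = ()


def composite_score(pattern_score, cad_score, age_years,
                    weights: CompositeWeights = CompositeWeights()):
    """w_pattern * pattern + w_cad * cad + w_age * age (vectorized)."""
    out = (weights.w_pattern * np.asarray(pattern_score, dtype=float)
           + weights.w_cad * np.asarray(cad_score, dtype=float)
           + weights.w_age * np.asarray(age_years, dtype=float))
    if not np.all(np.isfinite(out)):
        raise ValueError("composite score inputs must be finite")
    return out if np.ndim(out) else float(out)


def _ridge_logistic(X: np.ndarray, y: np.ndarray, alpha: float,
                    max_iter: int = 100, tol: float = 1e-10
                    ) -> tuple[np.ndarray, np.ndarray]:
    """L2-penalized logistic fit by Newton iterations (intercept free)."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = alpha * np.eye(p)
    pen[0, 0] = 0.0  # do not penalize the intercept
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu) - pen @ beta
        hess = (X.T * W) @ X + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    cov = np.linalg.inv((X.T * (mu * (1 - mu))) @ X + pen)
    return beta, np.sqrt(np.diag(cov))


def fit_composite_weights(pattern_scores, cad_scores, ages, labels,
                          threshold: float = 10.256,
                          ridge_alpha: float = 1e-4) -> CompositeWeights:
    """Logistic regression of case status on the three covariates.

    Coefficients (excluding the intercept) become the composite
    weights; per-covariate Wald p-values are attached.  Perfect
    separation triggers a flagged ridge refit instead of failing.
    """
    y = np.asarray(labels, dtype=float)
    X = np.column_stack([
        np.ones_like(y),
        np.asarray(pattern_scores, dtype=float),
        np.asarray(cad_scores, dtype=float),
        np.asarray(ages, dtype=float),
    ])
    if min((y == 1).sum(), (y == 0).sum()) < 10:
        raise ValueError("need at least 10 samples per class")
    warns: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, X).fit(disp=0, method="newton")
        params, bse = fit.params, fit.bse
        if not np.all(np.isfinite(bse)):
            raise np.linalg.LinAlgError("unstable standard errors")
    except Exception:
        warns.append("separation_or_nonconvergence: ridge refit "
                     f"(alpha={ridge_alpha})")
        params, bse = _ridge_logistic(X, y, ridge_alpha)
    from scipy.stats import norm
    z = params / bse
    p = 2 * norm.sf(np.abs(z))
    names = ("intercept", "pattern", "cad", "age")
    return CompositeWeights(
        w_pattern=float(params[1]), w_cad=float(params[2]),
        w_age=float(params[3]), threshold=threshold,
        pvalues=dict(zip(names, (float(v) for v in p))),
        warnings=tuple(warns),
    )
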