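"""Cis expression-prediction weight training.

A gene's expression is predicted from the standardized dosages of the SNPs in
its cis window by one of a small menu of linear models:

* ``top1`` — the single best marginal eQTL (its univariate coefficient at
  that SNP, zeros elsewhere);
* ``lasso`` — L1-penalized regression, penalty path chosen by inner CV;
* ``enet`` — elastic net with mixing fixed at 0.5;
* ``blup_ridge`` — ridge regression on all cis SNPs, serving as the BLUP
  model of the menu;
* ``marginal_impg`` — the closed-form marginal-covariance weights
  ``Σ_es · (Σ_ss + λI)⁻¹`` used for summary-based imputation.

Models compete by cross-validated R² (squared correlation of concatenated
held-out predictions with observed expression); ties break by the fixed
precedence lasso > enet > blup_ridge > top1.  A gene whose best model does
not clear a small usability floor is marked untestable.

The trainers are scikit-learn compatible estimators; the module-level
functions :func:`fit_model`, :func:`cross_validate`, :func:`select_model` and
:func:`marginal_impg_weights` are thin wrappers over them.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNetCV, LassoCV, RidgeCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .datatypes import MODEL_PRECEDENCE, GenotypePanel, WeightSet
from .errors import InputError, UntestableGeneError

logger = logging.getLogger(__name__)

#: Minimum cross-validated R² for a gene to be considered testable.
CV_R2_FLOOR = 0.01

#: Default LD ridge on the correlation scale for the marginal ImpG weights.
DEFAULT_IMPG_RIDGE = 0.1

_RIDGE_ALPHAS = np.logspace(-3, 3, 13)


def _standardize_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / safe
    Xs[:, sd == 0] = 0.0
    y_sd = y.std()
    if y_sd == 0:
        raise InputError("expression has zero variance")
    ys = (y - y.mean()) / y_sd
    return Xs, ys


class TopEqtlRegressor(RegressorMixin, BaseEstimator):
    """Prediction from the single best marginal eQTL.

    On standardized inputs the univariate OLS coefficient at SNP j is the
    sample correlation r_j; the fitted weight vector puts r_{j*} at the SNP
    with the largest |r| and zeros elsewhere.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        n = X.shape[0]
        r = X.T @ y / n
        j = int(np.argmax(np.abs(r)))
        coef = np.zeros(X.shape[1])
        coef[j] = r[j]
        self.coef_ = coef
        self.best_snp_ = j
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return check_array(X) @ self.coef_


class MarginalImpGRegressor(RegressorMixin, BaseEstimator):
    """Marginal-covariance imputation weights ``Σ_es · (Σ_ss + λI)⁻¹``.

    ``Σ_es`` is the SNP-expression covariance vector and ``Σ_ss`` the SNP
    correlation (LD) matrix, both estimated in-sample on standardized data.
    With ``ld_ridge=0`` on a full-rank locus this is exactly the multi-SNP
    ordinary least-squares fit.
    """

    def __init__(self, ld_ridge: float = DEFAULT_IMPG_RIDGE):
        self.ld_ridge = ld_ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        n, m = X.shape
        S = X.T @ X / n
        cov = X.T @ y / n
        lam = self.ld_ridge
        if lam == 0 and np.linalg.matrix_rank(S) < m:
            lam = 1e-6
            logger.warning(
                "singular LD with zero ridge; applying regularization floor %.0e", lam
            )
        try:
            coef = np.linalg.solve(S + lam * np.eye(m), cov)
        except np.linalg.LinAlgError:
            lam = max(lam, 1e-6)
            logger.warning("LD solve failed; retrying with ridge %.0e", lam)
            coef = np.linalg.solve(S + lam * np.eye(m), cov)
        self.coef_ = coef
        self.n_features_in_ = m
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return check_array(X) @ self.coef_


def _make_estimator(model: str, random_state: int | None, **hyper):
    cv = KFold(n_splits=hyper.pop("inner_folds", 5), shuffle=True, random_state=random_state)
    if model == "lasso":
        return LassoCV(cv=cv, alphas=hyper.pop("alphas", 50),
                       max_iter=hyper.pop("max_iter", 5000),
                       random_state=random_state, **hyper)
    if model == "enet":
        return ElasticNetCV(l1_ratio=hyper.pop("l1_ratio", 0.5), cv=cv,
                            alphas=hyper.pop("alphas", 50),
                            max_iter=hyper.pop("max_iter", 5000),
                            random_state=random_state, **hyper)
    if model == "blup_ridge":
        return RidgeCV(alphas=hyper.pop("alphas", _RIDGE_ALPHAS), **hyper)
    if model == "top1":
        return TopEqtlRegressor(**hyper)
    if model == "marginal_impg":
        return MarginalImpGRegressor(**hyper)
    raise InputError(f"unknown model {model!r}")


class CisWeightsRegressor(RegressorMixin, BaseEstimator):
    """Cross-validated cis expression predictor with model competition.

    Parameters
    ----------
    model
        One of the model labels, or ``"auto"`` to run the full competition
        (lasso, enet, blup_ridge, top1) and keep the best by CV R².
    n_folds
        Outer cross-validation folds for model scoring.
    cv_r2_floor
        Usability floor; with ``model="auto"`` a fit whose best CV R² is at
        or below the floor raises :class:`UntestableGeneError`.
    random_state
        Seeds fold assignment and any stochastic solver.

    Attributes
    ----------
    weights_ : ndarray
        Selected weight vector on the standardized-dosage scale.
    model_ : str
        Label of the selected model.
    cv_r2_ : float
        Cross-validated R² of the selected model.
    candidates_ : dict
        ``{label: (cv_r2, weights)}`` for every competitor fitted.
    """

    def __init__(
        self,
        model: str = "auto",
        n_folds: int = 5,
        cv_r2_floor: float = CV_R2_FLOOR,
        random_state: int | None = 0,
    ):
        self.model = model
        self.n_folds = n_folds
        self.cv_r2_floor = cv_r2_floor
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        Xs, ys = _standardize_xy(X, y)
        self.mean_ = np.asarray(X, float).mean(axis=0)
        sd = np.asarray(X, float).std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        models = MODEL_PRECEDENCE if self.model == "auto" else (self.model,)
        candidates = {}
        for label in models:
            w = fit_model(Xs, ys, label, random_state=self.random_state)
            r2 = cross_validate(Xs, ys, label, n_folds=self.n_folds,
                                random_state=self.random_state)
            candidates[label] = (r2, w)
        self.candidates_ = candidates
        if self.model == "auto":
            label, r2, w = select_model(
                [(lab, r2, w) for lab, (r2, w) in candidates.items()],
                floor=self.cv_r2_floor,
            )
        else:
            label = self.model
            r2, w = candidates[label]
        self.model_ = label
        self.cv_r2_ = r2
        self.weights_ = w
        self.coef_ = w
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X)
        return ((X - self.mean_) / self.scale_) @ self.weights_


def _as_matrix(panel_or_X) -> np.ndarray:
    if isinstance(panel_or_X, GenotypePanel):
        return panel_or_X.dosages
    return np.asarray(panel_or_X, dtype=float)


def fit_model(panel_or_X, expression, model: str, random_state: int | None = 0,
              **hyper) -> np.ndarray:
    """Fit one prediction model; returns weights on standardized dosages."""
    X = _as_matrix(panel_or_X)
    Xs, ys = _standardize_xy(X, expression)
    est = _make_estimator(model, random_state, **hyper)
    est.fit(Xs, ys)
    return np.asarray(est.coef_, dtype=float)


def cross_validate(panel_or_X, expression, model: str, n_folds: int = 5,
                   random_state: int | None = 0, **hyper) -> float:
    """Cross-validated R² of a model: squared correlation between
    concatenated held-out predictions and observed expression.

    Degenerate held-out predictions (zero variance) score 0.
    """
    X = _as_matrix(panel_or_X)
    y = np.asarray(expression, dtype=float)
    if n_folds < 2:
        raise InputError("n_folds must be >= 2")
    if X.shape[0] < n_folds:
        raise InputError(
            f"cannot run {n_folds}-fold CV with only {X.shape[0]} individuals"
        )
    Xs, ys = _standardize_xy(X, y)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    preds = np.empty_like(ys)
    for train, test in kf.split(Xs):
        est = _make_estimator(model, random_state, **hyper)
        est.fit(Xs[train], ys[train])
        preds[test] = est.predict(Xs[test])
    if preds.std() == 0 or ys.std() == 0:
        return 0.0
    return float(np.corrcoef(preds, ys)[0, 1] ** 2)


def select_model(
    candidates: Sequence[tuple[str, float, np.ndarray]],
    floor: float = CV_R2_FLOOR,
) -> tuple[str, float, np.ndarray]:
    """Pick the candidate with maximal CV R²; ties break by fixed precedence.

    Candidates with all-zero weights are unusable.  If no usable candidate
    clears the floor the gene is untestable.
    """
    if not candidates:
        raise InputError("select_model needs at least one candidate")
    rank = {label: i for i, label in enumerate(MODEL_PRECEDENCE)}
    usable = [
        (label, r2, w)
        for label, r2, w in candidates
        if np.any(np.asarray(w) != 0) and max(r2, 0.0) > floor
    ]
    if not usable:
        raise UntestableGeneError(
            f"no candidate model clears the cv_r2 floor {floor} with nonzero weights"
        )
    usable.sort(key=lambda c: (-c[1], rank.get(c[0], len(rank))))
    return usable[0]


def marginal_impg_weights(panel_or_X, expression,
                          ld_ridge: float = DEFAULT_IMPG_RIDGE) -> np.ndarray:
    """Closed-form marginal imputation weights ``Σ_es · (Σ_ss + λI)⁻¹``."""
    return fit_model(panel_or_X, expression, "marginal_impg", ld_ridge=ld_ridge)


def train_weight_set(
    panel: GenotypePanel,
    expression: np.ndarray,
    gene: str,
    tissue: str,
    model: str = "auto",
    n_folds: int = 5,
    random_state: int | None = 0,
    cv_r2_floor: float = CV_R2_FLOOR,
) -> WeightSet:
    """Train (optionally competing) models on a panel and package the winner.

    Raises :class:`UntestableGeneError` when ``model="auto"`` and no model
    clears the usability floor, or when a single requested model returns an
    all-zero weight vector.
    """
    if model == "marginal_impg":
        w = marginal_impg_weights(panel, expression)
        r2 = float("nan")
        label = model
    else:
        est = CisWeightsRegressor(model=model, n_folds=n_folds,
                                  cv_r2_floor=cv_r2_floor, random_state=random_state)
        est.fit(panel.dosages, expression)
        w, r2, label = est.weights_, est.cv_r2_, est.model_
    if not np.any(w != 0):
        raise UntestableGeneError(
            f"{gene}/{tissue}: model {label} produced an all-zero weight vector"
        )
    return WeightSet.from_panel(panel, w, gene=gene, tissue=tissue, model=label,
                                cv_r2=r2, n_folds=n_folds)
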