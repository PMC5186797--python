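"""The interaction-LASSO proliferation-rate predictor.

The predictor is trained in two stages. A first-order L1-penalized linear
model over all genes identifies the genes with clearly non-zero
coefficients; a second-order model is then trained on all pairwise products
(and squares) of the log2 expression values of those genes, again with an
L1 penalty and cross-validated regularization strength. Finally the
smallest non-zero coefficients (below the 25% quantile of the non-zero
absolute coefficients by default) are discarded and the model is refit on
the surviving interaction features.

Features are standardized internally for the penalty path (penalty-scale
invariance) and coefficients are reported back on the original feature
scale. Generalization is measured by leave-one-out cross-validation with a
five-metric suite (mse, rmse, mae, mre, R²).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold

from .matrix import LogExpressionMatrix

Feature = tuple[str, str]  # canonical gene pair; equal ids denote a square


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitMetrics:
    """The five-metric evaluation suite for a set of predictions."""

    mse: float
    rmse: float
    mae: float
    mre: float
    r_squared: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
            "mre": self.mre,
            "r_squared": self.r_squared,
        }


def compute_fit_metrics(predicted, observed) -> FitMetrics:
    """mse, rmse, mae, mre and R² of predictions against observations.

    ``mre`` averages ``|p−o|/|o|`` over observations with ``o ≠ 0``;
    ``R² = 1 − SS_res/SS_tot`` and may be negative under validation.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.shape != o.shape or p.size == 0:
        raise ValueError(f"length mismatch or empty input: {p.shape} vs {o.shape}")
    resid = p - o
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    nz = o != 0
    mre = float(np.mean(np.abs(resid[nz]) / np.abs(o[nz]))) if nz.any() else float("nan")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are all identical; R² is undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return FitMetrics(mse=mse, rmse=float(np.sqrt(mse)), mae=mae, mre=mre, r_squared=r2)


# ---------------------------------------------------------------------------
# L1 fits
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """A fitted (possibly L1-penalized) linear model.

    Coefficients are stored both on the original feature scale and on the
    internally standardized scale the penalty was applied on.
    """

    feature_names: tuple
    coefficients: np.ndarray
    standardized_coefficients: np.ndarray
    intercept: float
    lambda_: float

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients

    def nonzero_mask(self, tol: float = 0.0) -> np.ndarray:
        return np.abs(self.standardized_coefficients) > tol


def _as_design(X) -> tuple[np.ndarray, tuple]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    X = np.asarray(X, dtype=float)
    return X, tuple(range(X.shape[1]))


def fit_lasso_cv(
    X,
    y,
    seed: int,
    cv: int = 10,
    n_alphas: int = 100,
    lambda_: float | None = None,
    max_iter: int = 50000,
) -> LinearFit:
    """L1-penalized least squares with the penalty chosen by k-fold CV.

    The regularization strength minimizing the cross-validated MSE along an
    automatically generated path is selected unless ``lambda_`` is forced.
    ``lambda_ = 0`` falls back to ordinary least squares. Features are
    standardized internally; reported coefficients are on the original scale.
    """
    Xa, names = _as_design(X)
    ya = np.asarray(y, dtype=float).ravel()
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y have different numbers of samples")
    if not np.isfinite(Xa).all():
        raise ValueError("features contain NaN or infinite values")
    if not np.isfinite(ya).all():
        raise ValueError("targets contain NaN or infinite values")
    if np.ptp(ya) == 0:
        raise ValueError("constant target vector; nothing to fit")

    mu = Xa.mean(axis=0)
    sd = Xa.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (Xa - mu) / sd_safe

    if lambda_ is not None and lambda_ == 0:
        ols = LinearRegression().fit(Xs, ya)
        coef_s = np.asarray(ols.coef_, dtype=float)
        intercept_s = float(ols.intercept_)
        lam = 0.0
    elif lambda_ is not None:
        las = Lasso(alpha=lambda_, max_iter=max_iter).fit(Xs, ya)
        coef_s = np.asarray(las.coef_, dtype=float)
        intercept_s = float(las.intercept_)
        lam = float(lambda_)
    else:
        n = Xa.shape[0]
        folds = KFold(n_splits=min(cv, n), shuffle=True, random_state=seed)
        las = LassoCV(alphas=n_alphas, cv=folds, max_iter=max_iter).fit(Xs, ya)
        coef_s = np.asarray(las.coef_, dtype=float)
        intercept_s = float(las.intercept_)
        lam = float(las.alpha_)

    coef = coef_s / sd_safe
    intercept = intercept_s - float(np.dot(coef, mu))
    return LinearFit(
        feature_names=names,
        coefficients=coef,
        standardized_coefficients=coef_s,
        intercept=intercept,
        lambda_=lam,
    )


def select_nonzero_genes(first_order_fit: LinearFit, tol: float = 1e-8) -> list[str]:
    """Genes with clearly non-zero first-order coefficients, sorted.

    ``tol`` applies to the standardized-scale coefficients so that the notion
    of "clearly non-zero" does not depend on feature units.
    """
    for name in first_order_fit.feature_names:
        if isinstance(name, tuple):
            raise ValueError("select_nonzero_genes expects a first-order (single-gene) fit")
    mask = first_order_fit.nonzero_mask(tol)
    return sorted(str(n) for n, keep in zip(first_order_fit.feature_names, mask) if keep)


def build_interaction_features(gene_matrix, genes: Sequence[str]) -> pd.DataFrame:
    """Samples × features frame of pairwise products and squares.

    For ``k`` genes this emits exactly ``k(k−1)/2 + k`` columns: one per
    unordered gene pair (product of the two log2 values) followed by one
    square per gene, in canonical (sorted-gene) order. Column labels are
    ``(gene_a, gene_b)`` tuples with ``gene_a ≤ gene_b``.
    """
    if isinstance(gene_matrix, LogExpressionMatrix):
        frame = gene_matrix.samples_frame()
    else:
        frame = pd.DataFrame(gene_matrix)
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene in interaction gene list")
    missing = [g for g in genes if g not in frame.columns]
    if missing:
        raise KeyError(f"genes not present in the matrix: {missing[:5]}")
    ordered = sorted(genes)
    cols: dict[Feature, np.ndarray] = {}
    for a, b in combinations(ordered, 2):
        cols[(a, b)] = frame[a].to_numpy() * frame[b].to_numpy()
    for g in ordered:
        cols[(g, g)] = frame[g].to_numpy() ** 2
    out = pd.DataFrame(cols, index=frame.index)
    out.columns = pd.Index(list(cols.keys()), tupleize_cols=False)
    return out


def apply_coefficient_cutoff(
    fit: LinearFit,
    q: float,
    X,
    y,
    seed: int,
    cv: int = 10,
) -> LinearFit:
    """Drop the smallest non-zero coefficients and refit on the survivors.

    The threshold is the ``q``-quantile (linear interpolation) of the
    non-zero absolute standardized coefficients; features at or below it are
    dropped. The feature with the largest absolute coefficient is always
    retained so the model cannot be emptied. The L1 model is refit on the
    surviving feature columns (a plain truncation would leave the intercept
    and remaining coefficients at suboptimal values).
    """
    abs_c = np.abs(fit.standardized_coefficients)
    nz = abs_c > 0
    if not nz.any():
        raise ValueError("all coefficients are zero; nothing survives a cutoff")
    if q == 0:
        keep = nz.copy()  # q = 0 means no cutoff: every non-zero feature survives
    else:
        threshold = float(np.quantile(abs_c[nz], q))
        keep = abs_c > threshold
    keep[int(np.argmax(abs_c))] = True
    Xa, names = _as_design(X)
    if names != fit.feature_names:
        raise ValueError("feature matrix does not match the fitted feature names")
    kept_names = [n for n, k in zip(names, keep) if k]
    if isinstance(X, pd.DataFrame):
        X_kept = X.loc[:, [n in set(kept_names) for n in X.columns]]
    else:
        X_kept = Xa[:, keep]
    refit = fit_lasso_cv(X_kept, y, seed=seed, cv=cv)
    return refit


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class InteractionLassoRegressor(RegressorMixin, BaseEstimator):
    """Two-stage interaction-LASSO regressor for proliferation rates.

    Parameters
    ----------
    order : int, default 2
        1 fits a single L1 model on the gene columns; 2 adds the
        interaction stage (products and squares of the first-stage genes).
    cutoff_q : float or None, default 0.25
        Quantile of the non-zero absolute coefficients below which features
        are discarded before the final refit. ``None`` skips the cutoff.
    gene_tol : float, default 1e-8
        Threshold on standardized first-order coefficients for a gene to be
        carried into the interaction stage.
    cv : int, default 10
        Folds for the regularization-path cross-validation.
    random_state : int, default 0
        Seed for fold shuffling; makes fits reproducible.

    Attributes
    ----------
    genes_ : list of str
        Genes selected by the first-order stage (order 2) or all genes
        (order 1).
    features_ : tuple
        Feature labels of the final model (gene ids for order 1, canonical
        gene-pair tuples for order 2).
    coef_, intercept_, lambda_ : final-model parameters on the original
        feature scale.
    """

    def __init__(self, order: int = 2, cutoff_q: float | None = 0.25,
                 gene_tol: float = 1e-8, cv: int = 10, random_state: int = 0):
        self.order = order
        self.cutoff_q = cutoff_q
        self.gene_tol = gene_tol
        self.cv = cv
        self.random_state = random_state

    # -- internal helpers ----------------------------------------------------
    @staticmethod
    def _gene_frame(X) -> pd.DataFrame:
        if isinstance(X, LogExpressionMatrix):
            return X.samples_frame()
        return pd.DataFrame(X)

    def _design(self, frame: pd.DataFrame) -> pd.DataFrame:
        """The final-model design matrix for a samples × genes frame."""
        if self.order == 1:
            return frame.loc[:, list(self.features_)]
        return build_interaction_features(frame, self.genes_).loc[:, list(self.features_)]

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y) -> "InteractionLassoRegressor":
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        frame = self._gene_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if frame.shape[0] < 10:
            raise ValueError("at least 10 samples are required")
        seed = self.random_state
        self.first_order_fit_ = fit_lasso_cv(frame, y, seed=seed, cv=self.cv)
        if self.order == 1:
            self.genes_ = [str(g) for g in frame.columns]
            self.final_fit_ = self.first_order_fit_
        else:
            genes = select_nonzero_genes(self.first_order_fit_, tol=self.gene_tol)
            if not genes:
                raise ValueError("first-order stage selected no genes")
            self.genes_ = genes
            F = build_interaction_features(frame, genes)
            self.second_order_fit_ = fit_lasso_cv(F, y, seed=seed, cv=self.cv)
            if self.cutoff_q is not None:
                self.final_fit_ = apply_coefficient_cutoff(
                    self.second_order_fit_, self.cutoff_q, F, y, seed=seed, cv=self.cv
                )
            else:
                self.final_fit_ = self.second_order_fit_
        self.features_ = self.final_fit_.feature_names
        self.coef_ = self.final_fit_.coefficients
        self.intercept_ = self.final_fit_.intercept
        self.lambda_ = self.final_fit_.lambda_
        self.n_features_in_ = frame.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "final_fit_"):
            raise ValueError("estimator is not fitted")
        frame = self._gene_frame(X)
        missing = [g for g in self.genes_ if g not in frame.columns]
        if missing:
            raise KeyError(f"model genes missing from input: {missing[:10]}")
        return self.final_fit_.predict(self._design(frame).to_numpy(dtype=float))


def predict_rates(model: InteractionLassoRegressor, cohort_matrix: LogExpressionMatrix) -> pd.DataFrame:
    """Per-sample predicted proliferation rates for a cohort matrix.

    Negative predictions are returned as-is but flagged (column
    ``negative``); downstream flux analysis skips flagged samples, treating
    them as non-proliferating.
    """
    preds = model.predict(cohort_matrix)
    samples = cohort_matrix.sample_ids
    return pd.DataFrame({"rate": preds, "negative": preds < 0}, index=samples)


# ---------------------------------------------------------------------------
# leave-one-out evaluation
# ---------------------------------------------------------------------------

def loocv_evaluate(
    gene_matrix,
    targets,
    mode: str = "fixed_features",
    seed: int = 0,
    estimator: InteractionLassoRegressor | None = None,
) -> tuple[pd.Series, FitMetrics]:
    """Leave-one-out predictions and metrics for the configured pipeline.

    In ``fixed_features`` mode the feature set (selected genes, interaction
    features surviving the cutoff) and the regularization strength come from
    one full-data pass, and only the coefficients are refit per fold; this
    mirrors the usual reporting practice but leaks the held-out sample into
    feature selection. ``nested`` mode redoes the entire pipeline (gene
    selection, CV path, cutoff) inside every fold and is the honest but
    slower estimate.
    """
    if mode not in ("fixed_features", "nested"):
        raise ValueError(f"unknown LOOCV mode {mode!r}")
    if estimator is None:
        estimator = InteractionLassoRegressor(random_state=seed)
    frame = InteractionLassoRegressor._gene_frame(gene_matrix)
    y = np.asarray(targets, dtype=float).ravel()
    n = frame.shape[0]
    if n < 3:
        raise ValueError("LOOCV requires at least 3 samples")
    preds = np.empty(n)

    if mode == "fixed_features":
        est = clone(estimator).fit(frame, y)
        design = est._design(frame)
        lam = est.lambda_
        for i in range(n):
            idx = np.arange(n) != i
            fold_fit = fit_lasso_cv(design.iloc[idx], y[idx], seed=seed, lambda_=lam)
            preds[i] = fold_fit.predict(design.iloc[[i]].to_numpy(dtype=float))[0]
    else:
        for i in range(n):
            idx = np.arange(n) != i
            est = clone(estimator).fit(frame.iloc[idx], y[idx])
            preds[i] = est.predict(frame.iloc[[i]])[0]

    series = pd.Series(preds, index=frame.index, name="predicted")
    return series, compute_fit_metrics(preds, y)
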