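"""Calibration models: univariate curve, PCA exploration, PLSR, figures of merit.

The quantitative core is a single-response partial least squares regression
(NIPALS) on the scaled sample x channel matrix.  The latent-variable count is
chosen by a one-standard-error parsimony rule on the cross-validated RMSE,
with replicates of the same concentration level always held out together.
Figures of merit follow the multivariate-calibration conventions: SEP is the
SD of bias-corrected prediction residuals, sensitivity SEN is the reciprocal
norm of the regression vector, analytical sensitivity gamma is SEN over the
instrumental noise level, and LoD/LoQ are 3.3 and 10 times the
noise-to-analytical-sensitivity ratio (pseudounivariate form).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from .preprocess import Scaler, peak_height
from .types import CalibrationDataset, Spectrum

__all__ = [
    "UnivariateCalibration",
    "PCAResult",
    "PLSRModel",
    "FiguresOfMerit",
    "PredictionResult",
    "univariate_calibration",
    "pca",
    "plsr_fit",
    "figures_of_merit",
    "predict",
]


# ---------------------------------------------------------------------------
# univariate calibration (net band height vs concentration)
# ---------------------------------------------------------------------------


@dataclass
class UnivariateCalibration:
    slope: float  # intensity per uM
    intercept: float  # intensity
    r_squared: float
    band: float  # cm^-1
    level_stats: pd.DataFrame  # per-level mean, sd, n of the band height
    heights: np.ndarray  # per-sample band heights


def univariate_calibration(
    dataset: CalibrationDataset, band: float = 1559.0, halfwidth: float = 10.0
) -> UnivariateCalibration:
    """Ordinary least-squares line of net band height against concentration.

    Per-level mean and SD over replicates give the error bars of the
    classical one-band calibration curve.
    """
    levels = np.unique(dataset.y)
    if levels.size < 2:
        raise ValueError("univariate calibration needs >= 2 distinct levels")
    heights = np.array(
        [
            peak_height(Spectrum(dataset.axis, row), band, halfwidth)
            for row in dataset.X
        ]
    )
    fit = stats.linregress(dataset.y, heights)
    rows = []
    for lv in levels:
        h = heights[dataset.y == lv]
        rows.append(
            {
                "concentration_uM": lv,
                "mean_height": h.mean(),
                "sd_height": h.std(ddof=1) if h.size > 1 else 0.0,
                "n": h.size,
            }
        )
    return UnivariateCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        band=band,
        level_stats=pd.DataFrame(rows),
        heights=heights,
    )


# ---------------------------------------------------------------------------
# PCA exploration
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_samples, k)
    loadings: np.ndarray  # (k, n_channels)
    explained_variance_ratio: np.ndarray
    suggested_n_components: int
    cv_rmse: np.ndarray  # cross-validated reconstruction RMSE per k


def pca(dataset: CalibrationDataset, max_components: int = 10, n_splits: int = 5) -> PCAResult:
    """Mean-centered PCA with a cross-validated reconstruction-RMSE elbow.

    Rows are split venetian-blinds style; for each candidate k the PCA is
    refit on the training rows and held-out rows are projected and
    reconstructed.  The suggested component count is the first k whose
    marginal CV-RMSE improvement falls below 1% (or the minimum if none).
    """
    X = dataset.X
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    cap = min(n - 1, p)
    if max_components > cap:
        raise ValueError(f"max_components {max_components} exceeds min(rows-1, cols) = {cap}")
    model = _SKPCA(n_components=max_components, svd_solver="full")
    scores = model.fit_transform(X)
    folds = np.arange(n) % min(n_splits, n)
    cv_rmse = np.empty(max_components)
    for k in range(1, max_components + 1):
        sq = 0.0
        for f in np.unique(folds):
            tr, te = folds != f, folds == f
            if tr.sum() <= k:
                continue
            sub = _SKPCA(n_components=k, svd_solver="full").fit(X[tr])
            recon = sub.inverse_transform(sub.transform(X[te]))
            sq += ((X[te] - recon) ** 2).sum()
        cv_rmse[k - 1] = np.sqrt(sq / X.size)
    suggested = int(np.argmin(cv_rmse)) + 1
    for k in range(1, max_components):
        if cv_rmse[k - 1] <= 0 or (cv_rmse[k - 1] - cv_rmse[k]) / cv_rmse[k - 1] < 0.01:
            suggested = k
            break
    return PCAResult(
        scores=scores,
        loadings=model.components_,
        explained_variance_ratio=model.explained_variance_ratio_,
        suggested_n_components=suggested,
        cv_rmse=cv_rmse,
    )


# ---------------------------------------------------------------------------
# PLSR (single-response NIPALS)
# ---------------------------------------------------------------------------


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Single-response NIPALS on centered data.

    Returns weights W (p x A), loadings P (p x A), y-loadings q (A,) and the
    per-component training residuals of y.
    """
    X = Xc.copy()
    y = yc.copy()
    p = X.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    resid_ss = np.zeros(n_lv)
    for a in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:  # no covariance left; pad with the last state
            W[:, a:] = 0
            resid_ss[a:] = resid_ss[a - 1] if a > 0 else float(y @ y)
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            resid_ss[a:] = resid_ss[a - 1] if a > 0 else float(y @ y)
            break
        pa = X.T @ t / tt
        qa = float(y @ t) / tt
        X = X - np.outer(t, pa)
        y = y - t * qa
        W[:, a], P[:, a], q[a] = w, pa, qa
        resid_ss[a] = float(y @ y)
    return W, P, q, resid_ss


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    """b such that y_hat = Xc @ b using the first ``a`` components."""
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


def _venetian_folds(groups: np.ndarray, n_splits: int) -> np.ndarray:
    """Fold id per sample; groups are assigned round-robin in order of appearance."""
    _, first_idx = np.unique(groups, return_index=True)
    ordered = groups[np.sort(first_idx)]
    n_splits = min(n_splits, ordered.size)
    fold_of_group = {g: i % n_splits for i, g in enumerate(ordered)}
    return np.array([fold_of_group[g] for g in groups])


def _cv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    scaling: str,
    max_lv: int,
    n_splits: int = 5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Out-of-fold predictions per LV count.

    Returns (pred[(n, max_lv)], fold_rmse[(n_folds, max_lv)]).  Scaling and
    the NIPALS decomposition are refit inside every fold.
    """
    folds = _venetian_folds(groups, n_splits)
    uniq = np.unique(folds)
    n = X.shape[0]
    pred = np.full((n, max_lv), np.nan)
    fold_rmse = np.full((uniq.size, max_lv), np.nan)
    for fi, f in enumerate(uniq):
        tr, te = folds != f, folds == f
        a_cap = min(max_lv, tr.sum() - 1, X.shape[1])
        scaler = Scaler(scaling).fit(X[tr])
        Xt = scaler.transform(X[tr])
        xm, ym = Xt.mean(axis=0), y[tr].mean()
        W, P, q, _ = _nipals(Xt - xm, y[tr] - ym, a_cap)
        Xe = scaler.transform(X[te]) - xm
        for a in range(1, max_lv + 1):
            b = _regression_vector(W, P, q, min(a, a_cap))
            pred[te, a - 1] = ym + Xe @ b
            fold_rmse[fi, a - 1] = float(
                np.sqrt(np.mean((pred[te, a - 1] - y[te]) ** 2))
            )
    return pred, fold_rmse


@dataclass
class PLSRModel:
    """Fitted single-response PLSR with stored scaling and diagnostics."""

    axis: np.ndarray
    scaler: Scaler
    x_mean: np.ndarray  # mean of the scaled training matrix
    y_mean: float
    weights: np.ndarray  # W (p x A_max)
    loadings: np.ndarray  # P (p x A_max)
    y_loadings: np.ndarray  # q (A_max,)
    n_lv: int  # selected latent-variable count
    max_lv: int
    b: np.ndarray  # regression vector at n_lv, scaled-x space
    rmsec: np.ndarray  # per LV (1..max_lv)
    rmsecv: np.ndarray
    r2_cal: np.ndarray
    r2_cv: np.ndarray
    cv_predictions: np.ndarray  # out-of-fold predictions per LV
    y_train: np.ndarray

    @property
    def b_raw(self) -> np.ndarray:
        """Regression vector against raw intensities (uM per intensity unit).

        Defined for column-linear scalings; for row-wise nonlinear
        transforms the scaled-space vector is returned unchanged.
        """
        if self.scaler.is_column_linear and self.scaler.column_scale_ is not None:
            return self.b / self.scaler.column_scale_
        return self.b

    def regression_vector(self, n_lv: Optional[int] = None) -> np.ndarray:
        a = self.n_lv if n_lv is None else n_lv
        if not (1 <= a <= self.max_lv):
            raise ValueError(f"n_lv must lie in [1, {self.max_lv}]")
        return _regression_vector(self.weights, self.loadings, self.y_loadings, a)

    def _check_axis(self, X: np.ndarray, axis: Optional[np.ndarray]) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.axis.size:
            raise ValueError(
                f"expected {self.axis.size} channels, got {X.shape[1]}"
            )
        if axis is not None:
            axis = np.asarray(axis, dtype=float)
            if axis.shape != self.axis.shape:
                raise ValueError("axis length mismatch")
            if not np.array_equal(axis, self.axis):
                order = np.argsort(axis, kind="stable")
                if not np.array_equal(axis[order], self.axis):
                    raise ValueError("prediction axis does not match the training axis")
                X = X[:, order]
        return X

    def predict(self, X: np.ndarray, axis: Optional[np.ndarray] = None,
                n_lv: Optional[int] = None) -> np.ndarray:
        """Predicted concentrations (uM); negatives are NOT truncated."""
        X = self._check_axis(X, axis)
        b = self.b if n_lv is None else self.regression_vector(n_lv)
        Xs = self.scaler.transform(X) - self.x_mean
        return self.y_mean + Xs @ b


@dataclass
class PredictionResult:
    values: np.ndarray  # uM, reported as-is
    negative: np.ndarray  # flag per sample: prediction below zero


def predict(
    model: PLSRModel, new_X: np.ndarray, axis: Optional[np.ndarray] = None
) -> PredictionResult:
    """Apply a fitted model to new rows; negative predictions are flagged."""
    values = model.predict(new_X, axis=axis)
    return PredictionResult(values=values, negative=values < 0)


def plsr_fit(
    dataset: CalibrationDataset,
    scaling_method: str = "minmax",
    max_lv: int = 10,
    n_splits: int = 5,
    groups: Optional[np.ndarray] = None,
) -> PLSRModel:
    """Fit a single-response NIPALS PLSR with CV-based LV selection.

    Cross-validation uses venetian blinds over replicate groups (replicates
    of one concentration level share a fold).  The LV count is the smallest
    one whose RMSECV is within one standard error (over folds) of the global
    minimum.
    """
    X, y = dataset.X, dataset.y
    n, p = X.shape
    if n < 4:
        raise ValueError("PLSR needs at least 4 samples")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if np.allclose(y, y[0]):
        raise ValueError("y is constant; calibration undefined")
    if groups is None:
        groups = dataset.groups()
    eff_max = min(max_lv, n - 1, p)

    pred_cv, fold_rmse = _cv_predictions(X, y, groups, scaling_method, eff_max, n_splits)
    rmsecv = np.sqrt(np.mean((pred_cv - y[:, None]) ** 2, axis=0))
    best = int(np.argmin(rmsecv))
    fr = fold_rmse[:, best]
    fr = fr[np.isfinite(fr)]
    se = fr.std(ddof=1) / np.sqrt(fr.size) if fr.size > 1 else 0.0
    chosen = int(np.flatnonzero(rmsecv <= rmsecv[best] + se)[0]) + 1

    scaler = Scaler(scaling_method).fit(X)
    Xs = scaler.transform(X)
    x_mean, y_mean = Xs.mean(axis=0), float(y.mean())
    W, P, q, resid_ss = _nipals(Xs - x_mean, y - y_mean, eff_max)
    rmsec = np.sqrt(resid_ss / n)
    sstot = float(((y - y.mean()) ** 2).sum())
    r2_cal = 1.0 - resid_ss / sstot
    r2_cv = 1.0 - np.sum((pred_cv - y[:, None]) ** 2, axis=0) / sstot
    return PLSRModel(
        axis=dataset.axis.copy(),
        scaler=scaler,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=q,
        n_lv=chosen,
        max_lv=eff_max,
        b=_regression_vector(W, P, q, chosen),
        rmsec=rmsec,
        rmsecv=rmsecv,
        r2_cal=r2_cal,
        r2_cv=r2_cv,
        cv_predictions=pred_cv,
        y_train=y.copy(),
    )


# ---------------------------------------------------------------------------
# figures of merit
# ---------------------------------------------------------------------------


@dataclass
class FiguresOfMerit:
    """Multivariate calibration figures of merit (uM scale).

    ``sen`` is in intensity units per uM; ``gamma`` in uM^-1 and
    ``gamma_inverse`` in uM; the identity RMSEP^2 = bias^2 + SEP^2 (n-1)/n
    holds by construction.
    """

    rmsep: float
    bias: float
    sep: float
    sen: float
    gamma: float
    gamma_inverse: float
    lod: float
    loq: float
    r2_cal: float
    r2_cv: float
    r2_pred: float
    n_test: int
    sigma_blank: float  # SD of blank pseudo-concentration predictions, uM

    def as_table(self) -> pd.DataFrame:
        rows = [
            ("Accuracy", "RMSEP", self.rmsep, "uM"),
            ("Systematic error", "BIAS", self.bias, "uM"),
            ("Precision", "SEP", self.sep, "uM"),
            ("Sensitivity", "SEN", self.sen, "intensity/uM"),
            ("Analytical sensitivity", "gamma", self.gamma, "1/uM"),
            ("Inverse of analytical sensitivity", "gamma^-1", self.gamma_inverse, "uM"),
            ("LoD", "LoD", self.lod, "uM"),
            ("LoQ", "LoQ", self.loq, "uM"),
            ("Fitting", "R2 calibration", self.r2_cal, ""),
            ("Fitting", "R2 cross-validation", self.r2_cv, ""),
            ("Fitting", "R2 prediction", self.r2_pred, ""),
        ]
        return pd.DataFrame(rows, columns=["figure_of_merit", "parameter", "value", "unit"])


def figures_of_merit(
    model: PLSRModel,
    test_X: np.ndarray,
    test_y: np.ndarray,
    blank_replicates: np.ndarray,
) -> FiguresOfMerit:
    """Prediction accuracy, sensitivity and detection limits of a PLSR model.

    With residuals e = predicted - reference on the test set:
    RMSEP = sqrt(mean(e^2)); bias = mean(e); SEP = sqrt(sum((e-bias)^2)/(n-1)).
    Instrumental noise is estimated by projecting blank (0 uM) replicate
    spectra through the model: sigma_blank is the SD of the resulting
    pseudo-concentrations.  Then SEN = 1/||b||, gamma = 1/sigma_blank,
    LoD = 3.3 sigma_blank and LoQ = 10 sigma_blank (the pseudounivariate
    3.3 sigma_x ||b|| and 10 sigma_x ||b|| forms with
    sigma_x = sigma_blank/||b||).
    """
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    test_y = np.asarray(test_y, dtype=float)
    blank_replicates = np.atleast_2d(np.asarray(blank_replicates, dtype=float))
    if test_y.size < 3:
        raise ValueError("figures of merit need >= 3 test samples")
    if blank_replicates.shape[0] < 5:
        raise ValueError("need >= 5 blank replicate spectra for noise estimation")

    e = model.predict(test_X) - test_y
    n = e.size
    rmsep = float(np.sqrt(np.mean(e**2)))
    bias = float(np.mean(e))
    sep = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))

    blank_pred = model.predict(blank_replicates)
    sigma_blank = float(blank_pred.std(ddof=1))
    if sigma_blank == 0:
        raise ValueError("blank predictions have zero spread; LoD undefined")
    b_norm = float(np.linalg.norm(model.b_raw))
    sen = 1.0 / b_norm
    gamma = 1.0 / sigma_blank
    sstot = float(((test_y - test_y.mean()) ** 2).sum())
    r2_pred = 1.0 - float((e**2).sum()) / sstot if sstot > 0 else float("nan")
    return FiguresOfMerit(
        rmsep=rmsep,
        bias=bias,
        sep=sep,
        sen=sen,
        gamma=gamma,
        gamma_inverse=sigma_blank,
        lod=3.3 * sigma_blank,
        loq=10.0 * sigma_blank,
        r2_cal=float(model.r2_cal[model.n_lv - 1]),
        r2_cv=float(model.r2_cv[model.n_lv - 1]),
        r2_pred=r2_pred,
        n_test=n,
        sigma_blank=sigma_blank,
    )
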