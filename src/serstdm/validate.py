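"""Model-robustness procedures: leave-group-out PLSR and permutation testing.

Mirrors a clinical-validation workflow: the patient dataset is split into
small held-out groups (sizes 2-3) so that every sample is predicted exactly
once by a model that never saw it, and the calibration's apparent skill is
benchmarked against a permutation null in which concentrations are shuffled
and the entire pipeline (scaling, latent-variable selection,
cross-validation) is re-run per shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .calibrate import PLSRModel, _cv_predictions, plsr_fit
from .types import CalibrationDataset

__all__ = [
    "FoldPlan",
    "PermutationResult",
    "LeaveGroupOutResult",
    "make_fold_plan",
    "leave_group_out_plsr",
    "permutation_test",
    "overfitting_report",
]


@dataclass
class FoldPlan:
    """Disjoint held-out groups of size 2 or 3 covering every sample once."""

    groups: List[np.ndarray]
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        sizes = [len(g) for g in self.groups]
        if any(s not in (2, 3) for s in sizes):
            raise ValueError("every fold must hold out 2 or 3 samples")
        flat = np.concatenate(self.groups) if self.groups else np.array([], dtype=int)
        if sorted(flat.tolist()) != list(range(self.n_samples)):
            raise ValueError("folds must partition 0..n_samples-1 exactly")

    @property
    def n_folds(self) -> int:
        return len(self.groups)


def make_fold_plan(n_samples: int, n_folds: int, seed: int = 0) -> FoldPlan:
    """Random partition of ``n_samples`` indices into groups of size 2 or 3.

    Feasible only when 2*n_folds <= n_samples <= 3*n_folds; for 27 samples
    in 12 folds this yields nine groups of 2 and three groups of 3.
    """
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if not (2 * n_folds <= n_samples <= 3 * n_folds):
        raise ValueError(
            f"cannot split {n_samples} samples into {n_folds} groups of size 2 or 3"
        )
    n_three = n_samples - 2 * n_folds
    sizes = np.array([3] * n_three + [2] * (n_folds - n_three))
    rng = np.random.default_rng(seed)
    rng.shuffle(sizes)
    idx = rng.permutation(n_samples)
    groups, start = [], 0
    for s in sizes:
        groups.append(np.sort(idx[start : start + s]))
        start += s
    return FoldPlan(groups=groups, n_samples=n_samples, seed=seed)


@dataclass
class LeaveGroupOutResult:
    predictions: np.ndarray  # out-of-fold prediction per sample, uM
    fold_of_sample: np.ndarray
    models: List[PLSRModel]
    r2_pred: float  # pooled over all out-of-fold predictions
    rmsep: float


def leave_group_out_plsr(
    dataset: CalibrationDataset,
    fold_plan: FoldPlan,
    scaling_method: str = "minmax",
    max_lv: int = 10,
    n_splits: int = 5,
) -> LeaveGroupOutResult:
    """Iterated PLSR: each fold's samples are predicted by a model fit on the rest.

    The latent-variable count is re-selected inside every fold (no
    information from the held-out samples leaks into model selection).
    Pooled R2 and RMSEP are computed on the aggregated out-of-fold
    predictions.
    """
    n = dataset.n_samples
    if fold_plan.n_samples != n:
        raise ValueError("fold plan does not match the dataset size")
    y = dataset.y
    groups_all = dataset.groups()
    pred = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    models: List[PLSRModel] = []
    for fi, held in enumerate(fold_plan.groups):
        if np.any(held >= n) or np.any(held < 0):
            raise ValueError("fold plan index out of range")
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        sub = CalibrationDataset(
            X=dataset.X[mask],
            y=y[mask],
            axis=dataset.axis,
            metadata=dataset.metadata.iloc[mask].reset_index(drop=True)
            if dataset.metadata is not None
            else None,
        )
        model = plsr_fit(
            sub,
            scaling_method=scaling_method,
            max_lv=max_lv,
            n_splits=n_splits,
            groups=groups_all[mask],
        )
        pred[held] = model.predict(dataset.X[held])
        fold_of[held] = fi
        models.append(model)
    resid = pred - y
    rmsep = float(np.sqrt(np.mean(resid**2)))
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sstot
    return LeaveGroupOutResult(
        predictions=pred, fold_of_sample=fold_of, models=models, r2_pred=r2, rmsep=rmsep
    )


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray  # statistic under B label shuffles
    p_value: float
    statistic: str
    n_permutations: int


def _cv_statistic(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    scaling: str,
    max_lv: int,
    n_splits: int,
    statistic: str,
) -> float:
    """Cross-validated R2 or RMSECV at the one-SE-selected LV count."""
    eff_max = min(max_lv, X.shape[0] - 1, X.shape[1])
    pred, fold_rmse = _cv_predictions(X, y, groups, scaling, eff_max, n_splits)
    rmsecv = np.sqrt(np.mean((pred - y[:, None]) ** 2, axis=0))
    best = int(np.argmin(rmsecv))
    fr = fold_rmse[:, best]
    fr = fr[np.isfinite(fr)]
    se = fr.std(ddof=1) / np.sqrt(fr.size) if fr.size > 1 else 0.0
    chosen = int(np.flatnonzero(rmsecv <= rmsecv[best] + se)[0])
    if statistic == "rmsecv":
        return float(rmsecv[chosen])
    sstot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(((pred[:, chosen] - y) ** 2).sum()) / sstot


def permutation_test(
    dataset: CalibrationDataset,
    B: int = 999,
    statistic: str = "r2_cv",
    seed: int = 0,
    scaling_method: str = "minmax",
    max_lv: int = 10,
    n_splits: int = 5,
) -> PermutationResult:
    """Permutation test of the calibration's cross-validated skill.

    Concentrations are shuffled B times; the full pipeline (scaling, LV
    selection, CV) is re-run per shuffle.  For R2 the empirical p-value is
    (1 + #{null >= observed}) / (B + 1); for RMSECV the comparison is <=.
    The observed statistic always counts in its own comparison, so
    p >= 1/(B+1).
    """
    if statistic not in ("r2_cv", "rmsecv"):
        raise ValueError("statistic must be 'r2_cv' or 'rmsecv'")
    if B < 99:
        raise ValueError("B must be >= 99")
    X, y = dataset.X, dataset.y
    groups = dataset.groups()
    observed = _cv_statistic(X, y, groups, scaling_method, max_lv, n_splits, statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        yp = rng.permutation(y)
        null[b] = _cv_statistic(X, yp, groups, scaling_method, max_lv, n_splits, statistic)
    if statistic == "rmsecv":
        count = int(np.sum(null <= observed))
    else:
        count = int(np.sum(null >= observed))
    p = (1 + count) / (B + 1)
    return PermutationResult(
        observed=observed, null=null, p_value=p, statistic=statistic, n_permutations=B
    )


def overfitting_report(
    model: PLSRModel,
    test_X: Optional[np.ndarray] = None,
    test_y: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-LV table of RMSEC, RMSECV (and RMSEP when a test set is given).

    Flags LV counts where the cross-validated error rises while the
    calibration error keeps falling -- the classical overfitting signature.
    """
    rows = []
    for a in range(1, model.max_lv + 1):
        row = {
            "n_lv": a,
            "rmsec_uM": model.rmsec[a - 1],
            "rmsecv_uM": model.rmsecv[a - 1],
            "r2_cal": model.r2_cal[a - 1],
            "r2_cv": model.r2_cv[a - 1],
            "selected": a == model.n_lv,
        }
        if test_X is not None and test_y is not None:
            e = model.predict(test_X, n_lv=a) - np.asarray(test_y, dtype=float)
            row["rmsep_uM"] = float(np.sqrt(np.mean(e**2)))
            sstot = float(((test_y - np.mean(test_y)) ** 2).sum())
            row["r2_pred"] = 1.0 - float((e**2).sum()) / sstot if sstot > 0 else np.nan
        rows.append(row)
    report = pd.DataFrame(rows)
    overfit = np.zeros(len(report), dtype=bool)
    for a in range(1, len(report)):
        overfit[a] = (
            report.loc[a, "rmsecv_uM"] > report.loc[a - 1, "rmsecv_uM"]
            and report.loc[a, "rmsec_uM"] < report.loc[a - 1, "rmsec_uM"]
        )
    report["overfit_flag"] = overfit
    return report
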