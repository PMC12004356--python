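"""Method-comparison statistics: Bland-Altman agreement and scatter regression.

Compares a test method (SERS + PLSR predictions) against a reference method
(HPLC) on paired concentration series.  Differences are taken test -
reference throughout; the bias is their mean, the 95% limits of agreement
are bias +/- 1.96 SD, and the minimal detectable change (MDC) is 1.96 SD of
the paired differences -- the half-width of the limits-of-agreement interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AgreementReport",
    "ScatterRegression",
    "bland_altman",
    "mdc_from_loa",
    "micromolar_to_mg_per_l",
    "method_scatter",
    "MEROPENEM_MOLAR_MASS",
]

#: Meropenem (free acid) molar mass, g/mol.
MEROPENEM_MOLAR_MASS = 383.46

#: 95% two-sided normal quantile used for limits of agreement and MDC.
Z_95 = 1.96


def micromolar_to_mg_per_l(c: float, molar_mass: float = MEROPENEM_MOLAR_MASS) -> float:
    """Convert a concentration from uM to mg/L: c * M / 1000."""
    if np.any(np.asarray(c) < 0):
        raise ValueError("concentration must be non-negative")
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return c * molar_mass / 1000.0


def mdc_from_loa(ula: float, lla: float) -> float:
    """Minimal detectable change as the half-width of the agreement interval."""
    if ula < lla:
        raise ValueError("upper limit of agreement must be >= lower limit")
    return (ula - lla) / 2.0


@dataclass
class ScatterRegression:
    """OLS of test on reference with a mean-response 95% confidence band."""

    slope: float
    intercept: float
    r_squared: float
    slope_p_value: float  # two-sided test of slope = 0
    band_x: np.ndarray  # sorted reference values
    band_lower: np.ndarray  # 95% CI of the mean response at band_x
    band_upper: np.ndarray
    n_pairs: int


def method_scatter(reference: np.ndarray, test: np.ndarray) -> ScatterRegression:
    """Ordinary least squares of test (uM) on reference (uM)."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape or reference.ndim != 1:
        raise ValueError("reference and test must be 1-D and paired")
    if reference.size < 3:
        raise ValueError("scatter regression needs >= 3 pairs")
    if np.allclose(reference, reference[0]):
        raise ValueError("reference series has zero variance")
    X = sm.add_constant(reference)
    fit = sm.OLS(test, X).fit()
    order = np.argsort(reference, kind="stable")
    ci = fit.get_prediction(X[order]).conf_int(alpha=0.05)
    return ScatterRegression(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_p_value=float(fit.pvalues[1]),
        band_x=reference[order],
        band_lower=ci[:, 0],
        band_upper=ci[:, 1],
        n_pairs=reference.size,
    )


@dataclass
class AgreementReport:
    """Bland-Altman agreement between a test and a reference method (uM)."""

    bias: float  # mean of test - reference
    sd_diff: float  # sample SD (n-1) of the differences
    ula: float  # bias + z * sd_diff
    lla: float  # bias - z * sd_diff
    mdc: float  # z * sd_diff, uM
    mdc_mg_per_l: float
    z: float
    n_pairs: int
    outliers: np.ndarray  # indices of pairs outside [lla, ula]
    means: np.ndarray  # (test + reference) / 2, for the agreement plot
    differences: np.ndarray
    regression: Optional[ScatterRegression] = None

    def as_table(self) -> pd.DataFrame:
        rows = [
            ("bias", self.bias, "uM"),
            ("sd_diff", self.sd_diff, "uM"),
            ("ULA", self.ula, "uM"),
            ("LLA", self.lla, "uM"),
            ("MDC", self.mdc, "uM"),
            ("MDC", self.mdc_mg_per_l, "mg/L"),
            ("n_pairs", self.n_pairs, ""),
            ("n_outliers", len(self.outliers), ""),
        ]
        if self.regression is not None:
            rows += [
                ("regression_slope", self.regression.slope, ""),
                ("regression_intercept", self.regression.intercept, "uM"),
                ("regression_R2", self.regression.r_squared, ""),
                ("regression_slope_p", self.regression.slope_p_value, ""),
            ]
        return pd.DataFrame(rows, columns=["quantity", "value", "unit"])


def bland_altman(
    reference: np.ndarray,
    test: np.ndarray,
    z: float = Z_95,
    with_regression: bool = True,
) -> AgreementReport:
    """Bland-Altman analysis of paired test vs reference concentrations.

    d = test - reference; bias = mean(d); sd_diff = SD(d, n-1);
    ULA/LLA = bias +/- z * sd_diff; MDC = z * sd_diff.  The identities
    MDC = (ULA - LLA)/2 and bias = (ULA + LLA)/2 hold exactly.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("reference and test series must have equal length")
    n = reference.size
    if n < 3:
        raise ValueError("Bland-Altman needs >= 3 pairs")
    d = test - reference
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    ula, lla = bias + z * sd, bias - z * sd
    mdc = z * sd
    outliers = np.flatnonzero((d > ula) | (d < lla))
    regression = method_scatter(reference, test) if with_regression else None
    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        ula=ula,
        lla=lla,
        mdc=mdc,
        mdc_mg_per_l=micromolar_to_mg_per_l(mdc),
        z=z,
        n_pairs=n,
        outliers=outliers,
        means=(test + reference) / 2.0,
        differences=d,
        regression=regression,
    )
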