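"""Shape–haemodynamics association statistics.

The statistical stage of the study: Pearson correlations between shape
descriptors (PC weights, coarctation and arch indices) and haemodynamic /
cardiac variables, multivariable linear regression to test independence of
associated covariates, logistic regression of the subjective gothic-arch
label on shape weights, and a normality screen that log-transforms skewed
variables before analysis.

No multiple-testing adjustment is applied, deliberately: with 84 univariable
cells the aim is not to reject true associations, at the cost of a higher
false-discovery risk — which is why the in-silico stage exists as an
independent corroboration.  The correlation table's metadata records this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "pearson",
    "ols_multi",
    "logistic",
    "log_transform_if_nonnormal",
    "table1",
    "SHAPE_ROWS",
    "HEMO_COLS",
]


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the t distribution (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class OLSResult:
    coefficients: np.ndarray     # intercept first
    r_squared: float
    p_overall: float             # F-test
    p_coefficients: np.ndarray   # Wald t per coefficient (intercept first)


def ols_multi(x: np.ndarray, y: np.ndarray) -> OLSResult:
    """Multivariable least squares with intercept; errors on rank deficiency."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.size:
        x = x.T
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < p:
        # name the offending columns via the QR diagonal
        _, rdiag = np.linalg.qr(x - x.mean(axis=0))
        bad = [str(j) for j in range(p)
               if abs(rdiag[j, j]) < 1e-10 * max(1.0, abs(rdiag[0, 0]))]
        raise ValueError(f"collinear covariate columns: {', '.join(bad)}")
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    return OLSResult(
        coefficients=np.asarray(fit.params),
        r_squared=float(fit.rsquared),
        p_overall=float(fit.f_pvalue),
        p_coefficients=np.asarray(fit.pvalues),
    )


@dataclass
class LogisticResult:
    coefficients: np.ndarray     # intercept first
    p_values: np.ndarray         # Wald z per coefficient
    converged: bool


def logistic(y: np.ndarray, x: np.ndarray) -> LogisticResult:
    """Maximum-likelihood logistic regression (IRLS via statsmodels Logit).

    Perfect separation is reported as a warning with ``converged=False``
    rather than an exception, mirroring how a statistical package would
    flag an unstable fit.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.size:
        x = x.T
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=False, maxiter=200, tol=1e-8)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:  # perfect separation raises in statsmodels
        warnings.warn("logistic fit did not converge (possible perfect "
                      "separation)", stacklevel=2)
        return LogisticResult(np.full(x.shape[1] + 1, np.nan),
                              np.full(x.shape[1] + 1, np.nan), False)
    if not converged:
        warnings.warn("logistic fit did not converge", stacklevel=2)
    return LogisticResult(np.asarray(fit.params), np.asarray(fit.pvalues),
                          converged)


def log_transform_if_nonnormal(column: np.ndarray, test_alpha: float = 0.05,
                               ) -> tuple[np.ndarray, bool]:
    """Natural-log transform when a Shapiro–Wilk test rejects normality.

    Only strictly positive columns are transformed; a non-positive,
    non-normal column is left untouched with a warning (the flag stays
    False so downstream output does not mark it as transformed).
    """
    col = np.asarray(column, dtype=float)
    _, p = stats.shapiro(col)
    if p >= test_alpha:
        return col, False
    if np.any(col <= 0):
        warnings.warn("non-normal column contains non-positive values; "
                      "left untransformed", stacklevel=2)
        return col, False
    return np.log(col), True


SHAPE_ROWS = [f"pc_curvature_{i}" for i in range(1, 6)] + \
    [f"pc_radius_{i}" for i in range(1, 6)] + \
    ["coarctation_index", "arch_index"]
HEMO_COLS = ["c_sbp", "p_sbp", "taci", "bcw_area", "fcw_area", "lvmi", "lvef"]


def table1(cohort: pd.DataFrame, test_alpha: float = 0.05,
           sig_level: float = 0.05) -> pd.DataFrame:
    """Univariable correlation table: shape variables × haemodynamic variables.

    Rows are the 5 curvature PCs, 5 radius PCs and the two geometry indices;
    columns hold (r, p) pairs for each haemodynamic variable.  Shape weights
    and haemodynamic variables are screened for normality and log-transformed
    (natural log, positive columns only) when rejected.  ``attrs`` records
    transformed columns, the significance threshold, and that no multiplicity
    adjustment was applied.
    """
    missing = [c for c in SHAPE_ROWS + HEMO_COLS if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table is missing columns: {missing}")
    if cohort[SHAPE_ROWS + HEMO_COLS].isna().any().any():
        raise ValueError("cohort table contains missing values")

    transformed: list[str] = []
    data = {}
    for col in SHAPE_ROWS + HEMO_COLS:
        raw = cohort[col].to_numpy(dtype=float)
        if np.all(raw > 0):
            vals, flag = log_transform_if_nonnormal(raw, test_alpha)
        else:  # zero-mean scores are outside the log model's domain
            vals, flag = raw, False
        data[col] = vals
        if flag:
            transformed.append(col)

    out = pd.DataFrame(index=SHAPE_ROWS)
    for hemo in HEMO_COLS:
        rs, ps = [], []
        for row in SHAPE_ROWS:
            r, p = pearson(data[row], data[hemo])
            rs.append(r)
            ps.append(p)
        out[f"{hemo}_r"] = rs
        out[f"{hemo}_p"] = ps
    out.attrs["log_transformed"] = transformed
    out.attrs["significance_level"] = sig_level
    out.attrs["multiple_testing_adjustment"] = "none"
    return out
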