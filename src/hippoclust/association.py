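"""Age/sex-adjusted Spearman association matrices.

Each variable is first residualized on age and sex by ordinary least
squares, then the residuals are rank-correlated (Spearman, mid-ranks for
ties, p-values from the t approximation). Significance is reported at the
unadjusted p < 0.05 threshold; no multiple-testing correction is applied
to the matrix — a deliberate faithful-reproduction choice (the matrix is
descriptive, not confirmatory).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hippoclust.errors import UndefinedTestError


@dataclass
class AssociationMatrix:
    """Symmetric Spearman rho matrix with matching p-values."""

    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    adjusted: bool

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        out = self.p < alpha
        np.fill_diagonal(out.values, False)
        return out


def residualize(values: np.ndarray, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` on [intercept, age, sex].

    Sex is coded numerically (female = 1 by upstream convention); the
    residuals are invariant to a coding swap. A covariate that is constant
    (collinear with the intercept) is dropped with a warning; any other
    rank deficiency is an error.
    """
    y = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    n = len(y)
    if not (len(age) == len(sex) == n):
        raise ValueError("values, age and sex must have equal length")
    if n < 4:
        raise ValueError(f"residualization needs n >= 4, got {n}")
    if np.isnan(y).any() or np.isnan(age).any() or np.isnan(sex).any():
        raise ValueError("missing values: residualization is complete-case only")

    cols = [np.ones(n)]
    for name, cov in (("age", age), ("sex", sex)):
        if np.ptp(cov) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped from design", stacklevel=2)
        else:
            cols.append(cov)
    design = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient covariate design (age/sex collinear)")
    return y - design @ beta


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman correlation with mid-rank ties and t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 5:
        raise ValueError(f"spearman_rho needs n >= 5, got {len(x)}")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise UndefinedTestError("zero rank variance: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def association_matrix(
    cohort_features: pd.DataFrame,
    adjust: bool = True,
    age_col: str = "age",
    sex_col: str = "sex",
) -> AssociationMatrix:
    """Pairwise Spearman matrix over all feature columns.

    With ``adjust=True``, every column is first residualized on age and
    sex. ``sex`` may be categorical ({'female', 'male'}) and is coded
    female = 1. Missing values are an error: complete-case filtering is an
    upstream responsibility.
    """
    covs = {age_col, sex_col}
    feature_cols = [c for c in cohort_features.columns if c not in covs]
    block = cohort_features[feature_cols].astype(float)
    if block.isna().any().any():
        bad = block.columns[block.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}: complete-case input required")

    if adjust:
        if age_col not in cohort_features or sex_col not in cohort_features:
            raise ValueError(f"adjust=True requires {age_col!r} and {sex_col!r} columns")
        sex_raw = cohort_features[sex_col]
        sex = (
            (sex_raw == "female").astype(float).to_numpy()
            if sex_raw.dtype == object
            else sex_raw.astype(float).to_numpy()
        )
        age = cohort_features[age_col].astype(float).to_numpy()
        block = block.apply(lambda col: residualize(col.to_numpy(), age, sex))

    k = len(feature_cols)
    rho = np.eye(k)
    p = np.zeros((k, k))
    values = block.to_numpy()
    for i in range(k):
        for j in range(i + 1, k):
            r, pv = spearman_rho(values[:, i], values[:, j])
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    return AssociationMatrix(
        variables=feature_cols,
        rho=pd.DataFrame(rho, index=feature_cols, columns=feature_cols),
        p=pd.DataFrame(p, index=feature_cols, columns=feature_cols),
        adjusted=adjust,
    )
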