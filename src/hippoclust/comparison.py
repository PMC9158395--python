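"""Cluster comparison with normality-gated test selection.

Continuous variables are routed by a Shapiro-Wilk gate on pooled
within-cluster residuals: normal-looking variables get Welch's
unequal-variance t test, the rest Mann-Whitney U (exact enumeration when
the smaller group has <= 8 observations and no ties, otherwise the normal
approximation with continuity correction). Categorical variables use
Pearson chi-square (Yates-corrected for 2x2) with a Fisher-exact fallback
for sparse 2x2 tables. Significance is reported per variable at p < 0.05
with no multiple-testing correction (faithful-reproduction default); a
Benjamini-Hochberg column can be added on request.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from hippoclust.connectivity import CONNECTIVITY_FEATURES
from hippoclust.errors import JoinError, UndefinedTestError

log = logging.getLogger(__name__)

CONTINUOUS_VARS = (
    "age",
    "BMI",
    "WC",
    "SSPG",
    "FPI",
    "FPG",
    "leptin",
    "cortisol",
    "IQ",
    "memory_pairing",
    "memory_recall",
    "motion_mean_mm",
    "motion_max_mm",
)
CATEGORICAL_VARS = ("sex", "ethnicity")


def normality_gate(values: np.ndarray, groups: np.ndarray | None = None, alpha: float = 0.05) -> str:
    """'normal' or 'nonnormal' by Shapiro-Wilk on within-group residuals.

    Residuals pool each group around its own mean so a pure location shift
    between clusters does not trigger the gate. Degenerate or tiny samples
    default to 'nonnormal' with a warning.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 8:
        log.warning("normality gate: n=%d < 8, defaulting to nonnormal", len(values))
        return "nonnormal"
    if np.ptp(values) == 0:
        log.warning("normality gate: constant variable, defaulting to nonnormal")
        return "nonnormal"
    if groups is None:
        resid = values - values.mean()
    else:
        groups = np.asarray(groups)
        resid = np.concatenate(
            [values[groups == g] - values[groups == g].mean() for g in np.unique(groups)]
        )
    _, p = stats.shapiro(resid)
    return "normal" if p >= alpha else "nonnormal"


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t test (two-sided)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("welch_t needs group sizes >= 3")
    if np.ptp(np.concatenate([x, y])) == 0:
        raise UndefinedTestError("all observations tied: t test undefined")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U, exact for small tie-free samples, else asymptotic.

    Exact enumeration (scipy 'exact' method) is used when the smaller
    group has <= 8 observations and there are no ties; otherwise the
    normal approximation with continuity correction.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("mann_whitney needs group sizes >= 3")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise UndefinedTestError("all observations tied: Mann-Whitney undefined")
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square(table: np.ndarray) -> tuple[str, float, float]:
    """Association test for an r-x-c count table.

    2x2 tables use Yates continuity correction, larger tables plain
    Pearson chi-square. Sparse 2x2 tables (any expected count < 5) fall
    back to Fisher's exact test; larger sparse tables stay chi-square with
    a warning.
    Returns (test_name, statistic, p).
    """
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        raise UndefinedTestError("empty contingency table")
    # drop all-zero rows/columns (unobserved category levels)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise UndefinedTestError("contingency table degenerate after dropping empty levels")
    expected = stats.contingency.expected_freq(table)
    if table.shape == (2, 2):
        if (expected < 5).any():
            odds, p = stats.fisher_exact(table)
            return "Fisher exact", float(odds), float(p)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        return "chi-square", float(chi2), float(p)
    if (expected < 5).any():
        log.warning("sparse contingency table (%s); chi-square approximation may be poor",
                    table.shape)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi-square", float(chi2), float(p)


def _compare_continuous(x: np.ndarray, y: np.ndarray) -> tuple[str, float, float, str]:
    gate = normality_gate(np.concatenate([x, y]), np.r_[np.zeros(len(x)), np.ones(len(y))])
    if gate == "normal":
        t, p = welch_t(x, y)
        return "Welch t", t, p, gate
    u, p = mann_whitney(x, y)
    return "Mann-Whitney U", u, p, gate


def compare_clusters(
    cohort: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    connectivity: pd.DataFrame | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Publication-style comparison of cluster 1 vs cluster 2.

    ``cohort`` must be the complete-case table; ``labels`` (1/2) must
    align with it by position or by a shared ``subject_id`` index.
    ``connectivity`` optionally appends the 18 connectivity features.
    ``adjust='bh'`` adds a Benjamini-Hochberg adjusted-p column.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise JoinError(f"{len(labels)} labels for {len(cohort)} subjects")
    if set(np.unique(labels)) != {1, 2}:
        raise JoinError(f"expected labels {{1, 2}}, got {sorted(set(labels))}")

    data = cohort.reset_index(drop=True)
    if connectivity is not None:
        conn = connectivity.reset_index(drop=True)
        if len(conn) != len(data):
            raise JoinError("connectivity table does not align with cohort")
        data = pd.concat([data, conn], axis=1)

    in1, in2 = labels == 1, labels == 2
    rows = []
    continuous = [v for v in CONTINUOUS_VARS if v in data.columns]
    continuous += [v for v in CONNECTIVITY_FEATURES if v in data.columns]
    for var in continuous:
        x = data.loc[in1, var].to_numpy(dtype=float)
        y = data.loc[in2, var].to_numpy(dtype=float)
        test, statistic, p, gate = _compare_continuous(x, y)
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                "cluster1": f"{x.mean():.2f} ({x.std(ddof=1):.2f})",
                "cluster2": f"{y.mean():.2f} ({y.std(ddof=1):.2f})",
                "cluster1_mean": x.mean(),
                "cluster2_mean": y.mean(),
                "normality": gate,
                "test": test,
                "statistic": statistic,
                "p": p,
            }
        )
    for var in (v for v in CATEGORICAL_VARS if v in data.columns):
        tab = pd.crosstab(data[var], labels)
        test, statistic, p = chi_square(tab.to_numpy())
        counts1 = ", ".join(f"{lvl}={c}" for lvl, c in tab[1].items())
        counts2 = ", ".join(f"{lvl}={c}" for lvl, c in tab[2].items())
        rows.append(
            {
                "variable": var,
                "type": "categorical",
                "cluster1": counts1,
                "cluster2": counts2,
                "cluster1_mean": np.nan,
                "cluster2_mean": np.nan,
                "normality": "",
                "test": test,
                "statistic": statistic,
                "p": p,
            }
        )
    report = pd.DataFrame(rows)
    report["significant"] = report["p"] < 0.05
    if adjust == "bh":
        report["p_bh"] = _benjamini_hochberg(report["p"].to_numpy())
    return report


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        rank = m - rank_from_last
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj
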