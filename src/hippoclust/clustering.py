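"""k-means stratification with majority-vote selection of the cluster count.

Features are z-scored before clustering (metabolic mg/dL and connectivity
Fisher-Z units are incommensurable; unscaled Euclidean distance would be
dominated by SSPG variance). k-means (k-means++ seeding, 50 restarts,
Lloyd iterations) is run for each candidate k; thirteen cluster-validity
indices each nominate their optimal k, and the plurality k wins, with ties
broken toward smaller k (parsimony). Final clusters are relabelled by
*metabolic deviance* — the cluster with the higher mean standardized
SSPG + leptin becomes cluster 1.

Index suite (orientation in brackets): Calinski-Harabasz [max],
silhouette [max], Davies-Bouldin [min], Dunn [max], C-index [min],
McClain-Rao [min], gap statistic [one-SE rule], Hartigan [<=10 rule],
Krzanowski-Lai [max], Ratkowsky-Lance [max], Ball-Hall [max successive
difference], point-biserial [max], trace-W [max second difference, elbow].
An index abstains (is excluded from the vote) where it is undefined, e.g.
for singleton clusters; selection fails if fewer than three indices can
vote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from hippoclust.errors import ConfigError, SelectionError

log = logging.getLogger(__name__)

METABOLIC_FEATURES = ("BMI", "WC", "SSPG", "FPI", "FPG", "leptin", "cortisol")

INDEX_NAMES = (
    "calinski_harabasz",
    "silhouette",
    "davies_bouldin",
    "dunn",
    "c_index",
    "mcclain_rao",
    "gap",
    "hartigan",
    "krzanowski_lai",
    "ratkowsky_lance",
    "ball_hall",
    "point_biserial",
    "trace_w",
)

#: how each index's per-k criterion values are turned into a vote
INDEX_ORIENTATION = {
    "calinski_harabasz": "max",
    "silhouette": "max",
    "davies_bouldin": "min",
    "dunn": "max",
    "c_index": "min",
    "mcclain_rao": "min",
    "gap": "one_se",
    "hartigan": "threshold_10",
    "krzanowski_lai": "max",
    "ratkowsky_lance": "max",
    "ball_hall": "max_diff",
    "point_biserial": "max",
    "trace_w": "elbow",
}


@dataclass
class FeatureMatrix:
    """Standardized subjects-by-features matrix with stored scaling."""

    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # standardized
    means: np.ndarray
    sds: np.ndarray

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.feature_names)

    def inverse(self) -> pd.DataFrame:
        raw = self.values * self.sds + self.means
        return pd.DataFrame(raw, index=self.subject_ids, columns=self.feature_names)


@dataclass
class ClusterSolution:
    """Outcome of majority-vote k selection and final labelling."""

    k_range: tuple[int, ...]
    criteria: pd.DataFrame  # index-by-k criterion values
    votes: dict[str, int | None]  # None = abstained
    tally: dict[int, int]
    chosen_k: int
    labels: np.ndarray  # in {1..k}; 1 = highest metabolic deviance once ordered
    centroids: np.ndarray
    wss: float
    deviance_ordered: bool = False
    subject_ids: list[str] = field(default_factory=list)


def standardize(features: pd.DataFrame) -> FeatureMatrix:
    """Column z-scores with sample SD; scaling parameters retained."""
    if len(features) < 2:
        raise ValueError("standardize needs >= 2 subjects")
    values = features.astype(float).to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("standardize requires all-finite features")
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ConfigError(f"zero-SD feature column(s): {[features.columns[i] for i in zero]}")
    return FeatureMatrix(
        subject_ids=[str(i) for i in features.index],
        feature_names=list(features.columns),
        values=(values - means) / sds,
        means=means,
        sds=sds,
    )


def kmeans(
    matrix: np.ndarray, k: int, seed: int = 0, n_init: int = 50
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_init`` k-means++ Lloyd fit: (labels, centroids, within-SS).

    Labels are 0-based here; they become 1-based only after deviance
    ordering. Empty clusters are re-seeded at far points (library policy).
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    if k == 1:
        centroid = x.mean(axis=0, keepdims=True)
        return np.zeros(n, dtype=int), centroid, float(((x - centroid) ** 2).sum())
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n ({n}), got k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, tol=1e-8, random_state=seed, init="k-means++")
    labels = km.fit_predict(x)
    return labels, km.cluster_centers_, float(km.inertia_)


# ---------------------------------------------------------------------------
# validity indices (label-based criterion values)
# ---------------------------------------------------------------------------


def _cluster_stats(x: np.ndarray, labels: np.ndarray):
    ids = np.unique(labels)
    centroids = np.array([x[labels == c].mean(axis=0) for c in ids])
    sizes = np.array([(labels == c).sum() for c in ids])
    grand = x.mean(axis=0)
    w = sum(((x[labels == c] - centroids[i]) ** 2).sum() for i, c in enumerate(ids))
    b = float((sizes[:, None] * (centroids - grand) ** 2).sum())
    return ids, centroids, sizes, float(w), b


def _within_between_pairs(x: np.ndarray, labels: np.ndarray):
    d = pdist(x)
    n = x.shape[0]
    iu = np.triu_indices(n, 1)
    same = labels[iu[0]] == labels[iu[1]]
    return d, same


def validity_index(matrix: np.ndarray, labels: np.ndarray, index_name: str, seed: int = 0) -> float:
    """Scalar criterion value of one validity index for a given labelling.

    Returns ``nan`` where the index is undefined for this labelling
    (abstention). Curve-based indices (gap, Hartigan, Krzanowski-Lai,
    Ball-Hall, trace-W) are evaluated at this labelling's k, running
    auxiliary k-means fits at neighbouring k where their formulas need
    them.
    """
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    n, p = x.shape
    ids, centroids, sizes, w, b = _cluster_stats(x, labels)
    k = len(ids)

    if index_name == "trace_w":
        return w
    if index_name == "ball_hall":
        return w / k

    if index_name == "calinski_harabasz":
        if k < 2 or k >= n or w == 0:
            return np.nan
        return (b / (k - 1)) / (w / (n - k))

    if index_name == "silhouette":
        if k < 2:
            return np.nan
        dm = squareform(pdist(x))
        s = np.zeros(n)
        for i in range(n):
            own = labels == labels[i]
            n_own = own.sum()
            if n_own == 1:
                s[i] = 0.0
                continue
            a = dm[i, own].sum() / (n_own - 1)
            bvals = [dm[i, labels == c].mean() for c in ids if c != labels[i]]
            bi = min(bvals)
            s[i] = (bi - a) / max(a, bi) if max(a, bi) > 0 else 0.0
        return float(s.mean())

    if index_name == "davies_bouldin":
        if k < 2:
            return np.nan
        scatter = np.array(
            [np.linalg.norm(x[labels == c] - centroids[i], axis=1).mean() for i, c in enumerate(ids)]
        )
        ratio = np.zeros(k)
        for i in range(k):
            others = [
                (scatter[i] + scatter[j]) / np.linalg.norm(centroids[i] - centroids[j])
                for j in range(k)
                if j != i and np.linalg.norm(centroids[i] - centroids[j]) > 0
            ]
            if not others:
                return np.nan
            ratio[i] = max(others)
        return float(ratio.mean())

    if index_name == "dunn":
        if k < 2:
            return np.nan
        dm = squareform(pdist(x))
        diam = max(dm[np.ix_(labels == c, labels == c)].max() for c in ids)
        if diam == 0:
            return np.nan
        min_sep = min(
            dm[np.ix_(labels == a, labels == b)].min()
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
        )
        return float(min_sep / diam)

    if index_name == "c_index":
        if k < 2:
            return np.nan
        d, same = _within_between_pairs(x, labels)
        nw = int(same.sum())
        if nw == 0:
            return np.nan
        s = d[same].sum()
        d_sorted = np.sort(d)
        smin = d_sorted[:nw].sum()
        smax = d_sorted[-nw:].sum()
        if smax == smin:
            return np.nan
        return float((s - smin) / (smax - smin))

    if index_name == "mcclain_rao":
        if k < 2:
            return np.nan
        d, same = _within_between_pairs(x, labels)
        nw, nb = int(same.sum()), int((~same).sum())
        if nw == 0 or nb == 0:
            return np.nan
        sb = d[~same].mean()
        if sb == 0:
            return np.nan
        return float(d[same].mean() / sb)

    if index_name == "point_biserial":
        if k < 2:
            return np.nan
        d, same = _within_between_pairs(x, labels)
        ind = (~same).astype(float)
        if d.std() == 0 or ind.std() == 0:
            return np.nan
        return float(np.corrcoef(d, ind)[0, 1])

    if index_name == "ratkowsky_lance":
        if k < 2:
            return np.nan
        grand = x.mean(axis=0)
        tss_j = ((x - grand) ** 2).sum(axis=0)
        bgss_j = (sizes[:, None] * (centroids - grand) ** 2).sum(axis=0)
        ok = tss_j > 0
        if not ok.any():
            return np.nan
        cbar = np.sqrt(bgss_j[ok] / tss_j[ok]).mean()
        return float(cbar / np.sqrt(k))

    if index_name == "hartigan":
        if k >= n - 1:
            return np.nan
        _, _, w_next = kmeans(x, k + 1, seed=seed, n_init=10)
        if w_next == 0:
            return np.nan
        return float((w / w_next - 1.0) * (n - k - 1))

    if index_name == "krzanowski_lai":
        if k < 2 or k >= n - 1:
            return np.nan
        _, _, w_prev = kmeans(x, k - 1, seed=seed, n_init=10)
        _, _, w_next = kmeans(x, k + 1, seed=seed, n_init=10)
        diff_k = (k - 1) ** (2 / p) * w_prev - k ** (2 / p) * w
        diff_next = k ** (2 / p) * w - (k + 1) ** (2 / p) * w_next
        if diff_next == 0:
            return np.nan
        return float(abs(diff_k) / abs(diff_next))

    if index_name == "gap":
        gap, _ = _gap_statistic(x, {k: w}, [k], seed=seed)
        return float(gap[k])

    raise ValueError(f"unknown validity index {index_name!r}")


def _gap_statistic(
    x: np.ndarray,
    wss: dict[int, float],
    ks: list[int],
    seed: int = 0,
    n_refs: int = 50,
) -> tuple[dict[int, float], dict[int, float]]:
    """Gap(k) = E*[log W_ref(k)] - log W(k) against a uniform bounding-box
    reference (n_refs draws); also returns the one-SE term s_k."""
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    n = x.shape[0]
    log_wref = {k: np.empty(n_refs) for k in ks}
    for b in range(n_refs):
        ref = rng.uniform(lo, hi, size=x.shape)
        for k in ks:
            _, _, w_ref = kmeans(ref, k, seed=seed + b + 1, n_init=5)
            log_wref[k][b] = np.log(w_ref) if w_ref > 0 else -np.inf
    gap = {k: float(np.mean(log_wref[k]) - np.log(wss[k])) for k in ks}
    se = {k: float(np.std(log_wref[k]) * np.sqrt(1.0 + 1.0 / n_refs)) for k in ks}
    return gap, se


# ---------------------------------------------------------------------------
# majority vote
# ---------------------------------------------------------------------------


def _vote_from_curve(name: str, values: dict[int, float], ks: list[int],
                     extra: dict | None = None) -> int | None:
    """Turn an index's per-k criterion values into a single nominated k."""
    orientation = INDEX_ORIENTATION[name]
    arr = np.array([values.get(k, np.nan) for k in ks])

    if orientation in ("max", "min"):
        if np.isnan(arr).any():
            return None
        idx = int(np.argmax(arr)) if orientation == "max" else int(np.argmin(arr))
        return ks[idx]

    if orientation == "max_diff":  # Ball-Hall: largest drop from k-1 to k
        diffs = [values.get(k - 1, np.nan) - values.get(k, np.nan) for k in ks]
        if np.isnan(diffs).any():
            return None
        return ks[int(np.argmax(diffs))]

    if orientation == "elbow":  # trace-W: max second difference
        second = [
            values.get(k - 1, np.nan) - 2 * values.get(k, np.nan) + values.get(k + 1, np.nan)
            for k in ks
        ]
        if np.isnan(second).any():
            return None
        return ks[int(np.argmax(second))]

    if orientation == "threshold_10":  # Hartigan
        if np.isnan(arr).any():
            return None
        for k, h in zip(ks, arr):
            if h <= 10.0:
                return k
        drops = [values.get(k - 1, np.nan) - values.get(k, np.nan) for k in ks]
        if np.isnan(drops).any():
            return ks[int(np.argmax(arr))]
        return ks[int(np.argmax(drops))]

    if orientation == "one_se":  # gap statistic
        se = (extra or {}).get("se", {})
        if np.isnan(arr).any():
            return None
        for k in ks:
            nxt = values.get(k + 1)
            if nxt is None or np.isnan(nxt):
                continue
            if values[k] >= nxt - se.get(k + 1, 0.0):
                return k
        return ks[int(np.argmax(arr))]

    raise ValueError(f"unknown orientation {orientation!r}")  # pragma: no cover


def select_k_majority(
    matrix: np.ndarray | pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    n_init: int = 50,
    n_gap_refs: int = 50,
) -> ClusterSolution:
    """Run k-means over candidate k and choose k by index plurality.

    Each of the 13 validity indices nominates its criterion-optimal k
    (curve-based indices via their own rules); the plurality k wins and
    ties break toward smaller k. The returned labels come from the best
    k-means fit at the chosen k (0-based until deviance ordering).
    """
    if isinstance(matrix, pd.DataFrame):
        subject_ids = [str(i) for i in matrix.index]
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        subject_ids = [str(i) for i in range(x.shape[0])]
    n = x.shape[0]
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if not 2 <= k_lo <= k_hi < n:
        raise ValueError(f"invalid k range {k_range} for n={n}")
    ks = list(range(k_lo, k_hi + 1))

    # k-means solutions for candidates plus the neighbours curve rules need
    fits: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    for k in range(max(1, k_lo - 1), min(n - 1, k_hi + 1) + 1):
        fits[k] = kmeans(x, k, seed=seed, n_init=n_init)
    wss = {k: fit[2] for k, fit in fits.items()}

    label_based = (
        "calinski_harabasz",
        "silhouette",
        "davies_bouldin",
        "dunn",
        "c_index",
        "mcclain_rao",
        "ratkowsky_lance",
        "point_biserial",
    )
    criteria = pd.DataFrame(index=list(INDEX_NAMES), columns=ks, dtype=float)
    for k in ks:
        labels_k = fits[k][0]
        for name in label_based:
            criteria.loc[name, k] = validity_index(x, labels_k, name, seed=seed)
        criteria.loc["trace_w", k] = wss[k]
        criteria.loc["ball_hall", k] = wss[k] / k
        if k + 1 in wss and wss[k + 1] > 0:
            criteria.loc["hartigan", k] = (wss[k] / wss[k + 1] - 1.0) * (n - k - 1)
        if k - 1 in wss and k + 1 in wss:
            p = x.shape[1]
            diff_k = (k - 1) ** (2 / p) * wss[k - 1] - k ** (2 / p) * wss[k]
            diff_n = k ** (2 / p) * wss[k] - (k + 1) ** (2 / p) * wss[k + 1]
            criteria.loc["krzanowski_lai", k] = (
                np.nan if diff_n == 0 else abs(diff_k) / abs(diff_n)
            )
    gap_ks = [k for k in range(k_lo, min(k_hi + 1, n - 1) + 1) if k in wss]
    gap, gap_se = _gap_statistic(x, wss, gap_ks, seed=seed, n_refs=n_gap_refs)
    for k in ks:
        criteria.loc["gap", k] = gap.get(k, np.nan)

    # auxiliary curves outside the candidate range, for the curve rules
    curves: dict[str, dict[int, float]] = {
        "trace_w": dict(wss),
        "ball_hall": {k: w / k for k, w in wss.items()},
        "hartigan": {
            k: (wss[k] / wss[k + 1] - 1.0) * (n - k - 1)
            for k in wss
            if k + 1 in wss and wss[k + 1] > 0
        },
        "gap": gap,
    }

    votes: dict[str, int | None] = {}
    for name in INDEX_NAMES:
        values = curves.get(name, {k: criteria.loc[name, k] for k in ks})
        values = {**{k: criteria.loc[name, k] for k in ks}, **values}
        extra = {"se": gap_se} if name == "gap" else None
        votes[name] = _vote_from_curve(name, values, ks, extra=extra)

    voting = [v for v in votes.values() if v is not None]
    if len(voting) < 3:
        raise SelectionError(f"only {len(voting)} validity indices could vote (need >= 3)")
    tally = {k: voting.count(k) for k in ks if voting.count(k) > 0}
    best = max(tally.values())
    chosen_k = min(k for k, c in tally.items() if c == best)  # ties -> smaller k

    labels, centroids, w = fits[chosen_k]
    return ClusterSolution(
        k_range=tuple(ks),
        criteria=criteria,
        votes=votes,
        tally=tally,
        chosen_k=chosen_k,
        labels=labels.copy(),
        centroids=centroids,
        wss=w,
        subject_ids=subject_ids,
    )


def order_by_deviance(solution: ClusterSolution, features: pd.DataFrame) -> ClusterSolution:
    """Relabel clusters so label 1 is the most metabolically deviant.

    The deviance score of a cluster is the mean of standardized SSPG and
    leptin over its members; clusters are numbered 1..k by descending
    score. An exact tie falls back to descending cluster size (logged).
    """
    for col in ("SSPG", "leptin"):
        if col not in features.columns:
            raise ValueError(f"deviance ordering requires column {col!r}")
    z = features[["SSPG", "leptin"]].astype(float)
    z = (z - z.mean()) / z.std(ddof=1)
    score = z.mean(axis=1).to_numpy()

    old = np.unique(solution.labels)
    dev = np.array([score[solution.labels == c].mean() for c in old])
    sizes = np.array([(solution.labels == c).sum() for c in old])
    if len(np.unique(dev.round(12))) < len(dev):
        log.warning("deviance tie between clusters; ordering by size descending")
    order = np.lexsort((-sizes, -dev))  # primary: deviance desc; tie: size desc
    mapping = {old[o]: rank + 1 for rank, o in enumerate(order)}
    new_labels = np.array([mapping[c] for c in solution.labels])

    return ClusterSolution(
        k_range=solution.k_range,
        criteria=solution.criteria,
        votes=solution.votes,
        tally=solution.tally,
        chosen_k=solution.chosen_k,
        labels=new_labels,
        centroids=solution.centroids[[int(np.flatnonzero(old == o)[0]) for o in order]],
        wss=solution.wss,
        deviance_ordered=True,
        subject_ids=solution.subject_ids,
    )


def cluster_metabolic_only(
    features: pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    n_init: int = 50,
) -> ClusterSolution:
    """Supplementary variant: cluster on the 7 metabolic columns only."""
    cols = [c for c in METABOLIC_FEATURES if c in features.columns]
    if not cols:
        raise ValueError("no metabolic columns found")
    fm = standardize(features[cols])
    solution = select_k_majority(fm.frame, k_range=k_range, seed=seed, n_init=n_init)
    if {"SSPG", "leptin"}.issubset(features.columns):
        solution = order_by_deviance(solution, features)
    return solution
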