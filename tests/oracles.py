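"""Independent straight-from-formula oracles used by the test suite.

Everything here is deliberately naive (loops, exhaustive enumeration) and
shares no code with the package implementation.
"""

from itertools import combinations

import numpy as np


# ------------------------------------------------------------ k-means


def set_partitions(items, k):
    """All partitions of ``items`` into exactly k non-empty blocks."""
    items = list(items)
    if k == 1:
        yield [items]
        return
    if len(items) == k:
        yield [[i] for i in items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest, k - 1):
        yield [[first]] + part
    for part in set_partitions(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]


def brute_force_kmeans(x, k):
    """Globally optimal within-SS over all partitions (small n only)."""
    n = len(x)
    best, best_labels = np.inf, None
    for part in set_partitions(range(n), k):
        ss = 0.0
        for block in part:
            pts = x[block]
            ss += ((pts - pts.mean(axis=0)) ** 2).sum()
        if ss < best - 1e-12:
            best = ss
            labels = np.empty(n, int)
            for c, block in enumerate(part):
                labels[block] = c
            best_labels = labels
    return best, best_labels


# ----------------------------------------------------- validity indices


def _groups(x, labels):
    return [x[labels == c] for c in np.unique(labels)]


def oracle_within_ss(x, labels):
    return sum(((g - g.mean(axis=0)) ** 2).sum() for g in _groups(x, labels))


def oracle_calinski_harabasz(x, labels):
    n, k = len(x), len(np.unique(labels))
    grand = x.mean(axis=0)
    b = sum(len(g) * ((g.mean(axis=0) - grand) ** 2).sum() for g in _groups(x, labels))
    w = oracle_within_ss(x, labels)
    return (b / (k - 1)) / (w / (n - k))


def oracle_silhouette(x, labels):
    n = len(x)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    s = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            s.append(0.0)
            continue
        a = np.mean([d[i, j] for j in own])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == c])
            for c in np.unique(labels)
            if c != labels[i]
        )
        s.append((b - a) / max(a, b))
    return float(np.mean(s))


def oracle_davies_bouldin(x, labels):
    ids = np.unique(labels)
    cents = [x[labels == c].mean(axis=0) for c in ids]
    scatter = [
        np.mean([np.linalg.norm(p - cents[i]) for p in x[labels == c]])
        for i, c in enumerate(ids)
    ]
    total = 0.0
    for i in range(len(ids)):
        total += max(
            (scatter[i] + scatter[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(len(ids))
            if j != i
        )
    return total / len(ids)


def oracle_dunn(x, labels):
    ids = np.unique(labels)
    diam = max(
        max((np.linalg.norm(p - q) for p in x[labels == c] for q in x[labels == c]))
        for c in ids
    )
    sep = min(
        np.linalg.norm(p - q)
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
        for p in x[labels == a]
        for q in x[labels == b]
    )
    return sep / diam


def _pairs(x, labels):
    within, between = [], []
    for i, j in combinations(range(len(x)), 2):
        d = np.linalg.norm(x[i] - x[j])
        (within if labels[i] == labels[j] else between).append(d)
    return np.array(within), np.array(between)


def oracle_c_index(x, labels):
    within, between = _pairs(x, labels)
    nw = len(within)
    alldist = np.sort(np.concatenate([within, between]))
    smin, smax = alldist[:nw].sum(), alldist[-nw:].sum()
    return (within.sum() - smin) / (smax - smin)


def oracle_mcclain_rao(x, labels):
    within, between = _pairs(x, labels)
    return within.mean() / between.mean()


def oracle_point_biserial(x, labels):
    within, between = _pairs(x, labels)
    d = np.concatenate([within, between])
    ind = np.concatenate([np.zeros(len(within)), np.ones(len(between))])
    return float(np.corrcoef(d, ind)[0, 1])


def oracle_ratkowsky_lance(x, labels):
    ids = np.unique(labels)
    grand = x.mean(axis=0)
    sizes = np.array([(labels == c).sum() for c in ids])
    cents = np.array([x[labels == c].mean(axis=0) for c in ids])
    tss = ((x - grand) ** 2).sum(axis=0)
    bgss = (sizes[:, None] * (cents - grand) ** 2).sum(axis=0)
    return float(np.mean(np.sqrt(bgss / tss)) / np.sqrt(len(ids)))


ORACLE_INDICES = {
    "calinski_harabasz": oracle_calinski_harabasz,
    "silhouette": oracle_silhouette,
    "davies_bouldin": oracle_davies_bouldin,
    "dunn": oracle_dunn,
    "c_index": oracle_c_index,
    "mcclain_rao": oracle_mcclain_rao,
    "point_biserial": oracle_point_biserial,
    "ratkowsky_lance": oracle_ratkowsky_lance,
    "trace_w": oracle_within_ss,
    "ball_hall": lambda x, labels: oracle_within_ss(x, labels) / len(np.unique(labels)),
}


# --------------------------------------------------- Mann-Whitney exact


def mann_whitney_exact(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(idx_x):
        xs = pooled[list(idx_x)]
        ys = np.delete(pooled, list(idx_x))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(range(n1))
    us = np.array([u_stat(c) for c in combinations(range(len(pooled)), n1)])
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2 * min(lo, hi))
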