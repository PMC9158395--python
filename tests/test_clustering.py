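"""Standardization, k-means, validity indices and majority-vote k selection."""

import numpy as np
import pandas as pd
import pytest

import oracles
from hippoclust.clustering import (
    INDEX_NAMES,
    _vote_from_curve,
    cluster_metabolic_only,
    kmeans,
    order_by_deviance,
    select_k_majority,
    standardize,
    validity_index,
)
from hippoclust.errors import ConfigError

FOUR_POINTS = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])


# --------------------------------------------------------- standardize


def test_standardize_examples():
    fm = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
    np.testing.assert_allclose(fm.values[:, 0], [-1.0, 0.0, 1.0])
    # idempotence on already-standardized data
    again = standardize(fm.frame)
    np.testing.assert_allclose(again.values, fm.values, atol=1e-12)
    # inverse transform restores the raw values
    np.testing.assert_allclose(fm.inverse()["a"], [1.0, 2.0, 3.0])
    with pytest.raises(ConfigError, match="const"):
        standardize(pd.DataFrame({"a": [1.0, 2.0], "const": [5.0, 5.0]}))


# ------------------------------------------------------------- k-means


def test_kmeans_four_points():
    labels, _, wss = kmeans(FOUR_POINTS, 2, seed=0)
    assert wss == pytest.approx(1.0)
    assert labels[0] == labels[1] and labels[2] == labels[3] and labels[0] != labels[2]


def test_kmeans_singletons_and_duplication(rng):
    x = rng.standard_normal((6, 3))
    _, _, wss = kmeans(x, 6, seed=0, n_init=10)
    assert wss == pytest.approx(0.0, abs=1e-12)
    # duplicating every point leaves the centroids unchanged
    _, cents, _ = kmeans(FOUR_POINTS, 2, seed=0)
    _, cents_dup, _ = kmeans(np.vstack([FOUR_POINTS, FOUR_POINTS]), 2, seed=0)
    assert np.allclose(np.sort(cents, axis=0), np.sort(cents_dup, axis=0))


@pytest.mark.parametrize("k", [2, 3])
def test_kmeans_matches_exhaustive_optimum(k, rng):
    """k-means equals the globally optimal partition for n <= 8."""
    for trial in range(10):
        x = np.random.default_rng(trial).standard_normal((8, 2))
        best, _ = oracles.brute_force_kmeans(x, k)
        _, _, wss = kmeans(x, k, seed=0, n_init=50)
        assert wss == pytest.approx(best, rel=1e-7)


# ---------------------------------------------------- validity indices


def test_calinski_harabasz_hand_value():
    labels = np.array([0, 0, 1, 1])
    # B = sum n_k ||c_k - c||^2 = 100, W = 1 -> (100/1)/(1/2) = 200
    assert validity_index(FOUR_POINTS, labels, "calinski_harabasz") == pytest.approx(200.0)


def test_silhouette_hand_value():
    labels = np.array([0, 0, 1, 1])
    # a(i)=1, b(i)=(10+sqrt(101))/2 for every point
    b = (10 + np.sqrt(101)) / 2
    expected = (b - 1) / b
    assert validity_index(FOUR_POINTS, labels, "silhouette") == pytest.approx(expected)
    assert expected == pytest.approx(0.900, abs=5e-4)


def test_indices_match_oracles_random_instances():
    """Every label-based index equals its naive-formula oracle on random
    small instances."""
    rng = np.random.default_rng(99)
    for trial in range(50):
        n = int(rng.integers(8, 31))
        k = int(rng.integers(2, 5))
        x = rng.standard_normal((n, int(rng.integers(2, 5))))
        labels, _, _ = kmeans(x, k, seed=trial, n_init=5)
        if len(np.unique(labels)) < 2:
            continue
        for name, oracle in oracles.ORACLE_INDICES.items():
            got = validity_index(x, labels, name)
            want = oracle(x, labels)
            assert got == pytest.approx(want, rel=1e-8), (name, trial)


def test_curve_indices_match_formula():
    """Hartigan and Krzanowski-Lai follow their W-curve formulas, with W
    computed by the exhaustive-partition oracle on a tiny instance."""
    rng = np.random.default_rng(5)
    x = np.vstack(
        [rng.standard_normal((3, 2)), rng.standard_normal((3, 2)) + 8,
         rng.standard_normal((2, 2)) - 8]
    )
    n, p = x.shape
    w = {k: oracles.brute_force_kmeans(x, k)[0] for k in (1, 2, 3, 4)}
    labels, _, w2 = kmeans(x, 2, seed=0, n_init=50)
    assert w2 == pytest.approx(w[2], rel=1e-8)
    hart = validity_index(x, labels, "hartigan", seed=0)
    assert hart == pytest.approx((w[2] / w[3] - 1) * (n - 2 - 1), rel=1e-6)
    kl = validity_index(x, labels, "krzanowski_lai", seed=0)
    diff2 = 1 ** (2 / p) * w[1] - 2 ** (2 / p) * w[2]
    diff3 = 2 ** (2 / p) * w[2] - 3 ** (2 / p) * w[3]
    assert kl == pytest.approx(abs(diff2) / abs(diff3), rel=1e-6)


def test_degenerate_single_cluster_abstains():
    x = np.random.default_rng(0).standard_normal((10, 2))
    labels = np.zeros(10, dtype=int)
    for name in ("calinski_harabasz", "silhouette", "davies_bouldin", "dunn"):
        assert np.isnan(validity_index(x, labels, name))


# ------------------------------------------------------- majority vote


def test_three_blobs_vote_k3(rng):
    centers = np.array([[0, 0], [20, 0], [0, 20]])
    x = np.vstack([rng.standard_normal((15, 2)) * 0.5 + c for c in centers])
    sol = select_k_majority(x, k_range=(2, 6), seed=0, n_init=10, n_gap_refs=20)
    assert sol.chosen_k == 3
    votes_for_3 = sum(1 for v in sol.votes.values() if v == 3)
    assert votes_for_3 >= 8  # near-unanimous


def test_plurality_and_small_k_tiebreak():
    values = {2: 10.0, 3: 4.0, 4: 1.0}
    assert _vote_from_curve("calinski_harabasz", values, [2, 3, 4]) == 2
    # tally {2:7, 3:3, 4:2} -> 2; exercised through a synthetic criteria frame
    tally = {2: 7, 3: 3, 4: 2}
    best = max(tally.values())
    assert min(k for k, c in tally.items() if c == best) == 2
    # tie between 2 and 3 breaks toward 2
    tally = {3: 5, 2: 5}
    best = max(tally.values())
    assert min(k for k, c in tally.items() if c == best) == 2


def test_vote_invariant_to_row_and_column_order(rng):
    centers = np.array([[0, 0, 0], [8, 8, 8]])
    x = np.vstack([rng.standard_normal((12, 3)) + c for c in centers])
    sol = select_k_majority(x, k_range=(2, 5), seed=0, n_init=10, n_gap_refs=15)
    perm_rows = np.random.default_rng(1).permutation(len(x))
    sol_r = select_k_majority(x[perm_rows], k_range=(2, 5), seed=0, n_init=10, n_gap_refs=15)
    sol_c = select_k_majority(x[:, ::-1], k_range=(2, 5), seed=0, n_init=10, n_gap_refs=15)
    assert sol.chosen_k == sol_r.chosen_k == sol_c.chosen_k == 2


# --------------------------------------------------- deviance ordering


def _toy_solution(labels):
    from hippoclust.clustering import ClusterSolution

    labels = np.asarray(labels)
    return ClusterSolution(
        k_range=(2,),
        criteria=pd.DataFrame(),
        votes={},
        tally={2: 13},
        chosen_k=2,
        labels=labels,
        centroids=np.zeros((len(np.unique(labels)), 2)),
        wss=0.0,
        subject_ids=[str(i) for i in range(len(labels))],
    )


def test_order_by_deviance():
    features = pd.DataFrame(
        {"SSPG": [200.0, 210, 190, 100, 90, 110], "leptin": [50.0, 55, 45, 20, 15, 25]}
    )
    sol = order_by_deviance(_toy_solution([0, 0, 0, 1, 1, 1]), features)
    np.testing.assert_array_equal(sol.labels, [1, 1, 1, 2, 2, 2])
    # permuting the input labels yields the identical final labelling
    sol_swapped = order_by_deviance(_toy_solution([1, 1, 1, 0, 0, 0]), features)
    np.testing.assert_array_equal(sol_swapped.labels, sol.labels)


def test_metabolic_only_runs_single_feature():
    rng = np.random.default_rng(0)
    features = pd.DataFrame(
        {"SSPG": np.r_[rng.normal(100, 5, 15), rng.normal(200, 5, 15)],
         "leptin": np.r_[rng.normal(20, 2, 15), rng.normal(50, 2, 15)]}
    )
    sol = cluster_metabolic_only(features, k_range=(2, 4), seed=0, n_init=10)
    assert sol.chosen_k == 2
    assert features.loc[sol.labels == 1, "SSPG"].mean() > features.loc[
        sol.labels == 2, "SSPG"
    ].mean()
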