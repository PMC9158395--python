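"""Cohesiveness, integration and the 18-feature profile."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hippoclust.bold_io import VoxelTimeSeriesMatrix
from hippoclust.bold_sim import equicorrelated_series, generate_masks, simulate_roi_series
from hippoclust.cohort import complete_cases, generate_cohort
from hippoclust.connectivity import (
    CLIP_EPS,
    CONNECTIVITY_FEATURES,
    cohesiveness,
    connectivity_profile,
    fisher_z,
    integration,
)
from hippoclust.errors import DegenerateROIError, ShapeError


def _ts(data):
    return VoxelTimeSeriesMatrix(data=np.asarray(data, float), mask_name="toy")


# ------------------------------------------------------------- fisher_z


def test_fisher_z_values():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)
    # clip policy at |r| = 1: atanh(1 - 1e-7), computed exactly from eps
    assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - CLIP_EPS))
    assert fisher_z(1.0) == pytest.approx(8.4059, abs=2e-3)
    with pytest.raises(ValueError):
        fisher_z(1.01)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
def test_fisher_z_odd_and_increasing(r1, r2):
    assert fisher_z(-r1) == pytest.approx(-fisher_z(r1), abs=1e-12)
    if r1 < r2:
        assert fisher_z(r1) < fisher_z(r2)


# --------------------------------------------------------- cohesiveness


def test_cohesiveness_identical_series():
    """All voxels sharing one series gives r_v = 1 for all v (clipped)."""
    base = np.sin(np.linspace(0, 10, 50))
    ts = _ts(np.tile(base, (5, 1)))
    assert cohesiveness(ts) == pytest.approx(np.arctanh(1 - CLIP_EPS))


def test_cohesiveness_null(rng):
    t = 500
    ts = _ts(rng.standard_normal((30, t)))
    assert abs(cohesiveness(ts)) < 3 / np.sqrt(t)


def test_cohesiveness_closed_form(rng):
    """Equicorrelated data: statistic ~ atanh(rho sqrt((V-1)/(1+(V-2) rho)))."""
    rho, v, t = 0.3, 100, 200
    vals = [
        cohesiveness(_ts(equicorrelated_series(rng, v, t, rho)[0])) for _ in range(40)
    ]
    expected = np.arctanh(0.5413)
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - expected) < 3 * se + 0.01


def test_cohesiveness_invariances(rng):
    """Invariant to voxel order, constant offsets and positive scaling."""
    x = rng.standard_normal((20, 80))
    base = cohesiveness(_ts(x))
    assert cohesiveness(_ts(x[rng.permutation(20)])) == pytest.approx(base)
    assert cohesiveness(_ts(3.5 * x + 7.0)) == pytest.approx(base)


def test_cohesiveness_pairwise_variant(rng):
    """Pairwise-mean variant agrees with a direct corrcoef average."""
    x = rng.standard_normal((12, 100))
    c = np.corrcoef(x)
    expected_r = c[np.triu_indices(12, 1)].mean()
    got = cohesiveness(_ts(x), method="pairwise", aggregate="z_of_mean_r")
    assert got == pytest.approx(np.arctanh(expected_r))


def test_cohesiveness_needs_two_voxels():
    with pytest.raises(DegenerateROIError):
        cohesiveness(_ts(np.random.default_rng(0).standard_normal((1, 50))))


# ---------------------------------------------------------- integration


def test_integration_identity_and_null(rng):
    x = rng.standard_normal((5, 120))
    assert integration(_ts(x), _ts(x.copy())) == pytest.approx(np.arctanh(1 - CLIP_EPS))
    y = rng.standard_normal((5, 120))
    assert abs(integration(_ts(x), _ts(y))) < 0.35  # ~3/sqrt(T)


def test_integration_t_mismatch():
    with pytest.raises(ShapeError, match="mismatch"):
        integration(_ts(np.zeros((2, 10)) + np.arange(10)), _ts(np.ones((2, 12)) * np.arange(12)))


# -------------------------------------------------------------- profile


def test_profile_names_and_order(small_cfg, grid):
    masks = generate_masks(grid)
    subject = complete_cases(generate_cohort(small_cfg)).iloc[0]
    series = simulate_roi_series(subject, masks, grid, small_cfg)
    prof = connectivity_profile(series)
    assert tuple(prof) == CONNECTIVITY_FEATURES
    assert len(prof) == 18
    assert all(np.isfinite(v) for v in prof.values())


def test_profile_left_right_swap(small_cfg, grid):
    """Swapping hemispheres in the input swaps the L/R features."""
    masks = generate_masks(grid)
    subject = complete_cases(generate_cohort(small_cfg)).iloc[0]
    series = simulate_roi_series(subject, masks, grid, small_cfg)
    swapped = dict(series)
    for roi in ("hipp", "DG", "CA1sub"):
        swapped[f"L_{roi}"], swapped[f"R_{roi}"] = series[f"R_{roi}"], series[f"L_{roi}"]
    a = connectivity_profile(series)
    b = connectivity_profile(swapped)
    for name, value in a.items():
        if name.startswith("Hipp"):
            other = {"Hipp_L": "Hipp_R", "Hipp_R": "Hipp_L"}[name]
        else:
            seg, side, rsn = name.split("_")
            other = f"{seg}_{'R' if side == 'L' else 'L'}_{rsn}"
        assert b[other] == pytest.approx(value)


def test_cluster_direction(default_cfg, grid):
    """Cluster-1 subjects show lower cohesiveness and integration on average."""
    cfg = default_cfg.replace(
        n_enrolled=40,
        n_complete=40,
        cluster_sizes=[20, 20],
        grid={"dimensions": [24, 24, 12], "voxel_size_mm": 2.0,
              "n_timepoints": 120, "tr_seconds": 2.0},
    )
    masks = generate_masks(cfg.grid)
    cohort = complete_cases(generate_cohort(cfg))
    profiles = {}
    for _, subject in cohort.iterrows():
        series = simulate_roi_series(subject, masks, cfg.grid, cfg)
        profiles[subject.subject_id] = connectivity_profile(series)
    import pandas as pd

    feats = pd.DataFrame.from_dict(profiles, orient="index")
    latent = cohort.set_index("subject_id")["latent_cluster"]
    gap = feats[latent == 2].mean() - feats[latent == 1].mean()
    assert (gap > 0).all()
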