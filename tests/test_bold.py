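"""Masks, BOLD factor-model simulation, NIfTI I/O and ROI extraction."""

import numpy as np
import pytest

from hippoclust.bold_io import (
    MASK_NAMES,
    ROIMask,
    ROIMaskSet,
    extract_roi_timeseries,
    mean_timeseries,
    read_mask,
    read_volume,
    write_volume,
    VoxelTimeSeriesMatrix,
)
from hippoclust.bold_sim import (
    equicorrelated_series,
    expected_voxel_mean_correlation,
    generate_bold,
    generate_masks,
    mean_attenuation,
    simulate_roi_series,
    subject_rng,
)
from hippoclust.cohort import complete_cases, generate_cohort
from hippoclust.config import GridSpec
from hippoclust.errors import ConfigError, DegenerateROIError, ShapeError, SimulationError


# ---------------------------------------------------------------- masks


def test_mask_geometry(grid):
    masks = generate_masks(grid)
    for name in MASK_NAMES:
        assert masks[name].n_voxels > 0, name
    for side in ("L", "R"):
        hipp = masks[f"{side}_hipp"].data
        dg = masks[f"{side}_DG"].data
        ca1 = masks[f"{side}_CA1sub"].data
        assert hipp.sum() >= 50
        assert (dg & ~hipp).sum() == 0  # segment subset of hippocampus
        assert (ca1 & ~hipp).sum() == 0
        assert (dg & ca1).sum() == 0
        # partition arithmetic: whole = DG + CA1/sub + nonnegative remainder
        assert hipp.sum() - dg.sum() - ca1.sum() >= 0
    assert not (masks["L_hipp"].data & masks["R_hipp"].data).any()
    rsn_union = np.zeros(grid.dimensions, bool)
    for rsn in ("CEN", "SAL", "VIS", "SMN"):
        assert not (masks[rsn].data & (masks["L_hipp"].data | masks["R_hipp"].data)).any()
        assert not (masks[rsn].data & rsn_union).any()
        rsn_union |= masks[rsn].data


def test_mask_grid_too_small():
    with pytest.raises(ConfigError, match="too small"):
        generate_masks(GridSpec(dimensions=(6, 6, 4), n_timepoints=60))


# ------------------------------------------------------------- simulator


def _first_complete_subject(cfg):
    cohort = complete_cases(generate_cohort(cfg))
    return cohort.iloc[0]


def test_bold_determinism_and_order_independence(small_cfg, grid):
    masks = generate_masks(grid)
    cohort = complete_cases(generate_cohort(small_cfg))
    s0, s1 = cohort.iloc[0], cohort.iloc[1]
    a = simulate_roi_series(s0, masks, grid, small_cfg)
    # simulating another subject in between must not change s0's data
    _ = simulate_roi_series(s1, masks, grid, small_cfg)
    b = simulate_roi_series(s0, masks, grid, small_cfg)
    for name in MASK_NAMES:
        np.testing.assert_array_equal(a[name].data, b[name].data)
    assert not np.array_equal(a["L_hipp"].data,
                              simulate_roi_series(s1, masks, grid, small_cfg)["L_hipp"].data)


def test_roi_fast_path_matches_full_volume(small_cfg, grid):
    """Background-free simulation returns exactly the ROI blocks of the
    full 4D volume."""
    masks = generate_masks(grid)
    subject = _first_complete_subject(small_cfg)
    series = simulate_roi_series(subject, masks, grid, small_cfg)
    vol = generate_bold(subject, masks, grid, small_cfg)
    for name in MASK_NAMES:
        extracted = extract_roi_timeseries(vol, masks[name])
        np.testing.assert_allclose(extracted.data, series[name].data)


def test_simulation_requires_latent_cluster(small_cfg, grid):
    masks = generate_masks(grid)
    subject = _first_complete_subject(small_cfg).copy()
    subject["latent_cluster"] = np.nan
    with pytest.raises(SimulationError, match="latent cluster"):
        simulate_roi_series(subject, masks, grid, small_cfg)


def test_equicorrelated_null(rng):
    """rho = 0 gives pairwise correlations ~ 0 (within 3/sqrt(T))."""
    t = 400
    x, _ = equicorrelated_series(rng, 40, t, 0.0)
    c = np.corrcoef(x)
    off = c[np.triu_indices(40, 1)]
    assert abs(off.mean()) < 3 / np.sqrt(t)


def test_equicorrelated_closed_form(rng):
    """Mean leave-one-out voxel correlation matches
    rho * sqrt((V-1)/(1+(V-2) rho)) for rho=0.3, V=100 (Monte Carlo)."""
    rho, v, t, reps = 0.3, 100, 200, 60
    vals = []
    for _ in range(reps):
        x, _ = equicorrelated_series(rng, v, t, rho)
        total = x.sum(axis=0)
        others = (total - x) / (v - 1)
        xc = x - x.mean(1, keepdims=True)
        oc = others - others.mean(1, keepdims=True)
        r = (xc * oc).sum(1) / np.sqrt((xc**2).sum(1) * (oc**2).sum(1))
        vals.append(r.mean())
    expected = expected_voxel_mean_correlation(rho, v)
    assert expected == pytest.approx(0.5413, abs=1e-3)
    se = np.std(vals, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(vals) - expected) < 3 * se + 0.005


def test_cross_coupling_attenuation(rng):
    """Segment-mean x RSN-generator correlation approaches
    rho_cross * sqrt(V rho / (1 + (V-1) rho))."""
    rho_w, rho_c, v, t, reps = 0.3, 0.6, 100, 400, 40
    vals = []
    for _ in range(reps):
        s = rng.standard_normal(t)
        g = rho_c * s + np.sqrt(1 - rho_c**2) * rng.standard_normal(t)
        x, _ = equicorrelated_series(rng, v, t, rho_w, factor=s)
        m = x.mean(axis=0)
        vals.append(np.corrcoef(m, g)[0, 1])
    expected = rho_c * mean_attenuation(rho_w, v)
    assert expected == pytest.approx(0.5931, abs=1e-3)
    se = np.std(vals, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(vals) - expected) < 3 * se + 0.01


def test_subject_rng_stable_hash():
    a = subject_rng(42, "sub-001").standard_normal(4)
    b = subject_rng(42, "sub-001").standard_normal(4)
    c = subject_rng(42, "sub-002").standard_normal(4)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


# ------------------------------------------------------------------ I/O


def test_nifti_roundtrip(tmp_path, grid, rng):
    vol = rng.standard_normal(grid.dimensions + (grid.n_timepoints,))
    path = tmp_path / "bold.nii.gz"
    write_volume(path, vol, grid)
    back = read_volume(path, expected_grid=grid)
    np.testing.assert_allclose(back, vol, rtol=1e-6)


def test_read_volume_rejects_3d(tmp_path, grid, rng):
    path = tmp_path / "notbold.nii.gz"
    write_volume(path, rng.standard_normal(grid.dimensions), grid)
    with pytest.raises(ShapeError, match="4D"):
        read_volume(path)


def test_probabilistic_mask_binarized(tmp_path, grid):
    data = np.zeros(grid.dimensions)
    data[0, 0, 0] = 0.3
    data[1, 1, 1] = 0.9
    path = tmp_path / "prob.nii.gz"
    write_volume(path, data, grid)
    mask = read_mask(path, name="prob")
    assert mask.n_voxels == 1
    assert mask.data[1, 1, 1]


def test_mask_set_roundtrip(tmp_path, grid):
    masks = generate_masks(grid)
    masks.write(tmp_path / "masks")
    back = ROIMaskSet.read(tmp_path / "masks", grid)
    for name in MASK_NAMES:
        np.testing.assert_array_equal(back[name].data, masks[name].data)


def test_extraction_drops_constant_voxels(grid, rng):
    data = np.zeros(grid.dimensions, bool)
    data[:3, 0, 0] = True
    mask = ROIMask(name="toy", data=data)
    vol = rng.standard_normal(grid.dimensions + (50,))
    vol[2, 0, 0, :] = 7.0  # constant voxel
    ts = extract_roi_timeseries(vol, mask)
    assert ts.n_voxels == 2
    vol[:3, 0, 0, :] = 1.0
    with pytest.raises(DegenerateROIError, match="constant"):
        extract_roi_timeseries(vol, mask)


def test_mean_timeseries_examples():
    m = VoxelTimeSeriesMatrix(data=np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
    np.testing.assert_allclose(mean_timeseries(m), [2.0, 2.0, 2.0])
    single = VoxelTimeSeriesMatrix(data=np.array([[5.0, 6.0, 7.0]]))
    np.testing.assert_allclose(mean_timeseries(single), [5.0, 6.0, 7.0])
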