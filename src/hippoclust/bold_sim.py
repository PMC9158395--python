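"""Geometric ROI masks and a factor-model BOLD simulator.

The simulator plants, per subject, the correlation structure the
connectivity statistics measure:

* each hippocampus has one latent factor ``s_h(t)``; its voxels follow the
  equicorrelated model ``x_v = sqrt(rho_w) s_h + sqrt(1 - rho_w) eps_v``
  with unit-variance white noise, so every voxel pair correlates at
  ``rho_w``;
* each resting-state network has a generator
  ``g_j = c_L s_L + c_R s_R + sqrt(1 - c_L^2 - c_R^2) nu_j`` with
  hemisphere-specific couplings centred on ``rho_cross``, so
  ``corr(g_j, s_h) = c_h``;
* RSN voxels follow the same equicorrelated model around ``g_j`` at a high
  ``rho_rsn`` (default 0.9), keeping the RSN voxel mean nearly equal to
  the generator; non-ROI voxels are independent noise.

``rho_w`` and ``rho_cross`` come from the subject's latent cluster, with
per-subject jitter on the Fisher-z scale so connectivity features vary
between subjects within a cluster.

The per-subject random stream draws ROI content *first* and background
noise last, so ``simulate_roi_series`` (which skips the background)
returns bitwise the same ROI matrices as extracting them from the full
``generate_bold`` volume.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from hippoclust.bold_io import MASK_NAMES, ROIMask, ROIMaskSet, VoxelTimeSeriesMatrix
from hippoclust.config import CohortConfig, GridSpec
from hippoclust.errors import ConfigError, SimulationError

RSN_NAMES = ("CEN", "SAL", "VIS", "SMN")

#: per-subject jittered correlations are clipped into this range
_RHO_WITHIN_RANGE = (0.01, 0.95)
_RHO_CROSS_RANGE = (0.01, 0.70)  # construction needs rho_cross <= 1/sqrt(2)


def _box(dims: tuple[int, int, int], fx, fy, fz) -> np.ndarray:
    """Boolean box mask from fractional bounds on each axis."""
    out = np.zeros(dims, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = (
        (int(round(lo * d)), int(round(hi * d))) for (lo, hi), d in zip((fx, fy, fz), dims)
    )
    out[x0:x1, y0:y1, z0:z1] = True
    return out


def generate_masks(grid: GridSpec) -> ROIMaskSet:
    """Toy geometric stand-ins for the ten analysis ROIs.

    Two lateral hippocampus boxes (mid-depth) are each partitioned along
    the anteroposterior (y) axis into a posterior DG segment, an anterior
    CA1/subiculum segment, and an unlabelled middle remainder; four RSN
    boxes sit in the superior corners, disjoint from the hippocampi.
    """
    dims = grid.dimensions
    masks: dict[str, np.ndarray] = {}
    masks["L_hipp"] = _box(dims, (0.12, 0.34), (0.29, 0.63), (0.33, 0.67))
    masks["R_hipp"] = _box(dims, (0.66, 0.88), (0.29, 0.63), (0.33, 0.67))
    for side in ("L", "R"):
        hipp = masks[f"{side}_hipp"]
        ys = np.flatnonzero(hipp.any(axis=(0, 2)))
        seg = max(1, (len(ys) * 3) // 8)
        post = np.zeros_like(hipp)
        post[:, ys[:seg], :] = True
        ant = np.zeros_like(hipp)
        ant[:, ys[-seg:], :] = True
        masks[f"{side}_DG"] = hipp & post
        masks[f"{side}_CA1sub"] = hipp & ant
    corners = {
        "CEN": ((0.0, 0.21), (0.0, 0.21)),
        "SAL": ((0.79, 1.0), (0.0, 0.21)),
        "VIS": ((0.0, 0.21), (0.79, 1.0)),
        "SMN": ((0.79, 1.0), (0.79, 1.0)),
    }
    for name, (fx, fy) in corners.items():
        masks[name] = _box(dims, fx, fy, (0.67, 1.0))

    # sizing checks
    for side in ("L", "R"):
        if masks[f"{side}_hipp"].sum() < 50:
            raise ConfigError(
                f"grid {dims} too small: {side} hippocampus has "
                f"{int(masks[f'{side}_hipp'].sum())} voxels (< 50)"
            )
        if masks[f"{side}_DG"].sum() == 0 or masks[f"{side}_CA1sub"].sum() == 0:
            raise ConfigError(f"grid {dims} too small for hippocampal segments")
        if (masks[f"{side}_DG"] & masks[f"{side}_CA1sub"]).any():
            raise ConfigError(f"grid {dims} too small: segments overlap")
    if (masks["L_hipp"] & masks["R_hipp"]).any():
        raise ConfigError(f"grid {dims} too small: hippocampi overlap")
    hipp_union = masks["L_hipp"] | masks["R_hipp"]
    for i, a in enumerate(RSN_NAMES):
        if masks[a].sum() == 0:
            raise ConfigError(f"grid {dims} too small: RSN {a} empty")
        if (masks[a] & hipp_union).any():
            raise ConfigError(f"grid {dims} too small: RSN {a} touches hippocampus")
        for b in RSN_NAMES[i + 1 :]:
            if (masks[a] & masks[b]).any():
                raise ConfigError(f"grid {dims} too small: RSNs {a}/{b} overlap")

    return ROIMaskSet(
        masks={name: ROIMask(name=name, data=masks[name], affine=grid.affine) for name in MASK_NAMES},
        grid=grid,
    )


def subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    """Per-subject generator derived by hashing (master seed, subject id).

    Hash-based derivation makes generation order-independent: simulating
    subjects in any order or in parallel yields identical per-subject data.
    """
    digest = zlib.crc32(str(subject_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(master_seed) & 0x7FFFFFFF, digest)))


def equicorrelated_series(
    rng: np.random.Generator, n_voxels: int, n_timepoints: int, rho: float,
    factor: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the equicorrelated factor model; returns (X of shape (V, T), factor)."""
    if not 0.0 <= rho < 1.0:
        raise ConfigError(f"rho must be in [0, 1), got {rho}")
    if factor is None:
        factor = rng.standard_normal(n_timepoints)
    noise = rng.standard_normal((n_voxels, n_timepoints))
    x = np.sqrt(rho) * factor[None, :] + np.sqrt(1.0 - rho) * noise
    return x, factor


def expected_voxel_mean_correlation(rho: float, n_voxels: int) -> float:
    """Population correlation of one voxel with the mean of the other V-1
    voxels under the equicorrelated model: rho * sqrt((V-1)/(1+(V-2) rho))."""
    v = n_voxels
    return rho * np.sqrt((v - 1) / (1.0 + (v - 2) * rho))


def mean_attenuation(rho: float, n_voxels: int) -> float:
    """Correlation of the V-voxel mean with the latent factor:
    sqrt(V rho / (1 + (V-1) rho))."""
    v = n_voxels
    if rho == 0.0:
        return 0.0
    return np.sqrt(v * rho / (1.0 + (v - 1) * rho))


def _subject_rhos(
    subject: pd.Series | dict, config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    cluster = subject.get("latent_cluster", None)
    if cluster is None or (isinstance(cluster, float) and np.isnan(cluster)) or int(cluster) not in (1, 2):
        raise SimulationError(
            f"subject {subject.get('subject_id', '?')!r} has no latent cluster; "
            "real subjects cannot be simulated"
        )
    cluster = int(cluster)
    jitter_sd = float(config.connectivity.get("jitter_sd_z", 0.0))
    # fixed draw order: [within L, within R, cross (hemisphere x RSN, 2x4)]
    jitters = jitter_sd * rng.standard_normal(10)
    rho_w = np.tanh(np.arctanh(config.rho_within(cluster)) + jitters[:2])
    rho_c = np.tanh(np.arctanh(config.rho_cross(cluster)) + jitters[2:].reshape(2, 4))
    rho_w = np.clip(rho_w, *_RHO_WITHIN_RANGE)
    rho_c = np.clip(rho_c, *_RHO_CROSS_RANGE)
    return rho_w, rho_c


def _simulate_roi_blocks(
    subject: pd.Series | dict, masks: ROIMaskSet, grid: GridSpec, config: CohortConfig
) -> dict[str, np.ndarray]:
    """Core draw: ROI voxel blocks in a fixed stream order (background-free)."""
    rng = subject_rng(config.seed, subject["subject_id"])
    t = grid.n_timepoints
    rho_w, rho_c = _subject_rhos(subject, config, rng)

    factors = rng.standard_normal((2, t))  # s_L, s_R
    nu = rng.standard_normal((4, t))
    blocks: dict[str, np.ndarray] = {}
    generators = {}
    for j, name in enumerate(RSN_NAMES):
        c_l, c_r = rho_c[0, j], rho_c[1, j]
        generators[name] = (
            c_l * factors[0]
            + c_r * factors[1]
            + np.sqrt(1.0 - c_l**2 - c_r**2) * nu[j]
        )
    for h, side in enumerate(("L", "R")):
        v = masks[f"{side}_hipp"].n_voxels
        x, _ = equicorrelated_series(rng, v, t, float(rho_w[h]), factor=factors[h])
        blocks[f"{side}_hipp"] = x
    rho_rsn = float(config.connectivity.get("rho_rsn", 0.9))
    for name in RSN_NAMES:
        v = masks[name].n_voxels
        x, _ = equicorrelated_series(rng, v, t, rho_rsn, factor=generators[name])
        blocks[name] = x
    return blocks


def _segment_rows(masks: ROIMaskSet, side: str, segment: str) -> np.ndarray:
    """Row indices of a hippocampal segment inside the hemisphere block
    (both in canonical C-order)."""
    hipp_idx = np.flatnonzero(masks[f"{side}_hipp"].data.ravel())
    seg_idx = np.flatnonzero(masks[f"{side}_{segment}"].data.ravel())
    rows = np.searchsorted(hipp_idx, seg_idx)
    if not np.array_equal(hipp_idx[rows], seg_idx):
        raise ConfigError(f"{side}_{segment} is not a subset of {side}_hipp")
    return rows


def simulate_roi_series(
    subject: pd.Series | dict, masks: ROIMaskSet, grid: GridSpec, config: CohortConfig
) -> dict[str, VoxelTimeSeriesMatrix]:
    """ROI voxel time series for one subject, skipping background voxels.

    Returns matrices for all ten ROIs; hippocampal-segment matrices are row
    subsets of the hemisphere matrices. Bitwise identical to extracting the
    same ROIs from ``generate_bold`` output.
    """
    blocks = _simulate_roi_blocks(subject, masks, grid, config)
    sid = str(subject["subject_id"])
    out = {}
    for name in ("L_hipp", "R_hipp") + RSN_NAMES:
        out[name] = VoxelTimeSeriesMatrix(data=blocks[name], mask_name=name, subject_id=sid)
    for side in ("L", "R"):
        for segment in ("DG", "CA1sub"):
            rows = _segment_rows(masks, side, segment)
            out[f"{side}_{segment}"] = VoxelTimeSeriesMatrix(
                data=blocks[f"{side}_hipp"][rows], mask_name=f"{side}_{segment}", subject_id=sid
            )
    return out


def generate_bold(
    subject: pd.Series | dict, masks: ROIMaskSet, grid: GridSpec, config: CohortConfig
) -> np.ndarray:
    """Full 4D BOLD volume (x, y, z, t) for one synthetic subject."""
    blocks = _simulate_roi_blocks(subject, masks, grid, config)
    rng_tail = subject_rng(config.seed, subject["subject_id"])
    # fast-forward an independent stream for the background: jump far away
    rng_tail = rng_tail.spawn(1)[0]
    vol = np.empty(grid.dimensions + (grid.n_timepoints,))
    roi_union = np.zeros(grid.dimensions, dtype=bool)
    for name in ("L_hipp", "R_hipp") + RSN_NAMES:
        m = masks[name].data
        vol[m] = blocks[name]
        roi_union |= m
    n_bg = int((~roi_union).sum())
    vol[~roi_union] = rng_tail.standard_normal((n_bg, grid.n_timepoints))
    return vol
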