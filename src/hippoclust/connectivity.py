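"""Hippocampal cohesiveness and segment-RSN integration.

Two statistics summarise each subject's hippocampal connectivity:

* **cohesiveness** (one value per hemisphere): for each hippocampal voxel,
  the Pearson correlation of its BOLD series with the average series of
  all *other* hippocampal voxels; the per-voxel correlations are Fisher
  Z-transformed and averaged. An alternative reading — the mean of all
  pairwise voxel-voxel correlations — is available via ``method``.

* **integration** (16 values): the Fisher Z-transformed Pearson
  correlation between the mean series of a hippocampal segment (posterior
  = dentate gyrus, anterior = CA1/subiculum; left and right) and the mean
  series of each of four resting-state networks (CEN, SAL, VIS, SMN).

The Fisher transform is applied to both statistics so the 18-feature block
lives on one common scale; correlations at +/-1 are clipped at 1 - 1e-7 to
keep features finite.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from hippoclust.bold_io import (
    ROIMaskSet,
    VoxelTimeSeriesMatrix,
    extract_roi_timeseries,
    mean_timeseries,
)
from hippoclust.errors import DegenerateROIError, ShapeError

#: clip |r| at 1 - CLIP_EPS before atanh
CLIP_EPS = 1e-7

_SEGMENTS = (("pHipp", "DG"), ("aHipp", "CA1sub"))
_RSNS = ("CEN", "SAL", "VIS", "SMN")

#: fixed, documented feature order: 2 cohesiveness + 16 integration values
CONNECTIVITY_FEATURES = tuple(
    [f"Hipp_{side}" for side in ("L", "R")]
    + [
        f"{seg}_{side}_{rsn}"
        for side in ("L", "R")
        for seg, _ in _SEGMENTS
        for rsn in _RSNS
    ]
)


def fisher_z(r):
    """Fisher Z (atanh) transform with clipping at ``1 - 1e-7``.

    Accepts scalars or arrays; values outside [-1, 1] beyond numerical
    noise raise a domain error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError(f"correlation outside [-1, 1]: {arr[np.abs(arr) > 1 + 1e-12]}")
    z = np.arctanh(np.clip(arr, -1.0 + CLIP_EPS, 1.0 - CLIP_EPS))
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise DegenerateROIError("zero-variance series in correlation")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def leave_one_out_correlations(ts: VoxelTimeSeriesMatrix) -> np.ndarray:
    """r_v = Pearson(x_v, mean of the other V-1 voxel series), vectorized."""
    x = ts.data
    v = x.shape[0]
    if v < 2:
        raise DegenerateROIError(f"ROI {ts.mask_name!r}: cohesiveness needs >= 2 voxels, got {v}")
    total = x.sum(axis=0)
    others = (total[None, :] - x) / (v - 1)
    xc = x - x.mean(axis=1, keepdims=True)
    oc = others - others.mean(axis=1, keepdims=True)
    num = np.einsum("vt,vt->v", xc, oc)
    denom = np.sqrt(np.einsum("vt,vt->v", xc, xc) * np.einsum("vt,vt->v", oc, oc))
    if np.any(denom == 0):
        raise DegenerateROIError(f"ROI {ts.mask_name!r}: zero-variance series in cohesiveness")
    return np.clip(num / denom, -1.0, 1.0)


def pairwise_mean_correlation(ts: VoxelTimeSeriesMatrix) -> float:
    """Mean of the off-diagonal entries of the voxel correlation matrix."""
    v = ts.n_voxels
    if v < 2:
        raise DegenerateROIError(f"ROI {ts.mask_name!r}: cohesiveness needs >= 2 voxels, got {v}")
    c = np.corrcoef(ts.data)
    return float((c.sum() - v) / (v * (v - 1)))


def cohesiveness(
    ts: VoxelTimeSeriesMatrix,
    method: str = "leave_one_out",
    aggregate: str = "mean_z",
) -> float:
    """Within-ROI cohesiveness in Fisher-Z units.

    ``method='leave_one_out'`` (default) correlates each voxel with the
    mean of the others; ``'pairwise'`` averages all pairwise voxel
    correlations. ``aggregate='mean_z'`` (default) averages the Fisher-Z
    values; ``'z_of_mean_r'`` transforms the mean correlation instead.
    """
    if method == "leave_one_out":
        r = leave_one_out_correlations(ts)
    elif method == "pairwise":
        r = np.atleast_1d(pairwise_mean_correlation(ts))
    else:
        raise ValueError(f"unknown cohesiveness method {method!r}")
    if aggregate == "mean_z":
        return float(np.mean(fisher_z(r)))
    if aggregate == "z_of_mean_r":
        return float(fisher_z(float(np.mean(r))))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def integration(
    segment_ts: VoxelTimeSeriesMatrix,
    rsn_ts: VoxelTimeSeriesMatrix,
    fisher: bool = True,
) -> float:
    """Correlation of segment mean series with RSN mean series (Fisher-Z)."""
    if segment_ts.n_timepoints != rsn_ts.n_timepoints:
        raise ShapeError(
            f"timepoint mismatch: {segment_ts.mask_name!r} T={segment_ts.n_timepoints} vs "
            f"{rsn_ts.mask_name!r} T={rsn_ts.n_timepoints}"
        )
    r = _pearson(mean_timeseries(segment_ts), mean_timeseries(rsn_ts))
    return float(fisher_z(r)) if fisher else r


def connectivity_profile(
    volume_or_series: np.ndarray | Mapping[str, VoxelTimeSeriesMatrix],
    masks: ROIMaskSet | None = None,
    method: str = "leave_one_out",
    fisher: bool = True,
) -> dict[str, float]:
    """The 18 named connectivity features for one subject.

    Accepts either a 4D volume (ROIs are extracted with ``masks``) or a
    precomputed mapping of ROI name to voxel time-series matrix. Whole-
    hippocampus masks feed cohesiveness; DG masks feed posterior
    integration and CA1/subiculum masks anterior integration. Features are
    returned in the documented ``CONNECTIVITY_FEATURES`` order.
    """
    if isinstance(volume_or_series, Mapping):
        series = volume_or_series
    else:
        if masks is None:
            raise ValueError("masks are required when passing a 4D volume")
        series = {name: extract_roi_timeseries(volume_or_series, masks[name]) for name in masks.masks}

    profile: dict[str, float] = {}
    for side in ("L", "R"):
        z = cohesiveness(series[f"{side}_hipp"], method=method)
        profile[f"Hipp_{side}"] = z if fisher else float(np.tanh(z))
    for side in ("L", "R"):
        for seg_label, seg_roi in _SEGMENTS:
            for rsn in _RSNS:
                profile[f"{seg_label}_{side}_{rsn}"] = integration(
                    series[f"{side}_{seg_roi}"], series[rsn], fisher=fisher
                )
    out = {name: profile[name] for name in CONNECTIVITY_FEATURES}
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise DegenerateROIError(f"non-finite connectivity features: {bad}")
    return out
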