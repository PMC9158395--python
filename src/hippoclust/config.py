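"""Configuration objects for the synthetic cohort and the voxel grid.

The default configuration (``default_config()``) is shipped as
``table2_defaults.yaml`` next to this module. It encodes the two-cluster
world the pipeline is validated against: cluster sizes 51/53 out of 104
complete subjects (126 enrolled), published per-cluster SSPG and leptin
means/SDs, BMI and FPG marginals calibrated to the published category
percentages, and connectivity effect sizes expressed as per-cluster
(rho_within, rho_cross) pairs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from hippoclust.errors import ConfigError

METABOLIC_VARIABLES = ("BMI", "WC", "SSPG", "FPI", "FPG", "leptin", "cortisol")


@dataclass
class GridSpec:
    """Voxel lattice and sampling of the simulated BOLD volumes."""

    dimensions: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: float = 2.0
    n_timepoints: int = 200
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dimensions)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ConfigError(f"grid dimensions must be 3 positive ints, got {self.dimensions}")
        self.dimensions = dims
        if self.n_timepoints < 10:
            raise ConfigError(f"n_timepoints must be >= 10, got {self.n_timepoints}")
        if self.voxel_size_mm <= 0 or self.tr_seconds <= 0:
            raise ConfigError("voxel size and TR must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff


@dataclass
class CohortConfig:
    """Full specification of the synthetic cohort generator.

    ``metabolic`` holds, per cluster, a mean and SD for each of the seven
    panel variables plus one shared inter-variable correlation matrix.
    The configured mean/SD are the moments of the *generated* (zero-
    truncated) distribution, not of a pre-truncation normal.
    """

    n_enrolled: int = 126
    n_complete: int = 104
    cluster_sizes: tuple[int, int] = (51, 53)
    seed: int = 42
    metabolic: dict[str, Any] = field(default_factory=dict)
    female_fraction: tuple[float, float] = (0.75, 0.45)
    age: dict[str, float] = field(default_factory=dict)
    ethnicity: dict[str, Any] = field(default_factory=dict)
    cognitive: dict[str, Any] = field(default_factory=dict)
    motion: dict[str, Any] = field(default_factory=dict)
    connectivity: dict[str, Any] = field(default_factory=dict)
    grid: GridSpec = field(default_factory=GridSpec)

    # -- validation ---------------------------------------------------
    def __post_init__(self) -> None:
        self.cluster_sizes = tuple(int(c) for c in self.cluster_sizes)
        if len(self.cluster_sizes) != 2:
            raise ConfigError("cluster_sizes must have exactly two entries")
        if sum(self.cluster_sizes) != self.n_complete:
            raise ConfigError(
                f"cluster_sizes {self.cluster_sizes} must sum to n_complete={self.n_complete}"
            )
        if not (0 < self.n_complete <= self.n_enrolled):
            raise ConfigError("need 0 < n_complete <= n_enrolled")
        if self.metabolic:
            self._validate_metabolic()
        if self.connectivity:
            self._validate_connectivity()
        for f in self.female_fraction:
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"female_fraction {f} outside [0, 1]")

    def _validate_metabolic(self) -> None:
        variables = tuple(self.metabolic.get("variables", METABOLIC_VARIABLES))
        for cl in ("cluster1", "cluster2"):
            params = self.metabolic.get(cl, {})
            missing = [v for v in variables if v not in params]
            if missing:
                raise ConfigError(f"metabolic.{cl} missing variables {missing}")
            for v in variables:
                sd = params[v]["sd"]
                if sd <= 0:
                    raise ConfigError(f"metabolic.{cl}.{v}: SD must be > 0, got {sd}")
        corr = self.correlation_matrix()
        if corr.shape != (len(variables), len(variables)):
            raise ConfigError(
                f"metabolic correlation matrix must be {len(variables)}x{len(variables)}"
            )
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ConfigError("metabolic correlation matrix is not symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ConfigError("metabolic correlation matrix diagonal must be 1")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigError("metabolic correlation matrix is not positive semi-definite")

    def _validate_connectivity(self) -> None:
        for key in ("rho_within", "rho_cross"):
            pair = self.connectivity.get(key)
            if pair is None:
                raise ConfigError(f"connectivity.{key} missing")
            for rho in pair:
                if not 0.0 <= rho < 1.0:
                    raise ConfigError(f"connectivity.{key} value {rho} outside [0, 1)")
        for rho in self.connectivity["rho_cross"]:
            # the RSN generator couples to both hemisphere factors; the
            # construction requires rho_cross <= 1/sqrt(2)
            if rho > 1 / np.sqrt(2):
                raise ConfigError(f"rho_cross {rho} exceeds 1/sqrt(2)")

    # -- accessors ----------------------------------------------------
    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.metabolic.get("variables", METABOLIC_VARIABLES))

    def correlation_matrix(self) -> np.ndarray:
        return np.asarray(self.metabolic["correlation"], dtype=float)

    def cluster_params(self, cluster: int) -> dict[str, dict[str, float]]:
        """Per-variable {mean, sd} for latent cluster 1 or 2."""
        return self.metabolic[f"cluster{cluster}"]

    def rho_within(self, cluster: int) -> float:
        return float(self.connectivity["rho_within"][cluster - 1])

    def rho_cross(self, cluster: int) -> float:
        return float(self.connectivity["rho_cross"][cluster - 1])

    # -- (de)serialisation --------------------------------------------
    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "CohortConfig":
        raw = copy.deepcopy(raw)
        grid_raw = raw.pop("grid", {})
        grid = GridSpec(
            dimensions=tuple(grid_raw.get("dimensions", (24, 24, 12))),
            voxel_size_mm=float(grid_raw.get("voxel_size_mm", 2.0)),
            n_timepoints=int(grid_raw.get("n_timepoints", 200)),
            tr_seconds=float(grid_raw.get("tr_seconds", 2.0)),
        )
        known = {
            "n_enrolled",
            "n_complete",
            "cluster_sizes",
            "seed",
            "metabolic",
            "female_fraction",
            "age",
            "ethnicity",
            "cognitive",
            "motion",
            "connectivity",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(grid=grid, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "n_enrolled": self.n_enrolled,
            "n_complete": self.n_complete,
            "cluster_sizes": list(self.cluster_sizes),
            "seed": self.seed,
            "metabolic": copy.deepcopy(self.metabolic),
            "female_fraction": list(self.female_fraction),
            "age": dict(self.age),
            "ethnicity": copy.deepcopy(self.ethnicity),
            "cognitive": copy.deepcopy(self.cognitive),
            "motion": copy.deepcopy(self.motion),
            "connectivity": copy.deepcopy(self.connectivity),
            "grid": {
                "dimensions": list(self.grid.dimensions),
                "voxel_size_mm": self.grid.voxel_size_mm,
                "n_timepoints": self.grid.n_timepoints,
                "tr_seconds": self.grid.tr_seconds,
            },
        }
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **updates: Any) -> "CohortConfig":
        """Return a copy with top-level fields replaced."""
        raw = self.to_dict()
        raw.update(updates)
        return CohortConfig.from_dict(raw)


def default_config(seed: int | None = None) -> CohortConfig:
    """Load the shipped two-cluster default configuration."""
    text = resources.files("hippoclust").joinpath("table2_defaults.yaml").read_text()
    cfg = CohortConfig.from_dict(yaml.safe_load(text))
    if seed is not None:
        cfg = cfg.replace(seed=int(seed))
    return cfg
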