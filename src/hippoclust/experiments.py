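"""Repeated-cohort experiments used for validation and reporting.

These run the pipeline across many seeded synthetic cohorts and collect
the headline quantities: chosen cluster count, recovered cluster sizes,
metabolic means of the higher-deviance cluster, agreement with the
planted labels, and cohort-level category marginals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hippoclust.cohort import bmi_category, complete_cases, fpg_category, generate_cohort
from hippoclust.config import CohortConfig, default_config
from hippoclust.pipeline import synthetic_experiment


def derive_seed(base_seed: int, index: int) -> int:
    """Stable per-run seed below 2^31."""
    return int((base_seed * 1_000_003 + 7919 * index + 1) % (2**31))


def recovery_experiment(
    n_seeds: int = 100,
    base_seed: int = 0,
    config: CohortConfig | None = None,
    k_range: tuple[int, int] = (2, 8),
) -> pd.DataFrame:
    """Full pipeline on ``n_seeds`` synthetic cohorts; one row per seed.

    Columns: chosen_k, n1 (size of the higher-deviance cluster), SSPG and
    leptin means of that cluster, and the adjusted Rand index between
    recovered and planted labels.
    """
    base_cfg = config if config is not None else default_config()
    rows = []
    for i in range(n_seeds):
        cfg = base_cfg.replace(seed=derive_seed(base_seed, i))
        res = synthetic_experiment(
            cfg, k_range=k_range, compute_association=False, compare=False
        )
        s = res["summary"]
        rows.append(
            {
                "seed": cfg.seed,
                "chosen_k": s["chosen_k"],
                "n1": s["cluster_sizes"].get(1, 0),
                "sspg1": s.get("cluster1_SSPG_mean", np.nan),
                "leptin1": s.get("cluster1_leptin_mean", np.nan),
                "ari": s["ari_vs_latent"],
            }
        )
    return pd.DataFrame(rows)


def marginals_experiment(
    n_seeds: int = 100,
    base_seed: int = 0,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Cohort-level category marginals of the complete sample, per seed.

    Columns: pct_normal/pct_overweight/pct_obese (BMI categories) and
    pct_fpg_normal (fasting glucose < 100 mg/dL), in percent.
    """
    base_cfg = config if config is not None else default_config()
    rows = []
    for i in range(n_seeds):
        cfg = base_cfg.replace(seed=derive_seed(base_seed, i))
        complete = complete_cases(generate_cohort(cfg))
        cats = bmi_category(complete["BMI"].to_numpy())
        fpg = fpg_category(complete["FPG"].to_numpy())
        n = len(complete)
        rows.append(
            {
                "seed": cfg.seed,
                "n_complete": n,
                "pct_normal": 100.0 * (cats == "normal").mean(),
                "pct_overweight": 100.0 * (cats == "overweight").mean(),
                "pct_obese": 100.0 * (cats == "obese").mean(),
                "pct_fpg_normal": 100.0 * (fpg == "normal").mean(),
            }
        )
    return pd.DataFrame(rows)


def null_config(base: CohortConfig | None = None) -> CohortConfig:
    """A generator config with no planted separation at all: both latent
    clusters share metabolic parameters and connectivity effect sizes."""
    cfg = (base if base is not None else default_config()).to_dict()
    cfg["metabolic"]["cluster1"] = cfg["metabolic"]["cluster2"]
    rw = cfg["connectivity"]["rho_within"]
    rc = cfg["connectivity"]["rho_cross"]
    cfg["connectivity"]["rho_within"] = [rw[1], rw[1]]
    cfg["connectivity"]["rho_cross"] = [rc[1], rc[1]]
    cfg["female_fraction"] = [0.5, 0.5]
    return CohortConfig.from_dict(cfg)
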