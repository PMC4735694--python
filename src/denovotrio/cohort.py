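"""Trio-cohort covariate and count simulation.

`sample_ages` draws correlated parental ages at conception from a truncated
bivariate normal; `sample_counts` draws per-trio true DNM counts Poisson
around a linear (optionally maternal-quadratic) predictor.  Together they
reproduce the statistical structure the downstream regressions assume:
counts linear in both ages, highly correlated parental ages, and optional
covariates for conception mode, preterm status and sequencing batch.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import CohortConfig

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "trio_id",
    "father_age",
    "mother_age",
    "is_natural_conception",
    "is_preterm",
    "sex_of_proband",
    "batch_label",
    "fully_called_fraction",
    "gross_mapping_yield",
]


def sample_ages(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a trio-cohort covariate table (one row per trio).

    Ages are drawn jointly from a bivariate normal with the configured means,
    standard deviations and Pearson correlation, truncated by rejection to
    the configured bounds.  ART and preterm indicators, proband sex, batch
    labels and the two continuous sequencing-QC covariates are drawn
    independently.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    am = config.age_model
    n = config.n_trios

    cov = am.pearson_r * am.sd_father * am.sd_mother
    sigma = np.array([[am.sd_father**2, cov], [cov, am.sd_mother**2]])
    mean = np.array([am.mean_father, am.mean_mother])
    chol = np.linalg.cholesky(sigma)

    father = np.empty(n)
    mother = np.empty(n)
    filled = 0
    while filled < n:
        draw = mean + rng.standard_normal((2 * (n - filled) + 8, 2)) @ chol.T
        ok = (
            (draw[:, 0] >= am.bounds_father[0])
            & (draw[:, 0] <= am.bounds_father[1])
            & (draw[:, 1] >= am.bounds_mother[0])
            & (draw[:, 1] <= am.bounds_mother[1])
        )
        keep = draw[ok][: n - filled]
        father[filled : filled + len(keep)] = keep[:, 0]
        mother[filled : filled + len(keep)] = keep[:, 1]
        filled += len(keep)

    cm = config.count_model
    is_art = rng.random(n) < cm.art_fraction
    is_preterm = rng.random(n) < cm.preterm_fraction
    sex = np.where(rng.random(n) < 0.5, "M", "F")

    bm = config.batch
    probs = bm.version_probs
    if probs is None:
        probs = tuple(1.0 / len(bm.version_labels) for _ in bm.version_labels)
    batch = rng.choice(list(bm.version_labels), size=n, p=list(probs))
    fully_called = np.clip(rng.normal(0.95, 0.01, size=n), 0.85, 1.0)
    yield_gb = rng.normal(180.0, 10.0, size=n)

    return pd.DataFrame(
        {
            "trio_id": [f"T{i:04d}" for i in range(n)],
            "father_age": father,
            "mother_age": mother,
            "is_natural_conception": ~is_art,
            "is_preterm": is_preterm,
            "sex_of_proband": sex,
            "batch_label": batch,
            "fully_called_fraction": fully_called,
            "gross_mapping_yield": yield_gb,
        }
    )


def expected_counts(cohort: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    """Linear-predictor mean of true DNM counts per trio (floored at 0)."""
    cm = config.count_model
    mu = (
        cm.beta0
        + cm.beta_father * cohort["father_age"].to_numpy()
        + cm.beta_mother * cohort["mother_age"].to_numpy()
        + cm.maternal_quadratic
        * (cohort["mother_age"].to_numpy() - config.age_model.mean_mother) ** 2
        + cm.beta_art * (~cohort["is_natural_conception"].to_numpy(dtype=bool))
        + cm.beta_preterm * cohort["is_preterm"].to_numpy(dtype=bool)
    )
    if np.any(mu < 0):
        logger.warning("negative linear predictor for %d trios; clipped to 0", int((mu < 0).sum()))
        mu = np.clip(mu, 0.0, None)
    return mu


def sample_counts(
    cohort: pd.DataFrame, config: CohortConfig, seed: int | None = None
) -> pd.Series:
    """Per-trio true DNM counts, Poisson around the configured linear model."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    mu = expected_counts(cohort, config)
    counts = rng.poisson(mu)
    return pd.Series(counts, index=cohort["trio_id"].to_numpy(), name="n_dnm")
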