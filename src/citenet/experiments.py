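"""Reusable simulation experiments built on the generator and the models.

These functions drive the *whole* pipeline on generated networks — records
through matching, path enumeration, annotation and model fitting — so that
what they measure is the behaviour of the analysis as users run it, not of
any single stage in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .citation_matching import build_citation_edges
from .derived_metrics import annotate_paths, build_authority_table
from .path_builder import enumerate_paths
from .records_io import ArticleRecord
from .regression import ModelSpec, covariate_frame, fit_citation_model
from .synthetic_network import SyntheticConfig, generate_network, recovery_config


def pipeline_frame(records: Sequence[ArticleRecord]) -> pd.DataFrame:
    """Records -> annotated path covariate table (match, enumerate, annotate)."""
    edges = build_citation_edges(records)
    dataset = enumerate_paths(records, edges)
    authority = build_authority_table(records, edges)
    annotate_paths(dataset, records, authority)
    return covariate_frame(dataset, records)


@dataclass
class RecoveryResult:
    """Monte-Carlo parameter recovery for the planted self-citation effect."""

    true_log_or: float
    mean_log_or: float
    ci_coverage: float
    n_replicates: int
    n_converged: int
    mean_n_paths: float


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive *n* reproducible sub-seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def self_citation_recovery(
    seed: int,
    n_replicates: int = 200,
    random_intercept_sd: float = 0.0,
    log_or: float = math.log(5.0),
    estimator: str = "random-intercept",
    config_factory=recovery_config,
) -> RecoveryResult:
    """Estimate the planted self-citation log-OR over replicate networks.

    Each replicate generates a fresh network (~900 potential paths) with the
    stated effect and random-intercept SD, runs the full pipeline, fits the
    self-citation citation model, and records the estimate and whether the
    95% Wald interval covers the truth.
    """
    estimates, covered, n_paths = [], 0, []
    for rep_seed in child_seeds(seed, n_replicates):
        config: SyntheticConfig = config_factory(
            seed=rep_seed, random_intercept_sd=random_intercept_sd, log_or=log_or
        )
        records, _, _ = generate_network(config)
        frame = pipeline_frame(records)
        result = fit_citation_model(
            frame, ModelSpec(determinant="self_citation", estimator=estimator)
        )
        if not result.converged:
            continue
        effect = result.effect()
        estimates.append(effect.coef)
        covered += effect.ci_low <= math.exp(log_or) <= effect.ci_high
        n_paths.append(result.n_paths)
    n_ok = len(estimates)
    return RecoveryResult(
        true_log_or=log_or,
        mean_log_or=float(np.mean(estimates)) if n_ok else float("nan"),
        ci_coverage=covered / n_ok if n_ok else float("nan"),
        n_replicates=n_replicates,
        n_converged=n_ok,
        mean_n_paths=float(np.mean(n_paths)) if n_ok else float("nan"),
    )
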