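"""Baseline-choice diagnostics: dependent-correlation comparison.

In a parallel-arm weight-loss-maintenance trial, TEE is measured before
weight loss, after weight loss (just before randomization), and during
maintenance.  Which baseline better predicts the maintenance outcome is an
empirical question answered by comparing two correlations that share the
outcome variable — a dependent-correlation problem, tested here with the
Meng–Rosenthal–Rubin Z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import followup_tee

__all__ = [
    "CorrelationComparison",
    "pearson_r",
    "mengs_z",
    "baseline_comparison",
]


@dataclass(frozen=True)
class CorrelationComparison:
    """Result of comparing pre- vs post-weight-loss baselines.

    ``r_post``/``r_pre`` are the correlations of each baseline with the
    follow-up outcome, ``r_baselines`` the correlation between the two
    baselines, ``z`` Meng's statistic for r_post vs r_pre (positive when
    the post-weight-loss baseline correlates more strongly).
    """

    r_pre: float
    r_post: float
    r_baselines: float
    n: int
    z: float
    p_two_sided: float


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation.

    Requires equal lengths >= 3 and nonzero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, have {len(x)}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined for a zero-variance variable")
    return float(stats.pearsonr(x, y).statistic)


def mengs_z(r1: float, r2: float, rxx: float, n: int) -> tuple[float, float]:
    """Meng–Rosenthal–Rubin Z-test for two dependent correlations.

    ``r1`` and ``r2`` are the correlations of two predictors with a shared
    outcome, ``rxx`` the correlation between the predictors, ``n`` the
    sample size.  With z1, z2 the Fisher transforms,

        rbar2 = (r1^2 + r2^2) / 2
        f     = min(1, (1 - rxx) / (2 (1 - rbar2)))   (capped at 1)
        h     = (1 - f rbar2) / (1 - rbar2)
        Z     = (z1 - z2) sqrt((n - 3) / (2 (1 - rxx) h))

    with a two-sided normal p-value.  Z = 0 exactly when r1 = r2, and Z is
    antisymmetric in (r1, r2).
    """
    if n < 4:
        raise ValueError(f"need n >= 4, have {n}")
    for name, r in (("r1", r1), ("r2", r2)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} = {r!r} outside (-1, 1); Fisher transform diverges")
    if not -1.0 <= rxx <= 1.0:
        raise ValueError(f"rxx = {rxx!r} outside [-1, 1]")
    if r1 == r2:
        return 0.0, 1.0
    if rxx >= 1.0:
        raise ValueError("rxx = 1 with r1 != r2 leaves the statistic undefined")
    z1 = math.atanh(r1)
    z2 = math.atanh(r2)
    rbar2 = (r1 * r1 + r2 * r2) / 2.0
    f = min(1.0, (1.0 - rxx) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - rxx) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def baseline_comparison(
    cohort: pd.DataFrame, outcome: Sequence[float] | None = None
) -> CorrelationComparison:
    """Compare pre- vs post-weight-loss baseline TEE as outcome predictors.

    ``outcome`` defaults to the mean of the 10- and 20-week follow-up TEE.
    The comparison is invariant to linear rescaling of the TEE unit.  A
    degenerate cohort whose pre and post columns are identical yields
    z = 0.
    """
    if outcome is None:
        outcome = followup_tee(cohort)
    outcome = np.asarray(outcome, dtype=float)
    pre = cohort["tee_pre"].to_numpy(float)
    post = cohort["tee_post"].to_numpy(float)
    r_pre = pearson_r(pre, outcome)
    r_post = pearson_r(post, outcome)
    r_baselines = pearson_r(pre, post)
    z, p = mengs_z(r_post, r_pre, r_baselines, len(outcome))
    return CorrelationComparison(
        r_pre=r_pre,
        r_post=r_post,
        r_baselines=r_baselines,
        n=len(outcome),
        z=z,
        p_two_sided=p,
    )
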