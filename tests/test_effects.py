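"""Adjusted effect estimation, tertiles, and odds ratios."""

import numpy as np
import pandas as pd
import pytest

from dlwsens import (
    SimConfig,
    adjusted_diet_effect,
    odds_ratio_ci,
    simulate_cohort,
    tertile_effect_report,
    tertile_split,
)
from dlwsens.effects import EstimationError


def test_no_covariates_equals_difference_of_means(hand_cohort):
    est = adjusted_diet_effect(hand_cohort, covariates=())
    means = hand_cohort.groupby("arm")[["tee_wk10"]].mean()["tee_wk10"]
    assert est.contrast == pytest.approx(means["low"] - means["high"], abs=1e-10)
    assert est.ci_low <= est.contrast <= est.ci_high


def test_contrast_matches_normal_equations_oracle(hand_cohort):
    """Hand-solved least squares on a 6-row fixture with a binary covariate."""
    y = hand_cohort["tee_wk10"].to_numpy()
    X = np.column_stack(
        [
            np.ones(6),
            (hand_cohort["arm"] == "low").to_numpy(float),
            (hand_cohort["cohort"] == 2).to_numpy(float),
        ]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (6 - 3)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    est = adjusted_diet_effect(hand_cohort, covariates=("cohort",))
    assert est.contrast == pytest.approx(beta[1], abs=1e-8)
    assert est.se == pytest.approx(se, abs=1e-8)


def test_parameter_recovery_over_seeds():
    """Mean estimate across seeded cohorts sits near the 280 kcal/day truth."""
    estimates = [
        adjusted_diet_effect(
            simulate_cohort(SimConfig(), seed=s), covariates=("cohort", "tee_post")
        ).contrast
        for s in range(40)
    ]
    assert np.mean(estimates) == pytest.approx(280.0, abs=25.0)


def test_affine_covariate_rescaling_invariance(pp_cohort):
    base = adjusted_diet_effect(pp_cohort, covariates=("cohort", "age", "tee_post"))
    rescaled = pp_cohort.assign(age=pp_cohort["age"] * 3.0 + 7.0)
    est = adjusted_diet_effect(rescaled, covariates=("cohort", "age", "tee_post"))
    assert est.contrast == pytest.approx(base.contrast, abs=1e-8)


def test_uncorrelated_covariate_barely_moves_contrast(pp_cohort):
    """A noise covariate changes the contrast by less than its SE."""
    base = adjusted_diet_effect(pp_cohort, covariates=("cohort", "tee_post"))
    rng = np.random.default_rng(3)
    noisy = pp_cohort.assign(junk=rng.normal(size=len(pp_cohort)))
    est = adjusted_diet_effect(noisy, covariates=("cohort", "tee_post", "junk"))
    assert abs(est.contrast - base.contrast) < base.se


def test_estimation_errors(pp_cohort):
    with pytest.raises(EstimationError, match="at least 2"):
        adjusted_diet_effect(pp_cohort[pp_cohort["arm"] == "low"])
    doubled = pp_cohort.assign(age2=pp_cohort["age"] * 2.0)
    with pytest.raises(EstimationError, match="age2"):
        adjusted_diet_effect(doubled, covariates=("age", "age2"))
    with pytest.raises(EstimationError, match="not present"):
        adjusted_diet_effect(pp_cohort, covariates=("bmi",))


def _frame(n):
    return pd.DataFrame({"id": [f"P{i}" for i in range(n)]})


def test_tertile_split_sizes_and_order():
    ratios = [0.9, 0.5, 1.3, 0.7, 1.1, 0.6, 1.0, 0.8, 1.2]
    tert = tertile_split(_frame(9), ratios)
    assert [int(t) for t in tert] == [2, 1, 3, 1, 3, 1, 2, 2, 3]
    tert10 = tertile_split(_frame(10), np.arange(10) / 10.0)
    assert [np.sum(tert10 == t) for t in (1, 2, 3)] == [4, 3, 3]


def test_tertile_split_ties_and_partition():
    tert = tertile_split(_frame(9), np.ones(9))
    assert [int(t) for t in tert] == [1, 1, 1, 2, 2, 2, 3, 3, 3]  # stable id order
    assert np.isin(tert, (1, 2, 3)).all()
    with pytest.raises(ValueError):
        tertile_split(_frame(2), [1.0, 2.0])


def test_odds_ratio_ci():
    or_, lo, hi, p = odds_ratio_ci((10, 10, 10, 10))
    assert or_ == pytest.approx(1.0)
    assert np.log(lo) == pytest.approx(-np.log(hi), abs=1e-12)  # symmetric on log scale
    assert p == pytest.approx(1.0)

    or4, lo4, hi4, _ = odds_ratio_ci((10, 5, 5, 10))
    half = 1.96 * np.sqrt(1 / 10 + 1 / 5 + 1 / 5 + 1 / 10)
    assert or4 == pytest.approx(4.0)
    assert lo4 == pytest.approx(np.exp(np.log(4) - half), abs=1e-3)
    assert hi4 == pytest.approx(np.exp(np.log(4) + half), abs=2e-2)

    # Haldane-Anscombe correction with a zero cell
    assert odds_ratio_ci((5, 0, 5, 5))[0] == pytest.approx(11.0)
    with pytest.raises(ValueError, match="margin"):
        odds_ratio_ci((0, 0, 5, 5))
    with pytest.raises(ValueError):
        odds_ratio_ci((-1, 2, 3, 4))


def test_tertile_report_structure(pp_cohort):
    report = tertile_effect_report(pp_cohort)
    sizes = [np.sum(report.assignments == t) for t in (1, 2, 3)]
    assert sum(sizes) == len(pp_cohort) and max(sizes) - min(sizes) <= 1
    assert report.odds_ratio > 0
    for t in (1, 2, 3):
        if report.adjusted[t] is not None:
            assert report.adjusted[t].se > 0


def test_tertile_report_flags_missing_arm():
    """A tertile holding only one arm gets a missing effect, not an error."""
    tee = np.linspace(2600.0, 3150.0, 12)
    frame = pd.DataFrame(
        {
            "id": [f"P{i:02d}" for i in range(12)],
            "arm": ["low"] * 4 + ["low", "low", "high", "high"] * 2,
            "cohort": 1,
            "tee_post": tee,
            "tee_wk10": tee,
            "tee_wk20": tee,
            # lowest four ratios are the four leading low-arm rows
            "intake_reported": np.r_[tee[:4] * 0.5, tee[4:]],
        }
    )
    report = tertile_effect_report(frame, covariates=())
    assert report.unadjusted[1] is None and report.adjusted[1] is None
    assert report.unadjusted[2] is not None and report.unadjusted[3] is not None
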