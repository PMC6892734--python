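"""The synthetic-cohort generator and cohort CSV round trip."""

import numpy as np
import pandas as pd
import pytest

from dlwsens import (
    COHORT_COLUMNS,
    SchemaError,
    SimConfig,
    adjusted_diet_effect,
    read_cohort,
    simulate_cohort,
    weir_factor,
    write_cohort,
)
from dlwsens.sensitivity import fq_under_nonadherence


def test_determinism_and_seed_sensitivity():
    a = simulate_cohort(SimConfig(), seed=42)
    b = simulate_cohort(SimConfig(), seed=42)
    pd.testing.assert_frame_equal(a, b)
    c = simulate_cohort(SimConfig(), seed=43)
    assert not a["tee_wk10"].equals(c["tee_wk10"])


def test_schema_and_arm_balance(cohort):
    assert list(cohort.columns) == COHORT_COLUMNS
    counts = cohort["arm"].value_counts()
    assert set(counts.index) == {"low", "moderate", "high"}
    assert counts.max() - counts.min() <= 1
    assert (cohort[["tee_pre", "tee_post", "tee_wk10", "tee_wk20", "rco2"]] > 0).all().all()


def test_csv_round_trip(tmp_path, cohort):
    path = tmp_path / "cohort.csv"
    write_cohort(cohort, path)
    back = read_cohort(path)
    assert list(back.columns) == COHORT_COLUMNS
    pd.testing.assert_frame_equal(back, cohort, atol=1e-6, rtol=0.0)


def test_read_cohort_schema_errors(tmp_path, cohort):
    path = tmp_path / "bad.csv"
    cohort.drop(columns=["tee_post"]).to_csv(path, index=False)
    with pytest.raises(SchemaError, match="tee_post"):
        read_cohort(path)
    cohort.assign(extra=1.0).to_csv(path, index=False)
    with pytest.raises(SchemaError, match="extra"):
        read_cohort(path)


def test_read_cohort_empty_file_is_valid(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text(",".join(COHORT_COLUMNS) + "\n")
    empty = read_cohort(path)
    assert len(empty) == 0 and list(empty.columns) == COHORT_COLUMNS


def test_energy_conservation_before_reporting_noise():
    """True intake minus true TEE minus stored-energy rate is exactly zero."""
    _, latent = simulate_cohort(SimConfig(), seed=5, return_latent=True)
    gap = latent["intake_true"] - latent["tee_fup_true"] - latent["stored_rate"]
    assert np.allclose(gap, 0.0, atol=1e-9)


def test_rco2_consistent_with_weir_factor():
    """Measured TEE is exactly rCO2 times the assigned arm's Weir factor,
    and in the noise-free limit rCO2 recovers true TEE via FQ(arm, p)."""
    cfg = SimConfig(nonadherence_mean=0.2, nonadherence_sd=0.1)
    cohort, latent = simulate_cohort(cfg, seed=9, return_latent=True)
    fq0 = cohort["arm"].map(lambda a: fq_under_nonadherence(a, 0.0)).to_numpy()
    measured = (cohort["tee_wk10"] + cohort["tee_wk20"]) / 2
    assert np.allclose(measured, cohort["rco2"] * weir_factor(fq0), atol=1e-9)

    quiet, quiet_latent = simulate_cohort(
        cfg.with_(tee_noise_sd=0.0), seed=9, return_latent=True
    )
    w_actual = weir_factor(quiet_latent["rq_actual"].to_numpy())
    assert np.allclose(
        quiet["rco2"] * w_actual, quiet_latent["tee_fup_true"], atol=1e-6
    )


def test_noise_free_cohort_recovers_exact_effect():
    """With every noise source off, the adjusted contrast is exactly 280."""
    cfg = SimConfig(between_person_sd=0.0, tee_noise_sd=0.0)
    cohort = simulate_cohort(cfg, seed=2)
    est = adjusted_diet_effect(cohort, covariates=("cohort", "tee_post"))
    assert est.contrast == pytest.approx(280.0, abs=1e-6)


def test_arm_means_encode_effect_gradient():
    """True TEE means order low > moderate > high with the right gaps."""
    gaps_lh, gaps_lm = [], []
    for seed in range(10):
        cohort, latent = simulate_cohort(SimConfig(n=300), seed=seed, return_latent=True)
        means = latent.groupby(cohort["arm"])["tee_fup_true"].mean()
        gaps_lh.append(means["low"] - means["high"])
        gaps_lm.append(means["low"] - means["moderate"])
    assert np.mean(gaps_lh) == pytest.approx(280.0, abs=3 * 350 * np.sqrt(2 / 100 / 10))
    assert np.mean(gaps_lm) == pytest.approx(140.0, abs=3 * 350 * np.sqrt(2 / 100 / 10))


def test_post_baseline_couples_more_strongly_than_pre():
    wins = 0
    for seed in range(20):
        cohort = simulate_cohort(SimConfig(), seed=seed)
        fup = (cohort["tee_wk10"] + cohort["tee_wk20"]) / 2
        wins += np.corrcoef(cohort["tee_post"], fup)[0, 1] > np.corrcoef(
            cohort["tee_pre"], fup
        )[0, 1]
    assert wins >= 18


def test_per_protocol_flag_matches_weight_stability():
    cfg = SimConfig()
    cohort, latent = simulate_cohort(cfg, seed=3, return_latent=True)
    expected = latent["stored_rate"].abs() <= cfg.weight_stability_bound
    assert (cohort["per_protocol"] == expected).all()


def test_sensitivity_correction_recovers_true_effect_under_nonadherence():
    """Real nonadherence both attenuates the true effect and biases the
    measured TEE through the wrong-FQ assumption; re-expressing TEE at the
    true nonadherence fraction undoes the measurement bias exactly."""
    from dlwsens import sensitivity_table

    cfg = SimConfig(
        nonadherence_mean=0.5, between_person_sd=0.0, tee_noise_sd=0.0
    )
    cohort = simulate_cohort(cfg, seed=4)
    table = sensitivity_table(cohort, grid=(0.0, 0.5))
    # p = 0 row: biased upward (true contrast is 140, FQ bias adds ~155)
    assert table.loc[0, "effect_kcal"] > 250.0
    # correcting at the true p recovers the attenuated true effect exactly
    assert table.loc[1, "effect_kcal"] == pytest.approx(140.0, abs=1e-6)
    cohort = simulate_cohort(SimConfig(nonadherence_mean=0.9, nonadherence_sd=0.3), seed=0)
    assert cohort["p_nonadherence"].between(0.0, 1.0).all()


def test_config_validation():
    with pytest.raises(ValueError, match="positive definite"):
        SimConfig(coupling_pre=-0.9, coupling_post=0.9, pre_post_corr=0.9)
    with pytest.raises(ValueError):
        SimConfig(n=3)
    with pytest.raises(ValueError):
        SimConfig(coupling_post=1.5)
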